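"""Batched synthetic expression data with planted mediation structure.

The generator emulates the shape of a merged multi-series microarray dataset:
several batches of independent samples, background genes i.i.d. standard
normal, and *planted triplets* (X, Y, Z) in which Z ~ N(0, 1) and, given Z,
(X, Y) are bivariate normal with zero means, unit variances and correlation
c(Z) that depends monotonically on Z.  For this generative family the
population liquid-association value of a planted triplet has the closed form

    E[X Y Z] = E[Z * c(Z)],

evaluated here by Gauss–Hermite quadrature; every background triple has
expected value 0.  This analytic truth is what makes genome-wide scouting
testable without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import ExpressionDataset

__all__ = [
    "MediationFn",
    "SyntheticSpec",
    "TruthTable",
    "generate_dataset",
    "expected_la",
    "recovery_experiment",
]

#: Default batch sizes mirroring a three-series merge of 20 + 60 + 8 conditions.
DEFAULT_BATCH_SIZES = (20, 60, 8)


@dataclass(frozen=True)
class MediationFn:
    """A mediation curve c(z): the conditional (X, Y) correlation as a function of Z.

    Families: ``tanh`` — c(z) = rho_max * tanh(kappa * z); ``linear_clipped``
    — c(z) = rho_max * clip(kappa * z, -1, 1); ``constant`` — c(z) = rho_max.
    ``|rho_max| < 1`` keeps the conditional correlation valid everywhere.
    """

    family: str = "tanh"
    rho_max: float = 0.9
    kappa: float = 1.0

    def __post_init__(self):
        if self.family not in ("tanh", "linear_clipped", "constant"):
            raise ValueError(f"unknown mediation family {self.family!r}")
        if not -1.0 < self.rho_max < 1.0:
            raise ValueError("rho_max must lie in (-1, 1)")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        if self.family == "tanh":
            return self.rho_max * np.tanh(self.kappa * z)
        if self.family == "linear_clipped":
            return self.rho_max * np.clip(self.kappa * z, -1.0, 1.0)
        return np.full_like(z, self.rho_max)


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = 200
    batch_sizes: tuple[int, ...] = DEFAULT_BATCH_SIZES
    planted_triplets: tuple[tuple[int, int, int, MediationFn], ...] = ()
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if any(b < 2 for b in self.batch_sizes):
            raise ValueError("every batch needs >= 2 samples")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        used: set[int] = set()
        for (xi, yi, zi, m) in self.planted_triplets:
            trio = {xi, yi, zi}
            if len(trio) != 3 or not all(0 <= i < self.n_genes for i in trio):
                raise ValueError(f"planted indices {(xi, yi, zi)} invalid")
            if trio & used:
                raise ValueError(f"gene reused across planted triplets: {trio & used}")
            used |= trio
            if not isinstance(m, MediationFn):
                raise ValueError("mediation must be a MediationFn")


@dataclass(frozen=True)
class TruthTable:
    """Analytic expected LA per planted triplet (background triples expect 0)."""

    planted: tuple[tuple[int, int, int], ...]
    expected: tuple[float, ...]

    def expected_for(self, triplet: tuple[int, int, int]) -> float:
        for t, e in zip(self.planted, self.expected):
            if set(t) == set(triplet):
                return e
        return 0.0


def expected_la(m: MediationFn, n_nodes: int = 128) -> float:
    """E[Z * c(Z)] for Z ~ N(0, 1), by Gauss-Hermite quadrature.

    The change of variables z = sqrt(2) t turns the physicists' Hermite rule
    into an expectation under the standard normal.
    """
    t, w = np.polynomial.hermite.hermgauss(n_nodes)
    z = np.sqrt(2.0) * t
    return float(np.sum(w * z * m(z)) / np.sqrt(np.pi))


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, TruthTable]:
    """Draw one dataset from the generative model described by ``spec``.

    Gene ids are ``G0000..``; batch labels ``B1, B2, ...`` with the requested
    sizes; missing entries are masked uniformly at random at
    ``spec.missing_rate``.  Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(np.sum(spec.batch_sizes))
    values = rng.standard_normal((spec.n_genes, n))

    planted_keys = []
    expected = []
    for (xi, yi, zi, m) in spec.planted_triplets:
        z = rng.standard_normal(n)
        c = m(z)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        values[zi] = z
        values[xi] = a
        values[yi] = c * a + np.sqrt(1.0 - c**2) * b
        planted_keys.append((xi, yi, zi))
        expected.append(expected_la(m))

    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values[mask] = np.nan

    width = max(4, len(str(spec.n_genes - 1)))
    gene_ids = [f"G{i:0{width}d}" for i in range(spec.n_genes)]
    sample_ids = []
    batch_labels = []
    for bi, size in enumerate(spec.batch_sizes, start=1):
        for s in range(size):
            sample_ids.append(f"B{bi}S{s:03d}")
            batch_labels.append(f"B{bi}")

    ds = ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        batch_labels=batch_labels,
        values=values,
        name=f"synthetic_seed{spec.seed}",
    )
    return ds, TruthTable(planted=tuple(planted_keys), expected=tuple(expected))


def recovery_experiment(
    spec: SyntheticSpec,
    n_replicates: int,
    seed: int = 0,
) -> dict:
    """Replicate generation + transform + scouting; summarize planted-Z recovery.

    For each replicate (seeded from ``seed``) the dataset is regenerated,
    normal-scored per batch, and :func:`~lascout.la_core.scout_z` is run on
    each planted lead pair; the planted mediator's positive-end place and the
    error of its LA score against the analytic expectation are recorded.

    Returns a dict with per-replicate places and score errors plus summary
    statistics (fraction at place 1, mean/quantiles of places and errors).
    """
    from .la_core import scout_z
    from .preprocess import transform_dataset

    if not spec.planted_triplets:
        raise ValueError("spec must plant at least one triplet")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s) % (2**31) for s in ss.generate_state(n_replicates)]
    places: list[int] = []
    errors: list[float] = []
    for rs in rep_seeds:
        rep_spec = SyntheticSpec(
            n_genes=spec.n_genes,
            batch_sizes=spec.batch_sizes,
            planted_triplets=spec.planted_triplets,
            missing_rate=spec.missing_rate,
            seed=rs,
        )
        ds, truth = generate_dataset(rep_spec)
        tds = transform_dataset(ds)
        for (xi, yi, zi), exp_la in zip(truth.planted, truth.expected):
            x_id, y_id, z_id = ds.gene_ids[xi], ds.gene_ids[yi], ds.gene_ids[zi]
            table = scout_z(x_id, y_id, tds, top_k=tds.n_genes)
            place = table.place_of(z_id, end="top")
            score = next(e.la_score for e in table.top_list if e.ids[0] == z_id)
            places.append(place if place is not None else table.candidate_count)
            errors.append(score - exp_la)

    places_arr = np.asarray(places)
    errors_arr = np.asarray(errors)
    return {
        "places": places,
        "score_errors": errors,
        "frac_place1": float(np.mean(places_arr == 1)),
        "mean_place": float(places_arr.mean()),
        "place_quantiles": {
            q: float(np.quantile(places_arr, q)) for q in (0.5, 0.9)
        },
        "mean_error": float(errors_arr.mean()),
        "mean_abs_error": float(np.abs(errors_arr).mean()),
    }
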