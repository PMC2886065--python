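"""Significance machinery for liquid-association scores.

Two p-value routes are implemented:

* **Permutation** (default): the mediator profile Z is shuffled across
  samples — within each batch when ``scope="within_batch"``, respecting the
  per-series transform — and the score recomputed B times.  The p-value uses
  the add-one convention p = (1 + #extreme) / (B + 1), so it is never zero
  and never below 1/(B+1).
* **Asymptotic**: on normal-scored profiles the statistic is a mean of n
  bounded products with unit null variance per term, so sqrt(n) * LA is
  compared against a standard normal tail.

The null-pool experiment estimates how often a target gene would emerge as
the place-1 positive scouting gene for a *random* lead pair drawn from a
user-supplied pool, giving an empirical chance-detection rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .data_model import ExpressionDataset
from .la_core import MIN_TRIPLES, la_score, scout_z

__all__ = [
    "PValueConfig",
    "PValueResult",
    "NullPoolResult",
    "permutation_pvalue",
    "asymptotic_pvalue",
    "pvalue_for_triple",
    "null_pool_experiment",
]


@dataclass(frozen=True)
class PValueConfig:
    method: str = "permutation"         # or "asymptotic"
    B: int = 10_000
    seed: int = 0
    scope: str = "within_batch"         # or "global"
    sidedness: str = "one_sided_signed"  # or "two_sided"


@dataclass(frozen=True)
class PValueResult:
    method: str
    sidedness: str
    B: int
    p: float
    observed: float


@dataclass(frozen=True)
class NullPoolResult:
    pool_ids: tuple[str, ...]
    n_pairs: int
    seed: int
    counts: dict[str, int]
    sampled_pairs: list[tuple[str, str]]
    leader_by_pair: list[str]


def _perm_scores(x, y, z, B, rng, batch_labels=None):
    """B permutation replicates of the LA score, shuffling z (within batch if given)."""
    n = x.size
    # permute z over ALL sample positions (so missingness travels with z),
    # then score on whatever triples are complete per replicate; permutations
    # are generated in bulk as argsorts of uniform draws
    if batch_labels is None:
        perms = np.argsort(rng.random((B, n)), axis=1)
    else:
        lab = np.asarray(batch_labels)
        perms = np.empty((B, n), dtype=np.intp)
        for bl in np.unique(lab):
            cols = np.flatnonzero(lab == bl)
            perms[:, cols] = cols[np.argsort(rng.random((B, cols.size)), axis=1)]
    zp = z[perms]                       # (B, n)
    xy = np.where(np.isnan(x) | np.isnan(y), np.nan, x * y)
    prod = zp * xy                      # NaN propagates
    ok = ~np.isnan(prod)
    n_used = ok.sum(axis=1)
    sums = np.where(ok, prod, 0.0).sum(axis=1)
    valid = n_used >= MIN_TRIPLES
    return sums[valid] / n_used[valid]


def permutation_pvalue(
    x,
    y,
    z,
    B: int = 10_000,
    seed: int = 0,
    scope: str = "global",
    sidedness: str = "one_sided_signed",
    batch_labels: Sequence[str] | None = None,
) -> PValueResult:
    """Permutation p-value for LA(X, Y | Z), shuffling Z across samples.

    ``scope="within_batch"`` (requires ``batch_labels``) permutes sample
    positions only inside each batch.  ``one_sided_signed`` asks how often a
    permuted score is at least as extreme *in the observed direction*;
    ``two_sided`` compares absolute values.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if scope not in ("global", "within_batch"):
        raise ValueError(f"unknown scope {scope!r}")
    if sidedness not in ("one_sided_signed", "two_sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if scope == "within_batch" and batch_labels is None:
        raise ValueError("within_batch scope needs batch_labels")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    observed = la_score(x, y, z).la_score
    rng = np.random.default_rng(seed)
    null = _perm_scores(x, y, z, B, rng, batch_labels if scope == "within_batch" else None)
    if sidedness == "two_sided":
        extreme = int(np.sum(np.abs(null) >= abs(observed)))
    elif observed >= 0:
        extreme = int(np.sum(null >= observed))
    else:
        extreme = int(np.sum(null <= observed))
    p = (1 + extreme) / (B + 1)
    return PValueResult("permutation", sidedness, B, p, observed)


def asymptotic_pvalue(observed: float, n_used: int, sidedness: str = "one_sided_signed") -> PValueResult:
    """Normal-approximation p-value: sqrt(n) * LA against a standard-normal tail."""
    if n_used < 10:
        raise ValueError("asymptotic approximation needs n_used >= 10")
    if sidedness not in ("one_sided_signed", "two_sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    stat = np.sqrt(n_used) * abs(observed)
    tail = float(norm.sf(stat))
    p = min(1.0, 2 * tail) if sidedness == "two_sided" else (
        tail if observed != 0 else 0.5
    )
    return PValueResult("asymptotic", sidedness, 0, p, float(observed))


def pvalue_for_triple(
    ds: ExpressionDataset,
    x_id: str,
    y_id: str,
    z_id: str,
    observed: float | None = None,
    cfg: PValueConfig | None = None,
) -> PValueResult:
    """Dispatch to the configured p-value method for one dataset triple."""
    cfg = cfg or PValueConfig()
    x, y, z = ds.profile(x_id), ds.profile(y_id), ds.profile(z_id)
    if cfg.method == "permutation":
        return permutation_pvalue(
            x, y, z,
            B=cfg.B,
            seed=cfg.seed,
            scope=cfg.scope,
            sidedness=cfg.sidedness,
            batch_labels=ds.batch_labels if cfg.scope == "within_batch" else None,
        )
    if cfg.method == "asymptotic":
        res = la_score(x, y, z)
        obs = observed if observed is not None else res.la_score
        return asymptotic_pvalue(obs, res.n_used, sidedness=cfg.sidedness)
    raise ValueError(f"unknown p-value method {cfg.method!r}")


def null_pool_experiment(
    ds: ExpressionDataset,
    pool_ids: Iterable[str],
    target_ids: Iterable[str],
    n_pairs: int,
    seed: int = 0,
    end: str = "top",
) -> NullPoolResult:
    """Chance-detection rate of target genes as the leading mediator.

    Draws ``n_pairs`` distinct unordered lead pairs uniformly without
    replacement from ``pool_ids``, runs :func:`scout_z` for each over ALL
    candidate genes of the dataset, and counts how often each target gene is
    the place-1 gene of the positive end (``end="top"``; ``"either"`` also
    accepts the negative end's place 1).  count / n_pairs estimates the
    probability that the target would lead a random pair's ranking by chance.
    """
    pool = sorted(dict.fromkeys(pool_ids))
    targets = list(dict.fromkeys(target_ids))
    known = set(ds.gene_ids)
    bad = [g for g in list(pool) + targets if g not in known]
    if bad:
        raise ValueError(f"gene(s) absent from dataset: {bad}")
    if len(pool) < 2:
        raise ValueError("pool needs >= 2 genes")
    if end not in ("top", "either"):
        raise ValueError(f"unknown end {end!r}")
    n_avail = len(pool) * (len(pool) - 1) // 2
    if n_pairs > n_avail:
        raise ValueError(f"n_pairs={n_pairs} exceeds {n_avail} distinct pool pairs")

    rng = np.random.default_rng(seed)
    # sample distinct unordered pairs without replacement via linear pair indices
    flat = rng.choice(n_avail, size=n_pairs, replace=False)
    iu, ju = np.triu_indices(len(pool), k=1)
    pairs = [(pool[iu[f]], pool[ju[f]]) for f in flat]

    counts = {t: 0 for t in targets}
    leaders: list[str] = []
    for x_id, y_id in pairs:
        table = scout_z(x_id, y_id, ds, top_k=1)
        lead_genes = {table.top_list[0].ids[0]} if table.top_list else set()
        if end == "either" and table.bot_list:
            lead_genes.add(table.bot_list[0].ids[0])
        leaders.append(table.top_list[0].ids[0] if table.top_list else "")
        for t in targets:
            if t in lead_genes:
                counts[t] += 1
    return NullPoolResult(
        pool_ids=tuple(pool),
        n_pairs=n_pairs,
        seed=seed,
        counts=counts,
        sampled_pairs=pairs,
        leader_by_pair=leaders,
    )
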