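"""The liquid-association statistic and the genome-wide search modes.

Liquid association (LA) measures how a third gene Z mediates the correlation
between a gene pair (X, Y).  On normal-scored profiles it is the mean of the
elementwise triple products:

    LA(X, Y | Z) = (1/n) * sum_i  x_i * y_i * z_i

A large positive score means high Z accompanies stronger positive (X, Y)
correlation (Z is a *positive LA-scouting gene* for the pair); a large
negative score means the reverse.  The statistic is fully symmetric in its
three arguments.

Three search modes are provided:

* :func:`scout_z` — fix a lead pair (X, Y), rank every other gene as Z;
* :func:`search_pairs` — fix a single lead X, rank every unordered gene pair
  (Y, Z), vectorized as a weighted cross-product of the gene matrix;
* :func:`lead_set_report` — run :func:`scout_z` for every pair in a lead gene
  set and assemble a report with subgroup correlations and p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .data_model import ExpressionDataset

__all__ = [
    "LAResult",
    "ScoutTable",
    "PairSearchTable",
    "LeadSetReport",
    "la_score",
    "scout_z",
    "search_pairs",
    "lead_set_report",
]

MIN_TRIPLES = 3


@dataclass(frozen=True)
class LAResult:
    x_id: str
    y_id: str
    z_id: str
    la_score: float
    n_used: int


@dataclass(frozen=True)
class RankedEntry:
    """One row of a signed ranking: the candidate, its score and 1-based place."""

    ids: tuple[str, ...]
    la_score: float
    place: int


@dataclass
class ScoutTable:
    """Signed ranking of candidate mediator genes Z for a lead pair (X, Y).

    ``top_list`` holds the positive LA-scouting genes (scores descending),
    ``bot_list`` the negative ones (scores ascending); places run 1..k within
    each end.
    """

    x_id: str
    y_id: str
    top_list: list[RankedEntry]
    bot_list: list[RankedEntry]
    candidate_count: int

    def place_of(self, z_id: str, end: str = "top") -> int | None:
        for e in self.top_list if end == "top" else self.bot_list:
            if e.ids[0] == z_id:
                return e.place
        return None


@dataclass
class PairSearchTable:
    """Signed ranking of unordered (Y, Z) pairs for a single lead gene X."""

    x_id: str
    top_list: list[RankedEntry]
    bot_list: list[RankedEntry]
    candidate_count: int


@dataclass(frozen=True)
class ReportRow:
    x_id: str
    y_id: str
    z_id: str
    la_score: float
    corr_high: float
    corr_low: float
    p_value: float
    place: int


@dataclass
class LeadSetReport:
    """Rows of (X, Y, Z, LA score, corr-high, corr-low, p, place), one block per lead pair."""

    rows: list[ReportRow]

    def shared_top_z(self) -> dict[str, int]:
        """How many lead pairs have each Z in their reported positive list."""
        counts: dict[str, int] = {}
        for r in self.rows:
            counts[r.z_id] = counts.get(r.z_id, 0) + 1
        return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


# ---------------------------------------------------------------------------

def _as_profile(ds_or_profile, gene_id=None):
    if gene_id is None:
        return np.asarray(ds_or_profile, dtype=float)
    return ds_or_profile.profile(gene_id)


def la_score(x, y, z, denominator_policy: str = "complete_triples") -> LAResult:
    """Mean elementwise triple product of three equal-length profiles.

    Missing (NaN) entries remove the whole sample triple.  The default
    denominator is the number of complete triples, keeping the statistic a
    mean; ``denominator_policy="total_n"`` divides by the full profile length
    instead (the convention used when no values are missing).
    """
    if denominator_policy not in ("complete_triples", "total_n"):
        raise ValueError(f"unknown denominator_policy {denominator_policy!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("profiles must be equal-length 1-D vectors")
    mask = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    n_used = int(mask.sum())
    if n_used < MIN_TRIPLES:
        raise ValueError(f"need >= {MIN_TRIPLES} complete triples, got {n_used}")
    total = float(np.sum(x[mask] * y[mask] * z[mask]))
    denom = n_used if denominator_policy == "complete_triples" else x.size
    return LAResult("x", "y", "z", total / denom, n_used)


def _rank_ends(ids_or_pairs, scores, top_k):
    """Sort candidates to the two signed ends; ties broken lexicographically by id."""
    keys = [e if isinstance(e, str) else "\t".join(e) for e in ids_or_pairs]
    order_desc = sorted(range(len(scores)), key=lambda i: (-scores[i], keys[i]))
    order_asc = sorted(range(len(scores)), key=lambda i: (scores[i], keys[i]))

    def entries(order):
        out = []
        for place, i in enumerate(order[:top_k], start=1):
            e = ids_or_pairs[i]
            ids = (e,) if isinstance(e, str) else tuple(e)
            out.append(RankedEntry(ids=ids, la_score=float(scores[i]), place=place))
        return out

    return entries(order_desc), entries(order_asc)


def scout_z(
    x_id: str,
    y_id: str,
    ds: ExpressionDataset,
    top_k: int = 20,
    denominator_policy: str = "complete_triples",
) -> ScoutTable:
    """Rank every candidate gene Z by LA(X, Y | Z) for a fixed lead pair.

    Candidates are all genes except X and Y themselves; genes with fewer than
    3 complete triples against the pair are dropped from the candidate list.
    Vectorized as a matrix-vector product over the NaN-masked gene matrix.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if x_id == y_id:
        raise ValueError("lead genes X and Y must differ")
    ix, iy = ds.gene_row(x_id), ds.gene_row(y_id)
    x, y = ds.values[ix], ds.values[iy]

    w = x * y  # NaN wherever x or y missing
    mw = ~np.isnan(w)
    G = ds.values
    Mg = ~np.isnan(G)
    Gz = np.where(Mg, G, 0.0)
    wz = np.where(mw, w, 0.0)

    sums = Gz @ wz
    n_used = (Mg @ mw.astype(float)).astype(int)

    cand = np.ones(ds.n_genes, dtype=bool)
    cand[[ix, iy]] = False
    cand &= n_used >= MIN_TRIPLES

    idx = np.flatnonzero(cand)
    denom = n_used[idx] if denominator_policy == "complete_triples" else ds.n_samples
    scores = sums[idx] / denom
    ids = [ds.gene_ids[i] for i in idx]
    top, bot = _rank_ends(ids, scores, top_k)
    return ScoutTable(x_id=x_id, y_id=y_id, top_list=top, bot_list=bot, candidate_count=len(ids))


def search_pairs(
    x_id: str,
    ds: ExpressionDataset,
    top_k: int = 20,
    denominator_policy: str = "complete_triples",
) -> PairSearchTable:
    """Rank every unordered gene pair (Y, Z) by LA(X, Y | Z) for a single lead X.

    The score is symmetric in Y and Z, so each pair is reported once, its two
    members ordered lexicographically by gene id.  Implemented as the
    cross-product ``G diag(x) G^T`` of the NaN-masked gene matrix with itself.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ix = ds.gene_row(x_id)
    x = ds.values[ix]
    mx = ~np.isnan(x)
    if ds.n_genes < 3:
        raise ValueError("need at least 2 candidate genes besides X")

    keep = np.ones(ds.n_genes, dtype=bool)
    keep[ix] = False
    rows = np.flatnonzero(keep)
    G = ds.values[rows]
    Mg = ~np.isnan(G)
    Gz = np.where(Mg, G, 0.0)

    xz = np.where(mx, x, 0.0)
    S = Gz @ (Gz * xz).T
    N = (Mg.astype(float) @ (Mg & mx).T.astype(float)).astype(int)

    iu, ju = np.triu_indices(len(rows), k=1)
    ok = N[iu, ju] >= MIN_TRIPLES
    iu, ju = iu[ok], ju[ok]
    denom = N[iu, ju] if denominator_policy == "complete_triples" else ds.n_samples
    scores = S[iu, ju] / denom
    ids = [
        tuple(sorted((ds.gene_ids[rows[i]], ds.gene_ids[rows[j]])))
        for i, j in zip(iu, ju)
    ]
    top, bot = _rank_ends(ids, scores, top_k)
    return PairSearchTable(x_id=x_id, top_list=top, bot_list=bot, candidate_count=len(ids))


def lead_set_report(
    lead_ids: Sequence[str],
    ds: ExpressionDataset,
    top_k: int = 20,
    pvalue_cfg=None,
    split_cfg=None,
    ends: str = "top",
    z_filter: Iterable[str] | None = None,
) -> LeadSetReport:
    """Scout every unordered pair of a lead gene set and report annotated rows.

    For each lead pair (X, Y) the requested end(s) of its scouting ranking are
    reported as rows (X, Y, Z, LA score, corr-high, corr-low, p, place).
    ``z_filter`` restricts rows to particular Z genes (their place within the
    full ranking is kept).  Subgroup correlations come from the median split
    on Z and p-values from the configured significance method.
    """
    from .inference import PValueConfig, pvalue_for_triple
    from .lap_view import SplitConfig, lap_split

    leads = list(dict.fromkeys(lead_ids))
    if len(leads) < 2:
        raise ValueError("need at least 2 lead genes")
    missing = [g for g in leads if g not in set(ds.gene_ids)]
    if missing:
        raise ValueError(f"lead gene(s) absent from dataset: {missing}")
    if ends not in ("top", "bot", "both"):
        raise ValueError(f"unknown ends {ends!r}")
    pvalue_cfg = pvalue_cfg or PValueConfig()
    split_cfg = split_cfg or SplitConfig()
    zset = set(z_filter) if z_filter is not None else None

    rows: list[ReportRow] = []
    for a in range(len(leads)):
        for b in range(a + 1, len(leads)):
            x_id, y_id = leads[a], leads[b]
            table = scout_z(x_id, y_id, ds, top_k=top_k)
            chosen = []
            if ends in ("top", "both"):
                chosen.extend(table.top_list)
            if ends in ("bot", "both"):
                chosen.extend(table.bot_list)
            for entry in chosen:
                z_id = entry.ids[0]
                if zset is not None and z_id not in zset:
                    continue
                split = lap_split(
                    ds.profile(x_id),
                    ds.profile(y_id),
                    ds.profile(z_id),
                    split_fraction=split_cfg.split_fraction,
                )
                pres = pvalue_for_triple(
                    ds, x_id, y_id, z_id, observed=entry.la_score, cfg=pvalue_cfg
                )
                rows.append(
                    ReportRow(
                        x_id=x_id,
                        y_id=y_id,
                        z_id=z_id,
                        la_score=entry.la_score,
                        corr_high=split.corr_high,
                        corr_low=split.corr_low,
                        p_value=pres.p,
                        place=entry.place,
                    )
                )
    return LeadSetReport(rows=rows)
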