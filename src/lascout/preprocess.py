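"""Per-gene, per-batch normal-score (rank-Gaussianizing) transform and gene filtering.

The liquid-association statistic is defined on Gaussianized profiles.  Because
the samples of a merged dataset come from different experimental series, each
gene profile is rank-transformed *within each batch separately*: the observed
values of a gene in a batch are replaced by standard-normal quantiles
Phi^-1(r/(m+1)) of their ranks (van der Waerden scores), where m is the number
of non-missing values in that batch.  This removes between-series scale and
location differences without any cross-series modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from .data_model import ExpressionDataset

__all__ = [
    "normal_score_transform",
    "transform_dataset",
    "filter_genes",
    "TransformedDataset",
]

log = logging.getLogger(__name__)

_QUANTILE_OFFSETS = {
    # name -> (rank offset a, denominator offset b): score = Phi^-1((r+a)/(m+b))
    "vdw": (0.0, 1.0),      # van der Waerden: r/(m+1)
    "blom": (-0.375, 0.25),  # Blom: (r-3/8)/(m+1/4)
}


@dataclass
class TransformedDataset(ExpressionDataset):
    """An :class:`ExpressionDataset` after the per-batch normal-score transform."""

    quantile_convention: str = "vdw"
    tie_policy: str = "average_rank"
    per_batch: bool = True
    flagged_genes: dict[str, list[str]] = field(default_factory=dict)


def normal_score_transform(
    values,
    tie_policy: str = "average_rank",
    quantile_convention: str = "vdw",
):
    """Map a 1-D profile to standard-normal quantile scores of its ranks.

    The non-missing entry with rank r among the m observed values becomes
    ``Phi^-1((r+a)/(m+b))`` with (a, b) set by the quantile convention
    (default van der Waerden: r/(m+1)).  Missing (NaN) entries stay missing
    and output order matches input order.

    ``tie_policy="average_rank"`` gives tied entries the mean of the ranks
    they occupy before quantile mapping; ``"stable_order"`` breaks ties by
    input position (ordinal ranks), so the output is always an exact
    permutation of the quantile grid.
    """
    if tie_policy not in ("average_rank", "stable_order"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    try:
        a, b = _QUANTILE_OFFSETS[quantile_convention]
    except KeyError:
        raise ValueError(f"unknown quantile convention {quantile_convention!r}") from None

    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    obs = ~np.isnan(x)
    m = int(obs.sum())
    if m < 2:
        raise ValueError(f"need >= 2 non-missing values, got {m}")
    method = "average" if tie_policy == "average_rank" else "ordinal"
    r = rankdata(x[obs], method=method)
    out[obs] = norm.ppf((r + a) / (m + b))
    return out


def transform_dataset(
    ds: ExpressionDataset,
    tie_policy: str = "average_rank",
    quantile_convention: str = "vdw",
) -> TransformedDataset:
    """Apply :func:`normal_score_transform` to every (gene, batch) slice.

    Batches are transformed independently and re-concatenated in the original
    sample order.  A gene with fewer than 2 observed values in some batch is
    retained but fully missing-masked for that batch, and recorded in
    ``flagged_genes`` (batch label -> gene ids).
    """
    out = np.full_like(np.asarray(ds.values, dtype=float), np.nan)
    flagged: dict[str, list[str]] = {}
    for b in ds.batches:
        cols = ds.batch_columns(b)
        block = ds.values[:, cols]
        for i in range(ds.n_genes):
            row = block[i]
            if (~np.isnan(row)).sum() < 2:
                flagged.setdefault(b, []).append(ds.gene_ids[i])
                continue
            out[i, cols] = normal_score_transform(
                row, tie_policy=tie_policy, quantile_convention=quantile_convention
            )
    for b, genes in flagged.items():
        log.warning("batch %s: %d gene(s) missing-masked (<2 observed values)", b, len(genes))
    return TransformedDataset(
        gene_ids=list(ds.gene_ids),
        sample_ids=list(ds.sample_ids),
        batch_labels=list(ds.batch_labels),
        values=out,
        name=ds.name,
        quantile_convention=quantile_convention,
        tie_policy=tie_policy,
        per_batch=True,
        flagged_genes=flagged,
    )


def filter_genes(ds: ExpressionDataset, min_observed_fraction: float):
    """Keep genes whose overall non-missing fraction is >= the threshold.

    Returns ``(filtered_dataset, kept_count, dropped_count)``; gene order is
    preserved.
    """
    if not 0.0 <= min_observed_fraction <= 1.0:
        raise ValueError("min_observed_fraction must lie in [0, 1]")
    frac = (~np.isnan(ds.values)).mean(axis=1)
    keep = frac >= min_observed_fraction
    kept = int(keep.sum())
    dropped = ds.n_genes - kept
    if dropped == 0:
        return ds, kept, 0
    sub = type(ds)(
        gene_ids=[g for g, k in zip(ds.gene_ids, keep) if k],
        sample_ids=list(ds.sample_ids),
        batch_labels=list(ds.batch_labels),
        values=ds.values[keep],
        name=ds.name,
        **(
            dict(
                quantile_convention=ds.quantile_convention,
                tie_policy=ds.tie_policy,
                per_batch=ds.per_batch,
            )
            if isinstance(ds, TransformedDataset)
            else {}
        ),
    )
    log.info("filter_genes: kept %d, dropped %d (threshold %.3g)", kept, dropped, min_observed_fraction)
    return sub, kept, dropped
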