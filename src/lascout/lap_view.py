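"""Conditional (LAP) views: split samples by mediator level, compare subgroup correlations.

A liquid-association pair plot shows the lead pair (X, Y) as a scatter,
stratified by the mediator Z: samples with high Z drawn as red triangles,
samples with low Z as blue dots.  The Pearson correlation of (X, Y) within
each subgroup makes the mediation visible — for a positive scouting gene the
high-Z correlation exceeds the low-Z one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplitConfig", "LapSplit", "lap_split", "render_lap_plot"]


@dataclass(frozen=True)
class SplitConfig:
    split_fraction: float = 0.5
    data_space: str = "transformed"  # which values lap_split receives; "raw" variant available


@dataclass
class LapSplit:
    """A high/low stratification of samples by mediator level.

    ``high_idx``/``low_idx`` are sample positions (disjoint); every Z value in
    the high group is >= every Z value in the low group.  ``excluded_idx``
    holds the middle samples when the split fraction is below one half, plus
    samples with missing Z.
    """

    split_fraction: float
    high_idx: np.ndarray
    low_idx: np.ndarray
    excluded_idx: np.ndarray
    corr_high: float
    corr_low: float
    degenerate: dict[str, bool] = field(default_factory=dict)


def _pearson(x, y):
    """Pearson r over complete pairs; NaN (flagged) if either side is constant."""
    m = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[m], y[m]
    if xs.size < 3:
        raise ValueError(f"subgroup has {xs.size} complete pairs; need >= 3")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return np.nan, True
    return float(np.corrcoef(xs, ys)[0, 1]), False


def lap_split(x, y, z, split_fraction: float = 0.5) -> LapSplit:
    """Split samples into low/high halves of the mediator and correlate (X, Y) in each.

    Samples are ordered by z (ties resolved by sample position, so the split
    is deterministic); the top ``split_fraction`` of the observed-z samples
    form the high group and the bottom fraction the low group.  With fraction
    0.5 the two group sizes differ by at most one (the odd middle sample is
    excluded).  Pearson correlations are computed within each group over
    complete (x, y) pairs.
    """
    if not 0.0 < split_fraction <= 0.5:
        raise ValueError("split_fraction must lie in (0, 0.5]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("profiles must be equal-length 1-D vectors")

    obs = np.flatnonzero(~np.isnan(z))
    order = obs[np.argsort(z[obs], kind="stable")]
    m = order.size
    k = int(np.floor(m * split_fraction))
    if k < 3:
        raise ValueError(f"subgroups of size {k}; need >= 3 complete samples each")
    low_idx = order[:k]
    high_idx = order[m - k:]
    excluded = np.setdiff1d(np.arange(x.size), np.concatenate([low_idx, high_idx]))

    corr_high, deg_h = _pearson(x[high_idx], y[high_idx])
    corr_low, deg_l = _pearson(x[low_idx], y[low_idx])
    return LapSplit(
        split_fraction=split_fraction,
        high_idx=high_idx,
        low_idx=low_idx,
        excluded_idx=excluded,
        corr_high=corr_high,
        corr_low=corr_low,
        degenerate={"high": deg_h, "low": deg_l},
    )


def render_lap_plot(
    split: LapSplit,
    x,
    y,
    out_path,
    format: str = "png",
    la_score: float | None = None,
    labels: tuple[str, str, str] = ("X", "Y", "Z"),
):
    """Render the stratified scatter: high-Z samples as red triangles, low-Z as blue dots."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if format not in ("png", "svg"):
        raise ValueError(f"unknown format {format!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(
        x[split.high_idx], y[split.high_idx],
        marker="^", color="red",
        label=f"{labels[2]} high (r = {split.corr_high:.4f})",
    )
    ax.scatter(
        x[split.low_idx], y[split.low_idx],
        marker="o", color="blue",
        label=f"{labels[2]} low (r = {split.corr_low:.4f})",
    )
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    title = f"LAP plot: ({labels[0]}, {labels[1]}) | {labels[2]}"
    if la_score is not None:
        title += f"   LA = {la_score:.4f}"
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, format=format, dpi=120)
    plt.close(fig)
    return out_path
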