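"""Group-level summaries and comparisons of cytoband alteration scores.

Box summaries condense a sample group's scores per cytoband into
quartiles (linear-interpolation rule) in genome order; a box entirely
below (above) zero means at least 75% of the group's samples show a loss
(gain) there.  Two-group comparison uses Welch's unequal-variance t-test
per cytoband, flagged significant when |t| exceeds a threshold (default
2, with no multiple-testing correction -- a Benjamini-Hochberg column is
emitted alongside for reference but does not drive the flag).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import GenomeMap, parse_band_arm


@dataclass(frozen=True)
class GroupCompareConfig:
    stat_threshold: float = 2.0

    def __post_init__(self):
        if self.stat_threshold <= 0:
            raise ValueError("stat_threshold must be positive")


def group_box_summary(scores: pd.DataFrame, members=None) -> pd.DataFrame:
    """Per-cytoband (q1, median, q3) over a sample subset, in genome order.

    Returns a DataFrame indexed by cytoband with columns ``q1``, ``median``,
    ``q3``, ``n`` and ``flag`` ("loss" when the whole box is below zero,
    "gain" when above, else "none").
    """
    sub = scores if members is None else scores.loc[list(members)]
    if len(sub) < 2:
        raise ValueError("box summary requires at least 2 samples")
    vals = sub.to_numpy(dtype=float)
    q1, med, q3 = np.percentile(vals, [25, 50, 75], axis=0)
    flag = np.where(q3 < 0, "loss", np.where(q1 > 0, "gain", "none"))
    return pd.DataFrame(
        {"q1": q1, "median": med, "q3": q3, "n": len(sub), "flag": flag},
        index=scores.columns,
    )


def compare_groups(
    scores: pd.DataFrame,
    group_a,
    group_b,
    config: GroupCompareConfig | None = None,
) -> pd.DataFrame:
    """Welch two-sample t per cytoband between two sample groups.

    Returns a genome-ordered DataFrame with ``t_stat``, ``p_value``,
    ``p_bh`` (Benjamini-Hochberg adjusted, informational) and
    ``significant`` (|t| > threshold on the raw statistic).
    Antisymmetric in group order: swapping the groups negates t.
    """
    cfg = config or GroupCompareConfig()
    a = scores.loc[list(group_a)].to_numpy(dtype=float)
    b = scores.loc[list(group_b)].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 samples")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate (zero-variance) bands are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=False)
    # zero variance in both groups and equal means -> t defined as 0
    degenerate = np.isnan(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {
            "t_stat": t,
            "p_value": p,
            "p_bh": sps.false_discovery_control(p, method="bh"),
            "significant": np.abs(t) > cfg.stat_threshold,
        },
        index=scores.columns,
    )


def size_group(size_cm: float) -> str:
    """Tumor-size grouping: small (<3 cm), medium (3-7 cm), large (>7 cm)."""
    if size_cm < 3:
        return "small"
    if size_cm <= 7:
        return "medium"
    return "large"


def event_intensity(scores: pd.DataFrame, bands, sign: int) -> pd.Series:
    """Per-sample mean score over a band set, oriented so larger = more of
    the named event (``sign=-1`` for losses, ``+1`` for gains)."""
    if sign not in (-1, 1):
        raise ValueError("sign must be -1 or +1")
    missing = [b for b in bands if b not in scores.columns]
    if missing:
        raise KeyError(f"bands absent from score matrix: {missing}")
    return sign * scores[list(bands)].mean(axis=1)


def correlate_events(
    scores: pd.DataFrame, bands1, bands2, sign1: int, sign2: int
) -> tuple[float, float]:
    """Pearson correlation between two per-sample event intensities.

    Intensities are sign-oriented mean scores over each band set; returns
    (r, two-sided p from the t reference distribution).
    """
    if len(scores) < 3:
        raise ValueError("correlation requires at least 3 samples")
    i1 = event_intensity(scores, bands1, sign1)
    i2 = event_intensity(scores, bands2, sign2)
    if np.std(i1.to_numpy()) == 0 or np.std(i2.to_numpy()) == 0:
        raise ValueError("zero variance in an event intensity")
    r, p = sps.pearsonr(i1, i2)
    return float(r), float(p)


def plot_box_summary(box: pd.DataFrame, ax=None, chrom_colors=("#4477aa", "#ee6677")):
    """Render a genome-ordered box summary, alternating color per chromosome.

    Boxes span q1..q3 with the median marked; returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(14, 3))
    chroms = [parse_band_arm(b)[:-1] for b in box.index]
    boundaries = [i for i in range(1, len(chroms)) if chroms[i] != chroms[i - 1]]
    color_idx, colors = 0, []
    for i, c in enumerate(chroms):
        if i in boundaries:
            color_idx += 1
        colors.append(chrom_colors[color_idx % len(chrom_colors)])
    x = np.arange(len(box))
    ax.bar(x, box["q3"] - box["q1"], bottom=box["q1"], width=0.8, color=colors)
    ax.plot(x, box["median"], "k.", markersize=2)
    ax.axhline(0, color="gray", lw=0.5)
    ax.set_xlim(-1, len(box))
    ax.set_ylabel("cytoband score")
    ax.set_xticks(boundaries)
    ax.set_xticklabels([chroms[i] for i in boundaries], fontsize=6)
    return ax
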