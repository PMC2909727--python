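"""Tri-state cytoband calls, arm-level events, and cross-study pooling.

A cytoband score above the cutoff (default 10, strict inequality) is a
gain, below the negated cutoff a loss, otherwise neutral.  An arm's loss
(gain) proportion is the highest loss (gain) proportion among its
cytobands; the arm is an overall loss if its loss proportion exceeds its
gain proportion, and vice versa (ties -> undecided).

Cross-study pooling sums event and sample counts over studies (and
optionally stage strata) and reports the percentage rounded to the
nearest integer, half away from zero -- the convention that reproduces
every printed percentage of the packaged multi-study count table.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .genome import GenomeMap, parse_band_arm

LOSS, NEUTRAL, GAIN = -1, 0, 1

#: collapse map from this package's stage labels to the pooled S1..S4 strata
STAGE_COLLAPSE = {"S1a": "S1", "S1b": "S1", "S2": "S2", "S3a": "S3", "S3b4": "S4"}


@dataclass(frozen=True)
class CallConfig:
    cutoff: float = 10.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass(frozen=True)
class ArmCall:
    arm: str
    loss_prop: float
    gain_prop: float
    overall: str  # "loss" | "gain" | "undecided"
    n_loss: int  # event count at the loss-proportion-maximizing band
    n_gain: int


class CytobandCaller(TransformerMixin, BaseEstimator):
    """Threshold a score matrix into {loss=-1, neutral=0, gain=+1} calls."""

    def __init__(self, cutoff: float = 10.0):
        self.cutoff = cutoff

    def fit(self, X=None, y=None):
        CallConfig(self.cutoff)
        return self

    def transform(self, X) -> pd.DataFrame:
        CallConfig(self.cutoff)
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.atleast_2d(X))
        vals = df.to_numpy(dtype=float)
        calls = np.where(vals > self.cutoff, GAIN, np.where(vals < -self.cutoff, LOSS, NEUTRAL))
        return pd.DataFrame(calls.astype(np.int8), index=df.index, columns=df.columns)


def call_cytobands(scores: pd.DataFrame, config: CallConfig | None = None) -> pd.DataFrame:
    cfg = config or CallConfig()
    return CytobandCaller(cfg.cutoff).fit().transform(scores)


def call_proportions(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-cytoband loss/gain proportions across the samples of a call table."""
    if len(calls) == 0:
        raise ValueError("empty call table")
    return pd.DataFrame({
        "loss_prop": (calls == LOSS).mean(axis=0),
        "gain_prop": (calls == GAIN).mean(axis=0),
    })


def _arm_columns(calls: pd.DataFrame, arm: str) -> list[str]:
    cols = [c for c in calls.columns if parse_band_arm(c) == arm]
    if not cols:
        raise ValueError(f"no cytobands for arm {arm!r} in call table")
    return cols


def arm_summary(calls: pd.DataFrame, genome: GenomeMap, arm: str) -> ArmCall:
    """Arm-level loss/gain summary from a cytoband call table.

    ``genome`` validates that the arm exists; the bands used are the call
    table's columns on that arm (which may be post-merge names).
    """
    genome.arm_band_indices(arm)  # raises on unknown arm
    cols = _arm_columns(calls, arm)
    props = call_proportions(calls[cols])
    loss_band = props["loss_prop"].idxmax()
    gain_band = props["gain_prop"].idxmax()
    loss_prop = float(props.at[loss_band, "loss_prop"])
    gain_prop = float(props.at[gain_band, "gain_prop"])
    if loss_prop > gain_prop:
        overall = "loss"
    elif gain_prop > loss_prop:
        overall = "gain"
    else:
        overall = "undecided"
    return ArmCall(
        arm=arm, loss_prop=loss_prop, gain_prop=gain_prop, overall=overall,
        n_loss=int((calls[loss_band] == LOSS).sum()),
        n_gain=int((calls[gain_band] == GAIN).sum()),
    )


def arm_event_table(calls: pd.DataFrame, genome: GenomeMap) -> pd.DataFrame:
    """Arm summaries for every arm of the genome, in genome order."""
    rows = []
    for arm in genome.arm_ids:
        try:
            a = arm_summary(calls, genome, arm)
        except ValueError:
            continue  # arm lost its bands to merging
        rows.append({"arm": a.arm, "loss_prop": a.loss_prop, "gain_prop": a.gain_prop,
                     "overall": a.overall, "n_loss": a.n_loss, "n_gain": a.n_gain})
    return pd.DataFrame(rows).set_index("arm")


# -- cross-study pooling ------------------------------------------------------


@dataclass(frozen=True)
class PooledCounts:
    event: str
    stage: str
    events: int
    total: int
    percent: int  # rounded half away from zero

    @property
    def proportion(self) -> float:
        return self.events / self.total


def round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def load_study_counts() -> pd.DataFrame:
    """Published per-study event counts (study, event, stage, events, total).

    Stage ``all`` rows are each study's own totals; S1..S4 rows exist only
    for the studies that reported stage-stratified counts.
    """
    with resources.files("cytoscan.data").joinpath("study_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if (df["events"] > df["total"]).any() or (df["total"] <= 0).any():
        raise ValueError("malformed study count table")
    return df


def load_study_table() -> pd.DataFrame:
    """Study roster: study label, detection method, sample count."""
    with resources.files("cytoscan.data").joinpath("studies.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def pool_counts(counts: pd.DataFrame, event: str, stage: str = "all") -> PooledCounts:
    """Pool event counts over studies for one event and stage stratum.

    Sums events and totals over the matching rows; the pooled percentage is
    rounded to the nearest integer, half away from zero.
    """
    sel = counts[(counts["event"] == event) & (counts["stage"] == stage)]
    if sel.empty:
        raise ValueError(f"no study counts for event {event!r}, stage {stage!r}")
    ev, tot = int(sel["events"].sum()), int(sel["total"].sum())
    return PooledCounts(event=event, stage=stage, events=ev, total=tot,
                        percent=round_half_away(100.0 * ev / tot))


def cohort_event_counts(
    calls: pd.DataFrame,
    genome: GenomeMap,
    annotations: pd.DataFrame,
    events: dict[str, str],
    study: str = "current",
    stage_collapse: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Arm-level event counts for a (synthetic or real) cohort, in the same
    shape as the packaged study count table.

    ``events`` maps an event label to an arm, e.g. ``{"-3p": "3p"}``; a
    sample counts as an event if its call at the arm's proportion-maximizing
    band matches the event direction.
    """
    collapse = STAGE_COLLAPSE if stage_collapse is None else stage_collapse
    ann = annotations.set_index("sample_id").loc[calls.index]
    rows = []
    for label, arm in events.items():
        want = LOSS if label.startswith("-") else GAIN
        cols = _arm_columns(calls, arm)
        props = call_proportions(calls[cols])
        band = (props["loss_prop"] if want == LOSS else props["gain_prop"]).idxmax()
        hits = calls[band] == want
        rows.append({"study": study, "event": label, "stage": "all",
                     "events": int(hits.sum()), "total": len(calls)})
        strata = ann["stage"].map(lambda s: collapse.get(s, s))
        for stratum in sorted(strata.unique()):
            members = strata == stratum
            rows.append({"study": study, "event": label, "stage": stratum,
                         "events": int(hits[members.to_numpy()].sum()),
                         "total": int(members.sum())})
    return pd.DataFrame(rows)
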