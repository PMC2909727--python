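"""Synthetic SNP-array cohorts with known copy-number ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: segmental integer copy-number events, tumor/normal admixture
(so that a one-copy loss in a 60%-pure sample is observed as
``log2((0.6*1 + 0.4*2)/2) = -0.515`` rather than ``-1``), i.i.d. Gaussian
log-ratio noise, subtype- and stage-specific event sets, and survival
times optionally linked to chosen alterations.

The observed log2 ratio at a SNP covered by an event with tumor copy
number ``c`` in a sample with purity ``rho`` has expectation

    log2((rho * c + (1 - rho) * 2) / 2)

and 0 elsewhere; Gaussian noise with configurable standard deviation is
added everywhere.  Event boundaries snap to cytoband boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genome import AUTOSOMES, GenomeMap, SNPProfile

# observed-signal floor on the mixture copy number (log2 = -8), so that a
# homozygous deletion in a 100%-pure sample stays finite on the log scale
_MIN_MIXTURE_CN = 2.0 ** -8


def synthetic_genome(
    n_chroms: int = 22,
    bands_per_arm: int = 4,
    snps_per_band: int = 60,
    band_bp: int = 5_000_000,
) -> GenomeMap:
    """A synthetic, regular genome map for simulation and testing.

    Every autosome gets ``bands_per_arm`` equal-width cytobands per arm
    (named ``1p4..1p1, 1q1..1q4`` outward-in on p, inward-out on q, as on
    real karyograms) and ``snps_per_band`` evenly spaced SNP loci per band.
    The default density (60 SNPs per band, ~10.6k loci genome-wide) keeps
    cytobands several times wider than the 31-SNP smoothing window, as on
    a real 100K array.  This is a synthetic stand-in for a real banding
    file, not a transcription of one.
    """
    if n_chroms < 1 or n_chroms > 22:
        raise ValueError("n_chroms must be in 1..22")
    band_rows, snp_rows = [], []
    for chrom in AUTOSOMES[:n_chroms]:
        for j in range(2 * bands_per_arm):
            arm = "p" if j < bands_per_arm else "q"
            num = bands_per_arm - j if arm == "p" else j - bands_per_arm + 1
            start = j * band_bp
            band_rows.append((chrom, start, start + band_bp, f"{chrom}{arm}{num}", arm))
            step = band_bp / (snps_per_band + 1)
            for k in range(snps_per_band):
                pos = int(start + (k + 1) * step)
                snp_rows.append((f"s{chrom}_{j * snps_per_band + k}", chrom, pos))
    bands = pd.DataFrame(band_rows, columns=["chrom", "start", "end", "name", "arm"])
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos"])
    return GenomeMap(bands, snps)


# -- regions and events -------------------------------------------------------


def resolve_region(genome: GenomeMap, region: str) -> np.ndarray:
    """Band indices (genome order) covered by a region string.

    Accepted forms: ``"7"`` (whole chromosome), ``"3p"`` (arm), ``"3p25"``
    (single band), ``"5q31-5q35"`` (inclusive band range on one arm).
    """
    region = str(region).strip()
    if "-" in region:
        a, b = region.split("-", 1)
        ia, ib = genome.band_index(a), genome.band_index(b)
        if ia > ib:
            ia, ib = ib, ia
        return np.arange(ia, ib + 1)
    if region in AUTOSOMES:
        return genome.chrom_band_indices(region)
    try:
        return genome.arm_band_indices(region)
    except KeyError:
        pass
    return np.array([genome.band_index(region)])


@dataclass(frozen=True)
class EventSpec:
    """A segmental copy-number event planted in a sample group.

    ``tumor_copy_number`` is the integer copy number in the tumor cells
    (0 or 1 = loss, 3+ = gain; 2 is not an event).  ``penetrance`` is the
    probability that a sample of the group carries the event.
    """

    region: str
    tumor_copy_number: int
    penetrance: float = 1.0

    def __post_init__(self):
        if int(self.tumor_copy_number) != self.tumor_copy_number or self.tumor_copy_number < 0:
            raise ValueError("tumor_copy_number must be a non-negative integer")
        if self.tumor_copy_number == 2:
            raise ValueError("tumor_copy_number 2 is not an event")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")

    @property
    def label(self) -> str:
        sign = "-" if self.tumor_copy_number < 2 else "+"
        return sign + self.region

    def snp_indices(self, genome: GenomeMap) -> np.ndarray:
        bands = resolve_region(genome, self.region)
        return np.concatenate([genome.band_snp_indices(b) for b in bands])


def expected_log2_ratio(copy_number: float, purity: float) -> float:
    """Closed-form mixture expectation of the log2 ratio for an event SNP."""
    mix = purity * copy_number + (1.0 - purity) * 2.0
    return float(np.log2(max(mix, _MIN_MIXTURE_CN) / 2.0))


def simulate_profile(
    genome: GenomeMap,
    events: list[EventSpec],
    purity: float,
    noise_sd: float,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> SNPProfile:
    """Simulate one sample's log2-ratio profile given its realized events."""
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    expected = np.zeros(genome.n_snps)
    seen = np.zeros(genome.n_snps, dtype=bool)
    for ev in events:
        idx = ev.snp_indices(genome)
        if seen[idx].any():
            raise ValueError(f"event {ev.label} overlaps another event in SNP space")
        seen[idx] = True
        expected[idx] = expected_log2_ratio(ev.tumor_copy_number, purity)
    values = expected if noise_sd == 0 else expected + rng.normal(0.0, noise_sd, genome.n_snps)
    return SNPProfile(sample_id, values)


# -- cohorts ------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    label: str
    subtype: str
    stage: str
    n_samples: int
    events: tuple[EventSpec, ...] = ()

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        object.__setattr__(self, "events", tuple(self.events))


@dataclass(frozen=True)
class SurvivalSpec:
    """Exponential survival link: log-hazard = log(baseline) + sum of
    region coefficients over carried events."""

    baseline_hazard: float  # events per day
    coefficients: dict = field(default_factory=dict)  # region -> log-hazard
    censor_rate: float = 0.3

    def __post_init__(self):
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    purity_range: tuple[float, float] = (0.4, 0.9)
    noise_sd: float = 0.25
    survival: SurvivalSpec | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must satisfy 0 < lo <= hi <= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SimulatedCohort:
    profiles: list[SNPProfile]
    annotations: pd.DataFrame
    survival: pd.DataFrame | None
    truth: pd.DataFrame  # sample_id, group, region, copy_number, carrier


_STAGE_GRADE = {  # plausible nuclear-grade pools per stage
    "S1a": (1, 2), "S1b": (2, 2), "S2": (2, 3), "S3a": (3, 3), "S3b4": (3, 4),
    "unknown": (1, 4),
}
_STAGE_SIZE = {  # tumor size (cm) ranges per stage; T1a/T1b differ by size
    "S1a": (1.0, 4.0), "S1b": (4.0, 7.0), "S2": (7.0, 10.0),
    "S3a": (5.0, 12.0), "S3b4": (6.0, 15.0), "unknown": (1.0, 12.0),
}


def simulate_cohort(genome: GenomeMap, spec: CohortSpec) -> SimulatedCohort:
    """Simulate a cohort of profiles, annotations, survival, and ground truth.

    Fully reproducible from ``spec.seed`` (PCG64 generator, fixed draw
    order).  Each group event is realized independently per sample with
    its penetrance; purity is drawn uniformly from ``purity_range``.
    """
    rng = np.random.default_rng(spec.seed)
    for g in spec.groups:
        # validate non-overlap of the full planted set once per group
        simulate_profile(genome, list(g.events), 1.0, 0.0, rng, "_check")
    if spec.survival is not None:
        for region in spec.survival.coefficients:
            resolve_region(genome, region)  # raises on unknown regions
        coef_bands = {
            r: set(resolve_region(genome, r).tolist())
            for r in spec.survival.coefficients
        }
    profiles, ann_rows, surv_rows, truth_rows = [], [], [], []
    for g in spec.groups:
        for i in range(g.n_samples):
            sid = f"{g.label}_{i:03d}"
            carried = [rng.random() < ev.penetrance for ev in g.events]
            realized = [ev for ev, c in zip(g.events, carried) if c]
            purity = rng.uniform(*spec.purity_range)
            profiles.append(simulate_profile(genome, realized, purity, spec.noise_sd, rng, sid))
            lo, hi = _STAGE_GRADE[g.stage]
            ann_rows.append({
                "sample_id": sid, "group": g.label, "subtype": g.subtype,
                "stage": g.stage, "grade": int(rng.integers(lo, hi + 1)),
                "size_cm": round(float(rng.uniform(*_STAGE_SIZE[g.stage])), 1),
                "purity": round(purity, 4),
                "sarcomatoid": "unknown", "necrosis": "unknown",
                "vein_invasion": "unknown", "vascular_invasion": "unknown",
                "sex": "unknown",
            })
            for ev, c in zip(g.events, carried):
                truth_rows.append({
                    "sample_id": sid, "group": g.label, "region": ev.region,
                    "copy_number": ev.tumor_copy_number, "label": ev.label,
                    "carrier": bool(c),
                })
            if spec.survival is not None:
                carried_bands = set()
                for ev in realized:
                    carried_bands.update(resolve_region(genome, ev.region).tolist())
                loghaz = np.log(spec.survival.baseline_hazard) + sum(
                    coef for r, coef in spec.survival.coefficients.items()
                    if coef_bands[r] & carried_bands
                )
                t = rng.exponential(np.exp(-loghaz))
                if rng.random() < spec.survival.censor_rate:
                    surv_rows.append({"sample_id": sid,
                                      "duration_days": t * rng.random(), "event": False})
                else:
                    surv_rows.append({"sample_id": sid, "duration_days": t, "event": True})
    return SimulatedCohort(
        profiles=profiles,
        annotations=pd.DataFrame(ann_rows),
        survival=pd.DataFrame(surv_rows) if spec.survival is not None else None,
        truth=pd.DataFrame(truth_rows),
    )


# -- templates ----------------------------------------------------------------

# Stage-specific event signatures for clear cell RCC: the earliest tumors
# carry -3p, +5q, +7 and -14 only; later stages progressively accrue
# further whole-arm and whole-chromosome alterations.
STAGE_SIGNATURES: dict[str, tuple[tuple[str, int], ...]] = {
    "S1a": (("3p", 1), ("5q", 3), ("7", 3), ("14", 1)),
    "S1b": (("3p", 1), ("5q", 3), ("7", 3), ("14", 1), ("8p", 1)),
    "S2": (("3p", 1), ("5q", 3), ("7", 3), ("14", 1), ("8p", 1), ("6q", 1), ("9", 1)),
    "S3b4": (
        ("3p", 1), ("5q", 3), ("7", 3), ("14", 1), ("8p", 1), ("6q", 1), ("9", 1),
        ("1p", 1), ("1q", 3), ("8q", 3), ("12", 3), ("13", 1), ("18", 1),
        ("20", 3), ("22", 1),
    ),
}

# Subtype signatures: -3p/+5q/-8p are unique to clear cell; papillary gains
# 7, 12 and 3p; chromophobe shows broad whole-chromosome losses; oncocytoma
# is cytogenetically quiet.
SUBTYPE_SIGNATURES: dict[str, tuple[tuple[str, int], ...]] = {
    "CC": (("3p", 1), ("5q", 3), ("8p", 1), ("14q", 1)),
    "PA": (("7", 3), ("12", 3), ("3p", 3), ("17", 3)),
    "CH": (("1", 1), ("2", 1), ("6", 1), ("10", 1), ("13", 1), ("17", 1)),
    "ON": (),
}


def stage_template_spec(
    n_per_group: int = 40,
    purity_range: tuple[float, float] = (0.6, 0.9),
    noise_sd: float = 0.25,
    penetrance: float = 0.9,
    survival: SurvivalSpec | None = None,
    seed: int = 0,
) -> CohortSpec:
    """Stage-progression cohort template (clear cell subtype, 4 stage groups)."""
    groups = [
        GroupSpec(
            label=stage, subtype="CC", stage=stage, n_samples=n_per_group,
            events=tuple(EventSpec(r, c, penetrance) for r, c in sig),
        )
        for stage, sig in STAGE_SIGNATURES.items()
    ]
    return CohortSpec(groups=tuple(groups), purity_range=purity_range,
                      noise_sd=noise_sd, survival=survival, seed=seed)


def subtype_template_spec(
    n_per_group: int = 10,
    purity_range: tuple[float, float] = (0.6, 0.9),
    noise_sd: float = 0.25,
    penetrance: float = 1.0,
    seed: int = 0,
) -> CohortSpec:
    """Four-subtype cohort template for clustering experiments.

    Subtype signatures are treated as definitional (penetrance 1), since
    the clustering contract is recovery of the planted partition.
    """
    groups = [
        GroupSpec(
            label=sub, subtype=sub, stage="unknown", n_samples=n_per_group,
            events=tuple(EventSpec(r, c, penetrance) for r, c in sig),
        )
        for sub, sig in SUBTYPE_SIGNATURES.items()
    ]
    return CohortSpec(groups=tuple(groups), purity_range=purity_range,
                      noise_sd=noise_sd, seed=seed)


#: cytoband carrying the planted prognostic event in the survival testbed
SURVIVAL_TEMPLATE_BAND = "5q1"


def survival_template_genome() -> GenomeMap:
    """Compact genome map for survival-scan experiments (24 cytobands)."""
    return synthetic_genome(n_chroms=6, bands_per_arm=2, snps_per_band=40)


def survival_template_spec(
    n_samples: int = 200,
    log_hazard: float = 0.5,
    penetrance: float = 0.5,
    censor_rate: float = 0.2,
    purity_range: tuple[float, float] = (0.6, 0.9),
    seed: int = 0,
) -> CohortSpec:
    """One-group cohort with a single prognostic gain at
    :data:`SURVIVAL_TEMPLATE_BAND`: carriers have an additional
    ``log_hazard`` on the log scale (exponential baseline, ~3-year median)."""
    group = GroupSpec(
        label="CC", subtype="CC", stage="unknown", n_samples=n_samples,
        events=(EventSpec(SURVIVAL_TEMPLATE_BAND, 3, penetrance),),
    )
    surv = SurvivalSpec(
        baseline_hazard=1.0 / 1000.0,
        coefficients={SURVIVAL_TEMPLATE_BAND: log_hazard},
        censor_rate=censor_rate,
    )
    return CohortSpec(groups=(group,), purity_range=purity_range,
                      noise_sd=0.25, survival=surv, seed=seed)


def planted_arm_events(genome: GenomeMap, group: GroupSpec) -> tuple[set, set]:
    """(loss_arms, gain_arms) implied by a group's planted events."""
    arm_of_band = (genome.bands["chrom"] + genome.bands["arm"]).to_numpy()
    loss, gain = set(), set()
    for ev in group.events:
        arms = set(arm_of_band[resolve_region(genome, ev.region)])
        (loss if ev.tumor_copy_number < 2 else gain).update(arms)
    return loss, gain


# -- YAML round-trip ----------------------------------------------------------


def cohort_spec_to_yaml(spec: CohortSpec, path) -> None:
    d = asdict(spec)
    d["groups"] = [asdict(g) | {"events": [asdict(e) for e in g.events]}
                   for g in spec.groups]
    d["purity_range"] = list(spec.purity_range)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def cohort_spec_from_yaml(path) -> CohortSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    groups = tuple(
        GroupSpec(
            label=g["label"], subtype=g["subtype"], stage=g["stage"],
            n_samples=g["n_samples"],
            events=tuple(EventSpec(**e) for e in g.get("events", [])),
        )
        for g in d["groups"]
    )
    surv = d.get("survival")
    return CohortSpec(
        groups=groups,
        purity_range=tuple(d.get("purity_range", (0.4, 0.9))),
        noise_sd=d.get("noise_sd", 0.25),
        survival=SurvivalSpec(**surv) if surv else None,
        seed=d.get("seed", 0),
    )
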