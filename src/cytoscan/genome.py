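"""Genome coordinate backbone and plain-text IO.

The coordinate model is deliberately simple: autosomes ``"1"``..``"22"``,
each tiled by non-overlapping cytobands (0-based half-open coordinates, the
UCSC ``cytoBand.txt`` dialect), each cytoband belonging to one chromosome
arm, and a set of SNP loci each falling inside exactly one band.  Sex
chromosomes are excluded from every analysis and are dropped on input.

All per-cytoband output in this package is emitted in *genome order*:
chromosome 1 to 22, p arm before q arm, and within an arm by start
coordinate.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

SUBTYPES = frozenset({"CC", "PA", "CH", "ON"})
STAGES = frozenset({"S1a", "S1b", "S2", "S3a", "S3b4", "unknown"})
TRISTATE = frozenset({"yes", "no", "unknown"})

_BAND_RE = re.compile(r"^(\d{1,2})([pq])(\S*)$")


class MalformedMapError(ValueError):
    """Raised when a cytoband file violates the tiling invariants."""


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr`` prefix: ``chr3`` -> ``3``."""
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


def parse_band_arm(band_name: str) -> str:
    """Arm identifier (e.g. ``"3p"``) of a band name such as ``"3p25.1"``."""
    m = _BAND_RE.match(band_name)
    if m is None:
        raise ValueError(f"cannot parse cytoband name {band_name!r}")
    return m.group(1) + m.group(2)


@dataclass(frozen=True)
class SNPProfile:
    """One sample's per-SNP log2 copy-number ratios (0 = diploid).

    ``values`` is aligned index-for-index with the SNP loci of the
    :class:`GenomeMap` the profile was built against.
    """

    sample_id: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("profile values must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"profile {self.sample_id!r} contains non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SmoothedProfile:
    """Per-SNP moving-window t-statistics for one sample."""

    sample_id: str
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


class GenomeMap:
    """Ordered chromosomes -> arms -> cytobands -> SNP loci.

    Parameters
    ----------
    bands : pandas.DataFrame
        Columns ``chrom`` (str, "1".."22"), ``start``, ``end`` (ints,
        0-based half-open), ``name`` (e.g. ``"3p25"``), ``arm`` ("p"/"q").
        Must tile each chromosome without gaps or overlaps, p arm first.
    snps : pandas.DataFrame, optional
        Columns ``snp_id``, ``chrom``, ``pos``.  Sorted into genome order
        and assigned to bands on construction.
    """

    def __init__(self, bands: pd.DataFrame, snps: pd.DataFrame | None = None):
        bands = bands.reset_index(drop=True).copy()
        required = {"chrom", "start", "end", "name", "arm"}
        if not required.issubset(bands.columns):
            raise ValueError(f"band table needs columns {sorted(required)}")
        bands["chrom"] = bands["chrom"].astype(str)
        self._validate_bands(bands)
        self.bands = bands
        self._band_index = {n: i for i, n in enumerate(bands["name"])}
        if len(self._band_index) != len(bands):
            raise MalformedMapError("duplicate cytoband names in map")
        if snps is None:
            snps = pd.DataFrame({"snp_id": [], "chrom": [], "pos": []})
        self.snps = self._assign_snps(snps)

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _validate_bands(bands: pd.DataFrame) -> None:
        bad = set(bands["chrom"]) - set(AUTOSOMES)
        if bad:
            raise MalformedMapError(f"non-autosomal chromosomes in map: {sorted(bad)}")
        order = {c: i for i, c in enumerate(AUTOSOMES)}
        keys = [order[c] for c in bands["chrom"]]
        if keys != sorted(keys):
            raise MalformedMapError("chromosomes out of genome order")
        for chrom, sub in bands.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(ends <= starts):
                i = int(np.argmax(ends <= starts))
                raise MalformedMapError(
                    f"band {sub['name'].iloc[i]!r} on chromosome {chrom} has end <= start"
                )
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise MalformedMapError(
                    f"bands {sub['name'].iloc[i]!r} and {sub['name'].iloc[i + 1]!r} on "
                    f"chromosome {chrom} overlap or are out of order"
                )
            if np.any(starts[1:] != ends[:-1]) or starts[0] != 0:
                raise MalformedMapError(
                    f"cytobands do not tile chromosome {chrom} contiguously from 0"
                )
            arms = sub["arm"].tolist()
            if any(a not in ("p", "q") for a in arms):
                raise MalformedMapError(f"invalid arm labels on chromosome {chrom}")
            if arms != sorted(arms):  # all p's precede all q's
                raise MalformedMapError(f"q-arm band precedes p-arm band on chromosome {chrom}")

    def _assign_snps(self, snps: pd.DataFrame) -> pd.DataFrame:
        snps = snps.reset_index(drop=True).copy()
        required = {"snp_id", "chrom", "pos"}
        if not required.issubset(snps.columns):
            raise ValueError(f"SNP table needs columns {sorted(required)}")
        snps["chrom"] = snps["chrom"].astype(str).map(normalize_chrom)
        order = {c: i for i, c in enumerate(AUTOSOMES)}
        bad = set(snps["chrom"]) - set(order)
        if bad:
            raise ValueError(f"SNPs on chromosomes absent from map: {sorted(bad)}")
        snps["_ckey"] = snps["chrom"].map(order)
        snps = snps.sort_values(["_ckey", "pos"], kind="stable").drop(columns="_ckey")
        snps = snps.reset_index(drop=True)
        band_idx = np.empty(len(snps), dtype=int)
        for chrom, sub in snps.groupby("chrom", sort=False):
            cb = self.bands[self.bands["chrom"] == chrom]
            if cb.empty:
                raise ValueError(f"no cytobands for chromosome {chrom}")
            starts = cb["start"].to_numpy()
            end = int(cb["end"].iloc[-1])
            pos = sub["pos"].to_numpy()
            if np.any(pos < 0) or np.any(pos >= end):
                off = sub["snp_id"].iloc[int(np.argmax((pos < 0) | (pos >= end)))]
                raise ValueError(
                    f"SNP {off!r} at position outside any cytoband on chromosome {chrom}"
                )
            band_idx[sub.index] = cb.index[np.searchsorted(starts, pos, side="right") - 1]
        snps["band_idx"] = band_idx
        return snps

    # -- accessors ------------------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bands["chrom"]))

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def band_names(self) -> list[str]:
        return self.bands["name"].tolist()

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def arm_ids(self) -> list[str]:
        """Arm identifiers like ``"1p"`` in genome order."""
        ids = self.bands["chrom"].str.cat(self.bands["arm"])
        return list(dict.fromkeys(ids))

    def band_index(self, name: str) -> int:
        try:
            return self._band_index[name]
        except KeyError:
            raise KeyError(f"unknown cytoband {name!r}") from None

    def arm_band_indices(self, arm_id: str) -> np.ndarray:
        """Genome-order indices of the bands on an arm like ``"3p"``."""
        mask = (self.bands["chrom"] + self.bands["arm"]) == arm_id
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown chromosome arm {arm_id!r}")
        return idx

    def chrom_band_indices(self, chrom: str) -> np.ndarray:
        idx = np.flatnonzero((self.bands["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return idx

    def band_snp_indices(self, band_idx: int) -> np.ndarray:
        """Row positions (into the SNP axis) of one band's SNPs."""
        col = self.snps["band_idx"].to_numpy()
        lo = np.searchsorted(col, band_idx, side="left")
        hi = np.searchsorted(col, band_idx, side="right")
        return np.arange(lo, hi)

    def band_snp_counts(self) -> np.ndarray:
        """SNP count per band, in genome order."""
        counts = np.zeros(self.n_bands, dtype=int)
        vals, n = np.unique(self.snps["band_idx"].to_numpy(), return_counts=True)
        counts[vals] = n
        return counts

    def chrom_snp_slices(self) -> list[tuple[str, slice]]:
        """Contiguous SNP-axis slice per chromosome, in genome order."""
        col = self.snps["chrom"].to_numpy()
        out = []
        for chrom in self.chromosomes:
            idx = np.flatnonzero(col == chrom)
            if idx.size:
                out.append((chrom, slice(int(idx[0]), int(idx[-1]) + 1)))
        return out

    def with_snps(self, snps: pd.DataFrame) -> "GenomeMap":
        """Return a copy of this map bound to the given SNP loci."""
        return GenomeMap(self.bands, snps)

    def __repr__(self) -> str:
        return (
            f"GenomeMap({len(self.chromosomes)} chromosomes, "
            f"{self.n_bands} cytobands, {self.n_snps} SNPs)"
        )


# -- readers / writers --------------------------------------------------------


def read_cytoband_file(path) -> GenomeMap:
    """Parse a UCSC ``cytoBand.txt``-dialect file into a :class:`GenomeMap`.

    Expects >=4 tab-separated columns (chrom, start, end, band name);
    coordinates 0-based half-open.  Bands are renamed ``chrom + band``
    (``chr3  ...  p25`` -> ``"3p25"``); chrX/chrY and other non-autosomal
    rows are dropped with a warning.
    """
    rows = []
    dropped = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise MalformedMapError(f"line {lineno}: fewer than 4 tab-separated columns")
            chrom = normalize_chrom(parts[0])
            if chrom not in AUTOSOMES:
                dropped.add(chrom)
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise MalformedMapError(f"line {lineno}: non-integer coordinates") from None
            band = parts[3]
            if not band or band[0] not in ("p", "q"):
                raise MalformedMapError(
                    f"line {lineno}: band name {band!r} does not start with p or q"
                )
            if end <= start:
                raise MalformedMapError(f"line {lineno}: band end <= start")
            rows.append((chrom, start, end, chrom + band, band[0]))
    if dropped:
        log.warning("dropped non-autosomal chromosomes from cytoband file: %s", sorted(dropped))
    if not rows:
        raise MalformedMapError("no autosomal cytobands in file")
    bands = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "arm"])
    order = {c: i for i, c in enumerate(AUTOSOMES)}
    # stable sort by chromosome only: within-chromosome file order is validated,
    # not silently repaired
    bands["_ckey"] = bands["chrom"].map(order)
    bands = bands.sort_values("_ckey", kind="stable").drop(columns="_ckey")
    return GenomeMap(bands)


def read_profile_matrix(path, genome: GenomeMap) -> tuple[GenomeMap, list[SNPProfile]]:
    """Read a SNP x sample log2-ratio matrix (TSV).

    Columns: ``snp_id``, ``chrom``, ``pos``, then one column per sample.
    Rows in any order; they are normalized to genome order.  Returns the
    genome bound to these loci, and one :class:`SNPProfile` per sample.
    Missing values are an error (imputation is out of scope).
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str},
                     float_precision="round_trip")
    required = ["snp_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"profile matrix must start with columns {required}")
    sample_cols = list(df.columns[3:])
    if not sample_cols:
        raise ValueError("profile matrix has no sample columns")
    for col in sample_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            snp = df["snp_id"].iloc[int(vals.isna().idxmax())]
            raise ValueError(f"missing or non-numeric value for SNP {snp!r}, sample {col!r}")
        df[col] = vals
    if df["snp_id"].duplicated().any():
        raise ValueError("duplicate SNP identifiers in profile matrix")
    bound = genome.with_snps(df[["snp_id", "chrom", "pos"]])
    # reorder sample values to the normalized genome order
    df = df.set_index("snp_id").loc[bound.snps["snp_id"]]
    profiles = [SNPProfile(c, df[c].to_numpy(dtype=float)) for c in sample_cols]
    return bound, profiles


def write_profile_matrix(profiles, genome: GenomeMap, path) -> None:
    """Write profiles (raw or smoothed) in the profile-matrix TSV dialect."""
    out = genome.snps[["snp_id", "chrom", "pos"]].copy()
    for p in profiles:
        if len(p) != genome.n_snps:
            raise ValueError(f"profile {p.sample_id!r} length mismatch with genome")
        out[p.sample_id] = p.values
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_score_matrix(scores: pd.DataFrame, path) -> None:
    """Write a samples x cytobands score matrix losslessly to TSV."""
    if scores.columns.duplicated().any():
        raise ValueError("duplicate cytoband names in score matrix")
    if scores.size and not np.all(np.isfinite(scores.to_numpy(dtype=float))):
        raise ValueError("score matrix contains NaN or infinite values")
    scores.to_csv(path, sep="\t", index=True, index_label="sample_id", float_format="%.17g")


def read_score_matrix(path) -> pd.DataFrame:
    """Read back a score matrix written by :func:`write_score_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id",
                     float_precision="round_trip")
    if df.columns.duplicated().any():
        raise ValueError("duplicate cytoband names in score matrix")
    df.index = df.index.astype(str)
    df.index.name = None
    return df.astype(float)


def read_annotation_table(path) -> pd.DataFrame:
    """Read a sample annotation TSV and validate the closed category sets."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    if "sample_id" not in df.columns:
        raise ValueError("annotation table needs a sample_id column")
    if "subtype" in df.columns:
        bad = set(df["subtype"]) - SUBTYPES - {"unknown"}
        if bad:
            raise ValueError(f"unknown subtypes: {sorted(bad)}")
    if "stage" in df.columns:
        bad = set(df["stage"]) - STAGES
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
    return df


def write_annotation_table(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_survival_table(path) -> pd.DataFrame:
    """Read a survival TSV: sample_id, duration_days, event (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "duration_days", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    if (df["duration_days"] < 0).any():
        raise ValueError("negative survival duration")
    df["event"] = df["event"].astype(int).astype(bool)
    return df


def write_survival_table(survival: pd.DataFrame, path) -> None:
    out = survival.copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, sep="\t", index=False)
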