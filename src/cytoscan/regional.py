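"""Cytoband-level signed alteration scores (regional-bias summarization).

For every sample and every cytoband, the smoothed per-SNP statistics in
the band are collapsed to one signed score: positive = gain, negative =
loss, magnitude = strength of evidence.  Two summarization tests are
provided:

``"t"`` (default)
    one-sample t-statistic of the band's smoothed values against 0.
``"binomial"``
    signed z from a sign test: ``(n_pos - n/2) / sqrt(n/4)`` where ``n``
    counts nonzero values and ``n_pos`` those > 0 (zeros carry no sign
    information; an all-zero band scores 0).

Bands with fewer than ``min_snps`` SNPs are merged into their neighbor
toward the centromere before scoring, so every emitted score rests on at
least two SNPs.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .genome import GenomeMap
from .smoothing import _t_stat

log = logging.getLogger(__name__)


def _merged_band_structure(genome: GenomeMap, min_snps: int):
    """Band names and SNP-index arrays after merging small bands.

    Within each arm, a band with fewer than ``min_snps`` SNPs donates its
    SNPs to its neighbor toward the centromere (next band on p, previous
    band on q); if none exists, to its only other neighbor.  The receiving
    band keeps its name.
    """
    names, snp_sets = [], []
    for arm_id in genome.arm_ids:
        idx = genome.arm_band_indices(arm_id)
        arm_names = [genome.band_names[i] for i in idx]
        arm_snps = [genome.band_snp_indices(i) for i in idx]
        toward_centromere = 1 if arm_id.endswith("p") else -1
        changed = True
        while changed and len(arm_names) > 1:
            changed = False
            for j in range(len(arm_names)):
                if len(arm_snps[j]) < min_snps:
                    k = j + toward_centromere
                    if not 0 <= k < len(arm_names):
                        k = j - toward_centromere
                    log.info("merging cytoband %s into %s (<%d SNPs)",
                             arm_names[j], arm_names[k], min_snps)
                    arm_snps[k] = np.union1d(arm_snps[k], arm_snps[j])
                    del arm_names[j], arm_snps[j]
                    changed = True
                    break
        if len(arm_names) == 1 and len(arm_snps[0]) < min_snps:
            raise ValueError(
                f"arm {arm_id} has fewer than {min_snps} SNPs even after merging"
            )
        names.extend(arm_names)
        snp_sets.extend(np.sort(s) for s in arm_snps)
    return names, snp_sets


class CytobandSummarizer(TransformerMixin, BaseEstimator):
    """Transform smoothed SNP matrices into per-cytoband score matrices.

    ``transform`` accepts a (n_samples, n_snps) array or DataFrame and
    returns a DataFrame of shape (n_samples, n_bands) with cytoband
    columns in genome order and ``.attrs["method"]`` recording the test.
    """

    def __init__(self, genome: GenomeMap | None = None, method: str = "t",
                 min_snps: int = 2, zero_variance_cap: float = 50.0):
        self.genome = genome
        self.method = method
        self.min_snps = min_snps
        self.zero_variance_cap = zero_variance_cap

    def fit(self, X=None, y=None):
        if self.genome is None:
            raise ValueError("CytobandSummarizer requires a genome")
        if self.method not in ("t", "binomial"):
            raise ValueError("method must be 't' or 'binomial'")
        self.band_names_, self.band_snps_ = _merged_band_structure(self.genome, self.min_snps)
        self.n_features_in_ = self.genome.n_snps
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "band_names_"):
            self.fit()
        index = X.index if isinstance(X, pd.DataFrame) else None
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} SNPs, got {X.shape[1]}")
        cols = {}
        for name, snps in zip(self.band_names_, self.band_snps_):
            band = X[:, snps]
            if self.method == "t":
                cols[name] = _t_stat(band.mean(axis=1), band.std(axis=1, ddof=1),
                                     band.shape[1], self.zero_variance_cap)
            else:
                n_pos = (band > 0).sum(axis=1)
                n_neg = (band < 0).sum(axis=1)
                n = n_pos + n_neg
                with np.errstate(divide="ignore", invalid="ignore"):
                    z = (n_pos - n / 2.0) / np.sqrt(n / 4.0)
                cols[name] = np.where(n == 0, 0.0, z)
        out = pd.DataFrame(cols, index=index)
        out.attrs["method"] = self.method
        return out


def summarize_cytobands(smoothed, genome: GenomeMap, method: str = "t") -> pd.DataFrame:
    """Score a list of smoothed profiles; rows indexed by sample id."""
    summ = CytobandSummarizer(genome, method=method).fit()
    X = pd.DataFrame(
        np.vstack([p.values for p in smoothed]),
        index=[p.sample_id for p in smoothed],
    )
    return summ.transform(X)


def score_iqr(scores: pd.DataFrame, cytoband: str | None = None):
    """Cross-sample interquartile range of cytoband scores.

    Quartiles use linear interpolation between order statistics (the
    "type 7" rule).  With ``cytoband=None`` returns a Series over all
    bands.  Requires at least 2 samples.
    """
    if len(scores) < 2:
        raise ValueError("IQR requires at least 2 samples")
    q1, q3 = np.percentile(scores.to_numpy(dtype=float), [25, 75], axis=0)
    iqr = pd.Series(q3 - q1, index=scores.columns)
    return float(iqr[cytoband]) if cytoband is not None else iqr
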