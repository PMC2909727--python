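"""Moving-window t-statistic smoothing of per-SNP log2 ratios.

Copy-number alterations are segmental, so neighboring SNPs share the same
underlying copy number.  Each raw log2 ratio is therefore replaced by the
one-sample t-statistic of the values in a window centered on it, tested
against 0 (the diploid log2 ratio):

    t_i = mean(W_i) / (sd(W_i) / sqrt(|W_i|))

Windows are restricted to the SNP's own chromosome.  Near a chromosome
end the window shrinks symmetrically, but never below ``min_window``: when
the symmetric window would be smaller, it is extended asymmetrically
within the chromosome instead.  A zero-variance window maps to 0 when its
mean is 0 and to ``sign(mean) * zero_variance_cap`` otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .genome import GenomeMap, SmoothedProfile, SNPProfile


@dataclass(frozen=True)
class SmoothingConfig:
    window_snps: int = 31
    zero_variance_cap: float = 50.0
    min_window: int = 5

    def __post_init__(self):
        if self.window_snps < 3 or self.window_snps % 2 == 0:
            raise ValueError("window_snps must be an odd integer >= 3")
        if self.min_window < 3 or self.min_window % 2 == 0:
            raise ValueError("min_window must be an odd integer >= 3")
        if self.min_window > self.window_snps:
            raise ValueError("min_window must not exceed window_snps")
        if self.zero_variance_cap <= 0:
            raise ValueError("zero_variance_cap must be positive")


def _t_stat(mean: np.ndarray, sd: np.ndarray, n, cap: float) -> np.ndarray:
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    sd = np.atleast_1d(np.asarray(sd, dtype=float))
    out = np.empty_like(mean)
    zero = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out[~zero] = mean[~zero] / (sd[~zero] / np.sqrt(np.broadcast_to(n, mean.shape)[~zero]))
    out[zero] = np.sign(mean[zero]) * cap
    return out


def _smooth_chromosome(values: np.ndarray, cfg: SmoothingConfig) -> np.ndarray:
    n = len(values)
    w, h = cfg.window_snps, cfg.window_snps // 2
    out = np.empty(n)
    if n >= w:
        sw = sliding_window_view(values, w)
        out[h:n - h] = _t_stat(sw.mean(axis=1), sw.std(axis=1, ddof=1), w, cfg.zero_variance_cap)
        edge = [i for i in range(n) if i < h or i > n - 1 - h]
    else:
        edge = range(n)
    for i in edge:
        half = min(i, n - 1 - i, h)
        if 2 * half + 1 >= cfg.min_window:
            win = values[i - half:i + half + 1]
        else:  # asymmetric extension within the chromosome
            lo = min(max(i - cfg.min_window // 2, 0), n - cfg.min_window)
            win = values[lo:lo + cfg.min_window]
        out[i] = _t_stat(win.mean(), win.std(ddof=1), len(win), cfg.zero_variance_cap)[0]
    return out


class MovingTSmoother(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer applying moving-t smoothing per sample.

    Parameters
    ----------
    genome : GenomeMap
        Coordinate backbone; windows never span a chromosome boundary.
    window_snps : int, default 31
        Target (odd) window width in SNPs.
    zero_variance_cap : float, default 50
        Output magnitude for zero-variance, nonzero-mean windows.
    min_window : int, default 5
        Minimum (odd) window width at chromosome ends.
    """

    def __init__(self, genome: GenomeMap | None = None, window_snps: int = 31,
                 zero_variance_cap: float = 50.0, min_window: int = 5):
        self.genome = genome
        self.window_snps = window_snps
        self.zero_variance_cap = zero_variance_cap
        self.min_window = min_window

    def _config(self) -> SmoothingConfig:
        return SmoothingConfig(self.window_snps, self.zero_variance_cap, self.min_window)

    def fit(self, X=None, y=None):
        if self.genome is None:
            raise ValueError("MovingTSmoother requires a genome")
        cfg = self._config()
        for chrom, sl in self.genome.chrom_snp_slices():
            if sl.stop - sl.start < cfg.min_window:
                raise ValueError(
                    f"chromosome {chrom} has fewer than min_window={cfg.min_window} SNPs"
                )
        self.n_features_in_ = self.genome.n_snps
        self.chrom_slices_ = self.genome.chrom_snp_slices()
        return self

    def transform(self, X) -> np.ndarray:
        """Smooth a (n_samples, n_snps) matrix row by row."""
        if not hasattr(self, "chrom_slices_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} SNPs, got {X.shape[1]}"
            )
        cfg = self._config()
        out = np.empty_like(X)
        for _, sl in self.chrom_slices_:
            for row in range(X.shape[0]):
                out[row, sl] = _smooth_chromosome(X[row, sl], cfg)
        return out[0] if squeeze else out


def moving_t_smooth(
    profile: SNPProfile, genome: GenomeMap, config: SmoothingConfig | None = None
) -> SmoothedProfile:
    """Smooth a single profile; thin wrapper over :class:`MovingTSmoother`."""
    cfg = config or SmoothingConfig()
    sm = MovingTSmoother(genome, cfg.window_snps, cfg.zero_variance_cap, cfg.min_window).fit()
    if len(profile) != genome.n_snps:
        raise ValueError("profile is not aligned to the genome map")
    return SmoothedProfile(profile.sample_id, sm.transform(profile.values))


def smooth_profiles(
    profiles, genome: GenomeMap, config: SmoothingConfig | None = None
) -> list[SmoothedProfile]:
    cfg = config or SmoothingConfig()
    sm = MovingTSmoother(genome, cfg.window_snps, cfg.zero_variance_cap, cfg.min_window).fit()
    X = np.vstack([p.values for p in profiles])
    S = sm.transform(X)
    return [SmoothedProfile(p.sample_id, S[i]) for i, p in enumerate(profiles)]
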