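"""Nuclear-area distributions and departure from Gaussianity.

Control brain tissue shows a tight, nearly Gaussian distribution of
nuclear area; infiltrating gliomas show wider, more erratic
distributions (regional heterogeneity plus pleomorphism).  This module
builds per-sample area histograms, overlays the Gaussian model implied
by a group's mean and SD, and scores the departure from Gaussianity.

The deviation score uses the Kolmogorov-Smirnov distance against a
Normal fitted to the same data, scaled by sqrt(n): the raw KS distance
shrinks as 1/sqrt(n), so samples with different nucleus counts would not
be comparable, whereas the scaled statistic is asymptotically
sample-size-free under the null.  Because the parameters are estimated,
the plain KS P value is anticonservative; the Lilliefors-corrected P
value is reported and labelled approximate.  Two descriptive ratios
accompany it: observed peak height over the Gaussian peak, and observed
range over the mean +/- 3 SD span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .config import InvalidParameterError
from .stats import InsufficientDataError

DEFAULT_BIN_WIDTH_UM2 = 5.0

#: Minimum nuclei for a meaningful normality score.
MIN_DEVIATION_N = 20


@dataclass
class AreaDistribution:
    """Observed and Gaussian-expected counts over uniform area bins."""

    bin_edges: np.ndarray
    observed_counts: np.ndarray
    expected_counts: np.ndarray
    n: int
    mean: float
    sd: float


@dataclass
class DeviationScore:
    """Departure of an area sample from its fitted Gaussian."""

    statistic: float        # sqrt(n) * KS distance vs fitted Normal
    p_value: float          # Lilliefors-corrected, approximate
    peak_height_ratio: float  # observed max bin count / Gaussian peak count
    range_ratio: float        # observed range / (6 * sd)
    n: int


def gaussian_expected_counts(mean: float, sd: float, n: int,
                             bin_edges) -> np.ndarray:
    """Expected bin counts of Normal(mean, sd) scaled to ``n`` nuclei.

    Per bin: ``n * (Phi((hi - mean)/sd) - Phi((lo - mean)/sd))``.
    """
    if sd <= 0:
        raise InvalidParameterError("sd must be > 0 for the Gaussian model")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    edges = np.asarray(bin_edges, dtype=float)
    cdf = sps.norm.cdf(edges, loc=mean, scale=sd)
    return n * np.diff(cdf)


def area_histogram(areas, bin_width: float = DEFAULT_BIN_WIDTH_UM2,
                   bin_range: tuple[float, float] | None = None,
                   ) -> AreaDistribution:
    """Histogram of nuclear areas over uniform left-closed bins.

    The default range spans the data padded outward to bin-width
    boundaries.  Expected counts come from the Gaussian fitted to the
    same areas (all zeros when the sample SD is zero).
    """
    a = np.asarray(areas, dtype=float)
    if a.size == 0:
        raise InsufficientDataError("no areas to histogram")
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be > 0")
    if bin_range is None:
        lo = np.floor(a.min() / bin_width) * bin_width
        hi = np.ceil(a.max() / bin_width) * bin_width
        if hi == lo:
            hi = lo + bin_width
    else:
        lo, hi = bin_range
        if hi <= lo:
            raise InvalidParameterError("empty bin range")
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    # left-closed/right-open bins: exclude points at/after the last edge
    idx = np.floor((a - lo) / bin_width).astype(int)
    valid = (idx >= 0) & (idx < n_bins)
    observed = np.bincount(idx[valid], minlength=n_bins)
    mean = float(a.mean())
    sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
    if sd > 0:
        expected = gaussian_expected_counts(mean, sd, a.size, edges)
    else:
        expected = np.zeros(n_bins)
    return AreaDistribution(bin_edges=edges, observed_counts=observed,
                           expected_counts=expected, n=int(a.size),
                           mean=mean, sd=sd)


def gaussian_deviation(areas, bin_width: float = DEFAULT_BIN_WIDTH_UM2,
                       ) -> DeviationScore:
    """Score the departure of an area sample from Gaussianity.

    Requires >= 20 areas with nonzero spread.  The statistic is
    ``sqrt(n)`` times the KS distance against the fitted Normal, so
    scores are comparable across samples with different nucleus counts;
    the P value is the Lilliefors approximation (parameters estimated
    from the data).
    """
    a = np.asarray(areas, dtype=float)
    if a.size < MIN_DEVIATION_N:
        raise InsufficientDataError(
            f"need >= {MIN_DEVIATION_N} areas (got {a.size})")
    sd = float(a.std(ddof=1))
    if sd == 0:
        raise InvalidParameterError("zero variance: Gaussian model undefined")
    ks_dist, pval = lilliefors(a, dist="norm", pvalmethod="table")
    stat = np.sqrt(a.size) * ks_dist
    dist = area_histogram(a, bin_width=bin_width)
    gauss_peak = a.size * bin_width / (sd * np.sqrt(2.0 * np.pi))
    return DeviationScore(
        statistic=float(stat), p_value=float(pval),
        peak_height_ratio=float(dist.observed_counts.max() / gauss_peak),
        range_ratio=float(np.ptp(a) / (6.0 * sd)),
        n=int(a.size),
    )


def group_gaussian_curves(group_stats: dict[str, tuple[float, float]],
                          n: int = 100,
                          bin_width: float = DEFAULT_BIN_WIDTH_UM2,
                          bin_range: tuple[float, float] | None = None,
                          ) -> dict[str, AreaDistribution]:
    """Gaussian model curves per group from (mean, sd), for ``n`` nuclei.

    Emulates the group-level model overlay: each group's curve uses its
    own mean and SD.  A common bin range covering every group's mean
    +/- 4 SD is used unless one is given.
    """
    if bin_range is None:
        lo = min(m - 4 * s for m, s in group_stats.values())
        hi = max(m + 4 * s for m, s in group_stats.values())
        lo = np.floor(max(lo, 0.0) / bin_width) * bin_width
        hi = np.ceil(hi / bin_width) * bin_width
    else:
        lo, hi = bin_range
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    out = {}
    for group, (mean, sd) in group_stats.items():
        expected = gaussian_expected_counts(mean, sd, n, edges)
        out[group] = AreaDistribution(
            bin_edges=edges, observed_counts=np.zeros(n_bins, dtype=int),
            expected_counts=expected, n=n, mean=float(mean), sd=float(sd))
    return out
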