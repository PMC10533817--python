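"""Per-window profiles: coverage binning, LOESS GC correction, bin filters,
baseline z-scores, quantile normalization.

A :class:`BinProfile` is a numeric vector aligned to a
:class:`~themis.intervals.WindowSet`, with a per-window validity mask;
masked windows are excluded from every statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from themis.fragments import SampleFragments
from themis.intervals import WindowSet
from themis.reference import assign_to_windows


@dataclass
class BinProfile:
    """Numeric vector over the windows of one WindowSet."""

    values: np.ndarray
    mask: np.ndarray  # True = valid
    window_set_ref: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(
            {"window_index": np.arange(len(self.values)),
             "value": self.values,
             "mask": self.mask.astype(int)}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, window_set_ref: str = "") -> "BinProfile":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(df["value"].to_numpy(), df["mask"].to_numpy(bool), window_set_ref)


@dataclass
class BaselineStats:
    """Per-window mean/sd over a healthy baseline cohort, plus the bin mask
    derived from the stability filters."""

    mean: np.ndarray
    sd: np.ndarray
    n_baseline: int
    bin_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.bin_mask is None:
            self.bin_mask = np.ones_like(self.mean, dtype=bool)
        self.bin_mask = np.asarray(self.bin_mask, dtype=bool)
        if (self.sd[~np.isnan(self.sd)] < 0).any():
            raise ValueError("baseline sd must be non-negative")


def bin_coverage(
    sample: SampleFragments,
    bins: WindowSet,
    size_gate: Callable[[np.ndarray], np.ndarray] | None = None,
) -> BinProfile:
    """Count fragments per window by midpoint, after an optional length gate.

    ``size_gate`` is a vectorized predicate over fragment lengths (e.g. the
    aneuploidy gate ``lambda L: (L < 151) | (L > 220)``). Fragments are
    never split: each belongs to the single window containing its midpoint.
    """
    counts = np.zeros(len(bins), dtype=float)
    if sample.n_total:
        lengths = sample.lengths
        keep = size_gate(lengths) if size_gate is not None else np.ones(len(lengths), bool)
        chroms = sample.df["chrom"].to_numpy()[keep]
        mids = sample.midpoints[keep]
        widx = assign_to_windows(bins, chroms, mids)
        widx = widx[widx >= 0]
        np.add.at(counts, widx, 1.0)
    return BinProfile(counts, np.ones(len(bins), bool), window_set_ref=bins.provenance)


def loess_gc_correct(
    profile: BinProfile, gc: np.ndarray, span: float = 0.75
) -> BinProfile:
    """Remove GC-dependent trend from a bin profile by LOESS.

    Fits a locally weighted regression of value on GC fraction over the
    unmasked bins and returns residual + grand mean; the unmasked mean is
    preserved exactly (the residuals are recentred), satisfying the ≤1e-9
    relative contract. Masked bins pass through unchanged.
    """
    gc = np.asarray(gc, dtype=float)
    m = profile.mask & np.isfinite(gc) & np.isfinite(profile.values)
    if m.sum() == 0:
        raise ValueError("all bins masked; cannot GC-correct")
    if m.sum() < 10:
        raise ValueError(f"need >=10 unmasked bins for GC correction, got {int(m.sum())}")
    x, y = gc[m], profile.values[m]
    raw_mean = y.mean()
    if np.ptp(x) == 0:
        fitted = np.full_like(y, raw_mean)
    else:
        sm = lowess(y, x, frac=span, return_sorted=True)
        fitted = np.interp(x, sm[:, 0], sm[:, 1])
    corrected = y - fitted
    corrected += raw_mean - corrected.mean()
    out = profile.values.copy()
    out[m] = corrected
    return BinProfile(out, profile.mask.copy(), profile.window_set_ref)


def baseline_bin_filter(
    baseline_profiles: np.ndarray,
    z_soft: float = 2.0,
    soft_count: int | None = None,
    z_hard: float = 4.0,
) -> np.ndarray:
    """Mask out bins that are unstable across healthy baseline samples.

    Per bin, z-scores are computed across the baseline cohort; a bin is
    dropped if |z| > ``z_soft`` in more than ``soft_count`` samples or
    |z| > ``z_hard`` in any sample. ``soft_count`` defaults to
    round(0.17 · n_baseline), generalizing the published absolute count
    (60 of 352) to a fraction so small cohorts behave sensibly. Bins with
    zero variance are dropped as degenerate.

    Returns a boolean keep-mask over bins.
    """
    X = np.asarray(baseline_profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a samples x bins matrix with >=2 baseline samples")
    n = X.shape[0]
    if soft_count is None:
        soft_count = int(round(0.17 * n))
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs((X - mu) / sd)
    soft_hits = (z > z_soft).sum(axis=0)
    hard_hits = (z > z_hard).any(axis=0)
    keep &= ~(soft_hits > soft_count)
    keep &= ~hard_hits
    return keep


def also_filter_zero_after_correction(
    raw: BinProfile, corrected: BinProfile, raw_threshold: float = 100.0
) -> np.ndarray:
    """Keep-mask dropping bins with high raw coverage but none left after
    GC correction (raw > 100 and corrected <= 0)."""
    if len(raw) != len(corrected):
        raise ValueError("profiles not aligned")
    return ~((raw.values > raw_threshold) & (corrected.values <= 0))


def zscore_vs_baseline(profile: BinProfile, baseline: BaselineStats) -> BinProfile:
    """Per-window z = (value − baseline mean) / baseline sd; windows with
    zero baseline sd (or masked by the baseline) come back masked."""
    if len(profile) != len(baseline.mean):
        raise ValueError("profile and baseline not aligned")
    ok = profile.mask & baseline.bin_mask & (baseline.sd > 0)
    z = np.full(len(profile), np.nan)
    z[ok] = (profile.values[ok] - baseline.mean[ok]) / baseline.sd[ok]
    return BinProfile(z, ok, profile.window_set_ref)


def quantile_normalize_to_reference(
    sample_values: np.ndarray, reference_values: np.ndarray
) -> np.ndarray:
    """Map a sample vector onto a pooled-reference distribution by rank.

    The sample value at fractional rank r is replaced by the reference
    quantile at r (linear interpolation between reference order statistics);
    ties get average ranks and therefore tied outputs. A constant sample
    maps entirely to the reference median.
    """
    s = np.asarray(sample_values, dtype=float)
    ref = np.sort(np.asarray(reference_values, dtype=float))
    if s.size == 0 or ref.size == 0:
        raise ValueError("empty input")
    ranks = rankdata(s, method="average")
    frac = (ranks - 1) / max(len(s) - 1, 1) if len(s) > 1 else np.full(1, 0.5)
    if np.ptp(s) == 0:
        frac = np.full(len(s), 0.5)
    return np.quantile(ref, frac, method="linear")


def build_baseline(
    baseline_matrix: np.ndarray,
    z_soft: float = 2.0,
    soft_count: int | None = None,
    z_hard: float = 4.0,
) -> BaselineStats:
    """Baseline mean/sd plus the stability bin-mask from a samples x bins
    matrix of GC-corrected coverage."""
    X = np.asarray(baseline_matrix, dtype=float)
    mask = baseline_bin_filter(X, z_soft=z_soft, soft_count=soft_count, z_hard=z_hard)
    if not mask.any():
        warnings.warn("baseline filter dropped every bin")
    return BaselineStats(
        mean=X.mean(axis=0), sd=X.std(axis=0, ddof=1), n_baseline=X.shape[0], bin_mask=mask
    )
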