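"""The four per-sample cfDNA feature modalities.

* **MFR** (methylated fragment ratio) — per 1-Mb window, the fraction of
  QC-passing fragments whose observed CpGs are all methylated. Tumor
  genomes are globally hypomethylated, so MFR drops in cancer.
* **FSI** (fragment size index) — per 5-Mb window, the GC-corrected ratio
  of short (100–166 bp) to long (169–240 bp) fragment counts, z-scored
  across the genome. Tumor-derived fragments run short.
* **CAFF** (chromosomal aneuploidy of featured fragments) — arm-level
  copy-number z-scores computed on size-selected fragments (<151 bp or
  >220 bp, which are enriched for tumor molecules), summarized as the
  plasma aneuploidy (PA) score over the five most altered arms.
* **FEM** (fragment end motif) — the frequency vector of the 256 possible
  4-mers at the Crick-strand 5′ fragment end, over fragments <171 bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from themis.fragments import SampleFragments
from themis.intervals import ArmSet, WindowSet
from themis.profiles import BinProfile, bin_coverage, loess_gc_correct
from themis.reference import assign_to_windows

#: The 4-mer end-motif vocabulary, in lexicographic order (AAAA … TTTT).
MOTIFS_4MER: tuple[str, ...] = tuple("".join(p) for p in product("ACGT", repeat=4))
_MOTIF_INDEX = {m: i for i, m in enumerate(MOTIFS_4MER)}


@dataclass(frozen=True)
class SizeGates:
    """Fragment-length gates of the four modalities (bp).

    ``short_range``/``long_range`` are inclusive on both ends ("within
    100–166 bp"); the aneuploidy gate is strict ("shorter than 151 bp or
    longer than 220 bp"), as is the end-motif gate ("shorter than 171 bp");
    the methylation gate is inclusive ("between 80 and 250 bp").
    """

    short_range: tuple[int, int] = (100, 166)
    long_range: tuple[int, int] = (169, 240)
    caff_short_max: int = 150  # length <= 150, i.e. < 151
    caff_long_min: int = 221  # length >= 221, i.e. > 220
    fem_max: int = 170  # length <= 170, i.e. < 171
    mfr_range: tuple[int, int] = (80, 250)

    def __post_init__(self) -> None:
        if self.short_range[1] >= self.long_range[0]:
            raise ValueError("short and long ranges must be disjoint")

    def is_short(self, lengths: np.ndarray) -> np.ndarray:
        lo, hi = self.short_range
        return (lengths >= lo) & (lengths <= hi)

    def is_long(self, lengths: np.ndarray) -> np.ndarray:
        lo, hi = self.long_range
        return (lengths >= lo) & (lengths <= hi)

    def caff_gate(self, lengths: np.ndarray) -> np.ndarray:
        return (lengths <= self.caff_short_max) | (lengths >= self.caff_long_min)

    def fem_gate(self, lengths: np.ndarray) -> np.ndarray:
        return lengths <= self.fem_max

    def mfr_gate(self, lengths: np.ndarray) -> np.ndarray:
        lo, hi = self.mfr_range
        return (lengths >= lo) & (lengths <= hi)


DEFAULT_GATES = SizeGates()


@dataclass
class ModalityFeatureSet:
    """Per-sample feature vectors of the four modalities."""

    mfr: np.ndarray  # per 1-Mb window, fraction in [0,1] or NaN
    fsi: np.ndarray  # per 5-Mb window, z-scored genome-wide
    fem: np.ndarray  # 256 motif frequencies summing to 1 (or all zero)
    pa_score: float
    caff_log10: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.mfr = np.asarray(self.mfr, float)
        self.fsi = np.asarray(self.fsi, float)
        self.fem = np.asarray(self.fem, float)
        finite = self.mfr[np.isfinite(self.mfr)]
        if finite.size and ((finite < 0) | (finite > 1)).any():
            raise ValueError("MFR entries must lie in [0, 1]")
        if self.fem.shape != (256,):
            raise ValueError("FEM vector must have length 256")
        if self.pa_score < 0:
            raise ValueError("PA score must be non-negative")


def size_frequency_test(
    cancer_size_freqs: np.ndarray,
    healthy_size_freqs: np.ndarray,
    sizes: Sequence[int],
    alpha: float = 0.01,
) -> set[int]:
    """Select fragment sizes differentially represented between cohorts.

    Per size, a one-sided Wilcoxon rank-sum test is run in both directions
    (cancer > healthy and cancer < healthy) and the smaller p-value is
    used; sizes with p < ``alpha`` are returned. This is the screen that
    motivates the short/long size classes (most sizes in 50–300 bp differ
    except near the nucleosomal mode and the long tail).
    """
    C = np.asarray(cancer_size_freqs, float)
    H = np.asarray(healthy_size_freqs, float)
    if C.shape[0] < 3 or H.shape[0] < 3:
        raise ValueError("need >=3 samples per group")
    if C.shape[1] != H.shape[1] or C.shape[1] != len(sizes):
        raise ValueError("frequency matrices not aligned with sizes")
    if alpha <= 0:
        return set()
    selected: set[int] = set()
    for j, size in enumerate(sizes):
        c, h = C[:, j], H[:, j]
        if np.ptp(np.concatenate([c, h])) == 0:
            continue  # identical distributions carry no signal
        p_gt = mannwhitneyu(c, h, alternative="greater").pvalue
        p_lt = mannwhitneyu(c, h, alternative="less").pvalue
        if min(p_gt, p_lt) < alpha:
            selected.add(int(size))
    return selected


def compute_mfr(
    sample: SampleFragments, windows: WindowSet, gates: SizeGates = DEFAULT_GATES
) -> np.ndarray:
    """Methylated fragment ratio per 1-Mb window.

    A fragment qualifies when it covers >=3 CpGs, its length lies in the
    [80, 250] bp range, and its non-CpG cytosine conversion exceeds 95%
    (fragments with no non-CpG observation pass — there is no evidence of
    conversion failure). MFR is the fraction of qualifying fragments whose
    CpGs are all methylated; windows without qualifying fragments are NaN.
    """
    df = sample.df
    lengths = sample.lengths
    nc_t = df["noncpg_c_total"].to_numpy(float)
    nc_c = df["noncpg_c_converted"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        conv_ok = np.where(nc_t > 0, nc_c / np.maximum(nc_t, 1) > 0.95, True)
    qualify = (
        (df["cpg_total"].to_numpy() >= 3)
        & gates.mfr_gate(lengths)
        & conv_ok
    )
    fully = qualify & (
        df["cpg_methylated"].to_numpy() == df["cpg_total"].to_numpy()
    )
    widx = assign_to_windows(
        windows, df["chrom"].to_numpy(), sample.midpoints
    )
    n_qual = np.zeros(len(windows))
    n_full = np.zeros(len(windows))
    ok = (widx >= 0) & qualify
    np.add.at(n_qual, widx[ok], 1.0)
    okf = (widx >= 0) & fully
    np.add.at(n_full, widx[okf], 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mfr = np.where(n_qual > 0, n_full / np.maximum(n_qual, 1), np.nan)
    return mfr


def compute_fsi(
    sample: SampleFragments,
    bins: WindowSet,
    merge_map: Mapping[int, int],
    gc: np.ndarray,
    gates: SizeGates = DEFAULT_GATES,
    span: float = 0.75,
) -> np.ndarray:
    """Fragment size index per merged (5-Mb) window.

    Per 100-kb bin, the short/long count ratio uses a +1 pseudocount on
    both sides so sparse bins stay finite; ratios are LOESS GC-corrected,
    averaged over each merged window's member bins, and the final vector
    is z-scored across the genome (mean 0, sd 1).
    """
    lengths = sample.lengths
    short = bin_coverage(sample, bins, size_gate=gates.is_short).values
    long_ = bin_coverage(sample, bins, size_gate=gates.is_long).values
    ratio = (short + 1.0) / (long_ + 1.0)
    corrected = loess_gc_correct(
        BinProfile(ratio, np.ones(len(bins), bool)), gc, span=span
    ).values

    n_windows = max(merge_map.values()) + 1 if merge_map else 0
    if n_windows < 2:
        raise ValueError("need >=2 merged windows for FSI")
    sums = np.zeros(n_windows)
    counts = np.zeros(n_windows)
    for bin_idx, win_idx in merge_map.items():
        sums[win_idx] += corrected[bin_idx]
        counts[win_idx] += 1
    window_fsi = sums / np.maximum(counts, 1)
    sd = window_fsi.std()
    # guard: an (effectively) flat profile carries no positional signal
    if sd <= 1e-9 * max(1.0, abs(window_fsi.mean())):
        return np.zeros(n_windows)
    return (window_fsi - window_fsi.mean()) / sd


def reference_fsi_profile(healthy_fsi: np.ndarray) -> np.ndarray:
    """Per-window median FSI over healthy controls (the reference profile)."""
    X = np.asarray(healthy_fsi, float)
    if X.ndim == 1:
        return X.copy()
    if X.shape[0] < 1:
        raise ValueError("need at least one healthy sample")
    return np.median(X, axis=0)


def fsi_similarity(sample_fsi: np.ndarray, reference: np.ndarray) -> float:
    """Pearson correlation of a sample's FSI profile with the reference,
    over windows finite in both."""
    a = np.asarray(sample_fsi, float)
    b = np.asarray(reference, float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def pa_score(arm_z: Mapping[str, float], k: int = 5) -> float:
    """Plasma aneuploidy score: sum of |z| over the ``k`` arms with the
    most extreme copy-number z-scores (ties broken by arm label)."""
    if len(arm_z) < k:
        raise ValueError(f"need >={k} arms, got {len(arm_z)}")
    ordered = sorted(arm_z.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    return float(sum(abs(z) for _, z in ordered[:k]))


@dataclass
class CaffBaseline:
    """Arm-level baseline for the size-selected aneuploidy modality:
    the stable-bin mask plus mean/sd of normalized arm totals across the
    healthy baseline cohort."""

    bin_mask: np.ndarray
    arm_labels: list[str]
    arm_mean: np.ndarray
    arm_sd: np.ndarray
    bin_to_arm: dict[int, str] = field(default_factory=dict)


def _arm_membership(bins: WindowSet, arms: ArmSet) -> dict[int, str]:
    """Map bin index → arm label by bin midpoint."""
    out: dict[int, str] = {}
    for w in bins:
        mid = (w.interval.start + w.interval.end) // 2
        label = arms.arm_of(w.interval.chrom, mid)
        if label is not None:
            out[w.index] = label
    return out


def _gated_corrected_coverage(
    sample: SampleFragments,
    bins: WindowSet,
    gc: np.ndarray,
    gates: SizeGates,
    span: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(raw, GC-corrected) size-gated bin coverage for one sample."""
    raw = bin_coverage(sample, bins, size_gate=gates.caff_gate)
    if raw.values.sum() == 0:
        raise ValueError("no fragments pass the aneuploidy size gate")
    corrected = loess_gc_correct(raw, gc, span=span)
    return raw.values, corrected.values


def _arm_totals(
    corrected: np.ndarray, bin_mask: np.ndarray, bin_to_arm: Mapping[int, str],
    arm_labels: Sequence[str],
) -> np.ndarray:
    """Sum retained-bin corrected coverage per arm, normalized to the
    genome-wide retained total (relative coverage, so sequencing depth and
    global size-distribution shifts cancel)."""
    totals = {a: 0.0 for a in arm_labels}
    grand = 0.0
    for bin_idx, arm in bin_to_arm.items():
        if bin_mask[bin_idx] and arm in totals:
            totals[arm] += corrected[bin_idx]
            grand += corrected[bin_idx]
    if grand <= 0:
        raise ValueError("non-positive genome-wide gated coverage")
    return np.array([totals[a] / grand for a in arm_labels])


def build_caff_baseline(
    baseline_samples: Sequence[SampleFragments],
    bins: WindowSet,
    arms: ArmSet,
    gc: np.ndarray,
    gates: SizeGates = DEFAULT_GATES,
    span: float = 0.75,
    soft_count: int | None = None,
) -> CaffBaseline:
    """Fit the healthy baseline for CAFF: size-gated GC-corrected coverage
    per baseline sample, the bin stability filters, and per-arm mean/sd of
    normalized arm totals."""
    from themis.profiles import (
        BinProfile as _BP,
        also_filter_zero_after_correction,
        baseline_bin_filter,
    )

    raws, correcteds = [], []
    for s in baseline_samples:
        r, c = _gated_corrected_coverage(s, bins, gc, gates, span)
        raws.append(r)
        correcteds.append(c)
    X = np.vstack(correcteds)
    mask = baseline_bin_filter(X, soft_count=soft_count)
    for r, c in zip(raws, correcteds):
        mask &= also_filter_zero_after_correction(
            _BP(r, np.ones(len(r), bool)), _BP(c, np.ones(len(c), bool))
        )
    bin_to_arm = _arm_membership(bins, arms)
    arm_labels = [a for a in arms.labels() if any(
        mask[i] for i, lab in bin_to_arm.items() if lab == a
    )]
    dropped = set(arms.labels()) - set(arm_labels)
    if dropped:
        warnings.warn(f"arms with no retained bins skipped: {sorted(dropped)}")
    A = np.vstack([_arm_totals(c, mask, bin_to_arm, arm_labels) for c in correcteds])
    return CaffBaseline(
        bin_mask=mask,
        arm_labels=arm_labels,
        arm_mean=A.mean(axis=0),
        arm_sd=A.std(axis=0, ddof=1),
        bin_to_arm=bin_to_arm,
    )


def compute_caff(
    sample: SampleFragments,
    bins: WindowSet,
    arms: ArmSet,
    baseline: CaffBaseline,
    gc: np.ndarray,
    gates: SizeGates = DEFAULT_GATES,
    span: float = 0.75,
) -> tuple[float, float, dict[str, float]]:
    """Size-selected arm-level aneuploidy of one sample.

    Returns ``(pa_score, caff_log10, arm_z)`` where ``caff_log10`` is
    log10(PA + 1) (the +1 keeps scores in [0, 1) finite on the log scale).
    """
    _, corrected = _gated_corrected_coverage(sample, bins, gc, gates, span)
    totals = _arm_totals(
        corrected, baseline.bin_mask, baseline.bin_to_arm, baseline.arm_labels
    )
    arm_z: dict[str, float] = {}
    for i, label in enumerate(baseline.arm_labels):
        if baseline.arm_sd[i] > 0:
            arm_z[label] = float((totals[i] - baseline.arm_mean[i]) / baseline.arm_sd[i])
    k = 5
    if len(arm_z) < k:
        warnings.warn(f"only {len(arm_z)} scored arms; PA uses all of them")
        k = len(arm_z)
    pa = pa_score(arm_z, k=k)
    return pa, float(np.log10(pa + 1.0)), arm_z


def compute_fem(
    sample: SampleFragments, gates: SizeGates = DEFAULT_GATES
) -> np.ndarray:
    """End-motif frequency vector over the 256 4-mers.

    Uses fragments shorter than 171 bp whose Crick-strand 5′ end motif is
    known; motifs containing ambiguous bases are skipped. Frequencies sum
    to 1; with no qualifying fragment the vector is all zero.
    """
    df = sample.df
    counts = np.zeros(256)
    if len(df):
        motifs = df["motif_crick"]
        ok = gates.fem_gate(sample.lengths) & motifs.notna().to_numpy()
        for m in motifs.to_numpy()[ok]:
            idx = _MOTIF_INDEX.get(m)
            if idx is not None:
                counts[idx] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts
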