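"""Cancer signal origin (CSO): tissue-of-origin from accessible chromatin.

Tissue-specific ATAC-seq peak clusters are hypomethylated — and depleted
of fragment coverage — in the plasma of patients whose tumor arises from
the matching tissue. Per sample we compute, for each of the 18 clusters,
(1) the mean methylation of cancer-hypomethylated peaks, (2) aggregate
short-fragment counts, (3) aggregate long-fragment counts; each 18-vector
is z-scored against healthy controls and min-max scaled to [0, 1] within
the sample, giving 54 features for a random-forest classifier evaluated by
leave-one-out cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestClassifier

from themis.features import DEFAULT_GATES, SizeGates
from themis.fragments import SampleFragments
from themis.intervals import GenomicInterval, PeakCluster

#: Closely associated cancer types merged for lenient accuracy scoring.
MERGE_GROUPS: dict[str, frozenset[str]] = {
    "digestive": frozenset({"ESCA", "STAD", "COREAD"}),
    "hepatopancreatic": frozenset({"LIHC", "PACA"}),
}

N_TREES = 2000


def _peak_lookup(peaks: Sequence[GenomicInterval]):
    """Per-chromosome sorted starts/ends with original peak indices."""
    tmp: dict[str, list[tuple[int, int, int]]] = {}
    for i, p in enumerate(peaks):
        tmp.setdefault(p.chrom, []).append((p.start, p.end, i))
    out = {}
    for chrom, rows in tmp.items():
        rows.sort()
        out[chrom] = (
            np.array([r[0] for r in rows]),
            np.array([r[1] for r in rows]),
            np.array([r[2] for r in rows]),
        )
    return out


def _assign_to_peaks(
    peaks: Sequence[GenomicInterval], chroms: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """Point → peak index (−1 if in no peak). Peaks are non-overlapping."""
    lookup = _peak_lookup(peaks)
    out = np.full(len(positions), -1, dtype=np.int64)
    for chrom in np.unique(chroms):
        if chrom not in lookup:
            continue
        starts, ends, idx = lookup[chrom]
        sel = np.flatnonzero(chroms == chrom)
        pos = positions[sel]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        out[sel[ok]] = idx[j[ok]]
    return out


def peak_methylation(
    sample: SampleFragments, peaks: Sequence[GenomicInterval]
) -> np.ndarray:
    """Fraction of methylated CpG observations per peak.

    A fragment's CpG tallies are attributed to the peak containing its
    midpoint (midpoint convention, as in window binning). Peaks with no
    CpG observation come back NaN (missing, not zero).
    """
    meth = np.zeros(len(peaks))
    total = np.zeros(len(peaks))
    if sample.n_total:
        df = sample.df
        pidx = _assign_to_peaks(
            peaks, df["chrom"].to_numpy(), sample.midpoints
        )
        ok = pidx >= 0
        np.add.at(meth, pidx[ok], df["cpg_methylated"].to_numpy(float)[ok])
        np.add.at(total, pidx[ok], df["cpg_total"].to_numpy(float)[ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, meth / np.maximum(total, 1), np.nan)


def select_hypomethylated_peaks(
    cancer_peak_meth: np.ndarray,
    healthy_peak_meth: np.ndarray,
    alpha: float = 0.05,
) -> np.ndarray:
    """Keep-mask over peaks with lower methylation in cancer.

    Per peak, a one-sided Wilcoxon rank-sum test (cancer < healthy) over
    the per-sample peak methylation values; peaks with p < ``alpha`` are
    retained. NaN observations (peaks unobserved in a sample) are dropped
    per peak.
    """
    C = np.asarray(cancer_peak_meth, float)
    H = np.asarray(healthy_peak_meth, float)
    if C.ndim != 2 or H.ndim != 2 or C.shape[1] != H.shape[1]:
        raise ValueError("need aligned samples x peaks matrices")
    if C.shape[0] < 2 or H.shape[0] < 2:
        raise ValueError("need >=2 samples per group")
    keep = np.zeros(C.shape[1], dtype=bool)
    for j in range(C.shape[1]):
        c = C[:, j][np.isfinite(C[:, j])]
        h = H[:, j][np.isfinite(H[:, j])]
        if c.size < 2 or h.size < 2 or np.ptp(np.concatenate([c, h])) == 0:
            continue
        p = mannwhitneyu(c, h, alternative="less").pvalue
        keep[j] = p < alpha
    return keep


@dataclass
class ClusterBaseline:
    """Healthy-control mean/sd of the per-cluster quantities."""

    meth_mean: np.ndarray
    meth_sd: np.ndarray
    short_mean: np.ndarray
    short_sd: np.ndarray
    long_mean: np.ndarray
    long_sd: np.ndarray


@dataclass
class ClusterFeatureSet:
    """Scaled per-cluster features of one sample (each vector in [0,1])."""

    methylation_scaled: np.ndarray
    short_cov_scaled: np.ndarray
    long_cov_scaled: np.ndarray
    sample_id: str = ""

    def as_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.methylation_scaled, self.short_cov_scaled, self.long_cov_scaled]
        )

    @staticmethod
    def feature_names(n_clusters: int) -> list[str]:
        return (
            [f"m{i+1:02d}" for i in range(n_clusters)]
            + [f"s{i+1:02d}" for i in range(n_clusters)]
            + [f"l{i+1:02d}" for i in range(n_clusters)]
        )


def cluster_methylation(
    sample: SampleFragments,
    clusters: Sequence[PeakCluster],
    retained_peaks: Mapping[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Mean retained-peak methylation per cluster (NaN when no retained
    peak is observed). ``retained_peaks`` maps cluster position → keep-mask
    over that cluster's peaks; None keeps all."""
    out = np.full(len(clusters), np.nan)
    for ci, cluster in enumerate(clusters):
        mask = (
            retained_peaks[ci]
            if retained_peaks is not None
            else np.ones(len(cluster.peaks), bool)
        )
        peaks = [p for p, m in zip(cluster.peaks, mask) if m]
        if not peaks:
            continue
        pm = peak_methylation(sample, peaks)
        finite = pm[np.isfinite(pm)]
        if finite.size:
            out[ci] = finite.mean()
    return out


def cluster_fragment_counts(
    sample: SampleFragments,
    clusters: Sequence[PeakCluster],
    gates: SizeGates = DEFAULT_GATES,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate short- and long-fragment counts per cluster, normalized by
    the sample's total fragment count (depth-robust rates)."""
    short = np.zeros(len(clusters))
    long_ = np.zeros(len(clusters))
    if sample.n_total == 0:
        return short, long_
    df = sample.df
    lengths = sample.lengths
    mids = sample.midpoints
    chroms = df["chrom"].to_numpy()
    is_s, is_l = gates.is_short(lengths), gates.is_long(lengths)
    for ci, cluster in enumerate(clusters):
        pidx = _assign_to_peaks(cluster.peaks, chroms, mids)
        inside = pidx >= 0
        short[ci] = (inside & is_s).sum() / sample.n_total
        long_[ci] = (inside & is_l).sum() / sample.n_total
    return short, long_


def build_cluster_baseline(
    healthy_meth: np.ndarray, healthy_short: np.ndarray, healthy_long: np.ndarray
) -> ClusterBaseline:
    """Per-cluster mean/sd over healthy controls for the three feature
    families (samples x clusters matrices)."""

    def stats(X):
        X = np.asarray(X, float)
        return np.nanmean(X, axis=0), np.nanstd(X, axis=0, ddof=1)

    mm, ms = stats(healthy_meth)
    sm, ss = stats(healthy_short)
    lm, ls = stats(healthy_long)
    return ClusterBaseline(mm, ms, sm, ss, lm, ls)


def _scale_01(z: np.ndarray) -> np.ndarray:
    """Min-max scale a z-vector to [0,1]; degenerate (constant or missing)
    entries map to 0.5."""
    z = np.asarray(z, float)
    out = np.full(len(z), 0.5)
    finite = np.isfinite(z)
    if finite.sum() >= 2 and np.ptp(z[finite]) > 0:
        lo, hi = z[finite].min(), z[finite].max()
        out[finite] = (z[finite] - lo) / (hi - lo)
    if (~finite).any():
        warnings.warn(f"{int((~finite).sum())} cluster feature(s) missing; imputed 0.5")
    return out


def cluster_features(
    meth: np.ndarray,
    short: np.ndarray,
    long_: np.ndarray,
    baseline: ClusterBaseline,
    sample_id: str = "",
) -> ClusterFeatureSet:
    """z-score each per-cluster vector against the healthy baseline, then
    min-max scale to [0,1] within the sample."""

    def z(v, mean, sd):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd > 0, (v - mean) / np.where(sd > 0, sd, 1), np.nan)

    return ClusterFeatureSet(
        methylation_scaled=_scale_01(z(meth, baseline.meth_mean, baseline.meth_sd)),
        short_cov_scaled=_scale_01(z(short, baseline.short_mean, baseline.short_sd)),
        long_cov_scaled=_scale_01(z(long_, baseline.long_mean, baseline.long_sd)),
        sample_id=sample_id,
    )


@dataclass
class CSOModel:
    """Random forest over the 54 scaled cluster features."""

    forest: RandomForestClassifier
    classes: list[str]
    loo_predictions: list[str] = field(default_factory=list)
    loo_true: list[str] = field(default_factory=list)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.forest.predict(np.atleast_2d(features))

    def loo_accuracy(self) -> float:
        if not self.loo_predictions:
            raise ValueError("model trained without LOO evaluation")
        t = np.array(self.loo_true)
        p = np.array(self.loo_predictions)
        return float((t == p).mean())

    def loo_confusion(self) -> pd.DataFrame:
        labels = self.classes
        cm = pd.DataFrame(0, index=labels, columns=labels)
        for t, p in zip(self.loo_true, self.loo_predictions):
            cm.loc[t, p] += 1
        return cm


def train_cso(
    features: np.ndarray,
    labels: Sequence[str],
    seed: int = 0,
    n_trees: int = N_TREES,
    run_loo: bool = True,
) -> CSOModel:
    """Fit the CSO random forest and (optionally) record leave-one-out
    predictions for accuracy reporting. √p features per split, trees grown
    to purity, all seeded."""
    X = np.asarray(features, float)
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        bad = list(counts[counts < 2].index)
        raise ValueError(f"classes with <2 samples: {bad}")

    def make_forest(rs):
        return RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=rs, n_jobs=1
        )

    model = CSOModel(forest=make_forest(seed).fit(X, y), classes=sorted(counts.index))
    if run_loo:
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            f = make_forest(seed).fit(X[keep], y[keep])
            model.loo_predictions.append(str(f.predict(X[i : i + 1])[0]))
            model.loo_true.append(str(y[i]))
    return model


def merged_accuracy(
    confusion: pd.DataFrame,
    merge_groups: Mapping[str, frozenset[str]] | None = None,
) -> tuple[float, float]:
    """(raw, merged) accuracy from a true x predicted count matrix.

    Merged accuracy counts a prediction correct when true and predicted
    labels fall in the same merged group (e.g. gastric called colorectal
    within the digestive group); it can never fall below raw accuracy.
    """
    if merge_groups is None:
        merge_groups = MERGE_GROUPS
    group_of: dict[str, str] = {}
    for gname, members in merge_groups.items():
        for m in members:
            group_of[m] = gname
    total = float(confusion.to_numpy().sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    raw = merged = 0.0
    for t in confusion.index:
        for p in confusion.columns:
            n = float(confusion.loc[t, p])
            if n == 0:
                continue
            if t == p:
                raw += n
                merged += n
            elif group_of.get(str(t)) is not None and group_of.get(str(t)) == group_of.get(str(p)):
                merged += n
    return raw / total, merged / total
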