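"""End-to-end orchestration: scaffold → featurize → train → score → evaluate.

`run_pipeline` executes the canonical workflow on a cohort of fragment
samples with declared roles (baseline / train / test): builds the window
scaffolding, fits the healthy baselines, extracts the four modalities,
trains the base models and the logistic ensemble on the training cohort,
and scores everything. Deterministic under a fixed config and seed; every
run carries an audit manifest (config hash, package version, per-stage
record counts).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

import themis
from themis.features import (
    DEFAULT_GATES,
    SizeGates,
    build_caff_baseline,
    compute_caff,
    compute_fem,
    compute_fsi,
    compute_mfr,
)
from themis.fragments import SampleFragments
from themis.intervals import ArmSet, WindowSet
from themis.metrics import ScoredCohort, rank_auc, sensitivity_at_specificity
from themis.models import (
    VARIANCE_THRESHOLDS,
    BaseModelBundle,
    EnsembleModel,
    themis_score,
    train_base_model,
    train_ensemble,
)
from themis.reference import build_arms, compute_gc, merge_bins_to_windows, tile_autosomes


@dataclass
class RunConfig:
    """Run-level knobs; defaults mirror the published constants."""

    seed: int = 0
    bin_size_small: int = 100_000
    bin_size_mfr: int = 1_000_000
    merge_target: int = 5_000_000
    gates: SizeGates = field(default_factory=SizeGates)
    variance_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(VARIANCE_THRESHOLDS)
    )
    specificity_target: float = 0.99
    loess_span: float = 0.75
    train_fraction: float = 0.7
    n_bootstraps: int = 10
    ensemble_folds: int = 20

    def digest(self) -> str:
        payload = json.dumps(
            {k: (v if not isinstance(v, SizeGates) else vars(v).copy() | {})
             for k, v in vars(self).items()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Scaffold:
    """Fixed genomic scaffolding shared by every sample of a run."""

    bins_small: WindowSet
    windows_mfr: WindowSet
    windows_merged: WindowSet
    merge_map: dict[int, int]
    arms: ArmSet
    gc_small: np.ndarray


def build_scaffold(
    chrom_sizes: Mapping[str, int],
    reference,
    centromeres: Mapping[str, object],
    config: RunConfig,
    exclusions: Sequence = (),
) -> Scaffold:
    bins = compute_gc(reference, tile_autosomes(chrom_sizes, config.bin_size_small, exclusions))
    windows_mfr = tile_autosomes(chrom_sizes, config.bin_size_mfr, exclusions)
    merged, merge_map = merge_bins_to_windows(bins, config.merge_target)
    arms = build_arms(centromeres, chrom_sizes)
    return Scaffold(bins, windows_mfr, merged, merge_map, arms, bins.gc())


@dataclass
class SampleFeatures:
    sample_id: str
    mfr: np.ndarray
    fsi: np.ndarray
    fem: np.ndarray
    pa_score: float
    caff_log10: float


def featurize_sample(
    sample: SampleFragments, scaffold: Scaffold, caff_baseline, config: RunConfig
) -> SampleFeatures:
    mfr = compute_mfr(sample, scaffold.windows_mfr, config.gates)
    fsi = compute_fsi(
        sample,
        scaffold.bins_small,
        scaffold.merge_map,
        scaffold.gc_small,
        config.gates,
        span=config.loess_span,
    )
    fem = compute_fem(sample, config.gates)
    pa, caff_log10, _ = compute_caff(
        sample,
        scaffold.bins_small,
        scaffold.arms,
        caff_baseline,
        scaffold.gc_small,
        config.gates,
        span=config.loess_span,
    )
    return SampleFeatures(sample.sample_id, mfr, fsi, fem, pa, caff_log10)


def features_to_frame(features: Sequence[SampleFeatures], scaffold: Scaffold) -> pd.DataFrame:
    """One row per sample; columns named mfr_w####, fsi_w####, motif 4-mers,
    pa_score, caff_log10."""
    from themis.features import MOTIFS_4MER

    rows = []
    for f in features:
        row: dict[str, float] = {"sample_id": f.sample_id}
        row.update({f"mfr_w{i:04d}": v for i, v in enumerate(f.mfr)})
        row.update({f"fsi_w{i:04d}": v for i, v in enumerate(f.fsi)})
        row.update(dict(zip(MOTIFS_4MER, f.fem)))
        row["pa_score"] = f.pa_score
        row["caff_log10"] = f.caff_log10
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class PipelineResult:
    features: pd.DataFrame
    scores: pd.DataFrame  # per sample: role, label, modality scores, themis
    base_models: dict[str, BaseModelBundle]
    ensemble: EnsembleModel
    metrics: dict[str, float]
    manifest: dict


def _split_roles(
    truth: pd.DataFrame, train_fraction: float, seed: int
) -> pd.Series:
    """Stratified train/test role per sample; healthy training samples
    double as the baseline cohort."""
    from sklearn.model_selection import train_test_split

    roles = pd.Series("train", index=truth["sample_id"])
    for label, grp in truth.groupby("label"):
        ids = grp["sample_id"].to_numpy()
        if len(ids) < 2:
            continue
        tr, te = train_test_split(
            ids, train_size=train_fraction, random_state=seed
        )
        roles[te] = "test"
    return roles


def run_pipeline(
    cohort,
    config: RunConfig | None = None,
    roles: Mapping[str, str] | None = None,
    baseline_ids: Sequence[str] | None = None,
) -> PipelineResult:
    """Run the full detection workflow on a simulated (or loaded) cohort.

    ``cohort`` provides ``samples``, ``truth``, ``reference``,
    ``chrom_sizes`` and ``centromeres`` (the
    :class:`~themis.simulate.SimulatedCohort` surface). ``roles`` maps
    sample_id → "train"/"test"; absent, a stratified split at the
    configured fraction is drawn from the run seed. Healthy training
    samples form the baseline; a test sample in the baseline is a leakage
    error.
    """
    config = config or RunConfig()
    truth = cohort.truth
    if roles is None:
        roles = _split_roles(truth, config.train_fraction, config.seed).to_dict()
    role_s = pd.Series({sid: roles[sid] for sid in truth["sample_id"]})
    labels = truth.set_index("sample_id")["label"]

    if baseline_ids is None:
        baseline_ids = [
            sid for sid in truth["sample_id"]
            if role_s[sid] == "train" and labels[sid] == "healthy"
        ]
    else:
        baseline_ids = list(baseline_ids)
    test_ids = {sid for sid in truth["sample_id"] if role_s[sid] == "test"}
    if set(baseline_ids) & test_ids:
        raise ValueError("leakage: sample assigned to both baseline and test")
    if not baseline_ids:
        raise ValueError("no healthy training samples available as baseline")

    scaffold = build_scaffold(
        cohort.chrom_sizes, cohort.reference, cohort.centromeres, config
    )
    by_id = {s.sample_id: s for s in cohort.samples}
    caff_baseline = build_caff_baseline(
        [by_id[sid] for sid in baseline_ids],
        scaffold.bins_small,
        scaffold.arms,
        scaffold.gc_small,
        config.gates,
        span=config.loess_span,
    )
    feats = [
        featurize_sample(by_id[sid], scaffold, caff_baseline, config)
        for sid in truth["sample_id"]
    ]
    fdf = features_to_frame(feats, scaffold)

    y = (labels != "healthy").astype(int)
    train_mask = role_s == "train"
    mfr_cols = [c for c in fdf.columns if c.startswith("mfr_")]
    fsi_cols = [c for c in fdf.columns if c.startswith("fsi_")]
    fem_cols = [c for c in fdf.columns if len(c) == 4 and set(c) <= set("ACGT")]

    base_models: dict[str, BaseModelBundle] = {}
    base_scores = pd.DataFrame(index=fdf.index, columns=["MFR", "FSI", "FEM"], dtype=float)
    rng = np.random.default_rng(config.seed)
    for modality, cols in (("MFR", mfr_cols), ("FSI", fsi_cols), ("FEM", fem_cols)):
        X = fdf[cols].to_numpy(float)
        bundle = train_base_model(
            X[train_mask.to_numpy()],
            y[train_mask].to_numpy(),
            modality,  # type: ignore[arg-type]
            variance_threshold=config.variance_thresholds[modality],
            seed=int(rng.integers(0, 2**31 - 1)),
            n_bootstraps=config.n_bootstraps,
        )
        base_models[modality] = bundle
        base_scores.loc[train_mask, modality] = bundle.oof_scores(X[train_mask.to_numpy()])
        if (~train_mask).any():
            base_scores.loc[~train_mask, modality] = bundle.predict(
                X[(~train_mask).to_numpy()]
            )

    caff = fdf["caff_log10"].to_numpy(float)
    ensemble = train_ensemble(
        base_scores.loc[train_mask, ["MFR", "FSI", "FEM"]].to_numpy(float),
        caff[train_mask.to_numpy()],
        y[train_mask].to_numpy(),
        seed=config.seed,
        n_folds=config.ensemble_folds,
    )
    score = themis_score(
        ensemble,
        base_scores["MFR"].to_numpy(float),
        base_scores["FSI"].to_numpy(float),
        caff,
        base_scores["FEM"].to_numpy(float),
    )
    scores = pd.DataFrame(
        {
            "role": role_s,
            "label": labels,
            "mfr_score": base_scores["MFR"],
            "fsi_score": base_scores["FSI"],
            "caff_log10": fdf["caff_log10"],
            "fem_score": base_scores["FEM"],
            "themis_score": score,
        }
    )

    metrics: dict[str, float] = {}
    for role in ("train", "test"):
        sub = scores[scores["role"] == role]
        if sub.empty or sub["label"].nunique() < 2:
            continue
        y_sub = (sub["label"] != "healthy").to_numpy()
        metrics[f"{role}_auc"] = rank_auc(y_sub, sub["themis_score"].to_numpy())
        sc = ScoredCohort(
            list(sub.index), list(sub["label"]), sub["themis_score"].to_numpy()
        )
        thr, sens, (lo, hi) = sensitivity_at_specificity(sc, config.specificity_target)
        metrics[f"{role}_sens_at_{config.specificity_target:g}"] = sens
        metrics[f"{role}_threshold"] = thr

    manifest = {
        "package_version": themis.__version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_samples": len(truth),
        "n_baseline": len(baseline_ids),
        "n_train": int(train_mask.sum()),
        "n_test": int((~train_mask).sum()),
        "n_bins_small": len(scaffold.bins_small),
        "n_windows_mfr": len(scaffold.windows_mfr),
        "n_windows_merged": len(scaffold.windows_merged),
        "n_arms": len(scaffold.arms),
        "ensemble_intercept": ensemble.intercept,
        "ensemble_coefficients": list(ensemble.coefficients),
    }
    return PipelineResult(fdf, scores, base_models, ensemble, metrics, manifest)


class DirectoryCohort:
    """Cohort loaded from a directory written by
    :meth:`themis.simulate.SimulatedCohort.write` (or assembled by hand in
    the same layout: reference.fa, centromeres.bed, peaks.bed, truth.tsv,
    fragments/<id>.frags.tsv[.gz])."""

    def __init__(self, path: str) -> None:
        from pathlib import Path

        import pyfaidx

        from themis.fragments import read_fragment_table
        from themis.intervals import GenomicInterval
        from themis.reference import load_peak_clusters

        root = Path(path)
        self.reference = pyfaidx.Fasta(str(root / "reference.fa"))
        self.chrom_sizes = {k: len(self.reference[k]) for k in self.reference.keys()}
        self.centromeres = {}
        with open(root / "centromeres.bed") as fh:
            for line in fh:
                chrom, s, e = line.split()[:3]
                self.centromeres[chrom] = GenomicInterval(chrom, int(s), int(e))
        peaks_bed = root / "peaks.bed"
        self.clusters = load_peak_clusters(str(peaks_bed)) if peaks_bed.exists() else []
        self.truth = pd.read_csv(root / "truth.tsv", sep="\t")
        self.samples = []
        frag_dir = root / "fragments"
        for sid in self.truth["sample_id"]:
            for suffix in (".frags.tsv.gz", ".frags.tsv"):
                p = frag_dir / f"{sid}{suffix}"
                if p.exists():
                    self.samples.append(read_fragment_table(str(p), sample_id=str(sid)))
                    break
            else:
                raise FileNotFoundError(f"no fragment table for sample {sid}")


def cso_features_from_cohort(
    cohort,
    healthy_ids: Sequence[str],
    cancer_ids: Sequence[str],
    gates: SizeGates = DEFAULT_GATES,
    alpha: float = 0.05,
):
    """Cluster feature matrices for a CSO run.

    Computes per-peak methylation for every sample, selects
    cancer-hypomethylated peaks (healthy vs cancer over the given training
    ids), builds the healthy cluster baseline, and returns the scaled
    54-feature matrix for the cancer samples (plus metadata).
    """
    from themis.cso import (
        build_cluster_baseline,
        cluster_features,
        cluster_fragment_counts,
        cluster_methylation,
        peak_methylation,
        select_hypomethylated_peaks,
    )

    clusters = cohort.clusters
    by_id = {s.sample_id: s for s in cohort.samples}
    all_peaks = [p for cl in clusters for p in cl.peaks]
    cluster_of_peak = np.concatenate(
        [np.full(len(cl.peaks), ci) for ci, cl in enumerate(clusters)]
    )

    def peak_matrix(ids):
        return np.vstack([peak_methylation(by_id[s], all_peaks) for s in ids])

    H = peak_matrix(healthy_ids)
    C = peak_matrix(cancer_ids)
    keep = select_hypomethylated_peaks(C, H, alpha=alpha)
    retained = {
        ci: keep[cluster_of_peak == ci] for ci in range(len(clusters))
    }
    for ci in range(len(clusters)):
        if not retained[ci].any():
            warnings.warn(f"cluster {ci}: no retained peaks; falling back to all")
            retained[ci] = np.ones(len(clusters[ci].peaks), bool)

    def raw_feats(ids):
        meths, shorts, longs = [], [], []
        for sid in ids:
            s = by_id[sid]
            meths.append(cluster_methylation(s, clusters, retained))
            sh, lo = cluster_fragment_counts(s, clusters, gates)
            shorts.append(sh)
            longs.append(lo)
        return np.vstack(meths), np.vstack(shorts), np.vstack(longs)

    h_meth, h_short, h_long = raw_feats(healthy_ids)
    baseline = build_cluster_baseline(h_meth, h_short, h_long)

    def scaled_matrix(ids):
        m, s, l = raw_feats(ids)
        return np.vstack(
            [
                cluster_features(m[i], s[i], l[i], baseline, sample_id=ids[i]).as_vector()
                for i in range(len(ids))
            ]
        )

    return scaled_matrix, baseline, keep
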