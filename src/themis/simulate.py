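"""Fragment-level synthetic cfDNA cohorts.

The generator emulates the statistical structure of plasma methylome
sequencing in cancer: each cancer sample's fragments are a mixture — with
probability ``tumor_fraction`` a fragment is tumor-derived, drawn with
arm-weighted genomic position (copy-number alterations), a shorter size
mode, globally reduced per-CpG methylation, a distorted 5′ end-motif
spectrum, and extra hypomethylation plus elevated coverage at the
accessible-chromatin peak clusters of the sample's pseudo-type. Healthy
samples use the background model throughout. The toy reference carries a
CpG grid and smoothly varying GC content, so GC correction, methylation
tallies and reference-derived end motifs are all exercised for real.

Everything is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from themis.fragments import FRAGMENT_COLUMNS, SampleFragments, write_fragment_table
from themis.intervals import GenomicInterval, PeakCluster

_BASES = np.array(["A", "C", "G", "T"])
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

#: Cancer pseudo-types and the peak cluster index each one hypomethylates.
DEFAULT_CANCER_TYPES: tuple[str, ...] = (
    "BRCA",
    "NSCLC",
    "ESCA",
    "STAD",
    "COREAD",
    "LIHC",
    "PACA",
)

#: Clinical stages map to tumor-fraction bands.
STAGE_TF_BANDS: dict[str, tuple[float, float]] = {
    "I": (0.001, 0.01),
    "II": (0.005, 0.02),
    "III": (0.02, 0.08),
    "IV": (0.05, 0.20),
}


class _ChromSeq:
    """Sliceable view of an encoded chromosome (returns strings)."""

    def __init__(self, codes: np.ndarray) -> None:
        self.codes = codes

    def __len__(self) -> int:
        return len(self.codes)

    def __getitem__(self, key) -> str:
        part = self.codes[key]
        if np.isscalar(part) or part.ndim == 0:
            return str(_BASES[int(part)])
        return "".join(_BASES[part])

    def __str__(self) -> str:
        return "".join(_BASES[self.codes])


class ToyReference:
    """In-memory toy genome with CpG grid and GC structure.

    Behaves as a chrom → sliceable-sequence mapping, the interface the
    readers and GC annotation expect.
    """

    def __init__(self, codes: dict[str, np.ndarray], cpg_spacing: int) -> None:
        self._codes = codes
        self.cpg_spacing = cpg_spacing

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._codes

    def __getitem__(self, chrom: str) -> _ChromSeq:
        return _ChromSeq(self._codes[chrom])

    def keys(self):
        return self._codes.keys()

    def codes(self, chrom: str) -> np.ndarray:
        return self._codes[chrom]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self._codes.items()}

    def write_fasta(self, path: str, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom, codes in self._codes.items():
                fh.write(f">{chrom}\n")
                seq = "".join(_BASES[codes])
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults are fixed once: a 4 x 30-Mb toy genome with CpGs every 80 bp,
    167-bp healthy size mode (discretized lognormal, sigma 0.16), a 20-bp
    tumor short-shift, per-CpG healthy methylation 0.85 with a 0.85x tumor
    hypomethylation factor, arm-level copy gains/losses per pseudo-type,
    30% tumor end-motif distortion toward CC-started motifs, 99.4%
    cytosine conversion, and 18 peak clusters of 30 x 500-bp peaks.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 30_000_000 for i in range(1, 5)}
    )
    centromere_fraction: tuple[float, float] = (0.48, 0.52)
    cpg_spacing: int = 80
    gc_amplitude: float = 0.10  # GC fraction swings 0.5 +/- amplitude
    gc_wavelength: float = 7_300_000.0
    gc_coverage_coef: float = 1.5  # log-linear coverage bias in GC

    n_healthy: int = 30
    n_cancer_per_type: int = 5
    cancer_types: tuple[str, ...] = DEFAULT_CANCER_TYPES
    fragments_per_sample: int = 20_000

    healthy_meth_prob: float = 0.85
    peak_meth_prob: float = 0.70
    hypomethylation_factor: float = 0.85
    cluster_hypo_factor: float = 0.40

    size_mode_healthy: float = 167.0
    size_sigma: float = 0.16
    tumor_size_shift: float = 20.0

    motif_distortion: float = 0.30
    preferred_motif_prefix: str = "CC"

    conversion_error: float = 0.006
    noncpg_c_rate: float = 0.05

    n_clusters: int = 18
    peaks_per_cluster: int = 30
    peak_width: int = 500
    cluster_cov_boost: float = 0.05

    #: arm -> copy ratio per pseudo-type; types absent here get a default
    #: single-arm gain assigned round-robin.
    cna_spec: dict[str, dict[str, float]] = field(default_factory=dict)
    stage_tf_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(STAGE_TF_BANDS)
    )
    stages: tuple[str, ...] = ("I", "II", "III", "IV")
    tumor_fraction_override: tuple[float, float] | None = None

    mapq: int = 60

    def with_strong_signal(self) -> "SimulationConfig":
        """Late-stage-like conditions (tumor fraction 5-25%)."""
        return replace(self, tumor_fraction_override=(0.05, 0.25))

    def with_null_signal(self) -> "SimulationConfig":
        """Zero tumor fraction: 'cancer' samples drawn from the healthy
        model (negative control)."""
        return replace(self, tumor_fraction_override=(0.0, 0.0))


@dataclass
class SimulatedCohort:
    """A generated cohort plus its fixtures."""

    config: SimulationConfig
    reference: ToyReference
    centromeres: dict[str, GenomicInterval]
    clusters: list[PeakCluster]
    samples: list[SampleFragments]
    truth: pd.DataFrame  # sample_id, label, stage, tumor_fraction, ...

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self.reference.chrom_sizes

    def sample(self, sample_id: str) -> SampleFragments:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def healthy_samples(self) -> list[SampleFragments]:
        ids = set(self.truth.loc[self.truth.label == "healthy", "sample_id"])
        return [s for s in self.samples if s.sample_id in ids]

    def cancer_samples(self) -> list[SampleFragments]:
        ids = set(self.truth.loc[self.truth.label != "healthy", "sample_id"])
        return [s for s in self.samples if s.sample_id in ids]

    def write(self, out_dir: str) -> None:
        """Emit fragment TSVs, toy FASTA, exclusion/peak BEDs, truth TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.reference.write_fasta(str(out / "reference.fa"))
        (out / "exclusions.bed").write_text("")
        with open(out / "peaks.bed", "w") as fh:
            for cl in self.clusters:
                for p in cl.peaks:
                    fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{cl.cluster_id}:{cl.tissue_label}\n")
        with open(out / "centromeres.bed", "w") as fh:
            for chrom, iv in self.centromeres.items():
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\n")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        frag_dir = out / "fragments"
        frag_dir.mkdir(exist_ok=True)
        for s in self.samples:
            write_fragment_table(s, str(frag_dir / f"{s.sample_id}.frags.tsv.gz"))


def _build_reference(config: SimulationConfig, rng: np.random.Generator) -> ToyReference:
    codes: dict[str, np.ndarray] = {}
    for chrom, length in config.chrom_lengths.items():
        pos = np.arange(length)
        gc_target = 0.5 + config.gc_amplitude * np.sin(
            2 * np.pi * pos / config.gc_wavelength + rng.uniform(0, 2 * np.pi)
        )
        u = rng.random(length)
        v = rng.random(length)
        # GC with prob gc_target (split G/C evenly), else A/T evenly
        arr = np.where(u < gc_target, np.where(v < 0.5, 1, 2), np.where(v < 0.5, 0, 3))
        # CpG grid: force CG at multiples of the spacing
        grid = np.arange(0, length - 1, config.cpg_spacing)
        arr[grid] = _CODE["C"]
        arr[grid + 1] = _CODE["G"]
        codes[chrom] = arr.astype(np.int8)
    return ToyReference(codes, config.cpg_spacing)


def _centromeres(config: SimulationConfig) -> dict[str, GenomicInterval]:
    lo, hi = config.centromere_fraction
    return {
        chrom: GenomicInterval(chrom, int(lo * L), int(hi * L))
        for chrom, L in config.chrom_lengths.items()
    }


def _place_clusters(
    config: SimulationConfig,
    centromeres: Mapping[str, GenomicInterval],
    rng: np.random.Generator,
) -> list[PeakCluster]:
    """Lay non-overlapping 500-bp peaks on a slot grid, clusters drawn
    without replacement so peaks never collide."""
    slot_step = 4 * config.peak_width
    slots: list[tuple[str, int]] = []
    for chrom, L in config.chrom_lengths.items():
        cen = centromeres[chrom]
        for start in range(slot_step, L - slot_step, slot_step):
            if not (cen.start - config.peak_width < start < cen.end):
                slots.append((chrom, start))
    need = config.n_clusters * config.peaks_per_cluster
    if need > len(slots):
        raise ValueError("genome too small for the requested peak set")
    chosen = rng.choice(len(slots), size=need, replace=False)
    tissue_names = [f"tissue{k+1}" for k in range(config.n_clusters)]
    clusters = []
    for k in range(config.n_clusters):
        ivs = []
        for slot in chosen[k * config.peaks_per_cluster : (k + 1) * config.peaks_per_cluster]:
            chrom, start = slots[slot]
            ivs.append(GenomicInterval(chrom, start, start + config.peak_width))
        clusters.append(
            PeakCluster(k + 1, tissue_names[k], sorted(ivs, key=lambda p: (p.chrom, p.start)))
        )
    return clusters


def _type_cluster_map(config: SimulationConfig) -> dict[str, int]:
    """Pseudo-type → affected cluster position (round-robin)."""
    return {t: i % config.n_clusters for i, t in enumerate(config.cancer_types)}


def _type_cna(config: SimulationConfig) -> dict[str, dict[str, float]]:
    """Pseudo-type → arm copy ratios; defaults alternate single-arm gains
    and losses across the toy arms."""
    out: dict[str, dict[str, float]] = {}
    arms = []
    for chrom in config.chrom_lengths:
        stem = chrom.removeprefix("chr")
        arms += [f"{stem}p", f"{stem}q"]
    for i, t in enumerate(config.cancer_types):
        if t in config.cna_spec:
            out[t] = dict(config.cna_spec[t])
        else:
            gain = arms[i % len(arms)]
            loss = arms[(i + 3) % len(arms)]
            out[t] = {gain: 1.5, loss: 0.6}
    return out


class _PositionModel:
    """Block-level genomic position sampler with GC coverage bias and
    optional arm weighting."""

    BLOCK = 20_000

    def __init__(self, reference: ToyReference, config: SimulationConfig,
                 centromeres: Mapping[str, GenomicInterval]) -> None:
        self.chroms: list[str] = list(reference.keys())
        self.block_chrom: list[int] = []
        self.block_start: list[int] = []
        gcs: list[float] = []
        for ci, chrom in enumerate(self.chroms):
            codes = reference.codes(chrom)
            n_blocks = len(codes) // self.BLOCK
            trimmed = codes[: n_blocks * self.BLOCK].reshape(n_blocks, self.BLOCK)
            gc = ((trimmed == 1) | (trimmed == 2)).mean(axis=1)
            gcs.append(gc)
            self.block_chrom += [ci] * n_blocks
            self.block_start += list(np.arange(n_blocks) * self.BLOCK)
        self.block_chrom = np.array(self.block_chrom)
        self.block_start = np.array(self.block_start)
        self.gc = np.concatenate(gcs)
        self.base_w = np.exp(config.gc_coverage_coef * (self.gc - self.gc.mean()))
        # arm label per block (by block start; centromere blocks get q side)
        self.arm_label = np.empty(len(self.gc), dtype=object)
        for i in range(len(self.gc)):
            chrom = self.chroms[self.block_chrom[i]]
            cen = centromeres[chrom]
            stem = chrom.removeprefix("chr")
            mid = self.block_start[i] + self.BLOCK // 2
            self.arm_label[i] = f"{stem}p" if mid < cen.start else f"{stem}q"

    def sample(
        self,
        n: int,
        rng: np.random.Generator,
        arm_ratios: Mapping[str, float] | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw n (chrom-index, position) pairs."""
        w = self.base_w.copy()
        if arm_ratios:
            for arm, ratio in arm_ratios.items():
                w[self.arm_label == arm] *= ratio
        p = w / w.sum()
        blocks = rng.choice(len(p), size=n, p=p)
        offs = rng.integers(0, self.BLOCK, size=n)
        return self.block_chrom[blocks], self.block_start[blocks] + offs


def _draw_lengths(
    n: int, mode: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    mu = np.log(mode) + sigma**2  # lognormal mode = exp(mu - sigma^2)
    raw = rng.lognormal(mu, sigma, size=n)
    return np.clip(np.round(raw), 60, 400).astype(np.int64)


def _motif_indices(codes_by_chrom: list[np.ndarray], chrom_idx, ends) -> np.ndarray:
    """Crick 5′ motif index (0..255) for fragment ends; the motif is the
    reverse complement of reference bases [end-4, end)."""
    out = np.empty(len(ends), dtype=np.int64)
    for ci in np.unique(chrom_idx):
        sel = chrom_idx == ci
        e = ends[sel]
        c = codes_by_chrom[ci]
        c0, c1, c2, c3 = c[e - 4], c[e - 3], c[e - 2], c[e - 1]
        comp = lambda x: 3 - x.astype(np.int64)
        out[sel] = 64 * comp(c3) + 16 * comp(c2) + 4 * comp(c1) + comp(c0)
    return out


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full labelled cohort under the configured conditions."""
    rng = np.random.default_rng(config.seed)
    reference = _build_reference(config, rng)
    centromeres = _centromeres(config)
    clusters = _place_clusters(config, centromeres, rng)
    posmodel = _PositionModel(reference, config, centromeres)
    chroms = posmodel.chroms
    codes_by_chrom = [reference.codes(c) for c in chroms]
    chrom_len = np.array([len(codes_by_chrom[i]) for i in range(len(chroms))])
    type_cluster = _type_cluster_map(config)
    type_cna = _type_cna(config)

    # flat peak arrays for membership tests and relocation
    peak_chrom_idx, peak_start, peak_cluster_pos = [], [], []
    chrom_index = {c: i for i, c in enumerate(chroms)}
    for ci_pos, cl in enumerate(clusters):
        for p in cl.peaks:
            peak_chrom_idx.append(chrom_index[p.chrom])
            peak_start.append(p.start)
            peak_cluster_pos.append(ci_pos)
    peak_chrom_idx = np.array(peak_chrom_idx)
    peak_start = np.array(peak_start)
    peak_cluster_pos = np.array(peak_cluster_pos)

    # preferred end positions (reference [end-2, end) == "GG") per chromosome,
    # computed lazily for the motif-distortion rejection step
    preferred: list[np.ndarray | None] = [None] * len(chroms)

    def preferred_ends(ci: int) -> np.ndarray:
        if preferred[ci] is None:
            c = codes_by_chrom[ci]
            suffix = config.preferred_motif_prefix  # Crick prefix CC == ref GG
            want = [3 - _CODE[b] for b in suffix[::-1]]  # ref codes, 5'->3'
            m = np.ones(len(c) - len(want) + 1, dtype=bool)
            for off, code in enumerate(want):
                m &= c[off : len(c) - len(want) + 1 + off] == code
            preferred[ci] = np.flatnonzero(m) + len(want)  # end positions
        return preferred[ci]

    def peak_membership(ci_arr: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Cluster position per fragment midpoint (−1 outside peaks)."""
        out = np.full(len(pos), -1, dtype=np.int64)
        for ci in np.unique(ci_arr):
            mask = peak_chrom_idx == ci
            if not mask.any():
                continue
            starts = peak_start[mask]
            order = np.argsort(starts)
            starts_s = starts[order]
            clus_s = peak_cluster_pos[mask][order]
            sel = np.flatnonzero(ci_arr == ci)
            j = np.searchsorted(starts_s, pos[sel], side="right") - 1
            ok = (j >= 0) & (pos[sel] < starts_s[np.clip(j, 0, None)] + config.peak_width)
            out[sel[ok]] = clus_s[j[ok]]
        return out

    def make_sample(sample_id, label, tf, cna, affected_cluster):
        n = config.fragments_per_sample
        tumor = rng.random(n) < tf
        n_t = int(tumor.sum())
        lengths = np.empty(n, dtype=np.int64)
        lengths[~tumor] = _draw_lengths(
            n - n_t, config.size_mode_healthy, config.size_sigma, rng
        )
        if n_t:
            lengths[tumor] = _draw_lengths(
                n_t,
                config.size_mode_healthy - config.tumor_size_shift,
                config.size_sigma,
                rng,
            )
        ci = np.empty(n, dtype=np.int64)
        pos = np.empty(n, dtype=np.int64)
        ci[~tumor], pos[~tumor] = posmodel.sample(n - n_t, rng)
        if n_t:
            ci[tumor], pos[tumor] = posmodel.sample(n_t, rng, arm_ratios=cna)

        start = pos - lengths // 2
        # tumor fragments may relocate into an affected-cluster peak
        # (elevated accessibility at the tumor tissue's open chromatin)
        if n_t and affected_cluster is not None and config.cluster_cov_boost > 0:
            cand = np.flatnonzero(tumor & (rng.random(n) < config.cluster_cov_boost))
            aff = np.flatnonzero(peak_cluster_pos == affected_cluster)
            if cand.size and aff.size:
                pick = rng.choice(aff, size=cand.size)
                ci[cand] = peak_chrom_idx[pick]
                start[cand] = (
                    peak_start[pick] + config.peak_width // 2 - lengths[cand] // 2
                )
        # tumor end-motif distortion: snap the 3' (Crick 5') end to the
        # nearest preferred-motif site, keeping the length
        if n_t and config.motif_distortion > 0:
            dis = np.flatnonzero(tumor & (rng.random(n) < config.motif_distortion))
            for c in np.unique(ci[dis]):
                ends_c = preferred_ends(int(c))
                sub = dis[ci[dis] == c]
                target = start[sub] + lengths[sub]
                j = np.clip(np.searchsorted(ends_c, target), 0, len(ends_c) - 1)
                start[sub] = ends_c[j] - lengths[sub]

        start = np.clip(start, 4, chrom_len[ci] - lengths - 4)
        end = start + lengths

        mid = (start + end) // 2
        cluster_hit = peak_membership(ci, mid)
        in_peak = cluster_hit >= 0
        meth_p = np.where(in_peak, config.peak_meth_prob, config.healthy_meth_prob)
        if n_t:
            t_factor = np.where(
                tumor & in_peak & (cluster_hit == (affected_cluster if affected_cluster is not None else -2)),
                config.cluster_hypo_factor / config.hypomethylation_factor,
                1.0,
            )
            meth_p = np.where(
                tumor, meth_p * config.hypomethylation_factor * t_factor, meth_p
            )
        meth_p = np.clip(meth_p, 0.0, 1.0)

        # CpG sites sit on the grid (site at p covers p, p+1); a fragment
        # [start, end) observes sites with start <= p <= end-2
        sp = config.cpg_spacing
        cpg_total = np.maximum((end - 2) // sp - (start + sp - 1) // sp + 1, 0)
        cpg_meth = rng.binomial(cpg_total, meth_p)
        nc_total = rng.binomial(lengths, config.noncpg_c_rate)
        nc_conv = rng.binomial(nc_total, 1.0 - config.conversion_error)

        motif_idx = _motif_indices(codes_by_chrom, ci, end)
        from themis.features import MOTIFS_4MER

        motif_arr = np.array(MOTIFS_4MER, dtype=object)[motif_idx]
        df = pd.DataFrame(
            {
                "chrom": np.array(chroms, dtype=object)[ci],
                "start": start,
                "end": end,
                "mapq": np.full(n, config.mapq),
                "cpg_total": cpg_total,
                "cpg_methylated": cpg_meth,
                "noncpg_c_total": nc_total,
                "noncpg_c_converted": nc_conv,
                "motif_crick": motif_arr,
            }
        )[FRAGMENT_COLUMNS]
        return SampleFragments(sample_id, df)

    samples: list[SampleFragments] = []
    truth_rows = []
    for i in range(config.n_healthy):
        sid = f"H{i+1:03d}"
        samples.append(make_sample(sid, "healthy", 0.0, None, None))
        truth_rows.append(
            {"sample_id": sid, "label": "healthy", "stage": "", "tumor_fraction": 0.0,
             "cna_arms": "", "affected_cluster": ""}
        )
    for t in config.cancer_types:
        cna = type_cna[t]
        cluster_pos = type_cluster[t]
        for j in range(config.n_cancer_per_type):
            sid = f"{t}{j+1:03d}"
            stage = config.stages[j % len(config.stages)]
            if config.tumor_fraction_override is not None:
                lo, hi = config.tumor_fraction_override
            else:
                lo, hi = config.stage_tf_bands[stage]
            tf = float(rng.uniform(lo, hi))
            if not (0.0 <= tf <= 1.0):
                raise ValueError("tumor fraction outside [0, 1]")
            samples.append(make_sample(sid, t, tf, cna, cluster_pos))
            truth_rows.append(
                {
                    "sample_id": sid,
                    "label": t,
                    "stage": stage,
                    "tumor_fraction": tf,
                    "cna_arms": ";".join(f"{a}:{r}" for a, r in sorted(cna.items())),
                    "affected_cluster": clusters[cluster_pos].cluster_id,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(config, reference, centromeres, clusters, samples, truth)


def expected_healthy_fem(cohort: SimulatedCohort, stride: int = 7) -> np.ndarray:
    """Expected healthy end-motif distribution: the genome-wide Crick 4-mer
    spectrum at (strided) candidate end positions, GC-coverage-weighted
    sampling ignored (the bias is mild)."""
    counts = np.zeros(256)
    for chrom in cohort.reference.keys():
        c = cohort.reference.codes(chrom)
        ends = np.arange(4, len(c), stride)
        idx = _motif_indices([c], np.zeros(len(ends), dtype=np.int64), ends)
        np.add.at(counts, idx, 1.0)
    return counts / counts.sum()


def simulate_vaf_table(
    truth: pd.DataFrame,
    seed: int = 0,
    vaf_per_tf: float = 0.5,
    noise_sd_log10: float = 0.25,
    midpoint_vaf: float = 1.5e-3,
    slope: float = 4.0,
) -> pd.DataFrame:
    """Per-sample mean VAF and detection outcomes for the cLOD analysis.

    Mean VAF is proportional to tumor fraction with lognormal noise;
    detection is drawn from a logistic in log10(VAF) with the given slope
    and 50% midpoint. Only cancer samples are emitted.
    """
    rng = np.random.default_rng(seed)
    cancer = truth[truth.label != "healthy"].copy()
    tf = np.maximum(cancer["tumor_fraction"].to_numpy(float), 1e-5)
    log_vaf = np.log10(tf * vaf_per_tf) + rng.normal(0, noise_sd_log10, len(tf))
    vaf = 10**log_vaf
    p_detect = 1.0 / (1.0 + np.exp(-slope * (log_vaf - np.log10(midpoint_vaf))))
    detected = rng.random(len(tf)) < p_detect
    return pd.DataFrame(
        {
            "sample_id": cancer["sample_id"].to_numpy(),
            "mean_vaf": vaf,
            "detected": detected.astype(int),
        }
    )
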