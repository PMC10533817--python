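"""Fragment-level I/O for paired-end methylation sequencing.

A cfDNA *fragment* is one sequenced molecule: the merged span of a proper
read pair, with per-molecule CpG methylation tallies, non-CpG conversion
tallies, and the 4-mer at the Crick-strand 5′ end. Fragments are held
columnarly (one :class:`pandas.DataFrame` per sample) so genome-wide
featurization stays vectorized; :class:`Fragment` objects materialize rows
on demand.

Methylation call strings follow the standard bisulfite-aligner dialect:
``Z``/``z`` methylated/unmethylated CpG, ``X``/``x`` and ``H``/``h``
unconverted/converted non-CpG cytosine (CHG/CHH).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

FRAGMENT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "mapq",
    "cpg_total",
    "cpg_methylated",
    "noncpg_c_total",
    "noncpg_c_converted",
    "motif_crick",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Fragment:
    """One cfDNA molecule (coordinates 0-based half-open)."""

    chrom: str
    start: int
    end: int
    mapq: int
    cpg_total: int
    cpg_methylated: int
    noncpg_c_total: int
    noncpg_c_converted: int
    motif_crick: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError("fragment length must be positive")
        if self.cpg_methylated > self.cpg_total:
            raise ValueError("cpg_methylated exceeds cpg_total")
        if self.noncpg_c_converted > self.noncpg_c_total:
            raise ValueError("noncpg_c_converted exceeds noncpg_c_total")
        if self.motif_crick is not None and len(self.motif_crick) != 4:
            raise ValueError("motif_crick must have length 4")

    @property
    def length(self) -> int:
        return self.end - self.start


class SampleFragments:
    """All QC-passing fragments of one sample, stored columnarly."""

    def __init__(self, sample_id: str, df: pd.DataFrame) -> None:
        missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"fragment table missing columns {missing}")
        self.sample_id = sample_id
        self.df = df.reset_index(drop=True)

    @property
    def n_total(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Fragment]:
        for row in self.df.itertuples(index=False):
            motif = row.motif_crick
            yield Fragment(
                row.chrom,
                int(row.start),
                int(row.end),
                int(row.mapq),
                int(row.cpg_total),
                int(row.cpg_methylated),
                int(row.noncpg_c_total),
                int(row.noncpg_c_converted),
                None if motif is None or (isinstance(motif, float) and np.isnan(motif)) else str(motif),
            )

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy()

    @classmethod
    def from_fragments(cls, sample_id: str, fragments) -> "SampleFragments":
        rows = [
            (
                f.chrom,
                f.start,
                f.end,
                f.mapq,
                f.cpg_total,
                f.cpg_methylated,
                f.noncpg_c_total,
                f.noncpg_c_converted,
                f.motif_crick,
            )
            for f in fragments
        ]
        df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
        if df.empty:
            df = pd.DataFrame({c: [] for c in FRAGMENT_COLUMNS})
        return cls(sample_id, df)


def _validate_table(df: pd.DataFrame, source: str) -> None:
    lengths = df["end"].to_numpy() - df["start"].to_numpy()
    checks = [
        (lengths <= 0, "end - start must be positive"),
        (df["start"].to_numpy() < 0, "start must be >= 0"),
        (
            df["cpg_methylated"].to_numpy() > df["cpg_total"].to_numpy(),
            "cpg_methylated exceeds cpg_total",
        ),
        (
            df["noncpg_c_converted"].to_numpy() > df["noncpg_c_total"].to_numpy(),
            "noncpg_c_converted exceeds noncpg_c_total",
        ),
    ]
    for bad, msg in checks:
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"{source}: row {row + 1}: {msg}")
    motifs = df["motif_crick"]
    present = motifs.notna() & (motifs != ".")
    bad_len = present & (motifs.astype(str).str.len() != 4)
    if bad_len.any():
        row = int(np.flatnonzero(bad_len.to_numpy())[0])
        raise ValueError(f"{source}: row {row + 1}: motif_crick must have length 4")


def read_fragment_table(tsv_path: str, sample_id: str | None = None) -> SampleFragments:
    """Load a fragment TSV (header = :data:`FRAGMENT_COLUMNS`).

    ``motif_crick`` of ``.`` parses as absent. Gzipped input is handled
    transparently. Invariant violations raise with the offending row number.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str, "motif_crick": str})
    missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{tsv_path}: missing columns {missing}")
    _validate_table(df, str(tsv_path))
    df.loc[df["motif_crick"] == ".", "motif_crick"] = None
    name = sample_id if sample_id is not None else str(tsv_path)
    return SampleFragments(name, df[FRAGMENT_COLUMNS])


def write_fragment_table(sample: SampleFragments, tsv_path: str) -> None:
    df = sample.df.copy()
    df["motif_crick"] = df["motif_crick"].fillna(".")
    df.to_csv(tsv_path, sep="\t", index=False)


def read_fragments(
    alignment_source: str,
    min_mapq: int = 20,
    reference: Mapping[str, object] | None = None,
    sample_id: str | None = None,
) -> SampleFragments:
    """Merge proper pairs from SAM/BAM into QC'd fragments.

    The input must be deduplicated and carry per-read methylation call
    strings in the ``XM`` tag. Fragment span is the outer mate distance
    (template semantics); in mate overlaps the leftmost mate's calls win.
    Pairs whose minimum mate mapping quality falls below ``min_mapq`` are
    dropped. If ``reference`` (chrom → sliceable sequence) is given, the
    Crick-strand 5′ end 4-mer is taken from the reference as the reverse
    complement of bases [end−4, end).

    Unpaired/discordant/secondary/duplicate reads are skipped and tallied
    in the returned object's ``qc_counters`` attribute; reads lacking the
    methylation tag contribute a fragment with zero CpG tallies.
    """
    import pysam

    counters = {
        "pairs_kept": 0,
        "pairs_low_mapq": 0,
        "reads_skipped": 0,
        "pairs_missing_tag": 0,
        "motif_unavailable": 0,
    }
    pending: dict[str, object] = {}
    rows: list[tuple] = []

    with pysam.AlignmentFile(alignment_source, check_sq=False) as af:
        for read in af:
            if (
                read.is_unmapped
                or read.mate_is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or not read.is_proper_pair
            ):
                counters["reads_skipped"] += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            row = _merge_pair(mate, read, min_mapq, reference, counters)
            if row is not None:
                rows.append(row)
    counters["reads_skipped"] += len(pending)  # mateless leftovers

    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    if df.empty:
        df = pd.DataFrame({c: [] for c in FRAGMENT_COLUMNS})
    out = SampleFragments(sample_id or str(alignment_source), df)
    out.qc_counters = counters  # type: ignore[attr-defined]
    return out


def _tally_xm(read, ref_floor: int) -> tuple[int, int, int, int, bool]:
    """Count methylation calls at reference positions >= ref_floor.

    Returns (cpg_total, cpg_meth, noncpg_total, noncpg_converted, had_tag).
    """
    try:
        xm = read.get_tag("XM")
    except KeyError:
        return 0, 0, 0, 0, False
    cpg_t = cpg_m = nc_t = nc_c = 0
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos < ref_floor or qpos is None or qpos >= len(xm):
            continue
        call = xm[qpos]
        if call == "Z":
            cpg_t += 1
            cpg_m += 1
        elif call == "z":
            cpg_t += 1
        elif call in "XH":
            nc_t += 1
        elif call in "xh":
            nc_t += 1
            nc_c += 1
    return cpg_t, cpg_m, nc_t, nc_c, True


def _merge_pair(r1, r2, min_mapq, reference, counters):
    left, right = (r1, r2) if r1.reference_start <= r2.reference_start else (r2, r1)
    mapq = min(left.mapping_quality, right.mapping_quality)
    if mapq < min_mapq:
        counters["pairs_low_mapq"] += 1
        return None
    chrom = left.reference_name
    start = left.reference_start
    end = max(left.reference_end, right.reference_end)
    if end <= start:
        counters["reads_skipped"] += 2
        return None

    t1 = _tally_xm(left, -1)
    t2 = _tally_xm(right, left.reference_end)  # leftmost mate wins the overlap
    if not (t1[4] and t2[4]):
        counters["pairs_missing_tag"] += 1
        cpg_t = cpg_m = nc_t = nc_c = 0
    else:
        cpg_t = t1[0] + t2[0]
        cpg_m = t1[1] + t2[1]
        nc_t = t1[2] + t2[2]
        nc_c = t1[3] + t2[3]

    motif = None
    if reference is not None and chrom in reference and end >= 4:
        ref4 = str(reference[chrom][end - 4 : end]).upper()
        if len(ref4) == 4 and set(ref4) <= set("ACGT"):
            motif = revcomp(ref4)
        else:
            counters["motif_unavailable"] += 1
    counters["pairs_kept"] += 1
    return (chrom, start, end, mapq, cpg_t, cpg_m, nc_t, nc_c, motif)


def estimate_conversion(spikein: SampleFragments) -> float | None:
    """Cytosine conversion rate on an unmethylated spike-in.

    All cytosines on the spike-in are unmodified, so CpG and non-CpG
    contexts pool: converted = unmethylated-CpG calls + converted non-CpG
    calls, over all cytosine observations. Returns ``None`` when no
    cytosine was observed (undefined, not zero).
    """
    df = spikein.df
    total = int(df["cpg_total"].sum() + df["noncpg_c_total"].sum())
    if total == 0:
        return None
    converted = int(
        (df["cpg_total"] - df["cpg_methylated"]).sum() + df["noncpg_c_converted"].sum()
    )
    return converted / total


def downsample(sample: SampleFragments, n: int, seed: int) -> SampleFragments:
    """Uniform subsample of ``n`` fragments without replacement (seeded)."""
    if n > sample.n_total:
        raise ValueError(
            f"requested {n} fragments but sample holds {sample.n_total}; keep all instead"
        )
    if n == sample.n_total:
        return SampleFragments(sample.sample_id, sample.df.copy())
    rng = np.random.default_rng(seed)
    keep = rng.choice(sample.n_total, size=n, replace=False)
    keep.sort()
    return SampleFragments(sample.sample_id, sample.df.iloc[keep])
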