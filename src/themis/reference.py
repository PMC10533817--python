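"""Genome scaffolding: window tilings, GC content, chromosome arms, peak sets.

All tilings are restricted to the chromosomes the caller passes in
(autosomes, in the intended use); tiles overlapping an exclusion interval by
one or more bp are dropped entirely, and chromosome-terminal partial tiles
are dropped so every retained window has the nominal width.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np

from themis.intervals import (
    ArmSet,
    GenomicInterval,
    GenomicWindow,
    PeakCluster,
    WindowSet,
)

#: p-arms of the acrocentric human autosomes, excluded from arm-level
#: aneuploidy scoring (they are essentially unmappable rDNA/satellite).
ACROCENTRIC_P_ARMS = frozenset({"13p", "14p", "15p", "21p", "22p"})


def tile_autosomes(
    chrom_sizes: Mapping[str, int],
    bin_size: int,
    exclusions: Sequence[GenomicInterval] = (),
) -> WindowSet:
    """Tile chromosomes into adjacent, non-overlapping fixed-width windows.

    Each chromosome is tiled from position 0 in ``bin_size`` steps; a
    terminal remainder shorter than ``bin_size`` is discarded, as is any
    tile overlapping ≥1 bp of any exclusion interval.

    Parameters
    ----------
    chrom_sizes
        Chromosome name → length (bp). The caller restricts this to
        autosomes.
    bin_size
        Tile width in bp (e.g. 100_000 or 1_000_000).
    exclusions
        Intervals (blacklist, assembly gaps) whose overlap disqualifies a
        tile.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not chrom_sizes:
        raise ValueError("chrom_sizes is empty")

    # sorted exclusion starts/ends per chromosome for fast overlap queries
    excl: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in exclusions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda i: i.start)
        excl[chrom] = (
            np.array([i.start for i in ivs]),
            np.array([i.end for i in ivs]),
        )

    windows: list[GenomicWindow] = []
    for chrom in chrom_sizes:
        length = chrom_sizes[chrom]
        starts = np.arange(0, length - bin_size + 1, bin_size, dtype=np.int64)
        if starts.size == 0:
            continue
        ends = starts + bin_size
        if chrom in excl:
            e_start, e_end = excl[chrom]
            # tile [s, e) overlaps some exclusion iff any e_start < e and e_end > s
            # equivalently: exists j with e_start[j] < end and e_end[j] > start
            keep = np.ones(starts.size, dtype=bool)
            for j in range(e_start.size):
                keep &= ~((e_start[j] < ends) & (e_end[j] > starts))
        else:
            keep = np.ones(starts.size, dtype=bool)
        for s, e in zip(starts[keep], ends[keep]):
            windows.append(GenomicWindow(GenomicInterval(chrom, int(s), int(e)), 0))

    if not windows:
        warnings.warn("tiling produced no windows (bin_size exceeds every chromosome?)")
    prov = f"bin_size={bin_size}; {len(exclusions)} exclusion intervals"
    return WindowSet(windows, bin_size, provenance=prov)


def compute_gc(sequence_source, windows: WindowSet) -> WindowSet:
    """Annotate windows with GC fraction from a reference sequence.

    ``sequence_source`` is any mapping from chromosome name to an indexable
    sequence (a :class:`pyfaidx.Fasta`, or a plain dict of strings for toy
    genomes). GC fraction is (#G + #C) / (#A + #C + #G + #T); ambiguous
    bases count in neither numerator nor denominator. Windows with more
    than 50% ambiguous bases are dropped.
    """
    kept: list[GenomicWindow] = []
    for w in windows:
        iv = w.interval
        try:
            seq = str(sequence_source[iv.chrom][iv.start : iv.end]).upper()
        except KeyError as exc:
            raise ValueError(f"chromosome {iv.chrom!r} absent from reference") from exc
        if len(seq) < len(iv):
            raise ValueError(
                f"window {iv.chrom}:{iv.start}-{iv.end} extends beyond reference end"
            )
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        denom = gc + at
        if denom < 0.5 * len(iv):
            continue  # >50% ambiguous bases
        w.gc_fraction = gc / denom
        kept.append(w)
    return WindowSet(kept, windows.bin_size, provenance=windows.provenance + "; gc")


def build_arms(
    centromere_intervals: Mapping[str, GenomicInterval],
    chrom_sizes: Mapping[str, int],
    acrocentric: Iterable[str] = (),
) -> ArmSet:
    """Split each chromosome into p and q arms around its centromere.

    p = [0, centromere.start), q = [centromere.end, chrom_length). Arms named
    with the p-arm label in ``acrocentric`` (e.g. ``"13p"``) are excluded;
    with the human acrocentric list this yields 39 autosomal arms.
    """
    arms: list[tuple[str, GenomicInterval]] = []
    acro = set(acrocentric)
    for chrom, cen in centromere_intervals.items():
        if chrom not in chrom_sizes:
            raise ValueError(f"centromere given for unknown chromosome {chrom}")
        length = chrom_sizes[chrom]
        if not (0 <= cen.start and cen.end <= length):
            raise ValueError(f"centromere {cen} outside chromosome {chrom} (len {length})")
        stem = chrom.removeprefix("chr")
        p_label, q_label = f"{stem}p", f"{stem}q"
        if cen.start > 0 and p_label not in acro:
            arms.append((p_label, GenomicInterval(chrom, 0, cen.start)))
        if cen.end < length and q_label not in acro:
            arms.append((q_label, GenomicInterval(chrom, cen.end, length)))
    return ArmSet(sorted(arms, key=lambda a: (a[1].chrom, a[1].start)))


def merge_bins_to_windows(
    bins: WindowSet, target_size: int
) -> tuple[WindowSet, dict[int, int]]:
    """Group consecutive same-chromosome bins into larger windows.

    Retained bins are grouped in genome order, ``target_size / bin_size``
    per merged window; runs of consecutive bins are broken where retained
    bins are non-adjacent only by chromosome (gaps from dropped bins within
    a chromosome do not break a group — the merged windows tile the
    *retained* bins, mirroring how filtered 100-kb bins are pooled into
    5-Mb windows). A terminal group holding at least half the nominal
    complement is kept; smaller remainders are dropped.

    Returns
    -------
    (merged WindowSet, mapping bin index → merged window index)
    """
    if target_size % bins.bin_size != 0:
        raise ValueError("target_size must be an integer multiple of the bin width")
    per_window = target_size // bins.bin_size
    prev: GenomicWindow | None = None
    for w in bins:
        if (
            prev is not None
            and prev.interval.chrom == w.interval.chrom
            and w.interval.start < prev.interval.start
        ):
            raise ValueError("bins are not sorted")
        prev = w

    merged: list[GenomicWindow] = []
    mapping: dict[int, int] = {}
    groups: list[list[GenomicWindow]] = []
    current: list[GenomicWindow] = []
    current_chrom: str | None = None
    for w in bins:
        if w.interval.chrom != current_chrom or len(current) == per_window:
            if current:
                groups.append(current)
            current = []
            current_chrom = w.interval.chrom
        current.append(w)
    if current:
        groups.append(current)

    for group in groups:
        if len(group) < per_window and len(group) * 2 < per_window:
            continue  # terminal remainder below 50% of the complement
        widx = len(merged)
        iv = GenomicInterval(
            group[0].interval.chrom, group[0].interval.start, group[-1].interval.end
        )
        gcs = [b.gc_fraction for b in group if b.gc_fraction is not None]
        merged.append(
            GenomicWindow(iv, widx, gc_fraction=float(np.mean(gcs)) if gcs else None)
        )
        for b in group:
            mapping[b.index] = widx

    # merged windows are appended in genome order, so WindowSet's re-sort
    # leaves indices unchanged and the mapping stays valid
    ws = WindowSet(merged, target_size, provenance=f"merged from {bins.bin_size}-bp bins")
    return ws, mapping


def load_peak_clusters(bed_path: str) -> list[PeakCluster]:
    """Read an accessible-chromatin peak BED with a cluster-label column.

    Expects BED4+: chrom, start, end, cluster label. Labels may be bare
    integers (``2``) or ``<id>:<tissue>`` (``2:Colon``). A full
    tissue-of-origin peak set carries 18 clusters; fewer raises only a
    warning so toy fixtures remain usable.
    """
    groups: dict[str, list[GenomicInterval]] = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{bed_path}:{lineno}: expected ≥4 BED columns")
            chrom, start_s, end_s, label = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(start_s), int(end_s)
                iv = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{lineno}: {exc}") from exc
            groups.setdefault(label, []).append(iv)
    if len(groups) != 18:
        warnings.warn(f"peak file has {len(groups)} clusters, expected 18")
    clusters: list[PeakCluster] = []
    for i, label in enumerate(sorted(groups, key=_cluster_sort_key), start=1):
        if ":" in label:
            id_part, tissue = label.split(":", 1)
        else:
            id_part, tissue = label, label
        try:
            cid = int(id_part)
        except ValueError:
            cid = i
        clusters.append(
            PeakCluster(cid, tissue, sorted(groups[label], key=lambda p: (p.chrom, p.start)))
        )
    return clusters


def _cluster_sort_key(label: str):
    head = label.split(":", 1)[0]
    try:
        return (0, int(head), label)
    except ValueError:
        return (1, 0, label)


def assign_to_windows(
    windows: WindowSet, chroms: Sequence[str], positions: Sequence[int]
) -> np.ndarray:
    """Vectorized point → window-index lookup (−1 where no window contains
    the point). Used for midpoint binning of fragments."""
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    idx: dict[str, np.ndarray] = {}
    for w in windows:
        starts.setdefault(w.interval.chrom, [])  # type: ignore[arg-type]
    tmp: dict[str, list[tuple[int, int, int]]] = {}
    for w in windows:
        tmp.setdefault(w.interval.chrom, []).append(
            (w.interval.start, w.interval.end, w.index)
        )
    for chrom, rows in tmp.items():
        rows.sort()
        starts[chrom] = np.array([r[0] for r in rows], dtype=np.int64)
        ends[chrom] = np.array([r[1] for r in rows], dtype=np.int64)
        idx[chrom] = np.array([r[2] for r in rows], dtype=np.int64)

    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    out = np.full(positions.shape, -1, dtype=np.int64)
    for chrom in np.unique(chroms):
        if chrom not in starts:
            continue
        sel = np.flatnonzero(chroms == chrom)
        pos = positions[sel]
        j = np.searchsorted(starts[chrom], pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[chrom][np.clip(j, 0, None)])
        out[sel[ok]] = idx[chrom][j[ok]]
    return out
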