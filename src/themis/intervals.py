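"""Genomic interval and window containers.

Coordinates are 0-based half-open (BED convention) throughout the package;
1-based SAM records are converted at the reader boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class GenomicWindow:
    """One tile of a genome tiling, with optional annotations."""

    interval: GenomicInterval
    index: int
    gc_fraction: float | None = None
    arm_label: str | None = None
    compartment_label: str | None = None

    def __post_init__(self) -> None:
        if self.gc_fraction is not None and not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError(f"gc_fraction {self.gc_fraction} outside [0, 1]")


class WindowSet:
    """Ordered, non-overlapping genome tiles of one nominal width.

    Parameters
    ----------
    windows
        Windows sorted by (chrom, start); indices are renumbered 0..n-1.
    bin_size
        Nominal tile width in bp.
    provenance
        Free-text description of exclusion tracks applied when tiling.
    """

    def __init__(
        self,
        windows: Sequence[GenomicWindow],
        bin_size: int,
        provenance: str = "",
    ) -> None:
        ordered = sorted(windows, key=lambda w: (w.interval.chrom, w.interval.start))
        prev: GenomicWindow | None = None
        for w in ordered:
            if prev is not None and prev.interval.overlaps(w.interval):
                raise ValueError(
                    f"overlapping windows {prev.interval} and {w.interval}"
                )
            prev = w
        for i, w in enumerate(ordered):
            w.index = i
        self.windows: list[GenomicWindow] = list(ordered)
        self.bin_size = int(bin_size)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[GenomicWindow]:
        return iter(self.windows)

    def __getitem__(self, i: int) -> GenomicWindow:
        return self.windows[i]

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.windows:
            seen.setdefault(w.interval.chrom, None)
        return list(seen)

    def gc(self) -> np.ndarray:
        """GC fractions as an array (NaN where unannotated)."""
        return np.array(
            [np.nan if w.gc_fraction is None else w.gc_fraction for w in self.windows]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [w.interval.chrom for w in self.windows],
                "start": [w.interval.start for w in self.windows],
                "end": [w.interval.end for w in self.windows],
                "index": [w.index for w in self.windows],
                "gc_fraction": [w.gc_fraction for w in self.windows],
                "arm_label": [w.arm_label for w in self.windows],
                "compartment_label": [w.compartment_label for w in self.windows],
            }
        )

    def to_bed(self, path: str) -> None:
        """Persist as BED4 (name column = window index) plus a sidecar
        ``<path>.annot.tsv`` carrying gc/arm/compartment annotations."""
        df = self.to_frame()
        df[["chrom", "start", "end", "index"]].to_csv(
            path, sep="\t", header=False, index=False
        )
        df[["index", "gc_fraction", "arm_label", "compartment_label"]].to_csv(
            f"{path}.annot.tsv", sep="\t", index=False
        )

    @classmethod
    def from_bed(cls, path: str, bin_size: int, provenance: str = "") -> "WindowSet":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "index"]
        )
        windows = [
            GenomicWindow(GenomicInterval(r.chrom, int(r.start), int(r.end)), int(r.index))
            for r in df.itertuples()
        ]
        ws = cls(windows, bin_size, provenance)
        import os

        annot = f"{path}.annot.tsv"
        if os.path.exists(annot):
            adf = pd.read_csv(annot, sep="\t").set_index("index")
            for w in ws.windows:
                row = adf.loc[w.index]
                if pd.notna(row["gc_fraction"]):
                    w.gc_fraction = float(row["gc_fraction"])
                if pd.notna(row["arm_label"]):
                    w.arm_label = str(row["arm_label"])
                if pd.notna(row["compartment_label"]):
                    w.compartment_label = str(row["compartment_label"])
        return ws


@dataclass
class ArmSet:
    """Non-overlapping chromosome arms, at most two per autosome."""

    arms: list[tuple[str, GenomicInterval]] = field(default_factory=list)

    def __post_init__(self) -> None:
        per_chrom: dict[str, int] = {}
        for label, iv in self.arms:
            per_chrom[iv.chrom] = per_chrom.get(iv.chrom, 0) + 1
            if per_chrom[iv.chrom] > 2:
                raise ValueError(f"more than two arms on {iv.chrom}")
        for i, (_, a) in enumerate(self.arms):
            for _, b in self.arms[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(f"overlapping arms {a} and {b}")

    def __len__(self) -> int:
        return len(self.arms)

    def labels(self) -> list[str]:
        return [label for label, _ in self.arms]

    def arm_of(self, chrom: str, pos: int) -> str | None:
        for label, iv in self.arms:
            if iv.contains_point(chrom, pos):
                return label
        return None


@dataclass
class PeakCluster:
    """A tissue-specific group of accessible-chromatin peaks."""

    cluster_id: int
    tissue_label: str
    peaks: list[GenomicInterval]

    def __len__(self) -> int:
        return len(self.peaks)
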