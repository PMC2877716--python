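"""Sliding-window counting and peak assembly for WT-vs-KO ChIP comparison.

The genome is tiled with overlapping windows (default 240 bp wide, every
10 bp).  Each window's statistic is ``D = R - N``: the wild-type tag count
minus the knockout-control tag count.  Windows overlapping a repeat-masked
base are excluded.  Windows with ``D >= d0`` (the critical difference from the
local-fdr fit) are significant; each contributes its 10 bp step-bin, adjacent
bins are unioned into peaks, peaks closer than 100 bp are merged into one
region, and regions of 20 bp or less are set aside as "too short" for motif
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import GenomeAnnotation, TagTrack
from .skellam_stats import LocFdrModel


@dataclass(frozen=True)
class WindowSpec:
    width: int = 240
    step: int = 10

    def __post_init__(self) -> None:
        if self.width <= 0 or self.step <= 0:
            raise ValueError("window width and step must be positive")
        if self.step > self.width:
            raise ValueError("step must not exceed window width")


@dataclass(frozen=True)
class WindowStat:
    """One genomic window with its WT/KO counts and difference."""

    chrom: str
    start: int
    end: int
    r: int
    n: int
    excluded: bool

    @property
    def d(self) -> int:
        return self.r - self.n


@dataclass
class WindowCounts:
    """Vectorized per-chromosome window statistics (column arrays)."""

    spec: WindowSpec
    starts: dict[str, np.ndarray] = field(default_factory=dict)
    r: dict[str, np.ndarray] = field(default_factory=dict)
    n: dict[str, np.ndarray] = field(default_factory=dict)
    excluded: dict[str, np.ndarray] = field(default_factory=dict)

    def chroms(self) -> list[str]:
        return list(self.starts)

    def d(self, chrom: str) -> np.ndarray:
        return self.r[chrom] - self.n[chrom]

    def nonexcluded_d(self) -> np.ndarray:
        """All D values over non-excluded windows, genome-wide."""
        parts = [self.d(c)[~self.excluded[c]] for c in self.chroms()]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    def nonexcluded_counts(self, sample: str) -> np.ndarray:
        src = self.r if sample == "wt" else self.n
        parts = [src[c][~self.excluded[c]] for c in self.chroms()]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    def __iter__(self):
        w = self.spec.width
        for chrom in self.chroms():
            for s, r, n, ex in zip(
                self.starts[chrom], self.r[chrom], self.n[chrom], self.excluded[chrom]
            ):
                yield WindowStat(chrom, int(s), int(s) + w, int(r), int(n), bool(ex))


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    n_windows: int = 0
    max_d: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


def count_windows(
    wt: TagTrack, ko: TagTrack, ann: GenomeAnnotation, spec: WindowSpec = WindowSpec()
) -> WindowCounts:
    """Count WT and KO tag 5' positions in sliding windows per chromosome.

    Windows start at multiples of ``step`` from 0; the final partial window at
    the chromosome end is dropped.  A tag is counted in a window when its 5'
    position lies in ``[start, start + width)``.  A window overlapping any
    masked base (by >= 1 bp) is flagged excluded.
    """
    for track, name in ((wt, "WT"), (ko, "KO")):
        unknown = set(track.positions) - set(ann.chrom_sizes)
        if unknown:
            raise ValueError(
                f"{name} tags on chromosomes absent from chrom sizes: {sorted(unknown)}"
            )

    wc = WindowCounts(spec=spec)
    for chrom, length in ann.chrom_sizes.items():
        if length < spec.width:
            continue
        starts = np.arange(0, length - spec.width + 1, spec.step, dtype=np.int64)
        ends = starts + spec.width
        wc.starts[chrom] = starts
        wc.r[chrom] = _count_in_windows(wt.chrom_positions(chrom), starts, ends)
        wc.n[chrom] = _count_in_windows(ko.chrom_positions(chrom), starts, ends)
        wc.excluded[chrom] = _overlaps_mask(
            starts, ends, ann.mask.get(chrom, np.empty((0, 2), dtype=np.int64))
        )
    return wc


def _count_in_windows(positions: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    return (
        np.searchsorted(positions, ends, side="left")
        - np.searchsorted(positions, starts, side="left")
    ).astype(np.int64)


def _overlaps_mask(starts: np.ndarray, ends: np.ndarray, mask: np.ndarray) -> np.ndarray:
    if len(mask) == 0:
        return np.zeros(len(starts), dtype=bool)
    # first mask interval whose end is > window start; overlap iff it begins
    # before the window ends (mask is sorted and non-overlapping)
    idx = np.searchsorted(mask[:, 1], starts, side="right")
    hit = idx < len(mask)
    out = np.zeros(len(starts), dtype=bool)
    out[hit] = mask[idx[hit], 0] < ends[hit]
    return out


def call_significant(
    wc: WindowCounts, model: LocFdrModel | None = None, d0: int | None = None
) -> dict[str, np.ndarray]:
    """Flag non-excluded windows with D >= d0 (from the model or an override)."""
    if d0 is None:
        if model is None or model.d0 is None:
            raise ValueError(
                "locFDR fit yielded no critical difference (d0 is undefined); "
                "pass an explicit d0 threshold"
            )
        d0 = model.d0
    return {c: (wc.d(c) >= d0) & ~wc.excluded[c] for c in wc.chroms()}


def assemble_peaks(
    wc: WindowCounts, significant: dict[str, np.ndarray], spec: WindowSpec | None = None
) -> list[Peak]:
    """Union the central step-bins of significant windows into peaks.

    Each significant window contributes one ``step``-wide bin centred on the
    window: ``[start + (width - step)//2, start + (width + step)//2)``.  A
    window's count is evidence about its middle, not its left edge, so the
    central bin keeps single-window peaks (the minimum, ``step`` bp) on top
    of the tag cluster.  Runs of adjacent bins become one peak, carrying the
    number of supporting windows and their maximum D.
    """
    spec = spec or wc.spec
    offset = (spec.width - spec.step) // 2
    peaks: list[Peak] = []
    for chrom in wc.chroms():
        sig = significant.get(chrom)
        if sig is None or not sig.any():
            continue
        starts = wc.starts[chrom][sig] + offset
        dvals = wc.d(chrom)[sig]
        run_start = starts[0]
        run_end = starts[0] + spec.step
        run_n, run_max = 1, dvals[0]
        for s, d in zip(starts[1:], dvals[1:]):
            if s <= run_end:  # adjacent or overlapping step-bin
                run_end = s + spec.step
                run_n += 1
                run_max = max(run_max, d)
            else:
                peaks.append(Peak(chrom, int(run_start), int(run_end), run_n, int(run_max)))
                run_start, run_end, run_n, run_max = s, s + spec.step, 1, d
        peaks.append(Peak(chrom, int(run_start), int(run_end), run_n, int(run_max)))
    return peaks


def merge_close_peaks(peaks: list[Peak], max_gap: int = 100) -> list[Peak]:
    """Replace peaks separated by <= max_gap bp with their spanning interval.

    Idempotent: the merged set has pairwise gaps > max_gap.
    """
    merged: list[Peak] = []
    for peak in sorted(peaks, key=lambda p: (p.chrom, p.start)):
        if (
            merged
            and merged[-1].chrom == peak.chrom
            and peak.start - merged[-1].end <= max_gap
        ):
            last = merged[-1]
            merged[-1] = Peak(
                last.chrom,
                last.start,
                max(last.end, peak.end),
                last.n_windows + peak.n_windows,
                max(last.max_d, peak.max_d),
            )
        else:
            merged.append(Peak(peak.chrom, peak.start, peak.end, peak.n_windows, peak.max_d))
    return merged


def filter_short(peaks: list[Peak], min_exclusive: int = 20) -> tuple[list[Peak], list[Peak]]:
    """Drop peaks of length <= min_exclusive bp; return (kept, too_short).

    The discarded peaks are retained so downstream tables can flag them
    "too short" rather than silently losing them.
    """
    kept = [p for p in peaks if p.length > min_exclusive]
    too_short = [p for p in peaks if p.length <= min_exclusive]
    return kept, too_short
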