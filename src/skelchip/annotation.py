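"""Peak positioning relative to gene annotation.

Each peak is summarized by its center; the signed distance to the nearest
annotated transcription start site (TSS) is negative when the peak center
lies upstream of the TSS on the gene's strand and positive downstream.
Downstream summaries are the counts of peaks within 1 kB and 10 kB of a TSS
(inclusive boundaries) and a 100 bp positional histogram over +/- 1 kB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import GenomeAnnotation
from .peak_calling import Peak


@dataclass(frozen=True)
class TssDistance:
    peak_id: str
    gene: str | None
    distance: int | None           # signed bp; None when no TSS on the chromosome
    within_1kb: bool = False
    within_10kb: bool = False


def nearest_tss(peak: Peak, ann: GenomeAnnotation, peak_id: str = "") -> TssDistance:
    """Signed distance from the peak center to the nearest TSS.

    The nearest TSS is chosen by absolute distance; equidistant candidates
    are resolved toward the upstream TSS (smaller genomic coordinate), then
    by lexicographic gene symbol.  Returns the None sentinel when the peak's
    chromosome carries no TSS.
    """
    center = (peak.start + peak.end) // 2
    candidates = ann.tss_on(peak.chrom)
    if not candidates:
        return TssDistance(peak_id=peak_id, gene=None, distance=None)
    best = min(candidates, key=lambda t: (abs(t.pos - center), t.pos, t.gene))
    if best.strand == "+":
        dist = center - best.pos
    else:
        dist = best.pos - center
    return TssDistance(
        peak_id=peak_id,
        gene=best.gene,
        distance=int(dist),
        within_1kb=abs(dist) <= 1000,
        within_10kb=abs(dist) <= 10000,
    )


def positional_histogram(
    distances, bin_width: int = 100, half_range: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of signed TSS distances in half-open bins over [-range, range).

    Returns ``(bin_edges, counts)`` with ``len(edges) == len(counts) + 1``.
    """
    if half_range % bin_width != 0:
        raise ValueError("bin width must divide the range")
    edges = np.arange(-half_range, half_range + bin_width, bin_width)
    vals = [d.distance if isinstance(d, TssDistance) else d for d in distances]
    vals = np.asarray([v for v in vals if v is not None], dtype=float)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    if len(vals):
        in_range = (vals >= -half_range) & (vals < half_range)
        idx = ((vals[in_range] + half_range) // bin_width).astype(np.int64)
        np.add.at(counts, idx, 1)
    return edges, counts


def proximity_tally(distances) -> tuple[int, int]:
    """(count within 10 kB, count within 1 kB), inclusive boundaries.

    The 1 kB set is a subset of the 10 kB set by construction.
    """
    vals = [d.distance if isinstance(d, TssDistance) else d for d in distances]
    vals = [v for v in vals if v is not None]
    within_10k = sum(1 for v in vals if abs(v) <= 10000)
    within_1k = sum(1 for v in vals if abs(v) <= 1000)
    return within_10k, within_1k
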