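"""Readers and writers for every on-disk representation the pipeline touches.

Coordinate conventions are fixed package-wide: all genomic intervals are
0-based, half-open (the BED dialect on disk).  A sequencing tag is reduced to
the 5' position of its mapped read: interval start on the + strand and
``end - 1`` on the - strand.  Duplicate tags are preserved — no PCR-duplicate
collapsing is performed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A malformed line in an input file (message carries the line number)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TssRecord:
    chrom: str
    pos: int
    strand: str
    gene: str


@dataclass
class GenomeAnnotation:
    """Chromosome sizes, TSS records, and merged repeat-mask intervals."""

    chrom_sizes: dict[str, int]
    tss: list[TssRecord] = field(default_factory=list)
    # per-chromosome (n, 2) arrays of sorted, non-overlapping [start, end)
    mask: dict[str, np.ndarray] = field(default_factory=dict)

    def tss_on(self, chrom: str) -> list[TssRecord]:
        return [t for t in self.tss if t.chrom == chrom]


@dataclass
class TagTrack:
    """Per-chromosome sorted tag 5' positions for one sample (WT or KO)."""

    label: str = ""
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    strands: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_tags(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.positions.get(chrom, np.empty(0, dtype=np.int64))


#: required columns of the Table-S4-style peak table
PEAK_TABLE_COLUMNS = ["location", "start", "end", "gene_symbol", "motif", "affinity"]


# ---------------------------------------------------------------------------
# tags
# ---------------------------------------------------------------------------

def _bed_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split()


def read_tags(path, chrom_sizes: dict[str, int] | None = None, label: str = "") -> TagTrack:
    """Read mapped tags from a BED3+ file into a sorted TagTrack.

    The tag position is the read's 5' end: the interval start for + strand
    records and ``end - 1`` for - strand records; a missing strand column is
    treated as +.  Duplicate positions are preserved.
    """
    pos: dict[str, list[int]] = {}
    strands: dict[str, list[str]] = {}
    for lineno, fields in _bed_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if end <= start or start < 0:
            raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        strand = fields[5] if len(fields) >= 6 else "+"
        if strand not in ("+", "-", "."):
            raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
        if strand == ".":
            strand = "+"
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > chrom_sizes[chrom]:
                raise ParseError(
                    f"{path}:{lineno}: interval end {end} beyond {chrom} "
                    f"length {chrom_sizes[chrom]}"
                )
        p = start if strand == "+" else end - 1
        pos.setdefault(chrom, []).append(p)
        strands.setdefault(chrom, []).append(strand)

    track = TagTrack(label=label)
    for chrom, plist in pos.items():
        arr = np.asarray(plist, dtype=np.int64)
        order = np.argsort(arr, kind="stable")
        track.positions[chrom] = arr[order]
        track.strands[chrom] = np.asarray(strands[chrom])[order]
    return track


def write_tags(track: TagTrack, path, read_len: int = 35) -> None:
    """Write a TagTrack as BED6, inverting the 5'-position convention."""
    with open(path, "w") as fh:
        for chrom in sorted(track.positions):
            for p, s in zip(track.positions[chrom], track.strands[chrom]):
                if s == "+":
                    start, end = p, p + read_len
                else:
                    start, end = p - read_len + 1, p + 1
                start = max(start, 0)
                fh.write(f"{chrom}\t{start}\t{end}\t.\t0\t{s}\n")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, fields in _bed_lines(path):
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'chrom\\tsize'")
        try:
            sizes[fields[0]] = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer size") from exc
    return sizes


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/adjacent-overlap [start, end) intervals."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(intervals, dtype=np.int64)
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def read_annotation(tss_path, mask_path, chrom_sizes_path) -> GenomeAnnotation:
    """Assemble a GenomeAnnotation from TSS BED, repeat-mask BED, and sizes.

    The TSS file is BED-like with the gene symbol in column 4 and strand in
    column 6; the TSS position is the interval start.  Mask intervals are
    normalized (sorted, overlaps merged).  A TSS at or beyond its chromosome
    length is an error.
    """
    sizes = read_chrom_sizes(chrom_sizes_path)
    ann = GenomeAnnotation(chrom_sizes=sizes)

    if tss_path is not None:
        for lineno, fields in _bed_lines(tss_path):
            if len(fields) < 3:
                raise ParseError(f"{tss_path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            if chrom not in sizes:
                raise ParseError(f"{tss_path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{tss_path}:{lineno}: non-integer position") from exc
            if pos < 0 or pos >= sizes[chrom]:
                raise ParseError(
                    f"{tss_path}:{lineno}: TSS {pos} outside {chrom} [0, {sizes[chrom]})"
                )
            gene = fields[3] if len(fields) >= 4 else ""
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand not in ("+", "-"):
                raise ParseError(f"{tss_path}:{lineno}: strand must be + or -")
            ann.tss.append(TssRecord(chrom=chrom, pos=pos, strand=strand, gene=gene))

    if mask_path is not None:
        raw: dict[str, list[list[int]]] = {}
        for lineno, fields in _bed_lines(mask_path):
            if len(fields) < 3:
                raise ParseError(f"{mask_path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            if chrom not in sizes:
                raise ParseError(f"{mask_path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{mask_path}:{lineno}: non-integer coordinates") from exc
            if s < 0 or e > sizes[chrom] or e <= s:
                raise ParseError(f"{mask_path}:{lineno}: invalid interval [{s}, {e})")
            raw.setdefault(chrom, []).append([s, e])
        for chrom, ivs in raw.items():
            ann.mask[chrom] = merge_intervals(np.asarray(ivs))

    return ann


# ---------------------------------------------------------------------------
# peak tables (Table-S4 style)
# ---------------------------------------------------------------------------

def write_peak_table(peaks: pd.DataFrame, path) -> None:
    """Write a peak table as TSV with the fixed column set."""
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak table missing required columns: {missing}")
    peaks.loc[:, PEAK_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_peak_table(path) -> pd.DataFrame:
    """Read a Table-S4-style TSV; flags like 'none'/'too short' round-trip."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"location": str, "gene_symbol": str, "motif": str, "affinity": str},
        keep_default_na=False,
    )
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table at {path} missing required columns: {missing}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"peak table at {path} has records with start >= end")
    return df.loc[:, PEAK_TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_sequence_list(path) -> list[str]:
    """Plain one-sequence-per-line list (SELEX pools)."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip().upper()
            if not line or line.startswith("#"):
                continue
            if set(line) - set("ACGTN"):
                raise ParseError(f"{path}:{lineno}: non-nucleotide characters")
            out.append(line)
    return out


def write_sequence_list(seqs, path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(s + "\n")


# ---------------------------------------------------------------------------
# expression tables and config
# ---------------------------------------------------------------------------

def read_expression_table(path) -> pd.DataFrame:
    """TSV with columns animal_id, genotype (WT|KO), target, reference."""
    df = pd.read_csv(path, sep="\t")
    required = ["animal_id", "genotype", "target", "reference"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing required columns: {missing}")
    if (df["reference"] <= 0).any():
        raise ValueError("reference (Gapdh) measures must be positive")
    bad = set(df["genotype"]) - {"WT", "KO"}
    if bad:
        raise ValueError(f"unknown genotypes: {sorted(bad)}")
    return df


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_config(path) -> dict[str, str]:
    """Plain-text ``key = value`` configuration, '#' comments allowed."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            cfg[key.strip()] = value.strip()
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for key, value in cfg.items():
            fh.write(f"{key} = {value}\n")
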