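"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical regime the analysis assumes: per-window
background tag counts R ~ Poisson(lam_r = 0.15273) and N ~ Poisson(lam_n =
0.21607) (the empirically estimated per-240bp-window rates of the matched
WT/KO ChIP libraries), a small fraction of signal windows carrying extra WT
tags, planted motif instances in the genome sequence, iterative SELEX
selection with a logistic affinity function, and two-group expression values.
Each generator is deterministic under a fixed seed and returns (or writes)
the planted truth alongside the data, so realized error rates and recovery
statistics can be computed without re-deriving ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .formats_io import TagTrack
from .motif_tools import MotifModel, scan_best_site
from .selex_pipeline import SelexPool

#: per-window background rates of the matched WT/KO libraries
DEFAULT_LAM_R = 0.15273
DEFAULT_LAM_N = 0.21607

#: fixed 25 bp PCR-primer flanks used by the synthetic SELEX oligos
#: (25 + 16 + 25 = 66 bp total context).  Chosen once, like real primers, to
#: be dissimilar to the selected consensus (best PWM log-odds < -8 anywhere
#: in flank-only context), so selection acts on the random insert.
DEFAULT_FLANK5 = "ATCGAGATAAGCTGCTAAAATGTTA"
DEFAULT_FLANK3 = "GAATTGTATGCTATCTAATTTAGTG"

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationTruth:
    """Ground truth serialized alongside every generated dataset."""

    seed: int
    lam_r: float = DEFAULT_LAM_R
    lam_n: float = DEFAULT_LAM_N
    pi1: float = 0.0
    enrichment: float = 0.0
    window_width: int = 240
    window_step: int = 10
    planted_peaks: list[tuple[str, int, int]] = field(default_factory=list)
    planted_motifs: list[tuple[str, int, str]] = field(default_factory=list)
    planted_pwm: np.ndarray | None = None
    selection_strength: float = 0.0
    group_means: tuple[float, ...] = ()
    group_sds: tuple[float, ...] = ()

    def to_files(self, prefix) -> None:
        """Write key-value truth parameters plus TSVs of planted features."""
        prefix = str(prefix)
        scalars = {
            k: v
            for k, v in asdict(self).items()
            if not isinstance(v, (list, tuple, np.ndarray)) and v is not None
        }
        with open(prefix + ".truth.txt", "w") as fh:
            for k, v in scalars.items():
                fh.write(f"{k} = {v}\n")
        if self.planted_peaks:
            pd.DataFrame(
                self.planted_peaks, columns=["chrom", "start", "end"]
            ).to_csv(prefix + ".peaks.tsv", sep="\t", index=False)
        if self.planted_motifs:
            pd.DataFrame(
                self.planted_motifs, columns=["chrom", "offset", "site"]
            ).to_csv(prefix + ".motifs.tsv", sep="\t", index=False)


def gen_window_counts(
    n_windows: int,
    lam_r: float = DEFAULT_LAM_R,
    lam_n: float = DEFAULT_LAM_N,
    pi1: float = 1e-4,
    enrichment: float = 5.0,
    seed: int | None = None,
):
    """Paired per-window (R, N) counts from the null/signal mixture.

    With probability ``1 - pi1`` a window is null (R ~ Pois(lam_r)); with
    probability ``pi1`` it carries ``enrichment`` extra expected WT tags
    (R ~ Pois(lam_r + enrichment)).  N ~ Pois(lam_n) throughout.  Returns
    ``(r, n, labels)`` with ``labels`` True for signal windows.
    """
    if n_windows < 1:
        raise ValueError("need at least one window")
    if lam_r < 0 or lam_n < 0 or enrichment < 0:
        raise ValueError("rates must be non-negative")
    if not (0.0 <= pi1 <= 1.0):
        raise ValueError("signal fraction pi1 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = rng.random(n_windows) < pi1
    rates = np.where(labels, lam_r + enrichment, lam_r)
    r = rng.poisson(rates)
    n = rng.poisson(lam_n, size=n_windows)
    return r.astype(np.int64), n.astype(np.int64), labels


def _random_seq(rng, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def random_sequences(n: int, length: int, seed: int | None = None) -> list[str]:
    """Uniform-random nucleotide sequences (background / control regions)."""
    rng = np.random.default_rng(seed)
    return [_random_seq(rng, length) for _ in range(n)]


def gen_motif_dataset(
    n_seqs: int = 50,
    seq_len: int = 100,
    motif: str = "AAAGCGAGGC",
    motif_pwm: np.ndarray | None = None,
    occupancy: float = 0.9,
    both_strands: bool = True,
    seed: int | None = None,
):
    """Planted-motif sequence set for motif-discovery benchmarking.

    Each sequence carries one motif instance with probability ``occupancy``
    (ZOOPS ground truth), drawn from ``motif_pwm`` when given and otherwise
    the exact ``motif``, on a random strand when ``both_strands``.  Returns
    ``(seqs, truth)`` where ``truth`` is a list of (seq_index, offset,
    site_as_planted) for the sequences that received a site.
    """
    from .motif_tools import revcomp

    rng = np.random.default_rng(seed)
    width = motif_pwm.shape[0] if motif_pwm is not None else len(motif)
    if seq_len < width:
        raise ValueError("sequences shorter than the planted motif")
    seqs: list[str] = []
    truth: list[tuple[int, int, str]] = []
    for i in range(n_seqs):
        s = _random_seq(rng, seq_len)
        if rng.random() < occupancy:
            site = sample_site(motif_pwm, rng) if motif_pwm is not None else motif
            placed = site
            if both_strands and rng.random() < 0.5:
                placed = revcomp(site)
            off = int(rng.integers(0, seq_len - width + 1))
            s = s[:off] + placed + s[off + width:]
            truth.append((i, off, placed))
        seqs.append(s)
    return seqs, truth


def sample_site(pwm: np.ndarray, rng) -> str:
    """Draw one site from a position frequency matrix."""
    return "".join(
        _BASES[rng.choice(4, p=col / col.sum())] for col in np.asarray(pwm, dtype=float)
    )


def pwm_from_iupac(pattern: str, strength: float = 0.9) -> np.ndarray:
    """PWM with ``strength`` total mass on each position's allowed bases."""
    from .motif_tools import IUPAC_SETS

    pwm = np.zeros((len(pattern), 4))
    for j, sym in enumerate(pattern.upper()):
        allowed = sorted(IUPAC_SETS[sym])
        if len(allowed) == 4:
            pwm[j] = 0.25
            continue
        for b in "ACGT":
            idx = "ACGT".index(b)
            if b in allowed:
                pwm[j, idx] = strength / len(allowed)
            else:
                pwm[j, idx] = (1.0 - strength) / (4 - len(allowed))
    return pwm


def gen_genome_and_tags(
    genome_length: int = 200_000,
    n_peaks: int = 20,
    chrom: str = "chrS",
    footprint: int = 60,
    enrichment: float = 15.0,
    lam_r: float = DEFAULT_LAM_R,
    lam_n: float = DEFAULT_LAM_N,
    window_width: int = 240,
    motif: str = "AAAGCGAGGC",
    motif_pwm: np.ndarray | None = None,
    min_separation: int = 2000,
    tss_positions=None,
    seed: int | None = None,
    planted_starts=None,
):
    """End-to-end fixture: genome FASTA content, WT/KO tag tracks, and truth.

    Background tags are placed uniformly per sample at a per-base rate of
    ``lam / window_width`` so the expected count in any window of that width
    equals ``lam``.  Each planted peak is a ``footprint``-bp region receiving
    Poisson(``enrichment``) extra WT tags and carrying one motif instance
    (drawn from ``motif_pwm`` when given, else the exact ``motif``) embedded
    in the genome sequence at the footprint center.

    Returns ``(genome, wt_track, ko_track, truth)`` with ``genome`` a
    ``{chrom: sequence}`` dict.
    """
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, genome_length))

    if planted_starts is None:
        starts = _place_nonoverlapping(
            rng, n_peaks, genome_length, footprint, window_width, min_separation
        )
    else:
        starts = sorted(int(s) for s in planted_starts)
        for a, b in zip(starts, starts[1:]):
            if b < a + footprint:
                raise ValueError(f"planted peaks at {a} and {b} overlap")
        if starts and (starts[0] < 0 or starts[-1] + footprint > genome_length):
            raise ValueError("planted peak outside genome bounds")

    truth = SimulationTruth(
        seed=-1 if seed is None else int(seed),
        lam_r=lam_r,
        lam_n=lam_n,
        enrichment=enrichment,
        window_width=window_width,
        planted_pwm=motif_pwm,
    )

    wt_pos: list[int] = []
    for start in starts:
        end = start + footprint
        site = sample_site(motif_pwm, rng) if motif_pwm is not None else motif
        m_off = start + (footprint - len(site)) // 2
        seq[m_off:m_off + len(site)] = list(site)
        truth.planted_peaks.append((chrom, start, end))
        truth.planted_motifs.append((chrom, m_off, site))
        n_extra = rng.poisson(enrichment)
        wt_pos.extend(rng.integers(start, end, size=n_extra).tolist())

    n_bg_wt = rng.poisson(genome_length * lam_r / window_width)
    n_bg_ko = rng.poisson(genome_length * lam_n / window_width)
    wt_pos.extend(rng.integers(0, genome_length, size=n_bg_wt).tolist())
    ko_pos = rng.integers(0, genome_length, size=n_bg_ko)

    def _track(label, positions):
        arr = np.sort(np.asarray(positions, dtype=np.int64))
        strands = np.where(rng.random(len(arr)) < 0.5, "+", "-")
        return TagTrack(label=label, positions={chrom: arr}, strands={chrom: strands})

    genome = {chrom: "".join(seq)}
    return genome, _track("WT", wt_pos), _track("KO", ko_pos), truth


def _place_nonoverlapping(rng, n, genome_length, footprint, margin, min_sep):
    if n == 0:
        return []
    lo, hi = margin, genome_length - margin - footprint
    if hi <= lo:
        raise ValueError("genome too short for the requested plants")
    starts: list[int] = []
    for _ in range(10_000):
        cand = int(rng.integers(lo, hi))
        if all(abs(cand - s) >= min_sep + footprint for s in starts):
            starts.append(cand)
            if len(starts) == n:
                return sorted(starts)
    raise ValueError(f"could not place {n} peaks with separation {min_sep}")


def gen_selex(
    pool_size: int = 50_000,
    insert_len: int = 16,
    flank5: str = DEFAULT_FLANK5,
    flank3: str = DEFAULT_FLANK3,
    pwm: np.ndarray | None = None,
    rounds: int = 4,
    selection_strength: float = 1.5,
    selection_midpoint: float = 12.0,
    seed: int | None = None,
):
    """Simulated binding-site selection over a random-insert oligo pool.

    Round 0 holds uniform-random inserts.  Each later round keeps a sequence
    with probability ``logistic(selection_strength * (best-site PWM log-odds
    over the insert+flank context - selection_midpoint))`` — the standard
    occupancy form, with the midpoint playing the role of the affinity at
    which half the molecules are bound — then replenishes the pool to
    ``pool_size`` by resampling survivors with replacement (the
    PCR-amplification surrogate).  The pool must be large enough for strong
    sites to exist in round 0 at all; at the default size a handful of
    near-consensus inserts found the selected population, mirroring the low
    sequence diversity of cloned selection outputs.

    Returns ``(pools, truth)`` with one SelexPool per round 0..rounds.
    """
    if pool_size < 10:
        raise ValueError("pool_size must be >= 10")
    rng = np.random.default_rng(seed)
    if pwm is None:
        pwm = pwm_from_iupac("YSANAACGAGGC", strength=0.9)
    model = MotifModel.from_pfm(pwm)

    inserts = [_random_seq(rng, insert_len) for _ in range(pool_size)]
    pools = [SelexPool(round_no=0, inserts=list(inserts), flank5=flank5, flank3=flank3)]
    for rnd in range(1, rounds + 1):
        scores = np.array(
            [
                scan_best_site(flank5 + ins + flank3, model).log_odds
                for ins in inserts
            ]
        )
        keep_prob = expit(selection_strength * (scores - selection_midpoint))
        kept = [ins for ins, p in zip(inserts, keep_prob) if rng.random() < p]
        if not kept:
            # selection wiped the pool: carry the single most bindable oligo
            kept = [inserts[int(np.argmax(scores))]]
        idx = rng.integers(0, len(kept), size=pool_size)
        inserts = [kept[i] for i in idx]
        pools.append(
            SelexPool(round_no=rnd, inserts=list(inserts), flank5=flank5, flank3=flank3)
        )

    truth = SimulationTruth(
        seed=-1 if seed is None else int(seed),
        planted_pwm=np.asarray(pwm, dtype=float),
        selection_strength=selection_strength,
    )
    return pools, truth


def gen_expression(
    group_means=(1.0, 1.37),
    group_sds=(0.17, 0.25),
    n_per_group: int = 8,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-genotype expression table with normal per-animal target measures.

    Reference (Gapdh) measures are fixed at 1 so the target column is already
    the normalized ratio.  Defaults correspond to a modest (37%) up-regulation
    in the knockout with per-animal SDs of SEM * sqrt(n) scale.
    """
    if any(sd < 0 for sd in group_sds):
        raise ValueError("group SDs must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, mean, sd in zip(("WT", "KO"), group_means, group_sds):
        values = rng.normal(mean, sd, size=n_per_group)
        for i, v in enumerate(values):
            rows.append(
                {
                    "animal_id": f"{genotype}{i + 1}",
                    "genotype": genotype,
                    "target": float(v),
                    "reference": 1.0,
                }
            )
    return pd.DataFrame(rows)
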