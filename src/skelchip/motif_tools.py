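"""Gibbs-sampling motif discovery, PWM utilities, and affinity classification.

The sampler implements a ZOOPS model (zero or one motif occurrence per
sequence): in each iteration one sequence is withheld, a position frequency
matrix is rebuilt from the site assignments of the remaining sequences, and
the withheld sequence's site variable is resampled over all offsets on both
strands plus an explicit "absent" state, under a uniform positional prior.
Sequence likelihoods outside the motif are modelled with an order-k Markov
background (default order 3, add-one pseudocounts, lower-order fallback at
sequence starts).

The positional affinity classifier encodes the base requirements of the 10 bp
in vivo consensus (chCaRE): binding is essentially abolished by changes at
positions 3, 6, 7, 8 (Low), partially impaired by changes at 1, 9, 10
(Medium), and tolerant of any base at positions 2, 4, 5 (High).  The
unchanged reference 10-mer is AAAGCGAGGC (camCaRE, the Camk2n1 peak site).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_CODE["N"] = 4
_COMP = str.maketrans("ACGTN", "TGCAN")

#: two-base IUPAC degeneracy codes
IUPAC_2 = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[b] for b in seq.upper()), dtype=np.int8, count=len(seq))


def iupac_compatible(a: str, b: str) -> bool:
    """Whether two IUPAC symbols admit at least one common base."""
    return bool(IUPAC_SETS[a.upper()] & IUPAC_SETS[b.upper()])


# ---------------------------------------------------------------------------
# Markov background
# ---------------------------------------------------------------------------

class BackgroundModel:
    """Order-k Markov model of genomic background sequence.

    Conditional next-base probabilities are estimated with add-one
    pseudocounts for every context length 0..k; contexts shorter than k (at
    sequence starts) or unseen in training fall back to the longest available
    lower order.  Positions containing N are skipped during training and
    scored at order 0 uniform fallback.
    """

    def __init__(self, order: int = 3):
        if order < 0:
            raise ValueError("background order must be >= 0")
        self.order = order
        # per order: context string -> log2 conditional probabilities (len 4)
        self._logp: list[dict[str, np.ndarray]] = [{} for _ in range(order + 1)]
        self._counts: list[dict[str, np.ndarray]] = [{} for _ in range(order + 1)]

    def train(self, seqs) -> "BackgroundModel":
        for seq in seqs:
            s = seq.upper()
            for i, base in enumerate(s):
                if base not in _BASES:
                    continue
                for m in range(min(i, self.order) + 1):
                    ctx = s[i - m:i]
                    if "N" in ctx:
                        continue
                    cnt = self._counts[m].setdefault(ctx, np.zeros(4))
                    cnt[_CODE[base]] += 1.0
        for m in range(self.order + 1):
            for ctx, cnt in self._counts[m].items():
                self._logp[m][ctx] = np.log2((cnt + 1.0) / (cnt.sum() + 4.0))
        if "" not in self._logp[0]:
            self._logp[0][""] = np.full(4, -2.0)  # untrained: uniform
        return self

    def logp_base(self, context: str, base: str) -> float:
        """log2 P(base | context) with lower-order fallback."""
        if base not in _BASES:
            return -2.0
        ctx = context.upper()[-self.order:] if self.order else ""
        for m in range(len(ctx), -1, -1):
            table = self._logp[m].get(ctx[len(ctx) - m:])
            if table is not None:
                return float(table[_CODE[base]])
        return -2.0

    def logp_kmer(self, kmer: str) -> float:
        """log2 probability of a k-mer scored left-to-right from no context."""
        s = kmer.upper()
        return sum(self.logp_base(s[max(0, i - self.order):i], s[i]) for i in range(len(s)))

    def logp_seq(self, seq: str) -> float:
        return self.logp_kmer(seq)


def train_background(seqs, k: int = 3) -> BackgroundModel:
    """Train an order-k Markov background on nucleotide sequences."""
    return BackgroundModel(order=k).train(seqs)


# ---------------------------------------------------------------------------
# motif model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifSite:
    seq_index: int
    offset: int      # forward-strand coordinate of the site's left edge
    strand: str      # '+' or '-'
    kmer: str        # the site as read on its strand


@dataclass
class MotifModel:
    width: int
    pfm: np.ndarray                 # (W, 4) column-stochastic frequencies
    sites: list[MotifSite] = field(default_factory=list)
    score: float = 0.0              # total log2 likelihood ratio over sites

    @property
    def consensus(self) -> str:
        return iupac_consensus(self.pfm)

    @property
    def information_content(self) -> np.ndarray:
        return information_content(self.pfm)

    @classmethod
    def from_pfm(cls, pfm) -> "MotifModel":
        pfm = np.asarray(pfm, dtype=float)
        return cls(width=pfm.shape[0], pfm=pfm)

    @classmethod
    def from_sites(cls, kmers, pseudocount: float = 0.25) -> "MotifModel":
        if not kmers:
            raise ValueError("need at least one site")
        W = len(kmers[0])
        counts = np.full((W, 4), pseudocount)
        for kmer in kmers:
            for j, b in enumerate(kmer.upper()):
                counts[j, _CODE[b]] += 1.0
        pfm = counts / counts.sum(axis=1, keepdims=True)
        return cls(width=W, pfm=pfm)

    def log_odds(self, kmer: str, background: BackgroundModel | None = None) -> float:
        idx = encode(kmer)
        lp = float(np.log2(self.pfm[np.arange(self.width), idx]).sum())
        bg = background.logp_kmer(kmer) if background else -2.0 * self.width
        return lp - bg


def iupac_consensus(pfm, single: float = 0.6, pair: float = 0.8) -> str:
    """Degenerate consensus: one base if its frequency >= ``single``; a
    two-base IUPAC code if the top two sum to >= ``pair`` (and no single base
    qualifies); otherwise N."""
    pfm = np.asarray(pfm, dtype=float)
    out = []
    for col in pfm:
        order = np.argsort(col)[::-1]
        if col[order[0]] >= single:
            out.append(_BASES[order[0]])
        elif col[order[0]] + col[order[1]] >= pair:
            out.append(IUPAC_2[frozenset(_BASES[i] for i in order[:2])])
        else:
            out.append("N")
    return "".join(out)


def information_content(pfm) -> np.ndarray:
    """Per-column information content in bits: 2 + sum_b p log2 p."""
    pfm = np.asarray(pfm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pfm > 0, pfm * np.log2(pfm), 0.0)
    return 2.0 + plogp.sum(axis=1)


def score_motif(model: MotifModel, background: BackgroundModel) -> float:
    """Total log2 likelihood ratio of the model's sites vs the background.

    Additive over sites; zero for an empty site list.
    """
    total = 0.0
    logpfm = np.log2(model.pfm)
    for site in model.sites:
        idx = encode(site.kmer)
        total += float(logpfm[np.arange(model.width), idx].sum())
        total -= background.logp_kmer(site.kmer)
    return total


# ---------------------------------------------------------------------------
# Gibbs sampler (ZOOPS)
# ---------------------------------------------------------------------------

class _SeqWindows:
    """Precomputed window index matrices and background scores per strand."""

    def __init__(self, seq: str, width: int, background: BackgroundModel):
        self.length = len(seq)
        self.width = width
        fw = encode(seq)
        rv = encode(revcomp(seq))
        n_off = self.length - width + 1
        sw = np.lib.stride_tricks.sliding_window_view
        self.win_fw = sw(fw, width)[:n_off].astype(np.int64)
        self.win_rv = sw(rv, width)[:n_off].astype(np.int64)
        self.valid_fw = ~(self.win_fw == 4).any(axis=1)
        self.valid_rv = ~(self.win_rv == 4).any(axis=1)
        seq_u = seq.upper()
        rv_u = revcomp(seq_u)
        self.bg_fw = np.array(
            [background.logp_kmer(seq_u[o:o + width]) for o in range(n_off)]
        )
        self.bg_rv = np.array(
            [background.logp_kmer(rv_u[o:o + width]) for o in range(n_off)]
        )
        self.n_off = n_off


def gibbs_search(
    seqs,
    width: int = 10,
    trials: int = 20,
    iterations: int = 10000,
    background: BackgroundModel | None = None,
    seed: int | None = None,
    absent_weight: float = 0.1,
    pseudocount: float = 0.25,
) -> MotifModel:
    """ZOOPS Gibbs sampling motif discovery over both strands.

    Runs ``trials`` independent restarts of ``iterations`` single-sequence
    resampling steps each and returns the best-scoring model.  Deterministic
    for a fixed seed.  Sequences shorter than ``width`` are skipped with a
    warning (they are too short to meaningfully search).
    """
    seqs = [s.upper() for s in seqs]
    keep_idx = [i for i, s in enumerate(seqs) if len(s) >= width]
    if len(keep_idx) < len(seqs):
        warnings.warn(
            f"skipping {len(seqs) - len(keep_idx)} sequence(s) shorter than "
            f"motif width {width}",
            stacklevel=2,
        )
    if not keep_idx:
        raise ValueError(f"all sequences are shorter than the motif width {width}")

    if background is None:
        background = train_background([seqs[i] for i in keep_idx], k=3)

    prep = [_SeqWindows(seqs[i], width, background) for i in keep_idx]
    n = len(prep)
    ln2 = np.log(2.0)

    master = np.random.default_rng(seed)
    best_score, best_state = -np.inf, None

    for trial in range(trials):
        rng = np.random.default_rng(master.integers(0, 2**31))
        # state per sequence: (strand 0=+,1=-, offset) or None for absent
        state: list[tuple[int, int] | None] = []
        for sw in prep:
            choices = [(0, o) for o in np.flatnonzero(sw.valid_fw)] + [
                (1, o) for o in np.flatnonzero(sw.valid_rv)
            ]
            state.append(tuple(choices[rng.integers(len(choices))]) if choices else None)

        counts = np.full((width, 4), pseudocount)
        for i, st in enumerate(state):
            if st is not None:
                counts[np.arange(width), _site_codes(prep[i], st)] += 1.0

        trial_best, trial_state = -np.inf, None
        for it in range(iterations):
            i = it % n
            sw = prep[i]
            if state[i] is not None:
                counts[np.arange(width), _site_codes(sw, state[i])] -= 1.0

            logpfm = np.log2(counts / counts.sum(axis=1, keepdims=True))
            s_fw = logpfm[np.arange(width), sw.win_fw].sum(axis=1) - sw.bg_fw
            s_rv = logpfm[np.arange(width), sw.win_rv].sum(axis=1) - sw.bg_rv
            n_states = int(sw.valid_fw.sum() + sw.valid_rv.sum())
            if n_states == 0:
                state[i] = None
                continue
            prior = np.log2((1.0 - absent_weight) / n_states)
            lw = np.concatenate(
                [
                    np.where(sw.valid_fw, s_fw + prior, -np.inf),
                    np.where(sw.valid_rv, s_rv + prior, -np.inf),
                    [np.log2(absent_weight)],
                ]
            )
            w = np.exp((lw - lw.max()) * ln2)
            w /= w.sum()
            pick = int(rng.choice(len(w), p=w))
            if pick == 2 * sw.n_off:
                state[i] = None
            elif pick < sw.n_off:
                state[i] = (0, pick)
                counts[np.arange(width), sw.win_fw[pick]] += 1.0
            else:
                state[i] = (1, pick - sw.n_off)
                counts[np.arange(width), sw.win_rv[pick - sw.n_off]] += 1.0

            if i == n - 1:  # end of sweep: phase-shift move, then score
                state, counts = _shift_move(prep, state, width, pseudocount)
                sc = _state_score(prep, state, counts, width)
                if sc > trial_best:
                    trial_best, trial_state = sc, list(state)

        sc = _state_score(prep, state, counts, width)
        if sc > trial_best:
            trial_best, trial_state = sc, list(state)
        if trial_best > best_score:
            best_score, best_state = trial_best, trial_state

    return _build_model(
        seqs, keep_idx, prep, best_state, width, pseudocount, background
    )


def _build_counts(prep, state, width, pseudocount) -> np.ndarray:
    counts = np.full((width, 4), pseudocount)
    for sw, st in zip(prep, state):
        if st is not None:
            counts[np.arange(width), _site_codes(sw, st)] += 1.0
    return counts


def _shift_move(prep, state, width, pseudocount):
    """Greedy whole-alignment shift by -2..2 strand-local positions.

    The site sampler alone tends to lock onto a register displaced by a base
    or two from the optimum; shifting every present site in its own reading
    direction escapes that local mode.  A shift is only considered when every
    present site stays in bounds and N-free.
    """
    base_counts = _build_counts(prep, state, width, pseudocount)
    best = (_state_score(prep, state, base_counts, width), state, base_counts)
    for delta in (-2, -1, 1, 2):
        shifted = []
        for sw, st in zip(prep, state):
            if st is None:
                shifted.append(None)
                continue
            strand, off = st
            new = off + delta
            valid = sw.valid_fw if strand == 0 else sw.valid_rv
            if new < 0 or new >= sw.n_off or not valid[new]:
                shifted.append(st)  # cannot shift: keep; resampled next sweep
            else:
                shifted.append((strand, new))
        cnt = _build_counts(prep, shifted, width, pseudocount)
        sc = _state_score(prep, shifted, cnt, width)
        if sc > best[0]:
            best = (sc, shifted, cnt)
    return best[1], best[2]


def _site_codes(sw: _SeqWindows, st: tuple[int, int]) -> np.ndarray:
    strand, off = st
    return sw.win_fw[off] if strand == 0 else sw.win_rv[off]


def _state_score(prep, state, counts, width) -> float:
    logpfm = np.log2(counts / counts.sum(axis=1, keepdims=True))
    total = 0.0
    for sw, st in zip(prep, state):
        if st is None:
            continue
        strand, off = st
        codes = sw.win_fw[off] if strand == 0 else sw.win_rv[off]
        bg = sw.bg_fw[off] if strand == 0 else sw.bg_rv[off]
        total += float(logpfm[np.arange(width), codes].sum()) - bg
    return total


def _build_model(seqs, keep_idx, prep, state, width, pseudocount, background) -> MotifModel:
    sites: list[MotifSite] = []
    kmers: list[str] = []
    for local_i, st in enumerate(state):
        if st is None:
            continue
        strand, off = st
        seq_i = keep_idx[local_i]
        seq = seqs[seq_i]
        if strand == 0:
            kmer = seq[off:off + width]
            fw_off = off
            strand_c = "+"
        else:
            # rv offset o covers forward interval [L - W - o, L - o)
            fw_off = prep[local_i].length - width - off
            kmer = revcomp(seq[fw_off:fw_off + width])
            strand_c = "-"
        sites.append(MotifSite(seq_index=seq_i, offset=fw_off, strand=strand_c, kmer=kmer))
        kmers.append(kmer)
    if not kmers:
        raise ValueError("sampler converged to an all-absent state")
    model = MotifModel.from_sites(kmers, pseudocount=pseudocount)
    model.sites = sites
    model.score = score_motif(model, background)
    return model


def revcomp_model(model: MotifModel) -> MotifModel:
    """The same motif read on the opposite strand."""
    flipped = MotifModel(
        width=model.width,
        pfm=model.pfm[::-1, ::-1].copy(),
        sites=[
            MotifSite(s.seq_index, s.offset, "-" if s.strand == "+" else "+", revcomp(s.kmer))
            for s in model.sites
        ],
        score=model.score,
    )
    return flipped


def orient_model(model: MotifModel, reference: str) -> MotifModel:
    """Orient a discovered motif toward a reference site.

    A sampler returns the motif in an arbitrary orientation; this picks the
    strand whose PFM gives the reference k-mer the higher likelihood.  A
    no-op when widths differ or the motif is unrelated (either orientation
    is then as good as the other).
    """
    if len(reference) != model.width:
        return model
    flipped = revcomp_model(model)
    idx = encode(reference)
    pos = np.arange(model.width)
    fw = float(np.log2(model.pfm[pos, idx]).sum())
    rv = float(np.log2(flipped.pfm[pos, idx]).sum())
    return flipped if rv > fw else model


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanResult:
    status: str                 # "ok" | "none" | "too_short"
    offset: int | None = None
    strand: str | None = None
    site: str | None = None
    log_odds: float | None = None


def scan_best_site(
    seq: str,
    model: MotifModel,
    background: BackgroundModel | None = None,
    floor: float | None = None,
) -> ScanResult:
    """Best motif instance in a sequence over all offsets and both strands.

    Ties are broken by the smallest offset, then the + strand.  When a
    ``floor`` is given and the best log-odds falls below it, the result is
    the "none" sentinel; a sequence shorter than the motif width yields the
    "too_short" sentinel.
    """
    seq = seq.upper()
    W = model.width
    if len(seq) < W:
        return ScanResult(status="too_short")
    if background is None and "N" not in seq:
        return _scan_uniform_bg(seq, model, floor)
    best = None
    logpfm = np.log2(model.pfm)
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        for off in range(len(s) - W + 1):
            kmer = s[off:off + W]
            if "N" in kmer:
                continue
            idx = encode(kmer)
            lp = float(logpfm[np.arange(W), idx].sum())
            bg = background.logp_kmer(kmer) if background else -2.0 * W
            lo = lp - bg
            fw_off = off if strand == "+" else len(seq) - W - off
            key = (-lo, fw_off, 0 if strand == "+" else 1)
            if best is None or key < best[0]:
                best = (key, ScanResult("ok", fw_off, strand, kmer, lo))
    if best is None:
        return ScanResult(status="none")
    result = best[1]
    if floor is not None and result.log_odds < floor:
        return ScanResult(status="none")
    return result


def _scan_uniform_bg(seq: str, model: MotifModel, floor: float | None) -> ScanResult:
    """Vectorized scan against the uniform background (N-free sequences)."""
    W = model.width
    logpfm = np.log2(model.pfm)
    sw = np.lib.stride_tricks.sliding_window_view
    pos = np.arange(W)
    fw = encode(seq).astype(np.int64)
    rv = encode(revcomp(seq)).astype(np.int64)
    s_fw = logpfm[pos, sw(fw, W)].sum(axis=1) + 2.0 * W
    s_rv = logpfm[pos, sw(rv, W)].sum(axis=1) + 2.0 * W
    n_off = len(s_fw)
    # express both strands in forward coordinates; prefer + on ties
    fw_off_rv = n_off - 1 - np.arange(n_off)
    cand_scores = np.concatenate([s_fw, s_rv])
    cand_off = np.concatenate([np.arange(n_off), fw_off_rv])
    cand_strand = np.concatenate([np.zeros(n_off, int), np.ones(n_off, int)])
    order = np.lexsort((cand_strand, cand_off, -cand_scores))
    k = order[0]
    lo = float(cand_scores[k])
    if floor is not None and lo < floor:
        return ScanResult(status="none")
    off, strand = int(cand_off[k]), "+" if cand_strand[k] == 0 else "-"
    kmer = seq[off:off + W] if strand == "+" else revcomp(seq[off:off + W])
    return ScanResult("ok", off, strand, kmer, lo)


# ---------------------------------------------------------------------------
# affinity classification
# ---------------------------------------------------------------------------

#: reference (preferred) base per 1-based position of the 10 bp motif;
#: positions 2, 4, 5 carry no constraint
REFERENCE_SITE = "AAAGCGAGGC"
PREFERRED_BASES = {1: "A", 3: "A", 6: "G", 7: "A", 8: "G", 9: "G", 10: "C"}
CRITICAL_POSITIONS = {3, 6, 7, 8}    # changes abolish binding
PERIPHERAL_POSITIONS = {1, 9, 10}    # changes partially impair binding


@dataclass(frozen=True)
class AffinityCall:
    site: str
    category: str                    # High | Medium | Low
    changed_positions: tuple[int, ...]


def classify_affinity(site: str) -> AffinityCall:
    """Predict EMSA binding affinity of a 10-mer motif instance.

    Low: any deviation from the preferred base at positions 3, 6, 7 or 8;
    Medium: otherwise, any deviation at positions 1, 9 or 10; High: none.
    """
    s = site.upper()
    if len(s) != 10:
        raise ValueError(f"affinity classification requires a 10-mer, got {len(s)} bases")
    if set(s) - set(_BASES):
        raise ValueError(f"site contains non-ACGT characters: {site!r}")
    changed = tuple(
        pos for pos, base in PREFERRED_BASES.items() if s[pos - 1] != base
    )
    if any(pos in CRITICAL_POSITIONS for pos in changed):
        category = "Low"
    elif any(pos in PERIPHERAL_POSITIONS for pos in changed):
        category = "Medium"
    else:
        category = "High"
    return AffinityCall(site=s, category=category, changed_positions=changed)
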