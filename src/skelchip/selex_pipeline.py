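"""Consensus construction from binding-site-selection (SELEX) oligo pools.

A SELEX experiment starts from a pool of oligos carrying a random insert
(here 16 bp) between fixed PCR-primer flanks (66 bp total context) and
iteratively enriches protein-bound sequences over several selection rounds.
The final pool is aligned with the fixed-width Gibbs sampler from
``motif_tools`` to extract a degenerate consensus binding element.  The
sampler replaces a progressive multiple aligner here: for fixed-width motif
extraction from short oligos it is the stronger and better-specified tool.

Because the selected motif can straddle the insert/flank boundary, the flanks
are included in the searched context by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motif_tools import (
    BackgroundModel,
    MotifModel,
    gibbs_search,
    scan_best_site,
    train_background,
)


@dataclass
class SelexPool:
    """One round of a selection experiment: inserts plus fixed flanks."""

    round_no: int
    inserts: list[str]
    flank5: str = ""
    flank3: str = ""

    def full_sequences(self) -> list[str]:
        return [self.flank5 + ins + self.flank3 for ins in self.inserts]

    def anchored_sequences(self, width: int) -> list[str]:
        """Insert plus ``width // 4`` flank bases per side.

        Every ``width``-length window of this context then draws at least
        three quarters of its bases from the variable insert.  Windows dominated by the
        constant primer flanks — which are shared by every oligo and hence
        look perfectly "conserved" to any motif finder — are unreachable,
        while sites straddling the insert/flank boundary remain findable.
        """
        keep = width // 4
        f5 = self.flank5[len(self.flank5) - keep:] if keep else ""
        f3 = self.flank3[:keep]
        return [f5 + ins + f3 for ins in self.inserts]

    def sample_clones(self, n: int, seed: int | None = None) -> "SelexPool":
        """A cloned-and-sequenced subset of the pool (without replacement)."""
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(self.inserts), size=min(n, len(self.inserts)), replace=False)
        return SelexPool(
            round_no=self.round_no,
            inserts=[self.inserts[i] for i in idx],
            flank5=self.flank5,
            flank3=self.flank3,
        )

    def __post_init__(self) -> None:
        if self.round_no < 0:
            raise ValueError("round number must be >= 0")


def selex_consensus(
    pool,
    width: int = 12,
    include_flanks: bool = True,
    background: BackgroundModel | None = None,
    trials: int = 8,
    iterations: int = 2000,
    seed: int | None = None,
) -> MotifModel:
    """Extract a fixed-width consensus motif from a final selection pool.

    ``pool`` may be a SelexPool or a plain list of sequences.  With
    ``include_flanks`` (default) the sampler searches the insert plus
    ``width - 1`` bases of flank on each side, so consensus sites straddling
    the insert/flank boundary are found while windows lying wholly inside
    the constant primer flanks (shared by every oligo and therefore always
    perfectly "conserved") are unreachable.  On flank-free input the flag is
    a no-op.
    """
    if isinstance(pool, SelexPool):
        seqs = pool.anchored_sequences(width) if include_flanks else list(pool.inserts)
    else:
        seqs = list(pool)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to build a consensus")
    if all(len(s) < width for s in seqs):
        raise ValueError(f"motif width {width} exceeds every sequence length")
    if background is None:
        background = train_background(seqs, k=3)
    return gibbs_search(
        seqs,
        width=width,
        trials=trials,
        iterations=iterations,
        background=background,
        seed=seed,
    )


def enrichment_trace(
    pools: list[SelexPool],
    model,
    background: BackgroundModel | None = None,
    include_flanks: bool = True,
) -> np.ndarray:
    """Mean best-site log-odds per selection round against a given PWM.

    A diagnostic of selection pressure: on synthetic positively-selected
    pools the trace is non-decreasing; no stronger claim is made.
    """
    if len(pools) < 2:
        raise ValueError("need at least 2 rounds for a trace")
    if not isinstance(model, MotifModel):
        model = MotifModel.from_pfm(model)
    out = []
    for pool in pools:
        seqs = pool.full_sequences() if include_flanks else pool.inserts
        if not seqs:
            raise ValueError(f"round {pool.round_no} pool is empty")
        scores = [
            scan_best_site(s, model, background=background).log_odds for s in seqs
        ]
        out.append(float(np.mean(scores)))
    return np.asarray(out)
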