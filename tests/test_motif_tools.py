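"""Background model, Gibbs sampler, PWM utilities, affinity classifier."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from skelchip import motif_tools as mt
from skelchip import synthetic_data as sd


@pytest.fixture(scope="module")
def big_background():
    # order-3 conditionals need a large training corpus to be stable
    return mt.train_background(sd.random_sequences(1, 100_000, seed=999), k=3)


class TestBackgroundModel:
    def test_add_one_pseudocount_arithmetic(self):
        bg = mt.train_background(["AAAAAAAA"], k=3)
        # context AAA is followed by A five times: (5+1)/(5+4) = 2/3
        assert 2.0 ** bg.logp_base("AAA", "A") == pytest.approx(2.0 / 3.0)
        others = [2.0 ** bg.logp_base("AAA", b) for b in "CGT"]
        assert all(p < 2.0 / 3.0 for p in others)

    def test_order_zero_uniform_after_pseudocounts(self):
        bg = mt.train_background(["ACGT"], k=0)
        for b in "ACGT":
            assert 2.0 ** bg.logp_base("", b) == pytest.approx((1 + 1) / (4 + 4))

    def test_conditionals_normalized(self):
        bg = mt.train_background(sd.random_sequences(5, 200, seed=3), k=3)
        for order_table in bg._logp:
            for logp in order_table.values():
                assert np.sum(2.0 ** logp) == pytest.approx(1.0, abs=1e-9)

    def test_own_model_likelihood_beats_shuffled_model(self, rng):
        # trained model should fit its own training sequence at least as well
        # as a model trained on a shuffled version of it
        seq = "".join(rng.choice(list("AACGT"), size=500))  # A-rich bias
        shuffled = "".join(rng.permutation(list(seq.replace("A", "T"))))
        own = mt.train_background([seq], k=2)
        other = mt.train_background([shuffled], k=2)
        assert own.logp_seq(seq) > other.logp_seq(seq)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            mt.train_background(["ACGT"], k=-1)


class TestPwmUtilities:
    def test_iupac_consensus_thresholds(self):
        col = lambda a=0.0, c=0.0, g=0.0, t=0.0: [a, c, g, t]
        pfm = np.array(
            [
                col(a=1.0),
                col(a=0.5, g=0.5),
                col(a=0.3, c=0.3, g=0.2, t=0.2),
            ]
        )
        assert mt.iupac_consensus(pfm) == "ARN"

    def test_information_content_closed_forms(self):
        pfm = np.array(
            [[1.0, 0, 0, 0], [0.25, 0.25, 0.25, 0.25], [0.5, 0.5, 0, 0]]
        )
        np.testing.assert_allclose(mt.information_content(pfm), [2.0, 0.0, 1.0], atol=1e-12)

    @given(perm=st.permutations(range(6)))
    def test_consensus_consistent_under_column_permutation(self, perm):
        rng = np.random.default_rng(5)
        pfm = rng.dirichlet(np.full(4, 0.4), size=6)
        base = mt.iupac_consensus(pfm)
        permuted = mt.iupac_consensus(pfm[list(perm)])
        assert permuted == "".join(base[i] for i in perm)

    def test_score_motif_empty_sites_is_zero(self, big_background):
        model = mt.MotifModel.from_pfm(np.full((10, 4), 0.25))
        assert mt.score_motif(model, big_background) == 0.0

    def test_score_motif_near_deterministic_closed_form(self):
        eps = 1e-3
        W = 8
        pfm = np.full((W, 4), eps)
        pfm[:, 0] = 1.0 - 3 * eps
        model = mt.MotifModel.from_pfm(pfm)
        model.sites = [mt.MotifSite(0, 0, "+", "A" * W)]
        bg = mt.BackgroundModel(order=0).train(sd.random_sequences(1, 40_000, seed=1))
        q = 2.0 ** bg.logp_kmer("A" * W)
        expected = W * np.log2(1 - 3 * eps) - np.log2(q)
        assert mt.score_motif(model, bg) == pytest.approx(expected, abs=1e-9)


class TestGibbsSearch:
    def test_recovers_planted_exact_motif(self, big_background):
        ok = 0
        for seed in range(3):
            seqs, _ = sd.gen_motif_dataset(seed=300 + seed)
            m = mt.gibbs_search(
                seqs, width=10, trials=8, iterations=3000,
                background=big_background, seed=seed,
            )
            hd = min(
                sum(a != b for a, b in zip(m.consensus, ref))
                for ref in ("AAAGCGAGGC", mt.revcomp("AAAGCGAGGC"))
            )
            ok += hd <= 1
        assert ok >= 2

    def test_strand_mixing_does_not_break_recovery(self, big_background):
        # all plants forward vs half reverse-complemented: both recoverable
        seqs_fw, _ = sd.gen_motif_dataset(both_strands=False, seed=41)
        seqs_mix, _ = sd.gen_motif_dataset(both_strands=True, seed=41)
        for seqs in (seqs_fw, seqs_mix):
            m = mt.gibbs_search(
                seqs, width=10, trials=8, iterations=3000,
                background=big_background, seed=7,
            )
            hd = min(
                sum(a != b for a, b in zip(m.consensus, ref))
                for ref in ("AAAGCGAGGC", mt.revcomp("AAAGCGAGGC"))
            )
            assert hd <= 1

    def test_deterministic_under_fixed_seed(self, big_background):
        seqs, _ = sd.gen_motif_dataset(seed=11)
        a = mt.gibbs_search(seqs, width=10, trials=3, iterations=800,
                            background=big_background, seed=5)
        b = mt.gibbs_search(seqs, width=10, trials=3, iterations=800,
                            background=big_background, seed=5)
        assert a.consensus == b.consensus
        assert a.score == b.score
        assert a.sites == b.sites

    def test_short_sequences_skipped_with_warning(self, big_background):
        seqs, _ = sd.gen_motif_dataset(n_seqs=20, seed=2)
        with pytest.warns(UserWarning, match="shorter"):
            m = mt.gibbs_search(
                seqs + ["ACGT"], width=10, trials=2, iterations=400,
                background=big_background, seed=1,
            )
        assert all(s.seq_index < len(seqs) for s in m.sites)

    def test_all_too_short_rejected(self, big_background):
        with pytest.raises(ValueError):
            mt.gibbs_search(["ACGT", "GGTT"], width=10, background=big_background)

    def test_planted_data_outscores_background_only(self, big_background):
        seqs, _ = sd.gen_motif_dataset(seed=77)
        ctrl = sd.random_sequences(50, 100, seed=78)
        m_sig = mt.gibbs_search(seqs, width=10, trials=6, iterations=2500,
                                background=big_background, seed=9)
        m_ctrl = mt.gibbs_search(ctrl, width=10, trials=6, iterations=2500,
                                 background=big_background, seed=9)
        assert m_sig.score > m_ctrl.score


class TestScanBestSite:
    def _model(self):
        return mt.MotifModel.from_sites(["AAAGCGAGGC"] * 20)

    def test_consensus_sequence_found_at_origin(self):
        res = mt.scan_best_site("AAAGCGAGGC", self._model())
        assert (res.status, res.offset, res.strand) == ("ok", 0, "+")

    def test_reverse_complement_same_score_minus_strand(self):
        model = self._model()
        fwd = mt.scan_best_site("AAAGCGAGGC", model)
        rev = mt.scan_best_site(mt.revcomp("AAAGCGAGGC"), model)
        assert rev.strand == "-"
        assert rev.offset == 0
        assert rev.log_odds == pytest.approx(fwd.log_odds, abs=1e-9)

    def test_planted_offset_located_by_exhaustive_scan(self, rng):
        seq = sd.random_sequences(1, 120, seed=55)[0]
        seq = seq[:37] + "AAAGCGAGGC" + seq[47:]
        res = mt.scan_best_site(seq, self._model())
        assert (res.offset, res.site) == (37, "AAAGCGAGGC")

    def test_fast_and_generic_paths_agree(self, big_background):
        model = self._model()
        seq = sd.random_sequences(1, 80, seed=12)[0]
        fast = mt.scan_best_site(seq, model)  # uniform-bg vectorized path
        slow = mt.scan_best_site(seq + "N", model)  # N forces the generic path
        # the trailing N only adds windows containing N, which are skipped
        assert (fast.offset, fast.strand, fast.site) == (slow.offset, slow.strand, slow.site)
        assert fast.log_odds == pytest.approx(slow.log_odds, abs=1e-9)

    def test_sentinels(self):
        model = self._model()
        assert mt.scan_best_site("ACGT", model).status == "too_short"
        res = mt.scan_best_site("T" * 40, model, floor=5.0)
        assert res.status == "none"

    def test_orient_model_flips_reverse_complement_motif(self):
        model = mt.MotifModel.from_sites([mt.revcomp("AAAGCGAGGC")] * 10)
        oriented = mt.orient_model(model, mt.REFERENCE_SITE)
        assert oriented.consensus == "AAAGCGAGGC"
        assert all(s.strand == "-" for s in oriented.sites)


class TestAffinityClassifier:
    def test_reference_site_is_high(self):
        assert mt.classify_affinity("AAAGCGAGGC").category == "High"

    def test_peripheral_change_is_medium(self):
        call = mt.classify_affinity("GAAGCGAGGC")
        assert call.category == "Medium"
        assert call.changed_positions == (1,)

    def test_critical_change_is_low(self):
        call = mt.classify_affinity("AAAGCGCGGC")
        assert call.category == "Low"
        assert 7 in call.changed_positions

    def test_invalid_sites_rejected(self):
        with pytest.raises(ValueError):
            mt.classify_affinity("AAAGCGAGG")
        with pytest.raises(ValueError):
            mt.classify_affinity("AAAGCGAGGN")

    def test_partition_counts_match_enumeration_oracle(self):
        # independent oracle: vectorized enumeration of all 4^10 sites
        digits = np.indices((4,) * 10).reshape(10, -1).T.astype(np.int8)
        code = {b: i for i, b in enumerate("ACGT")}
        pref = {p - 1: code[b] for p, b in mt.PREFERRED_BASES.items()}
        changed = np.zeros((len(digits), 10), dtype=bool)
        for j, c in pref.items():
            changed[:, j] = digits[:, j] != c
        low = changed[:, [2, 5, 6, 7]].any(axis=1)
        med = ~low & changed[:, [0, 8, 9]].any(axis=1)
        high = ~low & ~med
        assert high.sum() == 4**3 == 64
        assert med.sum() == 63 * 64
        assert low.sum() == 255 * 64 * 64
        assert high.sum() + med.sum() + low.sum() == 4**10
        # classifier agrees with the oracle on every single-change 10-mer
        # and on a random sample of the full space
        ref = mt.REFERENCE_SITE
        for pos in range(10):
            for b in "ACGT":
                site = ref[:pos] + b + ref[pos + 1:]
                if pos + 1 in {3, 6, 7, 8} and b != ref[pos]:
                    want = "Low"
                elif pos + 1 in {1, 9, 10} and b != ref[pos]:
                    want = "Medium"
                else:
                    want = "High"
                assert mt.classify_affinity(site).category == want
        rng = np.random.default_rng(8)
        idx = rng.integers(0, len(digits), size=2000)
        cats = np.where(low[idx], "Low", np.where(med[idx], "Medium", "High"))
        bases = np.array(list("ACGT"))
        for row, want in zip(digits[idx], cats):
            site = "".join(bases[row])
            assert mt.classify_affinity(site).category == want


class TestIupacHelpers:
    @given(a=st.sampled_from("ACGTRYSWKMBDHVN"), b=st.sampled_from("ACGTRYSWKMBDHVN"))
    def test_compatibility_symmetric(self, a, b):
        assert mt.iupac_compatible(a, b) == mt.iupac_compatible(b, a)

    def test_revcomp_involution(self):
        for s in ("AAAGCGAGGC", "ACGTN", "T"):
            assert mt.revcomp(mt.revcomp(s)) == s
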