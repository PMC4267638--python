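"""PWM and maximum-entropy splice-site model behaviour.

The MaxEnt oracle here is iterative proportional fitting (IPF) over the
fully enumerated 4^L table — an independent route to the constrained
entropy maximum that never touches the package's chain factorization.
"""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scsnv.regions import acceptor_region, donor_region
from scsnv.splice_models import (
    MaxEntSpliceModel,
    PwmSpliceModel,
    encode_sequence,
    train_maxent,
    train_pwm,
)

BASES = "ACGT"


def random_seqs(rng, n, L):
    return ["".join(rng.choice(list(BASES), L)) for _ in range(n)]


class TestRegions:
    def test_window_geometry(self):
        donor, acceptor = donor_region(), acceptor_region()
        assert len(donor) == 11 and len(acceptor) == 14
        assert donor.invariant_offsets == (1, 2)
        assert acceptor.invariant_offsets == (-2, -1)
        assert len(donor.mutable_offsets) == 9
        assert len(acceptor.mutable_offsets) == 12
        assert donor.is_exonic(-1) and not donor.is_exonic(5)
        assert acceptor.is_exonic(1) and not acceptor.is_exonic(-5)


class TestPwm:
    def test_degenerate_frequencies_without_pseudocount(self):
        m = PwmSpliceModel("donor", pseudocount=0).fit(["CAGGTAAGTAT"] * 4)
        enc = encode_sequence("CAGGTAAGTAT")
        assert np.allclose(m.frequencies_[np.arange(11), enc], 1.0)

    def test_pseudocount_formula(self):
        # counts (1,1,0,0) at each position with pc=1 -> (count+1)/(2+4)
        m = PwmSpliceModel("donor", pseudocount=1.0).fit(["AA", "CC"])
        assert m.frequencies_[0, 0] == pytest.approx(2 / 6)  # A seen once
        assert m.frequencies_[0, 1] == pytest.approx(2 / 6)
        assert m.frequencies_[0, 2] == pytest.approx(1 / 6)  # G unseen

    def test_frequency_recovery_from_sampling(self, rng):
        truth = rng.dirichlet(np.full(4, 5.0), size=5)
        seqs = [
            "".join(BASES[rng.choice(4, p=truth[p])] for p in range(5))
            for _ in range(100)
        ]
        m = PwmSpliceModel("donor", pseudocount=0.5).fit(seqs)
        assert np.abs(m.frequencies_ - truth).max() < 0.1

    def test_consensus_scores_100_and_antikonsensus_0(self, rng):
        seqs = random_seqs(rng, 50, 11)
        m = PwmSpliceModel("donor").fit(seqs)
        best = m.consensus()
        worst = "".join(BASES[i] for i in m.frequencies_.argmin(axis=1))
        assert m.score_sequence(best) == pytest.approx(100.0)
        assert m.score_sequence(worst) == pytest.approx(0.0)

    def test_hand_computed_score(self):
        # 3-position toy matrix; frequencies forced by training counts + pc
        m = PwmSpliceModel("donor", pseudocount=0.5).fit(["ACG", "ACG", "ATG"])
        f = m.frequencies_
        ll = np.log(f[0, 0]) + np.log(f[1, 1]) + np.log(f[2, 2])  # "ACG"
        lo = np.log(f.min(axis=1)).sum()
        hi = np.log(f.max(axis=1)).sum()
        expect = 100 * (ll - lo) / (hi - lo)
        assert m.score_sequence("ACG") == pytest.approx(expect)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError, match="empty"):
            PwmSpliceModel().fit([])
        with pytest.raises(ValueError, match="ragged"):
            PwmSpliceModel().fit(["AC", "ACG"])
        with pytest.raises(ValueError, match="position 1"):
            PwmSpliceModel().fit(["ANG"])
        m = PwmSpliceModel().fit(["ACG", "CGT"])
        with pytest.raises(ValueError, match="non-ACGT"):
            m.score_sequence("ANG")
        # lowercase accepted
        assert m.score_sequence("acg") == m.score_sequence("ACG")

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.integers(0, 4), st.integers(0, 1_000))
    def test_monotone_in_base_frequency(self, seed, pos, seed2):
        """Swapping in a higher-frequency base never lowers the score."""
        rng = np.random.default_rng(seed)
        m = PwmSpliceModel("donor").fit(random_seqs(rng, 30, 5))
        rng2 = np.random.default_rng(seed2)
        seq = list(random_seqs(rng2, 1, 5)[0])
        base_score = m.score_sequence("".join(seq))
        cur_freq = m.frequencies_[pos, encode_sequence(seq[pos])[0]]
        for b in BASES:
            if m.frequencies_[pos, encode_sequence(b)[0]] >= cur_freq:
                alt = seq.copy()
                alt[pos] = b
                assert m.score_sequence("".join(alt)) >= base_score - 1e-9

    def test_json_roundtrip(self, rng):
        m = PwmSpliceModel("acceptor").fit(random_seqs(rng, 40, 14))
        m2 = PwmSpliceModel.from_json(m.to_json())
        seq = random_seqs(rng, 1, 14)[0]
        assert m2.score_sequence(seq) == pytest.approx(m.score_sequence(seq))


def ipf_distribution(pairs, L, iters=2000, tol=1e-12):
    """IPF over the enumerated 4^L table matching adjacent-pair marginals."""
    idx = np.array(list(product(range(4), repeat=L)))
    q = np.full(4**L, 1.0 / 4**L)
    for _ in range(iters):
        delta = 0.0
        for p in range(L - 1):
            cur = np.zeros((4, 4))
            np.add.at(cur, (idx[:, p], idx[:, p + 1]), q)
            ratio = pairs[p] / np.maximum(cur, 1e-300)
            q = q * ratio[idx[:, p], idx[:, p + 1]]
            delta = max(delta, np.abs(cur - pairs[p]).max())
        if delta < tol:
            break
    return q


class TestMaxEnt:
    def test_order1_is_independence_model(self, rng):
        seqs = random_seqs(rng, 30, 4)
        m = MaxEntSpliceModel("donor", constraint_order=1).fit(seqs)
        probs = m.distribution()
        idx = np.array(list(product(range(4), repeat=4)))
        indep = np.prod(m.singles_[np.arange(4), idx], axis=1)
        assert np.abs(probs - indep).max() < 1e-12

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_uniform_training_set_gives_uniform(self, order):
        seqs = ["".join(t) for t in product(BASES, repeat=3)]
        m = MaxEntSpliceModel("donor", constraint_order=order).fit(seqs)
        assert np.allclose(m.distribution(), 1 / 64)

    def test_order2_matches_ipf_oracle(self, rng):
        seqs = random_seqs(rng, 50, 4)
        m = MaxEntSpliceModel("donor", constraint_order=2).fit(seqs)
        oracle = ipf_distribution(m.pairs_, 4)
        tv = 0.5 * np.abs(m.distribution() - oracle).sum()
        assert tv < 1e-4

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_distribution_normalized_and_marginals_matched(self, order, rng):
        seqs = random_seqs(rng, 40, 5)
        m = MaxEntSpliceModel("donor", constraint_order=order).fit(seqs)
        assert m.distribution().sum() == pytest.approx(1.0, abs=1e-8)
        assert m.marginal_residual_ < 1e-8

    def test_entropy_at_least_empirical(self, rng):
        """Max-ent fit is smoother than the raw empirical distribution."""
        seqs = random_seqs(rng, 40, 4)
        m = MaxEntSpliceModel("donor", constraint_order=2, pseudocount=0.5).fit(seqs)
        probs = m.distribution()
        H_model = -(probs * np.log(probs)).sum()
        vals, counts = np.unique(seqs, return_counts=True)
        emp = counts / counts.sum()
        H_emp = -(emp * np.log(emp)).sum()
        assert H_model >= H_emp - 1e-9

    def test_score_zero_when_model_equals_background(self):
        seqs = ["".join(t) for t in product(BASES, repeat=3)]
        m = MaxEntSpliceModel("donor", constraint_order=2).fit(seqs)
        for s in ("AAA", "ACG", "TTT"):
            assert m.score_sequence(s) == pytest.approx(0.0, abs=1e-9)

    def test_score_is_log2_ratio(self, rng):
        seqs = random_seqs(rng, 50, 4)
        m = MaxEntSpliceModel("donor", constraint_order=2).fit(seqs)
        probs = m.distribution()
        idx = {"".join(t): i for i, t in enumerate(product(BASES, repeat=4))}
        for s in random_seqs(rng, 10, 4):
            expect = np.log2(probs[idx[s]] / 0.25**4)
            assert m.score_sequence(s) == pytest.approx(expect, abs=1e-9)

    def test_doubling_probability_scores_plus_one(self):
        m = MaxEntSpliceModel("donor", constraint_order=1)
        m.length_ = 1
        m.region_ = None
        m.singles_ = np.array([[0.5, 0.25, 0.125, 0.125]])
        m.background_ = np.full((1, 4), 0.25)
        assert m.score_sequence("A") == pytest.approx(1.0)  # P = 2 * background
        assert m.score_sequence("C") == pytest.approx(0.0)

    def test_reproducible_and_serializable(self, rng):
        seqs = random_seqs(rng, 30, 4)
        a = MaxEntSpliceModel("donor", constraint_order=2).fit(seqs)
        b = MaxEntSpliceModel("donor", constraint_order=2).fit(seqs)
        assert a.to_json() == b.to_json()
        c = MaxEntSpliceModel.from_json(a.to_json())
        s = random_seqs(rng, 1, 4)[0]
        assert c.score_sequence(s) == pytest.approx(a.score_sequence(s))

    def test_functional_wrappers(self, rng):
        region = donor_region()
        seqs = random_seqs(rng, 25, 11)
        pwm = train_pwm(seqs, region, pseudocount=0.5)
        me = train_maxent(seqs, region, constraint_order=2)
        assert 0 <= pwm.score_sequence(seqs[0]) <= 100
        assert np.isfinite(me.score_sequence(seqs[0]))
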