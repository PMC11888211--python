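import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chimehmm.airr_io import ReferenceMSA, ThreadedQuery
from chimehmm.hmm import (
    ModelConfig,
    NumericalDegeneracyError,
    OpCounter,
    StateSpace,
    build_state_space,
    chimera_call,
    db_rate_grid,
    emission_prob,
    forward_batch,
    forward_linear,
    forward_quadratic_oracle,
    transition_prob,
    viterbi_linear,
    viterbi_quadratic_oracle,
)
from chimehmm.airr_io import encode

from conftest import random_instance


class TestStateSpace:
    def test_state_counts(self):
        space = StateSpace(N=2, K=3)
        assert space.n_states == 12
        chim = [space.is_chimeric(i) for i in range(12)]
        assert sum(chim) == 6 and sum(not c for c in chim) == 6

    def test_layout_roundtrip_and_accessors(self):
        space = StateSpace(N=3, K=2)
        for i in range(space.n_states):
            c, r, k = space.unpack(i)
            assert space.index(c, r, k) == i
            assert len(space.R(i)) == space.K
            assert i in space.R(i)
            assert len(space.R_star(i)) == 2 * space.K
            assert space.psi_star(i, 0.1) == (0.1 if c == 1 else 0.0)

    @given(st.integers(1, 10), st.integers(1, 10))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_accessor_sizes_for_random_dimensions(self, n, k):
        space = StateSpace(N=n, K=k)
        i = space.n_states - 1
        assert len(space.R(i)) == k and len(space.R_star(i)) == 2 * k


class TestEmissionLaw:
    @pytest.mark.parametrize(
        "state_nt, obs, m, expected",
        [
            ("A", "A", 0.005, 0.995),
            ("A", "C", 0.03, 0.01),
            ("G", "-", 0.4, 1.0),
            ("G", "N", 0.005, 1.0),
            ("-", "A", 0.03, 0.01),  # reference gap opposite a base: mismatch
            ("T", "T", 0.0, 1.0),
            ("T", "G", 0.0, 0.0),
        ],
    )
    def test_values(self, state_nt, obs, m, expected):
        assert emission_prob(state_nt, obs, m) == pytest.approx(expected)

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError):
            emission_prob("A", "X", 0.1)
        with pytest.raises(ValueError):
            emission_prob("Z", "A", 0.1)


class TestTransitionLaw:
    def test_printed_values(self):
        space = StateSpace(N=50, K=15)
        cfg = ModelConfig(psi=1e-4, mu=1e-3)
        i = space.index(0, 3, 2)
        assert transition_prob(i, i, space, cfg) == pytest.approx(0.9989)
        j_c = space.index(1, 7, 0)
        assert transition_prob(i, j_c, space, cfg) == pytest.approx(1e-4 / 735)
        j_u = space.index(0, 7, 0)
        assert transition_prob(i, j_u, space, cfg) == 0.0

    @pytest.mark.parametrize("n,k", [(1, 1), (1, 4), (5, 1), (2, 2), (6, 3)])
    def test_rows_sum_to_one(self, n, k):
        space = StateSpace(N=n, K=k)
        mu = 0.0 if k == 1 else 1e-3
        cfg = ModelConfig(psi=1e-4, mu=mu, rates=db_rate_grid(k, 0.0, 0.2))
        for i in range(space.n_states):
            row = sum(transition_prob(i, j, space, cfg) for j in range(space.n_states))
            assert row == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(2, 8), st.integers(2, 6))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_rows_sum_to_one_random_dims(self, n, k):
        space = StateSpace(N=n, K=k)
        cfg = ModelConfig(psi=3e-4, mu=2e-3, rates=db_rate_grid(k, 0.0, 0.2))
        i = (n * k * 2) // 2  # first chimeric state
        row = sum(transition_prob(i, j, space, cfg) for j in range(space.n_states))
        assert row == pytest.approx(1.0, abs=1e-12)


class TestModelConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(psi=0.6, mu=0.5)
        with pytest.raises(ValueError):
            ModelConfig(rates=(0.2, 0.1))
        with pytest.raises(ValueError):
            ModelConfig(mu=0.1, rates=(0.05,))

    def test_db_grid_spans_endpoints(self):
        grid = db_rate_grid()
        assert len(grid) == 15
        assert grid[0] == 0.0 and grid[-1] == pytest.approx(0.25)
        assert np.allclose(np.diff(grid), 0.25 / 14)


def enumerate_paths(q, msa, space, cfg):
    """Brute-force sum/max over all state paths (tiny instances only)."""
    S = space.n_states
    nk = S // 2
    A = np.array(
        [[transition_prob(i, j, space, cfg) for j in range(S)] for i in range(S)]
    )
    obs = q.obs
    L = len(obs)
    rates = np.asarray(cfg.rates)
    b = np.empty((L, S))
    for t in range(L):
        for i in range(S):
            _, r, k = space.unpack(i)
            b[t, i] = emission_prob(msa.rows[r][t], obs[t], rates[k])
    pi = np.concatenate([np.full(nk, 1.0 / nk), np.zeros(nk)])
    total = 0.0
    chim = 0.0
    best_p, best_path = -1.0, None
    for path in itertools.product(range(S), repeat=L):
        p = pi[path[0]] * b[0, path[0]]
        for t in range(1, L):
            p *= A[path[t - 1], path[t]] * b[t, path[t]]
            if p == 0.0:
                break
        if p == 0.0:
            continue
        total += p
        if path[-1] >= nk:
            chim += p
        if p > best_p:
            best_p, best_path = p, path
    return total, chim, best_p, best_path


class TestForwardAgainstEnumeration:
    def test_forward_equals_path_sum_on_tiny_instance(self):
        msa = ReferenceMSA.from_records([("a*01", "ACGTAC"), ("b*01", "TGCAGA")])
        cfg = ModelConfig(psi=0.01, mu=0.02, rates=(0.05, 0.2))
        space = build_state_space(msa, cfg)
        q = ThreadedQuery("q", "ACCAGA", "a*01")
        total, chim, best_p, best_path = enumerate_paths(q, msa, space, cfg)
        res = forward_linear(q, msa, space, cfg)
        assert res.log_evidence == pytest.approx(np.log(total), rel=1e-10)
        assert res.posterior == pytest.approx(chim / total, rel=1e-10)
        v = viterbi_linear(q, msa, space, cfg)
        assert v.log_path_prob == pytest.approx(np.log(best_p), rel=1e-10)
        assert tuple(v.path) == best_path
        assert v.log_path_prob <= res.log_evidence


class TestOracleEquivalence:
    def test_linear_matches_dense_on_random_instances(self):
        """Forward and Viterbi linear recursions vs the dense quadratic forms."""
        rng = np.random.default_rng(7)
        n_checked = 0
        for _ in range(60):
            q, msa, space, cfg = random_instance(rng)
            fl = forward_linear(q, msa, space, cfg)
            fo = forward_quadratic_oracle(q, msa, space, cfg)
            assert fl.log_evidence == pytest.approx(fo.log_evidence, rel=1e-10)
            if fo.posterior == 0.0:
                assert fl.posterior == 0.0
            else:
                assert fl.posterior == pytest.approx(fo.posterior, rel=1e-10)
            vl = viterbi_linear(q, msa, space, cfg)
            vo = viterbi_quadratic_oracle(q, msa, space, cfg)
            assert np.array_equal(vl.path, vo.path)
            assert vl.log_path_prob == pytest.approx(vo.log_path_prob, rel=1e-10)
            n_checked += 1
        assert n_checked == 60

    def test_forward_deterministic(self):
        rng = np.random.default_rng(3)
        q, msa, space, cfg = random_instance(rng)
        a = forward_linear(q, msa, space, cfg)
        b = forward_linear(q, msa, space, cfg)
        assert a.log_evidence == b.log_evidence and a.posterior == b.posterior
        va = viterbi_linear(q, msa, space, cfg)
        vb = viterbi_linear(q, msa, space, cfg)
        assert np.array_equal(va.path, vb.path)


class TestAnalyticZeros:
    def test_single_reference_posterior_is_exactly_zero(self):
        msa = ReferenceMSA.from_records([("a*01", "ACGTACGT")])
        cfg = ModelConfig(psi=1e-3, mu=1e-3, rates=(0.01, 0.1))
        space = build_state_space(msa, cfg)
        q = ThreadedQuery("q", "ACGAACGT", "a*01")
        assert forward_linear(q, msa, space, cfg).posterior == 0.0

    def test_psi_zero_posterior_is_exactly_zero(self, tiny_msa):
        cfg = ModelConfig(psi=0.0, mu=1e-3, rates=(0.01, 0.1))
        space = build_state_space(tiny_msa, cfg)
        q = ThreadedQuery("q", tiny_msa.rows[0], "VA1-1*01")
        assert forward_linear(q, tiny_msa, space, cfg).posterior == 0.0


class TestForwardBehaviour:
    def test_posterior_nondecreasing_in_psi(self, tiny_msa):
        q = ThreadedQuery("q", "ACGTACGAACGT", tiny_msa.names[0])
        posts = []
        for psi in (1e-6, 1e-5, 1e-4, 1e-3, 1e-2):
            cfg = ModelConfig(psi=psi, mu=1e-3, rates=(0.01, 0.1))
            space = build_state_space(tiny_msa, cfg)
            posts.append(forward_linear(q, tiny_msa, space, cfg).posterior)
        assert all(b >= a for a, b in zip(posts, posts[1:]))

    def test_perfect_chimera_of_diverged_parents_scores_high(self):
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(list("ACGT"), size=60))
        b = "".join(
            c if rng.random() > 0.5 else "ACGT".replace(c, "")[rng.integers(3)]
            for c in a
        )
        msa = ReferenceMSA.from_records([("p1-1*01", a), ("p2-2*01", b)])
        cfg = ModelConfig(psi=1e-4, mu=0.0, rates=(0.005,))
        space = build_state_space(msa, cfg)
        q = ThreadedQuery("q", a[:30] + b[30:], "p1-1*01")
        res = forward_linear(q, msa, space, cfg)
        oracle = forward_quadratic_oracle(q, msa, space, cfg)
        assert res.posterior > 0.999
        assert res.posterior == pytest.approx(oracle.posterior, rel=1e-10)
        assert chimera_call(res, cfg)

    def test_degenerate_zero_rate_single_class_raises(self):
        msa = ReferenceMSA.from_records([("a*01", "AAAA"), ("b*01", "AAAA")])
        cfg = ModelConfig(psi=1e-4, mu=0.0, rates=(0.0,))
        space = build_state_space(msa, cfg)
        q = ThreadedQuery("q", "CCCC", "a*01")
        with pytest.raises(NumericalDegeneracyError):
            forward_linear(q, msa, space, cfg)

    def test_scale_factors_reconstruct_evidence(self, tiny_msa):
        cfg = ModelConfig(rates=(0.01, 0.1), mu=1e-3)
        space = build_state_space(tiny_msa, cfg)
        q = ThreadedQuery("q", "ACGTACCTACGT", tiny_msa.names[0])
        res = forward_linear(q, tiny_msa, space, cfg)
        assert np.log(res.scale_factors).sum() == pytest.approx(res.log_evidence)
        assert res.log_chimeric_mass <= res.log_evidence

    def test_complexity_linear_in_state_count(self):
        """Per-column work (elements touched) grows ~linearly in NK."""
        rng = np.random.default_rng(9)
        counts = {}
        for n in (5, 10, 20, 40):
            rows = [
                "".join(rng.choice(list("ACGT"), size=30)) for _ in range(n)
            ]
            refs = np.vstack([encode(r) for r in rows])
            obs = encode(rows[0])[None, :]
            counter = OpCounter()
            forward_batch(obs, refs, db_rate_grid(4, 0.0, 0.2), 1e-4, 1e-3, counter=counter)
            counts[n] = counter.elements
        assert counts[10] / counts[5] == pytest.approx(2.0, rel=0.2)
        assert counts[40] / counts[5] == pytest.approx(8.0, rel=0.2)


class TestViterbiSegmentation:
    def test_unmutated_copy_single_segment(self):
        rng = np.random.default_rng(4)
        rows = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(3)]
        msa = ReferenceMSA.from_records(
            [(f"g{i+1}-{i+1}*01", s) for i, s in enumerate(rows)]
        )
        cfg = ModelConfig(psi=1e-4, mu=1e-3, rates=(0.0, 0.05, 0.1))
        space = build_state_space(msa, cfg)
        q = ThreadedQuery("q", rows[1], msa.names[1])
        v = viterbi_linear(q, msa, space, cfg)
        assert v.breakpoints == []
        assert v.segments == [(msa.names[1], 0, 1, 40)]  # lowest-rate class

    def test_two_parent_chimera_breakpoint_in_homology_tract(self):
        left = "AAAAAAAAAACCCCCCCCCC"
        right = "GGGGGGGGGGTTTTTTTTTT"
        msa = ReferenceMSA.from_records([("L1-1*01", left), ("R2-2*01", right)])
        cfg = ModelConfig(psi=1e-3, mu=0.0, rates=(0.01,))
        space = build_state_space(msa, cfg)
        q = ThreadedQuery("q", left[:10] + right[10:], "L1-1*01")
        v = viterbi_linear(q, msa, space, cfg)
        vo = viterbi_quadratic_oracle(q, msa, space, cfg)
        assert np.array_equal(v.path, vo.path)
        assert len(v.breakpoints) == 1
        assert v.breakpoints[0] == 11  # first column of the new parent
        assert [s[0] for s in v.segments] == ["L1-1*01", "R2-2*01"]

    def test_tie_break_prefers_lowest_state_index(self):
        # two identical references: every path mass ties; U states of ref 0 win
        msa = ReferenceMSA.from_records([("a-1*01", "ACGT"), ("b-1*01", "ACGT")])
        cfg = ModelConfig(psi=1e-3, mu=0.0, rates=(0.05,))
        space = build_state_space(msa, cfg)
        q = ThreadedQuery("q", "ACGT", "a-1*01")
        v = viterbi_linear(q, msa, space, cfg)
        vo = viterbi_quadratic_oracle(q, msa, space, cfg)
        assert np.array_equal(v.path, vo.path)
        assert all(s == 0 for s in v.path)


class TestChimeraCall:
    @pytest.mark.parametrize(
        "posterior, expected", [(0.951, True), (0.949, False), (0.95, True)]
    )
    def test_threshold_convention(self, posterior, expected):
        from chimehmm.hmm import ForwardResult

        cfg = ModelConfig()
        res = ForwardResult(
            log_evidence=-10.0, log_chimeric_mass=-10.5,
            posterior=posterior, scale_factors=np.ones(1),
        )
        assert chimera_call(res, cfg) is expected
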