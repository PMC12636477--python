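import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberburst import hmm
from fiberburst.core import Fiber
from fiberburst.hmm import (
    EmissionTable,
    FootprintSegment,
    HMMParams,
    build_emission_table,
    decode_fiber,
    footprints_from_path,
    forward_backward,
    train_hmm,
    viterbi_path,
)

from conftest import brute_force_viterbi


def make_params(p_acc, p_inacc, stay=0.9, start=(0.5, 0.5)):
    T = np.array([[stay, 1 - stay], [1 - stay, stay]])
    return HMMParams(np.array(start), T, EmissionTable.flat(p_acc, p_inacc))


class TestEmissionTable:
    def test_frequency_definition(self):
        table = build_emission_table(
            {"AAAAAAA": (90, 100)}, {"AAAAAAA": (1, 100)}, pseudocount=0.0
        )
        pa, pi = table.lookup("AAAAAAA")
        assert pa == pytest.approx(0.9)
        assert pi == pytest.approx(0.01)

    def test_smoothing_limit(self):
        table = build_emission_table(
            {"AAATAAA": (0, 0), "CCCACCC": (5, 10)},
            {"AAATAAA": (0, 0), "CCCACCC": (1, 10)},
            pseudocount=1.0,
        )
        pa, pi = table.lookup("AAATAAA")
        assert pa == pytest.approx(0.5)
        assert pi == pytest.approx(0.5)

    def test_counting_oracle_mixed_contexts(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        kmers = []
        while len(kmers) < 10:
            k = "".join(rng.choice(list(bases), 7))
            if k[3] in "AT" and k not in kmers:
                kmers.append(k)
        acc = {k: (int(rng.integers(0, 50)), 50) for k in kmers}
        inacc = {k: (int(rng.integers(0, 50)), 50) for k in kmers}
        pc = 1.0
        table = build_emission_table(acc, inacc, pc)
        for k in kmers:
            pa, pi = table.lookup(k)
            assert pa == pytest.approx((acc[k][0] + pc) / (50 + 2 * pc))
            assert pi == pytest.approx((inacc[k][0] + pc) / (50 + 2 * pc))

    def test_empty_controls_error(self):
        with pytest.raises(ValueError):
            build_emission_table({}, {"AAAAAAA": (1, 2)})

    def test_fallback_to_center_base(self):
        table = build_emission_table(
            {"AAAAAAA": (40, 100), "GGGAGGG": (10, 100)},
            {"AAAAAAA": (5, 100)},
            pseudocount=0.0,
        )
        # GGGAGGG absent from the inaccessible control: falls back to
        # center-A rates pooled over both 7-mers of the accessible control
        pa, _ = table.lookup("GGGAGGG")
        assert pa == pytest.approx(50 / 200)


class TestDecoding:
    def test_viterbi_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            L = int(rng.integers(2, 11))
            logB = np.log(rng.uniform(0.05, 1.0, size=(L, 2)))
            start = rng.dirichlet([1, 1])
            T = np.vstack([rng.dirichlet([1, 1]) for _ in range(2)])
            params = HMMParams(start, T, EmissionTable.flat(0.5, 0.5))
            path = viterbi_path(logB, params)
            score = np.log(start[path[0]]) + logB[0, path[0]]
            for t in range(1, L):
                score += np.log(T[path[t - 1], path[t]]) + logB[t, path[t]]
            oracle_score, oracle_path = brute_force_viterbi(logB, start, T)
            assert score == pytest.approx(oracle_score, abs=1e-9)
            assert list(path) == oracle_path

    def test_degenerate_emissions_reproduce_mask(self):
        # all-A/T sequence: calls == accessibility mask run-for-run
        seq = "A" * 30
        mask = [1] * 10 + [0] * 8 + [1] * 12
        meth = tuple(i for i, m in enumerate(mask) if m)
        fiber = Fiber("f", "c", 0, 30, "+", meth)
        params = make_params(0.999, 0.001, stay=0.9)
        segs = decode_fiber(fiber, seq, params)
        assert [(s.start, s.end, s.state) for s in segs] == [
            (0, 10, "accessible"),
            (10, 18, "inaccessible"),
            (18, 30, "accessible"),
        ]

    def test_all_methylated_single_accessible_segment(self):
        seq = "A" * 50
        fiber = Fiber("f", "c", 0, 50, "+", tuple(range(50)))
        params = make_params(0.9, 0.01, stay=0.99)
        segs = decode_fiber(fiber, seq, params)
        assert len(segs) == 1
        assert segs[0].state == "accessible"
        assert (segs[0].start, segs[0].end) == (0, 50)

    def test_no_informative_positions_prior_dominant(self):
        seq = "G" * 20
        fiber = Fiber("f", "c", 0, 20, "+")
        params = make_params(0.9, 0.1, start=(0.8, 0.2))
        segs = decode_fiber(fiber, seq, params)
        assert len(segs) == 1
        assert segs[0].state == "accessible"

    def test_posterior_decoder_available(self):
        seq = "A" * 30
        fiber = Fiber("f", "c", 0, 30, "+", tuple(range(15)))
        params = make_params(0.9, 0.05)
        segs = decode_fiber(fiber, seq, params, decoder="posterior")
        assert segs[0].state == "accessible"
        with pytest.raises(ValueError):
            decode_fiber(fiber, seq, params, decoder="bogus")

    def test_posteriors_normalized(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            L = int(rng.integers(2, 200))
            logB = np.log(rng.uniform(0.01, 1.0, size=(L, 2)))
            start = rng.dirichlet([1, 1])
            T = np.vstack([rng.dirichlet([1, 1]) for _ in range(2)])
            params = HMMParams(start, T, EmissionTable.flat(0.5, 0.5))
            post, ll, *_ = forward_backward(logB, params)
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
            assert np.isfinite(ll)

    def test_long_fiber_no_underflow(self):
        # ~23 kb fiber must decode without NaN/inf issues
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 23000))
        meth = tuple(
            int(i) for i in np.nonzero(
                (np.array(list(seq)) != "G") & (np.array(list(seq)) != "C")
                & (rng.random(23000) < 0.5)
            )[0]
        )
        fiber = Fiber("f", "c", 0, 23000, "+", meth)
        segs = decode_fiber(fiber, seq, make_params(0.8, 0.05, stay=0.99))
        assert segs[0].start == 0 and segs[-1].end == 23000


class TestFootprintsFromPath:
    def test_single_inaccessible_run(self):
        segs = [
            FootprintSegment(0, 3, "accessible"),
            FootprintSegment(3, 6, "inaccessible"),
            FootprintSegment(6, 7, "accessible"),
        ]
        fps, gaps = footprints_from_path(segs)
        assert fps == [(3, 6)]
        assert gaps == [(0, 3), (6, 7)]

    def test_all_accessible_empty(self):
        fps, gaps = footprints_from_path([FootprintSegment(0, 10, "accessible")])
        assert fps == []
        assert gaps == [(0, 10)]

    @given(st.lists(st.integers(1, 5), min_size=1, max_size=12))
    def test_run_length_oracle(self, run_lengths):
        pos = 0
        segs = []
        n_inacc = 0
        for i, rl in enumerate(run_lengths):
            state = "inaccessible" if i % 2 else "accessible"
            if state == "inaccessible":
                n_inacc += 1
            segs.append(FootprintSegment(pos, pos + rl, state))
            pos += rl
        fps, gaps = footprints_from_path(segs)
        assert len(fps) == n_inacc
        assert len(fps) + len(gaps) == len(run_lengths)


class TestSegmentsInvariants:
    def test_segments_tile_and_alternate(self, degenerate_sim):
        sim = degenerate_sim
        params = make_params(0.999, 0.001)
        for fiber in sim.fibers[:5]:
            segs = decode_fiber(fiber, sim.sequence, params)
            assert segs[0].start == fiber.start
            assert segs[-1].end == fiber.end
            for a, b in zip(segs[:-1], segs[1:]):
                assert a.end == b.start
                assert a.state != b.state


class TestTraining:
    def test_transition_recovery(self):
        # fibers generated from a known chain with degenerate emissions
        rng = np.random.default_rng(5)
        T_true = np.array([[0.9, 0.1], [0.2, 0.8]])
        seq = "A" * 300
        fibers = []
        for i in range(200):
            states = [int(rng.random() < 0.5)]
            for _ in range(299):
                states.append(int(rng.random() < T_true[states[-1], 1]))
            meth = tuple(j for j, s in enumerate(states) if s == 0)
            fibers.append(Fiber(f"f{i}", "c", 0, 300, "+", meth))
        emissions = EmissionTable.flat(0.999, 0.001)
        params = train_hmm(fibers, seq, emissions, n_restarts=2, seed=0)
        assert np.abs(params.transitions - T_true).max() < 0.02

    def test_all_methylated_concentrates_accessible(self):
        seq = "A" * 100
        fiber = Fiber("f", "c", 0, 100, "+", tuple(range(100)))
        params = train_hmm([fiber], seq, EmissionTable.flat(0.95, 0.05), seed=1)
        assert params.transitions[0, 0] > 0.9

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), 500))
        ats = [i for i, b in enumerate(seq) if b in "AT"]
        meth = tuple(i for i in ats if rng.random() < 0.4)
        fibers = [Fiber("f", "c", 0, 500, "+", meth)]
        e = EmissionTable.flat(0.8, 0.05)
        p1 = train_hmm(fibers, seq, e, n_restarts=3, seed=7)
        p2 = train_hmm(fibers, seq, e, n_restarts=3, seed=7)
        assert np.array_equal(p1.transitions, p2.transitions)
        assert np.array_equal(p1.start, p2.start)

    def test_em_monotone_loglik(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 400))
        ats = [i for i, b in enumerate(seq) if b in "AT"]
        meth = tuple(i for i in ats if rng.random() < 0.5)
        fibers = [Fiber("f", "c", 0, 400, "+", meth)]
        params0 = make_params(0.8, 0.1, stay=0.6)
        trace = hmm.em_loglik_trace(fibers, seq, params0, n_iter=15)
        assert all(b >= a - 1e-8 for a, b in zip(trace[:-1], trace[1:]))

    def test_no_usable_fiber_errors(self):
        with pytest.raises(ValueError):
            train_hmm([Fiber("f", "c", 0, 5, "+")], "GGGGG",
                      EmissionTable.flat(0.5, 0.4))


class TestParamValidation:
    def test_bad_start(self):
        with pytest.raises(ValueError):
            HMMParams(np.array([0.7, 0.7]), np.eye(2) * 0.5 + 0.25,
                      EmissionTable.flat(0.5, 0.4))

    def test_zero_probability_rejected(self):
        with pytest.raises(ValueError):
            HMMParams(np.array([1.0, 0.0]), np.array([[0.5, 0.5], [0.5, 0.5]]),
                      EmissionTable.flat(0.5, 0.4))

    def test_emission_bounds(self):
        with pytest.raises(ValueError):
            EmissionTable({"AAAAAAA": (1.0, 0.5)})
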