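import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberburst.core import ClassifiedFootprint, Fiber, GeneModel
from fiberburst.simulate import simulate_fluorescence
from fiberburst.states import (
    Convoy,
    StateCall,
    assign_state,
    classify_burst,
    decile_concordance,
    detect_convoys,
    gmm_on_rate,
    kinetics,
)

BODY = (0, 5000)


def brute_force_convoys(fps, max_gap=100):
    """Transitive closure over pairwise edge gap <= max_gap (oracle)."""
    fps = sorted(fps)
    n = len(fps)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            gap = max(fps[j][0] - fps[i][1], fps[i][0] - fps[j][1])
            if gap <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(fps[i])
    return sorted(sorted(g) for g in groups.values() if len(g) >= 2)


class TestConvoys:
    def test_gap_90_groups(self):
        convoys = detect_convoys([(0, 50), (140, 190)], BODY)
        assert len(convoys) == 1
        assert convoys[0].size == 2
        assert convoys[0].center_spacings == [140.0]

    def test_gap_100_groups_gap_101_splits(self):
        assert len(detect_convoys([(0, 50), (150, 200)], BODY)) == 1
        assert len(detect_convoys([(0, 50), (151, 200)], BODY)) == 0

    def test_convoy_of_14(self):
        fps = []
        pos = 0
        for _ in range(14):
            fps.append((pos, pos + 50))
            pos += 60  # 10 bp gaps
        convoys = detect_convoys(fps, BODY)
        assert len(convoys) == 1
        assert convoys[0].size == 14

    def test_singletons_are_not_convoys(self):
        assert detect_convoys([(0, 50)], BODY) == []

    def test_outside_body_excluded(self):
        assert detect_convoys([(6000, 6050), (6100, 6150)], BODY) == []

    def test_center_mode(self):
        # centers 25 and 175: spacing 150 > 100 in center mode, edge gap 100
        fps = [(0, 50), (150, 200)]
        assert len(detect_convoys(fps, BODY, gap_mode="center")) == 0
        assert len(detect_convoys(fps, BODY, gap_mode="edge")) == 1

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(0, 3000), min_size=0, max_size=30), st.data())
    def test_chaining_equals_transitive_closure(self, starts, data):
        fps = []
        for s in sorted(set(starts)):
            w = data.draw(st.integers(40, 60))
            if not fps or s >= fps[-1][1]:
                fps.append((s, s + w))
        got = [c.members for c in detect_convoys(fps, (0, 10000))]
        assert sorted(got) == brute_force_convoys(fps)

    def test_convoy_requires_two(self):
        with pytest.raises(ValueError):
            Convoy("f", [(0, 50)])


def _gene():
    return GeneModel("g", "c", 1000, 3000, "+")


def _fiber():
    return Fiber("f", "c", 0, 4000, "+")


def _cls(intervals, klass):
    return [ClassifiedFootprint("f", "c", s, e, klass) for s, e in intervals]


class TestAssignState:
    def test_accessible_promoter(self):
        g = _gene()
        call = assign_state(_fiber(), g, [], [(0, 4000)])
        assert call.accessible_promoter is True
        assert call.paused is False
        assert call.elongating is False

    def test_promoter_blocked_by_polII(self):
        g = _gene()
        cls = _cls([(1500, 1550)], "polII")
        call = assign_state(_fiber(), g, cls, [(0, 4000)])
        assert call.accessible_promoter is False
        assert call.elongating is True

    def test_paused(self):
        g = _gene()
        cls = _cls([(1010, 1060)], "polII")  # 50 bp at TSS+10
        call = assign_state(_fiber(), g, cls, [(0, 1010), (1060, 4000)])
        assert call.paused is True
        assert call.elongating is False

    def test_paused_excluded_by_other_polII(self):
        g = _gene()
        cls = _cls([(1010, 1060), (2500, 2550)], "polII")
        call = assign_state(_fiber(), g, cls, [(0, 4000)])
        assert call.paused is False
        assert call.elongating is True

    def test_paused_loose_mode_ignores_other_polII(self):
        g = _gene()
        cls = _cls([(1010, 1060), (2500, 2550)], "polII")
        call = assign_state(_fiber(), g, cls, [(0, 4000)], strict=False)
        assert call.paused is True

    def test_hyperburst_55pct_accessible_body(self):
        g = _gene()  # body = [1200, 3000)
        acc = [(1200, 1200 + 990)]  # 55% of 1800
        call = assign_state(_fiber(), g, [], acc)
        assert call.hyperburst is True
        call2 = assign_state(_fiber(), g, [], [(1200, 1200 + 800)])
        assert call2.hyperburst is False

    def test_terminating(self):
        g = _gene()
        cls = _cls([(3100, 3150)], "polII")
        call = assign_state(_fiber(), g, cls, [(0, 4000)])
        assert call.terminating is True
        assert call.elongating is False

    def test_non_spanning_flags_undefined(self):
        g = _gene()
        short = Fiber("f", "c", 0, 2000, "+")  # does not span term region
        call = assign_state(short, g, [], [(0, 2000)])
        assert call.terminating is None

    def test_eviction_fraction(self):
        g = _gene()  # eviction window [1200, 2700)
        cls = _cls([(1200, 1650)], "nucleosome")  # covers 450/1500
        call = assign_state(_fiber(), g, cls, [(0, 1200), (1650, 4000)])
        assert call.nucleosome_eviction_fraction == pytest.approx(1 - 450 / 1500)


class TestBurst:
    def _call(self, evic, n_convoys):
        c = StateCall("f", "g")
        c.nucleosome_eviction_fraction = evic
        c.n_convoys = n_convoys
        return c

    def test_active(self):
        assert classify_burst(self._call(0.7, 2)) == "active"

    def test_refractory(self):
        assert classify_burst(self._call(0.7, 0)) == "refractory"

    def test_none_despite_convoys(self):
        assert classify_burst(self._call(0.3, 5)) == "none"

    def test_partition(self, degenerate_sim, degenerate_decoded):
        from fiberburst import classify as cl
        from fiberburst import states as st_mod

        sim = degenerate_sim
        _, classified = degenerate_decoded
        gene = sim.genes[0]
        counts = {"active": 0, "refractory": 0, "none": 0}
        for fiber in sim.fibers:
            cls = classified[fiber.fiber_id]
            acc = cl.accessible_regions(fiber, cls)
            call = st_mod.assign_state(fiber, gene, cls, acc)
            counts[call.burst_class] += 1
            if call.burst_class == "refractory":
                assert call.n_convoys == 0
        assert sum(counts.values()) == len(sim.fibers)


class TestKinetics:
    def _calls(self, convoy_flags, pol_counts, evic=None):
        calls = []
        for i, (c, p) in enumerate(zip(convoy_flags, pol_counts)):
            sc = StateCall(f"f{i}", "g")
            sc.n_convoys = c
            sc.n_polII = p
            sc.nucleosome_eviction_fraction = 0.0 if evic is None else evic[i]
            calls.append(sc)
        return calls

    def test_on_rate_fraction(self):
        calls = self._calls([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], [1] * 10)
        k = kinetics(_gene(), calls, n_boot=50)
        assert k.on_rate == pytest.approx(0.2)

    def test_amplitude_mean(self):
        calls = self._calls([0, 0, 1], [0, 0, 4])
        k = kinetics(_gene(), calls, n_boot=50)
        assert k.amplitude == pytest.approx(4 / 3)

    def test_on_rate_order_invariant(self):
        rng = np.random.default_rng(0)
        flags = list(rng.integers(0, 2, 30))
        pols = list(rng.integers(0, 5, 30))
        a = kinetics(_gene(), self._calls(flags, pols), n_boot=10)
        order = rng.permutation(30)
        b = kinetics(
            _gene(),
            self._calls([flags[i] for i in order], [pols[i] for i in order]),
            n_boot=10,
        )
        assert a.on_rate == b.on_rate
        assert a.amplitude == pytest.approx(b.amplitude)

    def test_bootstrap_deterministic(self):
        calls = self._calls([1, 0, 1, 0, 1], [3, 0, 2, 1, 4])
        a = kinetics(_gene(), calls, n_boot=200, seed=3)
        b = kinetics(_gene(), calls, n_boot=200, seed=3)
        assert a.on_rate_ci == b.on_rate_ci
        assert a.amplitude_ci == b.amplitude_ci

    def test_degenerate_flagged(self):
        calls = self._calls([1, 1, 1], [2, 2, 2])
        assert kinetics(_gene(), calls, n_boot=10).degenerate

    def test_eviction_bins_and_pvalues(self):
        rng = np.random.default_rng(1)
        evic = [0.1] * 20 + [0.9] * 20
        pols = [int(rng.integers(0, 2)) for _ in range(20)] + [
            int(rng.integers(3, 8)) for _ in range(20)
        ]
        flags = [0] * 20 + [1] * 20
        k = kinetics(
            _gene(), self._calls(flags, pols, evic),
            eviction_bins=[(0.0, 0.5), (0.5, 1.01)], n_boot=50,
        )
        assert k.per_bin["[0,0.5)"]["on_rate"] == 0.0
        assert k.per_bin["[0.5,1.01)"]["on_rate"] == 1.0
        assert k.per_bin["[0.5,1.01)"]["p_vs_previous_bin"] < 1e-4

    def test_flank_occupancy(self):
        g = _gene()
        convoy = Convoy("f0", [(2000, 2050), (2060, 2110)])
        nucs = {"f0": [(1700, 2000), (2110, 2410)]}  # fully occupied flanks
        calls = self._calls([1], [2])
        k = kinetics(
            g, calls, convoys_by_fiber={"f0": [convoy]},
            nucleosomes_by_fiber=nucs, fiber_spans={"f0": (0, 4000)},
            n_boot=20,
        )
        assert k.flank_occupancy["upstream"]["mean"] == pytest.approx(1.0)
        assert k.flank_occupancy["downstream"]["mean"] == pytest.approx(1.0)
        lo, hi = k.flank_occupancy["upstream"]["ci"]
        assert lo <= hi


class TestGMM:
    def test_recovery_within_tolerance(self):
        df = simulate_fluorescence(2500, 40, 0.16, 0.0, 10.0, 1.0, seed=2)
        thr, frac = gmm_on_rate(df["value"].values, seed=0)
        assert abs(frac - 0.16) < 0.01
        assert 3.0 < thr < 10.0

    def test_identical_values_error(self):
        with pytest.raises(ValueError):
            gmm_on_rate(np.ones(100))

    def test_collapsed_components_error(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5.0, 1e-12, 500)
        with pytest.raises(ValueError):
            gmm_on_rate(vals)


class TestDecileConcordance:
    def test_monotone_by_construction(self):
        scores = {f"g{i}": float(i) for i in range(20)}
        occ = {f"g{i}": float(i) for i in range(20)}
        means = decile_concordance(scores, occ)
        assert len(means) == 10
        assert (np.diff(means) > 0).all()

    def test_constant_signal_stable_ties(self):
        scores = {f"g{i}": 1.0 for i in range(20)}
        occ = {f"g{i}": float(i) for i in range(20)}
        means = decile_concordance(scores, occ)
        # stable order: deciles follow gene-id sort order
        genes = sorted(scores)
        expected = [np.mean([occ[g] for g in genes[i * 2 : i * 2 + 2]]) for i in range(10)]
        assert means == pytest.approx(expected)

    def test_correlated_signal_high_spearman(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(5)
        n = 200
        sig = rng.normal(size=n)
        occ_v = 0.9 * sig + np.sqrt(1 - 0.81) * rng.normal(size=n)
        scores = {f"g{i}": float(sig[i]) for i in range(n)}
        occ = {f"g{i}": float(occ_v[i]) for i in range(n)}
        means = decile_concordance(scores, occ)
        rho = spearmanr(np.arange(10), means).statistic
        assert rho >= 0.8

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            decile_concordance({"a": 1.0}, {"a": 1.0})


class TestSpacingRecovery:
    def test_mean_center_spacing_matches_planted_distribution(self):
        """Detected center-to-center spacings recover the analytic planted
        mean (mean Pol II size + mean gap) within 2 bp over >=1000 convoys."""
        from fiberburst.simulate import SimConfig, _place_convoys

        cfg = SimConfig(polII_size_range=(40, 60), convoy_gap_range=(10, 20))
        rng = np.random.default_rng(0)
        spacings = []
        n_convoys = 0
        while n_convoys < 1000:
            convoys = _place_convoys((0, 3000), 3, cfg, rng)
            for members in convoys:
                detected = detect_convoys(members, (0, 3000))
                assert len(detected) == 1
                spacings.extend(detected[0].center_spacings)
                n_convoys += 1
        planted_mean = (40 + 60) / 2 + (10 + 20) / 2  # E[size] + E[gap]
        assert abs(np.mean(spacings) - planted_mean) <= 2.0
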