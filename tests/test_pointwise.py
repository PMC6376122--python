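"""Paired t-maps, persistence criteria, sign-flip randomization, summaries."""

import itertools

import numpy as np
import pytest

from erpfield.containers import EvokedMap
from erpfield.montage import ElectrodeMontage
from erpfield.pointwise import (
    paired_t_map,
    signflip_randomization,
    spatial_extent_filter,
    summarize_effects,
    temporal_persistence_filter,
)


def _evoked(pid, cond, data):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return EvokedMap(pid, cond, data, 500.0, 0.0,
                     [f"c{i}" for i in range(data.shape[0])])


class TestPairedTMap:
    def test_identical_conditions(self, rng):
        x = rng.standard_normal((3, 20))
        ev_a = [_evoked(f"P{i}", "A", x) for i in range(4)]
        ev_b = [_evoked(f"P{i}", "B", x) for i in range(4)]
        tm = paired_t_map(ev_a, ev_b)
        assert np.all(tm.t == 0.0)
        assert np.all(tm.p == 1.0)

    def test_hand_computed_value(self):
        # diffs {1, 2, 3}: mean 2, sd 1, t = 2 sqrt(3), df = 2
        ev_a = [_evoked(f"P{i}", "A", [[float(d)]]) for i, d in enumerate([1, 2, 3])]
        ev_b = [_evoked(f"P{i}", "B", [[0.0]]) for i in range(3)]
        tm = paired_t_map(ev_a, ev_b)
        assert tm.t[0, 0] == pytest.approx(2.0 * np.sqrt(3.0))
        assert tm.df == 2

    def test_sign_swap_negates_t(self, rng):
        base = rng.standard_normal((5, 2, 10))
        ev_a = [_evoked(f"P{i}", "A", base[i]) for i in range(5)]
        ev_b = [_evoked(f"P{i}", "B", np.zeros((2, 10))) for i in range(5)]
        t1 = paired_t_map(ev_a, ev_b)
        t2 = paired_t_map(ev_b, ev_a)
        assert np.allclose(t2.t, -t1.t)
        assert np.allclose(t2.p, t1.p)

    def test_zero_variance_flagged(self):
        ev_a = [_evoked(f"P{i}", "A", [[1.0]]) for i in range(3)]
        ev_b = [_evoked(f"P{i}", "B", [[0.0]]) for i in range(3)]
        with pytest.warns(RuntimeWarning):
            tm = paired_t_map(ev_a, ev_b)
        assert np.isinf(tm.t[0, 0]) and tm.t[0, 0] > 0
        assert tm.p[0, 0] == 0.0

    def test_participant_mismatch_rejected(self, rng):
        ev_a = [_evoked("P1", "A", [[1.0]]), _evoked("P2", "A", [[1.0]])]
        ev_b = [_evoked("P1", "B", [[1.0]]), _evoked("P3", "B", [[1.0]])]
        with pytest.raises(ValueError):
            paired_t_map(ev_a, ev_b)


class TestTemporalFilter:
    @pytest.mark.parametrize("run_len,kept", [(9, False), (10, True), (11, True)])
    def test_boundary(self, run_len, kept):
        mask = np.zeros((1, 40), dtype=bool)
        mask[0, 5 : 5 + run_len] = True
        out = temporal_persistence_filter(mask, 10)
        assert out.any() == kept

    def test_min_one_is_identity(self, rng):
        mask = rng.random((4, 30)) < 0.4
        assert np.array_equal(temporal_persistence_filter(mask, 1), mask)

    def test_monotone_in_min_samples(self, rng):
        mask = rng.random((6, 80)) < 0.5
        prev = temporal_persistence_filter(mask, 2)
        for m in (4, 6, 9):
            cur = temporal_persistence_filter(mask, m)
            assert not (cur & ~prev).any()
            prev = cur

    def test_matches_brute_force_runs(self, rng):
        for _ in range(50):
            mask = rng.random((3, 25)) < 0.5
            out = temporal_persistence_filter(mask, 4)
            for c in range(3):
                # brute force: enumerate runs
                expect = np.zeros(25, dtype=bool)
                s = 0
                while s < 25:
                    if mask[c, s]:
                        e = s
                        while e < 25 and mask[c, e]:
                            e += 1
                        if e - s >= 4:
                            expect[s:e] = True
                        s = e
                    else:
                        s += 1
                assert np.array_equal(out[c], expect)


def _grid_montage():
    """A 3x3 planar-ish montage projected on the sphere; all one cluster."""
    pts = []
    for i in range(3):
        for j in range(3):
            v = np.array([0.15 * (i - 1), 0.15 * (j - 1) - 0.6, 1.0])
            pts.append(v / np.linalg.norm(v))
    labels = tuple(f"g{i}" for i in range(9))
    m = ElectrodeMontage(labels, np.array(pts))
    from erpfield.montage import compute_adjacency

    from dataclasses import replace

    m = replace(m, adjacency=compute_adjacency(m, 10.0))
    m = replace(m, clusters={l: "PM" for l in labels})
    return m


class TestSpatialFilter:
    def test_four_adjacent_cleared_five_kept(self):
        m = _grid_montage()
        mask = np.zeros((9, 1), dtype=bool)
        mask[[0, 1, 3, 4], 0] = True  # 2x2 corner block: 4 adjacent
        assert not spatial_extent_filter(mask, m, 5).any()
        mask[2, 0] = True  # grow to 5 connected channels
        out = spatial_extent_filter(mask, m, 5)
        assert out[:, 0].sum() == 5

    def test_five_nonadjacent_cleared(self):
        m = _grid_montage()
        # corners + center are pairwise non-adjacent at a tight threshold
        from dataclasses import replace

        from erpfield.montage import compute_adjacency

        m2 = replace(m, adjacency=compute_adjacency(m, 7.0))
        mask = np.zeros((9, 1), dtype=bool)
        mask[[0, 2, 6, 8, 4], 0] = True
        out = spatial_extent_filter(mask, m2, 5)
        assert not out.any()

    def test_matches_brute_force_components(self, small_montage, rng):
        adj = small_montage.adjacency_matrix()
        ret = small_montage.retained
        same = np.array([[small_montage.clusters[a] == small_montage.clusters[b]
                          for b in ret] for a in ret])
        eff = adj & same
        for _ in range(50):
            mask = rng.random((len(ret), 2)) < 0.5
            out = spatial_extent_filter(mask, small_montage, 3)
            for s in range(2):
                sig = set(np.flatnonzero(mask[:, s]))
                keep = set()
                for start in sig:
                    comp, stack = {start}, [start]
                    while stack:
                        u = stack.pop()
                        for v in np.flatnonzero(eff[u]):
                            if v in sig and v not in comp:
                                comp.add(v)
                                stack.append(v)
                    if len(comp) >= 3:
                        keep |= comp
                assert set(np.flatnonzero(out[:, s])) == keep


class TestSignFlip:
    def test_all_zero_diffs(self):
        diffs = np.zeros((4, 2, 15))
        p, mask = signflip_randomization(diffs, min_samples=1)
        assert np.all(p == 1.0)
        assert not mask.any()

    def test_exhaustive_matches_enumeration(self, rng):
        diffs = rng.standard_normal((5, 2, 4))
        p, _ = signflip_randomization(diffs, n_perm=5000, min_samples=1)
        n = 5

        def tstat(d):
            m = d.mean(axis=0)
            sd = d.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = m / (sd / np.sqrt(n))
            return np.nan_to_num(np.abs(t))

        t_obs = tstat(diffs)
        count = np.zeros_like(t_obs)
        for signs in itertools.product([-1.0, 1.0], repeat=n):
            flipped = np.array(signs)[:, None, None] * diffs
            count += tstat(flipped) >= t_obs - 1e-12
        assert np.allclose(p, count / 32.0)

    def test_sampled_mode_p_floor(self, rng):
        diffs = rng.standard_normal((15, 1, 5)) + 5.0
        p, _ = signflip_randomization(diffs, n_perm=200, min_samples=1, seed=3)
        assert p.min() >= 1.0 / 201.0

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            signflip_randomization(rng.standard_normal((15, 1, 5)), n_perm=50)

    def test_null_false_positive_rate(self, rng):
        # pooled point-wise level of the exhaustive test under a Gaussian null
        hits = total = 0
        for _ in range(100):
            diffs = rng.standard_normal((7, 3, 20))
            p, _ = signflip_randomization(diffs, n_perm=200, min_samples=1)
            hits += (p <= 0.05).sum()
            total += p.size
        rate = hits / total
        assert rate <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / total) + 0.01


class TestSummarize:
    def test_empty_mask(self, small_montage):
        from erpfield.pointwise import TTestMap

        tm = TTestMap(np.zeros((16, 20)), np.ones((16, 20)), 9)
        rep = summarize_effects(np.zeros((16, 20), dtype=bool), tm,
                                small_montage, 500.0, 0.0)
        assert len(rep) == 0

    def test_window_arithmetic(self, study_montage, rng):
        from erpfield.pointwise import TTestMap

        n_ch, n_s = 110, 120
        mask = np.zeros((n_ch, n_s), dtype=bool)
        # 5 mutually adjacent posterior channels, samples 84..102
        chans = [study_montage.retained.index(c)
                 for c in list(study_montage.neighbors("E70"))[:4] + ["E70"]]
        mask[np.ix_(chans, range(84, 103))] = True
        t = rng.standard_normal((n_ch, n_s))
        t[chans[0], 90] = 99.0
        tm = TTestMap(t, np.ones_like(t), 18, "Fear vs Neutral")
        rep = summarize_effects(mask, tm, study_montage, 500.0, 0.0)
        assert len(rep) == 1
        eff = rep.effects[0]
        assert eff.window_ms == (168.0, 204.0)
        assert eff.peak_t == 99.0
        assert eff.peak_latency_ms == 180.0

    def test_two_blocks_sorted_by_onset(self, small_montage):
        from erpfield.pointwise import TTestMap

        mask = np.zeros((16, 60), dtype=bool)
        nb = list(small_montage.neighbors("C1"))[:2] + ["C1"]
        idx = [small_montage.retained.index(c) for c in nb]
        mask[np.ix_(idx, range(40, 50))] = True
        mask[np.ix_(idx, range(5, 15))] = True
        tm = TTestMap(np.ones((16, 60)), np.ones((16, 60)), 9)
        rep = summarize_effects(mask, tm, small_montage, 500.0, 0.0)
        assert len(rep) == 2
        assert rep.effects[0].window_ms[0] < rep.effects[1].window_ms[0]
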