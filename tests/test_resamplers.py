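"""Resampling procedures: ranking, adaptive bins, count and weight invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mablwe import (ConfigError, CoordinateSpec, FixedBinConfig, MABConfig,
                    MABLConfig, MultiMABConfig, ScoreSpec, binned_resample,
                    mab_layout, mabl_resample, multi_mab_assign,
                    violating_merge_resample)
from mablwe.resamplers import (fixed_bin_assignments, mab_assignments,
                               multi_mab_assignments, outer_cell)

from conftest import make_ensemble

SPEC1 = ScoreSpec((CoordinateSpec("x", q_init=0.0, q_target=10.0),))


def random_ensemble(rng, n):
    w = rng.dirichlet(np.ones(n))
    w = np.maximum(w, 1e-12)
    w = w / w.sum()
    return make_ensemble(w, coords=rng.uniform(0, 10, (n, 1)))


class TestMABL:
    def test_five_walker_worked_shape(self, rng):
        """5 walkers with N=2: top 2 split, bottom 2 merged away, count stays 5."""
        e = random_ensemble(rng, 5)
        cfg = MABLConfig(n_split_merge=2, walker_count=5)
        out, events = mabl_resample(e, SPEC1, cfg, rng)
        assert len(out) == 5
        assert sum(ev["type"] == "split" for ev in events) == 2
        assert abs(out.total_weight - 1.0) <= 1e-12

    def test_n_zero_is_identity(self, rng):
        e = random_ensemble(rng, 6)
        cfg = MABLConfig(n_split_merge=0, walker_count=6)
        out, events = mabl_resample(e, SPEC1, cfg, rng)
        assert events == []
        np.testing.assert_array_equal(out.weights(), e.weights())

    def test_production_shape_long_loop(self, rng):
        """40 walkers, N=5 over 100 iterations of random coordinate motion:
        count fixed at 40 and weights conserved throughout."""
        e = random_ensemble(rng, 40)
        cfg = MABLConfig(n_split_merge=5, walker_count=40)
        for _ in range(100):
            for w in e.walkers:  # stand-in dynamics
                w.coords = np.clip(w.coords + rng.normal(0, 0.5, 1), 0, 10)
            e, _ = mabl_resample(e, SPEC1, cfg, rng)
            assert len(e) == 40
            assert abs(e.total_weight - 1.0) <= 1e-12

    def test_split_and_merge_sets_disjoint(self, rng):
        e = random_ensemble(rng, 12)
        cfg = MABLConfig(n_split_merge=4, walker_count=12)
        _, events = mabl_resample(e, SPEC1, cfg, rng)
        split_parents = {ev["parent"] for ev in events if ev["type"] == "split"}
        merged = set()
        for ev in events:
            if ev["type"] == "merge":
                merged.add(ev["survivor"])
                merged.update(ev["absorbed"])
        assert split_parents.isdisjoint(merged)

    def test_n_over_half_rejected(self):
        with pytest.raises(ConfigError):
            MABLConfig(n_split_merge=11, walker_count=20)

    def test_wrong_count_rejected(self, rng):
        e = random_ensemble(rng, 8)
        with pytest.raises(ConfigError):
            mabl_resample(e, SPEC1, MABLConfig(3, 10), rng)

    @settings(max_examples=40, deadline=None)
    @given(n=st.integers(4, 30), frac=st.floats(0.05, 0.5),
           seed=st.integers(0, 2 ** 31 - 1))
    def test_count_invariance_property(self, n, frac, seed):
        """Output count equals input count for every valid (count, N)."""
        rng = np.random.default_rng(seed)
        N = max(1, min(int(n * frac), n // 2))
        e = random_ensemble(rng, n)
        cfg = MABLConfig(n_split_merge=N, walker_count=n)
        out, _ = mabl_resample(e, SPEC1, cfg, rng)
        assert len(out) == n
        assert abs(out.total_weight - 1.0) <= 1e-12

    def test_balance_off_preserves_invariants(self, rng):
        spec = ScoreSpec(SPEC1.coordinates, balance="none")
        e = random_ensemble(rng, 10)
        out, _ = mabl_resample(e, spec, MABLConfig(3, 10), rng)
        assert len(out) == 10
        assert abs(out.total_weight - 1.0) <= 1e-12


class TestViolatingMode:
    def test_refuses_without_flag(self, rng):
        e = random_ensemble(rng, 6)
        with pytest.raises(ConfigError):
            violating_merge_resample(e, SPEC1, MABLConfig(2, 6), rng)

    def test_survivor_chosen_by_score_not_weight(self, rng):
        """A lower-weight, higher-progress walker deterministically absorbs a
        higher-weight one - the rule the correct mode must never break."""
        # 4 walkers; construct so ranks are unambiguous and the merge group
        # is {rank2 (w=0.3, low coord), rank3 (w=0.1, higher coord)}
        weights = [0.35, 0.25, 0.3, 0.1]
        coords = np.array([[9.0], [8.0], [1.0], [2.0]])
        e = make_ensemble(weights, coords=coords)
        cfg = MABLConfig(n_split_merge=1, walker_count=4)
        out, events = violating_merge_resample(e, SPEC1, cfg, rng,
                                               allow_biased=True)
        merge = [ev for ev in events if ev["type"] == "merge"][0]
        assert merge["survivor"] == 3          # the 0.1 walker, higher score
        assert merge["absorbed"] == [2]
        surv = [w for w in out.walkers if w.parent_id == 3][0]
        assert surv.weight == pytest.approx(0.4)


class TestMabLayout:
    def test_even_spacing(self):
        cfg = MABConfig(bins_per_dim=(5,), direction=(1,))
        lay = mab_layout([0.0, 3.0, 7.0, 10.0], [0.25] * 4, cfg, 0)
        np.testing.assert_allclose(lay.edges, [0, 2, 4, 6, 8, 10])
        assert lay.leading_value == 10.0 and lay.lagging_value == 0.0

    def test_degenerate_single_point(self):
        cfg = MABConfig(bins_per_dim=(5,), direction=(1,))
        lay = mab_layout([2.0, 2.0, 2.0], [1 / 3] * 3, cfg, 0)
        assert len(lay.edges) == 2
        assert lay.interior_index(2.0) == 0

    def test_direction_swaps_edges(self):
        cfg = MABConfig(bins_per_dim=(4,), direction=(-1,))
        lay = mab_layout([1.0, 5.0, 9.0], [1 / 3] * 3, cfg, 0)
        assert lay.leading_value == 1.0 and lay.lagging_value == 9.0

    def test_bottleneck_at_weight_drop(self):
        """The bottleneck walker sits just before the steepest drop in
        -ln(weight) along the progress direction."""
        cfg = MABConfig(bins_per_dim=(4,), direction=(1,))
        pos = [0.5, 2.5, 4.5, 6.5]
        wts = [0.5, 0.4, 0.004, 0.096]   # sharpest drop after the 0.4 bin
        lay = mab_layout(pos, wts, cfg, 0)
        assert lay.bottleneck_value == 2.5

    def test_special_bins_in_assignments(self):
        cfg = MABConfig(bins_per_dim=(4,), direction=(1,), bottleneck_enabled=False)
        coords = np.array([[0.0], [3.0], [6.0], [9.0]])
        labels = mab_assignments(coords, np.full(4, 0.25), cfg)
        assert labels[0] == ("lag", 0) and labels[-1] == ("lead", 0)
        assert isinstance(labels[1], tuple) and labels[1] != labels[2]


PAPER_BOUNDARIES = ((0.0, 7.5, 10.5, np.inf),
                    (-np.inf, 10.0, np.inf),
                    (0.0, 6.0, np.inf),
                    (0.0, 6.0, np.inf))
PAPER_SCHEMES = tuple(
    (key, MABConfig(bins_per_dim=bins, direction=(1, -1, 1, 1)))
    for key, bins in [((3.0, 55.0, 5.0, 5.0), (5, 1, 1, 1)),
                      ((8.0, 55.0, 5.0, 5.0), (5, 1, 5, 1)),
                      ((11.0, 55.0, 5.0, 5.0), (1, 5, 1, 1)),
                      ((11.0, 5.0, 5.0, 5.0), (1, 5, 1, 5))])


class TestMultiMab:
    def test_outer_cell_bisection(self):
        cfg = MultiMABConfig(outer_boundaries=((0.0, 7.5, 10.5, np.inf),),
                             schemes=(((8.0,), MABConfig((3,), (1,))),))
        cell, _ = multi_mab_assign(np.array([8.0]), cfg)
        assert cell == (1,)

    def test_boundary_value_goes_to_upper_cell(self):
        assert outer_cell(np.array([7.5]), ((0.0, 7.5, 10.5, np.inf),)) == (1,)

    def test_paper_placements_resolve_distinct_cells(self):
        cfg = MultiMABConfig(outer_boundaries=PAPER_BOUNDARIES,
                             schemes=PAPER_SCHEMES)
        cells = {outer_cell(np.array(key), PAPER_BOUNDARIES)
                 for key, _ in PAPER_SCHEMES}
        assert len(cells) == 4
        expected = {(0, 1, 0, 0), (1, 1, 0, 0), (2, 1, 0, 0), (2, 0, 0, 0)}
        assert cells == expected

    def test_unregistered_cell_is_config_error(self):
        cfg = MultiMABConfig(outer_boundaries=((0.0, 5.0, np.inf),),
                             schemes=(((1.0,), MABConfig((2,), (1,))),))
        with pytest.raises(ConfigError):
            multi_mab_assign(np.array([7.0]), cfg)

    def test_duplicate_placement_rejected(self):
        with pytest.raises(ConfigError):
            MultiMABConfig(outer_boundaries=((0.0, 5.0, np.inf),),
                           schemes=(((1.0,), MABConfig((2,), (1,))),
                                    ((2.0,), MABConfig((3,), (1,)))))

    def test_full_assignment_runs(self, rng):
        cfg = MultiMABConfig(outer_boundaries=PAPER_BOUNDARIES,
                             schemes=PAPER_SCHEMES)
        # confined to the outer cells that carry a registered scheme
        coords = np.column_stack([rng.uniform(0, 14, 20), rng.uniform(15, 60, 20),
                                  rng.uniform(0, 5.9, 20), rng.uniform(0, 5.9, 20)])
        labels = multi_mab_assignments(coords, np.full(20, 0.05), cfg)
        assert len(labels) == 20 and all(lab is not None for lab in labels)


class TestBinnedResample:
    def test_split_up_to_target(self, rng):
        e = make_ensemble([0.4, 0.6], coords=np.array([[0.0], [5.0]]))
        out, _ = binned_resample(e, [("a",), ("b",)], 4, rng)
        assert len(out) == 8
        bin_a = sorted(w.weight for w in out.walkers if w.coords[0] == 0.0)
        assert bin_a == pytest.approx([0.1] * 4)

    def test_exact_target_untouched(self, rng):
        e = make_ensemble([0.25] * 4)
        out, events = binned_resample(e, [("a",)] * 4, 4, rng)
        assert len(out) == 4 and events == []

    def test_merge_down_conserves_bin_weight(self, rng):
        w = rng.dirichlet(np.ones(9))
        e = make_ensemble(w / w.sum())
        out, _ = binned_resample(e, [("a",)] * 9, 4, rng)
        assert len(out) == 4
        assert abs(out.total_weight - 1.0) <= 1e-12

    def test_fixed_bin_assignment_half_open(self):
        cfg = FixedBinConfig(boundaries=((0.0, 1.0, 2.0, np.inf),))
        labels = fixed_bin_assignments(np.array([[0.5], [1.0], [5.0]]), cfg)
        assert labels == [(0,), (1,), (2,)]
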