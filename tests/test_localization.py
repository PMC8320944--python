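"""Dynamic-programming bone-surface extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneeus.localization import (
    BONE,
    BONELESS,
    JUMP,
    LocalizationParams,
    backtrace,
    classify_regions,
    compute_internal_energy,
    dp_minimize,
    external_energy,
    localize_bone,
)

from _dp_oracle import brute_force, path_costs

FULL = LocalizationParams(window=None)


class TestInternalEnergy:
    def test_zero_lp_gives_zero(self):
        assert np.all(compute_internal_energy(np.zeros((8, 8)), np.ones((8, 8))) == 0.0)

    def test_phantom_argmax_on_bone(self, default_features):
        shadow = default_features["shadow"]
        truth = default_features["truth"]
        eint = compute_internal_energy(default_features["features"].lp, shadow.bse)
        r, c = np.unravel_index(eint.argmax(), eint.shape)
        assert abs(r - truth.bone_rows[c]) <= 2.0

    def test_masking_suppresses_line_in_low_shadow_territory(self):
        lp = np.zeros((64, 32))
        lp[20] = 1.0  # bright line where the shadow image is low
        lp[40] = 1.0  # equally bright line in high-BSE territory
        bse = np.ones((64, 32))
        bse[:30] = 0.05
        eint = compute_internal_energy(lp, bse)
        assert eint[20].max() < 0.5 * 1.0  # < half its (normalized) lp value
        assert eint[40].max() == pytest.approx(1.0)


class TestClassifyRegions:
    def test_extremes(self):
        assert np.all(classify_regions(np.ones((6, 6))) == BONE)
        assert np.all(classify_regions(np.zeros((6, 6))) == BONELESS)

    def test_ramp_gives_three_ordered_bands(self):
        ramp = np.tile(np.linspace(0, 1, 101)[:, None], (1, 4))
        labels = classify_regions(ramp, LocalizationParams())
        col = labels[:, 0]
        # boneless at low probability, jump in between, bone at high
        changes = np.nonzero(np.diff(col))[0]
        assert len(changes) == 2
        assert col[0] == BONELESS and col[-1] == BONE
        assert np.all(col[changes[0] + 1 : changes[1] + 1] == JUMP)


class TestExternalEnergy:
    def test_straight_bone_step_costs_negative_reward(self):
        p = LocalizationParams()
        assert external_energy(0.0, 0.0, BONE, p) == -p.sigma_c

    def test_boneless_constant_is_150(self):
        # nu*D1**2 + xi*D2**2 with nu=50, xi=100, D1=D2=1
        assert external_energy(0.0, 0.0, BONELESS, LocalizationParams()) == 150.0

    def test_one_row_bone_step_hand_value(self):
        # step of 1 row after a straight run: first difference 1, second
        # difference 1 -> 50*1 + 100*1 - 0.15
        p = LocalizationParams()
        assert external_energy(1.0, 1.0, BONE, p) == pytest.approx(149.85)

    def test_jump_cost_flat(self):
        p = LocalizationParams()
        assert external_energy(5.0, 3.0, JUMP, p) == p.jump_cost


class TestDPOracle:
    def test_single_column_table_equals_costs(self):
        rng = np.random.default_rng(0)
        cost = rng.random((5, 1))
        labels = np.full((5, 1), BONE, dtype=np.int8)
        tables = dp_minimize(cost, labels, FULL)
        assert np.array_equal(tables.blmin, cost)
        surface = backtrace(tables)
        assert surface.rows[0] == cost[:, 0].argmin()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_rows = int(rng.integers(2, 6))
        n_cols = int(rng.integers(2, 7))
        cost = rng.random((n_rows, n_cols))
        labels = rng.integers(0, 3, size=(n_rows, n_cols)).astype(np.int8)
        tables = dp_minimize(cost, labels, FULL)
        surface = backtrace(tables)
        best, opt_paths = brute_force(cost, labels, FULL)
        assert tables.state_cost[-1].min() == best  # exact float equality
        dp_cost = path_costs(cost, labels, FULL, surface.path_rows[None, :])[0]
        assert dp_cost == best  # the traced path achieves the optimum exactly
        assert any(np.array_equal(p, surface.path_rows) for p in opt_paths)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_dp_cost_lower_bounds_random_paths(self, seed):
        """The DP optimum never exceeds the cost of any sampled path."""
        rng = np.random.default_rng(seed)
        n_rows, n_cols = 5, 5
        cost = rng.random((n_rows, n_cols))
        labels = rng.integers(0, 3, size=(n_rows, n_cols)).astype(np.int8)
        tables = dp_minimize(cost, labels, FULL)
        best = tables.state_cost[-1].min()
        random_paths = rng.integers(0, n_rows, size=(50, n_cols))
        assert np.all(path_costs(cost, labels, FULL, random_paths) >= best)

    def test_shift_invariance(self):
        rng = np.random.default_rng(42)
        cost = rng.random((6, 5))
        labels = rng.integers(0, 3, size=(6, 5)).astype(np.int8)
        t1 = dp_minimize(cost, labels, FULL)
        t2 = dp_minimize(cost + 0.7, labels, FULL)
        for j in range(5):
            finite = np.isfinite(t1.state_cost[j])
            shift = (j + 1) * 0.7
            assert np.allclose(
                t2.state_cost[j][finite], t1.state_cost[j][finite] + shift, atol=1e-9
            )
        assert np.array_equal(backtrace(t1).rows, backtrace(t2).rows)


class TestBacktrace:
    def test_all_boneless_gives_all_sentinels(self):
        cost = np.full((6, 8), 0.9)
        labels = np.full((6, 8), BONELESS, dtype=np.int8)
        surface = backtrace(dp_minimize(cost, labels, LocalizationParams()))
        assert np.all(surface.rows == 6)
        assert not surface.valid.any()

    def test_unambiguous_bright_path_recovered_exactly(self):
        rng = np.random.default_rng(7)
        n_rows, n_cols = 40, 30
        true_rows = (20 + 6 * np.sin(np.linspace(0, np.pi, n_cols))).astype(int)
        prob = np.zeros((n_rows, n_cols))
        prob[true_rows, np.arange(n_cols)] = 1.0
        labels = classify_regions(prob, LocalizationParams())
        tables = dp_minimize(255.0 * (1.0 - prob), labels, LocalizationParams())
        surface = backtrace(tables, eint_prob=prob)
        assert surface.valid.all()
        assert np.abs(surface.rows - true_rows).max() <= 1

    def test_path_continuity_within_window(self, default_features):
        shadow = default_features["shadow"]
        params = LocalizationParams()
        surface = localize_bone(default_features["features"].lp, shadow.bse, params)
        rows = surface.rows
        valid = surface.valid
        steps = np.abs(np.diff(rows))[valid[1:] & valid[:-1]]
        assert np.all(steps <= params.window)

    def test_csv_export(self, tmp_path, default_features):
        surface = localize_bone(
            default_features["features"].lp, default_features["shadow"].bse
        )
        path = tmp_path / "surface.csv"
        surface.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "column,row,confidence"
        assert len(lines) == 1 + len(surface.rows)
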