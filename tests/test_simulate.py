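import numpy as np
import pytest

from tilemeta import (
    DMRSpec,
    Fig1Scenario,
    draw_dmr_specs,
    insert_hidden_dmrs,
    make_template,
    simulate_fig1_panel,
    simulate_null_matrix,
)
from tilemeta.simulate import triangular_shifts


class TestTemplate:
    def test_deterministic_for_fixed_seed(self):
        a = make_template(100, seed=5)
        b = make_template(100, seed=5)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.sd, b.sd)

    def test_degenerate_ranges(self):
        t = make_template(50, mean_range=(0.0, 0.0), sd_range=(0.2, 0.2), seed=1)
        assert np.all(t.mean == 0.0)
        assert np.all(t.sd == 0.2)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            make_template(10, sd_range=(0.0, 0.1))


class TestNullMatrix:
    def test_seed_controls_identity(self):
        t = make_template(30, seed=2)
        a = simulate_null_matrix(t, 8, seed=3)
        b = simulate_null_matrix(t, 8, seed=3)
        c = simulate_null_matrix(t, 8, seed=4)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_probe_moments_match_template(self):
        """CLT check: sample mean/SD per probe converge on the template."""
        t = make_template(200, seed=7)
        m = simulate_null_matrix(t, 2000, seed=8)
        tol = 4 * t.sd / np.sqrt(2000)
        mean_ok = np.abs(m.values.mean(axis=1) - t.mean) <= tol
        sd_ok = np.abs(m.values.std(axis=1, ddof=1) - t.sd) <= 4 * t.sd / np.sqrt(2 * 2000)
        assert mean_ok.mean() >= 0.99
        assert sd_ok.mean() >= 0.99

    def test_no_sign_run_bias(self):
        """Probe-wise group mean differences are symmetric around zero."""
        t = make_template(2000, seed=9)
        m = simulate_null_matrix(t, 20, seed=10)
        diff = m.values[:, 10:].mean(axis=1) - m.values[:, :10].mean(axis=1)
        frac_pos = (diff > 0).mean()
        assert frac_pos == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(2000))


class TestTriangularProfile:
    def test_five_probe_shape_and_mean(self):
        shifts = triangular_shifts(5, 1.0)
        raw = np.array([2 / 3, 4 / 3, 2.0, 4 / 3, 2 / 3])
        np.testing.assert_allclose(shifts, raw / raw.mean())
        assert shifts.mean() == pytest.approx(1.0)
        assert np.argmax(shifts) == 2
        np.testing.assert_allclose(shifts, shifts[::-1])

    def test_mean_equals_effect_for_any_length(self):
        for L in (2, 5, 8, 30):
            for effect in (0.1, 0.5, 2.0):
                assert triangular_shifts(L, effect).mean() == pytest.approx(effect)

    def test_zero_effect_is_identity_shift(self):
        np.testing.assert_array_equal(triangular_shifts(7, 0.0), np.zeros(7))


class TestInsertHiddenDmrs:
    def test_case_shift_recovered_exactly_controls_untouched(self):
        t = make_template(60, seed=1)
        base = simulate_null_matrix(t, 10, seed=2)
        cases = base.sample_ids[5:]
        spec = DMRSpec(20, 24, effect=1.0)
        shifted, truth = insert_hidden_dmrs(base, cases, [spec])
        delta = shifted.values - base.values
        np.testing.assert_array_equal(delta[:20], 0.0)
        np.testing.assert_array_equal(delta[25:], 0.0)
        np.testing.assert_array_equal(delta[20:25, :5], 0.0)
        expected = triangular_shifts(5, 1.0)
        for j in range(5, 10):
            np.testing.assert_allclose(delta[20:25, j], expected)
        assert truth[0].start == int(base.position[20])
        assert truth[0].end == int(base.position[24])

    def test_realized_group_difference_near_effect(self):
        t = make_template(40, mean_range=(0, 0), sd_range=(0.1, 0.1), seed=3)
        base = simulate_null_matrix(t, 2000, seed=4)
        cases = base.sample_ids[1000:]
        shifted, truth = insert_hidden_dmrs(base, cases, [DMRSpec(10, 19, 0.5)])
        sl = slice(10, 20)
        diff = shifted.values[sl, 1000:].mean() - shifted.values[sl, :1000].mean()
        assert diff == pytest.approx(0.5, abs=0.01)

    def test_overlapping_specs_rejected(self):
        t = make_template(30, seed=5)
        base = simulate_null_matrix(t, 8, seed=6)
        with pytest.raises(ValueError, match="overlap"):
            insert_hidden_dmrs(
                base, base.sample_ids[4:], [DMRSpec(5, 10, 1.0), DMRSpec(10, 15, 1.0)]
            )

    def test_draw_specs_non_overlapping_with_buffer(self):
        specs = draw_dmr_specs(2000, lengths=(5, 10), effects=(0.5, 1.0),
                               n_dmrs=40, seed=7)
        assert len(specs) == 40
        for a, b in zip(specs, specs[1:]):
            assert b.first - a.last > 2


class TestFig1Panels:
    def test_enforced_all_probes_significant_at_100_pct(self):
        sc = Fig1Scenario(dmr_length=5, pct_significant=100)
        reps = simulate_fig1_panel(sc, n_replicates=5, seed=1, enforce_exact=True)
        for rep in reps:
            assert rep.significant.all()
            assert np.array_equal(rep.realized, rep.significant)

    def test_enforced_exact_count_20_pct_of_5(self):
        sc = Fig1Scenario(dmr_length=5, pct_significant=20)
        reps = simulate_fig1_panel(sc, n_replicates=5, seed=2, enforce_exact=True)
        for rep in reps:
            assert rep.significant.sum() == 1
            assert np.array_equal(rep.realized, rep.significant)

    def test_fixed_seed_reproducible(self):
        sc = Fig1Scenario(dmr_length=10, pct_significant=40)
        a = simulate_fig1_panel(sc, n_replicates=3, seed=9)
        b = simulate_fig1_panel(sc, n_replicates=3, seed=9)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.values, rb.values)
            np.testing.assert_array_equal(ra.significant, rb.significant)

    def test_unenforced_records_realized_flags(self):
        sc = Fig1Scenario(dmr_length=20, pct_significant=40)
        reps = simulate_fig1_panel(sc, n_replicates=10, seed=3)
        assert all(rep.retries == 0 for rep in reps)
        assert all(rep.significant.sum() == 8 for rep in reps)
        # realized flags vary around the design; they are measured, not forced
        assert any(
            not np.array_equal(rep.realized, rep.significant) for rep in reps
        )

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            Fig1Scenario(dmr_length=5, pct_significant=30)  # 1.5 probes
        with pytest.raises(ValueError):
            Fig1Scenario(dmr_length=4, pct_significant=50)  # length out of range
        with pytest.raises(ValueError):
            Fig1Scenario(dmr_length=10, pct_significant=110)
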