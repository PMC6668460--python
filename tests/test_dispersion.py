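"""Tests for dataset assembly, exchange fitting, profiles, weighting and BIC."""

import math

import numpy as np
import pandas as pd
import pytest

import relaxdisp as rd
from conftest import make_rate_dataset
from oracles import grid_search_chi2


def make_rates_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "residue_label", "field_mhz", "spinlock_khz", "r1rho_obs",
            "r1rho_obs_error",
        ],
    )


class TestAssembly:
    def test_zero_offsets_leave_rates_unchanged(self):
        rates = make_rates_table(
            [("A", 600.0, sl, 12.0 + sl, 0.3) for sl in (2.0, 5.0, 10.0)]
        )
        ds = rd.assemble_onres_dataset(rates, {"A": 0.0}, {"A": 1.5})
        assert ds.points["r1rho"].to_numpy() == pytest.approx(
            rates["r1rho_obs"].to_numpy()
        )
        assert ds.points["error"].to_numpy() == pytest.approx(
            rates["r1rho_obs_error"].to_numpy()
        )

    def test_low_tilt_points_excluded_with_reason(self):
        """|Omega| = 3*omega_1 at the lowest lock only -> that point excluded."""
        f = rd.FieldContext(600.0)
        # offset (ppm) chosen so Omega = 3 * omega1 at a 1 kHz lock
        omega1 = 2 * math.pi * 1e3
        offset_ppm = 3 * omega1 / (1e-6 * f.omega_n)
        rates = make_rates_table(
            [("A", 600.0, sl, 14.0, 0.3) for sl in (1.0, 10.0, 20.0)]
        )
        ds = rd.assemble_onres_dataset(rates, {"A": offset_ppm}, {"A": 1.5})
        assert len(ds.exclusions) == 1
        row = ds.exclusions.iloc[0]
        assert row.spinlock_khz == 1.0
        assert row.reason == "tilt-below-threshold"
        assert set(ds.points["spinlock_khz"]) == {10.0, 20.0}

    def test_missing_ancillary_excluded(self):
        rates = make_rates_table(
            [("A", 600.0, 5.0, 14.0, 0.3), ("B", 600.0, 5.0, 10.0, 0.3)]
        )
        ds = rd.assemble_onres_dataset(rates, {"A": 0.0}, {"A": 1.5})
        assert list(ds.exclusions["residue_label"]) == ["B"]
        assert ds.exclusions.iloc[0].reason == "missing-ancillary"

    def test_forward_construction_roundtrip(self, noiseless_config):
        """Tilt-forward then assemble-back recovers the true on-resonance rates."""
        cfg = noiseless_config
        table = rd.simulate_dispersion_experiment(cfg)
        rates = rd.fit_rate_table(table, replicates=2, seed=0)
        truth = cfg.truth()
        ds = rd.assemble_onres_dataset(
            rates,
            dict(zip(truth.residue_label, truth.offset_ppm)),
            {lab: cfg.r1_value for lab in truth.residue_label},
        )
        for _, row in truth.iterrows():
            params = rd.ExchangeParameters(
                kex=row.kex, phi_ex=row.phi_ex, r1rho_plateau=row.r1rho_plateau
            )
            for mhz in (600.0, 700.0):
                scale = (mhz / 600.0) ** 2
                pts = ds.points[
                    (ds.points.residue_label == row.residue_label)
                    & (ds.points.field_mhz == mhz)
                ]
                w1 = 2 * math.pi * pts["spinlock_khz"].to_numpy() * 1e3
                expected = rd.bm_r1rho(params, w1, scale)
                assert pts["r1rho"].to_numpy() == pytest.approx(expected, rel=1e-7)


class TestChiSquare:
    def test_perfect_predictions_zero(self):
        assert rd.chi2(np.ones(5), np.ones(5), np.full(5, 0.3)) == 0.0

    def test_single_point_unit_residual(self):
        assert rd.chi2([1.0], [1.5], [0.5]) == pytest.approx(1.0)

    def test_field_weights_scale_contributions(self):
        exp = np.array([1.0, 1.0]); calc = np.array([2.0, 2.0])
        sig = np.array([1.0, 1.0]); fields = np.array([600.0, 700.0])
        one_field = rd.chi2([1.0], [2.0], [1.0])
        combined = rd.chi2(exp, calc, sig, fields, {600.0: 1.0, 700.0: 2.0})
        assert combined == pytest.approx(3.0 * one_field)

    def test_zero_error_invalid(self):
        with pytest.raises(ValueError):
            rd.chi2([1.0], [2.0], [0.0])


class TestFieldWeighting:
    def test_equal_minima_unit_weights(self):
        w = rd.field_weighting({600.0: 50.0, 700.0: 50.0}, 600.0)
        assert w == {600.0: 1.0, 700.0: 1.0}

    def test_ratio_weights(self):
        w = rd.field_weighting({600.0: 50.0, 700.0: 100.0}, 600.0)
        assert w == {600.0: 1.0, 700.0: 0.5}

    def test_single_field_unit_weight(self):
        assert rd.field_weighting({600.0: 42.0}, 600.0) == {600.0: 1.0}

    def test_weighted_minima_equalised(self):
        """With the computed weights, each field contributes equally at its optimum."""
        minima = {600.0: 37.0, 700.0: 81.0}
        w = rd.field_weighting(minima, 600.0)
        contrib = {f: w[f] * m for f, m in minima.items()}
        assert contrib[600.0] == pytest.approx(contrib[700.0])


class TestGroupFit:
    def test_noiseless_group_recovery(self, five_residue_noiseless):
        fit = rd.fit_group(five_residue_noiseless)
        assert fit.kex == pytest.approx(1.4e4, rel=1e-6)
        for i, m in enumerate(sorted(fit.member_residues)):
            assert fit.phi_ex[m] == pytest.approx(3.0e4 + 2.0e4 * i, rel=1e-6)
            assert fit.r1rho_plateau[(m, 600.0)] == pytest.approx(
                8.0 + 0.5 * i, rel=1e-6
            )
        assert fit.chi2 == pytest.approx(0.0, abs=1e-10)

    def test_single_member_group_equals_individual_fit(self, two_residue_noiseless):
        ds = two_residue_noiseless
        alone = rd.fit_group(ds, ["A1"])
        in_group = rd.fit_group(ds.restrict(["A1"]))
        assert alone.kex == pytest.approx(in_group.kex, rel=1e-9)
        assert alone.phi_ex["A1"] == pytest.approx(in_group.phi_ex["A1"], rel=1e-9)

    def test_kex_fixed_at_truth_gives_zero_chi2(self, two_residue_noiseless):
        fit = rd.fit_group(two_residue_noiseless, kex_fixed=1.4e4)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-12)
        assert fit.n_params == 2 + 2 * 2  # no kex; phi per residue, plateau per field

    def test_parameter_count_shared_kex(self, five_residue_noiseless):
        fit = rd.fit_group(five_residue_noiseless)
        assert fit.n_params == 1 + 5 + 5 * 2
        assert fit.bic == pytest.approx(
            fit.chi2 + fit.n_params * math.log(fit.n_points)
        )

    def test_underdetermined_group_refused(self):
        ds = make_rate_dataset(
            {"A": (5e4, 10.0)}, kex=1e4, fields=(600.0,),
            spin_locks_khz=(2.0, 8.0, 20.0),
        )
        # 3 points, 3 params: fits; 2 points would refuse via curve precondition
        rd.fit_group(ds)
        with pytest.raises(ValueError):
            rd.fit_group(
                make_rate_dataset(
                    {"A": (5e4, 10.0)}, kex=1e4, fields=(600.0,),
                    spin_locks_khz=(2.0, 8.0),
                )
            )

    def test_continuous_fit_beats_lattice_search(self, two_residue_noiseless):
        """Grid-search oracle: the continuous optimum is at most the lattice minimum."""
        ds = two_residue_noiseless
        fit = rd.fit_group(ds)
        points = [
            (r.residue_label, r.field_mhz, 2 * math.pi * r.spinlock_khz * 1e3,
             r.r1rho, r.error)
            for r in ds.points.itertuples()
        ]
        lattice = grid_search_chi2(
            points,
            kex_grid=np.linspace(1.0e4, 1.8e4, 9),
            phi_grid=np.linspace(2.0e4, 1.0e5, 17),
            plateau_grid=np.linspace(8.0, 11.0, 13),
            reference_mhz=ds.reference_mhz,
        )
        assert fit.chi2 <= lattice + 1e-12

    def test_nonneg_constraints_respected(self):
        """A residue with no exchange fits phi_ex = 0, not negative."""
        ds = make_rate_dataset({"F": (0.0, 10.0)}, kex=1.4e4, noise_sigma=0.2, seed=8)
        fit = rd.fit_group(ds)
        assert fit.phi_ex["F"] >= 0.0
        assert all(v >= 0.0 for v in fit.r1rho_plateau.values())


class TestKexProfile:
    def test_noiseless_minimum_at_generating_kex(self, five_residue_noiseless):
        grid = np.logspace(3, 5, 41)
        prof = rd.kex_profile(five_residue_noiseless, grid=grid)
        assert prof.normalized_chi2.min() == 1.0
        # chi2 at truth is ~0 so the normalized minimum sits at the grid point
        # closest to the generating kex
        assert prof.kex_at_minimum == pytest.approx(1.4e4, rel=0.06)

    def test_flat_data_gives_shallow_profile(self):
        """No-exchange data: kex is unrestrained, the profile stays near 1."""
        ds = make_rate_dataset(
            {f"F{i}": (0.0, 10.0 + i) for i in range(3)},
            kex=1.4e4, noise_sigma=0.4, seed=10,
        )
        prof = rd.kex_profile(ds, grid=np.logspace(3, 5, 31))
        assert prof.normalized_chi2.max() < 1.5

    def test_grid_refinement_keeps_minimum_location(self, five_residue_noiseless):
        coarse = np.logspace(3, 5, 31)
        fine = np.logspace(3, 5, 61)
        p_c = rd.kex_profile(five_residue_noiseless, grid=coarse)
        p_f = rd.kex_profile(five_residue_noiseless, grid=fine)
        step = coarse[1] / coarse[0]
        assert abs(math.log(p_f.kex_at_minimum / p_c.kex_at_minimum)) <= math.log(step)

    def test_profile_grid_preconditions(self, two_residue_noiseless):
        with pytest.raises(ValueError):
            rd.kex_profile(two_residue_noiseless, grid=np.array([1e4]))
        with pytest.raises(ValueError):
            rd.kex_profile(
                two_residue_noiseless, grid=np.linspace(1e4, 2e4, 30)
            )  # under two decades


class TestBic:
    @pytest.mark.parametrize(
        "c2, k, n, expected",
        [
            (100.0, 3, 20, 100.0 + 3 * math.log(20)),
            (0.0, 0, 7, 0.0),
            (42.5, 5, 1, 42.5),
        ],
    )
    def test_values(self, c2, k, n, expected):
        assert rd.bic(c2, k, n) == pytest.approx(expected, rel=1e-14)

    def test_bic_recomputable_from_stored_fields(self, five_residue_noiseless):
        fit = rd.fit_group(five_residue_noiseless)
        assert fit.bic == rd.bic(fit.chi2, fit.n_params, fit.n_points)


class TestModelSelection:
    def _candidates(self, ds, groups):
        fits = [rd.fit_group(ds, g, label=str(i)) for i, g in enumerate(groups)]
        return rd.combine_group_fits(fits) if len(fits) > 1 else fits[0]

    def test_common_kex_data_prefers_global_model(self):
        residues = {f"G{i}": (3e4 + 1.5e4 * i, 8.0 + 0.4 * i) for i in range(6)}
        ds = make_rate_dataset(residues, kex=1.4e4, noise_sigma=0.4, seed=17)
        labels = sorted(residues)
        global_fit = rd.fit_group(ds, labels, label="global")
        two_group = rd.combine_group_fits(
            [rd.fit_group(ds, labels[:3]), rd.fit_group(ds, labels[3:])],
            label="two-group",
        )
        per_residue = rd.combine_group_fits(
            [rd.fit_group(ds, [m]) for m in labels], label="individual"
        )
        ranked = rd.model_selection([per_residue, two_group, global_fit])
        assert ranked[0].label == "global"

    def test_distinct_kex_groups_prefer_two_group_model(self):
        slow = {f"S{i}": (6e4 + 1e4 * i, 9.0) for i in range(3)}
        fast = {f"X{i}": (6e4 + 1e4 * i, 9.0) for i in range(3)}
        ds_slow = make_rate_dataset(slow, kex=5e3, noise_sigma=0.4, seed=23)
        ds_fast = make_rate_dataset(fast, kex=5e4, noise_sigma=0.4, seed=24)
        pts = pd.concat([ds_slow.points, ds_fast.points], ignore_index=True)
        ds = rd.DispersionDataset(pts, 600.0)
        global_fit = rd.fit_group(ds, label="global")
        two_group = rd.combine_group_fits(
            [rd.fit_group(ds, sorted(slow)), rd.fit_group(ds, sorted(fast))],
            label="two-group",
        )
        ranked = rd.model_selection([global_fit, two_group])
        assert ranked[0].label == "two-group"

    def test_single_candidate_returned_unchanged(self, two_residue_noiseless):
        fit = rd.fit_group(two_residue_noiseless)
        assert rd.model_selection([fit]) == [fit]

    def test_mismatched_point_sets_refused(self, two_residue_noiseless):
        full = rd.fit_group(two_residue_noiseless)
        partial = rd.fit_group(two_residue_noiseless, ["A1"])
        with pytest.raises(ValueError):
            rd.model_selection([full, partial])


class TestMonteCarloFitError:
    def test_tiny_rate_errors_give_tiny_parameter_errors(self):
        ds = make_rate_dataset({"A": (8e4, 10.0)}, kex=1.4e4, error=1e-12)
        fit = rd.fit_group(ds)
        fit = rd.mc_fit_error(ds, fit, replicates=20, seed=1)
        assert fit.kex_error == pytest.approx(0.0, abs=1e-4)
        assert fit.phi_ex_error["A"] == pytest.approx(0.0, abs=1e-4)

    def test_errors_shrink_with_noise(self, five_residue_noiseless):
        errs = []
        for sigma in (0.8, 0.4, 0.1):
            ds = make_rate_dataset(
                {f"G{i}": (3e4 + 2e4 * i, 8.0 + 0.5 * i) for i in range(5)},
                kex=1.4e4, error=sigma,
            )
            fit = rd.fit_group(ds)
            fit = rd.mc_fit_error(ds, fit, replicates=60, seed=3)
            errs.append(fit.kex_error)
        assert errs[0] > errs[1] > errs[2]

    def test_seed_determinism(self, two_residue_noiseless):
        ds = two_residue_noiseless
        f1 = rd.mc_fit_error(ds, rd.fit_group(ds), replicates=25, seed=11)
        f2 = rd.mc_fit_error(ds, rd.fit_group(ds), replicates=25, seed=11)
        assert f1.kex_error == f2.kex_error
        assert f1.phi_ex_error == f2.phi_ex_error


class TestClassifyDispersion:
    def test_flat_residue(self):
        ds = make_rate_dataset({"F": (0.0, 10.0)}, kex=1.4e4, noise_sigma=0.3, seed=4)
        assert rd.classify_dispersion(ds, "F") == "flat"

    def test_dispersive_residue(self):
        ds = make_rate_dataset(
            {"D": (1e5, 10.0)}, kex=1.5e4, noise_sigma=0.5, error=1.0, seed=4
        )
        assert rd.classify_dispersion(ds, "D") == "dispersive"

    def test_stable_under_point_reordering(self):
        ds = make_rate_dataset(
            {"M": (2.0e4, 10.0)}, kex=1.5e4, noise_sigma=0.8, error=0.8, seed=6
        )
        shuffled = rd.DispersionDataset(
            ds.points.sample(frac=1.0, random_state=1).reset_index(drop=True),
            ds.reference_mhz,
        )
        assert rd.classify_dispersion(ds, "M") == rd.classify_dispersion(
            shuffled, "M"
        )
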