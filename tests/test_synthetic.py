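"""Generator: linkage fold fractions, shift/decay tables, intrinsic rates."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afhdx import synthetic as syn
from afhdx.constructs import ATOM_NH, ATOM_REPORTER_SPLIT, Condition
from conftest import make_params
from oracles import fold_fraction_by_enumeration


class TestFoldFraction:
    @pytest.mark.parametrize(
        "K_fold, Ka, conc, expected",
        [
            (3.0, 1.5, 0.0, 0.75),            # zero salt reduces to K/(1+K)
            (3.0, 0.0, 0.65, 0.75),           # no linkage: constant in salt
            (3.0, 1.5, 0.65, 3.0 / (3.0 + 1.975)),  # closed form vs enumeration below
        ],
    )
    def test_linkage_closed_form(self, K_fold, Ka, conc, expected):
        p = make_params(K_fold=K_fold, Ka_anion=Ka)
        f = syn.simulate_fold_fraction(p, conc)
        assert f == pytest.approx(expected, abs=1e-12)
        assert f == pytest.approx(fold_fraction_by_enumeration(K_fold, Ka, conc), abs=1e-12)

    def test_negative_concentration_rejected(self, params):
        with pytest.raises(ValueError, match="negative anion concentration"):
            syn.simulate_fold_fraction(params, -0.1)

    @given(
        K=st.floats(0.01, 100.0),
        Ka=st.floats(0.001, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonincreasing_in_salt(self, K, Ka):
        p = make_params(K_fold=K, Ka_anion=Ka)
        grid = np.linspace(0.0, 1.0, 100)
        f = np.array([syn.simulate_fold_fraction(p, c) for c in grid])
        assert (np.diff(f) <= 1e-15).all()
        assert ((f >= 0) & (f <= 1)).all()


class TestShiftTable:
    def test_fully_folded_limit_returns_folded_shifts(self):
        p = make_params(K_fold=1e12, Ka_anion=0.0, shift_noise_sd=0.0)
        t = syn.simulate_shift_table(p, Condition(), seed=1)
        for r in range(1, 13):
            assert t.get(r, ATOM_NH)[0] == pytest.approx(p.delta_F[r - 1], abs=1e-9)

    def test_fully_unfolded_limit_returns_coil_shifts(self):
        p = make_params(K_fold=1e-12, Ka_anion=0.0, shift_noise_sd=0.0)
        t = syn.simulate_shift_table(p, Condition(), seed=1)
        for r in range(1, 13):
            assert t.get(r, ATOM_NH)[0] == pytest.approx(p.delta_U[r - 1], abs=1e-9)

    def test_noise_sd_matches_stated_model(self):
        """Monte-Carlo: residue-wise deviations have SD within 30% of 0.002 ppm."""
        p0 = make_params(shift_noise_sd=0.0)
        clean = syn.simulate_shift_table(p0, Condition(), seed=17)
        p = make_params(shift_noise_sd=0.002)
        devs = []
        for rep in range(200):
            noisy = syn.simulate_shift_table(p, Condition(), seed=17 + rep)
            for r in range(1, 13):
                devs.append(noisy.get(r, ATOM_NH)[0] - clean.get(r, ATOM_NH)[0])
        sd = np.std(devs)
        assert abs(sd - 0.002) / 0.002 < 0.30

    def test_identical_seed_reproduces_identical_table(self, params, salt_230):
        a = syn.simulate_shift_table(params, salt_230, seed=5)
        b = syn.simulate_shift_table(params, salt_230, seed=5)
        assert a.data.equals(b.data)

    def test_mismatched_residue_arrays_rejected(self):
        with pytest.raises(ValueError, match="delta_F"):
            make_params(delta_F=np.zeros(5))

    def test_concentration_above_model_validity_rejected(self, params):
        with pytest.raises(ValueError, match="1 M"):
            syn.simulate_shift_table(params, Condition(anion="Cl", concentration_mM=1500), 1)


class TestHDXTimecourse:
    def test_unprotected_peptide_exchanges_at_intrinsic_rate(self, hdx_times):
        p = make_params(PF=np.ones(12), deprotect=np.ones(12), intensity_noise_sd=0.0)
        _, truth = syn.simulate_hdx_timecourse(p, Condition(), hdx_times, seed=1)
        kint = syn.intrinsic_rates(p.sequence, 2.3)
        for r in range(1, 13):
            assert truth[r] == pytest.approx(kint[r - 1], rel=1e-12)

    def test_fully_protected_folded_state_is_flat(self, hdx_times):
        p = make_params(K_fold=1e12, PF=np.full(12, 1e6), intensity_noise_sd=0.0)
        tcs, truth = syn.simulate_hdx_timecourse(p, Condition(), hdx_times, seed=1)
        assert max(truth.values()) < 1e-6
        assert np.allclose(tcs[0].intensities, 1.0, atol=1e-3)

    def test_ex2_closed_form(self, hdx_times):
        """k_obs = k_int*( (1-f_F) + f_F/PF ) at f_F=0.79, PF=50, no binding."""
        p = make_params(
            K_fold=0.79 / 0.21, Ka_anion=0.0, PF=np.full(12, 50.0),
            intensity_noise_sd=0.0,
        )
        _, truth = syn.simulate_hdx_timecourse(p, Condition(), hdx_times, seed=1)
        kint = syn.intrinsic_rates(p.sequence, 2.3)
        for r in range(1, 13):
            expected = kint[r - 1] * (0.21 + 0.79 / 50.0)
            assert truth[r] == pytest.approx(expected, rel=1e-9)

    def test_too_few_time_points_rejected(self, params):
        with pytest.raises(ValueError, match=">= 4"):
            syn.simulate_hdx_timecourse(params, Condition(), [0.0, 1.0, 2.0], seed=1)

    def test_byte_identical_under_same_seed(self, params, hdx_times, salt_230):
        a, _ = syn.simulate_hdx_timecourse(params, salt_230, hdx_times, seed=9)
        b, _ = syn.simulate_hdx_timecourse(params, salt_230, hdx_times, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.intensities, y.intensities)


class TestIntrinsicRate:
    def test_acid_catalysis_slope_of_one(self):
        r1 = syn.intrinsic_rate("RW", 2.3)
        r2 = syn.intrinsic_rate("RW", 3.3)
        assert r1 / r2 == pytest.approx(10.0, rel=1e-12)

    def test_reference_context_returns_reference_rate(self):
        p = syn.KintParams(k_ref=0.5)
        assert syn.intrinsic_rate("AA", p.pH_ref, kint_params=p) == pytest.approx(0.5)

    def test_full_hairpin_matches_hand_lookup(self):
        """Spot-check three residues against lookup * slope arithmetic."""
        rates = syn.intrinsic_rates(syn.HAIRPIN_SEQUENCE, 2.3)
        assert (rates > 0).all() and np.isfinite(rates).all()
        F = syn.CONTEXT_FACTORS
        # W2: left R, own W
        assert rates[1] == pytest.approx(0.5 * np.sqrt(F["R"] * F["W"]), rel=1e-12)
        # G7: left N, own G
        assert rates[6] == pytest.approx(0.5 * np.sqrt(F["N"] * F["G"]), rel=1e-12)
        # R1: N-terminal factor in place of a left neighbour
        assert rates[0] == pytest.approx(0.5 * np.sqrt(2.0 * F["R"]), rel=1e-12)

    def test_unknown_residue_label_rejected(self):
        with pytest.raises(KeyError, match="Z"):
            syn.intrinsic_rate("Z", 2.3)

    def test_basic_branch_rejected(self):
        with pytest.raises(ValueError, match="pH"):
            syn.intrinsic_rate("A", 8.0)


class TestStudyBundle:
    def test_truth_sidecar_round_trip(self, params, tmp_path):
        path = tmp_path / "truth.json"
        syn.write_truth(params, path)
        back = syn.read_truth(path)
        assert back.K_fold == params.K_fold
        assert np.array_equal(back.PF, params.PF)
        assert back.kint_params == params.kint_params

    def test_fold_fraction_truth_in_unit_interval(self):
        study = syn.simulate_study(seed=3, salt_grid_mM=(0.0, 230.0, 650.0))
        assert all(0.0 <= f <= 1.0 for f in study.fold_fraction_truth.values())
        assert study.seed == 3
        for t in study.shift_tables:
            assert t.seed is not None

    def test_scenario_presets_deprotect_stated_sites(self):
        chel = syn.scenario_params("terminal_chelation")
        core = syn.scenario_params("core_intercalation")
        assert set(np.flatnonzero(chel.deprotect > 1) + 1) == {1, 12}
        assert set(np.flatnonzero(core.deprotect > 1) + 1) == {2, 9, 10, 11}
        with pytest.raises(ValueError, match="unknown scenario"):
            syn.scenario_params("nope")
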