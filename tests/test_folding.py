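"""Fraction folded, percent unfolding, referencing and delta-shift maps."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from afhdx import synthetic as syn
from afhdx.constructs import (
    ATOM_NH,
    ATOM_REF_METHYL,
    ATOM_REPORTER_SPLIT,
    Condition,
    PeptideConstruct,
    ShiftTable,
    default_constructs,
)
from afhdx.folding import (
    FoldFraction,
    delta_shift_map,
    fraction_folded,
    percent_unfolding,
    reference_correct,
)
from conftest import make_params


class TestFractionFolded:
    @pytest.mark.parametrize(
        "obs, d0, d100, expected",
        [
            (0.50, 0.00, 0.50, 1.00),   # fully folded endpoint
            (0.00, 0.00, 0.50, 0.00),   # fully unfolded endpoint
            (0.26, 0.00, 0.50, 0.52),   # linear interpolation
        ],
    )
    def test_endpoint_and_interpolation(self, obs, d0, d100, expected):
        ff = fraction_folded(obs, d0, d100)
        assert ff.value == pytest.approx(expected, abs=1e-12)
        assert ff.sigma > 0

    def test_exactly_linear_in_observed_shift(self):
        d0, d100 = 0.01, 0.56
        for lam in np.linspace(0.0, 1.0, 100):
            ff = fraction_folded(lam * d100 + (1 - lam) * d0, d0, d100)
            assert ff.value == pytest.approx(lam, abs=1e-12)

    def test_reference_collapse_rejected_naming_constructs(self):
        with pytest.raises(ValueError, match="cyclic.*half|half.*cyclic"):
            fraction_folded(0.1, 0.100, 0.101,
                            reference_ids=("half", "cyclic"))

    def test_propagated_sigma_matches_first_order_formula(self):
        obs, d0, d100, s = 0.30, 0.01, 0.56, 0.005
        ff = fraction_folded(obs, d0, d100, s, s, s)
        den = d100 - d0
        expect = s / den * np.sqrt(
            1 + ((obs - d100) / den) ** 2 + ((obs - d0) / den) ** 2
        )
        assert ff.sigma == pytest.approx(expect, rel=1e-12)

    def test_out_of_range_estimate_is_flagged(self):
        ff = fraction_folded(0.70, 0.01, 0.56)
        assert ff.value > 1.05 and ff.flagged


class TestPercentUnfolding:
    def test_subtraction_on_table_scale(self):
        a = FoldFraction(0.79, 0.005, "hairpin")
        b = FoldFraction(0.677, 0.005, "hairpin")
        points, sigma = percent_unfolding(a, b)
        assert points == pytest.approx(11.3, abs=1e-9)
        assert sigma == pytest.approx(100 * np.hypot(0.005, 0.005), rel=1e-12)

    def test_no_change_gives_zero(self):
        f = FoldFraction(0.6, 0.01, "hairpin")
        assert percent_unfolding(f, f)[0] == 0.0

    def test_antisymmetry(self):
        a = FoldFraction(0.79, 0.005, "h")
        b = FoldFraction(0.70, 0.005, "h")
        assert percent_unfolding(a, b)[0] + percent_unfolding(b, a)[0] == 0.0

    def test_mismatched_constructs_rejected(self):
        with pytest.raises(ValueError, match="different constructs"):
            percent_unfolding(FoldFraction(0.8, 0.01, "h1"), FoldFraction(0.7, 0.01, "h2"))

    def test_linkage_oracle_noise_free(self):
        """Pipeline subtraction equals the closed-form linkage prediction."""
        p = make_params(K_fold=0.79 / 0.21, Ka_anion=2.0, shift_noise_sd=0.0)
        f0t = syn.simulate_fold_fraction(p, 0.0)
        fst = syn.simulate_fold_fraction(p, 0.23)
        t0 = syn.simulate_shift_table(p, Condition(), seed=1)
        ts = syn.simulate_shift_table(p, Condition(anion="A", concentration_mM=230), seed=2)
        d0, d100 = p.reporter_split_U, p.reporter_split_F
        F0 = fraction_folded(t0.get(7, ATOM_REPORTER_SPLIT)[0], d0, d100, construct_id="hairpin")
        Fs = fraction_folded(ts.get(7, ATOM_REPORTER_SPLIT)[0], d0, d100, construct_id="hairpin")
        points, _ = percent_unfolding(F0, Fs)
        assert points == pytest.approx(100 * (f0t - fst), abs=1e-9)

    def test_noisy_recovery_within_2sigma_95pct(self):
        """Coverage of fold-fraction truth by +/-2 sigma over 1000 replicates."""
        p = make_params()
        truth = syn.simulate_fold_fraction(p, 0.0)
        d0, d100 = p.reporter_split_U, p.reporter_split_F
        hits = 0
        n = 1000
        for i in range(n):
            t = syn.simulate_shift_table(p, Condition(), seed=40_000 + i)
            ff = fraction_folded(t.get(7, ATOM_REPORTER_SPLIT)[0], d0, d100)
            hits += abs(ff.value - truth) <= 2 * ff.sigma
        assert hits / n >= 0.95


def _table(construct, cond, rows, seed=None):
    return ShiftTable(construct, cond, pd.DataFrame(rows), seed=seed)


class TestReferenceCorrect:
    def _offset_table(self, offset, noise_seed=None):
        p = make_params(shift_noise_sd=0.0)
        return syn.simulate_shift_table(
            p, Condition(anion="Cl", concentration_mM=100), seed=1,
            reference_offset=offset,
        )

    def test_uniform_offset_removed(self):
        t = self._offset_table(0.03)
        corrected = reference_correct(t)
        clean = self._offset_table(0.0)
        for r in range(1, 13):
            assert corrected.get(r, ATOM_NH)[0] == pytest.approx(
                clean.get(r, ATOM_NH)[0], abs=1e-12
            )

    def test_zero_offset_is_identity(self):
        t = self._offset_table(0.0)
        corrected = reference_correct(t)
        pd.testing.assert_frame_equal(corrected.data, t.data)

    def test_idempotent(self):
        t = self._offset_table(0.04)
        once = reference_correct(t)
        twice = reference_correct(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_random_offsets_equal_offset_free_pipeline(self):
        """Corrected maps match the same run on offset-free data to 1e-12."""
        rng = np.random.default_rng(7)
        p = make_params(shift_noise_sd=0.0)
        base_clean = syn.simulate_shift_table(p, Condition(), seed=1)
        for k, conc in enumerate((100.0, 230.0, 650.0)):
            offset = float(rng.uniform(-0.05, 0.05))
            cond = Condition(anion="Cl", concentration_mM=conc)
            with_off = syn.simulate_shift_table(p, cond, seed=2 + k, reference_offset=offset)
            no_off = syn.simulate_shift_table(p, cond, seed=2 + k, reference_offset=0.0)
            m_corr = delta_shift_map(reference_correct(base_clean), reference_correct(with_off))
            m_free = delta_shift_map(base_clean, no_off)
            assert np.allclose(
                m_corr.data["delta_ppm"], m_free.data["delta_ppm"], atol=1e-12
            )

    def test_missing_reference_row_rejected(self):
        t = _table("h", Condition(), [
            {"residue": 1, "atom": ATOM_NH, "delta_ppm": 8.0, "sigma_ppm": 0.005}
        ])
        with pytest.raises(ValueError, match="internal-reference"):
            reference_correct(t)

    def test_large_drift_warns(self):
        t = self._offset_table(0.2)
        with pytest.warns(UserWarning, match="exceeds"):
            reference_correct(t)


class TestDeltaShiftMap:
    def test_self_comparison_all_insignificant(self):
        p = make_params(shift_noise_sd=0.0)
        t = syn.simulate_shift_table(p, Condition(), seed=1)
        m = delta_shift_map(t, t)
        assert (m.data["delta_ppm"] == 0).all()
        assert (m.data["direction"] == "insignificant").all()

    def test_antisymmetry_under_argument_swap(self):
        p = make_params()
        a = syn.simulate_shift_table(p, Condition(), seed=1)
        b = syn.simulate_shift_table(p, Condition(anion="Cl", concentration_mM=230), seed=2)
        ab = delta_shift_map(a, b)
        ba = delta_shift_map(b, a)
        assert np.allclose(ab.data["delta_ppm"], -ba.data["delta_ppm"])
        flip = {"downfield": "upfield", "upfield": "downfield"}
        for x, y in zip(ab.data["direction"], ba.data["direction"]):
            assert y == flip.get(x, x)
        # negate() gives the same result as swapping arguments
        assert np.allclose(ab.negate().data["delta_ppm"], ba.data["delta_ppm"])

    def test_sign_pattern_matches_folded_minus_unfolded_truth(self):
        p = make_params(shift_noise_sd=0.0)
        unfolded = dataclasses.replace(p, K_fold=1e-12)
        folded = dataclasses.replace(p, K_fold=1e12)
        tu = syn.simulate_shift_table(unfolded, Condition(), seed=1)
        tf = syn.simulate_shift_table(folded, Condition(), seed=1)
        m = delta_shift_map(tu, tf)
        for _, row in m.data.iterrows():
            if row["residue"] == 0:
                continue
            truth_sign = np.sign(p.delta_F[int(row["residue"]) - 1] - p.delta_U[int(row["residue"]) - 1])
            assert np.sign(row["delta_ppm"]) == truth_sign

    def test_half_peptide_alignment_maps_onto_parent(self):
        constructs = default_constructs()
        rows_half = [
            {"residue": i, "atom": ATOM_NH, "delta_ppm": 8.0 + 0.01 * i, "sigma_ppm": 0.005}
            for i in range(1, 7)
        ]
        rows_hairpin = [
            {"residue": i, "atom": ATOM_NH, "delta_ppm": 8.5, "sigma_ppm": 0.005}
            for i in range(7, 13)
        ]
        half_c = _table("half_C", Condition(), rows_half)
        hairpin = _table("hairpin", Condition(), rows_hairpin)
        m = delta_shift_map(half_c, hairpin, constructs["half_C"], constructs["hairpin"])
        assert sorted(m.data["residue"]) == list(range(7, 13))
        matched = m.data[m.data["direction"] != "missing"]
        assert len(matched) == 6  # C-half residues 1..6 land on parent 7..12

    def test_unmatched_residue_reported_missing_never_dropped(self):
        a = _table("a", Condition(), [
            {"residue": 1, "atom": ATOM_NH, "delta_ppm": 8.0, "sigma_ppm": 0.005},
            {"residue": 2, "atom": ATOM_NH, "delta_ppm": 8.1, "sigma_ppm": 0.005},
        ])
        b = _table("b", Condition(), [
            {"residue": 1, "atom": ATOM_NH, "delta_ppm": 8.2, "sigma_ppm": 0.005},
        ])
        m = delta_shift_map(a, b)
        row = m.data[m.data["residue"] == 2].iloc[0]
        assert row["direction"] == "missing" and np.isnan(row["delta_ppm"])

    @given(delta=st.floats(-0.5, 0.5), sig_mult=st.floats(0.5, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_direction_consistent_with_significance_rule(self, delta, sig_mult):
        sigma = 0.005 * np.sqrt(2)
        a = _table("a", Condition(), [
            {"residue": 1, "atom": ATOM_NH, "delta_ppm": 8.0, "sigma_ppm": 0.005}
        ])
        b = _table("b", Condition(), [
            {"residue": 1, "atom": ATOM_NH, "delta_ppm": 8.0 + delta, "sigma_ppm": 0.005}
        ])
        m = delta_shift_map(a, b, significance_multiple=sig_mult)
        row = m.data.iloc[0]
        if abs(delta) <= sig_mult * sigma:
            assert row["direction"] == "insignificant"
        else:
            assert row["direction"] == ("downfield" if delta > 0 else "upfield")
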