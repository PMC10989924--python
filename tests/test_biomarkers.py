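"""PLFA quantitation, fumigation biomass, enzyme activities, GeoChip filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from microtraits.biomarkers import (
    CalibrationError,
    EnzymePlate,
    GeoChipMatrix,
    PlfaProfile,
    enzyme_activity,
    filter_geochip,
    microbial_biomass,
    normalize_geochip,
    plfa_concentrations,
    plfa_ratios,
)


class TestPlfaConcentrations:
    def _profile(self, areas, std_area=1000.0, amount=100.0, mass=5.0):
        return PlfaProfile("s1", areas, std_area, amount, mass)

    def test_unit_ratio(self):
        conc = plfa_concentrations(self._profile({"i15:0": 1000.0}))
        assert conc["i15:0"] == pytest.approx(20.0)

    def test_zero_area_zero_concentration(self):
        assert plfa_concentrations(self._profile({"i15:0": 0.0}))["i15:0"] == 0.0

    @given(
        st.floats(1e-3, 1e6), st.floats(1e-3, 1e3), st.floats(0.1, 100.0)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linear_in_area_inverse_in_mass(self, area, amount, mass):
        base = plfa_concentrations(self._profile({"m": area}, amount=amount, mass=mass))
        doubled_area = plfa_concentrations(
            self._profile({"m": 2 * area}, amount=amount, mass=mass)
        )
        doubled_mass = plfa_concentrations(
            self._profile({"m": area}, amount=amount, mass=2 * mass)
        )
        assert doubled_area["m"] == pytest.approx(2 * base["m"], rel=1e-9)
        assert doubled_mass["m"] == pytest.approx(base["m"] / 2, rel=1e-9)

    def test_zero_internal_standard_rejected(self):
        with pytest.raises(CalibrationError):
            PlfaProfile("s", {}, 0.0, 100.0, 5.0)


class TestPlfaRatios:
    def test_fb_ratio(self):
        conc = {"18:2w6,9c": 10.0, "i15:0": 8.0, "16:1w7c": 7.0, "15:0": 5.0}
        traits = plfa_ratios(conc)
        assert traits.fb_ratio == pytest.approx(10.0 / 20.0)

    def test_kr_equals_one_when_balanced(self):
        traits = plfa_ratios({"i15:0": 6.0, "16:1w7c": 6.0})
        assert traits.kr_ratio == pytest.approx(1.0)
        assert traits.gpgn_ratio == traits.kr_ratio

    def test_zero_denominator_flagged_not_raised(self):
        traits = plfa_ratios({"i15:0": 6.0})
        assert traits.gpgn_ratio is None and traits.fb_ratio is not None

    def test_total_is_sum_of_classes(self):
        conc = {"i15:0": 1.0, "16:1w7c": 2.0, "18:1w9c": 3.0, "unknown": 4.0}
        traits = plfa_ratios(conc)
        assert traits.total_nmol_g == pytest.approx(10.0)
        assert traits.class_nmol_g["other"] == pytest.approx(4.0)

    def test_fb_decreases_along_synthetic_gradient(self, default_world):
        fractions = default_world.true_plfa_fractions()
        ages = default_world.sample_ages()
        fb = fractions["fungal"] / (
            fractions["gram_positive"]
            + fractions["gram_negative"]
            + fractions["general_bacterial"]
        )
        by_age = fb.groupby(ages).mean().sort_index()
        assert (np.diff(by_age.to_numpy()) < 0).all()


class TestMicrobialBiomass:
    @pytest.mark.parametrize(
        "analyte, fum, nonfum, expected",
        [("C", 190.0, 100.0, 200.0), ("N", 74.0, 20.0, 100.0), ("P", 52.0, 12.0, 100.0)],
    )
    def test_fixture_pairs_exact(self, analyte, fum, nonfum, expected):
        assert microbial_biomass(analyte, fum, nonfum) == pytest.approx(expected)

    @given(st.floats(0, 500), st.floats(0, 500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip(self, nonfum, biomass):
        from microtraits.biomarkers import BIOMASS_K

        for analyte, k in BIOMASS_K.items():
            fum = nonfum + biomass * k
            assert microbial_biomass(analyte, fum, nonfum) * k + nonfum == pytest.approx(
                fum, abs=1e-6
            )

    def test_negative_flush_warns_but_reports(self):
        with pytest.warns(UserWarning, match="negative fumigation flush"):
            assert microbial_biomass("C", 90.0, 100.0) == pytest.approx(-10.0 / 0.45)

    def test_unknown_analyte_rejected(self):
        with pytest.raises(ValueError):
            microbial_biomass("S", 10.0, 5.0)


class TestEnzymeActivity:
    def _plate(self, wells, slope=120.0, noise=0.0, **kwargs):
        standards = {c: slope * c for c in (0.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0)}
        return EnzymePlate(standards=standards, wells=pd.DataFrame(wells), **kwargs)

    def test_worked_unit_conversion(self):
        # net fluorescence equivalent to 50 µM MUB in a 250 µL well over
        # 1 g soil and 3 h -> 50*0.25/3 = 4.1667 nmol g^-1 h^-1
        slope = 120.0
        plate = self._plate(
            [{"sample": "s", "enzyme": "AP", "test": 200.0 + slope * 50, "control": 200.0}],
            soil_equivalent_g=1.0,
        )
        got = enzyme_activity(plate)["activity_nmol_g_h"].iloc[0]
        assert got == pytest.approx(50 * 0.25 / 3.0, abs=1e-9)

    def test_test_equal_control_is_zero(self):
        plate = self._plate([{"sample": "s", "enzyme": "AP", "test": 300.0, "control": 300.0}])
        assert enzyme_activity(plate)["activity_nmol_g_h"].iloc[0] == 0.0

    def test_planted_activity_round_trip_noiseless(self):
        activity = 37.5
        soil, inc, vol, slope = 0.01, 3.0, 0.25, 120.0
        net = activity * soil * inc / vol * slope
        plate = self._plate(
            [{"sample": "s", "enzyme": "NAG", "test": 100.0 + net, "control": 100.0}]
        )
        got = enzyme_activity(plate)["activity_nmol_g_h"].iloc[0]
        assert got == pytest.approx(activity, abs=1e-9)

    def test_quench_factor_scales_net_fluorescence(self):
        wells = [{"sample": "s", "enzyme": "AP", "test": 800.0, "control": 200.0}]
        a1 = enzyme_activity(self._plate(wells))["activity_nmol_g_h"].iloc[0]
        a2 = enzyme_activity(self._plate(wells, quench_factor=2.0))["activity_nmol_g_h"].iloc[0]
        assert a1 == pytest.approx(2 * a2)

    def test_poor_standard_curve_rejected(self):
        wells = pd.DataFrame([{"sample": "s", "enzyme": "AP", "test": 1.0, "control": 0.0}])
        plate = EnzymePlate(
            standards={0.0: 50.0, 10.0: 20.0, 50.0: 900.0, 100.0: 400.0}, wells=wells
        )
        with pytest.raises(CalibrationError):
            enzyme_activity(plate)

    def test_gaussian_noise_bias_small(self):
        # planted 40 nmol/g/h, fluorescence noise sd 2 on a slope-120 curve
        rng = np.random.default_rng(41)
        activity, soil, inc, vol, slope = 40.0, 0.01, 3.0, 0.25, 120.0
        net = activity * soil * inc / vol * slope
        recovered = []
        for _ in range(20):
            wells = [
                {
                    "sample": f"s{i}",
                    "enzyme": "AG",
                    "test": 200.0 + net + rng.normal(0, 2.0),
                    "control": 200.0 + rng.normal(0, 2.0),
                }
                for i in range(8)
            ]
            standards = {
                c: slope * c + rng.normal(0, 2.0)
                for c in (0.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0)
            }
            plate = EnzymePlate(standards=standards, wells=pd.DataFrame(wells))
            recovered.append(enzyme_activity(plate)["activity_nmol_g_h"].mean())
        bias = abs(np.mean(recovered) - activity) / activity
        assert bias < 0.02


def _geochip_fixture():
    """6 probes x 4 samples; groups g1={s1,s2}, g2={s3,s4}.

    A: passes everywhere.  B: below 2x background.  C: SNR < 2.
    D: detected only in s1 (single replicate).  E: detected in group 1 only.
    F: never detected.
    """
    samples = ["s1", "s2", "s3", "s4"]
    sig = pd.DataFrame(
        {
            "s1": [1000.0, 190.0, 1000.0, 800.0, 600.0, 0.0],
            "s2": [1200.0, 190.0, 1000.0, 0.0, 700.0, 0.0],
            "s3": [900.0, 190.0, 1000.0, 0.0, 0.0, 0.0],
            "s4": [1100.0, 190.0, 1000.0, 0.0, 0.0, 0.0],
        },
        index=list("ABCDEF"),
    )
    bg = pd.DataFrame(100.0, index=sig.index, columns=samples)
    snr = pd.DataFrame(5.0, index=sig.index, columns=samples)
    snr.loc["C"] = 1.5
    groups = {"s1": "g1", "s2": "g1", "s3": "g2", "s4": "g2"}
    return GeoChipMatrix(signal=sig, background=bg, snr=snr, groups=groups)


def _brute_force_filter(matrix, fold=2.0, min_snr=2.0, min_prev=0.10):
    """Independent per-cell rule application."""
    sig = {p: dict(matrix.signal.loc[p]) for p in matrix.signal.index}
    for p in sig:
        for s in sig[p]:
            v = sig[p][s]
            if v > 0 and (
                v < fold * matrix.background.loc[p, s] or matrix.snr.loc[p, s] < min_snr
            ):
                sig[p][s] = 0.0
    groups = {}
    for s, g in matrix.groups.items():
        groups.setdefault(g, []).append(s)
    for p in sig:
        for g, members in groups.items():
            detected = [s for s in members if sig[p][s] > 0]
            if len(detected) < 2:
                for s in members:
                    sig[p][s] = 0.0
    survivors = []
    n = len(matrix.signal.columns)
    for p in sig:
        prevalence = sum(v > 0 for v in sig[p].values()) / n
        if prevalence >= min_prev:
            survivors.append(p)
    return set(survivors)


class TestGeochipFilter:
    def test_survivors_match_brute_force(self):
        matrix = _geochip_fixture()
        filtered = filter_geochip(matrix)
        assert set(filtered.signal.index) == _brute_force_filter(matrix) == {"A", "E"}

    def test_random_matrix_matches_brute_force(self):
        rng = np.random.default_rng(51)
        samples = [f"s{i}" for i in range(6)]
        probes = [f"p{i}" for i in range(40)]
        sig = pd.DataFrame(
            rng.lognormal(np.log(500), 1.0, (40, 6)) * (rng.random((40, 6)) > 0.3),
            index=probes, columns=samples,
        )
        matrix = GeoChipMatrix(
            signal=sig,
            background=pd.DataFrame(rng.uniform(50, 400, (40, 6)), index=probes, columns=samples),
            snr=pd.DataFrame(rng.uniform(0.5, 8, (40, 6)), index=probes, columns=samples),
            groups={s: f"g{i // 3}" for i, s in enumerate(samples)},
        )
        assert set(filter_geochip(matrix).signal.index) == _brute_force_filter(matrix)

    def test_idempotent(self):
        once = filter_geochip(_geochip_fixture())
        twice = filter_geochip(once)
        pd.testing.assert_frame_equal(once.signal, twice.signal)

    def test_all_passing_conserved(self):
        samples = ["s1", "s2", "s3", "s4"]
        sig = pd.DataFrame(1000.0, index=["p1", "p2"], columns=samples)
        matrix = GeoChipMatrix(
            signal=sig,
            background=pd.DataFrame(100.0, index=sig.index, columns=samples),
            snr=pd.DataFrame(5.0, index=sig.index, columns=samples),
            groups={"s1": "g1", "s2": "g1", "s3": "g2", "s4": "g2"},
        )
        assert filter_geochip(matrix).signal.shape == sig.shape

    def test_all_removed_warns(self):
        matrix = _geochip_fixture()
        with pytest.warns(UserWarning, match="all probes removed"):
            filtered = filter_geochip(matrix, fold_background=1e6)
        assert filtered.signal.empty

    def test_normalization_rows_and_log(self):
        filtered = filter_geochip(_geochip_fixture())
        norm = normalize_geochip(filtered)
        back = np.expm1(norm)
        assert back.sum(axis=1).to_numpy() == pytest.approx(np.ones(len(back)))
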