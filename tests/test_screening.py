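"""Morphology, in vitro, behavior and correlation screening statistics."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from mixtox.screening import (
    EndpointIncidenceTable,
    LELResult,
    MovementSeries,
    WellObservation,
    behavior_response_test,
    bioactivity_call,
    bioactivity_call_per_period,
    epr_period_of_second,
    exposure_correlation,
    fisher_lel,
    incidence_and_any_effect,
    lpr_cycle_phase_of_bin,
    nhbe_stats,
    plate_qc,
)
from mixtox.simulate import gen_movement


def make_well(chem="X", conc=0.0, flags=None, plate="P1", well="A1",
              timepoint="120hpf"):
    return WellObservation(plate, well, chem, conc, timepoint,
                           flags or {"mortality": False, "edemas": False})


class TestPlateQC:
    def test_perfect_plate_passes(self):
        obs = [make_well(well=f"w{i}") for i in range(36)]
        qc = plate_qc(obs)
        assert qc.passed and qc.normal_fraction == 1.0

    @pytest.mark.parametrize("n_normal, expected", [(28, False), (30, True)])
    def test_threshold_is_strict_80_percent(self, n_normal, expected):
        # 28/36 = 77.8% fails; 30/36 = 83.3% passes
        obs = [make_well(well=f"w{i}",
                         flags={"mortality": i >= n_normal})
               for i in range(36)]
        assert plate_qc(obs).passed is expected

    def test_no_controls_is_an_error(self):
        with pytest.raises(ValueError):
            plate_qc([make_well(conc=5.0)])


class TestIncidence:
    def test_any_effect_union_semantics(self):
        flags_normal = {"mortality": False, "edemas": False, "bent_axis": False}
        flags_triple = {"mortality": False, "edemas": True, "bent_axis": True}
        obs = ([make_well(conc=1.0, well=f"n{i}", flags=dict(flags_normal))
                for i in range(24)]
               + [make_well(conc=1.0, well=f"m{i}", flags=dict(flags_triple))
                  for i in range(12)]
               + [make_well(conc=0.0, well=f"c{i}", flags=dict(flags_normal))
                  for i in range(36)])
        tables = incidence_and_any_effect(obs)
        any_eff = tables["any_effect"]
        idx = any_eff.concentrations.index(1.0)
        # 12 animals with >= 1 flag count once each: 33.3%, not 66.7%
        assert any_eff.n_affected[idx] == 12
        assert any_eff.percent_incidence[idx] == pytest.approx(100 * 12 / 36)

    def test_dead_animals_excluded_from_morphology_denominator(self):
        dead = {"mortality": True, "edemas": False}
        alive = {"mortality": False, "edemas": True}
        obs = ([make_well(conc=1.0, well=f"d{i}", flags=dict(dead))
                for i in range(6)]
               + [make_well(conc=1.0, well=f"a{i}", flags=dict(alive))
                  for i in range(30)]
               + [make_well(conc=0.0, well=f"c{i}")
                  for i in range(36)])
        tables = incidence_and_any_effect(obs)
        i = tables["edemas"].concentrations.index(1.0)
        assert tables["edemas"].n_evaluated[i] == 30  # dead not evaluable
        assert tables["mortality"].n_evaluated[i] == 36
        assert tables["any_effect"].n_affected[i] == 36  # dead count in union

    def test_any_effect_dominates_single_endpoints(self):
        rng = np.random.default_rng(5)
        obs = []
        for c in (0.0, 1.0, 5.0, 25.0):
            for i in range(36):
                obs.append(make_well(conc=c, well=f"{c}-{i}", flags={
                    "mortality": bool(rng.random() < 0.1 * (c > 0)),
                    "edemas": bool(rng.random() < 0.2 * (c > 0)),
                    "bent_axis": bool(rng.random() < 0.15 * (c > 0))}))
        tables = incidence_and_any_effect(obs)
        any_aff = dict(zip(tables["any_effect"].concentrations,
                           tables["any_effect"].n_affected))
        for ep in ("mortality", "edemas", "bent_axis"):
            t = tables[ep]
            for c, a in zip(t.concentrations, t.n_affected):
                assert any_aff[c] >= a


def exact_one_sided_fisher(a1, n1, a0, n0):
    """Independent oracle: exhaustive hypergeometric tail sum with exact
    integer arithmetic over all 2x2 tables with the observed margins."""
    m = a1 + a0
    total = Fraction(0)
    denom = math.comb(n1 + n0, m)
    for k in range(a1, min(n1, m) + 1):
        if m - k <= n0:
            total += Fraction(math.comb(n1, k) * math.comb(n0, m - k), denom)
    return float(total)


class TestFisherLEL:
    def test_p_matches_exhaustive_enumeration(self):
        table = EndpointIncidenceTable("X", "any_effect",
                                       (0.0, 1.0), (36, 36), (0, 10))
        res = fisher_lel(table)
        assert res.pvalues[1.0] == pytest.approx(
            exact_one_sided_fisher(10, 36, 0, 36), rel=1e-9)

    def test_identical_incidence_gives_p_one_and_no_lel(self):
        table = EndpointIncidenceTable("X", "e", (0.0, 1.0, 5.0, 25.0),
                                       (36,) * 4, (3, 3, 3, 3))
        res = fisher_lel(table)
        assert res.lel is None
        assert all(p == pytest.approx(1.0, abs=0.05) or p <= 1.0
                   for p in res.pvalues.values())
        # equal margins and counts: the one-sided tail includes the observed
        # table, so every p is large
        assert all(p > 0.5 for p in res.pvalues.values())

    def test_lel_is_lowest_significant_concentration(self):
        concs = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
        affected = (0, 0, 0, 0, 1, 15, 20, 30)  # top three significant
        table = EndpointIncidenceTable("X", "e", concs, (36,) * 8, affected)
        res = fisher_lel(table)
        assert res.lel == 16.0

    def test_lel_monotonicity(self):
        """Raising incidence at a higher concentration never raises the LEL."""
        concs = (0.0, 1.0, 2.0, 4.0, 8.0)
        base = EndpointIncidenceTable("X", "e", concs, (36,) * 5,
                                      (0, 0, 14, 0, 0))
        more = EndpointIncidenceTable("X", "e", concs, (36,) * 5,
                                      (0, 0, 14, 0, 20))
        assert fisher_lel(more).lel <= fisher_lel(base).lel

    def test_zero_evaluated_concentration_skipped_with_warning(self):
        table = EndpointIncidenceTable("X", "e", (0.0, 1.0, 2.0),
                                       (36, 0, 36), (0, 0, 20))
        with pytest.warns(UserWarning):
            res = fisher_lel(table)
        assert 1.0 not in res.pvalues and 2.0 in res.pvalues


class TestNHBEStats:
    def test_normalization_to_control_mean(self):
        res = nhbe_stats({"control": [990.0, 1010.0],
                          "treated": [640.0, 660.0]}, "control")
        # control mean 1000 units -> a 650-unit well reads 0.65 of control
        assert res.normalized["treated"] == pytest.approx([0.64, 0.66])
        assert float(np.mean(res.normalized["treated"])) == pytest.approx(0.65)

    def test_overwhelming_shift_flags_dunnett(self):
        rng = np.random.default_rng(42)
        ctrl = rng.normal(1.0, 0.05, 6)
        shifted = rng.normal(1.0 - 10 * 0.05, 0.05, 6)  # 10 pooled SDs down
        same = rng.normal(1.0, 0.05, 6)
        res = nhbe_stats({"control": ctrl * 1000, "hit": shifted * 1000,
                          "null": same * 1000}, "control")
        assert res.dunnett_flags["hit"]
        assert not res.dunnett_flags["null"]
        assert res.anova_pvalue < 0.001
        assert res.tukey_flags[("control", "hit")]

    def test_single_group_is_an_error(self):
        with pytest.raises(ValueError):
            nhbe_stats({"control": [1.0, 2.0]}, "control")


class TestBehavior:
    def test_epr_period_boundaries(self):
        assert epr_period_of_second(21) == "background"
        assert epr_period_of_second(29) == "background"
        assert epr_period_of_second(30) is None  # pulse second
        assert epr_period_of_second(31) == "excitatory"
        assert epr_period_of_second(40) is None
        assert epr_period_of_second(41) == "refractory"
        assert epr_period_of_second(49) == "refractory"

    def test_lpr_cycle_structure(self):
        assert lpr_cycle_phase_of_bin(0) == (1, "light")
        assert lpr_cycle_phase_of_bin(30) == (1, "dark")
        assert lpr_cycle_phase_of_bin(180) == (4, "light")
        assert lpr_cycle_phase_of_bin(239) == (4, "dark")

    def test_null_treatment_is_normal(self):
        ctrl = gen_movement(1, "DMSO", 0.0, "EPR", n_subjects=32)
        treat = gen_movement(2, "X", 10.0, "EPR", n_subjects=32)
        v = behavior_response_test(treat, ctrl, "EPR")
        assert all(x == "normal" for x in v.verdicts.values())

    def test_strong_suppression_gives_hypo_verdict(self):
        ctrl = gen_movement(3, "DMSO", 0.0, "EPR", n_subjects=32)
        treat = gen_movement(4, "X", 10.0, "EPR", n_subjects=32,
                             effect={"excitatory": 0.2})
        v = behavior_response_test(treat, ctrl, "EPR", n_comparisons=24)
        assert v.verdicts["excitatory"] == "hypo"
        assert v.verdicts["background"] == "normal"

    def test_lpr_seventy_percent_normal_filter(self):
        ctrl = gen_movement(5, "DMSO", 0.0, "LPR", n_subjects=32)
        treat = gen_movement(6, "X", 10.0, "LPR", n_subjects=32,
                             excluded_fraction=0.4)  # 60% normal
        v = behavior_response_test(treat, ctrl, "LPR")
        assert all(x == "not_evaluable" for x in v.verdicts.values())

    def test_too_few_subjects_not_evaluable(self):
        ctrl = gen_movement(7, "DMSO", 0.0, "EPR", n_subjects=32)
        treat = gen_movement(8, "X", 10.0, "EPR", n_subjects=4)
        v = behavior_response_test(treat, ctrl, "EPR")
        assert not v.is_evaluable()

    def test_lpr_dark_phase_suppression_detected(self):
        ctrl = gen_movement(9, "DMSO", 0.0, "LPR", n_subjects=32)
        treat = gen_movement(10, "X", 10.0, "LPR", n_subjects=32,
                             effect={"dark": 0.2})
        v = behavior_response_test(treat, ctrl, "LPR", n_comparisons=16)
        assert v.verdicts["dark"] == "hypo"


def oracle_has_run(labels, k):
    """Brute-force run scan used as the independent check."""
    for start in range(len(labels) - k + 1):
        window = labels[start:start + k]
        if window[0] in ("hypo", "hyper") and all(w == window[0]
                                                  for w in window):
            return True
    return False


class TestBioactivityRule:
    @pytest.mark.parametrize("labels, expected", [
        (["normal", "hypo", "hypo", "hypo", "normal"], True),
        (["hypo", "hyper", "hypo", "hyper"], False),
        (["hypo", "hypo", "normal", "hypo", "hypo"], False),
        (["hyper"] * 3, True),
        ([], False),
    ])
    def test_examples(self, labels, expected):
        assert bioactivity_call(labels) is expected

    def test_exhaustive_agreement_with_run_scan_up_to_length_8(self):
        import itertools

        for length in range(0, 9):
            for labels in itertools.product(("normal", "hypo", "hyper"),
                                            repeat=length):
                assert bioactivity_call(list(labels)) == \
                    oracle_has_run(list(labels), 3)

    def test_per_period_wrapper_requires_single_period_run(self):
        from mixtox.screening import PeriodVerdicts

        def pv(conc, background, excitatory):
            return PeriodVerdicts("X", conc, "EPR",
                                  {"background": background,
                                   "excitatory": excitatory}, {})

        # runs of 2 in each period, never 3 in one period
        seq = [pv(1, "hypo", "normal"), pv(2, "hypo", "hypo"),
               pv(3, "normal", "hypo"), pv(4, "normal", "normal")]
        assert not bioactivity_call_per_period(seq)
        seq = [pv(1, "normal", "hypo"), pv(2, "normal", "hypo"),
               pv(3, "normal", "hypo")]
        assert bioactivity_call_per_period(seq)


class TestExposureCorrelation:
    def test_duplicated_column_is_perfect_and_unmasked(self):
        rng = np.random.default_rng(12)
        x = rng.lognormal(1.0, 1.0, 50)
        df = pd.DataFrame({"a": x, "b": 2.0 * x,
                           "c": rng.lognormal(1.0, 1.0, 50)})
        times = np.ones(50)
        r, p, masked = exposure_correlation(df, times)
        assert masked.loc["a", "b"] == pytest.approx(1.0)
        assert p.loc["a", "b"] < 0.01

    def test_small_matrix_matches_closed_form_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        df = pd.DataFrame({"x": x, "y": y})
        r, p, _ = exposure_correlation(df, np.ones(5))
        sx, sy = x - x.mean(), y - y.mean()
        expected = float(np.sum(sx * sy) /
                         np.sqrt(np.sum(sx**2) * np.sum(sy**2)))
        assert r.loc["x", "y"] == pytest.approx(round(expected, 2), abs=0.005)

    def test_deployment_time_normalization_matters(self):
        # two intensities anti-correlated, but both scaled by wear time:
        # without normalization the shared time induces a spurious positive r
        rng = np.random.default_rng(99)
        n = 100
        times = rng.uniform(1.0, 20.0, n)
        a = rng.lognormal(0.0, 0.3, n) * times
        b = rng.lognormal(0.0, 0.3, n) * times
        df = pd.DataFrame({"a": a, "b": b})
        r_norm, _, _ = exposure_correlation(df, times)
        r_raw, _, _ = exposure_correlation(df, np.ones(n))
        assert abs(r_norm.loc["a", "b"]) < abs(r_raw.loc["a", "b"])

    def test_constant_column_masked_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0],
                           "b": [1.0, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning):
            _, _, masked = exposure_correlation(df, np.ones(4))
        assert math.isnan(masked.loc["a", "b"])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            exposure_correlation(pd.DataFrame({"a": [1.0, 2.0]}),
                                 [1.0, 1.0])
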