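"""Synthetic-data generators: determinism, degenerate truths, CA exactness."""

import numpy as np
import pytest

from mixtox.fitting import estimate_bmc
from mixtox.mixtures import MixtureDesign, interaction_index
from mixtox.models import (
    BenchmarkResponse,
    ParameterVector,
    evaluate,
    get_family,
    inverse_at_benchmark,
)
from mixtox.simulate import (
    NHBE_GRID,
    ZF_GRID,
    gen_ca_mixture_tables,
    gen_continuous_table,
    gen_exposure_matrix,
    gen_morphology_wells,
    gen_movement,
    gen_quantal_table,
)


def equimolar3():
    return MixtureDesign("mix", (("a", None), ("b", None), ("c", None)),
                         "equimolar")


class TestDeterminism:
    def test_all_generators_are_pure_functions_of_seed(self):
        pv = ParameterVector(get_family("quantal_linear"), (0.05, 0.1))
        assert gen_quantal_table(4, "X", pv) == gen_quantal_table(4, "X", pv)
        assert (gen_continuous_table(4, "X", pv)
                == gen_continuous_table(4, "X", pv))
        m1 = gen_movement(4, "X", 1.0, "EPR", n_subjects=8)
        m2 = gen_movement(4, "X", 1.0, "EPR", n_subjects=8)
        assert [s.values for s in m1] == [s.values for s in m2]
        e1, t1 = gen_exposure_matrix(4, ("a", "b"), n_samples=20)
        e2, t2 = gen_exposure_matrix(4, ("a", "b"), n_samples=20)
        assert np.array_equal(e1.to_numpy(), e2.to_numpy())
        assert np.array_equal(t1, t2)
        d = equimolar3()
        g1 = gen_ca_mixture_tables(4, d, pv, (1.0, 2.0, 2.0))
        g2 = gen_ca_mixture_tables(4, d, pv, (1.0, 2.0, 2.0))
        assert g1 == g2

    def test_different_seeds_differ(self):
        pv = ParameterVector(get_family("quantal_linear"), (0.05, 0.1))
        assert gen_quantal_table(1, "X", pv) != gen_quantal_table(2, "X", pv)


class TestQuantalGenerator:
    def test_degenerate_zero_curve_yields_zero_counts(self):
        pv = ParameterVector(get_family("quantal_linear"), (0.0, 0.0))
        t = gen_quantal_table(8, "X", pv)
        assert all(a == 0 for a in t.n_affected)

    def test_background_only_curve_has_binomial_mean(self):
        pv = ParameterVector(get_family("quantal_linear"), (0.5, 0.0))
        counts = [a for s in range(30)
                  for a in gen_quantal_table(s, "X", pv, n=36).n_affected]
        assert np.mean(counts) == pytest.approx(18.0, abs=1.0)

    def test_default_grid_and_replication(self):
        pv = ParameterVector(get_family("quantal_linear"), (0.0, 0.05))
        t = gen_quantal_table(8, "X", pv)
        assert t.concentrations == ZF_GRID
        assert all(n == 36 for n in t.n_tested)


class TestContinuousGenerator:
    def test_noiseless_flat_truth_is_exactly_one(self):
        flat = ParameterVector(get_family("quantal_linear"), (0.0, 0.0))
        t = gen_continuous_table(3, "X", flat, noise_sd=0.0)
        assert all(r == 1.0 for reps in t.responses for r in reps)

    def test_responses_floored_at_zero(self):
        steep = ParameterVector(get_family("quantal_linear"), (0.0, 10.0))
        t = gen_continuous_table(3, "X", steep, grid=NHBE_GRID, noise_sd=0.3)
        assert all(r >= 0.0 for reps in t.responses for r in reps)


class TestCAMixtures:
    def test_equal_potency_mixture_matches_component_curve(self):
        """With identical components, the CA mixture at total T responds
        exactly like any single component dosed at T."""
        pv = ParameterVector(get_family("quantal_linear"), (0.0, 0.05))
        tabs = gen_ca_mixture_tables(5, equimolar3(), pv, (1.0, 1.0, 1.0),
                                     n=2000)
        mix = np.asarray(tabs["mix"].n_affected) / 2000
        expected = np.asarray(evaluate(pv, np.asarray(ZF_GRID)))
        assert np.allclose(mix, expected, atol=0.04)

    def test_effective_dose_closed_form(self):
        """Potencies (1,2,2) equimolar: effective reference dose at total T
        is (T/3)(1+2+2); the mixture's expected curve obeys it exactly."""
        pv = ParameterVector(get_family("quantal_linear"), (0.0, 0.03))
        tabs = gen_ca_mixture_tables(6, equimolar3(), pv, (1.0, 2.0, 2.0),
                                     n=5000)
        T = np.asarray(ZF_GRID)
        expected = np.asarray(evaluate(pv, (T / 3.0) * 5.0))
        mix = np.asarray(tabs["mix"].n_affected) / 5000
        assert np.allclose(mix, expected, atol=0.03)

    def test_antagonism_factor_raises_recovered_index(self):
        """k = 1.5 shifts the end-to-end estimated index above 1."""
        pv = ParameterVector(get_family("log_logistic"), (0.01, -6.0, 2.0))
        d = equimolar3()
        idx = []
        for seed in range(3):
            tabs = gen_ca_mixture_tables(100 + seed, d, pv, (1.0, 1.5, 0.8),
                                         n=500, interaction_factor=1.5)
            bmcs = {c: estimate_bmc(t, (0.5,))[0].bmc
                    for c, t in tabs.items()}
            a = interaction_index(d, bmcs["mix"],
                                  [bmcs[c] for c in ("a", "b", "c")])
            idx.append(a.index)
        assert np.median(idx) > 1.2

    def test_mismatched_potency_count_rejected(self):
        pv = ParameterVector(get_family("quantal_linear"), (0.0, 0.05))
        with pytest.raises(ValueError):
            gen_ca_mixture_tables(1, equimolar3(), pv, (1.0, 2.0))


class TestMorphologyWells:
    def test_counts_match_rates_roughly(self):
        hot = ParameterVector(get_family("quantal_linear"), (0.0, 1.0))
        cold = ParameterVector(get_family("quantal_linear"), (0.0, 0.0))
        wells = gen_morphology_wells(7, "X", {"mortality": cold,
                                              "edemas": hot},
                                     grid=(0.0, 100.0), n=100)
        top = [w for w in wells if w.concentration == 100.0]
        assert sum(w.endpoint_flags["edemas"] for w in top) > 90
        assert sum(w.endpoint_flags["mortality"] for w in top) == 0


class TestMovementGenerator:
    def test_epr_structure(self):
        s = gen_movement(1, "X", 0.0, "EPR", n_subjects=2)[0]
        assert len(s.values) == 50
        vals = np.asarray(s.values)
        # excitatory burst dominates background quiescence on average
        assert vals[31:40].mean() > vals[21:30].mean()

    def test_lpr_structure(self):
        s = gen_movement(1, "X", 0.0, "LPR", n_subjects=2)[0]
        assert len(s.values) == 240
        vals = np.asarray(s.values)
        dark = np.concatenate([vals[c * 60 + 30:(c + 1) * 60]
                               for c in range(4)])
        light = np.concatenate([vals[c * 60:c * 60 + 30] for c in range(4)])
        assert dark.mean() > light.mean()

    def test_excluded_fraction(self):
        series = gen_movement(2, "X", 1.0, "LPR", n_subjects=10,
                              excluded_fraction=0.3)
        assert sum(s.excluded for s in series) == 3


class TestExposureGenerator:
    def test_identity_target_keeps_off_diagonals_small(self):
        df, times = gen_exposure_matrix(11, tuple("abcdef"), n_samples=262)
        norm = df.div(times, axis=0)
        r = np.corrcoef(np.log(norm.to_numpy()).T)
        off = r[~np.eye(6, dtype=bool)]
        assert np.quantile(np.abs(off), 0.95) < 0.2

    def test_target_correlation_recovered(self):
        target = np.array([[1.0, 0.9], [0.9, 1.0]])
        df, times = gen_exposure_matrix(12, ("a", "b"), target,
                                        n_samples=262)
        r = np.corrcoef(np.log(df["a"] / times), np.log(df["b"] / times))[0, 1]
        assert 0.8 < r < 0.96

    def test_non_psd_target_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            gen_exposure_matrix(1, ("a", "b"), bad)
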