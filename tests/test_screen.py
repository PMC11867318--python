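"""Strain screening, PLS-DA, best-fit selection and the statistics layer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmbsim.screen import (
    STRAIN_BOUNDS,
    fit_plsda,
    modal_class,
    sample_strains,
    screen_strains,
    select_best_fit_strains,
)
from vmbsim.stats import bh_adjust, chi_square_frequency_test, rank_sum_test
from vmbsim.therapy import STRAIN_PARAMS, evaluate_regimen, make_regimen, make_strain

from oracles import bh_stepup, nipals_pls2, pearson_chi2_2x2


class TestModalClass:
    def test_worked_example(self):
        # 10% nAB, 20% Li, 60% oLB, 10% P -> an oLB-promoting strain
        assert modal_class(np.array([0.1, 0.2, 0.6, 0.1])) == "oLB"

    def test_tie_resolves_toward_nab(self):
        assert modal_class(np.array([0.25, 0.25, 0.25, 0.25])) == "nAB"


class TestSampleStrains:
    def test_bounds_and_nab_inhibition_constraint(self):
        strains = sample_strains(50, rng=4)
        mat = np.array([s.as_array() for s in strains])
        for j, p in enumerate(STRAIN_PARAMS):
            lo, hi = STRAIN_BOUNDS[p]
            assert (mat[:, j] >= lo).all() and (mat[:, j] <= hi).all()
        assert (mat[:, STRAIN_PARAMS.index("a_P_to_nAB")] <= 0).all()

    def test_deterministic(self):
        a = np.array([s.as_array() for s in sample_strains(10, rng=7)])
        b = np.array([s.as_array() for s in sample_strains(10, rng=7)])
        np.testing.assert_array_equal(a, b)


class TestScreen:
    @pytest.fixture(scope="class")
    def screen(self, tiny_pop, tiny_dose):
        reg = make_regimen("lactin_v", dose_amount=tiny_dose, eval_offsets=(89.0, 173.0))
        strains = sample_strains(12, rng=5) + [make_strain("null")]
        return screen_strains(tiny_pop, reg, strains=strains, dose_amount=tiny_dose)

    def test_modal_classes_partition_the_strains(self, screen):
        assert len(screen.modal_classes) == 13
        assert set(screen.modal_classes.tolist()) <= {"nAB", "Li", "oLB", "P"}

    def test_injected_null_strain_matches_direct_evaluation(self, screen, tiny_pop, tiny_dose):
        reg = make_regimen("lactin_v", dose_amount=tiny_dose)
        direct = evaluate_regimen(tiny_pop, make_strain("null"), reg)
        np.testing.assert_allclose(screen.fractions[-1], direct.fractions, atol=1e-12)

    def test_best_fit_selection_is_an_exhaustive_sort(self, screen):
        k = len(screen.strains)
        best, dist = select_best_fit_strains(screen, k=k)
        assert (np.diff(np.sort(dist)) >= 0).all()
        assert [s.name for s in best[:1]][0] == screen.strains[int(np.argmin(dist))].name
        with pytest.raises(ValueError):
            select_best_fit_strains(screen, k=k + 1)

    def test_exact_match_has_zero_distance_and_ranks_first(self, screen):
        obs12 = float(screen.failure_rates(89.0)[3])
        obs24 = float(screen.failure_rates(173.0)[3])
        best, dist = select_best_fit_strains(
            screen, clinical_rates={"12wk": obs12, "24wk": obs24}, k=1
        )
        assert dist[3] == pytest.approx(0.0, abs=1e-15)
        names = [s.name for s in screen.strains]
        assert dist[names.index(best[0].name)] == pytest.approx(0.0, abs=1e-15)
        assert (dist >= 0).all()


class TestPLSDA:
    def test_matches_nipals_oracle_on_synthetic_matrix(self, rng):
        X = rng.normal(size=(20, 8))
        classes = np.where(X[:, 1] + 0.5 * X[:, 4] > 0, "Li", "nAB")
        Y = np.column_stack([(classes == c).astype(float) for c in ("nAB", "Li")])
        model = fit_plsda(X, classes, n_components=2, n_folds=2)
        T_o, P_o = nipals_pls2(X, Y, n_components=2)
        for comp in range(2):
            t_impl = model.scores[:, comp]
            t_oracle = T_o[:, comp]
            sign = np.sign(t_impl @ t_oracle)
            np.testing.assert_allclose(t_impl, sign * t_oracle, rtol=1e-6, atol=1e-8)
            p_impl = model.loadings.iloc[:, comp].to_numpy()
            np.testing.assert_allclose(p_impl, sign * P_o[:, comp], rtol=1e-6, atol=1e-8)

    def test_discriminative_feature_dominates_lv1(self, rng):
        X = rng.normal(size=(40, 6)) * 0.1
        classes = np.array(["Li"] * 20 + ["nAB"] * 20, dtype=object)
        X[:20, 3] += 3.0  # single separating feature
        model = fit_plsda(X, classes)
        assert model.loadings["LV1"].abs().idxmax() == "x3"
        assert model.cv_accuracy > 0.9

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_plsda(rng.normal(size=(10, 4)), ["nAB"] * 10)

    def test_loadings_invariant_to_feature_order(self, rng):
        X = rng.normal(size=(30, 5))
        classes = np.where(X[:, 0] > 0, "P", "oLB")
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
        m1 = fit_plsda(df, classes)
        perm = [3, 0, 4, 1, 2]
        m2 = fit_plsda(df.iloc[:, perm], classes)
        for comp in ("LV1", "LV2"):
            a = m1.loadings[comp]
            b = m2.loadings[comp].reindex(a.index)
            sign = np.sign(a @ b)
            np.testing.assert_allclose(a.to_numpy(), sign * b.to_numpy(), atol=1e-8)


class TestStats:
    def test_identical_proportions_give_unit_p(self):
        stat, p = chi_square_frequency_test(500, 1000, 500, 1000)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_pearson_formula(self):
        stat, _ = chi_square_frequency_test(930, 2000, 640, 2000)
        expected = pearson_chi2_2x2(930, 2000 - 930, 640, 2000 - 640)
        assert stat == pytest.approx(expected, rel=1e-12)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            chi_square_frequency_test(0, 100, 0, 50)
        with pytest.raises(ValueError):
            chi_square_frequency_test(120, 100, 10, 50)

    def test_rank_sum_symmetric_under_identical_samples(self):
        assert rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_rank_sum_detects_shift(self, rng):
        x = rng.normal(0, 1, 200)
        assert rank_sum_test(x, x + 2.0) < 1e-10

    def test_bh_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.037]), [0.037])

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_bh_matches_stepup_oracle_and_invariants(self, pvals):
        adj = bh_adjust(pvals)
        np.testing.assert_allclose(adj, bh_stepup(pvals), rtol=1e-12, atol=1e-12)
        p = np.asarray(pvals)
        assert (adj >= p - 1e-15).all() and (adj <= 1 + 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
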