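import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fastdisc import (
    MODELS,
    MODELS_BY_NAME,
    bootstrap_mean_ci,
    cauchy_loglik,
    compare_all,
    delta_matrix,
    fit_model_ml,
    information_criteria,
    model_weights,
    paired_cohens_d,
    read_delta_csv,
    spillover_ratio,
    write_delta_csv,
)

from _oracles import grid_search_ll


def long_table(arr):
    arr = np.atleast_2d(arr)
    rows = []
    for i, row in enumerate(arr):
        for com, v in zip(("food", "money", "music"), row):
            rows.append((f"p{i + 1:03d}", com, v))
    return pd.DataFrame(rows, columns=["participant", "commodity", "delta_logk"])


class TestDeltaTable:
    def test_matrix_ordering_and_round_trip(self, tmp_path):
        arr = np.arange(12, dtype=float).reshape(4, 3)
        df = long_table(arr)
        assert np.array_equal(delta_matrix(df), arr)
        path = tmp_path / "deltas.csv"
        write_delta_csv(path, df, ["meta"])
        assert np.array_equal(delta_matrix(read_delta_csv(path)), arr)

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda df: df.drop(columns=["delta_logk"]),
            lambda df: df.iloc[:-1],  # missing cell
            lambda df: df.iloc[:3],  # single participant
            lambda df: df.assign(delta_logk=[np.inf] + [0.0] * (len(df) - 1)),
        ],
    )
    def test_invalid_tables_rejected(self, mutate):
        df = long_table(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            delta_matrix(mutate(df))


class TestCauchyLoglik:
    def test_density_peak_single_cell(self):
        ll = cauchy_loglik(np.array([[1.7]]), [1.7], 1.0)
        assert ll == pytest.approx(np.log(1 / np.pi), abs=1e-12)

    def test_unit_offset_single_cell(self):
        ll = cauchy_loglik(np.array([[2.0]]), [1.0], 1.0)
        assert ll == pytest.approx(np.log(1 / (2 * np.pi)), abs=1e-12)

    def test_additivity_over_cells(self, rng):
        a, b = rng.normal(size=2)
        two = cauchy_loglik(np.array([[a], [b]]), [0.3], 0.7)
        assert two == pytest.approx(
            cauchy_loglik(np.array([[a]]), [0.3], 0.7) + cauchy_loglik(np.array([[b]]), [0.3], 0.7)
        )

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            cauchy_loglik(np.zeros((2, 3)), [0, 0, 0], 0.0)


class TestFitModelML:
    def test_trait_only_matches_1d_grid(self, rng):
        arr = rng.standard_cauchy((8, 3)) * 0.4
        fit = fit_model_ml(arr, "trait_only")
        scales = np.linspace(1e-3, 3, 40_000)
        grid_ll = max(cauchy_loglik(arr, [0, 0, 0], s) for s in scales)
        assert fit.LL == pytest.approx(grid_ll, abs=1e-6)

    def test_noiseless_spillover_recovery(self):
        arr = np.tile([2.0, 0.5, 0.5], (6, 1))
        fit = fit_model_ml(arr, "spillover")
        assert fit.ml_params["epsilon"] == pytest.approx(2.0, abs=1e-3)
        assert fit.ml_params["zeta"] == pytest.approx(0.5, abs=1e-3)

    def test_nesting_ll_ordering(self, spillover_table):
        fits = {m.name: fit_model_ml(spillover_table, m) for m in MODELS}
        tol = 1e-6
        for other in fits:
            assert fits["trait_only"].LL <= fits[other].LL + tol
        assert fits["in_domain"].LL <= fits["spillover"].LL + tol
        assert fits["in_domain"].LL <= fits["negative_spillover"].LL + tol
        assert fits["state_only"].LL <= fits["spillover"].LL + tol

    def test_boundary_equality_on_positive_out_of_domain_change(self, spillover_table):
        # positive mean out-of-domain change drives the decrease parameter
        # of negative_spillover to 0, collapsing it onto in_domain
        f_neg = fit_model_ml(spillover_table, "negative_spillover")
        f_in = fit_model_ml(spillover_table, "in_domain")
        assert f_neg.ml_params["delta"] == pytest.approx(0.0, abs=1e-6)
        assert f_neg.LL == pytest.approx(f_in.LL, abs=1e-6)

    @pytest.mark.parametrize("model", [m.name for m in MODELS])
    def test_matches_grid_search_oracle_small_tables(self, model, rng):
        for rep in range(2):
            arr = rng.standard_cauchy((5, 3)) * 0.5 + np.array([1.5, 0.6, 0.4])
            fit = fit_model_ml(arr, model)
            ll_grid, _ = grid_search_ll(arr, model, len(MODELS_BY_NAME[model].param_names))
            assert fit.LL >= ll_grid - 1e-4
            assert fit.LL == pytest.approx(ll_grid, abs=1e-4)

    def test_spillover_constraint_epsilon_ge_zeta(self, rng):
        # even when the data favour zeta > epsilon, the fit must not
        arr = rng.standard_cauchy((30, 3)) * 0.3 + np.array([0.2, 1.5, 1.5])
        fit = fit_model_ml(arr, "spillover")
        assert fit.ml_params["epsilon"] >= fit.ml_params["zeta"] - 1e-12


class TestInformationCriteria:
    def test_aic_by_hand(self):
        aic, _ = information_criteria(-340.17, 3, 50)
        assert aic == pytest.approx(686.34)

    def test_bic_by_hand(self):
        _, bic = information_criteria(-347.37, 2, 50)
        assert bic == pytest.approx(2 * np.log(50) + 694.74, abs=1e-3)
        assert bic == pytest.approx(702.565, abs=1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            information_criteria(0.0, 0, 50)
        with pytest.raises(ValueError):
            information_criteria(0.0, 2, 1)

    def test_aic_bic_consistency_in_model_fit(self, spillover_table):
        fit = fit_model_ml(spillover_table, "spillover", n_bic=50)
        assert fit.AIC == pytest.approx(2 * 3 - 2 * fit.LL)
        assert fit.BIC == pytest.approx(3 * np.log(50) - 2 * fit.LL)


class TestModelWeights:
    def test_two_equal_ics(self):
        assert model_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])

    def test_delta_two(self):
        w = model_weights([0.0, 2.0])
        assert w == pytest.approx([1 / (1 + np.exp(-1)), 1 - 1 / (1 + np.exp(-1))], abs=1e-4)
        assert w == pytest.approx([0.7311, 0.2689], abs=1e-4)

    @given(st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=1, max_size=10))
    def test_probability_vector_and_shift_invariance(self, ics):
        w = model_weights(ics)
        assert np.all(w >= 0) and np.sum(w) == pytest.approx(1.0, abs=1e-12)
        assert model_weights(np.asarray(ics) + 123.4) == pytest.approx(w)


class TestCompareAll:
    def test_spillover_data_selects_spillover(self, spillover_table):
        df = compare_all(spillover_table)
        assert df.loc[df["wAIC"].idxmax(), "model"] == "spillover"
        assert df["dAIC"].min() == 0.0 and df["dBIC"].min() == 0.0
        assert df["wAIC"].sum() == pytest.approx(1.0, abs=1e-12)
        assert df["wBIC"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_null_data_selects_trait_only_by_bic(self, rng):
        arr = rng.standard_cauchy((50, 3)) * 0.1
        df = compare_all(arr)
        assert df.loc[df["wBIC"].idxmax(), "model"] == "trait_only"

    def test_row_order_is_canonical(self, spillover_table):
        df = compare_all(spillover_table)
        assert list(df["model"]) == [m.name for m in MODELS]
        assert list(df["n"]) == [1, 2, 2, 3, 3, 2]


class TestChangeStatistics:
    def test_cohens_d_examples(self):
        assert paired_cohens_d([1.0, 2.0, 3.0], [2.0, 4.0, 6.0]) == pytest.approx(2.0)
        assert paired_cohens_d([0.0, 0.0], [-1.0, 1.0]) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            paired_cohens_d([1.0, 2.0], [1.0, 2.0])  # zero-variance differences

    def test_bootstrap_ci_degenerate_and_deterministic(self):
        lo, hi = bootstrap_mean_ci([3.0] * 10, n_boot=1000, rng_seed=1)
        assert (lo, hi) == (3.0, 3.0)
        a = bootstrap_mean_ci(list(range(20)), rng_seed=5)
        b = bootstrap_mean_ci(list(range(20)), rng_seed=5)
        assert a == b
        with pytest.raises(ValueError):
            bootstrap_mean_ci([1.0, 2.0], n_boot=10)

    def test_bootstrap_width_matches_clt(self, rng):
        widths = []
        for i in range(10):
            x = rng.standard_normal(50)
            lo, hi = bootstrap_mean_ci(x, 0.95, 2000, rng_seed=i)
            assert lo <= x.mean() <= hi
            widths.append(hi - lo)
        expected = 2 * 1.96 / np.sqrt(50)
        assert np.mean(widths) == pytest.approx(expected, rel=0.25)

    def test_spillover_ratio_patterns(self):
        assert spillover_ratio(np.tile([2.0, 0.5, 0.5], (4, 1))) == pytest.approx(25.0)
        assert spillover_ratio(np.tile([1.3, 1.3, 1.3], (4, 1))) == pytest.approx(100.0)
        assert spillover_ratio(np.tile([1.3, 0.0, 0.0], (4, 1))) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            spillover_ratio(np.tile([0.0, 1.0, 1.0], (4, 1)))
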