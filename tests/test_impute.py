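"""Chained-equations imputation: starting fill, Bayesian draws, PMM closure,
determinism, and closed-form conditional-normal oracles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cvmipred import (
    ChainedEquationsImputer,
    Cohort,
    ColumnSpec,
    impute_multiple,
    impute_once,
    initialize_fill,
)
from cvmipred.impute import _draw_binary
from conftest import make_bivariate_cohort
from cvmipred.simulation import DEFAULT_SIGMA


def tiny_cohort(x_values):
    df = pd.DataFrame({"x": x_values, "y": [0.0, 1.0, 0.0][: len(x_values)]})
    return Cohort(df, "y")


class TestInitializeFill:
    def test_two_donor_column_draws_each_donor(self):
        cohort = tiny_cohort([1.0, np.nan, 3.0])
        fills = [
            initialize_fill(cohort, np.random.default_rng(seed)).X[1, 0]
            for seed in range(1000)
        ]
        assert set(fills) <= {1.0, 3.0}
        frac = np.mean(np.array(fills) == 1.0)
        assert 0.4 < frac < 0.6  # fair coin over the two donors

    def test_complete_cohort_is_identity(self, complete_cohort):
        filled = initialize_fill(complete_cohort, np.random.default_rng(0))
        assert np.array_equal(filled.X, complete_cohort.X)

    def test_degenerate_donor_set(self):
        cohort = tiny_cohort([5.0, 5.0, np.nan])
        for seed in range(50):
            filled = initialize_fill(cohort, np.random.default_rng(seed))
            assert filled.X[2, 0] == 5.0


class TestContinuousDraws:
    def test_pmm_closure(self, bivariate_cohort):
        cohort, _, miss, _ = bivariate_cohort
        observed = set(cohort.X[cohort.observed[:, 0], 0])
        for seed in range(5):
            comp = impute_once(cohort, random_state=seed)
            assert set(comp.X[miss, 0]) <= observed

    def test_constant_observed_target_imputes_constant(self):
        rng = np.random.default_rng(4)
        x1 = np.full(60, 2.5)
        x1[:12] = np.nan
        df = pd.DataFrame({
            "x1": x1,
            "x2": rng.standard_normal(60),
            "y": (rng.random(60) < 0.5).astype(float),
        })
        cohort = Cohort(df, "y")
        comp = impute_once(cohort, random_state=9)
        assert np.all(comp.X[:12, 0] == 2.5)

    def test_conditional_normal_oracle_cell_average(self):
        """Imputed-cell means track the closed-form conditional-normal mean
        rho * x2 (outcome independent by design).  Donor matching is
        discrete, so each cell carries a persistent local donor offset; the
        oracle comparison therefore averages over cells, with the cell-level
        spread providing the Monte Carlo error scale."""
        cohort, _, miss, rho = make_bivariate_cohort(n=2000, seed=5)
        x2 = cohort.X[:, 1]
        oracle = rho * x2[miss]
        draws = np.stack([
            impute_once(cohort, random_state=1000 + s).X[miss, 0]
            for s in range(100)
        ])
        err = draws.mean(axis=0) - oracle
        se = err.std(ddof=1) / np.sqrt(err.size)
        assert abs(err.mean()) < 3 * se + 0.03


class TestBinaryDraws:
    @staticmethod
    def _binary_setup(n=2000, missing=600, seed=21):
        rng = np.random.default_rng(seed)
        D = np.column_stack([np.ones(n), rng.standard_normal(n)])
        target = (rng.random(n) < 0.5).astype(float)
        obs = np.ones(n, dtype=bool)
        obs[:missing] = False
        return D, target, obs

    def test_predictor_independent_prevalence(self):
        D, target, obs = self._binary_setup()
        rng = np.random.default_rng(77)
        draws = [
            _draw_binary(D, target, obs, ridge=1e-5, rng=rng).mean()
            for _ in range(500)
        ]
        assert 0.4 < np.mean(draws) < 0.6

    def test_no_missing_cells_is_noop(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "b": (rng.random(80) < 0.5).astype(float),
            "x": rng.standard_normal(80),
            "y": (rng.random(80) < 0.5).astype(float),
        })
        cohort = Cohort(df, "y")
        comp = impute_once(cohort, random_state=3)
        assert np.array_equal(comp.X, cohort.X)

    def test_perfectly_predictive_covariate(self):
        """Under complete separation the ridge-stabilized draw still tracks
        the predictive covariate in at least 95% of imputed cells."""
        rng = np.random.default_rng(6)
        n = 500
        x = (rng.random(n) < 0.5).astype(float)
        target = x.astype(object)
        miss = rng.random(n) < 0.5
        target[miss] = np.nan
        df = pd.DataFrame({
            "t": target, "x": x,
            "y": (rng.random(n) < 0.5).astype(float),
        })
        cohort = Cohort(df, "y")
        matches, total = 0, 0
        with pytest.warns(UserWarning):
            for seed in range(50):
                comp = impute_once(cohort, random_state=seed)
                matches += int((comp.X[miss, 0] == x[miss]).sum())
                total += int(miss.sum())
        assert matches / total >= 0.95

    def test_single_observed_level_errors(self):
        df = pd.DataFrame({
            "t": [1.0, 1.0, 1.0, np.nan, np.nan],
            "x": [0.1, 0.4, -0.2, 0.5, 0.9],
            "y": [0.0, 1.0, 0.0, 1.0, 0.0],
        })
        cohort = Cohort(df, "y", column_spec={"t": ColumnSpec("binary", (0, 1))})
        with pytest.raises(ValueError, match="single observed level"):
            impute_once(cohort, random_state=0)


class TestCategoricalDraws:
    def test_values_stay_in_level_set(self, mixed_cohort):
        j = mixed_cohort.columns.index("cat")
        n_levels = len(mixed_cohort.specs[j].levels)
        comp = impute_once(mixed_cohort, random_state=14)
        assert set(comp.X[:, j]) <= set(range(n_levels))


class TestSingleDrawSurface:
    """The per-column draw operations, exercised directly on a filled
    dataset (one chained-equations sub-step)."""

    def test_draws_respect_column_kinds(self, mixed_cohort):
        from cvmipred import draw_binary, draw_categorical, draw_continuous, initialize_fill

        filled = initialize_fill(mixed_cohort, np.random.default_rng(3))
        rng = np.random.default_rng(4)
        cont = draw_continuous("x1", filled, rng=rng)
        j1 = mixed_cohort.columns.index("x1")
        observed = set(mixed_cohort.X[mixed_cohort.observed[:, j1], j1])
        assert set(cont) <= observed  # PMM closure
        assert set(draw_binary("x2", filled, rng=rng)) <= {0.0, 1.0}
        jc = mixed_cohort.columns.index("cat")
        levels = set(range(len(mixed_cohort.specs[jc].levels)))
        assert set(draw_categorical("cat", filled, rng=rng)) <= levels

    def test_kind_mismatch_rejected(self, mixed_cohort):
        from cvmipred import draw_continuous, initialize_fill

        filled = initialize_fill(mixed_cohort, np.random.default_rng(3))
        with pytest.raises(ValueError, match="not continuous"):
            draw_continuous("cat", filled, rng=np.random.default_rng(1))


class TestImputeOnce:
    def test_complete_data_unchanged(self, complete_cohort):
        comp = impute_once(complete_cohort, random_state=1)
        assert np.array_equal(comp.X, complete_cohort.X)
        assert comp.outcome_imputed is None

    def test_seed_determinism(self, mixed_cohort):
        a = impute_once(mixed_cohort, random_state=123)
        b = impute_once(mixed_cohort, random_state=123)
        assert np.array_equal(a.X, b.X)

    def test_observed_cells_preserved(self, mixed_cohort):
        obs = mixed_cohort.observed
        for seed in range(5):
            comp = impute_once(mixed_cohort, random_state=seed)
            assert np.array_equal(comp.X[obs], mixed_cohort.X[obs])
            assert not np.isnan(comp.X).any()

    def test_masked_outcomes_imputed_and_flagged(self, bivariate_cohort):
        cohort, _, _, _ = bivariate_cohort
        masked = cohort.mask_outcomes(np.arange(40))
        comp = impute_once(masked, random_state=8)
        assert comp.outcome_imputed is not None
        assert set(np.unique(comp.outcome_imputed)) <= {0.0, 1.0}
        # observed outcomes pass through untouched
        assert np.array_equal(comp.outcome_imputed[40:], cohort.y[40:])

    def test_mvn_conditional_oracle(self):
        """Imputed-cell means track the exact 4-variate conditional-normal
        mean (outcome independent of predictors so it carries no signal)."""
        rng = np.random.default_rng(31)
        n = 500
        L = np.linalg.cholesky(DEFAULT_SIGMA)
        X = rng.standard_normal((n, 4)) @ L.T
        y = (rng.random(n) < 0.3).astype(float)
        miss = rng.random(n) < 0.10
        Xm = X.copy()
        Xm[miss, 0] = np.nan
        df = pd.DataFrame(Xm, columns=["x1", "x2", "x3", "x4"])
        df["y"] = y
        cohort = Cohort(df, "y")

        S = np.asarray(DEFAULT_SIGMA)
        w = np.linalg.solve(S[1:, 1:], S[1:, 0])
        oracle = X[miss][:, 1:] @ w  # E[x1 | x2..x4], mu = 0

        draws = np.stack([
            impute_once(cohort, random_state=500 + s).X[miss, 0]
            for s in range(100)
        ])
        cell_means = draws.mean(axis=0)
        err = cell_means - oracle
        se = err.std(ddof=1) / np.sqrt(err.size)
        assert abs(err.mean()) < 3 * se + 0.05


class TestImputeMultiple:
    def test_k1_equals_first_substream(self, mixed_cohort):
        multi = impute_multiple(mixed_cohort, 1, random_state=55)
        imputer = ChainedEquationsImputer()
        from cvmipred._rng import seed_sequence, substream

        single = imputer.impute_once(
            mixed_cohort, random_state=substream(seed_sequence(55), 0)
        )
        assert np.array_equal(multi[0].X, single.X)

    def test_complete_data_gives_identical_copies(self, complete_cohort):
        draws = impute_multiple(complete_cohort, 4, random_state=2)
        assert len(draws) == 4
        for d in draws:
            assert np.array_equal(d.X, complete_cohort.X)

    def test_between_imputation_variance_positive(self, bivariate_cohort):
        cohort, _, miss, _ = bivariate_cohort
        draws = impute_multiple(cohort, 50, random_state=9)
        cell = np.flatnonzero(miss)[0]
        values = np.array([d.X[cell, 0] for d in draws])
        assert values.var() > 0

    def test_invalid_count_errors(self, mixed_cohort):
        with pytest.raises(ValueError):
            impute_multiple(mixed_cohort, 0)


class TestSettingsValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(n_cycles=0), dict(pmm_donors=0), dict(ridge=-1.0)]
    )
    def test_invalid_settings_rejected(self, kwargs, mixed_cohort):
        with pytest.raises(ValueError):
            ChainedEquationsImputer(**kwargs).impute_once(mixed_cohort, random_state=0)


def _property_cohort():
    rng = np.random.default_rng(123)
    x1 = rng.standard_normal(40)
    x1[:8] = np.nan
    df = pd.DataFrame({
        "x1": x1,
        "x2": rng.standard_normal(40),
        "y": (rng.random(40) < 0.5).astype(float),
    })
    return Cohort(df, "y")


@given(st.integers(min_value=0, max_value=10_000))
def test_determinism_property(seed):
    """Identical (cohort, settings, seed) -> identical draws, any seed."""
    cohort = _property_cohort()
    a = impute_once(cohort, random_state=seed)
    b = impute_once(cohort, random_state=seed)
    assert np.array_equal(a.X, b.X)
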