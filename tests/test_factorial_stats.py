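"""Balanced factorial ANOVA, Welch t-test and Pearson correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from crustgas.errors import InvalidInputError, UndefinedCorrelationError, UnsupportedDesignError
from crustgas.factorial_stats import (
    FactorialDataset,
    factorial_anova,
    log_transform,
    pearson_correlation,
    welch_t_test,
)

CELLS = list(itertools.product("FW", "LD", "NO"))


def make_dataset(responses_by_cell, n):
    rows = []
    for (w, l, h), values in responses_by_cell.items():
        assert len(values) == n
        for v in values:
            rows.append((v, w, l, h))
    arr = np.array(rows, dtype=object)
    return FactorialDataset(
        responses=arr[:, 0].astype(float),
        wetting=arr[:, 1],
        light=arr[:, 2],
        headspace=arr[:, 3],
    )


def random_dataset(rng, n=3, effects=False):
    data = {}
    for cell in CELLS:
        mu = 0.0
        if effects:
            mu = (cell[0] == "F") * 1.5 + (cell[2] == "N") * 3.0 + (cell[0] == "F") * (cell[1] == "L") * 0.8
        data[cell] = rng.normal(mu, 1.0, size=n).tolist()
    return make_dataset(data, n)


def statsmodels_oracle(data: FactorialDataset) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "y": data.responses,
            "w": data.wetting.astype(str),
            "l": data.light.astype(str),
            "h": data.headspace.astype(str),
        }
    )
    model = smf.ols("y ~ C(w) * C(l) * C(h)", data=df).fit()
    return anova_lm(model, typ=1)


class TestLogTransform:
    def test_natural_log(self):
        out = log_transform([1.0, np.e, np.e**2])
        assert out == pytest.approx([0.0, 1.0, 2.0])

    def test_log10_mode(self):
        assert log_transform([3.15e4], base="log10")[0] == pytest.approx(4.4983, abs=1e-4)

    def test_nonpositive_reports_rows(self):
        with pytest.raises(InvalidInputError, match=r"\[1\]"):
            log_transform([2.0, 0.0, 3.0])


class TestFactorialAnova:
    def test_constant_response_gives_zero_ss(self):
        data = make_dataset({cell: [5.0, 5.0, 5.0] for cell in CELLS}, 3)
        table = factorial_anova(data)
        for term in ("wetting", "light", "headspace", "wetting:light:headspace"):
            assert table.loc[term, "sum_sq"] == pytest.approx(0.0, abs=1e-12)
            assert table.loc[term, "F"] == 0.0

    def test_pure_main_effect_against_cell_means_oracle(self, rng):
        # +c on every flooded cell, noise-free: SS_wetting = N c^2 / 4
        c = 2.0
        data = make_dataset(
            {cell: [c if cell[0] == "F" else 0.0] * 3 for cell in CELLS}, 3
        )
        table = factorial_anova(data)
        n_tot = 24
        assert table.loc["wetting", "sum_sq"] == pytest.approx(n_tot * c**2 / 4)
        for term in ("light", "headspace", "wetting:light"):
            assert table.loc[term, "sum_sq"] == pytest.approx(0.0, abs=1e-10)

    def test_residual_df_is_sixteen_for_triplicates(self, rng):
        table = factorial_anova(random_dataset(rng))
        assert table.loc["Residual", "df"] == 16

    def test_matches_statsmodels_glm_oracle(self, rng):
        """F statistics equal an independent OLS/ANOVA fit to 1e-8."""
        name_map = {
            "C(w)": "wetting",
            "C(l)": "light",
            "C(h)": "headspace",
            "C(w):C(l)": "wetting:light",
            "C(w):C(h)": "wetting:headspace",
            "C(l):C(h)": "light:headspace",
            "C(w):C(l):C(h)": "wetting:light:headspace",
        }
        for _ in range(100):
            data = random_dataset(rng, effects=True)
            ours = factorial_anova(data)
            oracle = statsmodels_oracle(data)
            for sm_name, our_name in name_map.items():
                assert ours.loc[our_name, "F"] == pytest.approx(
                    oracle.loc[sm_name, "F"], rel=1e-8
                )
                assert ours.loc[our_name, "sum_sq"] == pytest.approx(
                    oracle.loc[sm_name, "sum_sq"], rel=1e-8, abs=1e-10
                )

    def test_ss_decomposition_sums_to_total(self, rng):
        data = random_dataset(rng, effects=True)
        table = factorial_anova(data)
        terms = table.drop(index=["Residual", "Total"])["sum_sq"].sum()
        assert terms + table.loc["Residual", "sum_sq"] == pytest.approx(
            table.loc["Total", "sum_sq"], rel=1e-10
        )

    def test_unbalanced_design_rejected(self, rng):
        data = random_dataset(rng)
        unbalanced = FactorialDataset(
            responses=data.responses[:-1],
            wetting=data.wetting[:-1],
            light=data.light[:-1],
            headspace=data.headspace[:-1],
        )
        with pytest.raises(UnsupportedDesignError):
            factorial_anova(unbalanced)

    def test_type_one_error_calibration_under_null(self):
        """Rejection rate per term at alpha=0.05 stays within [0.03, 0.07]."""
        rng = np.random.default_rng(2024)
        reps = 1000
        terms = [
            "wetting",
            "light",
            "headspace",
            "wetting:light",
            "wetting:headspace",
            "light:headspace",
            "wetting:light:headspace",
        ]
        rejections = {t: 0 for t in terms}
        for _ in range(reps):
            table = factorial_anova(random_dataset(rng, effects=False))
            for t in terms:
                if table.loc[t, "p"] < 0.05:
                    rejections[t] += 1
        for t in terms:
            assert 0.03 <= rejections[t] / reps <= 0.07, (t, rejections[t] / reps)


class TestWelchAndPearson:
    def test_identical_groups(self):
        t, _, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_separated_groups(self):
        t, _, p = welch_t_test([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert p == 0.0
        assert np.isinf(t)

    def test_degenerate_equal_groups(self):
        t, _, p = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_matches_manual_welch_formula(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, size=rng.integers(3, 10))
            b = rng.normal(0.5, 2, size=rng.integers(3, 10))
            t, df, p = welch_t_test(a, b)
            va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
            t_manual = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df_manual = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
            assert t == pytest.approx(t_manual, rel=1e-8)
            assert df == pytest.approx(df_manual, rel=1e-8)
            from scipy import stats as sps

            assert p == pytest.approx(2 * sps.t.sf(abs(t_manual), df_manual), rel=1e-8)

    def test_pearson_exact_lines(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_pearson_independent_samples_near_zero(self):
        rng = np.random.default_rng(7)
        r, _ = pearson_correlation(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.1

    def test_pearson_zero_variance_errors(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
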