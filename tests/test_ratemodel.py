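"""y-equidistant splitting, MLR fitting, screening and agreement metrics."""

import numpy as np
import pandas as pd
import pytest

from confdesc.ratemodel import (
    RateModel,
    fit_mlr,
    source_agreement,
    virtual_screen,
    y_equidistant_split,
)


class TestYEquidistantSplit:
    def test_n10_enumerated_positions(self):
        """N=10, 70:30 -> sorted positions {1,3,4,6,7,9,10} train, {2,5,8} test."""
        y = np.array([10.0, 1, 5, 3, 8, 2, 9, 4, 7, 6])
        train, test = y_equidistant_split(y, 0.7)
        order = np.argsort(y)
        train_pos = sorted(np.nonzero(np.isin(order, train))[0] + 1)
        test_pos = sorted(np.nonzero(np.isin(order, test))[0] + 1)
        assert train_pos == [1, 3, 4, 6, 7, 9, 10]
        assert test_pos == [2, 5, 8]

    @pytest.mark.parametrize("n", [4, 7, 10, 25, 100])
    def test_extremes_always_in_train(self, n, rng):
        y = rng.normal(size=n)
        train, _test = y_equidistant_split(y, 0.7)
        assert np.argmin(y) in train and np.argmax(y) in train

    def test_full_train_fraction_empty_test(self, rng):
        y = rng.normal(size=9)
        train, test = y_equidistant_split(y, 1.0)
        assert len(train) == 9 and len(test) == 0

    def test_duplicate_targets_are_stable(self):
        y = [1.0, 1.0, 1.0, 2.0, 2.0, 3.0]
        a = y_equidistant_split(y, 0.7)
        b = y_equidistant_split(y, 0.7)
        np.testing.assert_array_equal(a[0], b[0])
        assert set(a[0]) | set(a[1]) == set(range(6))
        assert not set(a[0]) & set(a[1])

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            y_equidistant_split([1.0, 2.0, 3.0], 0.7)


class TestFitMLR:
    def _synthetic(self, rng, n=100, sigma=0.1):
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = 2 * a - b + rng.normal(0, sigma, size=n)
        return pd.DataFrame({"a": a, "b": b, "ln_k": y})

    def test_recovers_coefficients_within_three_se(self, rng):
        df = self._synthetic(rng)
        res = fit_mlr(df, ["a", "b"])
        # standardized truth: 2*std(a), -1*std(b); se ~ sigma/sqrt(n)
        se = 3 * 0.1 / np.sqrt(len(df))
        assert res.coefficients[0] == pytest.approx(2 * df["a"].std(ddof=0), abs=3 * se)
        assert res.coefficients[1] == pytest.approx(-df["b"].std(ddof=0), abs=3 * se)

    def test_noise_free_fit_is_exact(self, rng):
        df = self._synthetic(rng, sigma=0.0)
        res = fit_mlr(df, ["a", "b"])
        assert res.train_r2 == pytest.approx(1.0, abs=1e-12)
        assert res.train_mae == pytest.approx(0.0, abs=1e-10)

    def test_permuted_targets_have_no_signal(self, rng):
        df = self._synthetic(rng, n=200)
        df["ln_k"] = rng.permutation(df["ln_k"].to_numpy())
        split = y_equidistant_split(df["ln_k"].to_numpy(), 0.7)
        res = fit_mlr(df, ["a", "b"], split=split)
        assert res.test_r2 <= 0.2

    def test_rank_deficiency_names_columns(self, rng):
        df = self._synthetic(rng)
        df["a2"] = 2 * df["a"]
        with pytest.raises(ValueError, match="a"):
            fit_mlr(df, ["a", "b", "a2"])

    def test_scale_invariance_of_standardized_fit(self, rng):
        df = self._synthetic(rng)
        split = y_equidistant_split(df["ln_k"].to_numpy(), 0.7)
        r1 = fit_mlr(df, ["a", "b"], split=split)
        df2 = df.copy()
        df2["a"] = df2["a"] * 1000.0
        r2 = fit_mlr(df2, ["a", "b"], split=split)
        assert r1.test_r2 == pytest.approx(r2.test_r2, abs=1e-8)

    def test_refit_is_reproducible(self, rng):
        df = self._synthetic(rng)
        c1 = fit_mlr(df, ["a", "b"]).coefficients
        c2 = fit_mlr(df, ["a", "b"]).coefficients
        np.testing.assert_allclose(c1, c2, atol=1e-8)

    def test_estimator_protocol(self, rng):
        df = self._synthetic(rng)
        m = RateModel(["a", "b"]).fit(df[["a", "b"]], df["ln_k"])
        assert m.get_params()["descriptor_names"] == ["a", "b"]
        assert m.score(df[["a", "b"]], df["ln_k"]) > 0.9


class TestVirtualScreen:
    def _model(self, rng):
        df = pd.DataFrame({
            "acid_x": rng.normal(size=20), "amine_y": rng.normal(size=20),
        })
        df["ln_k"] = df["acid_x"] - df["amine_y"]
        return fit_mlr(df.rename(columns={"acid_x": "acid_x", "amine_y": "amine_y"}),
                       ["acid_x", "amine_y"])

    def test_full_cross_product(self, rng):
        model = self._model(rng)
        acids = pd.DataFrame({"x": rng.normal(size=3)},
                             index=[f"ac{i}" for i in range(3)])
        amines = pd.DataFrame({"y": rng.normal(size=4)},
                              index=[f"am{i}" for i in range(4)])
        preds = virtual_screen(model, acids, amines)
        assert len(preds) == 12

    def test_missing_descriptor_skips_pairs(self, rng):
        model = self._model(rng)
        acids = pd.DataFrame({"x": rng.normal(size=3)},
                             index=[f"ac{i}" for i in range(3)])
        amines = pd.DataFrame({"y": [0.1, np.nan, 0.3, 0.4]},
                              index=[f"am{i}" for i in range(4)])
        preds = virtual_screen(model, acids, amines)
        assert len(preds) == 9

    def test_rowwise_equals_batched(self, rng):
        model = self._model(rng)
        acids = pd.DataFrame({"x": rng.normal(size=2)}, index=["a0", "a1"])
        amines = pd.DataFrame({"y": rng.normal(size=2)}, index=["b0", "b1"])
        batched = virtual_screen(model, acids, amines)
        for _, row in batched.iterrows():
            single = virtual_screen(model, acids.loc[[row.acid_id]],
                                    amines.loc[[row.amine_id]])
            assert single.ln_k_pred.iloc[0] == pytest.approx(row.ln_k_pred,
                                                             abs=1e-12)


class TestSourceAgreement:
    def test_identical_vectors(self, rng):
        v = rng.normal(size=30)
        m = source_agreement(v, v)
        assert m["r2"] == pytest.approx(1.0) and m["mae"] == pytest.approx(0.0)

    def test_constant_shift_gives_exact_mae(self, rng):
        v = rng.normal(size=30)
        m = source_agreement(v, v + 0.5)
        assert m["mae"] == pytest.approx(0.5, abs=1e-12)

    def test_range_filter_is_exclusive(self):
        a = np.array([-4.0, 0.0, 3.0, -3.5, 2.5, 1.0])
        b = a + 0.1
        m = source_agreement(a, b, range_filter=(-3.5, 2.5))
        # strict inequalities: the -3.5 and 2.5 boundary pairs are dropped
        assert m["n"] == 2

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError):
            source_agreement([1.0], [1.0])
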