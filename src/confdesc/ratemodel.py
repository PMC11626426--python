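"""Downstream linear rate modeling and virtual screening.

Rebuilds a multivariate linear regression of ln(k) for amide couplings on
condensed descriptors of the acid and amine partners, using a 70:30
y-equidistant train:test split (training molecules span the sorted response
range at even index spacing, extremes always in train).  The fitted equation
is applied to the full acid x amine cross product for virtual screening, and
agreement between two descriptor sources (e.g. quantum-chemistry-derived vs
surrogate-predicted) is quantified by R^2 and MAE over the paired
predictions, optionally restricted to an experimentally measurable ln(k)
window.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_absolute_error, r2_score

log = logging.getLogger(__name__)


def y_equidistant_split(targets, train_frac: float = 0.7) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic split whose train set spans the sorted response evenly.

    With the N targets sorted ascending (ties stabilized by original index)
    and n_train = ceil(train_frac * N), training picks sorted positions
    round(1 + (i - 1)(N - 1)/(n_train - 1)) for i = 1..n_train (round half
    up), advancing to the next unused position on collision; min and max are
    always in train.  Returns (train, test) as arrays of original indices.
    """
    y = np.asarray(targets, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if not 0 < train_frac <= 1:
        raise ValueError("train_frac must be in (0, 1]")
    order = np.lexsort((np.arange(n), y))  # ascending y, original index breaks ties
    n_train = math.ceil(train_frac * n)
    if n_train >= n:
        return order.copy(), np.array([], dtype=int)
    taken: list[int] = []
    used = set()
    for i in range(1, n_train + 1):
        if n_train == 1:
            pos = 1
        else:
            pos = math.floor(1 + (i - 1) * (n - 1) / (n_train - 1) + 0.5)  # half-up
        p = pos - 1  # to 0-based sorted position
        while p in used and p < n - 1:
            p += 1
        while p in used:  # fell off the top: walk down instead
            p -= 1
        used.add(p)
        taken.append(p)
    train = order[sorted(taken)]
    test = order[sorted(set(range(n)) - used)]
    return train, test


@dataclass
class FitResult:
    """Standardized-descriptor OLS fit of ln(k)."""

    descriptor_names: list[str]
    coefficients: np.ndarray  # on z-scored descriptors
    intercept: float
    feature_means: np.ndarray
    feature_stds: np.ndarray
    train_r2: float
    train_mae: float
    test_r2: float | None = None
    test_mae: float | None = None

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.descriptor_names].to_numpy(dtype=float)
        z = (x - self.feature_means) / self.feature_stds
        return z @ self.coefficients + self.intercept

    def to_json(self) -> str:
        return json.dumps(
            {
                "descriptors": self.descriptor_names,
                "standardized_coefficients": list(self.coefficients),
                "intercept": self.intercept,
                "feature_means": list(self.feature_means),
                "feature_stds": list(self.feature_stds),
                "train_r2": self.train_r2,
                "train_mae": self.train_mae,
                "test_r2": self.test_r2,
                "test_mae": self.test_mae,
            }
        )


class RateModel(BaseEstimator, RegressorMixin):
    """OLS regression of ln(k) on z-scored descriptor columns.

    A thin scikit-learn estimator: ``fit(X, y)`` standardizes the descriptor
    matrix on the training data, checks for collinear columns, and fits
    ordinary least squares.  ``result_`` holds the exportable
    :class:`FitResult`.
    """

    def __init__(self, descriptor_names: list[str] | None = None):
        self.descriptor_names = descriptor_names

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = self.descriptor_names or list(X.columns)
            x = X[names].to_numpy(dtype=float)
        else:
            x = np.asarray(X, dtype=float)
            names = self.descriptor_names or [f"x{i}" for i in range(x.shape[1])]
        y = np.asarray(y, dtype=float).ravel()
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("missing descriptor or target values in the fit set")

        self.feature_means_ = x.mean(axis=0)
        self.feature_stds_ = x.std(axis=0)
        if np.any(self.feature_stds_ == 0):
            bad = [names[i] for i in np.nonzero(self.feature_stds_ == 0)[0]]
            raise ValueError(f"constant descriptor column(s): {bad}")
        z = (x - self.feature_means_) / self.feature_stds_

        rank = np.linalg.matrix_rank(np.column_stack([z, np.ones(len(z))]))
        if rank < z.shape[1] + 1:
            # name the offending columns via pivoted QR
            _q, r, piv = scipy.linalg.qr(z, pivoting=True)
            diag = np.abs(np.diag(r))
            bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < 1e-10 * diag[0]]
            bad += [names[p] for p in piv[len(diag):]]
            raise ValueError(f"rank-deficient design; collinear column(s): {bad}")

        self._ols = LinearRegression().fit(z, y)
        pred = self._ols.predict(z)
        self.names_ = names
        self.coef_ = self._ols.coef_
        self.intercept_ = float(self._ols.intercept_)
        self.result_ = FitResult(
            descriptor_names=names,
            coefficients=self._ols.coef_.copy(),
            intercept=float(self._ols.intercept_),
            feature_means=self.feature_means_.copy(),
            feature_stds=self.feature_stds_.copy(),
            train_r2=float(r2_score(y, pred)),
            train_mae=float(mean_absolute_error(y, pred)),
        )
        return self

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            x = X[self.names_].to_numpy(dtype=float)
        else:
            x = np.asarray(X, dtype=float)
        z = (x - self.feature_means_) / self.feature_stds_
        return self._ols.predict(z)


def fit_mlr(
    dataset: pd.DataFrame,
    descriptor_names: list[str],
    target: str = "ln_k",
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> FitResult:
    """Fit ln(k) ~ descriptors by OLS on standardized columns.

    ``split`` is an optional (train_idx, test_idx) pair of positional indices
    (e.g. from :func:`y_equidistant_split`); without it the model is fit to
    the full dataset, as done when refitting the screening equation.
    """
    clean = dataset.dropna(subset=descriptor_names + [target])
    if len(clean) < len(dataset):
        log.warning("dropped %d rows with missing values", len(dataset) - len(clean))
    if split is None:
        train_df, test_df = clean, None
    else:
        train_df = clean.iloc[split[0]]
        test_df = clean.iloc[split[1]] if len(split[1]) else None

    model = RateModel(descriptor_names).fit(train_df[descriptor_names],
                                            train_df[target])
    result = model.result_
    if test_df is not None:
        pred = model.predict(test_df[descriptor_names])
        result.test_r2 = float(r2_score(test_df[target], pred))
        result.test_mae = float(mean_absolute_error(test_df[target], pred))
    return result


def virtual_screen(
    model: FitResult,
    acids: pd.DataFrame,
    amines: pd.DataFrame,
) -> pd.DataFrame:
    """Predict ln(k) for every acid x amine pair.

    Descriptor columns are looked up in whichever table provides them (acid
    tables may share column names with amine tables only if disambiguated by
    an 'acid_'/'amine_' prefix in the model's descriptor names).  Pairs with
    any missing required descriptor are skipped and logged.
    """
    rows = []
    skipped = 0
    for acid_id, acid_row in acids.iterrows():
        for amine_id, amine_row in amines.iterrows():
            feats = {}
            ok = True
            for name in model.descriptor_names:
                if name.startswith("acid_"):
                    v = acid_row.get(name[5:])
                elif name.startswith("amine_"):
                    v = amine_row.get(name[6:])
                else:
                    v = acid_row.get(name)
                    if v is None or (isinstance(v, float) and math.isnan(v)):
                        v = amine_row.get(name)
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    ok = False
                    break
                feats[name] = float(v)
            if not ok:
                skipped += 1
                log.info("skipped pair (%s, %s): missing descriptor", acid_id, amine_id)
                continue
            rows.append({"acid_id": acid_id, "amine_id": amine_id, **feats})
    if skipped:
        log.warning("virtual screen skipped %d pairs with missing descriptors", skipped)
    if not rows:
        return pd.DataFrame(columns=["acid_id", "amine_id", "ln_k_pred"])
    df = pd.DataFrame(rows)
    df["ln_k_pred"] = model.predict(df)
    return df[["acid_id", "amine_id", "ln_k_pred"]]


def source_agreement(
    pred_a: pd.Series | np.ndarray,
    pred_b: pd.Series | np.ndarray,
    range_filter: tuple[float, float] | None = None,
) -> dict[str, float]:
    """R^2 and MAE between two aligned prediction vectors.

    ``range_filter=(lo, hi)`` keeps only pairs whose reference prediction
    (``pred_a``) lies strictly inside the open interval, mirroring an
    experimentally measurable rate window.
    """
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("prediction vectors must be aligned")
    if range_filter is not None:
        lo, hi = range_filter
        keep = (a > lo) & (a < hi)
        a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("fewer than 2 aligned pairs after filtering")
    return {
        "r2": float(r2_score(a, b)),
        "mae": float(mean_absolute_error(a, b)),
        "n": int(len(a)),
    }


LN10 = math.log(10.0)


def lnk_to_reaction_time(ln_k: float, conversion: float = 0.97,
                         conc: float = 0.5) -> float:
    """Hours to reach ``conversion`` for an equal-concentration second-order
    reaction at initial concentration ``conc`` (mol/L).

    Provided as an optional convenience for interpreting screened ln(k)
    values; t = x / (k * c0 * (1 - x)) with x the fractional conversion.
    """
    k = math.exp(ln_k)
    x = conversion
    return x / (k * conc * (1.0 - x)) / 3600.0
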