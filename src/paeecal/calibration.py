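"""Population-specific PAEE prediction models from PAC and heart rate.

The calibration model is an ordinary-least-squares multiple linear
regression of criterion PAEE (kcal·min⁻¹, from indirect calorimetry) on
accelerometer counts (PAC, counts·min⁻¹) and heart rate (bpm):

    PAEE = β₀ + β_PAC·PAC + β_HR·HR + ε

fitted separately per population (unilateral amputee, bilateral amputee,
control). Because calibration cohorts in clinical populations are small,
out-of-sample performance is estimated by leave-one-participant-out
cross-validation: for each participant, the model is refitted on everyone
else and that participant's stages are predicted with the held-out model.
An optional participant-level bootstrap is provided for uncertainty on the
coefficients.

:class:`PaeeRegressor` follows the scikit-learn estimator contract and
composes with sklearn model selection; the module-level functions are thin
wrappers preserving a record-oriented interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.utils.validation import check_is_fitted

from . import reference


class SingularFitError(ValueError):
    """Design matrix is rank deficient; names the offending column."""


@dataclass(frozen=True)
class PredictionModel:
    """A fitted (or published) linear PAEE prediction equation.

    Coefficients are in kcal·min⁻¹ per unit of each predictor; diagnostics
    (Pearson r against criterion, R², standard error of the estimate, n) are
    ``None`` for published fixture equations whose fit internals are unknown.
    """

    group: str
    beta_pac: float
    beta_hr: float
    intercept: float
    r: float | None = None
    r_squared: float | None = None
    see: float | None = None
    n: int | None = None

    def predict(self, pac, hr, clamp_zero: bool = False):
        return predict_paee(self, pac, hr, clamp_zero=clamp_zero)


def _printed(group: str) -> PredictionModel:
    c = reference.PRINTED_COEFFICIENTS[group]
    a = reference.PUBLISHED_AGREEMENT[group]
    return PredictionModel(
        group=group,
        beta_pac=c["beta_pac"],
        beta_hr=c["beta_hr"],
        intercept=c["intercept"],
        r=a["r"],
        r_squared=a["r_squared"],
        see=a["see"],
    )


#: The three published population-specific equations, as immutable fixtures.
PRINTED_UNILATERAL = _printed("unilateral")
PRINTED_BILATERAL = _printed("bilateral")
PRINTED_CONTROL = _printed("control")
PRINTED_MODELS = {
    "unilateral": PRINTED_UNILATERAL,
    "bilateral": PRINTED_BILATERAL,
    "control": PRINTED_CONTROL,
}


class PaeeRegressor(RegressorMixin, BaseEstimator):
    """OLS PAEE calibration model on [PAC, HR] features.

    Parameters
    ----------
    use_pac : bool, default True
        If False, fit the HR-only comparator: the PAC column is ignored and
        the model reduces to PAEE = β₀ + β_HR·HR.
    clamp_zero : bool, default False
        If True, negative predictions are clamped to zero. Off by default:
        the criterion itself can dip below resting level and clamping biases
        agreement statistics.

    Attributes
    ----------
    coef_ : ndarray of shape (2,)
        (β_PAC, β_HR); β_PAC is 0.0 when ``use_pac=False``.
    intercept_ : float
    r_, r_squared_ : float
        Pearson correlation between fitted and observed criterion, and R².
    see_ : float
        Standard error of the estimate, sqrt(RSS / (n − p)) with p counting
        the intercept.
    n_ : int
        Number of observations fitted.

    Examples
    --------
    >>> X = [[0, 60], [2000, 90], [4000, 110], [6000, 130]]
    >>> y = [0.0, 2.0, 4.1, 6.0]
    >>> PaeeRegressor().fit(X, y).predict([[3000, 100]])  # doctest: +SKIP
    """

    _FEATURES = ("pac", "hr")

    def __init__(self, use_pac: bool = True, clamp_zero: bool = False):
        self.use_pac = use_pac
        self.clamp_zero = clamp_zero

    def _design(self, X: np.ndarray) -> np.ndarray:
        cols = [np.ones(len(X))]
        if self.use_pac:
            cols.append(X[:, 0])
        cols.append(X[:, 1])
        return np.column_stack(cols)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): columns [pac, hr]")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("X and y must not contain NaN")
        p = 3 if self.use_pac else 2
        if len(X) < p + 1:
            raise ValueError(f"need at least {p + 1} observations, got {len(X)}")
        A = self._design(X)
        # Rank check on centred columns so a constant predictor is named, not
        # silently absorbed by lstsq's minimum-norm solution.
        used = ["pac", "hr"] if self.use_pac else ["hr"]
        for j, name in enumerate(used, start=1):
            if np.ptp(A[:, j]) == 0:
                raise SingularFitError(f"predictor '{name}' is constant")
        if np.linalg.matrix_rank(A) < p:
            raise SingularFitError("design matrix is rank deficient (collinear predictors)")
        beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        self.intercept_ = float(beta[0])
        if self.use_pac:
            self.coef_ = np.array([beta[1], beta[2]])
        else:
            self.coef_ = np.array([0.0, beta[1]])
        fitted = A @ beta
        resid = y - fitted
        self.n_ = len(y)
        self.n_params_ = p
        self.see_ = float(np.sqrt(resid @ resid / (self.n_ - p)))
        # classical OLS standard errors, aligned to [intercept(, pac), hr]
        cov = self.see_**2 * np.linalg.inv(A.T @ A)
        self.bse_ = np.sqrt(np.diag(cov))
        if np.ptp(fitted) == 0 or np.ptp(y) == 0:
            self.r_ = float("nan")
        else:
            self.r_ = float(stats.pearsonr(y, fitted)[0])
        self.r_squared_ = self.r_**2
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): columns [pac, hr]")
        out = self.intercept_ + X @ self.coef_
        if self.clamp_zero:
            out = np.maximum(out, 0.0)
        return out

    @property
    def beta_pac_(self) -> float:
        check_is_fitted(self, "coef_")
        return float(self.coef_[0])

    @property
    def beta_hr_(self) -> float:
        check_is_fitted(self, "coef_")
        return float(self.coef_[1])

    def to_prediction_model(self, group: str = "") -> PredictionModel:
        check_is_fitted(self, "coef_")
        return PredictionModel(
            group=group,
            beta_pac=self.beta_pac_,
            beta_hr=self.beta_hr_,
            intercept=self.intercept_,
            r=self.r_,
            r_squared=self.r_squared_,
            see=self.see_,
            n=self.n_,
        )


REQUIRED_COLUMNS = ("pac", "hr", "criterion_paee")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise KeyError(f"records missing required columns: {missing}")
    return records


def fit_paee_model(records: pd.DataFrame, use_pac: bool = True) -> PredictionModel:
    """Fit the PAC+HR (or HR-only) OLS equation on summary records.

    ``records`` needs columns ``pac, hr, criterion_paee`` and optionally
    ``group`` (used to label the returned model).
    """
    records = _check_records(records)
    est = PaeeRegressor(use_pac=use_pac).fit(
        records[["pac", "hr"]].to_numpy(float), records["criterion_paee"].to_numpy(float)
    )
    group = ""
    if "group" in records.columns:
        labels = records["group"].unique()
        group = labels[0] if len(labels) == 1 else "+".join(sorted(map(str, labels)))
    return est.to_prediction_model(group=group)


def predict_paee(model: PredictionModel, pac, hr, clamp_zero: bool = False):
    """Evaluate a prediction equation at (PAC, HR); vectorised."""
    pac = np.asarray(pac, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any(pac < 0):
        raise ValueError("pac must be non-negative")
    if np.any(hr <= 0):
        raise ValueError("hr must be positive")
    out = model.intercept + model.beta_pac * pac + model.beta_hr * hr
    if clamp_zero:
        out = np.maximum(out, 0.0)
    return float(out) if np.ndim(out) == 0 else out


def loocv_predict(
    records: pd.DataFrame,
    participant_col: str = "participant",
    use_pac: bool = True,
    clamp_zero: bool = False,
) -> pd.DataFrame:
    """Leave-one-participant-out out-of-sample predictions.

    For each participant the model is refitted on all other participants'
    records and the held-out participant's stages are predicted. Returns a
    copy of ``records`` with ``predicted_paee`` and integer ``fold`` columns;
    a fold whose training fit is singular is skipped with a warning and its
    predictions set to NaN. Entirely deterministic.
    """
    records = _check_records(records)
    if participant_col not in records.columns:
        raise KeyError(f"records missing participant column '{participant_col}'")
    participants = records[participant_col].to_numpy()
    if len(np.unique(participants)) < 3:
        raise ValueError("leave-one-participant-out needs >= 3 distinct participants")
    X = records[["pac", "hr"]].to_numpy(float)
    y = records["criterion_paee"].to_numpy(float)
    pred = np.full(len(records), np.nan)
    fold_id = np.full(len(records), -1, dtype=int)
    splitter = LeaveOneGroupOut()
    for k, (train, test) in enumerate(splitter.split(X, y, groups=participants)):
        fold_id[test] = k
        est = PaeeRegressor(use_pac=use_pac, clamp_zero=clamp_zero)
        try:
            est.fit(X[train], y[train])
        except (SingularFitError, ValueError) as exc:
            warnings.warn(
                f"fold {k} (held out {records[participant_col].iloc[test[0]]!r}) "
                f"skipped: {exc}",
                stacklevel=2,
            )
            continue
        pred[test] = est.predict(X[test])
    out = records.copy()
    out["predicted_paee"] = pred
    out["fold"] = fold_id
    return out


def bootstrap_models(
    records: pd.DataFrame,
    n_boot: int = 200,
    seed: int = 0,
    participant_col: str = "participant",
    use_pac: bool = True,
) -> pd.DataFrame:
    """Participant-level bootstrap of the calibration equation.

    Resamples participants with replacement ``n_boot`` times and refits;
    returns one row of coefficients per successful replicate. Provided as an
    optional uncertainty summary alongside (not instead of) the
    leave-one-participant-out analysis.
    """
    records = _check_records(records)
    rng = np.random.default_rng(seed)
    ids = np.unique(records[participant_col].to_numpy())
    rows = []
    for b in range(n_boot):
        take = rng.choice(ids, size=len(ids), replace=True)
        boot = pd.concat(
            [records[records[participant_col] == i] for i in take], ignore_index=True
        )
        try:
            m = fit_paee_model(boot, use_pac=use_pac)
        except (SingularFitError, ValueError):
            continue
        rows.append(
            {"replicate": b, "beta_pac": m.beta_pac, "beta_hr": m.beta_hr,
             "intercept": m.intercept, "see": m.see}
        )
    return pd.DataFrame(rows)


def with_group(model: PredictionModel, group: str) -> PredictionModel:
    """Return a copy of ``model`` relabelled to ``group``."""
    return replace(model, group=group)
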