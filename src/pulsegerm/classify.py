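"""The germinated / non-germinated logistic classifier.

A spore counts as germinated once its germ tube reaches half the body's
largest dimension.  On pulse-shape data this morphological transition is
captured by a logistic regression on five per-particle features::

    ln  p(non-germinated) / p(germinated)
        = a0 + a1·FWS length + a2·CVRMSE + a3·FLY max
             + a4·FLY inertia + a5·FLY fill factor

Positive log-odds mean "non-germinated".  Published coefficient sets for
two FLY sensitivity (gain) levels ship as defaults
(:func:`default_model`); :class:`GerminationLogit` refits the model by
maximum likelihood on labelled feature tables, with Wald tests and
optional backward elimination of non-significant predictors.

Sign conventions of the default coefficients: longer signals (germ
tube), worse Gaussian fits (second lobe) and brighter FLY (rising
esterase activity) all push toward "germinated" (a1, a2, a3 < 0), while
edge-heavy (a4 > 0) and rectangle-like (a5 < 0 on fill factor) FLY
profiles move the log-odds per their fitted weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .pulse_model import known_sensitivity_levels

__all__ = [
    "PREDICTORS",
    "GerminationLogit",
    "GerminationLogitResults",
    "LogisticModel",
    "SaturationWarning",
    "SeparationError",
    "classify",
    "classify_table",
    "default_model",
    "linear_score",
]

#: Predictor columns, in coefficient order a1..a5.
PREDICTORS = (
    "fws_length",
    "fws_cvrmse",
    "fly_max",
    "fly_inertia",
    "fly_fill_factor",
)

COEFFICIENT_NAMES = ("a0", "a1", "a2", "a3", "a4", "a5")

# Published coefficient sets per FLY sensitivity level (a0..a5).
_DEFAULT_COEFFICIENTS: dict[int, tuple[float, ...]] = {
    50: (28.31, -0.337, -0.184, -0.006, 54.05, -59.54),
    65: (29.01, -0.346, -0.106, -0.001, 40.35, -52.44),
}


class SaturationWarning(UserWarning):
    """A scored particle has a clipped FLY signal; its FLY max is a lower
    bound and the score may be biased toward 'germinated'."""


class SeparationError(RuntimeError):
    """The likelihood is unbounded (perfectly separable classes).

    Refit with ``ridge=1e-6`` (or larger) to obtain a finite penalised
    estimate."""

    def __init__(self, message: str, n_iterations: Optional[int] = None):
        self.n_iterations = n_iterations
        super().__init__(message)


@dataclass(frozen=True)
class LogisticModel:
    """Coefficients a0..a5 bound to a FLY sensitivity level."""

    a0: float
    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    sensitivity_level: int = 50
    provenance: str = "fitted"

    def __post_init__(self):
        coeffs = self.coefficients
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("all coefficients must be finite")
        if self.sensitivity_level not in known_sensitivity_levels():
            raise ValueError(
                f"unregistered sensitivity level {self.sensitivity_level}"
            )

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2, self.a3, self.a4, self.a5])

    def to_json(self) -> str:
        return json.dumps(
            {
                "sensitivity_level": self.sensitivity_level,
                "coefficients": dict(zip(COEFFICIENT_NAMES, self.coefficients)),
                "provenance": self.provenance,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LogisticModel":
        d = json.loads(text)
        coeffs = d["coefficients"]
        return cls(
            *(float(coeffs[name]) for name in COEFFICIENT_NAMES),
            sensitivity_level=int(d["sensitivity_level"]),
            provenance=d.get("provenance", "fitted"),
        )


def default_model(sensitivity_level: int) -> LogisticModel:
    """The published coefficient set for a FLY sensitivity level."""
    try:
        coeffs = _DEFAULT_COEFFICIENTS[int(sensitivity_level)]
    except (KeyError, TypeError, ValueError):
        raise KeyError(
            f"no default model for sensitivity level {sensitivity_level!r}; "
            f"known levels: {sorted(_DEFAULT_COEFFICIENTS)}"
        ) from None
    return LogisticModel(*coeffs, sensitivity_level=int(sensitivity_level),
                         provenance="published")


def _predictor_value(features, name: str) -> float:
    if isinstance(features, Mapping):
        if name not in features:
            raise KeyError(f"missing predictor {name!r}")
        value = features[name]
    elif isinstance(features, pd.Series):
        if name not in features.index:
            raise KeyError(f"missing predictor {name!r}")
        value = features[name]
    else:
        try:
            value = getattr(features, name)
        except AttributeError:
            raise KeyError(f"missing predictor {name!r}") from None
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"predictor {name!r} is not finite: {value}")
    return value


def linear_score(features, model: LogisticModel) -> float:
    """Log-odds of 'non-germinated' for one particle.

    Warns (:class:`SaturationWarning`) when the particle's FLY signal is
    saturated — the score is still computed from the clipped value; the
    method's remedy for saturation is a lower sensitivity level, not
    imputation.
    """
    values = np.array([_predictor_value(features, p) for p in PREDICTORS])
    saturated = False
    try:
        saturated = bool(_predictor_value(features, "fly_saturated"))
    except (KeyError, ValueError):
        pass
    if saturated:
        warnings.warn(
            "FLY signal is saturated; score uses the clipped FLY max",
            SaturationWarning,
            stacklevel=2,
        )
    return float(model.a0 + model.coefficients[1:] @ values)


def classify(features, model: LogisticModel) -> tuple[str, float]:
    """Assign 'non_germinated' or 'germinated' with the class probability.

    Score > 0 → non-germinated; score ≤ 0 → germinated (ties break toward
    detecting germination onset).  Returns ``(label, p(label))``;
    p(non-germinated) + p(germinated) = 1.
    """
    score = linear_score(features, model)
    p_non = float(expit(score))
    if score > 0:
        return "non_germinated", p_non
    return "germinated", 1.0 - p_non


def classify_table(
    table: pd.DataFrame, model: LogisticModel
) -> pd.DataFrame:
    """Vectorised classification of a feature table.

    Returns a copy with ``score``, ``p_non_germinated`` and
    ``predicted_class`` columns appended.
    """
    missing = [p for p in PREDICTORS if p not in table.columns]
    if missing:
        raise KeyError(f"missing predictors {missing}")
    X = table[list(PREDICTORS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite predictor values in table")
    if "fly_saturated" in table.columns and bool(table["fly_saturated"].any()):
        warnings.warn(
            f"{int(table['fly_saturated'].sum())} particles have saturated "
            "FLY signals; scores use the clipped FLY max",
            SaturationWarning,
            stacklevel=2,
        )
    scores = model.a0 + X @ model.coefficients[1:]
    out = table.copy()
    out["score"] = scores
    out["p_non_germinated"] = expit(scores)
    out["predicted_class"] = np.where(scores > 0, "non_germinated", "germinated")
    return out


# ---------------------------------------------------------------------------
# Maximum-likelihood refitting (Model / Results)
# ---------------------------------------------------------------------------


class GerminationLogit:
    """Binary logistic model of germination state on pulse-shape features.

    Parameters
    ----------
    endog
        Binary outcome per particle: 1 for non-germinated, 0 for
        germinated (matching the sign convention of the log-odds).
        String labels are accepted and mapped accordingly.
    exog
        Feature table containing the predictor columns (a subset of
        :data:`PREDICTORS` may be selected via ``predictors``).
    predictors
        Predictor columns to use, default all five.
    sensitivity_level
        FLY sensitivity level the data were acquired at; carried into the
        fitted :class:`LogisticModel`.

    Examples
    --------
    >>> model = GerminationLogit.from_feature_table(table, "truth_label")
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        endog,
        exog: pd.DataFrame,
        predictors: Sequence[str] = PREDICTORS,
        sensitivity_level: int = 50,
    ):
        self.predictors = tuple(predictors)
        missing = [p for p in self.predictors if p not in exog.columns]
        if missing:
            raise KeyError(f"missing predictor columns {missing}")
        y = np.asarray(
            [self._encode(v) for v in np.asarray(endog).ravel()], dtype=float
        )
        X = exog[list(self.predictors)].to_numpy(dtype=float)
        if len(y) != len(X):
            raise ValueError("endog and exog lengths differ")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite predictor values")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("both classes must be present to fit")
        if counts.min() < 30:
            raise ValueError(
                f"need >= 30 observations per class, got {counts.min()}"
            )
        self.endog = y
        self.exog = np.column_stack([np.ones(len(X)), X])
        self.sensitivity_level = sensitivity_level

    @staticmethod
    def _encode(value) -> float:
        if isinstance(value, str):
            mapping = {
                "non_germinated": 1.0,
                "germinated": 0.0,
                # Intermediates belong to the germinated class for training.
                "germinating": 0.0,
            }
            try:
                return mapping[value]
            except KeyError:
                raise ValueError(
                    f"cannot encode label {value!r} as a training class"
                ) from None
        v = float(value)
        if v not in (0.0, 1.0):
            raise ValueError(f"labels must be binary, got {value!r}")
        return v

    @classmethod
    def from_feature_table(
        cls,
        table: pd.DataFrame,
        label_column: str = "truth_label",
        predictors: Sequence[str] = PREDICTORS,
        sensitivity_level: int = 50,
    ) -> "GerminationLogit":
        """Build the model from one table holding features and labels."""
        if label_column not in table.columns:
            raise KeyError(f"no label column {label_column!r}")
        return cls(
            table[label_column],
            table,
            predictors=predictors,
            sensitivity_level=sensitivity_level,
        )

    # -- likelihood machinery ------------------------------------------------

    def loglike(self, params: np.ndarray) -> float:
        eta = self.exog @ params
        # log-likelihood via the numerically stable log1p(exp) form
        return float(np.sum(self.endog * eta - np.logaddexp(0.0, eta)))

    def fit(
        self,
        ridge: float = 0.0,
        tol: float = 1e-8,
        max_iterations: int = 100,
        backward: bool = False,
        alpha: float = 0.05,
    ) -> "GerminationLogitResults":
        """Maximum-likelihood fit by iteratively reweighted least squares.

        Convergence is declared when the log-likelihood changes by less
        than ``tol`` (relative) between Newton steps.  ``ridge`` adds an
        L2 penalty (intercept excluded) as the documented fallback for
        perfectly separable data.  With ``backward=True``, predictors are
        eliminated one at a time (largest Wald p first) until all retained
        predictors have p < ``alpha``.
        """
        results = self._fit_once(self.exog, ridge, tol, max_iterations)
        dropped: list[tuple[str, float]] = []
        kept = list(self.predictors)
        if backward:
            exog = self.exog
            while True:
                pvals = results["pvalues"][1:]
                worst = int(np.argmax(pvals))
                if pvals[worst] < alpha:
                    break
                dropped.append((kept[worst], float(pvals[worst])))
                del kept[worst]
                if not kept:
                    break
                cols = [0] + [1 + self.predictors.index(p) for p in kept]
                exog = self.exog[:, cols]
                results = self._fit_once(exog, ridge, tol, max_iterations)
        return GerminationLogitResults(
            model=self,
            predictors=tuple(kept),
            dropped=tuple(dropped),
            ridge=ridge,
            **results,
        )

    def _fit_once(self, exog, ridge, tol, max_iterations) -> dict:
        n, p = exog.shape
        beta = np.zeros(p)
        penalty = np.full(p, ridge)
        penalty[0] = 0.0  # never penalise the intercept
        y = self.endog
        ll_old = -np.inf
        converged = False
        hessian = None
        for iteration in range(1, max_iterations + 1):
            eta = exog @ beta
            mu = expit(eta)
            ll = float(np.sum(y * eta - np.logaddexp(0.0, eta))
                       - 0.5 * np.sum(penalty * beta**2))
            grad = exog.T @ (y - mu) - penalty * beta
            w = mu * (1.0 - mu)
            hessian = exog.T @ (exog * w[:, None]) + np.diag(penalty)
            try:
                step = np.linalg.solve(hessian, grad)
            except np.linalg.LinAlgError:
                raise SeparationError(
                    "singular information matrix (complete separation "
                    "suspected); retry with ridge=1e-6",
                    n_iterations=iteration,
                ) from None
            beta = beta + step
            if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 1e8:
                raise SeparationError(
                    "diverging coefficients (complete separation "
                    "suspected); retry with ridge=1e-6",
                    n_iterations=iteration,
                )
            if ridge == 0.0:
                eta_new = exog @ beta
                separated = np.all((eta_new > 0) == (y == 1.0)) and np.min(
                    np.abs(eta_new)
                ) > 10.0
                if separated:
                    raise SeparationError(
                        "complete separation detected: all fitted "
                        "probabilities within 5e-5 of 0 or 1; retry with "
                        "ridge=1e-6",
                        n_iterations=iteration,
                    )
            if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
                converged = True
                n_iter = iteration
                break
            ll_old = ll
        else:
            n_iter = max_iterations
        eta = exog @ beta
        llf = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        cov = np.linalg.inv(hessian)
        bse = np.sqrt(np.diag(cov))
        z = beta / bse
        pvalues = 2.0 * norm.sf(np.abs(z))
        return {
            "params": beta,
            "bse": bse,
            "zvalues": z,
            "pvalues": pvalues,
            "cov_params": cov,
            "llf": llf,
            "n_iterations": n_iter,
            "converged": converged,
            "nobs": n,
        }


@dataclass
class GerminationLogitResults:
    """Fit results: estimates, uncertainties, Wald tests, diagnostics."""

    model: GerminationLogit
    predictors: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    cov_params: np.ndarray
    llf: float
    n_iterations: int
    converged: bool
    nobs: int
    ridge: float = 0.0
    dropped: tuple[tuple[str, float], ...] = ()

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("intercept",) + self.predictors

    @property
    def nonsignificant(self) -> tuple[str, ...]:
        """Retained predictors whose Wald p >= 0.05."""
        return tuple(
            name
            for name, p in zip(self.predictors, self.pvalues[1:])
            if p >= 0.05
        )

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.param_names)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """p(non-germinated) per row of a feature table."""
        X = table[list(self.predictors)].to_numpy(dtype=float)
        return expit(self.params[0] + X @ self.params[1:])

    def to_model(self) -> LogisticModel:
        """Export as a portable coefficient set (dropped predictors get a
        zero coefficient)."""
        coeffs = dict.fromkeys(PREDICTORS, 0.0)
        for name, value in zip(self.predictors, self.params[1:]):
            coeffs[name] = float(value)
        return LogisticModel(
            float(self.params[0]),
            *(coeffs[p] for p in PREDICTORS),
            sensitivity_level=self.model.sensitivity_level,
            provenance="fitted",
        )

    def summary(self) -> str:
        lines = [
            "Germination logistic regression "
            f"(n={self.nobs}, sensitivity level {self.model.sensitivity_level})",
            f"log-likelihood {self.llf:.3f}  "
            f"({'converged' if self.converged else 'NOT converged'} "
            f"in {self.n_iterations} iterations"
            + (f", ridge={self.ridge:g}" if self.ridge else "")
            + ")",
            "",
            f"{'term':<16}{'coef':>12}{'std err':>10}{'z':>9}{'P>|z|':>9}",
        ]
        for name, b, se, z, p in zip(
            self.param_names, self.params, self.bse, self.zvalues, self.pvalues
        ):
            lines.append(f"{name:<16}{b:>12.4f}{se:>10.4f}{z:>9.2f}{p:>9.3g}")
        if self.nonsignificant:
            lines.append("")
            lines.append(
                "not significant at p<0.05: " + ", ".join(self.nonsignificant)
            )
        for name, p in self.dropped:
            lines.append(f"eliminated {name} (p={p:.3g})")
        return "\n".join(lines)
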