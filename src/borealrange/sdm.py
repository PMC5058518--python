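"""Logistic species distribution model: prediction, classification, fitting.

The core model is a binomial GLM with logit link relating presence to five
covariates — proportion deciduous forest, proportion wetland, total land-use
footprint, long-term mean winter severity index (WSI) and long-term mean
growing-season length:

    logit p = β0 + β1·deciduous + β2·wetland + β3·footprint + β4·WSI + β5·GS

The published coefficients (−10.12, 4.98, −3.11, 9.79, −0.07, 0.11) are the
package defaults; hindcasting and forecasting apply them as fixed
configuration.  Refitting (for parameter recovery on synthetic data) goes
through :class:`SpeciesDistributionModel`, a thin statsmodels-backed
model/results pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.special import expit
import statsmodels.api as sm

from .landscape import LANDSCAPE_COLUMNS, DecadalLandscape

__all__ = [
    "SDMCoefficients",
    "PredictionGrid",
    "predict_probability",
    "classify",
    "prevalence",
    "SpeciesDistributionModel",
    "SDMResults",
    "COVARIATE_COLUMNS",
]

COVARIATE_COLUMNS = LANDSCAPE_COLUMNS  # deciduous, wetland, footprint, wsi, gs


@dataclass(frozen=True)
class SDMCoefficients:
    """Logit-scale coefficients of the species distribution model."""

    intercept: float = -10.12
    b_deciduous: float = 4.98
    b_wetland: float = -3.11
    b_footprint: float = 9.79
    b_wsi: float = -0.07
    b_gs: float = 0.11

    def __post_init__(self) -> None:
        if not all(np.isfinite(getattr(self, f.name)) for f in fields(self)):
            raise ValueError("coefficients must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.intercept,
                self.b_deciduous,
                self.b_wetland,
                self.b_footprint,
                self.b_wsi,
                self.b_gs,
            ]
        )

    @classmethod
    def from_array(cls, values) -> "SDMCoefficients":
        v = np.asarray(values, dtype=float)
        if v.shape != (6,):
            raise ValueError("expected 6 coefficients (intercept + 5 slopes)")
        return cls(*v)


def linear_predictor(landscape: DecadalLandscape, coef: SDMCoefficients | None = None) -> pd.Series:
    """Logit-scale linear predictor per cell."""
    coef = coef or SDMCoefficients()
    x = landscape.frame[COVARIATE_COLUMNS].to_numpy()
    bad = ~np.isfinite(x).all(axis=1)
    if bad.any():
        cell = landscape.frame.index[bad][0]
        raise ValueError(f"non-finite covariate in cell {cell}")
    beta = coef.as_array()
    lp = beta[0] + x @ beta[1:]
    return pd.Series(lp, index=landscape.frame.index, name="logit_p")


@dataclass
class PredictionGrid:
    """Per-cell probability of presence for one decade."""

    decade: int
    frame: pd.DataFrame  # index cell_id, column 'probability'

    def __post_init__(self) -> None:
        f = pd.DataFrame(self.frame)
        if "probability" not in f.columns:
            raise ValueError("prediction grid needs a 'probability' column")
        p = f["probability"]
        if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
            raise ValueError("probabilities must lie in [0, 1]")
        self.frame = f

    @property
    def probability(self) -> pd.Series:
        return self.frame["probability"]

    def classify(self, threshold: float) -> pd.Series:
        return classify(self, threshold)


def predict_probability(
    landscape: DecadalLandscape, coef: SDMCoefficients | None = None
) -> PredictionGrid:
    """Apply the logistic model to a decadal landscape (inverse-logit scale)."""
    lp = linear_predictor(landscape, coef)
    frame = pd.DataFrame({"probability": expit(lp.to_numpy())}, index=lp.index)
    return PredictionGrid(landscape.decade, frame)


def classify(grid: PredictionGrid, threshold: float) -> pd.Series:
    """Presence layer: probability ≥ threshold (inclusive)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    out = grid.probability >= threshold
    out.name = "presence"
    return out


def prevalence(observations) -> float:
    """Fraction of presences among observations (full precision).

    ``observations`` is a boolean/0-1 sequence or a DataFrame with a
    ``presence`` column.
    """
    if isinstance(observations, pd.DataFrame):
        obs = observations["presence"]
    else:
        obs = pd.Series(observations)
    if len(obs) == 0:
        raise ValueError("prevalence of an empty observation set is undefined")
    vals = obs.astype(float)
    if not vals.isin([0.0, 1.0]).all():
        raise ValueError("observations must be binary presence/absence")
    return float(vals.mean())


class SpeciesDistributionModel:
    """Binomial-logit presence/absence model over the five SDM covariates.

    A statsmodels-style model object: construct from arrays or a DataFrame,
    call :meth:`fit` for maximum-likelihood estimates.  Used for parameter
    recovery and calibration on synthetic data; the hindcast itself applies
    fixed published coefficients via :func:`predict_probability`.
    """

    def __init__(self, presence, covariates, covariate_names=None):
        y = np.asarray(presence, dtype=float)
        X = np.asarray(covariates, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("covariates must be (n_obs, n_covariates)")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("presence must be binary")
        if y.min() == y.max():
            raise ValueError("need both presences and absences to fit")
        self.covariate_names = list(
            covariate_names
            if covariate_names is not None
            else [f"x{i}" for i in range(X.shape[1])]
        )
        self.endog = y
        self.exog = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise ValueError("rank-deficient design (collinear covariates)")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str = "presence", covariates=None):
        covariates = list(covariates) if covariates is not None else COVARIATE_COLUMNS
        return cls(data[response], data[covariates], covariate_names=covariates)

    def fit(self, maxiter: int = 200, tol: float = 1e-10) -> "SDMResults":
        model = sm.GLM(self.endog, self.exog, family=sm.families.Binomial())
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = model.fit(maxiter=maxiter, tol=tol)
        separation = any("separat" in str(w.message).lower() for w in caught) or (
            np.abs(res.params).max() > 1e3
        )
        grad = np.linalg.norm(model.score(res.params))
        return SDMResults(self, res, separation_flag=bool(separation), gradient_norm=float(grad))


class SDMResults:
    """Fit results: estimates, standard errors, diagnostics, summary."""

    def __init__(self, model, statsmodels_results, separation_flag=False, gradient_norm=np.nan):
        self.model = model
        self._res = statsmodels_results
        self.separation_flag = separation_flag
        self.gradient_norm = gradient_norm

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self._res.params)

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self._res.bse)

    @property
    def converged(self) -> bool:
        return bool(self._res.converged) and self.gradient_norm < 1e-6

    @property
    def coefficients(self) -> SDMCoefficients:
        if len(self.params) != 6:
            raise ValueError("not a five-covariate SDM fit")
        return SDMCoefficients.from_array(self.params)

    def predict(self, covariates) -> np.ndarray:
        X = sm.add_constant(np.asarray(covariates, dtype=float), has_constant="add")
        return expit(X @ self.params)

    def summary(self):
        names = ["intercept"] + self.model.covariate_names
        return self._res.summary(xname=names)

    def __repr__(self) -> str:
        terms = ", ".join(
            f"{n}={v:.3g}" for n, v in zip(["intercept"] + self.model.covariate_names, self.params)
        )
        return f"<SDMResults {terms}, separation={self.separation_flag}>"
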