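"""Validation of presence/absence predictions and synthetic-data refits.

Covers the accuracy statistics used to score hindcasts against independent
surveys: confusion counts at the prevalence threshold, sensitivity and
specificity with bootstrap standard deviations, the true skill statistic
(TSS = sensitivity + specificity − 1), rank-based AUC, and a calibration
regression (binomial GLM of observed outcomes on predicted probability).
Also provides full SDM refitting for parameter-recovery experiments and the
township-level aggregation used to build survey validation sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.metrics import roc_auc_score

from .sdm import SDMResults, SpeciesDistributionModel

__all__ = [
    "ValidationSet",
    "ConfusionCounts",
    "ValidationStats",
    "confusion",
    "sensitivity_specificity",
    "tss",
    "auc",
    "CalibrationResult",
    "calibration_fit",
    "resample_rate_sd",
    "fit_sdm",
    "validate",
    "aggregate_townships",
]


@dataclass
class ValidationSet:
    """Observed presence/absence paired with predicted probability per cell."""

    frame: pd.DataFrame  # columns: cell_id, observed (0/1), probability

    def __post_init__(self) -> None:
        f = pd.DataFrame(self.frame).copy()
        missing = {"observed", "probability"} - set(f.columns)
        if missing:
            raise ValueError(f"validation set missing columns: {sorted(missing)}")
        if len(f) == 0:
            raise ValueError("validation set is empty")
        f["observed"] = f["observed"].astype(float)
        if not f["observed"].isin([0.0, 1.0]).all():
            raise ValueError("observed must be binary")
        p = f["probability"]
        if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
            raise ValueError("probabilities must lie in [0, 1]")
        self.frame = f

    @property
    def observed(self) -> np.ndarray:
        return self.frame["observed"].to_numpy()

    @property
    def probability(self) -> np.ndarray:
        return self.frame["probability"].to_numpy()

    @property
    def both_classes(self) -> bool:
        return 0.0 < self.observed.mean() < 1.0


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int


def confusion(vs: ValidationSet, threshold: float) -> ConfusionCounts:
    """Confusion counts with the inclusive (≥ threshold) presence rule."""
    pred = vs.probability >= threshold
    obs = vs.observed.astype(bool)
    return ConfusionCounts(
        tp=int((pred & obs).sum()),
        fp=int((pred & ~obs).sum()),
        tn=int((~pred & ~obs).sum()),
        fn=int((~pred & obs).sum()),
    )


def sensitivity_specificity(counts: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity, specificity); NaN where a class is absent."""
    pos, neg = counts.tp + counts.fn, counts.tn + counts.fp
    sens = counts.tp / pos if pos else float("nan")
    spec = counts.tn / neg if neg else float("nan")
    return sens, spec


def tss(sensitivity: float, specificity: float) -> float:
    """True skill statistic: sensitivity + specificity − 1, in [−1, 1]."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return sensitivity + specificity - 1.0


def auc(vs: ValidationSet) -> float:
    """Rank-based AUC: probability a random presence outranks a random absence.

    Ties count one half; equivalent to the Mann–Whitney pair-counting
    formulation.
    """
    if not vs.both_classes:
        raise ValueError("AUC needs at least one presence and one absence")
    return float(roc_auc_score(vs.observed, vs.probability))


@dataclass
class CalibrationResult:
    """Logistic calibration of observed outcome on predicted probability.

    A perfectly calibrated model pushed through this regression reproduces
    the identity curve; slope/intercept drift flags over- or
    under-confidence.  ``degenerate`` marks a constant regressor,
    ``separation`` a perfectly separating one (coefficients unbounded).
    """

    slope: float
    intercept: float
    regressor: str = "probability"
    degenerate: bool = False
    separation: bool = False
    converged: bool = True

    def curve(self, p) -> np.ndarray:
        """Fitted probability of presence at predicted probability ``p``."""
        x = logit(np.asarray(p, dtype=float)) if self.regressor == "logit" else np.asarray(p, dtype=float)
        return expit(self.intercept + self.slope * x)


def calibration_fit(vs: ValidationSet, regressor: str = "probability") -> CalibrationResult:
    """Binomial-logit GLM of observed presence on predicted probability.

    The regressor defaults to the raw probability; ``regressor='logit'``
    fits on the logit scale instead.
    """
    if regressor not in ("probability", "logit"):
        raise ValueError("regressor must be 'probability' or 'logit'")
    if not vs.both_classes:
        raise ValueError("calibration needs both presences and absences")
    x = vs.probability
    if regressor == "logit":
        x = logit(np.clip(x, 1e-12, 1 - 1e-12))
    y = vs.observed

    if np.ptp(x) == 0:
        return CalibrationResult(
            slope=0.0, intercept=float(logit(np.clip(y.mean(), 1e-12, 1 - 1e-12))),
            regressor=regressor, degenerate=True,
        )
    lo, hi = x[y == 1].min(), x[y == 0].max()
    if lo > hi or x[y == 0].min() > x[y == 1].max():
        sign = 1.0 if lo > hi else -1.0
        return CalibrationResult(
            slope=sign * np.inf, intercept=-sign * np.inf,
            regressor=regressor, separation=True, converged=False,
        )

    res = SpeciesDistributionModel(y, x.reshape(-1, 1), covariate_names=[regressor]).fit()
    return CalibrationResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        regressor=regressor,
        separation=res.separation_flag,
        converged=res.converged,
    )


def resample_rate_sd(
    vs: ValidationSet, threshold: float, reps: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Bootstrap standard deviations of sensitivity and specificity.

    Records are resampled with replacement; replicates in which a class is
    absent contribute NaN and are excluded from that rate's spread.  Returns
    NaN (degenerate) for a rate whose class is absent from the original set.
    """
    if reps < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    obs = vs.observed.astype(bool)
    pred = vs.probability >= threshold
    n = len(obs)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    o, p = obs[idx], pred[idx]
    pos = o.sum(axis=1)
    neg = n - pos
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(pos > 0, (o & p).sum(axis=1) / pos, np.nan)
        spec = np.where(neg > 0, (~o & ~p).sum(axis=1) / neg, np.nan)
    sens_sd = float(np.nanstd(sens, ddof=1)) if obs.any() else float("nan")
    spec_sd = float(np.nanstd(spec, ddof=1)) if (~obs).any() else float("nan")
    return sens_sd, spec_sd


def fit_sdm(observations, covariates, covariate_names=None) -> SDMResults:
    """Maximum-likelihood SDM refit (parameter recovery on synthetic data)."""
    return SpeciesDistributionModel(observations, covariates, covariate_names).fit()


@dataclass
class ValidationStats:
    """One accuracy-table row for a validation set at a threshold."""

    n: int
    n_presence: int
    prevalence: float
    auc: float
    tss: float
    sensitivity: float
    sens_sd: float
    specificity: float
    spec_sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def validate(
    vs: ValidationSet, threshold: float, reps: int = 1000, seed: int = 0
) -> ValidationStats:
    """Assemble the full accuracy row: prevalence, AUC, TSS, rates and SDs."""
    counts = confusion(vs, threshold)
    sens, spec = sensitivity_specificity(counts)
    sens_sd, spec_sd = resample_rate_sd(vs, threshold, reps=reps, seed=seed)
    return ValidationStats(
        n=len(vs.frame),
        n_presence=int(vs.observed.sum()),
        prevalence=float(vs.observed.mean()),
        auc=auc(vs) if vs.both_classes else float("nan"),
        tss=tss(sens, spec) if np.isfinite([sens, spec]).all() else float("nan"),
        sensitivity=sens,
        sens_sd=sens_sd,
        specificity=spec,
        spec_sd=spec_sd,
    )


def aggregate_townships(
    surveys: pd.DataFrame, sticky: bool = True
) -> pd.DataFrame:
    """Aggregate cell-level surveys to township presence records.

    ``surveys`` columns: township, year, presence.  A township-year is a
    presence if any survey that year found one; with ``sticky=True`` a
    township once scored present stays present in all later years (later
    absences are treated as false absences).  Returns one record per
    surveyed township-year.
    """
    f = pd.DataFrame(surveys).copy()
    missing = {"township", "year", "presence"} - set(f.columns)
    if missing:
        raise ValueError(f"survey table missing columns: {sorted(missing)}")
    yearly = (
        f.groupby(["township", "year"], as_index=False)["presence"]
        .max()
        .sort_values(["township", "year"])
    )
    if sticky:
        yearly["presence"] = yearly.groupby("township")["presence"].cummax()
    return yearly.reset_index(drop=True)
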