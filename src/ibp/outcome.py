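"""Logistic outcome-classification models with ROC/AUC, LOO validation and calibration.

The core object pair follows the statsmodels convention: ``OutcomeLogit`` is
built from a patient-level DataFrame (10 clinical covariates, optionally one
Subtraction biomarker column) and ``fit()`` returns an ``OutcomeResults``
carrying maximum-likelihood coefficients, Wald 95% CIs, odds ratios,
Cox-Snell and Nagelkerke pseudo-R², the ROC curve with its AUC, and methods
for leave-one-out cross-validation, the per-threshold sensitivity*specificity
comparison test, and calibration/rank diagnostics.

Covariate coding: male=1, left hemisphere=1, binary yes=1, age in years,
number of AEDs numeric, resection size in % of the hemisphere.  Surgical
success is ILAE class 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "OutcomeLogit",
    "OutcomeResults",
    "fit_logistic",
    "roc_auc",
    "sens_spec_products",
    "auc_comparison_test",
    "loo_predict",
    "calibration_and_rank",
    "STANDARD_COVARIATES",
]

STANDARD_COVARIATES = [
    "age",
    "male",
    "daily_seizures",
    "n_aeds",
    "left_hemisphere",
    "mri_lesion",
    "habitual_sz_captured",
    "soz_fully_resected",
    "extratemporal_resection",
    "resection_size_pct",
]

SEPARATION_BETA = 15.0  # |coefficient| beyond which a fit is flagged as separated


# ---------------------------------------------------------------------------
# ROC machinery (free functions; also used by the results object)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC curve over all unique score thresholds and its trapezoidal AUC.

    The AUC equals the Mann-Whitney U probability P(score_pos > score_neg)
    with ties counted half.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    curve = pd.DataFrame(
        {"threshold": thr, "sensitivity": tpr, "specificity": 1.0 - fpr}
    )
    return curve, float(roc_auc_score(labels, scores))


def sens_spec_products(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """sensitivity*specificity at the n-1 thresholds between sorted scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    s = np.sort(scores)
    thr = (s[:-1] + s[1:]) / 2.0
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    sens = np.array([(pos > t).mean() for t in thr])
    spec = np.array([(neg <= t).mean() for t in thr])
    return sens * spec


def auc_comparison_test(
    scores_a: np.ndarray,
    labels: np.ndarray,
    scores_b: np.ndarray | None = None,
    bonferroni: int = 1,
) -> tuple[float, float]:
    """Paired t-test on per-threshold sensitivity*specificity products.

    With ``scores_b`` given, model A's products are compared to model B's on
    the same cohort; otherwise against the chance level (sens*spec = 0.25
    everywhere).  Returns (t statistic, Bonferroni-corrected p).  Identical
    product sequences give t = 0, p = 1.
    """
    pa = sens_spec_products(scores_a, labels)
    if scores_b is None:
        diffs = pa - 0.25
    else:
        pb = sens_spec_products(scores_b, labels)
        if pb.size != pa.size:  # unequal grids: resample to a common grid
            warnings.warn("unequal threshold grids; resampling to a common grid")
            m = min(pa.size, pb.size)
            grid = np.linspace(0, 1, m)
            pa = np.interp(grid, np.linspace(0, 1, pa.size), pa)
            pb = np.interp(grid, np.linspace(0, 1, pb.size), pb)
        diffs = pa - pb
    if np.allclose(diffs, 0):
        return 0.0, 1.0
    t, p = stats.ttest_1samp(diffs, 0.0)
    return float(t), float(min(1.0, p * bonferroni))


# ---------------------------------------------------------------------------
# model / results


class OutcomeLogit:
    """Logistic outcome model: success ~ clinical covariates (+ biomarker)."""

    def __init__(self, endog: np.ndarray, exog: pd.DataFrame):
        self.endog = np.asarray(endog, dtype=int)
        if not isinstance(exog, pd.DataFrame):
            exog = pd.DataFrame(np.asarray(exog, dtype=float))
        if "const" not in exog.columns:
            exog = sm.add_constant(exog, has_constant="add")
        self.exog = exog.astype(float)
        if self.endog.shape[0] != len(self.exog):
            raise ValueError("endog and exog lengths differ")
        if len(np.unique(self.endog)) < 2:
            raise ValueError("outcome must contain both classes")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        covariates: list[str] | None = None,
        biomarker: str | None = None,
        outcome: str = "success",
    ) -> "OutcomeLogit":
        covariates = list(covariates if covariates is not None else STANDARD_COVARIATES)
        if biomarker is not None:
            covariates.append(biomarker)
        sub = data[covariates + [outcome]].dropna()
        model = cls(sub[outcome].to_numpy(), sub[covariates])
        model.dropped = len(data) - len(sub)
        model.index = sub.index  # rows that entered the fit (listwise per model)
        return model

    def fit(self) -> "OutcomeResults":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(self.endog, self.exog).fit(disp=0, maxiter=200)
            except Exception:
                res = sm.Logit(self.endog, self.exog).fit(
                    disp=0, method="bfgs", maxiter=500
                )
        return OutcomeResults(self, res)


@dataclass
class CalibrationReport:
    bins: pd.DataFrame  # decile bins with n, observed success frequency
    high_confidence: tuple[int, int]  # (n predicted > 0.8, n of them successful)
    low_confidence: tuple[int, int]  # (n predicted < 0.2, n of them successful)
    spearman_rho: float  # probability vs ILAE class (negative = concordant)
    spearman_p: float


class OutcomeResults:
    """Estimates, uncertainties and diagnostics of a fitted outcome model."""

    def __init__(self, model: OutcomeLogit, sm_results):
        self.model = model
        self._res = sm_results
        self.params = pd.Series(sm_results.params, index=model.exog.columns)
        self.bse = pd.Series(sm_results.bse, index=model.exog.columns)
        self.separation = bool(np.any(np.abs(self.params.to_numpy()) > SEPARATION_BETA))
        self.fittedvalues = np.asarray(sm_results.predict(model.exog))
        self.roc, self.auc = roc_auc(self.fittedvalues, model.endog)

    # -- inferential quantities --------------------------------------------

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald CIs; unbounded (reported as +/-inf) where the fit separated."""
        zq = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - zq * self.bse
        hi = self.params + zq * self.bse
        if self.separation:
            bad = np.abs(self.params) > SEPARATION_BETA
            lo[bad], hi[bad] = -np.inf, np.inf
        return pd.DataFrame({"lower": lo, "upper": hi})

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        with np.errstate(over="ignore"):
            return pd.DataFrame(
                {
                    "OR": np.exp(self.params),
                    "lower": np.exp(ci["lower"]),
                    "upper": np.exp(ci["upper"]),
                }
            )

    @property
    def r2_cox_snell(self) -> float:
        n = self.model.endog.size
        return float(1.0 - np.exp(2.0 * (self._res.llnull - self._res.llf) / n))

    @property
    def r2_nagelkerke(self) -> float:
        n = self.model.endog.size
        denom = 1.0 - np.exp(2.0 * self._res.llnull / n)
        return float(self.r2_cox_snell / denom) if denom > 0 else float("nan")

    @property
    def lr_pvalue(self) -> float:
        return float(self._res.llr_pvalue)

    # -- validation ---------------------------------------------------------

    def loo(self) -> tuple[np.ndarray, float]:
        """Leave-one-out out-of-sample probabilities and their pooled AUC."""
        return loo_predict(self.model.exog, self.model.endog)

    def calibration(
        self, probs: np.ndarray | None = None, ilae_classes: np.ndarray | None = None
    ) -> CalibrationReport:
        if probs is None:
            probs = self.fittedvalues
        if ilae_classes is None:
            ilae_classes = np.where(self.model.endog == 1, 1, 3)
        return calibration_and_rank(probs, ilae_classes)

    def summary(self) -> str:
        or_tab = self.odds_ratios()
        lines = [
            "Outcome classification model (logistic)",
            f"  n = {self.model.endog.size}, successes = {int(self.model.endog.sum())}",
            f"  R2 (Nagelkerke) = {self.r2_nagelkerke:.3f}   "
            f"R2 (Cox-Snell) = {self.r2_cox_snell:.3f}   LR p = {self.lr_pvalue:.4g}",
            f"  in-sample AUC = {self.auc:.3f}"
            + ("   [separation flagged]" if self.separation else ""),
            "",
            f"  {'covariate':<24}{'coef':>9}{'OR':>12}{'95% CI':>26}",
        ]
        for name in self.params.index:
            lo, hi = or_tab.loc[name, "lower"], or_tab.loc[name, "upper"]
            ci = "--" if not np.isfinite(lo) or not np.isfinite(hi) else f"[{lo:.3g}, {hi:.3g}]"
            lines.append(
                f"  {name:<24}{self.params[name]:>9.3f}{or_tab.loc[name, 'OR']:>12.3g}{ci:>26}"
            )
        return "\n".join(lines)


def fit_logistic(exog: pd.DataFrame, endog: np.ndarray) -> OutcomeResults:
    """Maximum-likelihood logistic fit returning the full results object."""
    return OutcomeLogit(endog, exog).fit()


def loo_predict(exog: pd.DataFrame, endog: np.ndarray) -> tuple[np.ndarray, float]:
    """For each patient, fit on the other n-1 and predict the held-out one.

    Folds whose training outcome is single-class yield NaN probabilities and
    are excluded from the pooled AUC.  Fitting is deterministic, so identical
    inputs give identical probabilities.
    """
    if not isinstance(exog, pd.DataFrame):
        exog = pd.DataFrame(np.asarray(exog, dtype=float))
    if "const" not in exog.columns:
        exog = sm.add_constant(exog, has_constant="add")
    endog = np.asarray(endog, dtype=int)
    n = endog.size
    if n < 10:
        raise ValueError("leave-one-out needs at least 10 patients")
    X = exog.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            start = sm.Logit(endog, X).fit(disp=0, maxiter=200).params
        except Exception:
            start = np.zeros(X.shape[1])
    probs = np.full(n, np.nan)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        y_tr = endog[mask]
        if len(np.unique(y_tr)) < 2:
            mask[i] = True
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y_tr, X[mask]).fit(
                    disp=0, maxiter=200, start_params=start
                )
            except Exception:
                fit = sm.Logit(y_tr, X[mask]).fit(disp=0, method="bfgs", maxiter=500)
        probs[i] = 1.0 / (1.0 + np.exp(-(X[i] @ fit.params)))
        mask[i] = True
    ok = ~np.isnan(probs)
    auc = float(roc_auc_score(endog[ok], probs[ok])) if len(np.unique(endog[ok])) == 2 else float("nan")
    return probs, auc


def calibration_and_rank(
    probs: np.ndarray, ilae_classes: np.ndarray
) -> CalibrationReport:
    """Decile calibration bins and the Spearman rank association.

    Success is ILAE class 1.  The Spearman correlation relates the predicted
    success probability to the ordinal outcome class; class worsens as the
    number grows, so a concordant model gives a negative rho.
    """
    probs = np.asarray(probs, dtype=float)
    ilae = np.asarray(ilae_classes, dtype=int)
    ok = ~np.isnan(probs)
    probs, ilae = probs[ok], ilae[ok]
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    success = (ilae == 1).astype(int)
    edges = np.linspace(0, 1, 11)
    idx = np.clip(np.digitize(probs, edges[1:-1]), 0, 9)
    rows = []
    for b in range(10):
        sel = idx == b
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n": int(sel.sum()),
                "observed_success": float(success[sel].mean()) if sel.any() else float("nan"),
            }
        )
    hi = probs > 0.8
    lo = probs < 0.2
    rho, p = stats.spearmanr(probs, ilae) if probs.size > 1 else (float("nan"), float("nan"))
    return CalibrationReport(
        bins=pd.DataFrame(rows),
        high_confidence=(int(hi.sum()), int(success[hi].sum())),
        low_confidence=(int(lo.sum()), int(success[lo].sum())),
        spearman_rho=float(rho),
        spearman_p=float(p),
    )
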