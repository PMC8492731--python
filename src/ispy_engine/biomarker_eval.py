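"""Qualifying biomarker evaluation: per-arm association and interaction tests.

A biomarker qualifies as a specific predictor of response to the experimental
regimen when (a) it associates with pCR within the experimental arm (model M1,
likelihood-ratio test p < 0.05) and (b) the marker x treatment interaction is
significant (model M3, LR p < 0.05). The control-arm association (M2) and
HR-adjusted variants (M1-2b, M3b) are reported alongside. No multiplicity
adjustment is applied; the statistics are descriptive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: absolute logistic coefficient beyond which we flag (quasi-)separation
_SEPARATION_COEF = 15.0


@dataclass
class MarkerEvalResult:
    """Outcome of the 3-step qualifying evaluation for one biomarker."""

    marker: str
    lr_p_pgm: float
    lr_p_control: float
    lr_p_interaction: float
    hr_adjusted_ps: tuple[float, float, float] | None = None
    subset: str = "all"  # all | HRpos_HER2neg | HRneg_HER2neg
    qualified: bool = False
    warnings_: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "marker": self.marker,
            "subset": self.subset,
            "lr_p_pgm": self.lr_p_pgm,
            "lr_p_control": self.lr_p_control,
            "lr_p_interaction": self.lr_p_interaction,
            "qualified": self.qualified,
        }
        if self.hr_adjusted_ps is not None:
            d["lr_p_pgm_hr_adj"] = self.hr_adjusted_ps[0]
            d["lr_p_control_hr_adj"] = self.hr_adjusted_ps[1]
            d["lr_p_interaction_hr_adj"] = self.hr_adjusted_ps[2]
        return d


def _fit_logistic(y: np.ndarray, X: np.ndarray):
    """Fit a binomial GLM and return (llf, df_model, separation_flag)."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
        # under (quasi-)separation fitted probabilities touch 0/1 and the
        # reported llf is NaN; recompute it from clipped probabilities
        mu = np.clip(res.mu, 1e-12, 1.0 - 1e-12)
    llf = float(np.sum(y * np.log(mu) + (1.0 - y) * np.log1p(-mu)))
    separated = bool(np.any(np.abs(res.params) > _SEPARATION_COEF))
    return llf, X.shape[1], separated


def lr_test_logistic(outcome: np.ndarray, full_terms: np.ndarray,
                     reduced_terms: np.ndarray) -> float:
    """Likelihood-ratio test between nested logistic models.

    ``full_terms`` / ``reduced_terms`` are design matrices including any
    intercept column. Returns the chi-square p-value with df equal to the
    difference in column counts. Separation is flagged with a warning but the
    p-value is still reported.
    """
    y = np.asarray(outcome, dtype=float)
    full = np.atleast_2d(np.asarray(full_terms, dtype=float))
    red = np.atleast_2d(np.asarray(reduced_terms, dtype=float))
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if full.shape[1] < red.shape[1]:
        raise ValueError("full model has fewer terms than reduced model")

    llf_full, k_full, sep_f = _fit_logistic(y, full)
    llf_red, k_red, sep_r = _fit_logistic(y, red)
    if sep_f or sep_r:
        warnings.warn("possible separation in logistic fit; LR p-value may be "
                      "unreliable", stacklevel=2)
    df = k_full - k_red
    if df == 0:
        return 1.0
    stat = max(0.0, 2.0 * (llf_full - llf_red))
    return float(stats.chi2.sf(stat, df))


def _design(*cols: np.ndarray) -> np.ndarray:
    n = len(cols[0])
    return np.column_stack([np.ones(n), *cols])


def evaluate_marker(
    marker: np.ndarray,
    pcr: np.ndarray,
    arm: np.ndarray,
    hr_status: np.ndarray | None = None,
    treatment_label: str = "pgm",
    marker_name: str = "marker",
    subset: str = "all",
    standardize: bool = True,
    alpha: float = 0.05,
) -> MarkerEvalResult:
    """Run the 3-model qualifying evaluation for one biomarker.

    M1: pCR ~ marker (treatment arm); M2: pCR ~ marker (control arm);
    M3: pCR ~ marker + Tx + marker x Tx, tested against pCR ~ marker + Tx.
    When ``hr_status`` is given, the HR-adjusted variants (M1-2b, M3b) are
    fitted as well. Continuous markers are standardized (mean 0, SD 1) for
    comparability across biomarkers.
    """
    x = np.asarray(marker, dtype=float)
    y = np.asarray(pcr, dtype=float)
    arm = np.asarray(arm)
    tx = (arm == treatment_label).astype(float)
    if tx.sum() == 0:
        raise ValueError(f"no patients in treatment arm {treatment_label!r}")

    msgs: list[str] = []
    if x.std(ddof=0) == 0.0:
        msgs.append("constant marker; all tests return p = 1")
        warnings.warn(msgs[-1], stacklevel=2)
        return MarkerEvalResult(marker=marker_name, lr_p_pgm=1.0,
                                lr_p_control=1.0, lr_p_interaction=1.0,
                                subset=subset, qualified=False, warnings_=msgs)
    if standardize:
        x = (x - x.mean()) / x.std(ddof=0)

    def arm_p(mask: np.ndarray) -> float:
        if mask.sum() == 0 or len(np.unique(y[mask])) < 2:
            msgs.append("degenerate arm subset; association p = 1")
            return 1.0
        return lr_test_logistic(y[mask], _design(x[mask]),
                                _design(x[mask])[:, :1])

    p_pgm = arm_p(tx == 1)
    p_ctl = arm_p(tx == 0)

    both_arms = len(np.unique(tx)) == 2
    if both_arms:
        full = _design(x, tx, x * tx)
        red = _design(x, tx)
        p_int = lr_test_logistic(y, full, red)
    else:
        msgs.append("single-arm data; interaction undefined")
        p_int = float("nan")

    hr_ps = None
    if hr_status is not None:
        hr = np.asarray(hr_status, dtype=float)

        def arm_p_hr(mask: np.ndarray) -> float:
            if mask.sum() == 0 or len(np.unique(y[mask])) < 2:
                return 1.0
            full = _design(x[mask], hr[mask])
            red = _design(hr[mask])
            return lr_test_logistic(y[mask], full, red)

        p_pgm_b = arm_p_hr(tx == 1)
        p_ctl_b = arm_p_hr(tx == 0)
        if both_arms:
            full = _design(x, hr, tx, x * tx)
            red = _design(x, hr, tx)
            p_int_b = lr_test_logistic(y, full, red)
        else:
            p_int_b = float("nan")
        hr_ps = (p_pgm_b, p_ctl_b, p_int_b)

    qualified = bool(p_pgm < alpha and np.isfinite(p_int) and p_int < alpha)
    return MarkerEvalResult(marker=marker_name, lr_p_pgm=p_pgm,
                            lr_p_control=p_ctl, lr_p_interaction=p_int,
                            hr_adjusted_ps=hr_ps, subset=subset,
                            qualified=qualified, warnings_=msgs)


def evaluate_markers(scores: pd.DataFrame, pcr: pd.Series, arm: pd.Series,
                     hr_status: pd.Series | None = None,
                     treatment_label: str = "pgm",
                     subset: str = "all") -> pd.DataFrame:
    """Evaluate every column of ``scores`` and return a results table."""
    rows = []
    for name in scores.columns:
        res = evaluate_marker(
            scores[name].to_numpy(), pcr.to_numpy(), arm.to_numpy(),
            hr_status=None if hr_status is None else hr_status.to_numpy(),
            treatment_label=treatment_label, marker_name=name, subset=subset)
        rows.append(res.to_dict())
    return pd.DataFrame(rows)


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Uses the probability-mass rule: the sum of hypergeometric probabilities of
    all tables no more probable than the observed one. An empty margin gives
    p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("counts must be nonnegative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("empty margin in 2x2 table; p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
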