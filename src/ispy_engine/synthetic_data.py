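"""Synthetic-data generators with the statistical structure the analyses assume.

Three generators produce (i) patient-level trial tables from a logistic
outcome model with clinical covariates, per-arm effects and calendar drift,
(ii) gene-expression matrices with correlated signature blocks driven by a
latent factor, and (iii) longitudinal HbA1c trajectories with a
treatment-induced elevation. All are pure functions of their configuration
(which carries the seed).

Defaults emulate the study conditions of a two-arm HER2-negative platform
comparison: 106 experimental vs 128 control patients, HR-positive prevalence
~53.5% and MammaPrint-Hi2 prevalence ~50.5% (the two arms' observed
prevalences averaged), and pCR logits placed so that marginal rates land near
22% (experimental) and 16-17% (control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy import stats

from .hba1c_analysis import HbA1cSeries
from .signature_scores import ExpressionMatrix, SignedSignature
from .trial_engine import HER2_NEG, HER2_POS, assign_time_bin

logger = logging.getLogger(__name__)


def linear_ramp(n_bins: int, slope: float, start_bin: int = 6) -> np.ndarray:
    """True drift path delta(t) = slope * max(0, t - start_bin), bin-1-first."""
    t = np.arange(1, n_bins + 1)
    return slope * np.maximum(0, t - start_bin).astype(float)


# ---------------------------------------------------------------------------
# trial tables


@dataclass
class ArmSpec:
    """One arm's accrual window (days from trial start) and true effect."""

    name: str
    n: int
    accrual_start: int
    accrual_end: int
    log_or: float = 0.0


@dataclass
class TrialScenario:
    seed: int
    arms: tuple[ArmSpec, ...] = (
        ArmSpec("control", 128, 0, 1800, 0.0),
        ArmSpec("pgm", 106, 850, 1800, 0.4),
    )
    hr_pos_frac: float = 0.535
    mp_hi2_frac: float = 0.505
    her2_pos_frac: float = 0.0
    intercept: float = -1.6
    hr_coef: float = -0.7
    mp_coef: float = 0.6
    her2_coef: float = 0.0
    mp_sd: float = 0.5
    #: true per-bin drift offsets per HER2 stratum (bin-1-first; 0 beyond)
    drift: dict[str, np.ndarray] = field(default_factory=dict)
    deviation_frac: float = 0.03
    analysis_day: int | None = None
    bin_width_days: int = 90

    def __post_init__(self) -> None:
        self.arms = tuple(a if isinstance(a, ArmSpec) else ArmSpec(*a)
                          for a in self.arms)
        for frac in (self.hr_pos_frac, self.mp_hi2_frac):
            if not (0 < frac < 1):
                raise ValueError("prevalences must lie in (0, 1)")
        if not (0 <= self.her2_pos_frac < 1):
            raise ValueError("her2_pos_frac must lie in [0, 1)")


#: MammaPrint Hi2 cut; scores below are Hi2
_MP_CUT = -0.573
_DEVIATION_KINDS = ("nonprotocol_therapy", "no_surgery", "withdrew")


def simulate_trial(config: TrialScenario) -> pd.DataFrame:
    """Simulate a patient-level trial table (the patient-CSV schema).

    Covariates are drawn at the configured prevalences, accrual days
    uniformly within each arm's window, and pCR from the logistic model
    ``logit p = intercept + hr_coef*HR + mp_coef*Hi2 + her2_coef*HER2 +
    arm log-OR + delta_stratum(t)``. Patients flagged with a protocol
    deviation carry a missing pCR (the analysis imputes them to non-pCR).
    """
    rng = np.random.default_rng(config.seed)
    analysis_day = config.analysis_day
    if analysis_day is None:
        analysis_day = max(a.accrual_end for a in config.arms)

    rows = []
    pid = 0
    for arm in config.arms:
        days = rng.integers(arm.accrual_start, arm.accrual_end + 1,
                            size=arm.n)
        hr = rng.uniform(size=arm.n) < config.hr_pos_frac
        her2 = rng.uniform(size=arm.n) < config.her2_pos_frac
        # MP scores normal around a mean placed so P(score < cut) = hi2 frac
        mp_mean = _MP_CUT - config.mp_sd * stats.norm.ppf(config.mp_hi2_frac)
        mp = rng.normal(mp_mean, config.mp_sd, size=arm.n)
        hi2 = mp < _MP_CUT

        lp = (config.intercept + config.hr_coef * hr + config.mp_coef * hi2
              + config.her2_coef * her2 + arm.log_or)
        for i in range(arm.n):
            stratum = HER2_POS if her2[i] else HER2_NEG
            path = config.drift.get(stratum)
            if path is not None:
                t = assign_time_bin(int(days[i]), analysis_day,
                                    config.bin_width_days)
                if t <= len(path):
                    lp[i] += path[t - 1]
        pcr = (rng.uniform(size=arm.n) < expit(lp)).astype(int)
        deviates = rng.uniform(size=arm.n) < config.deviation_frac
        for i in range(arm.n):
            pid += 1
            dev = (str(rng.choice(_DEVIATION_KINDS)) if deviates[i]
                   else "none")
            rows.append({
                "patient_id": f"P{pid:04d}",
                "arm": arm.name,
                "hr": "pos" if hr[i] else "neg",
                "her2": "pos" if her2[i] else "neg",
                "mp_score": round(float(mp[i]), 4),
                "randomization_day": int(days[i]),
                "pcr": pd.NA if dev != "none" else int(pcr[i]),
                "deviation": dev,
            })
    return pd.DataFrame(rows)


def simulate_biomarker_cohort(n_per_arm: int, log_or_treatment: float,
                              log_or_control: float, seed: int,
                              base_logit: float = -1.2,
                              treatment_label: str = "pgm") -> pd.DataFrame:
    """Two-arm cohort with an arm-specific continuous-marker effect on pCR."""
    rng = np.random.default_rng(seed)
    marker = rng.standard_normal(2 * n_per_arm)
    arm = np.array([treatment_label] * n_per_arm + ["control"] * n_per_arm)
    lor = np.where(arm == treatment_label, log_or_treatment, log_or_control)
    p = expit(base_logit + lor * marker)
    pcr = (rng.uniform(size=2 * n_per_arm) < p).astype(int)
    return pd.DataFrame({"marker": marker, "pcr": pcr, "arm": arm})


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class ExpressionScenario:
    seed: int
    n_patients: int = 233
    n_genes: int = 2000
    ligand_block_size: int = 120
    creighton_block_size: int = 200
    within_block_corr: float = 0.7
    ligand_pos_frac: float = 0.8
    creighton_pos_frac: float = 364 / 802
    base_level: float = 8.0

    def __post_init__(self) -> None:
        if self.ligand_block_size < 2 or self.creighton_block_size < 2:
            raise ValueError("block sizes must be >= 2")
        if not (0 <= self.within_block_corr <= 1):
            raise ValueError("within_block_corr must lie in [0, 1]")


#: IGF-pathway genes placed inside the two signature blocks
_LIGAND_SEED_GENES = ("IGF1", "IGF2", "IGFBP4", "IGFBP5", "IRS1", "CDH1")
_CREIGHTON_SEED_GENES = ("IGF1R", "INSR", "IGFBP2", "IRS2", "IGFBP3")


def simulate_expression(config: ExpressionScenario
                        ) -> tuple[ExpressionMatrix, dict]:
    """Simulate a genes x patients log-scale matrix with two signature blocks.

    A latent per-patient factor u drives a signed "ligand" block (IGF1 is its
    anchor, loading positively) and a signed "Creighton" block. Because the
    Creighton score negates the regression t-statistic, a block loading on +u
    yields a score proportional to -u, so the two recomputed signature scores
    are negatively dependent — mirroring the inverse relation seen on real
    arrays. Background genes are independent noise. Returns the matrix plus a
    truth dict with the factor, the two gene lists and the Creighton sign
    vector.
    """
    rng = np.random.default_rng(config.seed)
    n_p = config.n_patients
    rho = config.within_block_corr
    u = rng.standard_normal(n_p)

    def block(size: int, seeds: tuple[str, ...], prefix: str,
              orientation: float, pos_frac: float):
        names = list(seeds) + [f"{prefix}{i:04d}"
                               for i in range(size - len(seeds))]
        signs = np.ones(size)
        n_neg = int(round((1 - pos_frac) * size))
        if n_neg:
            # keep the anchor genes positively signed
            neg_idx = rng.choice(np.arange(len(seeds), size), size=n_neg,
                                 replace=False)
            signs[neg_idx] = -1.0
        eps = rng.standard_normal((size, n_p))
        vals = signs[:, None] * (np.sqrt(rho) * orientation * u[None, :]
                                 + np.sqrt(1 - rho) * eps)
        return names, signs, vals

    lig_names, lig_signs, lig_vals = block(
        config.ligand_block_size, _LIGAND_SEED_GENES, "LIGSIG",
        orientation=+1.0, pos_frac=config.ligand_pos_frac)
    cre_names, cre_signs, cre_vals = block(
        config.creighton_block_size, _CREIGHTON_SEED_GENES, "CRESIG",
        orientation=+1.0, pos_frac=config.creighton_pos_frac)

    n_bg = config.n_genes - len(lig_names) - len(cre_names)
    if n_bg < 0:
        raise ValueError("n_genes smaller than the signature blocks")
    bg_names = [f"BG{i:05d}" for i in range(n_bg)]
    bg_vals = rng.standard_normal((n_bg, n_p))

    gene_means = rng.normal(config.base_level, 1.0, size=config.n_genes)
    values = np.vstack([lig_vals, cre_vals, bg_vals]) + gene_means[:, None]
    genes = lig_names + cre_names + bg_names
    patients = [f"S{i:04d}" for i in range(n_p)]
    expr = ExpressionMatrix(values=pd.DataFrame(values, index=genes,
                                                columns=patients))
    creighton = SignedSignature(name="igfr_creighton_synthetic",
                                genes=cre_names, signs=cre_signs)
    truth = {
        "factor": pd.Series(u, index=patients),
        "ligand_genes": lig_names,
        "ligand_signs": lig_signs,
        "creighton_signature": creighton,
    }
    return expr, truth


# ---------------------------------------------------------------------------
# HbA1c trajectories


@dataclass
class HbA1cScenario:
    seed: int
    n_treated: int = 72
    n_control: int = 0
    treatment_label: str = "pgm"
    baseline_mean: float = 5.4
    baseline_sd: float = 0.49
    elevation_effect: float = 0.25
    noise_sd: float = 0.15
    n_on_treatment: int = 2
    baseline_day: int = -14
    on_day_mean: float = 56.0
    on_day_sd: float = 16.0
    pcr_rate: float = 0.22

    def __post_init__(self) -> None:
        if self.n_on_treatment < 1:
            raise ValueError("need at least one on-treatment measurement")
        if self.baseline_mean <= 0 or self.baseline_sd <= 0:
            raise ValueError("baseline distribution must be positive")


def simulate_hba1c(config: HbA1cScenario
                   ) -> tuple[list[HbA1cSeries], dict[str, int]]:
    """Simulate per-patient HbA1c series and binary pCR outcomes.

    Baselines are Normal(mean, sd) truncated above 0; on-treatment values add
    the treatment elevation effect (treated arm only) plus measurement noise.
    The default baseline distribution puts the median at 5.4% with roughly a
    quarter of patients above the 5.7% limit of normal, and on-treatment
    sampling times average 56 days (SD 16). pCR is drawn independently of
    glycemia at the configured rate.
    """
    rng = np.random.default_rng(config.seed)
    series: list[HbA1cSeries] = []
    pcr: dict[str, int] = {}
    specs = ([(config.treatment_label, config.elevation_effect)]
             * config.n_treated
             + [("control", 0.0)] * config.n_control)
    for i, (arm, effect) in enumerate(specs):
        pid = f"H{i + 1:04d}"
        base = max(0.5, rng.normal(config.baseline_mean, config.baseline_sd))
        meas = [(config.baseline_day, round(base, 2), "baseline")]
        day = 0.0
        for j in range(config.n_on_treatment):
            if j == 0:
                day = max(1.0, rng.normal(config.on_day_mean,
                                          config.on_day_sd))
            else:
                day += rng.uniform(14.0, 42.0)
            val = max(0.5, base + effect + rng.normal(0.0, config.noise_sd))
            meas.append((int(round(day)), round(val, 2), "on_treatment"))
        series.append(HbA1cSeries(patient_id=pid, measurements=meas, arm=arm))
        pcr[pid] = int(rng.uniform() < config.pcr_rate)
    return series, pcr


@dataclass
class ScenarioConfig:
    """Bundle of the three generator configurations sharing one seed."""

    seed: int
    trial: TrialScenario | None = None
    expression: ExpressionScenario | None = None
    hba1c: HbA1cScenario | None = None

    def __post_init__(self) -> None:
        if self.trial is None:
            self.trial = TrialScenario(seed=self.seed)
        if self.expression is None:
            self.expression = ExpressionScenario(seed=self.seed + 1)
        if self.hba1c is None:
            self.hba1c = HbA1cScenario(seed=self.seed + 2)
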