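"""Bayesian adaptive platform-trial engine with NDLM time-drift adjustment.

The pCR endpoint is modeled by a Bayesian logistic regression with clinical
covariates (HR status, HER2 status, MammaPrint Hi1/Hi2 class), one additive
log-odds effect per experimental arm, and calendar-time drift offsets
("the time machine"). Calendar time before the analysis is partitioned into
90-day bins, most recent bin first; within each HER2 stratum the per-bin
offsets delta(t) follow a second-order normal dynamic linear model:

    delta(1) = ... = delta(4) = 0
    delta(5) ~ N(mu0, tau0^2)
    delta(6) - delta(5) ~ N(mu1, tau1^2)
    delta(t) - 2 delta(t-1) + delta(t-2) ~ N(0, tau^2)   for t > 6
    tau^2 ~ InverseGamma(alpha, beta)

with design defaults mu0 = mu1 = 0, tau0^2 = tau1^2 = 0.001, alpha = 1,
beta = 0.001. The most recent year counts fully (frozen bins); older data are
discounted through the smoothed drift path.

Decision rules: an arm graduates when its predictive probability of success
in a hypothetical 300-patient 1:1 phase-3 trial reaches 0.85 in any clinical
signature; it may be dropped for futility when all signatures fall below
0.10. Adaptive randomization assigns 20% of patients to control and splits
the rest among experimental arms proportionally to the posterior probability
of being the best arm in the patient's subtype.

Posterior inference uses a component-wise adaptive random-walk Metropolis
sampler with a conjugate inverse-gamma Gibbs step for the NDLM innovation
variance; it is seeded and reproducible.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

from .signature_scores import mp_class

logger = logging.getLogger(__name__)

DEVIATIONS = ("none", "nonprotocol_therapy", "no_surgery", "withdrew")
HER2_POS, HER2_NEG = "HER2+", "HER2-"


# ---------------------------------------------------------------------------
# domain types


@dataclass
class PatientRecord:
    """One randomized participant."""

    patient_id: str
    arm: str
    hr_status: bool
    her2_status: bool
    mp_score: float
    randomization_day: int
    pcr: int | None = None
    deviation: str = "none"

    def __post_init__(self) -> None:
        if self.deviation not in DEVIATIONS:
            raise ValueError(f"unknown deviation {self.deviation!r}")
        if self.pcr is not None and self.pcr not in (0, 1):
            raise ValueError("pcr must be 0, 1 or None")

    @property
    def mp_class(self) -> str:
        return mp_class(self.mp_score)

    @property
    def stratum(self) -> str:
        return HER2_POS if self.her2_status else HER2_NEG


@dataclass
class TimeMachinePrior:
    """Hyperparameters of the NDLM drift prior (design defaults)."""

    mu0: float = 0.0
    mu1: float = 0.0
    tau0_sq: float = 0.001
    tau1_sq: float = 0.001
    alpha: float = 1.0
    beta: float = 0.001
    bin_width_days: int = 90
    frozen_bins: int = 4

    def __post_init__(self) -> None:
        if min(self.tau0_sq, self.tau1_sq, self.alpha, self.beta) <= 0:
            raise ValueError("variance and IG hyperparameters must be > 0")
        if self.bin_width_days <= 0:
            raise ValueError("bin_width_days must be > 0")
        if self.frozen_bins < 0:
            raise ValueError("frozen_bins must be >= 0")


@dataclass
class DriftPath:
    """Per-bin drift offsets for one HER2 stratum.

    ``delta[k]`` is delta(k+1), i.e. the array is bin-1-first; the first
    ``frozen_bins`` entries must be exactly zero.
    """

    stratum: str
    delta: np.ndarray
    tau_sq: float

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if self.tau_sq <= 0:
            raise ValueError("tau_sq must be > 0")


@dataclass
class SignatureDef:
    """A clinical signature: a predicate over HR / HER2 / MP class.

    ``None`` fields are unconstrained; e.g. all-HER2-negative is
    ``SignatureDef("all HER2-", her2=False)``.
    """

    name: str
    hr: bool | None = None
    her2: bool | None = None
    mp: str | None = None  # "Hi1" | "Hi2" | None

    def matches(self, hr: bool, her2: bool, mp: str) -> bool:
        return ((self.hr is None or self.hr == hr)
                and (self.her2 is None or self.her2 == her2)
                and (self.mp is None or self.mp == mp))


#: the three HER2-negative signatures analyzed for a HER2-negative-only arm
DEFAULT_SIGNATURES = (
    SignatureDef("all HER2-", her2=False),
    SignatureDef("HR+/HER2-", hr=True, her2=False),
    SignatureDef("HR-/HER2-", hr=False, her2=False),
)


@dataclass
class TrialConfig:
    """Platform decision-rule configuration (design defaults)."""

    signatures: tuple[SignatureDef, ...] = DEFAULT_SIGNATURES
    graduation_threshold: float = 0.85
    futility_threshold: float = 0.10
    control_fraction: float = 0.20
    phase3_n: int = 300
    phase3_alpha: float = 0.025
    max_accrual: int = 120
    control_arm: str = "control"
    randomization_temper: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.futility_threshold < self.graduation_threshold < 1):
            raise ValueError("need 0 < futility < graduation < 1")
        if not (0 < self.control_fraction < 1):
            raise ValueError("control_fraction must be in (0, 1)")
        if self.phase3_n % 2 != 0:
            raise ValueError("phase3_n must be even under 1:1 allocation")
        if not (0 < self.phase3_alpha < 1):
            raise ValueError("invalid phase3_alpha")


@dataclass
class GraduationDecision:
    arm: str
    per_signature_pps: dict[str, float]
    status: str  # graduate | futility_stop | continue | max_accrual_stop


# ---------------------------------------------------------------------------
# time bins and endpoint imputation


def assign_time_bin(randomization_day: int, analysis_day: int,
                    bin_width: int = 90) -> int:
    """Index of the 90-day calendar bin for a randomization day.

    Time is 0 at the analysis; the previous 0-90 days are bin 1, 91-180 days
    are bin 2, and so on (750 days back falls in bin 9).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    days_back = analysis_day - randomization_day
    if days_back < 0:
        raise ValueError(
            f"future-dated record: randomized {randomization_day}, "
            f"analysis at {analysis_day}")
    return max(1, math.ceil(days_back / bin_width))


def impute_endpoint(record: PatientRecord) -> int:
    """Apply the non-pCR imputation rule.

    Observed outcomes pass through; patients who switched to non-protocol
    therapy, forwent surgery, or withdrew count as non-pCR. A missing outcome
    without a deviation is unevaluable (ValueError; callers exclude it).
    """
    if record.pcr is not None:
        return int(record.pcr)
    if record.deviation != "none":
        return 0
    raise ValueError(f"{record.patient_id}: missing pCR without deviation "
                     "(unevaluable)")


def prepare_analysis_set(patients: list[PatientRecord]
                         ) -> list[PatientRecord]:
    """Impute endpoints and drop unevaluable patients (with a warning)."""
    out, dropped = [], 0
    for p in patients:
        try:
            y = impute_endpoint(p)
        except ValueError:
            dropped += 1
            continue
        out.append(PatientRecord(p.patient_id, p.arm, p.hr_status,
                                 p.her2_status, p.mp_score,
                                 p.randomization_day, y, p.deviation))
    if dropped:
        warnings.warn(f"excluded {dropped} unevaluable patients "
                      "(missing pCR, no deviation)", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# drift prior


def _drift_normal_terms(delta: np.ndarray, prior: TimeMachinePrior,
                        tau_sq: float) -> float:
    """Sum of the normal log-density terms of the NDLM for one full path.

    ``delta`` is bin-1-first and includes the frozen bins. The inverse-gamma
    term for tau^2 is not included here.
    """
    f = prior.frozen_bins
    T = len(delta)
    total = 0.0
    if T >= f + 1:
        total += stats.norm.logpdf(delta[f], prior.mu0,
                                   math.sqrt(prior.tau0_sq))
    if T >= f + 2:
        total += stats.norm.logpdf(delta[f + 1] - delta[f], prior.mu1,
                                   math.sqrt(prior.tau1_sq))
    if T >= f + 3:
        d2 = delta[f + 2:] - 2.0 * delta[f + 1:-1] + delta[f:-2]
        total += float(np.sum(stats.norm.logpdf(d2, 0.0, math.sqrt(tau_sq))))
    return float(total)


def drift_log_prior(path: DriftPath, prior: TimeMachinePrior) -> float:
    """Joint log prior density of a drift path and its innovation variance.

    Returns -inf when the frozen-bin constraint delta(1..frozen) = 0 is
    violated; raises for tau^2 <= 0.
    """
    if path.tau_sq <= 0:
        raise ValueError("tau_sq must be > 0")
    f = prior.frozen_bins
    if len(path.delta) < f + 1:
        raise ValueError(f"path must cover at least {f + 1} bins")
    if np.any(path.delta[:f] != 0.0):
        return float("-inf")
    total = _drift_normal_terms(path.delta, prior, path.tau_sq)
    total += float(stats.invgamma.logpdf(path.tau_sq, a=prior.alpha,
                                         scale=prior.beta))
    return total


# ---------------------------------------------------------------------------
# model construction


@dataclass
class ModelSpec:
    """A fully specified logistic model ready for posterior sampling."""

    X: np.ndarray                  # n x P design (covariates + arm columns)
    y: np.ndarray                  # n binary outcomes
    coef_names: list[str]
    arm_cols: dict[str, int]       # experimental arm -> column index
    # arm -> [(interaction column, source covariate column)], optional
    interaction_cols: dict[str, list[tuple[int, int]]]
    bins: np.ndarray               # per-patient time bin
    strata: np.ndarray             # per-patient HER2 stratum label
    drift_rows: dict[str, list[np.ndarray]]  # stratum -> row idx per free bin
    drift_bins: dict[str, list[int]]         # stratum -> free bin indices
    prior: TimeMachinePrior
    coef_prior_sd: float
    control_arm: str
    # per-patient clinical profile for signature mixing
    hr: np.ndarray
    her2: np.ndarray
    mp: np.ndarray                 # "Hi1"/"Hi2"

    @property
    def n_patients(self) -> int:
        return len(self.y)

    @property
    def has_drift(self) -> bool:
        return any(self.drift_bins.values())


def build_model(patients: list[PatientRecord], arms: list[str],
                prior: TimeMachinePrior, analysis_day: int,
                control_arm: str = "control", coef_prior_sd: float = 2.0,
                include_drift: bool = True,
                arm_covariate_interactions: bool = False) -> ModelSpec:
    """Assemble the covariate-plus-drift logistic model.

    The linear predictor is intercept + HR + HER2 + MP(Hi2) main effects, one
    additive log-odds effect per experimental arm (control carries none), and
    the HER2-stratum drift offset delta(t_i). Constant covariate columns are
    dropped (they are collinear with the intercept). Arms without patients are
    excluded with a warning; drift offsets are created per HER2 stratum for
    bins beyond the frozen window, so a trial fully inside the frozen window
    collapses to a plain covariate logistic model.
    """
    present = {a for a in arms if any(p.arm == a for p in patients)}
    for a in arms:
        if a not in present:
            warnings.warn(f"arm {a!r} has no patients; excluded", stacklevel=2)
    if control_arm not in present:
        raise ValueError("need at least one control patient")
    pts = [p for p in patients if p.arm in present]
    for p in pts:
        if p.pcr is None:
            raise ValueError(f"{p.patient_id}: unimputed endpoint; run "
                             "prepare_analysis_set first")

    y = np.array([p.pcr for p in pts], dtype=float)
    hr = np.array([p.hr_status for p in pts], dtype=float)
    her2 = np.array([p.her2_status for p in pts], dtype=float)
    mp = np.array([p.mp_class for p in pts])
    mp_hi2 = (mp == "Hi2").astype(float)

    cols = [np.ones(len(pts))]
    names = ["intercept"]
    for nm, col in (("hr", hr), ("her2", her2), ("mp_hi2", mp_hi2)):
        if np.ptp(col) > 0:
            cols.append(col)
            names.append(nm)
        else:
            logger.info("covariate %s constant; dropped from design", nm)
    exp_arms = sorted(a for a in present if a != control_arm)
    arm_cols = {}
    for a in exp_arms:
        arm_cols[a] = len(cols)
        cols.append(np.array([1.0 if p.arm == a else 0.0 for p in pts]))
        names.append(f"arm[{a}]")
    interaction_cols: dict[str, list[tuple[int, int]]] = {a: [] for a in
                                                          exp_arms}
    if arm_covariate_interactions:
        cov_positions = [j for j, nm in enumerate(names)
                         if nm in ("hr", "her2", "mp_hi2")]
        for a in exp_arms:
            arm_ind = cols[arm_cols[a]]
            for j in cov_positions:
                col = arm_ind * cols[j]
                if np.ptp(col) > 0:
                    interaction_cols[a].append((len(cols), j))
                    cols.append(col)
                    names.append(f"arm[{a}]:{names[j]}")
    X = np.column_stack(cols)

    bins = np.array([assign_time_bin(p.randomization_day, analysis_day,
                                     prior.bin_width_days) for p in pts])
    strata = np.array([p.stratum for p in pts])

    drift_rows: dict[str, list[np.ndarray]] = {}
    drift_bins: dict[str, list[int]] = {}
    f = prior.frozen_bins
    for s in (HER2_POS, HER2_NEG):
        in_s = strata == s
        drift_rows[s], drift_bins[s] = [], []
        if include_drift and in_s.any() and bins[in_s].max() > f:
            T = int(bins[in_s].max())
            for t in range(f + 1, T + 1):
                drift_bins[s].append(t)
                drift_rows[s].append(np.flatnonzero(in_s & (bins == t)))
    return ModelSpec(X=X, y=y, coef_names=names, arm_cols=arm_cols,
                     interaction_cols=interaction_cols,
                     bins=bins, strata=strata, drift_rows=drift_rows,
                     drift_bins=drift_bins, prior=prior,
                     coef_prior_sd=coef_prior_sd, control_arm=control_arm,
                     hr=hr.astype(bool), her2=her2.astype(bool), mp=mp)


# ---------------------------------------------------------------------------
# posterior sampling


@dataclass
class SamplerConfig:
    seed: int
    chains: int = 4
    warmup: int = 500
    draws: int = 1000
    rhat_threshold: float = 1.05


@dataclass
class PosteriorDraws:
    """Joint posterior draws of coefficients, drift paths and tau^2."""

    coefficients: np.ndarray          # (total draws) x P
    coef_names: list[str]
    drift: dict[str, np.ndarray]      # stratum -> draws x n_free_bins
    drift_bins: dict[str, list[int]]
    tau_sq: dict[str, np.ndarray]     # stratum -> draws
    model: ModelSpec
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.coefficients.shape[0]

    def drift_paths(self, stratum: str) -> list[DriftPath]:
        """Materialize full DriftPath objects (frozen zeros included)."""
        f = self.model.prior.frozen_bins
        bins_ = self.drift_bins.get(stratum, [])
        out = []
        for i in range(self.n_draws):
            delta = np.zeros(f + len(bins_))
            if bins_:
                delta[f:] = self.drift[stratum][i]
            out.append(DriftPath(stratum=stratum, delta=delta,
                                 tau_sq=float(self.tau_sq[stratum][i])))
        return out


def _split_rhat(x: np.ndarray) -> float:
    """Split R-hat over an array of shape (chains, draws)."""
    c, d = x.shape
    if d < 4:
        return float("nan")
    halves = x[:, : 2 * (d // 2)].reshape(2 * c, d // 2)
    m, n = halves.shape
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def _innovation_matrix(m: int) -> np.ndarray:
    """Map C from NDLM innovations e to drift offsets: delta_free = C @ e.

    Innovations are e1 = delta(f+1), e2 = delta(f+2) - delta(f+1), and the
    second differences thereafter, so C[j, 0] = 1 and C[j, k] = j - k + 1
    (1-based, clipped at 0) for k >= 2. The e's are a-priori independent,
    which is what lets a component-wise sampler mix through the strongly
    correlated delta path.
    """
    j = np.arange(1, m + 1)[:, None]
    k = np.arange(1, m + 1)[None, :]
    C = np.maximum(0, j - k + 1).astype(float)
    C[:, 0] = 1.0
    return C


def _run_chain(model: ModelSpec, seed, warmup: int, draws: int):
    rng = np.random.default_rng(seed)
    X, y, prior = model.X, model.y, model.prior
    n, P = X.shape
    sd0 = model.coef_prior_sd

    strata = [s for s in model.drift_bins if model.drift_bins[s]]
    n_free = {s: len(model.drift_bins[s]) for s in strata}
    C = {s: _innovation_matrix(n_free[s]) for s in strata}

    # per-innovation affected rows and weights: changing e_k moves delta(f+j)
    # for every j >= k by C[j, k] for all patients in those bins
    inov_rows: dict[str, list[np.ndarray]] = {}
    inov_wts: dict[str, list[np.ndarray]] = {}
    local_j: dict[str, np.ndarray] = {}
    all_rows: dict[str, np.ndarray] = {}
    for s in strata:
        rows_per_bin = model.drift_rows[s]
        all_rows[s] = (np.concatenate(rows_per_bin)
                       if rows_per_bin else np.empty(0, dtype=int))
        local_j[s] = np.concatenate(
            [np.full(len(r), j + 1) for j, r in enumerate(rows_per_bin)]
        ) if rows_per_bin else np.empty(0, dtype=int)
        inov_rows[s], inov_wts[s] = [], []
        for k in range(1, n_free[s] + 1):
            mask = local_j[s] >= k
            inov_rows[s].append(all_rows[s][mask])
            w = (np.ones(mask.sum()) if k == 1
                 else (local_j[s][mask] - k + 1).astype(float))
            inov_wts[s].append(w)

    e_mean = {s: np.zeros(n_free[s]) for s in strata}
    e_var0 = {s: np.zeros(n_free[s]) for s in strata}
    for s in strata:
        e_mean[s][0] = prior.mu0
        e_var0[s][0] = prior.tau0_sq
        if n_free[s] >= 2:
            e_mean[s][1] = prior.mu1
            e_var0[s][1] = prior.tau1_sq

    # init: intercept at the empirical logit, everything else near 0
    beta = rng.normal(0.0, 0.3, size=P)
    p0 = (y.sum() + 0.5) / (n + 1.0)
    beta[0] += math.log(p0 / (1.0 - p0))
    e = {s: rng.normal(0.0, 0.01, size=n_free[s]) for s in strata}
    tau2 = {s: 0.001 for s in strata}

    def delta_of(s):
        return C[s] @ e[s]

    lp = X @ beta
    for s in strata:
        d = delta_of(s)
        for jj, rows in enumerate(model.drift_rows[s]):
            lp[rows] += d[jj]
    ll = y * lp - np.logaddexp(0.0, lp)

    col_rows = [np.flatnonzero(X[:, j] != 0.0) for j in range(P)]
    col_vals = [X[col_rows[j], j] for j in range(P)]
    step_b = np.full(P, 0.3)
    step_e = {s: np.full(n_free[s], 0.05) for s in strata}
    step_s = {s: 1.0 for s in strata}

    out_beta = np.empty((draws, P))
    out_delta = {s: np.empty((draws, n_free[s])) for s in strata}
    out_tau2 = {s: np.empty(draws) for s in strata}

    total = warmup + draws
    for it in range(total):
        gamma = min(0.2, 2.0 / math.sqrt(it + 10.0)) if it < warmup else 0.0
        # coefficients
        for j in range(P):
            rows, vals = col_rows[j], col_vals[j]
            prop = beta[j] + step_b[j] * rng.standard_normal()
            lp_new = lp[rows] + vals * (prop - beta[j])
            ll_new = y[rows] * lp_new - np.logaddexp(0.0, lp_new)
            log_acc = (ll_new.sum() - ll[rows].sum()
                       - (prop**2 - beta[j]**2) / (2.0 * sd0**2))
            acc = math.log(rng.uniform()) < log_acc
            if acc:
                beta[j] = prop
                lp[rows] = lp_new
                ll[rows] = ll_new
            if gamma:
                step_b[j] *= math.exp(gamma * ((1.0 if acc else 0.0) - 0.44))
        # NDLM innovations, one at a time (independent priors)
        for s in strata:
            for k in range(n_free[s]):
                v_k = e_var0[s][k] if k < 2 else tau2[s]
                prop = e[s][k] + step_e[s][k] * rng.standard_normal()
                rows, w = inov_rows[s][k], inov_wts[s][k]
                diff = prop - e[s][k]
                lp_new = lp[rows] + w * diff
                ll_new = y[rows] * lp_new - np.logaddexp(0.0, lp_new)
                log_acc = (ll_new.sum() - ll[rows].sum()
                           - ((prop - e_mean[s][k])**2
                              - (e[s][k] - e_mean[s][k])**2) / (2.0 * v_k))
                acc = math.log(rng.uniform()) < log_acc
                if acc:
                    e[s][k] = prop
                    lp[rows] = lp_new
                    ll[rows] = ll_new
                if gamma:
                    step_e[s][k] *= math.exp(
                        gamma * ((1.0 if acc else 0.0) - 0.44))
            # conjugate Gibbs update of the innovation variance
            if n_free[s] >= 3:
                ee = e[s][2:]
                shape = prior.alpha + 0.5 * len(ee)
                scale = prior.beta + 0.5 * float(ee @ ee)
            else:
                shape, scale = prior.alpha, prior.beta
            tau2[s] = scale / rng.standard_gamma(shape)
            # joint rescale of (tau^2, e[3:]) along the funnel axis; the
            # innovation prior terms cancel against the Jacobian, leaving
            # the likelihood and -alpha*log(tau2) - beta/tau2
            if n_free[s] >= 3:
                lam = math.log(tau2[s])
                sstep = step_s[s] * rng.standard_normal()
                lam_new = lam + sstep
                fac = math.exp(0.5 * sstep)
                e_new = e[s].copy()
                e_new[2:] *= fac
                d_change = C[s] @ (e_new - e[s])
                rows = all_rows[s]
                lp_new = lp[rows] + d_change[local_j[s] - 1]
                ll_new = y[rows] * lp_new - np.logaddexp(0.0, lp_new)
                log_acc = (ll_new.sum() - ll[rows].sum()
                           - prior.alpha * (lam_new - lam)
                           - prior.beta * (math.exp(-lam_new)
                                           - math.exp(-lam)))
                acc = math.log(rng.uniform()) < log_acc
                if acc:
                    tau2[s] = math.exp(lam_new)
                    e[s] = e_new
                    lp[rows] = lp_new
                    ll[rows] = ll_new
                if gamma:
                    step_s[s] *= math.exp(
                        gamma * ((1.0 if acc else 0.0) - 0.44))

        if it >= warmup:
            i = it - warmup
            out_beta[i] = beta
            for s in strata:
                out_delta[s][i] = delta_of(s)
                out_tau2[s][i] = tau2[s]
    return out_beta, out_delta, out_tau2


def sample_posterior(model: ModelSpec, config: SamplerConfig
                     ) -> PosteriorDraws:
    """Draw from the joint posterior; reproducible given the seed.

    Runs ``config.chains`` independent adaptive-Metropolis chains, discards
    warm-up, and attaches split-R-hat convergence diagnostics (a warning is
    raised when any coefficient exceeds the configured threshold).
    """
    if config.warmup <= 0 or config.draws <= 0:
        raise ValueError("warmup and draws must be positive")
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains_b, chains_d, chains_t = [], [], []
    for ss in seeds:
        b, d, t = _run_chain(model, ss, config.warmup, config.draws)
        chains_b.append(b)
        chains_d.append(d)
        chains_t.append(t)

    strata = [s for s in model.drift_bins if model.drift_bins[s]]
    coef = np.concatenate(chains_b, axis=0)
    drift = {s: np.concatenate([d[s] for d in chains_d], axis=0)
             for s in strata}
    tau_sq = {s: np.concatenate([t[s] for t in chains_t]) for s in strata}

    rhats = {}
    stacked = np.stack(chains_b)  # chains x draws x P
    for j, nm in enumerate(model.coef_names):
        rhats[nm] = _split_rhat(stacked[:, :, j])
    for s in strata:
        rhats[f"tau_sq[{s}]"] = _split_rhat(
            np.stack([np.log(t[s]) for t in chains_t]))
    worst = max((v for v in rhats.values() if np.isfinite(v)), default=1.0)
    converged = worst <= config.rhat_threshold
    if not converged:
        warnings.warn(f"possible non-convergence: max R-hat {worst:.3f} > "
                      f"{config.rhat_threshold}", stacklevel=2)
    return PosteriorDraws(
        coefficients=coef, coef_names=list(model.coef_names), drift=drift,
        drift_bins={s: list(model.drift_bins[s]) for s in strata},
        tau_sq=tau_sq, model=model,
        diagnostics={"rhat": rhats, "max_rhat": worst,
                     "converged": converged})


# ---------------------------------------------------------------------------
# derived rates and decision rules


def _signature_profiles(model: ModelSpec, signature: SignatureDef):
    """Unique covariate profiles (and mixing weights) within a signature."""
    mask = np.array([signature.matches(h, e, m) for h, e, m in
                     zip(model.hr, model.her2, model.mp)])
    if not mask.any():
        raise ValueError(f"no patients match signature {signature.name!r}")
    arm_idx = set(model.arm_cols.values())
    for pairs in model.interaction_cols.values():
        arm_idx.update(c for c, _ in pairs)
    cov_idx = [j for j in range(model.X.shape[1]) if j not in arm_idx]
    cov = model.X[mask][:, cov_idx]
    profiles, counts = np.unique(cov, axis=0, return_counts=True)
    return profiles, counts / counts.sum(), cov_idx


def subtype_rate(draws: PosteriorDraws, arm: str,
                 signature: SignatureDef) -> np.ndarray:
    """Per-draw pCR rate for an arm within a signature.

    Rates are evaluated at current time (all drift offsets 0, i.e. the frozen
    bins) and averaged over the covariate-profile mix observed among patients
    in the signature.
    """
    model = draws.model
    if arm != model.control_arm and arm not in model.arm_cols:
        raise ValueError(f"unknown arm {arm!r}")
    profiles, weights, cov_idx = _signature_profiles(model, signature)
    eta = draws.coefficients[:, cov_idx] @ profiles.T  # draws x profiles
    if arm != model.control_arm:
        eta = eta + draws.coefficients[:, [model.arm_cols[arm]]]
        for col, cov_col in model.interaction_cols.get(arm, []):
            prof_vals = profiles[:, cov_idx.index(cov_col)]
            eta = eta + np.outer(draws.coefficients[:, col], prof_vals)
    return expit(eta) @ weights


def prob_superior(draws: PosteriorDraws, arm: str,
                  signature: SignatureDef) -> float:
    """Posterior probability that the arm's signature pCR rate beats control."""
    ra = subtype_rate(draws, arm, signature)
    rc = subtype_rate(draws, draws.model.control_arm, signature)
    return float(np.mean(ra > rc))


def _phase3_success_region(n_per_arm: int, alpha: float) -> np.ndarray:
    """Indicator matrix S[xa, xc] of phase-3 success under the pooled z-test.

    Success: one-sided two-proportion z-test (pooled variance) rejects at
    level ``alpha`` in favor of the experimental arm.
    """
    k = np.arange(n_per_arm + 1)
    pa = k[:, None] / n_per_arm
    pc = k[None, :] / n_per_arm
    pbar = (k[:, None] + k[None, :]) / (2.0 * n_per_arm)
    var = pbar * (1.0 - pbar) * (2.0 / n_per_arm)
    z_crit = stats.norm.ppf(1.0 - alpha)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (pa - pc) / np.sqrt(var)
    return np.where(var > 0, z > z_crit, False)


def phase3_success_prob(p_arm, p_control, n_per_arm: int = 150,
                        alpha: float = 0.025) -> np.ndarray:
    """Exact success probability of the hypothetical phase-3 trial.

    Enumerates the joint binomial distribution of pCR counts at ``n_per_arm``
    per arm for given true rates (vectorized over draws).
    """
    pa = np.atleast_1d(np.asarray(p_arm, dtype=float))
    pc = np.atleast_1d(np.asarray(p_control, dtype=float))
    S = _phase3_success_region(n_per_arm, alpha).astype(float)
    k = np.arange(n_per_arm + 1)
    fa = stats.binom.pmf(k[None, :], n_per_arm, pa[:, None])
    fc = stats.binom.pmf(k[None, :], n_per_arm, pc[:, None])
    return np.einsum("di,ij,dj->d", fa, S, fc)


def predictive_prob_phase3(draws: PosteriorDraws, arm: str,
                           signature: SignatureDef,
                           config: TrialConfig) -> float:
    """Predictive probability of success in the hypothetical phase-3 trial.

    For each posterior draw the exact (binomially enumerated) success
    probability of a 1:1 two-arm trial with ``config.phase3_n`` patients is
    computed at the draw's signature pCR rates; the posterior mean is
    returned.
    """
    ra = subtype_rate(draws, arm, signature)
    rc = subtype_rate(draws, draws.model.control_arm, signature)
    probs = phase3_success_prob(ra, rc, n_per_arm=config.phase3_n // 2,
                                alpha=config.phase3_alpha)
    return float(np.mean(probs))


def evaluate_arm_status(pps: dict[str, float], config: TrialConfig,
                        arm: str = "", accrual_reached: bool = False
                        ) -> GraduationDecision:
    """Graduation / futility decision from per-signature predictive probs."""
    if not pps:
        raise ValueError("pps mapping must be non-empty")
    vals = np.array(list(pps.values()), dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("predictive probabilities must lie in [0, 1]")
    if np.any(vals >= config.graduation_threshold):
        status = "graduate"
    elif np.all(vals < config.futility_threshold):
        status = "futility_stop"
    elif accrual_reached:
        status = "max_accrual_stop"
    else:
        status = "continue"
    return GraduationDecision(arm=arm, per_signature_pps=dict(pps),
                              status=status)


def randomization_probabilities(draws: PosteriorDraws,
                                subtype: SignatureDef,
                                open_arms: list[str],
                                config: TrialConfig) -> dict[str, float]:
    """Adaptive randomization probabilities within a subtype.

    Control receives exactly ``control_fraction``; experimental arms share the
    rest proportionally to the posterior probability of having the best pCR
    rate in the subtype (optionally tempered by an exponent). Per-draw ties
    for best split equally.
    """
    exp_arms = [a for a in open_arms if a != config.control_arm]
    if not exp_arms:
        raise ValueError("no open experimental arms")
    rates = np.stack([subtype_rate(draws, a, subtype) for a in exp_arms])
    best = rates == rates.max(axis=0, keepdims=True)
    p_best = (best / best.sum(axis=0, keepdims=True)).mean(axis=1)
    g = config.randomization_temper
    share = p_best**g
    share = share / share.sum()
    probs = {config.control_arm: config.control_fraction}
    for a, s in zip(exp_arms, share):
        probs[a] = (1.0 - config.control_fraction) * float(s)
    return probs


def arm_report(draws: PosteriorDraws, arm: str,
               config: TrialConfig) -> dict:
    """Per-signature summary: rates, probability intervals, decision inputs."""
    rows = {}
    for sig in config.signatures:
        try:
            ra = subtype_rate(draws, arm, sig)
            rc = subtype_rate(draws, draws.model.control_arm, sig)
        except ValueError:
            continue
        rows[sig.name] = {
            "estimated_pcr_rate_pct": round(100 * float(ra.mean()), 1),
            "probability_interval_95_pct": [
                round(100 * float(np.quantile(ra, q)), 1)
                for q in (0.025, 0.975)],
            "control_pcr_rate_pct": round(100 * float(rc.mean()), 1),
            "control_interval_95_pct": [
                round(100 * float(np.quantile(rc, q)), 1)
                for q in (0.025, 0.975)],
            "prob_superior_pct": round(100 * prob_superior(draws, arm, sig), 1),
            "predictive_prob_phase3_pct": round(
                100 * predictive_prob_phase3(draws, arm, sig, config), 1),
        }
    decision = evaluate_arm_status(
        {k: v["predictive_prob_phase3_pct"] / 100 for k, v in rows.items()},
        config, arm=arm)
    return {"arm": arm, "signatures": rows, "status": decision.status}
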