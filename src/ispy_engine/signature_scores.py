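"""IGF-axis expression signature scoring and related patient-level classifiers.

Two published signature scores are implemented:

* the IGF-1 ligand score: per patient, the Pearson correlation between a
  ternary gene "sign" vector (built from each signature gene's population
  correlation with IGF1) and the patient's centered expression over the
  signature genes;
* the Creighton IGF-1R signature: per patient, the t-statistic of the slope
  from regressing the patient's median-centered signature-gene expression on
  a published +/-1 sign vector, multiplied by -1, then z-scored over the
  population.

Also here: the MammaPrint Hi1/Hi2 dichotomization, tertile classification of
a score vector, and pass-through extraction of single-gene IGF-pathway
biomarkers with the IGFBP5/IGFBP4 log-ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: MammaPrint score below which a tumor is classed Hi2 (strict inequality).
MP_HI2_THRESHOLD = -0.573

#: The 11 IGF-1R pathway single-gene biomarkers.
IGF_PATHWAY_GENES = (
    "IGF1", "IGF2", "IGF1R", "INSR", "IGFBP2", "IRS1",
    "IRS2", "IGFBP3", "IGFBP4", "IGFBP5", "CDH1",
)


@dataclass
class ExpressionMatrix:
    """Genes x patients expression values (log-scale array data).

    ``centered`` records which gene-wise centering has been applied:
    ``"none"``, ``"gene-mean"`` or ``"gene-median"``.
    """

    values: pd.DataFrame  # index: gene symbols, columns: patient ids
    centered: str = "none"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dups)[:5]}")
        if self.centered not in ("none", "gene-mean", "gene-median"):
            raise ValueError(f"unknown centering flag: {self.centered!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def patients(self) -> list[str]:
        return list(self.values.columns)

    def center(self, method: str = "gene-mean") -> "ExpressionMatrix":
        """Return a gene-wise centered copy (mean or median across patients)."""
        if method == "gene-mean":
            shifted = self.values.sub(self.values.mean(axis=1), axis=0)
        elif method == "gene-median":
            shifted = self.values.sub(self.values.median(axis=1), axis=0)
        else:
            raise ValueError(f"unknown centering method: {method!r}")
        return ExpressionMatrix(values=shifted, centered=method)


@dataclass
class SignedSignature:
    """A gene list with a per-gene sign vector in {-1, 0, +1}.

    For the Creighton signature the published list has 802 genes with 364
    positive and 438 negative signs; for the ligand score the 274-gene list
    carries signs derived at run time from correlations with IGF1.
    """

    name: str
    genes: list[str]
    signs: np.ndarray
    expected_size: int | None = None
    expected_sign_counts: tuple[int, int] | None = None  # (+1 count, -1 count)

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=float)
        if len(self.signs) != len(self.genes):
            raise ValueError("signs length must equal gene-list length")
        if not np.all(np.isin(self.signs, (-1.0, 0.0, 1.0))):
            raise ValueError("signs must lie in {-1, 0, +1}")
        if self.expected_size is not None and len(self.genes) != self.expected_size:
            warnings.warn(
                f"signature {self.name}: {len(self.genes)} genes, expected "
                f"{self.expected_size}", stacklevel=2)
        if self.expected_sign_counts is not None:
            n_pos = int(np.sum(self.signs == 1))
            n_neg = int(np.sum(self.signs == -1))
            if (n_pos, n_neg) != tuple(self.expected_sign_counts):
                warnings.warn(
                    f"signature {self.name}: sign counts (+{n_pos}/-{n_neg}) "
                    f"differ from expected {self.expected_sign_counts}",
                    stacklevel=2)


@dataclass
class ScoreVector:
    """Per-patient signature or biomarker scores."""

    patients: list[str]
    values: np.ndarray
    score_type: str  # ligand_mu | igfr_creighton | single_gene | ratio

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.patients):
            raise ValueError("values length must equal patient count")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.patients, name=self.score_type)


# ---------------------------------------------------------------------------
# sign-vector construction


def ternary_sign_vector(
    expr: ExpressionMatrix,
    signature_genes: list[str],
    anchor_gene: str = "IGF1",
    p_threshold: float = 0.01,
) -> SignedSignature:
    """Build the ternary sign vector from per-gene correlations with an anchor.

    Each signature gene is correlated (Pearson, across patients) with the
    anchor gene; the sign of the correlation is kept when its two-sided p-value
    is <= ``p_threshold``, otherwise the entry is 0. Genes with zero variance
    get sign 0 with a warning (their correlation is undefined).
    """
    if anchor_gene not in expr.values.index:
        raise ValueError(f"anchor gene {anchor_gene!r} not in expression matrix")
    n = expr.values.shape[1]
    if n < 3:
        raise ValueError("need at least 3 patients to correlate")

    anchor = expr.values.loc[anchor_gene].to_numpy(dtype=float)
    a = anchor - anchor.mean()
    a_ss = float(a @ a)
    if a_ss == 0.0:
        raise ValueError(f"anchor gene {anchor_gene!r} has zero variance")

    signs = np.zeros(len(signature_genes))
    missing = [g for g in signature_genes if g not in expr.values.index]
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent from matrix",
                      stacklevel=2)
    for i, g in enumerate(signature_genes):
        if g not in expr.values.index:
            continue
        x = expr.values.loc[g].to_numpy(dtype=float)
        xc = x - x.mean()
        x_ss = float(xc @ xc)
        if x_ss == 0.0:
            warnings.warn(f"gene {g} has zero variance; sign set to 0",
                          stacklevel=2)
            continue
        r = float(xc @ a) / np.sqrt(x_ss * a_ss)
        r = float(np.clip(r, -1.0, 1.0))
        # two-sided p via the exact t transform with n-2 df
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        if p <= p_threshold:
            signs[i] = np.sign(r)
    return SignedSignature(name="ternary_sign_vector", genes=list(signature_genes),
                           signs=signs)


# ---------------------------------------------------------------------------
# signature scores


def igf1_ligand_score(expr: ExpressionMatrix,
                      signature: SignedSignature) -> ScoreVector:
    """IGF-1 ligand score: per-patient correlation with the ternary vector.

    ``expr`` must already be centered (gene-wise mean by default; the
    ``centered`` flag is checked). The score is the Pearson correlation, over
    the signature genes available in the matrix, between the ternary sign
    vector and the patient's centered expression; it lies in [-1, 1].
    """
    if expr.centered == "none":
        raise ValueError("expression must be gene-wise centered before scoring")
    present = [i for i, g in enumerate(signature.genes)
               if g in expr.values.index]
    if len(present) < len(signature.genes):
        warnings.warn(
            f"{len(signature.genes) - len(present)} signature genes missing",
            stacklevel=2)
    genes = [signature.genes[i] for i in present]
    s = signature.signs[present]
    if np.count_nonzero(s) < 2:
        raise ValueError("non-informative signature: fewer than 2 nonzero signs")
    sub = expr.values.loc[genes].to_numpy(dtype=float)  # genes x patients

    sc = s - s.mean()
    s_ss = float(sc @ sc)
    xc = sub - sub.mean(axis=0, keepdims=True)
    x_ss = np.einsum("gp,gp->p", xc, xc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (sc @ xc) / np.sqrt(s_ss * x_ss)
    if np.any(~np.isfinite(r)):
        warnings.warn("patients with zero-variance signature expression get "
                      "score 0", stacklevel=2)
        r = np.where(np.isfinite(r), r, 0.0)
    return ScoreVector(patients=expr.patients, values=np.clip(r, -1.0, 1.0),
                       score_type="ligand_mu")


def igfr_creighton_score(expr: ExpressionMatrix,
                         signature: SignedSignature) -> ScoreVector:
    """Creighton IGF-1R signature score.

    For each patient the median-centered expression of the signature genes is
    regressed on the binary +/-1 sign vector; the slope t-statistic times -1 is
    the raw score, and the population vector is z-scored to mean 0, SD 1.
    """
    if expr.centered != "gene-median":
        raise ValueError("Creighton scoring requires gene-median centered data")
    if not np.all(np.isin(signature.signs, (-1.0, 1.0))):
        raise ValueError("Creighton signature signs must be binary {-1, +1}")
    present = [i for i, g in enumerate(signature.genes)
               if g in expr.values.index]
    if len(present) < 3:
        raise ValueError("fewer than 3 signature genes present in the matrix")
    if len(present) < len(signature.genes):
        warnings.warn(
            f"{len(signature.genes) - len(present)} signature genes missing",
            stacklevel=2)
    genes = [signature.genes[i] for i in present]
    s = signature.signs[present]
    sub = expr.values.loc[genes].to_numpy(dtype=float)  # genes x patients
    m = len(genes)

    # slope t-statistic of x ~ sign (with intercept), via the correlation
    # identity t = r * sqrt((m - 2) / (1 - r^2))
    sc = s - s.mean()
    s_ss = float(sc @ sc)
    if s_ss == 0.0:
        raise ValueError("sign vector is constant over the present genes")
    xc = sub - sub.mean(axis=0, keepdims=True)
    x_ss = np.einsum("gp,gp->p", xc, xc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (sc @ xc) / np.sqrt(s_ss * x_ss)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((m - 2) / np.maximum(1.0 - r * r, 1e-300))
    raw = -t
    raw = np.where(np.isfinite(raw), raw, 0.0)

    sd = raw.std(ddof=0)
    if sd == 0.0:
        warnings.warn("degenerate score vector (zero variance); z-scores set "
                      "to 0", stacklevel=2)
        z = np.zeros_like(raw)
    else:
        z = (raw - raw.mean()) / sd
    return ScoreVector(patients=expr.patients, values=z,
                       score_type="igfr_creighton")


# ---------------------------------------------------------------------------
# classifiers


def mp_class(mp_score: float) -> str:
    """Dichotomize a MammaPrint score: ``Hi2`` iff score < -0.573, else ``Hi1``."""
    return "Hi2" if mp_score < MP_HI2_THRESHOLD else "Hi1"


def tertile_class(scores: ScoreVector) -> pd.Series:
    """Split a score vector into low / intermediate / high population tertiles.

    Cuts at the empirical 1/3 and 2/3 quantiles; values tied with a boundary
    fall into the lower group.
    """
    v = scores.values
    if len(v) < 3:
        raise ValueError("need at least 3 patients for tertiles")
    q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
    if q1 == q2 and np.all(v == v[0]):
        warnings.warn("all scores equal; every patient assigned 'low'",
                      stacklevel=2)
        return pd.Series("low", index=scores.patients)
    labels = np.where(v <= q1, "low", np.where(v <= q2, "intermediate", "high"))
    return pd.Series(labels, index=scores.patients)


def gene_level_biomarkers(expr: ExpressionMatrix) -> pd.DataFrame:
    """Extract the 11 IGF-pathway single-gene values plus the IGFBP5/IGFBP4 ratio.

    Returns a patients x markers table. The ratio is a difference on the log
    scale (array data are log-scale). Missing genes are omitted with a warning.
    """
    cols: dict[str, np.ndarray] = {}
    for g in IGF_PATHWAY_GENES:
        if g in expr.values.index:
            cols[g] = expr.values.loc[g].to_numpy(dtype=float)
        else:
            warnings.warn(f"gene {g} absent; column omitted", stacklevel=2)
    if "IGFBP5" in cols and "IGFBP4" in cols:
        cols["IGFBP5_IGFBP4_ratio"] = cols["IGFBP5"] - cols["IGFBP4"]
    else:
        warnings.warn("IGFBP5/IGFBP4 ratio unavailable (gene missing)",
                      stacklevel=2)
    return pd.DataFrame(cols, index=expr.patients)
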