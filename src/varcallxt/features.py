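"""Evidence preprocessing: rank scaling, PCA summaries and Align-GVGD odds.

Raw in-silico deleteriousness scores from a panel of predictors (27 in the
motivating application) are strongly correlated and live on arbitrary scales.
They are therefore (i) expressed per predictor as rank scores scaled to
[0, 1], so a score of 0.9 means "more likely damaging than 90% of the other
variants scored by that predictor", and (ii) summarized by the leading
principal components that capture a target fraction (default 90%) of total
variation, capped at ``max_K`` components (default 10).

Align-GVGD supplies a per-variant pathogenicity *probability*; it enters the
classification model as the log Bayes factor implied by reading that
probability as a posterior under a configurable reference prior.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class PredictorMatrix:
    """Variants x predictors score matrix with explicit missingness (NaN)."""

    variants: list[str]
    scores: np.ndarray
    predictor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D matrix")
        n, p = self.scores.shape
        if n != len(self.variants):
            raise ValueError("row count does not match variant list")
        if not self.predictor_names:
            self.predictor_names = [f"pred_{j + 1}" for j in range(p)]
        if p != len(self.predictor_names):
            raise ValueError("column count does not match predictor list")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, id_column: str = "variant_id"
                   ) -> "PredictorMatrix":
        cols = [c for c in df.columns if c != id_column]
        return cls(
            variants=df[id_column].astype(str).tolist(),
            scores=df[cols].to_numpy(dtype=float),
            predictor_names=cols,
        )


@dataclass
class PCSummary:
    loadings: np.ndarray                       # predictors x K
    explained_variance_fraction: np.ndarray    # length K
    pc_scores: np.ndarray                      # variants x K
    K: int

    def scores_frame(self, variants: list[str]) -> pd.DataFrame:
        out = pd.DataFrame({"variant_id": variants})
        for k in range(self.K):
            out[f"pc_{k + 1}"] = self.pc_scores[:, k]
        return out


def rank_scale(matrix: PredictorMatrix) -> PredictorMatrix:
    """Rank-scale each predictor column to [0, 1].

    Non-missing entries of a column are replaced by ``(rank - 1)/(n - 1)``
    with average ranks for ties, so the column minimum maps to 0 and the
    maximum to 1.  Missing entries stay missing.  A constant column carries no
    ordering information; it maps to 0.5 everywhere with a warning.
    """
    scores = matrix.scores.copy()
    for j, name in enumerate(matrix.predictor_names):
        col = scores[:, j]
        ok = ~np.isnan(col)
        n = int(ok.sum())
        if n < 2:
            raise ValueError(
                f"predictor {name!r} has fewer than 2 non-missing values"
            )
        vals = col[ok]
        if np.all(vals == vals[0]):
            warnings.warn(f"predictor {name!r} is constant; rank score set to 0.5")
            scores[ok, j] = 0.5
            continue
        scores[ok, j] = (rankdata(vals, method="average") - 1.0) / (n - 1.0)
    return PredictorMatrix(matrix.variants, scores, list(matrix.predictor_names))


def impute_missing(matrix: PredictorMatrix) -> PredictorMatrix:
    """Column-median imputation of missing entries (logged when applied)."""
    scores = matrix.scores.copy()
    nan_mask = np.isnan(scores)
    if nan_mask.any():
        medians = np.nanmedian(scores, axis=0)
        medians = np.where(np.isnan(medians), 0.5, medians)
        idx = np.where(nan_mask)
        scores[idx] = medians[idx[1]]
        logger.warning("imputed %d missing predictor entries by column median",
                       int(nan_mask.sum()))
    return PredictorMatrix(matrix.variants, scores, list(matrix.predictor_names))


def pca_summarize(matrix: PredictorMatrix, target_fraction: float = 0.90,
                  max_K: int = 10) -> PCSummary:
    """Principal-component summary of a complete score matrix.

    Columns are mean-centered (no rescaling: rank scaling has already
    homogenized the scales).  K is the smallest component count whose
    cumulative explained-variance fraction reaches ``target_fraction``,
    capped at ``max_K``.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    scores = matrix.scores
    if np.isnan(scores).any():
        rows, cols = np.where(np.isnan(scores))
        cells = [
            f"({matrix.variants[r]}, {matrix.predictor_names[c]})"
            for r, c in list(zip(rows, cols))[:5]
        ]
        raise ValueError("matrix has missing entries; impute first: "
                         + ", ".join(cells))
    n, p = scores.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 variants and 2 predictors")
    pca = PCA(n_components=min(n - 1, p), svd_solver="full")
    full_scores = pca.fit_transform(scores)
    frac = pca.explained_variance_ratio_
    cum = np.cumsum(frac)
    K = int(np.searchsorted(cum, target_fraction - 1e-12) + 1)
    K = min(K, max_K, len(frac))
    return PCSummary(
        loadings=pca.components_[:K].T.copy(),
        explained_variance_fraction=frac[:K].copy(),
        pc_scores=full_scores[:, :K].copy(),
        K=K,
    )


def agvgd_to_log_bf(p: float, reference_prior: float = 0.5,
                    eps: float = 1e-4) -> float:
    """Log Bayes factor implied by a pathogenicity probability ``p``.

    Treats ``p`` as a posterior computed under ``reference_prior`` and returns
    ``log[(p/(1-p)) / (prior/(1-prior))]``.  Probabilities of exactly 0 or 1
    are clipped to [eps, 1-eps] with a warning.
    """
    if not 0 < reference_prior < 1:
        raise ValueError("reference_prior must be in (0, 1)")
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if p in (0.0, 1.0):
        warnings.warn(f"agvgd probability {p} clipped to [{eps}, {1 - eps}]")
        p = min(max(p, eps), 1 - eps)
    return float(np.log(p / (1 - p)) - np.log(reference_prior / (1 - reference_prior)))


def agvgd_interval_log_bf_sd(lo: float, hi: float, eps: float = 1e-4) -> float:
    """SD of a Gaussian log-BF contribution from a 95% probability interval.

    Optional widened mode: treats the interval (lo, hi) as a +/-1.96-SD range
    on the logit scale, returning (logit(hi) - logit(lo)) / 3.92.
    """
    lo = min(max(lo, eps), 1 - eps)
    hi = min(max(hi, eps), 1 - eps)
    if hi < lo:
        raise ValueError("interval bounds out of order")
    logit = lambda q: np.log(q / (1 - q))
    return float((logit(hi) - logit(lo)) / 3.92)


def build_evidence_frame(matrix: PredictorMatrix, target_fraction: float = 0.90,
                         max_K: int = 10) -> pd.DataFrame:
    """Rank-scale, impute and PCA-summarize raw predictor scores.

    Returns a ``variant_id, pc_1..pc_K`` frame ready to merge into an
    evidence table.
    """
    ranked = impute_missing(rank_scale(matrix))
    summary = pca_summarize(ranked, target_fraction=target_fraction, max_K=max_K)
    return summary.scores_frame(matrix.variants)
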