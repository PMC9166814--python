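"""Operating characteristics of classification models.

Known variants are scored by leave-one-variant-out (LOVO) calling: each
labeled variant is in turn treated as unlabeled, the model refit, and the
variant's posterior probability of pathogenicity thresholded into
called-benign / no-call / called-pathogenic.  The per-condition call counts
are then summarized by a Dirichlet-multinomial model with Jeffreys prior
(posterior category mean ``(count + 1/2)/(n + 3/2)``), 95% highest-density
credible intervals from the exact Beta marginals, raw accuracy with no-calls
counted as errors, and the scaled Brier score (mean squared error of the
predicted probabilities divided by that of the constant prevalence
predictor).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import beta as beta_dist

from . import io_tables, model as model_mod
from .model import (CALLED_BENIGN, CALLED_PATHOGENIC, NO_CALL, ModelConfig,
                    PosteriorSummary, classify)

logger = logging.getLogger(__name__)

KNOWN_BENIGN = "known_benign"
KNOWN_PATHOGENIC = "known_pathogenic"
CATEGORIES = (CALLED_BENIGN, NO_CALL, CALLED_PATHOGENIC)


@dataclass
class CallCounts:
    """Call-category tallies for the known variants of one condition."""

    condition: str
    n_called_benign: int = 0
    n_no_call: int = 0
    n_called_pathogenic: int = 0

    @property
    def total(self) -> int:
        return self.n_called_benign + self.n_no_call + self.n_called_pathogenic

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.n_called_benign, self.n_no_call, self.n_called_pathogenic],
            dtype=float,
        )


def dirichlet_oc(counts: CallCounts) -> dict[str, float]:
    """Jeffreys-prior Dirichlet posterior category means, as percentages.

    With three call categories and prior Dirichlet(1/2, 1/2, 1/2), the
    posterior mean of category i is ``(count_i + 1/2) / (n + 3/2)``.
    """
    c = counts.as_array()
    means = (c + 0.5) / (c.sum() + 1.5)
    return dict(zip(CATEGORIES, (means * 100.0).tolist()))


def _beta_marginal(counts: CallCounts, category: str) -> tuple[float, float]:
    c = counts.as_array()
    i = CATEGORIES.index(category)
    a = c[i] + 0.5
    b = c.sum() - c[i] + 1.0
    return a, b


def beta_hdr(a: float, b: float, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval of a Beta(a, b) distribution.

    Interior-mode case (a > 1 and b > 1): the narrowest interval of the
    requested mass, found by minimizing ``ppf(F(lo) + mass) - lo`` over the
    left endpoint.  Monotone cases (a shape parameter <= 1) get the
    boundary-attached one-sided interval; with both shapes <= 1 (bathtub
    density) the interval attaches to the heavier boundary.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    dist = beta_dist(a, b)
    if a <= 1 and b <= 1:
        if a == 1 and b == 1:
            lo = (1 - mass) / 2
            return lo, lo + mass
        if a / (a + b) < 0.5:
            return 0.0, float(dist.ppf(mass))
        return float(dist.ppf(1 - mass)), 1.0
    if a <= 1:   # density decreasing on (0, 1)
        return 0.0, float(dist.ppf(mass))
    if b <= 1:   # density increasing
        return float(dist.ppf(1 - mass)), 1.0

    def width(lo: float) -> float:
        return dist.ppf(dist.cdf(lo) + mass) - lo

    upper = float(dist.ppf(1 - mass))
    res = optimize.minimize_scalar(width, bounds=(0.0, upper), method="bounded",
                                   options={"xatol": 1e-12})
    lo = float(res.x)
    return lo, float(dist.ppf(dist.cdf(lo) + mass))


def dirichlet_hdr(counts: CallCounts, category: str, mass: float = 0.95
                  ) -> tuple[float, float]:
    """95% (by default) HDR of one call-category rate, from its Beta marginal.

    The marginal of the Jeffreys Dirichlet posterior for category i is
    Beta(count_i + 1/2, n - count_i + 1).  Returned on the probability scale.
    """
    a, b = _beta_marginal(counts, category)
    return beta_hdr(a, b, mass)


def raw_accuracy(benign: CallCounts, pathogenic: CallCounts) -> float:
    """Percent of known variants called correctly; no-calls count as errors."""
    total = benign.total + pathogenic.total
    if total == 0:
        raise ValueError("no known variants")
    correct = benign.n_called_benign + pathogenic.n_called_pathogenic
    return 100.0 * correct / total


def scaled_brier(probs, labels) -> float:
    """Brier score scaled by the constant prevalence predictor's score.

    ``mean((p_i - y_i)^2)`` divided by ``pbar (1 - pbar)`` with
    ``pbar = mean(y)``.  0 is perfect, 1 matches the prevalence predictor and
    values above 1 indicate predictions worse than ignoring the evidence.
    If all labels are identical the reference is undefined; the unscaled
    Brier score is returned with a warning.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.shape != labels.shape or probs.size == 0:
        raise ValueError("probs and labels must be equal-length, non-empty")
    brier = float(np.mean((probs - labels) ** 2))
    pbar = float(labels.mean())
    reference = pbar * (1.0 - pbar)
    if reference == 0.0:
        warnings.warn("all labels identical; returning unscaled Brier score")
        return brier
    return brier / reference


def tally_calls(probs: pd.DataFrame, config: ModelConfig
                ) -> dict[str, CallCounts]:
    """Tally classify() over a per-variant frame with prob + label columns."""
    out = {
        KNOWN_BENIGN: CallCounts(KNOWN_BENIGN),
        KNOWN_PATHOGENIC: CallCounts(KNOWN_PATHOGENIC),
    }
    cond_of = {io_tables.BENIGN: KNOWN_BENIGN,
               io_tables.PATHOGENIC: KNOWN_PATHOGENIC}
    attr = {CALLED_BENIGN: "n_called_benign", NO_CALL: "n_no_call",
            CALLED_PATHOGENIC: "n_called_pathogenic"}
    for _, row in probs.iterrows():
        cond = cond_of.get(row["label"])
        if cond is None:
            continue
        call = classify(row["prob_pathogenic"], config)
        counts = out[cond]
        setattr(counts, attr[call], getattr(counts, attr[call]) + 1)
    return out


def lovo_evaluate(assay: pd.DataFrame | None, evidence: pd.DataFrame | None,
                  config: ModelConfig, warm_start: bool = True
                  ) -> tuple[dict[str, CallCounts], pd.DataFrame]:
    """Leave-one-variant-out calling of every labeled variant.

    Each known variant is in turn unlabeled, the model refit (warm-started
    from the full fit's final chain states by default; burn-in is still
    discarded) and its posterior probability recorded and thresholded.
    Folds whose removal would leave a class without labels are skipped with a
    warning and reported with ``skipped=True``.
    """
    if assay is not None and "mean_log_ratio" not in assay.columns:
        assay = io_tables.average_within_batch(assay)
    full = model_mod.fit(assay, evidence, config, diagnostics=False)
    labeled = full.df[full.df["label"] != io_tables.UNLABELED]
    class_sizes = labeled["label"].value_counts().to_dict()

    rows = []
    for vid, true_label in zip(labeled["variant_id"], labeled["label"]):
        needs_function = "function" in config.evidence_set
        if needs_function and class_sizes.get(true_label, 0) <= 1:
            warnings.warn(f"skipping LOVO fold for {vid}: last labeled "
                          f"variant of class {true_label}")
            rows.append(dict(variant_id=vid, label=true_label,
                             prob_pathogenic=np.nan, call="skipped",
                             skipped=True))
            continue
        masked_assay = assay
        if assay is not None:
            masked_assay = assay.copy()
            sel = masked_assay["variant_id"].astype(str) == vid
            masked_assay.loc[sel, "label"] = io_tables.UNLABELED
        masked_evidence = evidence
        if evidence is not None:
            masked_evidence = evidence.copy()
            sel = masked_evidence["variant_id"].astype(str) == vid
            if "label" in masked_evidence.columns:
                masked_evidence.loc[sel, "label"] = io_tables.UNLABELED
        init = full.final_states if warm_start else None
        refit = model_mod.fit(masked_assay, masked_evidence, config,
                              init_states=init, diagnostics=False)
        prob = float(refit.df.set_index("variant_id")
                     .loc[vid, "prob_pathogenic"])
        rows.append(dict(variant_id=vid, label=true_label,
                         prob_pathogenic=prob,
                         call=classify(prob, config), skipped=False))
    probs = pd.DataFrame(rows)
    counts = tally_calls(probs[~probs["skipped"]], config)
    return counts, probs


def oc_report(counts: dict[str, CallCounts], mass: float = 0.95
              ) -> pd.DataFrame:
    """Per-condition x category table of posterior means and HDR bounds (%)."""
    rows = []
    for cond, cc in counts.items():
        means = dirichlet_oc(cc)
        for cat in CATEGORIES:
            lo, hi = dirichlet_hdr(cc, cat, mass)
            rows.append(dict(condition=cond, category=cat,
                             posterior_mean=means[cat],
                             hdr_lo=100.0 * lo, hdr_hi=100.0 * hi))
    return pd.DataFrame(rows)


def odds_shift_report(summary_a: PosteriorSummary | pd.DataFrame,
                      summary_b: PosteriorSummary | pd.DataFrame
                      ) -> pd.DataFrame:
    """Per-variant odds ratios and call transitions between two fits.

    OR = odds_B / odds_A in favor of pathogenicity; the transition column
    records ``call_A -> call_B``.  Adds per-known-class geometric-mean ORs as
    a ``.attrs['geometric_mean_or']`` annotation.
    """
    a = summary_a.df if isinstance(summary_a, PosteriorSummary) else summary_a
    b = summary_b.df if isinstance(summary_b, PosteriorSummary) else summary_b
    set_a, set_b = set(a["variant_id"]), set(b["variant_id"])
    if set_a != set_b:
        diff = sorted(set_a.symmetric_difference(set_b))
        raise ValueError(f"variant sets differ: {diff[:10]}")
    a = a.set_index("variant_id")
    b = b.reindex(columns=b.columns).set_index("variant_id").loc[a.index]
    log_or = b["log_odds"].to_numpy() - a["log_odds"].to_numpy()
    out = pd.DataFrame({
        "variant_id": a.index,
        "label": a["label"].to_numpy(),
        "log_odds_a": a["log_odds"].to_numpy(),
        "log_odds_b": b["log_odds"].to_numpy(),
        "odds_ratio": np.exp(log_or),
        "transition": [f"{ca} -> {cb}" for ca, cb in
                       zip(a["call"], b["call"])],
        "changed": (a["call"].to_numpy() != b["call"].to_numpy()),
    })
    gm = {}
    for lab, cls in ((io_tables.BENIGN, "benign"),
                     (io_tables.PATHOGENIC, "pathogenic")):
        sel = out["label"] == lab
        if sel.any():
            gm[cls] = float(np.exp(np.log(out.loc[sel, "odds_ratio"]).mean()))
    out.attrs["geometric_mean_or"] = gm
    return out
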