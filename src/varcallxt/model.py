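"""Semi-supervised Bayesian hierarchical classification of variant effects.

The functional-assay response is the within-batch mean log-ratio y_vb for
variant v in experimental batch b.  The first level is a mixed-effects
regression,

    y_vb = theta_v + beta_b + eps_vb,      eps_vb ~ N(0, sigma_e^2),
    beta_b ~ N(0, sigma_b^2),

decomposing readout variation into a variant effect, a batch effect and
background noise.  The second level is a two-component Gaussian
classification model on the variant effects,

    theta_v | D_v = d ~ N(mu_d, tau_d^2),      D_v ~ Bernoulli(pi),

where D_v = 1 indicates a damaging (pathogenic) variant.  Variants assayed
as positive or negative controls have D frozen at their label
("semi-supervised"); D for the variants of uncertain significance is
inferred.  Optional per-variant evidence enters the full conditional of D_v
multiplicatively: class-conditional Gaussian densities for principal-
component summaries of in-silico predictors, and Bayes-factor terms
exp(d * log BF) for family-history data and Align-GVGD probabilities.

Inference is by blocked Gibbs sampling with conjugate updates; D_v is
sampled with theta_v integrated out in closed form (given the batch
effects), which improves mixing, and theta_v is then redrawn given D_v.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from . import io_tables
from .features import agvgd_to_log_bf

logger = logging.getLogger(__name__)

EVIDENCE_TYPES = ("function", "family", "protein_pred", "agvgd")

CALLED_BENIGN = "called_benign"
NO_CALL = "no_call"
CALLED_PATHOGENIC = "called_pathogenic"


class IdentifiabilityError(RuntimeError):
    """The mixture cannot be anchored: a class has no labeled variants."""


class NumericsError(RuntimeError):
    """Non-finite quantity encountered during sampling."""


@dataclass
class ModelConfig:
    """Priors, MCMC settings and calling thresholds.

    Component-mean hyperpriors left at None are derived from the labeled
    controls: the hyperprior mean is the labeled class mean of the per-variant
    average response and the SD is 10x the labeled class SD (weakly
    informative, centered on the controls).
    """

    evidence_set: tuple[str, ...] = ("function",)
    # component-mean hyperpriors (None => derived from labeled controls)
    mu0_mean: float | None = None
    mu0_sd: float | None = None
    mu1_mean: float | None = None
    mu1_sd: float | None = None
    # variance hyperpriors (inverse-gamma shape/rate)
    tau_shape: float = 0.01
    tau_rate: float = 0.01
    sigma_b_shape: float = 0.01
    sigma_b_rate: float = 0.01
    sigma_e_shape: float = 0.01
    sigma_e_rate: float = 0.01
    pc_var_shape: float = 0.01
    pc_var_rate: float = 0.01
    # prevalence prior
    pi_a: float = 1.0
    pi_b: float = 1.0
    # class-conditional PC mean hyperprior SD
    pc_mean_sd: float = 10.0
    # MCMC
    n_iter: int = 20_000
    n_burn: int = 10_000
    thin: int = 5
    n_chains: int = 4
    seed: int = 0
    # calling thresholds
    benign_cut: float = 0.05
    pathogenic_cut: float = 0.99
    agvgd_reference_prior: float = 0.5
    # point-mass overrides: keys among {"mu", "tau2", "sigma_b2", "sigma_e2",
    # "pi", "pc_means", "pc_var"}; the parameter is held fixed (not updated).
    fixed: dict = field(default_factory=dict)
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        self.evidence_set = tuple(sorted(set(self.evidence_set)))
        unknown = set(self.evidence_set) - set(EVIDENCE_TYPES)
        if unknown:
            raise ValueError(f"unknown evidence type(s): {sorted(unknown)}")
        if not self.evidence_set:
            raise ValueError("evidence_set must be non-empty")
        if not 0 < self.benign_cut < self.pathogenic_cut <= 1:
            raise ValueError("need 0 < benign_cut < pathogenic_cut <= 1")
        if not self.n_burn < self.n_iter:
            raise ValueError("n_burn must be < n_iter")
        for name in ("tau_shape", "tau_rate", "sigma_b_shape", "sigma_b_rate",
                     "sigma_e_shape", "sigma_e_rate", "pi_a", "pi_b",
                     "pc_mean_sd", "pc_var_shape", "pc_var_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kw) -> "ModelConfig":
        d = asdict(self)
        d.update(kw)
        return ModelConfig(**d)


@dataclass
class PosteriorSummary:
    """Per-variant posterior calls plus model-level posterior summaries."""

    df: pd.DataFrame
    params: dict
    param_draws: dict
    prob_by_chain: np.ndarray
    diagnostics: dict
    n_retained: int
    config: ModelConfig
    final_states: list


def classify(prob: float, config: ModelConfig) -> str:
    """IARC-style call from a posterior probability of pathogenicity."""
    if not 0 <= prob <= 1:
        raise ValueError(f"probability {prob} outside [0, 1]")
    if prob < config.benign_cut:
        return CALLED_BENIGN
    if prob >= config.pathogenic_cut:
        return CALLED_PATHOGENIC
    return NO_CALL


def combine_log_odds(model_log_odds: float, extra_log_bf: float) -> float:
    """Posterior log-odds after an additional independent log Bayes factor."""
    return float(model_log_odds) + float(extra_log_bf)


def enumerate_models(evidence_types: Iterable[str] = EVIDENCE_TYPES
                     ) -> list[tuple[str, ...]]:
    """All non-empty evidence subsets, ordered by size then lexicographically."""
    types = sorted(set(evidence_types))
    if not types:
        raise ValueError("evidence_types must be non-empty")
    subsets: list[tuple[str, ...]] = []
    for r in range(1, len(types) + 1):
        subsets.extend(itertools.combinations(types, r))
    return subsets


# ---------------------------------------------------------------------------
# data assembly


@dataclass
class _FitData:
    variant_ids: list[str]
    labels: np.ndarray          # 0 benign / 1 pathogenic / -1 unlabeled
    # assay part (None when function excluded)
    v_idx: np.ndarray | None
    b_idx: np.ndarray | None
    y: np.ndarray | None
    n_batches: int
    has_theta: np.ndarray       # bool per variant
    # evidence part
    pc: np.ndarray | None       # n x K (NaN rows excluded via pc_mask)
    pc_mask: np.ndarray | None
    family_lbf: np.ndarray      # per variant, 0 where absent
    agvgd_lbf: np.ndarray


_LABEL_CODE = {io_tables.BENIGN: 0, io_tables.PATHOGENIC: 1, io_tables.UNLABELED: -1}


def _assemble(assay: pd.DataFrame | None, evidence: pd.DataFrame | None,
              config: ModelConfig) -> _FitData:
    use_function = "function" in config.evidence_set
    if use_function:
        if assay is None or len(assay) == 0:
            raise ValueError("evidence_set includes 'function' but no assay data given")
        if "mean_log_ratio" not in assay.columns:
            assay = io_tables.average_within_batch(assay)

    ids: list[str] = []
    if use_function:
        ids.extend(assay["variant_id"].astype(str))
    if evidence is not None:
        ids.extend(evidence["variant_id"].astype(str))
    variant_ids = sorted(set(ids))
    if not variant_ids:
        raise ValueError("no variants found in the supplied tables")
    index = {v: i for i, v in enumerate(variant_ids)}
    n = len(variant_ids)

    labels = np.full(n, -1, dtype=int)

    def apply_labels(frame: pd.DataFrame) -> None:
        for vid, lab in zip(frame["variant_id"].astype(str), frame["label"]):
            code = _LABEL_CODE[lab]
            i = index[vid]
            if code == -1:
                continue
            if labels[i] not in (-1, code):
                raise io_tables.ValidationError(
                    f"conflicting labels for variant {vid!r}")
            labels[i] = code

    if use_function:
        apply_labels(assay)
    if evidence is not None and "label" in evidence.columns:
        apply_labels(evidence)

    v_idx = b_idx = y = None
    n_batches = 0
    has_theta = np.zeros(n, dtype=bool)
    if use_function:
        batches = sorted(set(assay["batch_id"].astype(str)))
        b_index = {b: i for i, b in enumerate(batches)}
        n_batches = len(batches)
        v_idx = assay["variant_id"].astype(str).map(index).to_numpy(dtype=int)
        b_idx = assay["batch_id"].astype(str).map(b_index).to_numpy(dtype=int)
        y = assay["mean_log_ratio"].to_numpy(dtype=float)
        has_theta[np.unique(v_idx)] = True

    pc = pc_mask = None
    family_lbf = np.zeros(n)
    agvgd_lbf = np.zeros(n)
    if evidence is not None:
        ev_idx = evidence["variant_id"].astype(str).map(index).to_numpy(dtype=int)
        if "protein_pred" in config.evidence_set:
            pc_cols = sorted((c for c in evidence.columns if c.startswith("pc_")),
                             key=lambda c: int(c.split("_", 1)[1]))
            if pc_cols:
                K = len(pc_cols)
                pc = np.full((n, K), np.nan)
                pc[ev_idx] = evidence[pc_cols].to_numpy(dtype=float)
                pc_mask = ~np.isnan(pc).any(axis=1)
                pc = np.nan_to_num(pc)
        if "family" in config.evidence_set and "family_log_bf" in evidence.columns:
            vals = evidence["family_log_bf"].to_numpy(dtype=float)
            family_lbf[ev_idx] = np.nan_to_num(vals)
        if "agvgd" in config.evidence_set and "agvgd_prob" in evidence.columns:
            vals = evidence["agvgd_prob"].to_numpy(dtype=float)
            lbf = np.array([
                agvgd_to_log_bf(p, config.agvgd_reference_prior)
                if np.isfinite(p) else 0.0
                for p in vals
            ])
            agvgd_lbf[ev_idx] = lbf
    if pc is None:
        pc_mask = None

    if "protein_pred" in config.evidence_set and pc is None:
        raise ValueError("evidence_set includes 'protein_pred' but no pc_* columns given")

    return _FitData(variant_ids, labels, v_idx, b_idx, y, n_batches,
                    has_theta, pc, pc_mask, family_lbf, agvgd_lbf)


# ---------------------------------------------------------------------------
# Gibbs sampler


def _log_normal_pdf(x, mean, var):
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def _derive_mu_priors(data: _FitData, config: ModelConfig) -> tuple:
    """Hyperprior (mean, sd) per component, centered on labeled controls."""
    vals = [None, None]
    per_variant = np.zeros(len(data.variant_ids))
    counts = np.zeros(len(data.variant_ids))
    np.add.at(per_variant, data.v_idx, data.y)
    np.add.at(counts, data.v_idx, 1.0)
    with np.errstate(invalid="ignore"):
        vbar = np.where(counts > 0, per_variant / np.maximum(counts, 1), np.nan)
    pooled_sd = float(np.nanstd(vbar))
    if not np.isfinite(pooled_sd) or pooled_sd == 0:
        pooled_sd = 1.0
    for d in (0, 1):
        members = (data.labels == d) & data.has_theta
        if not members.any():
            raise IdentifiabilityError(
                f"no labeled variants with assay data in class {d}; "
                "supply mu hyperpriors explicitly or fix mu")
        class_vals = vbar[members]
        mean = float(np.mean(class_vals))
        sd = float(np.std(class_vals, ddof=1)) if members.sum() > 1 else 0.0
        if not np.isfinite(sd) or sd == 0:
            sd = pooled_sd
        vals[d] = (mean, 10.0 * sd)
    return vals[0], vals[1]


def _init_state(data: _FitData, config: ModelConfig, mu_priors, rng) -> dict:
    n = len(data.variant_ids)
    state: dict = {}
    fixed = config.fixed
    if "mu" in fixed:
        mu = np.array(fixed["mu"], dtype=float)
    elif mu_priors is not None:
        mu = np.array([mu_priors[0][0], mu_priors[1][0]])
    else:
        mu = np.array([0.0, 1.0])
    state["mu"] = mu
    state["tau2"] = np.array(fixed.get("tau2", (0.25, 0.25)), dtype=float)
    state["sigma_b2"] = float(fixed.get("sigma_b2", 0.1))
    state["sigma_e2"] = float(fixed.get("sigma_e2", 0.25))
    state["pi"] = float(fixed.get("pi", config.pi_a / (config.pi_a + config.pi_b)))

    D = np.where(data.labels >= 0, data.labels, -1)
    unlab = D < 0
    D = D.copy()
    D[unlab] = (rng.random(int(unlab.sum())) < state["pi"]).astype(int)
    state["D"] = D

    theta = np.zeros(n)
    beta = np.zeros(data.n_batches)
    if data.y is not None:
        sums = np.zeros(n)
        cnts = np.zeros(n)
        np.add.at(sums, data.v_idx, data.y)
        np.add.at(cnts, data.v_idx, 1.0)
        theta = np.where(cnts > 0, sums / np.maximum(cnts, 1), 0.0)
        if "sigma_e2" not in fixed:
            resid = data.y - theta[data.v_idx]
            state["sigma_e2"] = float(max(np.var(resid), 1e-3))
    state["theta"] = theta
    state["beta"] = beta

    if data.pc is not None:
        K = data.pc.shape[1]
        m = np.zeros((2, K))
        if "pc_means" in fixed:
            m = np.array(fixed["pc_means"], dtype=float)
        else:
            for d in (0, 1):
                sel = data.pc_mask & (D == d)
                if sel.any():
                    m[d] = data.pc[sel].mean(axis=0)
        state["pc_means"] = m
        state["pc_var"] = np.array(
            fixed.get("pc_var", np.ones(K)), dtype=float).reshape(K)
    return state


def _run_chain(data: _FitData, config: ModelConfig, mu_priors, rng,
               init: dict | None = None) -> dict:
    n = len(data.variant_ids)
    fixed = config.fixed
    use_function = data.y is not None
    use_pc = data.pc is not None

    state = {k: (np.array(v, copy=True) if isinstance(v, np.ndarray) else v)
             for k, v in (init or _init_state(data, config, mu_priors, rng)).items()}
    D = np.asarray(state["D"], dtype=int).copy()
    lab_mask = data.labels >= 0
    D[lab_mask] = data.labels[lab_mask]
    theta = np.asarray(state["theta"], dtype=float).copy()
    beta = np.asarray(state["beta"], dtype=float).copy()
    mu = np.asarray(state["mu"], dtype=float).copy()
    tau2 = np.asarray(state["tau2"], dtype=float).copy()
    sigma_b2, sigma_e2, pi = state["sigma_b2"], state["sigma_e2"], state["pi"]
    pc_means = np.asarray(state.get("pc_means", np.zeros((2, 1))), dtype=float).copy()
    pc_var = np.asarray(state.get("pc_var", np.ones(1)), dtype=float).copy()

    mu_dir = 0.0
    if mu_priors is not None and "mu" not in fixed:
        mu_dir = np.sign(mu_priors[1][0] - mu_priors[0][0])

    if use_function:
        n_v = np.zeros(n)
        np.add.at(n_v, data.v_idx, 1.0)
        assayed = data.has_theta
        n_obs = len(data.y)

    unlab = data.labels < 0
    n_kept = (config.n_iter - config.n_burn) // config.thin
    kept_D = np.zeros(n)
    kept_D2 = 0
    theta_sum = np.zeros(n)
    theta_sumsq = np.zeros(n)
    draws = {k: np.empty(n_kept) for k in
             ("mu0", "mu1", "tau2_0", "tau2_1", "sigma_b2", "sigma_e2", "pi")}
    D_draws = np.zeros((n_kept, n), dtype=np.int8)

    for it in range(config.n_iter):
        # --- D (collapsed over theta) then theta -------------------------
        log_odds = np.full(n, np.log(pi) - np.log1p(-pi))
        log_odds += data.family_lbf + data.agvgd_lbf
        if use_pc:
            lp = (_log_normal_pdf(data.pc, pc_means[1], pc_var).sum(axis=1)
                  - _log_normal_pdf(data.pc, pc_means[0], pc_var).sum(axis=1))
            log_odds[data.pc_mask] += lp[data.pc_mask]
        if use_function:
            r = data.y - beta[data.b_idx]
            r_sum = np.zeros(n)
            np.add.at(r_sum, data.v_idx, r)
            with np.errstate(divide="ignore", invalid="ignore"):
                rbar = np.where(assayed, r_sum / np.maximum(n_v, 1), 0.0)
                s0 = tau2[0] + sigma_e2 / np.maximum(n_v, 1)
                s1 = tau2[1] + sigma_e2 / np.maximum(n_v, 1)
            lp = (_log_normal_pdf(rbar, mu[1], s1)
                  - _log_normal_pdf(rbar, mu[0], s0))
            log_odds[assayed] += lp[assayed]
        if not np.all(np.isfinite(log_odds[unlab])):
            raise NumericsError(
                "non-finite full conditional for D; state: "
                f"mu={mu}, tau2={tau2}, sigma_b2={sigma_b2}, "
                f"sigma_e2={sigma_e2}, pi={pi}")
        p1 = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
        new_D = (rng.random(n) < p1).astype(int)
        D = np.where(unlab, new_D, data.labels)

        if use_function:
            prior_mu = mu[D]
            prior_tau2 = tau2[D]
            prec = 1.0 / prior_tau2 + n_v / sigma_e2
            mean = (prior_mu / prior_tau2 + r_sum / sigma_e2) / prec
            theta = mean + rng.standard_normal(n) / np.sqrt(prec)
            theta[~assayed] = 0.0

            # --- beta ----------------------------------------------------
            res_b = data.y - theta[data.v_idx]
            b_sum = np.zeros(data.n_batches)
            b_cnt = np.zeros(data.n_batches)
            np.add.at(b_sum, data.b_idx, res_b)
            np.add.at(b_cnt, data.b_idx, 1.0)
            prec_b = 1.0 / sigma_b2 + b_cnt / sigma_e2
            mean_b = (b_sum / sigma_e2) / prec_b
            beta = mean_b + rng.standard_normal(data.n_batches) / np.sqrt(prec_b)

            # translation-group move: the likelihood only constrains
            # theta_v + beta_b, so the common level (theta + c, beta - c)
            # mixes slowly under one-at-a-time updates; resample it directly
            # from its Gaussian conditional (the y-term is shift-invariant)
            inv_tau = 1.0 / tau2[D[assayed]]
            prec_c = inv_tau.sum() + data.n_batches / sigma_b2
            mean_c = (((mu[D[assayed]] - theta[assayed]) * inv_tau).sum()
                      + beta.sum() / sigma_b2) / prec_c
            c_shift = mean_c + rng.standard_normal() / np.sqrt(prec_c)
            theta[assayed] += c_shift
            beta -= c_shift

            # --- mu, tau2 ------------------------------------------------
            if "mu" not in fixed:
                prop = mu.copy()
                for _attempt in range(10):
                    for d in (0, 1):
                        members = assayed & (D == d)
                        pm, psd = mu_priors[d]
                        prec_m = 1.0 / psd ** 2 + members.sum() / tau2[d]
                        mean_m = (pm / psd ** 2
                                  + theta[members].sum() / tau2[d]) / prec_m
                        prop[d] = mean_m + rng.standard_normal() / np.sqrt(prec_m)
                    if mu_dir == 0 or np.sign(prop[1] - prop[0]) == mu_dir:
                        mu = prop
                        break
                else:
                    logger.warning("component-mean ordering guard engaged; "
                                   "keeping previous draw")
            if "tau2" not in fixed:
                for d in (0, 1):
                    members = assayed & (D == d)
                    ss = float(((theta[members] - mu[d]) ** 2).sum())
                    shape = config.tau_shape + members.sum() / 2.0
                    rate = config.tau_rate + ss / 2.0
                    tau2[d] = rate / rng.gamma(shape, 1.0)

            # --- sigma_b2, sigma_e2 -------------------------------------
            if "sigma_b2" not in fixed:
                shape = config.sigma_b_shape + data.n_batches / 2.0
                rate = config.sigma_b_rate + float((beta ** 2).sum()) / 2.0
                sigma_b2 = rate / rng.gamma(shape, 1.0)
            if "sigma_e2" not in fixed:
                resid = data.y - theta[data.v_idx] - beta[data.b_idx]
                shape = config.sigma_e_shape + n_obs / 2.0
                rate = config.sigma_e_rate + float((resid ** 2).sum()) / 2.0
                sigma_e2 = rate / rng.gamma(shape, 1.0)

        # --- PC class-conditional model ----------------------------------
        if use_pc:
            K = data.pc.shape[1]
            if "pc_means" not in fixed:
                for d in (0, 1):
                    sel = data.pc_mask & (D == d)
                    cnt = int(sel.sum())
                    prec = 1.0 / config.pc_mean_sd ** 2 + cnt / pc_var
                    mean = (data.pc[sel].sum(axis=0) / pc_var) / prec
                    pc_means[d] = mean + rng.standard_normal(K) / np.sqrt(prec)
            if "pc_var" not in fixed:
                sel = data.pc_mask
                dev = data.pc[sel] - pc_means[D[sel]]
                shape = config.pc_var_shape + sel.sum() / 2.0
                rate = config.pc_var_rate + (dev ** 2).sum(axis=0) / 2.0
                pc_var = rate / rng.gamma(shape, np.ones(K))

        # --- pi -----------------------------------------------------------
        # prevalence is informed by the unlabeled variants only: the labeled
        # controls are chosen by study design, not sampled from the VUS
        # population, so their class split carries no prevalence information
        if "pi" not in fixed:
            n1 = int(D[unlab].sum())
            n_u = int(unlab.sum())
            pi = rng.beta(config.pi_a + n1, config.pi_b + n_u - n1)

        # --- record -------------------------------------------------------
        if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
            j = (it - config.n_burn) // config.thin
            kept_D += D
            kept_D2 += 1
            theta_sum += theta
            theta_sumsq += theta ** 2
            D_draws[j] = D
            draws["mu0"][j] = mu[0]
            draws["mu1"][j] = mu[1]
            draws["tau2_0"][j] = tau2[0]
            draws["tau2_1"][j] = tau2[1]
            draws["sigma_b2"][j] = sigma_b2
            draws["sigma_e2"][j] = sigma_e2
            draws["pi"][j] = pi

    final_state = dict(D=D, theta=theta, beta=beta, mu=mu, tau2=tau2,
                       sigma_b2=sigma_b2, sigma_e2=sigma_e2, pi=pi,
                       pc_means=pc_means if use_pc else None,
                       pc_var=pc_var if use_pc else None)
    final_state = {k: v for k, v in final_state.items() if v is not None}
    return dict(
        prob=kept_D / max(kept_D2, 1),
        theta_mean=theta_sum / max(kept_D2, 1),
        theta_sq=theta_sumsq / max(kept_D2, 1),
        draws=draws,
        D_draws=D_draws,
        n_kept=n_kept,
        final_state=final_state,
    )


def _mcmc_diagnostics(param_draws: dict, threshold: float) -> dict:
    """Split-chain R-hat and bulk ESS per scalar parameter (via ArviZ)."""
    import arviz as az

    diag = {}
    flagged = []
    for name, arr in param_draws.items():
        if arr.shape[0] * arr.shape[1] < 8 or np.allclose(arr.std(), 0):
            continue
        ds = az.convert_to_dataset(np.asarray(arr, dtype=float))
        rhat = float(az.rhat(ds)["x"].values)
        ess = float(az.ess(ds)["x"].values)
        diag[name] = {"rhat": rhat, "ess": ess}
        if np.isfinite(rhat) and rhat > threshold:
            flagged.append(name)
    diag["converged"] = not flagged
    diag["flagged"] = flagged
    return diag


def fit(assay: pd.DataFrame | None, evidence: pd.DataFrame | None,
        config: ModelConfig, init_states: list | None = None,
        diagnostics: bool = True) -> PosteriorSummary:
    """Fit the hierarchical classification model by Gibbs sampling.

    Parameters
    ----------
    assay
        Within-batch mean table (``variant_id, batch_id, mean_log_ratio,
        n_replicates, label``) or a replicate-level table, which is averaged
        first.  May be None when ``function`` is not in the evidence set.
    evidence
        Per-variant evidence table (PC scores, family log Bayes factor,
        Align-GVGD probability, label); may be None.
    config
        Priors, evidence set, MCMC settings and thresholds.
    init_states
        Optional warm-start states, one per chain (e.g. the final states of a
        previous fit); burn-in is still discarded.
    """
    data = _assemble(assay, evidence, config)
    use_function = data.y is not None

    mu_priors = None
    if use_function:
        if config.mu0_mean is not None and config.mu1_mean is not None:
            mu_priors = ((config.mu0_mean, config.mu0_sd or 1.0),
                         (config.mu1_mean, config.mu1_sd or 1.0))
        elif "mu" in config.fixed:
            m = config.fixed["mu"]
            mu_priors = ((float(m[0]), 1.0), (float(m[1]), 1.0))
        else:
            mu_priors = _derive_mu_priors(data, config)

    ss = np.random.SeedSequence(config.seed)
    chains = []
    for c, child in enumerate(ss.spawn(config.n_chains)):
        rng = np.random.default_rng(child)
        init = init_states[c] if init_states else None
        chains.append(_run_chain(data, config, mu_priors, rng, init=init))

    n = len(data.variant_ids)
    n_kept_total = sum(ch["n_kept"] for ch in chains)
    prob = sum(ch["prob"] * ch["n_kept"] for ch in chains) / n_kept_total
    theta_mean = sum(ch["theta_mean"] * ch["n_kept"] for ch in chains) / n_kept_total
    theta_sq = sum(ch["theta_sq"] * ch["n_kept"] for ch in chains) / n_kept_total
    theta_sd = np.sqrt(np.maximum(theta_sq - theta_mean ** 2, 0.0))

    M = n_kept_total
    clipped = np.clip(prob, 1.0 / (M + 1), M / (M + 1.0))
    log_odds = np.log(clipped) - np.log1p(-clipped)
    calls = [classify(p, config) for p in prob]
    label_names = {0: io_tables.BENIGN, 1: io_tables.PATHOGENIC,
                   -1: io_tables.UNLABELED}
    df = pd.DataFrame({
        "variant_id": data.variant_ids,
        "prob_pathogenic": prob,
        "log_odds": log_odds,
        "call": calls,
        "theta_mean": theta_mean if use_function else np.nan,
        "theta_sd": theta_sd if use_function else np.nan,
        "label": [label_names[code] for code in data.labels],
    })

    param_draws = {
        k: np.stack([ch["draws"][k] for ch in chains])
        for k in chains[0]["draws"]
    }
    params = {k: float(v.mean()) for k, v in param_draws.items()}
    prob_by_chain = np.stack([ch["prob"] for ch in chains])

    diag: dict = {}
    if diagnostics and use_function and config.n_chains > 1:
        diag = _mcmc_diagnostics(param_draws, config.rhat_threshold)

    return PosteriorSummary(
        df=df,
        params=params,
        param_draws=param_draws,
        prob_by_chain=prob_by_chain,
        diagnostics=diag,
        n_retained=M,
        config=config,
        final_states=[ch["final_state"] for ch in chains],
    )
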