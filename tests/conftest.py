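import numpy as np
import pandas as pd
import pytest

import varcallxt as vx
from varcallxt import io_tables


@pytest.fixture(scope="session")
def tiny_batch_means() -> pd.DataFrame:
    """3 variants (one per class plus one unlabeled) in 2 batches."""
    rows = [
        ("b1", "x1", 0.10, io_tables.BENIGN),
        ("b1", "x2", -0.05, io_tables.BENIGN),
        ("p1", "x1", -2.90, io_tables.PATHOGENIC),
        ("p1", "x2", -3.10, io_tables.PATHOGENIC),
        ("u1", "x1", -1.20, io_tables.UNLABELED),
        ("u1", "x2", -1.50, io_tables.UNLABELED),
    ]
    df = pd.DataFrame(rows, columns=["variant_id", "batch_id",
                                     "mean_log_ratio", "label"])
    df["n_replicates"] = 1
    return df


#: point-mass hyperparameters for the tiny instance (benign component at 0,
#: damaging at -3)
TINY_FIXED = dict(mu=(0.0, -3.0), tau2=(0.25, 0.25), sigma_b2=0.04,
                  sigma_e2=0.09, pi=0.5)


def exact_posterior_probs(batch_means: pd.DataFrame, fixed: dict,
                          family_lbf: dict | None = None) -> dict[str, float]:
    """Exact Pr(D=1 | y) for unlabeled variants at fixed hyperparameters.

    Independent oracle: enumerates every configuration of the unlabeled
    indicators and evaluates the marginal multivariate-normal likelihood of
    the batch-mean vector with theta and beta integrated out in closed form.
    """
    from itertools import product

    from scipy.stats import multivariate_normal

    variants = sorted(batch_means["variant_id"].unique())
    batches = sorted(batch_means["batch_id"].unique())
    label_of = dict(zip(batch_means["variant_id"], batch_means["label"]))
    v_idx = batch_means["variant_id"].map(variants.index).to_numpy()
    b_idx = batch_means["batch_id"].map(batches.index).to_numpy()
    y = batch_means["mean_log_ratio"].to_numpy(dtype=float)
    n_obs = len(y)
    Zt = np.zeros((n_obs, len(variants)))
    Zb = np.zeros((n_obs, len(batches)))
    Zt[np.arange(n_obs), v_idx] = 1.0
    Zb[np.arange(n_obs), b_idx] = 1.0

    unlabeled = [v for v in variants if label_of[v] == io_tables.UNLABELED]
    mu = np.asarray(fixed["mu"])
    tau2 = np.asarray(fixed["tau2"])
    pi = fixed["pi"]
    lbf = family_lbf or {}

    log_weights = []
    configs = list(product((0, 1), repeat=len(unlabeled)))
    for conf in configs:
        code = {io_tables.BENIGN: 0, io_tables.PATHOGENIC: 1}
        D = np.array([
            code[label_of[v]] if label_of[v] in code
            else conf[unlabeled.index(v)]
            for v in variants
        ])
        mean = Zt @ mu[D]
        cov = (Zt @ np.diag(tau2[D]) @ Zt.T
               + fixed["sigma_b2"] * Zb @ Zb.T
               + fixed["sigma_e2"] * np.eye(n_obs))
        lp = multivariate_normal(mean, cov).logpdf(y)
        for v, d in zip(unlabeled, conf):
            lp += d * np.log(pi) + (1 - d) * np.log(1 - pi)
            lp += d * lbf.get(v, 0.0)
        log_weights.append(lp)
    log_weights = np.array(log_weights)
    log_norm = np.logaddexp.reduce(log_weights)
    probs = {}
    for j, v in enumerate(unlabeled):
        sel = np.array([conf[j] == 1 for conf in configs])
        probs[v] = float(np.exp(
            np.logaddexp.reduce(log_weights[sel]) - log_norm))
    return probs


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated draw of the small recovery preset (batch means ready)."""
    assay, evidence, truth = vx.simulate_dataset(
        vx.PRESETS["small"].replace(seed=42))
    return io_tables.average_within_batch(assay), evidence, truth
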