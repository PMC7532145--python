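"""Bayesian logistic model for dichotomized biomarkers with treatment interactions.

The model has the eight fixed terms

    logit P(pCR) = b0 + b_HR*HR + b_HER2*HER2 + b_bm*biomarker + b_trt*T
                   + b_trt:HR*T*HR + b_trt:HER2*T*HER2 + b_trt:bm*T*biomarker

with independent normal(0, sd) priors on every coefficient (sd = 3 by
default, weakly informative on the logit scale). The posterior is sampled by
a self-contained adaptive random-walk Metropolis scheme: the proposal
covariance is the Laplace approximation at the posterior mode, rescaled
during burn-in toward a standard multivariate acceptance rate. Because every
covariate is binary, the likelihood aggregates over the (at most 16) distinct
covariate rows, so each posterior evaluation is O(16) regardless of cohort
size.

Subgroup pCR rates are posterior predictive means: for each retained draw the
inverse-logit linear predictor is averaged over the observed covariate rows
of the subgroup, giving a posterior distribution of that subgroup's pCR rate
whose mean and central 95% interval are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import ClinicalTable

TERMS = (
    "intercept", "hr", "her2", "biomarker",
    "treatment", "treatment:hr", "treatment:her2", "treatment:biomarker",
)


@dataclass
class BayesModelSpec:
    """Priors and MCMC settings for the eight-term logistic model."""

    prior_sd: float = 3.0
    chains: int = 4
    iterations: int = 20000
    burn_in: int = 5000
    thin: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.prior_sd <= 0:
            raise ValueError("prior sd must be > 0")
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")


@dataclass
class SubsetEstimate:
    """Posterior distribution of one subgroup's pCR rate."""

    name: str
    draws: np.ndarray
    mean: float
    ci95: tuple[float, float]
    n_patients: int


@dataclass
class PosteriorSummary:
    """Retained MCMC draws plus convergence diagnostics.

    ``draws``: (retained iterations x 8) coefficient frame (chains stacked);
    ``rhat`` / ``ess``: split-R-hat and effective sample size per
    coefficient; ``converged`` is True when every R-hat < 1.05 and every
    ESS >= 400.
    """

    draws: pd.DataFrame
    chain_draws: np.ndarray  # (chains, retained-per-chain, 8)
    rhat: pd.Series
    ess: pd.Series
    converged: bool
    accept_rate: float
    spec: BayesModelSpec
    flags: list[str] = field(default_factory=list)
    subset_estimates: dict[str, SubsetEstimate] = field(default_factory=dict)


def build_design(clinical: ClinicalTable, biomarker_bin: pd.Series,
                 allow_continuous: bool = False) -> pd.DataFrame:
    """Assemble the eight-column design matrix from clinical + binary biomarker.

    ``biomarker_bin`` must be 0/1 (a continuous biomarker is permitted only
    behind ``allow_continuous=True``); patients with a missing biomarker are
    dropped.
    """
    bm = biomarker_bin.reindex(clinical.patient_ids).dropna()
    vals = bm.unique()
    if not allow_continuous and not set(np.unique(vals)).issubset({0.0, 1.0, 0, 1}):
        raise ValueError("biomarker_bin must be coded 0/1 (use allow_continuous to override)")
    df = clinical.df.loc[bm.index]
    trt = (df["arm"] == "treated").astype(float)
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "hr": df["hr"].astype(float),
            "her2": df["her2"].astype(float),
            "biomarker": bm.astype(float),
            "treatment": trt,
            "treatment:hr": trt * df["hr"],
            "treatment:her2": trt * df["her2"],
            "treatment:biomarker": trt * bm.astype(float),
        },
        index=bm.index,
    )
    return X


def _aggregate(X: np.ndarray, y: np.ndarray):
    """Collapse to unique covariate rows: (rows, trials, events)."""
    rows, inv = np.unique(X, axis=0, return_inverse=True)
    trials = np.bincount(inv, minlength=len(rows)).astype(float)
    events = np.bincount(inv, weights=y, minlength=len(rows))
    return rows, trials, events


def _log_post(beta: np.ndarray, rows, trials, events, prior_sd: float) -> np.ndarray:
    """Log posterior, vectorized over the last axis of ``beta`` (8 x chains)."""
    eta = rows @ beta
    ll = events @ eta - trials @ np.logaddexp(0.0, eta)
    return ll - 0.5 * (beta**2).sum(axis=0) / prior_sd**2


def _laplace_mode(rows, trials, events, prior_sd: float, p: int):
    """Posterior mode and covariance by damped Newton on the log posterior."""
    beta = np.zeros(p)
    prec0 = np.eye(p) / prior_sd**2
    for _ in range(100):
        eta = rows @ beta
        mu = expit(eta)
        grad = rows.T @ (events - trials * mu) - beta / prior_sd**2
        w = trials * mu * (1 - mu)
        H = (rows * w[:, None]).T @ rows + prec0
        step = np.linalg.solve(H, grad)
        if np.max(np.abs(step)) > 5.0:
            step *= 5.0 / np.max(np.abs(step))
        beta = beta + step
        if np.max(np.abs(grad)) < 1e-8:
            break
    eta = rows @ beta
    mu = expit(eta)
    w = trials * mu * (1 - mu)
    H = (rows * w[:, None]).T @ rows + prec0
    return beta, np.linalg.inv(H)


def sample_posterior(design: pd.DataFrame, outcome, spec: BayesModelSpec | None = None
                     ) -> PosteriorSummary:
    """Sample the logistic posterior by adaptive random-walk Metropolis.

    Works for any number of rows, including zero (the posterior is then the
    prior). Zero events is flagged (prior-dominated) but still sampled. The
    chains start from the posterior mode plus dispersed noise; the proposal
    is the Laplace covariance scaled by 2.38^2/d, with the scale adapted
    during burn-in toward ~25% acceptance.
    """
    spec = spec or BayesModelSpec()
    X = design.to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float)
    p = X.shape[1] if X.ndim == 2 and X.shape[0] else len(design.columns)
    names = list(design.columns)
    flags: list[str] = []

    if len(y) == 0:
        rows = np.zeros((0, p))
        trials = np.zeros(0)
        events = np.zeros(0)
        mode = np.zeros(p)
        cov = np.eye(p) * spec.prior_sd**2
        flags.append("no_data")
    else:
        rows, trials, events = _aggregate(X, y)
        if events.sum() == 0 or events.sum() == trials.sum():
            flags.append("prior_dominated")
        if np.linalg.matrix_rank(X) < p:
            flags.append("rank_deficient")
        mode, cov = _laplace_mode(rows, trials, events, spec.prior_sd, p)

    rng = np.random.default_rng(spec.seed)
    nchain = spec.chains
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    scale = 2.38 / np.sqrt(p)
    beta = mode[:, None] + L @ rng.standard_normal((p, nchain)) * 1.0
    lp = _log_post(beta, rows, trials, events, spec.prior_sd)

    kept = []
    n_accept = 0
    n_prop = 0
    adapt_block = 200
    block_accept = 0
    for it in range(spec.iterations):
        prop = beta + scale * (L @ rng.standard_normal((p, nchain)))
        lp_prop = _log_post(prop, rows, trials, events, spec.prior_sd)
        accept = np.log(rng.uniform(size=nchain)) < lp_prop - lp
        beta = np.where(accept, prop, beta)
        lp = np.where(accept, lp_prop, lp)
        block_accept += int(accept.sum())
        if it >= spec.burn_in:
            n_accept += int(accept.sum())
            n_prop += nchain
            if (it - spec.burn_in) % spec.thin == 0:
                kept.append(beta.T.copy())
        elif (it + 1) % adapt_block == 0:
            rate = block_accept / (adapt_block * nchain)
            scale *= np.exp(rate - 0.25)
            block_accept = 0

    # kept entries are (nchain, p); stack and reorder to (nchain, n_kept, p)
    chain_draws = np.transpose(np.stack(kept, axis=0), (1, 0, 2))
    draws = pd.DataFrame(chain_draws.reshape(-1, p), columns=names)

    idata = az.from_dict(posterior={n: chain_draws[:, :, j] for j, n in enumerate(names)})
    rhat = az.rhat(idata).to_pandas().reindex(names)
    ess = az.ess(idata).to_pandas().reindex(names)
    converged = bool((rhat < 1.05).all() and (ess >= 400).all())
    if not converged:
        flags.append("nonconverged")

    return PosteriorSummary(
        draws=draws,
        chain_draws=chain_draws,
        rhat=rhat,
        ess=ess,
        converged=converged,
        accept_rate=n_accept / max(n_prop, 1),
        spec=spec,
        flags=flags,
    )


def subset_pcr_estimate(posterior: PosteriorSummary, design: pd.DataFrame,
                        mask, name: str = "subset") -> SubsetEstimate:
    """Posterior predictive pCR rate of the patients selected by ``mask``.

    For each retained draw, the inverse-logit linear predictor is computed
    for every selected patient row and averaged, yielding a posterior draw of
    the subgroup rate. An empty subgroup is fatal.
    """
    mask = np.asarray(mask, dtype=bool)
    Xs = design.to_numpy(dtype=float)[mask]
    if Xs.shape[0] == 0:
        raise ValueError(f"empty subset: {name!r}")
    B = posterior.draws.to_numpy()  # draws x p
    rate_draws = expit(Xs @ B.T).mean(axis=0)
    lo, hi = np.percentile(rate_draws, [2.5, 97.5])
    return SubsetEstimate(
        name=name,
        draws=rate_draws,
        mean=float(rate_draws.mean()),
        ci95=(float(lo), float(hi)),
        n_patients=int(Xs.shape[0]),
    )


def subset_mask(design: pd.DataFrame, clinical: ClinicalTable,
                subset: str = "all", biomarker: int | None = None,
                arm: str | None = None) -> np.ndarray:
    """Boolean mask over design rows for a (receptor subset, biomarker, arm) cell."""
    df = clinical.df.reindex(design.index)
    m = clinical.subset_mask(subset).reindex(design.index).to_numpy()
    if biomarker is not None:
        m = m & (design["biomarker"].to_numpy() == float(biomarker))
    if arm is not None:
        m = m & (df["arm"] == arm).to_numpy()
    return m
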