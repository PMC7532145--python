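"""Logistic-regression biomarker screening against a binary pCR outcome.

Four pre-specified model forms are screened per biomarker:

- arm-wise (``treated_arm`` / ``control_arm``): ``pCR ~ biomarker`` within one
  arm (optionally within a receptor subset), testing the biomarker slope;
- ``interaction``: ``pCR ~ treatment + biomarker + treatment:biomarker`` on
  both arms, testing the interaction term;
- ``interaction_adjusted``: the interaction model with additive HR and HER2
  receptor-status adjustments.

All tests are likelihood-ratio chi-square tests with one degree of freedom,
reported as descriptive p-values (no multiplicity correction at the screening
stage). Fits are maximum likelihood by Newton-Raphson; (quasi-)separated or
nonconvergent fits are refit with a tiny ridge and flagged rather than
dropped, so small subsets still yield a reportable result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .data_model import ClinicalTable, OmicsMatrix

logger = logging.getLogger(__name__)

POPULATIONS = ("treated_arm", "control_arm", "interaction", "interaction_adjusted")

#: |coefficient| on the standardized-predictor scale beyond which a fit is
#: treated as (quasi-)separated.
SEPARATION_COEF = 15.0
RIDGE_EPS = 1e-4


@dataclass
class LogisticFit:
    """A fitted logistic model: coefficients, log-likelihood, and health flags."""

    params: pd.Series
    log_likelihood: float
    converged: bool
    separation_flag: bool
    n: int
    n_events: int
    dropped_terms: list[str] = field(default_factory=list)
    patient_ids: tuple | None = None


def _newton_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                     tol: float = 1e-8, max_iter: int = 100):
    """Newton-Raphson MLE with optional ridge on all coefficients.

    Returns (beta, penalized log-likelihood is NOT returned; the plain
    log-likelihood is), convergence flag. Step-halving keeps the likelihood
    monotone.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ybar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    if np.allclose(X[:, 0], 1.0):
        beta[0] = np.log(ybar / (1 - ybar))

    def negpen_ll(b):
        eta = X @ b
        return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * ridge * b @ b)

    ll = negpen_ll(beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu) - ridge * beta
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = mu * (1 - mu)
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_cand = negpen_ll(cand)
            if ll_cand >= ll - 1e-12:
                break
            t /= 2.0
        beta, ll = cand, ll_cand
    eta = X @ beta
    llf = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return beta, llf, converged


def fit_logistic(outcome, design: pd.DataFrame, penalty: float = 0.0) -> LogisticFit:
    """Maximum-likelihood logistic fit of ``outcome ~ design``.

    ``design`` must contain an intercept column if one is wanted. Constant
    non-intercept columns are dropped (and logged). On detected separation
    (any standardized |coefficient| > 15, or nonconvergence) the model is
    refit with ridge 1e-4 on the standardized scale and flagged. A constant
    outcome raises ``ValueError("degenerate outcome")``.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate outcome")
    X = design.to_numpy(dtype=float)
    names = list(design.columns)
    n = len(y)

    # drop constant columns, keeping a single intercept
    keep, dropped, seen_const = [], [], False
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0.0:
            if not seen_const and X[0, j] != 0.0:
                keep.append(j)
                seen_const = True
            else:
                dropped.append(name)
        else:
            keep.append(j)
    if dropped:
        logger.debug("fit_logistic: dropped constant column(s) %s", dropped)
    X = X[:, keep]
    names = [names[j] for j in keep]
    if n < X.shape[1] + 1:
        raise ValueError(f"n={n} too small for {X.shape[1]} columns")

    # standardize non-constant columns internally: Newton tolerance and the
    # separation threshold are both defined on this scale
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    center = X.mean(axis=0)
    is_icpt = np.ptp(X, axis=0) == 0.0
    center[is_icpt] = 0.0
    scale[is_icpt] = 1.0
    Z = (X - center) / scale

    beta_z, llf, converged = _newton_logistic(Z, y, ridge=penalty)
    separation = (not converged) or bool(np.any(np.abs(beta_z[~is_icpt]) > SEPARATION_COEF))
    if separation and penalty == 0.0:
        beta_z, llf, converged = _newton_logistic(Z, y, ridge=RIDGE_EPS)

    # back-transform to the raw predictor scale
    beta = beta_z / scale
    if is_icpt.any():
        j0 = int(np.flatnonzero(is_icpt)[0])
        beta[j0] = beta_z[j0] / X[0, j0] - float((beta * center).sum()) / X[0, j0]

    return LogisticFit(
        params=pd.Series(beta, index=names),
        log_likelihood=llf,
        converged=converged,
        separation_flag=separation,
        n=n,
        n_events=int(y.sum()),
        dropped_terms=dropped,
        patient_ids=tuple(design.index) if design.index is not None else None,
    )


def lr_pvalue(full: LogisticFit, reduced: LogisticFit) -> tuple[float, int]:
    """Likelihood-ratio test of nested logistic fits: (p-value, df).

    The statistic ``2 * (ll_full - ll_reduced)`` is clipped at zero and
    referred to chi-square with df = difference in fitted term counts.
    Mismatched patient sets are fatal.
    """
    full_terms = set(full.params.index)
    red_terms = set(reduced.params.index)
    if not red_terms <= full_terms:
        raise ValueError("reduced-model terms are not a subset of the full model")
    if full.patient_ids is not None and reduced.patient_ids is not None:
        if full.patient_ids != reduced.patient_ids:
            raise ValueError("mismatched patient sets between full and reduced fits")
    elif (full.n, full.n_events) != (reduced.n, reduced.n_events):
        raise ValueError("mismatched patient sets between full and reduced fits")
    df = len(full.params) - len(reduced.params)
    if df == 0:
        return 1.0, 0
    stat = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    return float(chi2.sf(stat, df)), df


@dataclass
class AssociationResult:
    """One biomarker under one model form: direction, LR p, and counts."""

    biomarker: str
    population: str
    subset: str
    direction: int
    lr_p: float
    n: int
    n_pcr: int
    flags: list[str] = field(default_factory=list)

    def neglog10_p(self) -> float:
        return float(-np.log10(max(self.lr_p, 1e-300)))


def _screen_frames(biomarker: pd.Series, clinical: ClinicalTable,
                   population: str, subset: str):
    """Assemble (y, full design, reduced design) for one screen."""
    mask = clinical.subset_mask(subset)
    if population in ("treated_arm", "control_arm"):
        arm = "treated" if population == "treated_arm" else "control"
        mask = mask & (clinical.df["arm"] == arm)
    df = clinical.df.loc[mask]
    bm = biomarker.reindex(df.index)
    ok = bm.notna()
    df, bm = df.loc[ok], bm.loc[ok]

    y = df["pcr"].to_numpy(dtype=float)
    icpt = pd.Series(1.0, index=df.index, name="intercept")
    if population in ("treated_arm", "control_arm"):
        full = pd.DataFrame({"intercept": icpt, "biomarker": bm})
        reduced = full[["intercept"]]
        tested = "biomarker"
    elif population in ("interaction", "interaction_adjusted"):
        trt = (df["arm"] == "treated").astype(float)
        cols = {"intercept": icpt, "treatment": trt, "biomarker": bm,
                "treatment:biomarker": trt * bm}
        if population == "interaction_adjusted":
            cols["hr"] = df["hr"].astype(float)
            cols["her2"] = df["her2"].astype(float)
        full = pd.DataFrame(cols)
        reduced = full.drop(columns=["treatment:biomarker"])
        tested = "treatment:biomarker"
    else:
        raise ValueError(f"unknown population: {population!r}")
    return y, full, reduced, tested


def screen(biomarker: pd.Series, clinical: ClinicalTable, population: str,
           subset: str = "all") -> AssociationResult:
    """Screen one biomarker under one pre-specified model form.

    Complete-case per biomarker: patients missing this feature are excluded
    from this screen only. Small subsets (< 10 patients or < 3 events) are
    flagged "underpowered" with the p-value still reported; a degenerate fit
    (constant biomarker or constant outcome) yields a flagged null result
    with ``lr_p = 1``.
    """
    name = biomarker.name if biomarker.name is not None else "biomarker"
    y, full, reduced, tested = _screen_frames(biomarker, clinical, population, subset)
    n, n_pcr = len(y), int(y.sum())
    flags = []
    if n < 10 or n_pcr < 3 or (n - n_pcr) < 3:
        flags.append("underpowered")
    try:
        fit_full = fit_logistic(y, full)
        fit_red = fit_logistic(y, reduced)
        if tested not in fit_full.params.index:
            raise ValueError("tested term dropped (constant)")
        p, _ = lr_pvalue(fit_full, fit_red)
        direction = int(np.sign(fit_full.params[tested]))
        if fit_full.separation_flag:
            flags.append("separation")
        if not (fit_full.converged and fit_red.converged):
            flags.append("nonconverged")
    except ValueError as exc:
        flags.append(f"degenerate:{exc}")
        p, direction = 1.0, 0
    return AssociationResult(str(name), population, subset, direction, p, n, n_pcr, flags)


def screen_all(matrix: OmicsMatrix, clinical: ClinicalTable, population: str,
               subset: str = "all", alpha: float = 0.05
               ) -> tuple[pd.DataFrame, int]:
    """Screen every feature of a matrix; report the count passing ``alpha``.

    Returns a tidy results frame (one row per feature, descriptive p-values,
    no multiplicity correction) and the number of features with
    ``lr_p < alpha``.
    """
    rows = []
    for fid in matrix.feature_ids:
        res = screen(matrix.values.loc[fid], clinical, population, subset)
        rows.append({
            "biomarker": res.biomarker, "population": res.population,
            "subset": res.subset, "direction": res.direction, "lr_p": res.lr_p,
            "neglog10_p": res.neglog10_p(), "n": res.n, "n_pCR": res.n_pcr,
            "flags": ";".join(res.flags),
        })
    table = pd.DataFrame(rows, columns=["biomarker", "population", "subset",
                                        "direction", "lr_p", "neglog10_p",
                                        "n", "n_pCR", "flags"])
    n_pass = int((table["lr_p"] < alpha).sum()) if len(table) else 0
    return table, n_pass


def signature_score(expression: OmicsMatrix, gene_set) -> pd.Series:
    """Per-patient mean of median-centered member-gene expression rows.

    Genes absent from the matrix are logged and skipped; no overlap at all is
    fatal.
    """
    present = [g for g in gene_set if g in expression.feature_ids]
    missing = [g for g in gene_set if g not in expression.feature_ids]
    if not present:
        raise ValueError(f"no gene of the set present in the matrix: {list(gene_set)}")
    if missing:
        logger.warning("signature_score: %d gene(s) not in matrix: %s",
                       len(missing), missing[:10])
    sub = expression.values.loc[present]
    centered = sub.sub(sub.median(axis=1), axis=0)
    return centered.mean(axis=0)
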