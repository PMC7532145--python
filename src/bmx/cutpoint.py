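"""Cross-validated optimal-cutpoint dichotomization of a continuous biomarker.

Candidate thresholds are the midpoints between consecutive distinct observed
values (with a minimum group size on each side). Twofold cross-validation,
stratified on the binary pCR outcome, is repeated many times (500 by
default); in every fold each candidate dichotomizes the biomarker and a
logistic likelihood-ratio test of ``pCR ~ 1{biomarker > c}`` yields a
p-value. Per candidate the test-fold p-values are combined with the
Mudholkar-George logit method; the candidate with the minimum combined
test-set p is selected as "optimal", subject to a stability filter: it must
also have been the argmin-p candidate in the training sets at least
``stability_min`` of the repeats (10/500 by default), else no cutpoint is
declared.

For a single binary predictor the logistic LR statistic has a closed form:
it equals the 2x2 G-test statistic ``2 * sum O * log(O/E)``. The search
exploits this identity to evaluate all candidates in every fold with array
arithmetic; the identity itself is asserted against the full Newton fit in
the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.special import logit as _logit
from scipy.stats import chi2
from scipy.stats import t as t_dist

P_CLIP = 1e-15


def _t_logsf(T: float, df: float) -> float:
    """log of the upper-tail t probability, stable for extreme statistics.

    scipy's ``t.logsf`` underflows to -inf once the tail probability drops
    below the smallest double; beyond that the first-order asymptotic tail
    ``sf(T) ~ C(df) * df / ((df-1) T) * (1 + T^2/df)^(-(df-1)/2)`` is used
    (relative error O(T^-2), ample for ordering and reporting log p-values).
    """
    exact = float(t_dist.logsf(T, df))
    if np.isfinite(exact):
        return exact
    logC = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)
    return float(logC + np.log(df / ((df - 1) * T))
                 - 0.5 * (df - 1) * np.log1p(T**2 / df))


def candidate_cutpoints(values, min_group: int = 5) -> np.ndarray:
    """Midpoints between consecutive distinct values, min_group per side.

    Candidates are restricted so that dichotomizing at any of them leaves at
    least ``min_group`` observations on each side. Fewer than ``2*min_group``
    finite values, or all values identical, is fatal.
    """
    x = np.asarray(values, dtype=float)
    x = np.sort(x[np.isfinite(x)])
    n = len(x)
    if n < 2 * min_group:
        raise ValueError(f"need at least {2 * min_group} finite values, got {n}")
    distinct = np.unique(x)
    if len(distinct) < 2:
        raise ValueError("all values identical; no cutpoint possible")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    low = np.searchsorted(x, mids, side="left")   # count of values < mid
    high = n - low
    mids = mids[(low >= min_group) & (high >= min_group)]
    if len(mids) == 0:
        raise ValueError("no candidate satisfies the min_group constraint")
    return mids


def combine_pvalues_logit(ps, log: bool = False) -> float:
    """Combine p-values by the Mudholkar-George logit method.

    ``T = -sum(logit(p_i)) * sqrt(3 * (5k+4) / (k * pi^2 * (5k+2)))`` referred
    to the upper tail of a t distribution with ``5k + 4`` degrees of freedom.
    p-values at 0 or 1 are clipped to [1e-15, 1 - 1e-15] with a warning.
    With ``log=True`` the natural log of the combined p is returned, which
    stays finite when combining many small p-values would underflow.
    """
    p = np.asarray(ps, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1-D list of p-values")
    if (p <= 0).any() or (p >= 1).any():
        warnings.warn("p-value at 0 or 1 clipped before logit combination",
                      stacklevel=2)
        p = np.clip(p, P_CLIP, 1 - P_CLIP)
    k = len(p)
    scale = np.sqrt(3.0 * (5 * k + 4) / (k * np.pi**2 * (5 * k + 2)))
    T = -_logit(p).sum() * scale
    if log:
        return _t_logsf(T, 5 * k + 4)
    return float(t_dist.sf(T, 5 * k + 4))


def dichotomize(values, cut: float) -> pd.Series | np.ndarray:
    """1 iff value > cut; missing values stay missing."""
    if not np.isfinite(cut):
        raise ValueError("cutpoint must be finite")
    if isinstance(values, pd.Series):
        out = (values > cut).astype(float)
        out[values.isna()] = np.nan
        return out
    x = np.asarray(values, dtype=float)
    out = (x > cut).astype(float)
    out[~np.isfinite(x)] = np.nan
    return out


@dataclass
class CutpointResult:
    """Full audit record of one cross-validated cutpoint search."""

    endpoint: str
    candidates: np.ndarray
    combined_p_test: np.ndarray
    train_select_count: np.ndarray
    selected: float | None
    pass_stability: bool
    n_repeats: int
    seed: int | None
    stability_min: int
    stability_mode: str
    n_skipped_fold_ps: int

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "candidates": [float(c) for c in self.candidates],
            "combined_p_test": [None if not np.isfinite(p) else float(p)
                                for p in self.combined_p_test],
            "train_select_count": [int(c) for c in self.train_select_count],
            "selected": None if self.selected is None else float(self.selected),
            "pass_stability": bool(self.pass_stability),
            "n_repeats": int(self.n_repeats),
            "seed": self.seed,
            "stability_min": int(self.stability_min),
            "stability_mode": self.stability_mode,
            "n_skipped_fold_ps": int(self.n_skipped_fold_ps),
        }


def _g_test_pvalues(B: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized 2x2 G-test p-values, one per candidate column of B.

    ``B[i, j]`` indicates observation i above candidate j. Candidates with an
    empty high or low group get NaN (skipped, not imputed). The G statistic
    is identical to the logistic LR statistic for a single binary predictor.
    """
    n = len(y)
    e = float(y.sum())
    n1 = B.sum(axis=0).astype(float)          # high-group size
    e1 = (y @ B).astype(float)                # high-group events
    n0 = n - n1
    e0 = e - e1
    obs = np.stack([e1, n1 - e1, e0, n0 - e0])           # 4 x m
    exp = np.stack([n1 * e / n, n1 * (n - e) / n,
                    n0 * e / n, n0 * (n - e) / n])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    G = 2.0 * terms.sum(axis=0)
    p = chi2.sf(np.maximum(G, 0.0), 1)
    p[(n1 == 0) | (n0 == 0)] = np.nan
    return p


def _stratified_two_folds(y: np.ndarray, rng: np.random.Generator):
    """Random twofold split balanced over the outcome; returns a bool mask."""
    in_a = np.zeros(len(y), dtype=bool)
    for stratum in (0, 1):
        idx = np.flatnonzero(y == stratum)
        idx = rng.permutation(idx)
        in_a[idx[: len(idx) // 2]] = True
    return in_a


def cv_cutpoint_search(
    biomarker,
    pcr,
    n_repeats: int = 500,
    folds: int = 2,
    stability_min: int = 10,
    min_group: int = 5,
    seed: int | None = None,
    stability_mode: str = "filter",
    endpoint: str = "biomarker",
) -> CutpointResult:
    """Repeated stratified twofold CV search for an optimal dichotomizing cut.

    Per repeat both folds serve once as test (2 p-values per candidate per
    repeat) and the first configuration's training fold contributes one
    argmin-p selection count. ``stability_mode``:

    - ``"filter"`` (default): the global minimum-combined-test-p candidate is
      selected only if its own training count reaches ``stability_min``,
      else no cutpoint is declared;
    - ``"restrict"``: the minimum-combined-p candidate among those with
      training count >= ``stability_min``.

    Ties in any argmin break toward the smaller cutpoint. Observations with a
    missing biomarker or outcome are excluded.
    """
    if folds != 2:
        raise ValueError("only twofold cross-validation is supported")
    if stability_mode not in ("filter", "restrict"):
        raise ValueError(f"unknown stability_mode: {stability_mode!r}")
    x = np.asarray(biomarker, dtype=float)
    y = np.asarray(pcr, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok].astype(int)
    if y.sum() < 3 or (1 - y).sum() < 3:
        raise ValueError("need at least 3 events and 3 non-events")

    cand = candidate_cutpoints(x, min_group=min_group)
    m = len(cand)
    B = x[:, None] > cand[None, :]

    rng = np.random.default_rng(seed)
    test_ps = np.full((2 * n_repeats, m), np.nan)
    train_count = np.zeros(m, dtype=int)
    n_skipped = 0
    for r in range(n_repeats):
        in_a = _stratified_two_folds(y, rng)
        p_a = _g_test_pvalues(B[in_a], y[in_a])
        p_b = _g_test_pvalues(B[~in_a], y[~in_a])
        test_ps[2 * r] = p_a      # fold A as test (fold B trains)
        test_ps[2 * r + 1] = p_b  # fold B as test
        n_skipped += int(np.isnan(p_a).sum() + np.isnan(p_b).sum())
        # training role of the first configuration: fold B
        if not np.all(np.isnan(p_b)):
            train_count[np.nanargmin(p_b)] += 1

    # comparisons run on the log scale: combining 1000 small p-values makes
    # the combined p underflow to an uninformative plateau of exact zeros
    log_combined = np.full(m, np.nan)
    for j in range(m):
        pj = test_ps[:, j]
        pj = pj[np.isfinite(pj)]
        if len(pj):
            log_combined[j] = combine_pvalues_logit(
                np.clip(pj, P_CLIP, 1 - P_CLIP), log=True)
    combined = np.exp(log_combined)

    if np.all(np.isnan(log_combined)):
        raise ValueError("no candidate produced any test-fold p-value")
    best = int(np.nanargmin(log_combined))  # first minimum -> smaller cutpoint
    if stability_mode == "filter":
        passed = train_count[best] >= stability_min
        selected = float(cand[best]) if passed else None
    else:
        qual = np.flatnonzero(train_count >= stability_min)
        qual = qual[np.isfinite(log_combined[qual])]
        passed = len(qual) > 0
        selected = float(cand[qual[np.argmin(log_combined[qual])]]) if passed else None

    return CutpointResult(
        endpoint=endpoint,
        candidates=cand,
        combined_p_test=combined,
        train_select_count=train_count,
        selected=selected,
        pass_stability=bool(passed),
        n_repeats=n_repeats,
        seed=seed,
        stability_min=stability_min,
        stability_mode=stability_mode,
        n_skipped_fold_ps=n_skipped,
    )
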