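"""Cross-array RPPA standardization and the multi-caller variant consensus filter.

RPPA samples assayed on different arrays carry array-level location/scale
batch effects. Each array is standardized independently before the columns are
combined: within a batch, stratified resamples (with replacement, receptor-
subtype quotas matching a fixed target mix) are drawn many times; the mean and
SD of every endpoint are computed in each resample and averaged across
resamples ("mean of means", "mean of SDs"); the endpoint is then z-scored with
those averaged parameters. Resampling at a fixed subtype balance makes the
standardization insensitive to which subtypes happen to dominate an array.

Somatic variant calls from several callers are reduced to a consensus set by
keeping only (patient, gene, variant) triples supported by a minimum number of
distinct callers (two of three by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import SUBTYPES, ClinicalTable, OmicsMatrix
from .synthetic_data import DEFAULT_SUBTYPE_PROPS

logger = logging.getLogger(__name__)


@dataclass
class StandardizationParams:
    """Per-batch standardization parameters: endpoint -> (mean, sd).

    ``params`` has one row per endpoint with columns ``mean_of_means`` and
    ``mean_of_sds``; endpoints constant within the batch (mean_of_sds = 0) are
    listed in ``flagged`` and never divided by zero.
    """

    batch: str
    params: pd.DataFrame
    n_resamples: int
    target_props: tuple[float, ...]
    seed: int | None
    flagged: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "batch": self.batch,
            "n_resamples": self.n_resamples,
            "target_props": list(self.target_props),
            "seed": self.seed,
            "flagged": list(self.flagged),
            "endpoints": {
                e: {"mean": float(m), "sd": float(s)}
                for e, m, s in zip(self.params.index,
                                   self.params["mean_of_means"],
                                   self.params["mean_of_sds"])
            },
        }


def subtype_quotas(counts: pd.Series, size: int,
                   target_props: dict[str, float]) -> dict[str, int]:
    """Integer per-subtype resample quotas summing to ``size``.

    Quotas are ``size * target_prop`` rounded by largest remainder, ties
    broken by the fixed subtype order. A subtype with positive target
    proportion but no patients in the batch has its quota redistributed
    proportionally over the represented subtypes, with a warning.
    """
    props = pd.Series({s: target_props.get(s, 0.0) for s in SUBTYPES}, dtype=float)
    absent = props.index[(props > 0) & (counts.reindex(props.index).fillna(0) == 0)]
    if len(absent):
        warnings.warn(
            f"subtype(s) {list(absent)} absent from batch; quota redistributed",
            stacklevel=2,
        )
        props[absent] = 0.0
    if props.sum() <= 0:
        raise ValueError("no represented subtype has positive target proportion")
    props = props / props.sum()

    exact = props * size
    base = np.floor(exact).astype(int)
    remainder = exact - base
    short = size - int(base.sum())
    # largest remainder; pd sort is stable, so ties keep the SUBTYPES order
    order = remainder.sort_values(ascending=False, kind="stable").index
    for s in order[:short]:
        base[s] += 1
    return {s: int(base[s]) for s in SUBTYPES if base[s] > 0}


def _resample_count_matrix(
    subtype: pd.Series, quotas: dict[str, int], n_resamples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_patients x n_resamples) matrix of with-replacement draw counts.

    Within each subtype the quota draws are uniform with replacement, so the
    per-patient counts of one resample are multinomial over that subtype's
    patients.
    """
    n = len(subtype)
    counts = np.zeros((n, n_resamples), dtype=np.int64)
    positions = {s: np.flatnonzero((subtype == s).to_numpy()) for s in quotas}
    for s, q in quotas.items():
        pos = positions[s]
        if len(pos) == 0 or q == 0:
            continue
        draws = rng.multinomial(q, np.full(len(pos), 1.0 / len(pos)), size=n_resamples)
        counts[pos, :] = draws.T
    return counts


def rppa_standardize(
    matrix: OmicsMatrix,
    clinical: ClinicalTable,
    target_props: tuple[float, ...] = DEFAULT_SUBTYPE_PROPS,
    n_resamples: int = 5000,
    seed: int | None = None,
) -> tuple[OmicsMatrix, dict[str, StandardizationParams]]:
    """Standardize each batch independently, then recombine the columns.

    For every batch: draw ``n_resamples`` stratified samples of the batch's
    own size (with replacement, subtype quotas at ``target_props``), average
    the per-resample endpoint means and SDs, and z-score the batch's values
    with those averages. Returns the standardized matrix (original column
    order) and per-batch parameters. Endpoints constant within a batch are
    flagged and set to missing for that batch.
    """
    if matrix.batch is None:
        batch = pd.Series("batch1", index=matrix.patient_ids)
    else:
        batch = matrix.batch
    subtype = clinical.df["subtype"].reindex(matrix.patient_ids)
    if subtype.isna().any():
        missing = list(subtype.index[subtype.isna()][:5])
        raise ValueError(f"patients without clinical subtype: {missing}")
    tprops = dict(zip(SUBTYPES, target_props))

    rng = np.random.default_rng(seed)
    out = matrix.values.copy()
    all_params: dict[str, StandardizationParams] = {}
    for b in sorted(batch.dropna().unique()):
        cols = matrix.patient_ids[(batch == b).to_numpy()]
        V = matrix.values.loc[:, cols].to_numpy(dtype=float)
        sub = subtype.loc[cols]
        size = len(cols)
        quotas = subtype_quotas(sub.value_counts(), size, tprops)
        C = _resample_count_matrix(sub, quotas, n_resamples, rng)  # size x R

        # mean/SD per resample from draw counts: E[x], E[x^2] under counts
        denom = C.sum(axis=0).astype(float)  # == size for every resample
        m1 = (V @ C) / denom
        m2 = (V**2 @ C) / denom
        var = np.maximum(m2 - m1**2, 0.0)
        if size > 1:
            var = var * (denom / (denom - 1.0))  # sample SD (ddof=1)
        mean_of_means = m1.mean(axis=1)
        mean_of_sds = np.sqrt(var).mean(axis=1)

        flagged = [str(e) for e, s in zip(matrix.feature_ids, mean_of_sds) if s == 0.0]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (V - mean_of_means[:, None]) / mean_of_sds[:, None]
        z[mean_of_sds == 0.0, :] = np.nan
        out.loc[:, cols] = z
        if flagged:
            logger.warning("batch %s: %d constant endpoint(s) flagged", b, len(flagged))
        all_params[str(b)] = StandardizationParams(
            batch=str(b),
            params=pd.DataFrame(
                {"mean_of_means": mean_of_means, "mean_of_sds": mean_of_sds},
                index=matrix.feature_ids,
            ),
            n_resamples=n_resamples,
            target_props=tuple(target_props),
            seed=seed,
            flagged=flagged,
        )
    return OmicsMatrix(out, kind=matrix.kind, batch=matrix.batch), all_params


@dataclass
class ConsensusCallSet:
    """Variant calls supported by at least ``min_support`` distinct callers."""

    calls: pd.DataFrame  # columns: patient_id, gene, variant_key, n_callers_supporting
    min_support: int

    def __len__(self) -> int:
        return len(self.calls)


def consensus_mutations(
    callsets: dict[str, pd.DataFrame], n_callers: int | None = None,
    min_support: int = 2,
) -> ConsensusCallSet:
    """Keep (patient, gene, variant) triples called by >= ``min_support`` callers.

    ``callsets`` maps caller name to a frame with columns patient_id, gene,
    variant_key; duplicate rows within one caller count once. ``n_callers``
    defaults to the number of callsets provided.
    """
    if n_callers is None:
        n_callers = len(callsets)
    if min_support > n_callers:
        raise ValueError(f"min_support {min_support} exceeds n_callers {n_callers}")
    key_cols = ["patient_id", "gene", "variant_key"]
    frames = []
    for caller, df in callsets.items():
        sub = df.loc[:, key_cols].drop_duplicates().assign(caller=caller)
        frames.append(sub)
    if not frames or sum(map(len, frames)) == 0:
        empty = pd.DataFrame(columns=key_cols + ["n_callers_supporting"])
        return ConsensusCallSet(empty, min_support)
    combined = pd.concat(frames, ignore_index=True)
    support = (combined.groupby(key_cols)["caller"].nunique()
               .rename("n_callers_supporting").reset_index())
    kept = support.loc[support["n_callers_supporting"] >= min_support]
    kept = kept.sort_values(key_cols, kind="stable").reset_index(drop=True)
    return ConsensusCallSet(kept, min_support)
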