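"""Orchestration: pre-specified screen reports and the cutpoint -> Bayes chain.

Ties the modules together behind a single run configuration: the
pre-specified association screen produces a tidy dotplot-ready table (one row
per biomarker x model-form cell); the exploratory chain searches a
cross-validated cutpoint, dichotomizes the endpoint, fits the Bayesian
interaction model, and reports posterior pCR estimates for the
biomarker-high and biomarker-low subgroups of a receptor subset in the
treated arm. Every stage derives its own seed deterministically from one
master seed, so single-stage reruns match full-pipeline runs.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association, bayes, cutpoint
from .data_model import Cohort

logger = logging.getLogger(__name__)

#: The model-form x subset cells of the pre-specified association report:
#: both arms overall, the interaction models, and treated-arm receptor subsets.
PRESPECIFIED_CELLS = (
    ("treated_arm", "all"),
    ("control_arm", "all"),
    ("interaction", "all"),
    ("interaction_adjusted", "all"),
    ("treated_arm", "HER2+"),
    ("treated_arm", "TN"),
    ("treated_arm", "HR+HER2-"),
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from a master seed."""
    return (int(master_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Parameters of one orchestrated run."""

    master_seed: int = 0
    biomarkers: list[str] = field(default_factory=list)
    matrix: str = "rppa"
    cutpoint_repeats: int = 500
    stability_min: int = 10
    stability_mode: str = "filter"
    bayes_spec: bayes.BayesModelSpec | None = None


@dataclass
class CutpointBayesReport:
    """End-to-end result of the cutpoint -> Bayes chain for one endpoint."""

    endpoint: str
    subset: str
    cutpoint_result: cutpoint.CutpointResult
    posterior: bayes.PosteriorSummary | None
    estimate_high: bayes.SubsetEstimate | None
    estimate_low: bayes.SubsetEstimate | None
    fraction_high: float | None
    status: str  # "ok" or "no stable cutpoint"

    def to_dict(self) -> dict:
        out = {
            "endpoint": self.endpoint,
            "subset": self.subset,
            "status": self.status,
            "cutpoint": self.cutpoint_result.to_dict(),
            "fraction_high": self.fraction_high,
        }
        for label, est in (("high", self.estimate_high), ("low", self.estimate_low)):
            if est is not None:
                out[f"pcr_{label}"] = {
                    "mean": est.mean, "ci95": list(est.ci95), "n": est.n_patients,
                }
        if self.posterior is not None:
            out["rhat_max"] = float(self.posterior.rhat.max())
            out["mcmc_converged"] = self.posterior.converged
        return out


def consort_counts(cohort: Cohort) -> dict:
    """Consort-style patient accounting per source after alignment."""
    counts = {"analyzed": len(cohort.clinical),
              "clinical_excluded_unparseable": cohort.clinical.n_excluded}
    for src, dropped in cohort.dropped.items():
        counts[f"dropped_{src}"] = len(dropped)
    return counts


def run_prespecified(cohort: Cohort, biomarkers: list[str], matrix: str = "rppa",
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Screen each listed biomarker through the pre-specified model cells.

    Returns a tidy table with one row per biomarker x cell (direction,
    LR p, -log10 p, n, n_pCR, flags) plus the list of biomarkers skipped
    because they are absent from the matrix. An unresolvable biomarker never
    aborts the run.
    """
    mat = cohort.matrices[matrix]
    rows, skipped = [], []
    for bm in biomarkers:
        if bm not in mat.feature_ids:
            skipped.append(bm)
            continue
        values = mat.values.loc[bm]
        for population, subset in PRESPECIFIED_CELLS:
            res = association.screen(values, cohort.clinical, population, subset)
            rows.append({
                "biomarker": bm, "population": population, "subset": subset,
                "direction": res.direction, "lr_p": res.lr_p,
                "neglog10_p": res.neglog10_p(), "n": res.n, "n_pCR": res.n_pcr,
                "flags": ";".join(res.flags),
            })
    if skipped:
        logger.warning("run_prespecified: skipped unresolvable biomarker(s): %s", skipped)
    table = pd.DataFrame(rows, columns=["biomarker", "population", "subset",
                                        "direction", "lr_p", "neglog10_p",
                                        "n", "n_pCR", "flags"])
    return table, skipped


def run_cutpoint_bayes(cohort: Cohort, endpoint: str, subset: str = "all",
                       matrix: str = "rppa", config: RunConfig | None = None,
                       ) -> CutpointBayesReport:
    """Chain cutpoint search -> dichotomize -> Bayesian subgroup estimation.

    The cutpoint is searched within the treated arm of the given receptor
    subset (where the biomarker's association with response is screened);
    the Bayesian model is then fit on the full trial with the dichotomized
    biomarker, and posterior pCR rates are reported for the treated-arm
    biomarker-high and biomarker-low subgroups of the subset. If no stable
    cutpoint is found the chain stops with status "no stable cutpoint".
    """
    config = config or RunConfig()
    mat = cohort.matrices[matrix]
    if endpoint not in mat.feature_ids:
        raise KeyError(f"endpoint {endpoint!r} not in matrix {matrix!r}")
    values = mat.values.loc[endpoint]
    clin = cohort.clinical

    arm_mask = clin.subset_mask(subset) & (clin.df["arm"] == "treated")
    cp = cutpoint.cv_cutpoint_search(
        values[arm_mask], clin.df.loc[arm_mask, "pcr"],
        n_repeats=config.cutpoint_repeats,
        stability_min=config.stability_min,
        stability_mode=config.stability_mode,
        seed=stage_seed(config.master_seed, f"cutpoint:{endpoint}:{subset}"),
        endpoint=endpoint,
    )
    if not cp.pass_stability:
        return CutpointBayesReport(endpoint, subset, cp, None, None, None, None,
                                   status="no stable cutpoint")

    bm_bin = cutpoint.dichotomize(values, cp.selected)
    spec = config.bayes_spec or bayes.BayesModelSpec()
    spec = bayes.BayesModelSpec(
        prior_sd=spec.prior_sd, chains=spec.chains, iterations=spec.iterations,
        burn_in=spec.burn_in, thin=spec.thin,
        seed=stage_seed(config.master_seed, f"bayes:{endpoint}:{subset}"),
    )
    design = bayes.build_design(clin, bm_bin)
    y = clin.df.loc[design.index, "pcr"].to_numpy(dtype=float)
    posterior = bayes.sample_posterior(design, y, spec)

    mask_high = bayes.subset_mask(design, clin, subset, biomarker=1, arm="treated")
    mask_low = bayes.subset_mask(design, clin, subset, biomarker=0, arm="treated")
    est_high = bayes.subset_pcr_estimate(posterior, design, mask_high,
                                         name=f"{subset}/{endpoint}-high/treated")
    est_low = bayes.subset_pcr_estimate(posterior, design, mask_low,
                                        name=f"{subset}/{endpoint}-low/treated")
    in_subset = clin.subset_mask(subset).reindex(design.index).to_numpy()
    frac_high = float(design.loc[in_subset, "biomarker"].mean())
    return CutpointBayesReport(endpoint, subset, cp, posterior, est_high, est_low,
                               frac_high, status="ok")


def average_linkage_order(matrix: pd.DataFrame) -> list:
    """Leaf order from plain average-linkage hierarchical clustering of rows.

    Convenience utility for heatmap-style displays; Euclidean distance,
    untuned and deliberately minimal.
    """
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import pdist

    if len(matrix) < 3:
        return list(matrix.index)
    Z = average(pdist(matrix.to_numpy(dtype=float)))
    return [matrix.index[i] for i in leaves_list(Z)]


def write_report(report: CutpointBayesReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)


def run_manifest(seed: int, inputs: dict[str, str]) -> dict:
    """Reproducibility manifest: package version, master seed, input hashes."""
    from . import __version__

    hashes = {}
    for name, path in inputs.items():
        try:
            with open(path, "rb") as fh:
                hashes[name] = f"crc32:{zlib.crc32(fh.read()):08x}"
        except OSError:
            hashes[name] = None
    return {"bmx_version": __version__, "master_seed": int(seed), "inputs": hashes}
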