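"""Domain types and I/O for clinical tables and omics matrices.

The core containers are thin wrappers around pandas objects: a
:class:`ClinicalTable` (one row per patient: arm, receptor status, MammaPrint
class, pCR outcome), an :class:`OmicsMatrix` (features x patients, continuous,
with an optional per-patient batch label), and a :class:`Cohort` that ties a
clinical table to one or more matrices after aligning their patient sets.

All file I/O is plain delimited text (TSV by default, CSV by extension), so
cohorts are fully reproducible from version-controllable inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ARMS = ("control", "treated")
#: Fixed receptor-subtype order (HR+HER2-, TN, HR+HER2+, HR-HER2+).
#: Downstream quota rounding and reporting rely on this order being stable.
SUBTYPES = ("HR+HER2-", "TN", "HR+HER2+", "HR-HER2+")
MP_CLASSES = ("MP1", "MP2", "unknown")

_CLINICAL_COLS = ("patient_id", "arm", "hr", "her2", "mp_class", "pcr")


def subtype_from_receptors(hr: int, her2: int) -> str:
    """Map binary (HR, HER2) status to the four-level receptor subtype."""
    if her2:
        return "HR+HER2+" if hr else "HR-HER2+"
    return "HR+HER2-" if hr else "TN"


@dataclass
class ClinicalTable:
    """Per-patient clinical annotations, indexed by unique patient id.

    ``df`` columns: ``arm`` in {control, treated}; ``hr``, ``her2``, ``pcr``
    coded 0/1; ``mp_class`` in {MP1, MP2, unknown}; ``subtype`` derived from
    (hr, her2).
    """

    df: pd.DataFrame
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            dup = self.df.index[self.df.index.duplicated()][0]
            raise ValueError(f"duplicate patient_id: {dup!r}")
        if "subtype" not in self.df.columns:
            self.df = self.df.assign(
                subtype=[
                    subtype_from_receptors(h, e)
                    for h, e in zip(self.df["hr"], self.df["her2"])
                ]
            )

    @property
    def patient_ids(self) -> pd.Index:
        return self.df.index

    def __len__(self) -> int:
        return len(self.df)

    def subset_mask(self, subset: str) -> pd.Series:
        """Boolean mask for a named analysis subset.

        ``subset`` is ``"all"``, one of the four subtypes, or ``"HER2+"`` /
        ``"HER2-"`` / ``"HR+"`` / ``"HR-"`` margins.
        """
        if subset == "all":
            return pd.Series(True, index=self.df.index)
        if subset in SUBTYPES:
            return self.df["subtype"] == subset
        margins = {
            "HER2+": self.df["her2"] == 1,
            "HER2-": self.df["her2"] == 0,
            "HR+": self.df["hr"] == 1,
            "HR-": self.df["hr"] == 0,
        }
        if subset in margins:
            return margins[subset]
        raise ValueError(f"unknown subset: {subset!r}")


@dataclass
class OmicsMatrix:
    """Features x patients continuous matrix with optional batch labels.

    ``values``: DataFrame, rows = feature ids, columns = patient ids, entries
    platform intensity (RPPA) or log-expression. Missing values are explicit
    NaN, never silent zeros. ``batch``: per-patient label Series or None.
    ``kind``: "expression" or "rppa".
    """

    values: pd.DataFrame
    kind: str = "expression"
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated feature id: {dup!r}")
        if self.batch is not None:
            self.batch = self.batch.reindex(self.values.columns)

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def patient_ids(self) -> pd.Index:
        return self.values.columns

    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def select_patients(self, ids) -> "OmicsMatrix":
        batch = self.batch.loc[ids] if self.batch is not None else None
        return OmicsMatrix(self.values.loc[:, ids], kind=self.kind, batch=batch)


@dataclass
class Cohort:
    """A clinical table and named omics matrices over a common patient set."""

    clinical: ClinicalTable
    matrices: dict[str, OmicsMatrix] = field(default_factory=dict)
    dropped: dict[str, list[str]] = field(default_factory=dict)

    @property
    def patient_ids(self) -> pd.Index:
        return self.clinical.patient_ids


def _sep_for(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def load_clinical(path, dialect: dict[str, str] | None = None) -> ClinicalTable:
    """Read a delimited clinical table.

    ``dialect`` maps canonical column names (patient_id, arm, hr, her2,
    mp_class, pcr) to the names used in the file. Rows whose arm or pcr (or
    hr/her2) cannot be parsed are excluded, with the count logged; a missing
    required column or a duplicated patient id is fatal.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    dialect = dialect or {}
    colmap = {canon: dialect.get(canon, canon) for canon in _CLINICAL_COLS}
    for canon, name in colmap.items():
        if canon != "mp_class" and name not in raw.columns:
            raise ValueError(f"missing required column: {name!r}")

    df = pd.DataFrame(index=raw.index)
    df["patient_id"] = raw[colmap["patient_id"]].astype(str)
    arm = raw[colmap["arm"]].str.strip().str.lower()
    df["arm"] = arm.where(arm.isin(ARMS))
    for col in ("hr", "her2", "pcr"):
        vals = pd.to_numeric(raw[colmap[col]], errors="coerce")
        df[col] = vals.where(vals.isin([0.0, 1.0]))
    if colmap["mp_class"] in raw.columns:
        mp = raw[colmap["mp_class"]].fillna("unknown")
        df["mp_class"] = mp.where(mp.isin(MP_CLASSES), "unknown")
    else:
        df["mp_class"] = "unknown"

    ok = df[["arm", "hr", "her2", "pcr"]].notna().all(axis=1)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("load_clinical: excluded %d unparseable row(s)", n_excluded)
    df = df.loc[ok].copy()
    for col in ("hr", "her2", "pcr"):
        df[col] = df[col].astype(int)
    df = df.set_index("patient_id")
    return ClinicalTable(df, n_excluded=n_excluded)


def load_matrix(path, kind: str = "expression",
                batch_map: dict[str, str] | pd.Series | None = None) -> OmicsMatrix:
    """Read a features-in-rows delimited matrix; empty cells become NaN.

    A non-numeric, non-empty cell is fatal, reported with its (feature,
    patient) coordinates.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    coerced = raw.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & raw.notna() & (raw.apply(lambda s: s.str.strip()) != "")
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at feature {raw.index[r]!r}, patient {raw.columns[c]!r}: "
            f"{raw.iat[r, c]!r}"
        )
    # re-parse with exact (shortest-round-trip) float conversion so that
    # write_matrix(load_matrix(f)) is bit-identical for finite entries
    values = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                         float_precision="round_trip")
    values.index = values.index.astype(str)
    batch = None
    if batch_map is not None:
        batch = pd.Series(batch_map).reindex(values.columns)
    return OmicsMatrix(values.astype(float), kind=kind, batch=batch)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    """Write a matrix as delimited text; finite values round-trip bit-identically."""
    matrix.values.to_csv(path, sep=_sep_for(path))


def load_batch_map(path) -> pd.Series:
    """Read a two-column (patient_id, batch) delimited file into a Series."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str).values)


def align_cohort(clinical: ClinicalTable, **matrices: OmicsMatrix) -> Cohort:
    """Restrict the clinical table and every matrix to their common patients.

    Patients are ordered lexicographically by id so that all downstream
    seeded procedures are independent of input file order. The per-source
    ``dropped`` lists account exactly for the set differences; an empty
    intersection is fatal.
    """
    if not matrices:
        raise ValueError("align_cohort requires at least one matrix")
    common = set(clinical.patient_ids)
    for m in matrices.values():
        common &= set(m.patient_ids)
    if not common:
        raise ValueError("empty patient intersection across clinical table and matrices")
    order = sorted(common)

    dropped = {"clinical": sorted(set(clinical.patient_ids) - common)}
    aligned = {}
    for name, m in matrices.items():
        dropped[name] = sorted(set(m.patient_ids) - common)
        aligned[name] = m.select_patients(order)
    clin = ClinicalTable(clinical.df.loc[order].copy(), n_excluded=clinical.n_excluded)
    return Cohort(clinical=clin, matrices=aligned, dropped=dropped)
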