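"""Hypergeometric over-representation analysis with Benjamini-Hochberg control.

A transparent generic ORA: given a hit list (e.g. genes passing a
transcriptome-wide screen), a gene universe, and a collection of gene sets
(GMT format), each set is tested for over-representation with the upper-tail
hypergeometric probability, and p-values are adjusted across the tested sets
by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSet:
    set_id: str
    name: str
    members: frozenset

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)


@dataclass
class EnrichmentResult:
    set_id: str
    n_universe: int
    n_hits: int
    n_set: int
    n_overlap: int
    p: float
    p_bh: float = float("nan")


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (set id, description, members, tab-separated)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets.append(GeneSet(parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return sets


def bh_adjust(ps) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(ps, dtype=float)
    if len(p) == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(hits, gene_sets: list[GeneSet], universe) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each set, BH-adjusted across sets.

    ``hits`` must be a subset of ``universe``; each set is intersected with
    the universe before testing. p = P[X >= n_overlap] for X hypergeometric
    (n_universe, n_set, n_hits).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    hits = set(hits)
    if not hits <= universe:
        raise ValueError(f"{len(hits - universe)} hit(s) outside the universe")
    M, N = len(universe), len(hits)
    results = []
    for gs in gene_sets:
        members = gs.members & universe
        k = len(members & hits)
        n = len(members)
        p = float(hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        results.append(EnrichmentResult(gs.set_id, M, N, n, k, min(p, 1.0)))
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_bh = float(a)
    return results
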