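"""Overlap enrichment and ranked-table filters.

Two-set overlap significance uses the one-sided Fisher exact test (the upper
hypergeometric tail, i.e. an enrichment alternative), with the sample odds
ratio (overlap * neither) / (a_only * b_only) reported alongside; a zero
denominator is reported as +infinity rather than continuity-corrected, so the
printed magnitude is the raw ratio. Families of p-values are adjusted with
the Benjamini-Hochberg step-up procedure.

Ranked-table filters implement the recurring "top X%" selections used in the
cancer-association analyses (top 5% most mutated, top 10% most differentially
expressed, top-1,000 hazardous/protective caps) plus the ">= cutoff fraction"
rule for gene-dependency scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    """2x2 overlap test result; ``q`` stays None until BH adjustment."""

    set_a: str
    set_b: str
    overlap: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float
    p: float
    q: float | None = None


@dataclass
class RankedGeneTable:
    """Genes with a real-valued score and a declared sort direction.

    ``ascending=False`` (default) means larger values rank first.
    """

    table: pd.DataFrame
    ascending: bool = False

    def __post_init__(self):
        required = {"gene", "value"}
        if not required.issubset(self.table.columns):
            raise ValueError("ranked table needs 'gene' and 'value' columns")
        if self.table["gene"].duplicated().any():
            dups = self.table.loc[self.table["gene"].duplicated(), "gene"]
            raise ValueError(f"duplicate gene(s) in ranked table: {sorted(set(dups))[:5]}")

    @classmethod
    def read_tsv(cls, path, ascending: bool = False) -> "RankedGeneTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.rename(columns={df.columns[0]: "gene", df.columns[1]: "value"})
        return cls(df[["gene", "value"]], ascending=ascending)

    def __len__(self):
        return len(self.table)


def fisher_overlap(a, b, universe, set_a: str = "A", set_b: str = "B",
                   alternative: str = "greater") -> EnrichmentRecord:
    """Fisher exact test for the overlap of two gene sets in a universe.

    Members outside the universe are intersected away (count logged). The
    default alternative is one-sided enrichment: p = P[X >= overlap] under
    the hypergeometric null.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    a, b = set(a), set(b)
    n_outside = len(a - universe) + len(b - universe)
    if n_outside:
        logger.info("fisher_overlap: %d member(s) outside universe dropped", n_outside)
    a &= universe
    b &= universe
    overlap = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = len(universe) - overlap - a_only - b_only
    if a_only * b_only > 0:
        odds_ratio = (overlap * neither) / (a_only * b_only)
    elif overlap * neither > 0:
        odds_ratio = math.inf
    else:
        odds_ratio = math.nan
    _, p = stats.fisher_exact([[overlap, a_only], [b_only, neither]],
                              alternative=alternative)
    return EnrichmentRecord(set_a=set_a, set_b=set_b, overlap=overlap,
                            a_only=a_only, b_only=b_only, neither=neither,
                            odds_ratio=odds_ratio, p=float(p))


def adjust_bh(pvalues) -> list:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1)) or np.any(np.isnan(ps)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(stats.false_discovery_control(ps, method="bh"))


def top_fraction(table: RankedGeneTable, fraction: float,
                 max_n: int | None = None) -> set:
    """Top-k genes of a ranked table, k = ceil(fraction * rows), capped.

    Ties at the k-th value are broken by ascending gene identifier so that
    repeated runs return identical membership.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(table) == 0:
        raise ValueError("ranked table is empty")
    k = math.ceil(fraction * len(table))
    if max_n is not None:
        k = min(k, max_n)
    ordered = table.table.sort_values(
        ["value", "gene"], ascending=[table.ascending, True], kind="mergesort")
    return set(ordered["gene"].head(k))


def threshold_fraction(table: RankedGeneTable, cutoff: float,
                       genes=None) -> float:
    """Fraction of (optionally restricted) rows with value >= cutoff."""
    df = table.table
    if genes is not None:
        df = df[df["gene"].isin(set(genes))]
    if len(df) == 0:
        raise ValueError("no rows left in denominator")
    return float((df["value"] >= cutoff).sum() / len(df))
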