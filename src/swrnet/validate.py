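"""Fractional characterization and annotation enrichment of candidate lists.

After genome-wide scoring, the highest- and lowest-scoring candidate lists
are compared feature by feature: for each cancer-associated feature list
(top differentially expressed, frequently mutated, hazardous, protective,
dependency-high, ...) the fraction of candidates carrying the feature is
computed in each list and summarized as a log2 ratio. Fractions entering the
ratio receive a (k+0.5)/(n+1) continuity correction so empty overlaps stay
finite; the raw fractions are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

from .enrich import adjust_bh, fisher_overlap


@dataclass
class FractionComparison:
    list_a: str
    list_b: str
    feature: str
    k_a: int
    n_a: int
    k_b: int
    n_b: int
    frac_a: float
    frac_b: float
    log2_ratio: float


def feature_fraction(candidates, feature_set):
    """(k, n, k/n) for a candidate list against a feature gene set."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    n = len(candidates)
    k = len(set(candidates) & set(feature_set))
    return k, n, k / n


def log_ratio(candidates_a, candidates_b, feature_set, list_a: str = "A",
              list_b: str = "B", feature: str = "feature") -> FractionComparison:
    """log2 ratio of continuity-corrected feature fractions of two lists."""
    from math import log2

    k_a, n_a, frac_a = feature_fraction(candidates_a, feature_set)
    k_b, n_b, frac_b = feature_fraction(candidates_b, feature_set)
    corrected_a = (k_a + 0.5) / (n_a + 1)
    corrected_b = (k_b + 0.5) / (n_b + 1)
    return FractionComparison(
        list_a=list_a, list_b=list_b, feature=feature,
        k_a=k_a, n_a=n_a, k_b=k_b, n_b=n_b,
        frac_a=frac_a, frac_b=frac_b,
        log2_ratio=log2(corrected_a / corrected_b))


def annotate_enrichment(candidates, annotation, universe):
    """Fisher overlap of a candidate list with every annotation set, BH-adjusted.

    Returns EnrichmentRecords sorted by q ascending, then odds ratio
    descending (infinite odds first within a q tie).
    """
    candidates = set(candidates)
    records = [fisher_overlap(candidates, s.members, universe,
                              set_a="candidates", set_b=s.name)
               for s in annotation]
    qs = adjust_bh([r.p for r in records])
    for rec, q in zip(records, qs):
        rec.q = float(q)
    records.sort(key=lambda r: (r.q, -r.odds_ratio, r.set_b))
    return records
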