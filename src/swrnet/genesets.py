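"""Consensus gene-set construction and GMT I/O.

Gene sets for the three homeostatic processes — stress response (SR), wound
healing (WH) and regeneration (RG) — are built from per-experiment
differential-expression tables: significant genes are filtered per direction
(adjusted p < alpha, |log2 fold-change| >= threshold), mapped to human
orthologs through a user-supplied table, unioned to dataset level, and a gene
enters the consensus set when it recurs in at least ``min_datasets`` datasets.
Together with three direction-agnostic database-derived sets this yields the
nine-set collection that drives the downstream proximity features.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

PROCESSES = ("SR", "WH", "RG", "other")
DIRECTIONS = ("UP", "DOWN", "AGNOSTIC")

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_ABS_LFC = 1.0
DEFAULT_MIN_DATASETS = 2


class GmtFormatError(ValueError):
    """Raised for malformed GMT content (duplicate names, empty sets)."""


@dataclass(frozen=True)
class DifferentialRecord:
    """One gene's differential-expression result in one experiment."""

    gene: str
    log_fc: float
    adj_p: float

    def __post_init__(self):
        if not self.gene:
            raise ValueError("gene identifier must be non-empty")
        if not 0.0 <= self.adj_p <= 1.0:
            raise ValueError(f"adj_p must be in [0, 1], got {self.adj_p}")


@dataclass
class GeneSet:
    name: str
    members: set
    process: str = "other"
    direction: str = "AGNOSTIC"

    def __post_init__(self):
        if self.process not in PROCESSES:
            raise ValueError(f"unknown process {self.process!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        self.members = set(self.members)


class GeneSetCollection:
    """Ordered, name-unique list of gene sets.

    The order is fixed and defines the feature-column order downstream.
    """

    def __init__(self, sets=()):
        self._sets: list = []
        self._by_name: dict = {}
        for s in sets:
            self.append(s)

    def append(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._by_name:
            raise GmtFormatError(f"duplicate gene-set name {gene_set.name!r}")
        self._by_name[gene_set.name] = gene_set
        self._sets.append(gene_set)

    @property
    def names(self) -> list:
        return [s.name for s in self._sets]

    def __len__(self):
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def __getitem__(self, key):
        if isinstance(key, str):
            return self._by_name[key]
        return self._sets[key]

    def __contains__(self, name):
        return name in self._by_name


def _as_records(records):
    if isinstance(records, pd.DataFrame):
        return (DifferentialRecord(str(r.gene), float(r.log_fc), float(r.adj_p))
                for r in records.itertuples())
    return records


def filter_significant(records, alpha: float = DEFAULT_ALPHA,
                       min_abs_lfc: float = DEFAULT_MIN_ABS_LFC,
                       direction: str = "UP", name: str | None = None) -> GeneSet:
    """Significant up- or downregulated genes from a differential table.

    UP keeps genes with adj_p < alpha and log_fc >= min_abs_lfc; DOWN keeps
    adj_p < alpha and log_fc <= -min_abs_lfc. The p cutoff is strict (<) and
    the fold-change cutoff inclusive (>=). Duplicate genes collapse.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if min_abs_lfc < 0:
        raise ValueError("min_abs_lfc must be >= 0")
    if direction not in ("UP", "DOWN"):
        raise ValueError("direction must be UP or DOWN")
    members = set()
    for rec in _as_records(records):
        if rec.adj_p >= alpha:
            continue
        if direction == "UP" and rec.log_fc >= min_abs_lfc:
            members.add(rec.gene)
        elif direction == "DOWN" and rec.log_fc <= -min_abs_lfc:
            members.add(rec.gene)
    return GeneSet(name=name or f"significant-{direction}", members=members,
                   direction=direction)


def map_orthologs(genes, mapping) -> set:
    """Map a gene set to human orthologs through a lookup table.

    ``mapping`` is a dict source gene -> human gene (or iterable of human
    genes; one-to-many sources contribute all targets). Genes without an
    entry are dropped and their count logged.
    """
    mapped = set()
    n_dropped = 0
    for gene in genes:
        targets = mapping.get(gene)
        if targets is None:
            n_dropped += 1
            continue
        if isinstance(targets, str):
            mapped.add(targets)
        else:
            mapped.update(targets)
    if n_dropped:
        logger.info("map_orthologs: %d gene(s) without a human ortholog dropped",
                    n_dropped)
    return mapped


def build_consensus(per_dataset_sets, min_datasets: int = DEFAULT_MIN_DATASETS,
                    name: str = "consensus", process: str = "other",
                    direction: str = "AGNOSTIC") -> GeneSet:
    """Genes recurring in at least ``min_datasets`` of the input sets.

    Each input set must already be collapsed to dataset level (experiments
    within a dataset unioned first), so one multi-experiment dataset counts
    once per gene.
    """
    if min_datasets < 1:
        raise ValueError("min_datasets must be >= 1")
    sets = [set(s.members if isinstance(s, GeneSet) else s) for s in per_dataset_sets]
    if len(sets) < min_datasets:
        logger.warning(
            "build_consensus: %d input set(s) < min_datasets=%d; empty consensus",
            len(sets), min_datasets)
        return GeneSet(name=name, members=set(), process=process, direction=direction)
    counts = Counter()
    for s in sets:
        counts.update(s)
    members = {g for g, c in counts.items() if c >= min_datasets}
    return GeneSet(name=name, members=members, process=process, direction=direction)


def _parse_description(desc: str):
    parts = desc.split("|")
    if len(parts) == 2 and parts[0] in PROCESSES and parts[1] in DIRECTIONS:
        return parts[0], parts[1]
    return "other", "AGNOSTIC"


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file; the description field may carry "process|direction"."""
    collection = GeneSetCollection()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}: line {lineno}: gene set {fields[0]!r} has no members")
            name, desc = fields[0], fields[1]
            members = {f for f in fields[2:] if f}
            if not members:
                raise GmtFormatError(
                    f"{path}: line {lineno}: gene set {name!r} has no members")
            process, direction = _parse_description(desc)
            collection.append(GeneSet(name=name, members=members,
                                      process=process, direction=direction))
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for gene_set in collection:
            desc = f"{gene_set.process}|{gene_set.direction}"
            members = "\t".join(sorted(gene_set.members))
            handle.write(f"{gene_set.name}\t{desc}\t{members}\n")


def read_differential_table(path) -> pd.DataFrame:
    """Read a differential-expression TSV with header gene/log_fc/adj_p."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "log_fc", "adj_p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_ortholog_table(path) -> dict:
    """Read a two-column TSV (source gene, human gene) into a mapping."""
    mapping: dict = {}
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (source, human)")
    src_col, dst_col = df.columns[:2]
    for src, dst in zip(df[src_col], df[dst_col]):
        mapping.setdefault(str(src), set()).add(str(dst))
    return mapping


def read_gene_list(path) -> list:
    """One gene per line; blank lines and # comments ignored."""
    with open(path) as handle:
        return [ln.strip() for ln in handle
                if ln.strip() and not ln.startswith("#")]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as handle:
        for gene in genes:
            handle.write(f"{gene}\n")
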