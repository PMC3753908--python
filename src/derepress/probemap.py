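"""Probe-set-to-gene mapping and the uniqueness filter.

A probe set measuring more than one gene is nonspecific and is discarded;
probe sets mapping to no gene are also dropped but tallied separately.
Percentages are kept at full precision internally and rounded half-up to
two decimals only for reporting, with the full array as denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .core import logger


@dataclass
class ProbeGeneMap:
    """probe_id -> set of gene_ids, plus the array and gene universes."""

    relations: dict[str, set[str]] = field(default_factory=dict)
    universe: int = 0  # total probe sets on the array
    gene_universe: int = 0  # total genes in the annotation

    def __post_init__(self) -> None:
        if self.universe == 0:
            self.universe = len(self.relations)

    def __len__(self) -> int:
        return len(self.relations)

    def genes_of(self, probe_id: str) -> set[str]:
        return self.relations.get(probe_id, set())


@dataclass(frozen=True)
class MappingSummary:
    n_probes_total: int
    n_probes_unique: int
    n_probes_multi: int
    n_probes_unmapped: int
    n_genes_covered: int
    pct_probes_unique: float
    pct_genes_covered: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report convention), not banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def read_probe_map(
    path: str | Path, universe: int | None = None, gene_universe: int = 0
) -> ProbeGeneMap:
    """Read a two-column TSV (probe_id, gene_id; one row per relation).

    A row with an empty gene_id records an unmapped probe set.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path}: need columns probe_id, gene_id")
    relations: dict[str, set[str]] = {}
    for probe, gene in zip(df["probe_id"], df["gene_id"]):
        relations.setdefault(probe, set())
        if gene:
            relations[probe].add(gene)
    return ProbeGeneMap(
        relations=relations,
        universe=universe or len(relations),
        gene_universe=gene_universe,
    )


def filter_unique(pmap: ProbeGeneMap) -> tuple[ProbeGeneMap, MappingSummary]:
    """Keep exactly the probe sets that map to a single gene.

    Idempotent. The uniqueness percentage is taken over the full array
    universe; gene coverage over the gene universe when one is known.
    """
    unique = {p: set(gs) for p, gs in pmap.relations.items() if len(gs) == 1}
    n_multi = sum(1 for gs in pmap.relations.values() if len(gs) > 1)
    n_unmapped = sum(1 for gs in pmap.relations.values() if len(gs) == 0)
    covered = {next(iter(gs)) for gs in unique.values()}
    total = pmap.universe
    gene_universe = pmap.gene_universe
    summary = MappingSummary(
        n_probes_total=total,
        n_probes_unique=len(unique),
        n_probes_multi=n_multi,
        n_probes_unmapped=n_unmapped,
        n_genes_covered=len(covered),
        pct_probes_unique=round_half_up(100.0 * len(unique) / total) if total else 0.0,
        pct_genes_covered=(
            round_half_up(100.0 * len(covered) / gene_universe) if gene_universe else 0.0
        ),
    )
    if n_unmapped:
        logger.info("dropped %d probe sets mapping to no gene", n_unmapped)
    filtered = ProbeGeneMap(
        relations=unique, universe=total, gene_universe=gene_universe
    )
    return filtered, summary


def genes_covered(pmap: ProbeGeneMap) -> tuple[int, float]:
    """Distinct genes with at least one uniquely mapping probe set.

    Returns (count, percent of the gene universe).
    """
    if pmap.gene_universe <= 0:
        raise ValueError("gene_universe must be positive to compute coverage")
    covered = {next(iter(gs)) for gs in pmap.relations.values() if len(gs) == 1}
    return len(covered), round_half_up(100.0 * len(covered) / pmap.gene_universe)
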