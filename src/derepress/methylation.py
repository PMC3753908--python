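"""CpG methylation: Sequenom-style table comparison and bisulfite clones.

Percent-methylation tables are summarized per sample (mean over non-missing
CpG units) and compared between genotype groups with a two-sided unpaired
pooled-variance Student t (Welch available). Bisulfite clone calling
assumes clones pre-aligned (equal length) to the reference amplicon:
a CpG cytosine read as C is methylated, as T unmethylated; non-CpG
cytosines are the conversion-QC positions, and clones converting below a
threshold are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .core import logger

MIN_CONVERSION_DEFAULT = 0.97


@dataclass
class MethylationTable:
    """Tidy per-unit percent methylation with sample metadata.

    Columns: amplicon_id, sample_id, group, unit_index, pct (optionally
    sex, tissue). Missing units are NaN rows or absent rows.
    """

    data: pd.DataFrame

    REQUIRED = ("amplicon_id", "sample_id", "group", "unit_index", "pct")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"methylation table missing columns {sorted(missing)}")
        vals = self.data["pct"].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError("pct values must lie in [0, 100]")

    @classmethod
    def read(cls, path: str | Path) -> "MethylationTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def amplicons(self) -> list[str]:
        return sorted(self.data["amplicon_id"].unique())


@dataclass
class BisulfiteClone:
    clone_id: str
    sequence: str
    calls: list[Literal["M", "U", "ambiguous"]]
    conversion_rate: float
    accepted: bool
    allele: str | None = None  # optional label, passed through untouched

    @property
    def pct_methylated(self) -> float:
        m = self.calls.count("M")
        u = self.calls.count("U")
        return 100.0 * m / (m + u) if (m + u) else math.nan


@dataclass
class GroupComparison:
    amplicon_id: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    p: float
    significant: bool
    testable: bool


def amplicon_mean(table: MethylationTable, amplicon_id: str, sample_id: str) -> float:
    """Per-sample amplicon summary: mean over non-missing CpG units."""
    sel = table.data[
        (table.data["amplicon_id"] == amplicon_id)
        & (table.data["sample_id"] == sample_id)
    ]
    if sel.empty:
        raise KeyError(f"sample {sample_id!r} absent for amplicon {amplicon_id!r}")
    vals = sel["pct"].dropna()
    if vals.empty:
        logger.warning("%s/%s: all units missing; sample excluded", amplicon_id, sample_id)
        return math.nan
    return float(vals.mean())


def compare_groups(
    table: MethylationTable,
    amplicon_id: str,
    group_a: str = "wt",
    group_b: str = "mutant",
    alpha: float = 0.05,
    variance: Literal["pooled", "welch"] = "pooled",
) -> GroupComparison:
    """Unpaired t on per-sample amplicon means between two groups.

    Requires >= 2 samples per group; otherwise the comparison is returned
    marked not testable. Degenerate complete separation (both groups
    constant but different) is reported as p = 0 with a warning.
    """
    sel = table.data[table.data["amplicon_id"] == amplicon_id]
    means: dict[str, list[float]] = {group_a: [], group_b: []}
    for (sample, group), _sub in sel.groupby(["sample_id", "group"], sort=True):
        if group in means:
            m = amplicon_mean(table, amplicon_id, sample)
            if not math.isnan(m):
                means[group].append(m)
    va, vb = np.array(means[group_a]), np.array(means[group_b])

    def _stats(v: np.ndarray) -> tuple[float, float]:
        mean = float(np.mean(v)) if v.size else math.nan
        sd = float(np.std(v, ddof=1)) if v.size > 1 else math.nan
        return mean, sd

    mean_a, sd_a = _stats(va)
    mean_b, sd_b = _stats(vb)
    if len(va) < 2 or len(vb) < 2:
        return GroupComparison(
            amplicon_id, group_a, group_b, mean_a, sd_a, len(va),
            mean_b, sd_b, len(vb), math.nan, math.nan, False, False,
        )
    t, p = stats.ttest_ind(vb, va, equal_var=(variance == "pooled"))
    t, p = float(t), float(p)
    if math.isnan(t):  # zero variance in both groups
        if mean_a == mean_b:
            t, p = 0.0, 1.0
        else:
            logger.warning("%s: zero within-group variance with separated means", amplicon_id)
            t, p = math.copysign(math.inf, mean_b - mean_a), 0.0
    return GroupComparison(
        amplicon_id, group_a, group_b, mean_a, sd_a, len(va),
        mean_b, sd_b, len(vb), t, p, bool(p <= alpha), True,
    )


def compare_all(
    table: MethylationTable,
    group_a: str = "wt",
    group_b: str = "mutant",
    alpha: float = 0.05,
    variance: Literal["pooled", "welch"] = "pooled",
) -> pd.DataFrame:
    rows = [
        compare_groups(table, amp, group_a, group_b, alpha, variance).__dict__
        for amp in table.amplicons()
    ]
    return pd.DataFrame(rows).set_index("amplicon_id")


# ---------------------------------------------------------------------------
# Bisulfite clones
# ---------------------------------------------------------------------------

_ACGT = set("ACGT")


def convert_reference(seq: str) -> tuple[list[int], str]:
    """CpG cytosine positions and the fully-unmethylated conversion.

    Returns (cpg_positions, expected sequence when no CpG is methylated:
    every C read as T). Non-CpG cytosines are the conversion-QC positions.
    """
    seq = seq.upper()
    if set(seq) - _ACGT:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(set(seq) - _ACGT)}")
    cpg = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
    converted = seq.replace("C", "T")
    return cpg, converted


def qc_positions(seq: str) -> list[int]:
    """Indices of non-CpG reference cytosines (conversion controls)."""
    cpg, _ = convert_reference(seq)
    cpg_set = set(cpg)
    return [i for i, b in enumerate(seq.upper()) if b == "C" and i not in cpg_set]


def call_clone(
    reference: str,
    clone: str,
    min_conversion: float = MIN_CONVERSION_DEFAULT,
    clone_id: str = "clone",
    allele: str | None = None,
) -> BisulfiteClone:
    """Per-CpG methylation calls for one pre-aligned clone.

    At each reference CpG cytosine: C -> methylated, T -> unmethylated,
    anything else ambiguous. The conversion rate is the fraction of
    non-CpG reference cytosines read as T; clones below ``min_conversion``
    are flagged rejected (their calls are still reported).
    """
    reference = reference.upper()
    clone_seq = clone.upper()
    if len(reference) != len(clone_seq):
        raise ValueError(
            f"clone length {len(clone_seq)} != reference length {len(reference)}"
        )
    cpg, _ = convert_reference(reference)
    qc = qc_positions(reference)
    calls: list[str] = []
    for i in cpg:
        base = clone_seq[i]
        calls.append("M" if base == "C" else "U" if base == "T" else "ambiguous")
    if qc:
        converted = sum(1 for i in qc if clone_seq[i] == "T")
        conversion_rate = converted / len(qc)
    else:
        conversion_rate = 1.0  # no QC positions: nothing to fail on
    return BisulfiteClone(
        clone_id=clone_id,
        sequence=clone_seq,
        calls=calls,  # type: ignore[arg-type]
        conversion_rate=conversion_rate,
        accepted=conversion_rate >= min_conversion,
        allele=allele,
    )


def call_clones_fasta(
    reference: str,
    fasta_path: str | Path,
    min_conversion: float = MIN_CONVERSION_DEFAULT,
) -> list[BisulfiteClone]:
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    return [
        call_clone(reference, str(rec.seq), min_conversion, clone_id=rec.id)
        for rec in records
    ]


def write_clones_fasta(clones: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for clone_id, seq in clones:
            fh.write(f">{clone_id}\n{seq}\n")


@dataclass
class CloneSummary:
    per_cpg_pct: list[float]
    overall_pct: float
    n_accepted: int
    n_rejected: int
    status: Literal["ok", "no_accepted_clones"]


def clone_summary(clones: Sequence[BisulfiteClone]) -> CloneSummary:
    """Per-CpG and overall % methylation over accepted clones.

    Ambiguous calls are excluded from both numerator and denominator.
    """
    accepted = [c for c in clones if c.accepted]
    n_rejected = len(clones) - len(accepted)
    if not accepted:
        return CloneSummary([], math.nan, 0, n_rejected, "no_accepted_clones")
    n_cpg = len(accepted[0].calls)
    if any(len(c.calls) != n_cpg for c in accepted):
        raise ValueError("clones disagree on CpG count")
    per_cpg = []
    total_m = total_mu = 0
    for j in range(n_cpg):
        m = sum(1 for c in accepted if c.calls[j] == "M")
        u = sum(1 for c in accepted if c.calls[j] == "U")
        per_cpg.append(100.0 * m / (m + u) if (m + u) else math.nan)
        total_m += m
        total_mu += m + u
    overall = 100.0 * total_m / total_mu if total_mu else math.nan
    return CloneSummary(per_cpg, overall, len(accepted), n_rejected, "ok")


def lollipop_report(clones: Sequence[BisulfiteClone]) -> str:
    """Text lollipop diagram: one row per accepted clone, o=U, *=M, ?=ambiguous."""
    sym = {"M": "*", "U": "o", "ambiguous": "?"}
    lines = []
    for c in clones:
        if not c.accepted:
            continue
        row = "".join(sym[call] for call in c.calls)
        pct = c.pct_methylated
        lines.append(f"{c.clone_id:<12} {row}  {pct:5.1f}%")
    summary = clone_summary(clones)
    if summary.status == "ok":
        lines.append(f"{'overall':<12} {'':{len(clones[0].calls)}}  {summary.overall_pct:5.1f}%")
    return "\n".join(lines)
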