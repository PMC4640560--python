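"""Expression normalization, fold changes and ovary-set calling.

Raw arm counts are normalised to reads per million miRNA-mapped reads
(RPM) within each sample; fold changes compare a tissue sample's RPM to a
whole-body reference library's RPM for the same gene group. A gene is
'ovary_upregulated' when its fold change strictly exceeds the threshold
(default 4) in every tissue sample, and 'ovary_specific' when it has zero
reads in the reference but passes the per-sample expression cutoff in
every tissue sample; the ovary set is the union of the two classes.
Reference-zero fold changes are an explicit undefined flag, never
infinity, and no pseudocounts are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .arm_profiling import ArmProfile
from .curation import CutoffPolicy

CALLS = ("ovary_upregulated", "ovary_specific", "expressed", "not_called")


@dataclass
class ExpressionTable:
    """Per gene-group x sample raw and normalised counts.

    ``raw`` maps sample_id -> DataFrame indexed by gene/group id with
    columns total, count_5p, count_3p; ``denominators`` holds each
    sample's total miRNA-mapped read count (the RPM denominator).
    """

    raw: dict
    denominators: dict

    def __post_init__(self):
        for s, d in self.denominators.items():
            if d <= 0:
                raise ValueError(f"normalization denominator for sample {s!r} must be > 0")

    @classmethod
    def from_profiles(
        cls,
        profiles: Mapping[str, Mapping[str, ArmProfile]],
        denominators: Mapping[str, float] | None = None,
    ) -> "ExpressionTable":
        """Build from {sample_id: {gene_id: ArmProfile}}. When denominators
        are not given, each sample's is the sum of its gene totals."""
        raw = {}
        for sample_id, by_gene in profiles.items():
            raw[sample_id] = pd.DataFrame(
                {
                    "total": {g: p.total for g, p in by_gene.items()},
                    "count_5p": {g: p.count_5p for g, p in by_gene.items()},
                    "count_3p": {g: p.count_3p for g, p in by_gene.items()},
                }
            )
        if denominators is None:
            denominators = {s: float(df["total"].sum()) for s, df in raw.items()}
        return cls(raw, dict(denominators))

    def samples(self) -> list:
        return list(self.raw)

    def genes(self) -> list:
        out: list = []
        for df in self.raw.values():
            out.extend(g for g in df.index if g not in out)
        return out

    def raw_total(self, gene: str, sample: str) -> float:
        df = self.raw[sample]
        return float(df.at[gene, "total"]) if gene in df.index else 0.0

    def dominant_count(self, gene: str, sample: str) -> float:
        df = self.raw[sample]
        if gene not in df.index:
            return 0.0
        return float(max(df.at[gene, "count_5p"], df.at[gene, "count_3p"]))

    def normalized(self, gene: str, sample: str) -> float:
        return normalize_counts(self.raw_total(gene, sample), self.denominators[sample])


def normalize_counts(raw: float, denominator: float) -> float:
    """Reads per million: raw / denominator * 1e6."""
    if denominator <= 0:
        raise ValueError("normalization denominator must be > 0")
    return raw / denominator * 1e6


def fold_change(tissue_norm: float, reference_norm: float) -> float | None:
    """tissue RPM / reference RPM; None (undefined) when the reference is
    zero — including the both-zero case."""
    if tissue_norm < 0 or reference_norm < 0:
        raise ValueError("normalized counts must be >= 0")
    if reference_norm == 0:
        return None
    return tissue_norm / reference_norm


@dataclass
class EnrichmentCall:
    gene_id: str
    fold_changes: dict = field(default_factory=dict)  # tissue sample -> fold or None
    call: str = "not_called"

    def __post_init__(self):
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")


def _passes_cutoffs(table: ExpressionTable, gene: str, tissue_samples: Sequence[str], cutoffs: CutoffPolicy) -> bool:
    return all(table.dominant_count(gene, s) > cutoffs.threshold(s) for s in tissue_samples)


def call_ovary_set(
    table: ExpressionTable,
    tissue_samples: Sequence[str],
    reference_sample: str,
    cutoffs: CutoffPolicy,
    fold_threshold: float = 4.0,
) -> list:
    """Classify every gene group against the reference library.

    ovary_upregulated: fold change > fold_threshold (strict) in every
    tissue sample, and above the expression cutoff in every tissue sample.
    ovary_specific: zero reference reads, above cutoff in every tissue
    sample. Genes above cutoff that meet neither are 'expressed';
    the rest are 'not_called'.
    """
    if reference_sample not in table.raw:
        raise KeyError(f"reference sample {reference_sample!r} absent from expression table")
    calls = []
    for gene in table.genes():
        ref_norm = table.normalized(gene, reference_sample)
        folds = {s: fold_change(table.normalized(gene, s), ref_norm) for s in tissue_samples}
        above_cutoff = _passes_cutoffs(table, gene, tissue_samples, cutoffs)
        if above_cutoff and table.raw_total(gene, reference_sample) == 0:
            call = "ovary_specific"
        elif above_cutoff and all(f is not None and f > fold_threshold for f in folds.values()):
            call = "ovary_upregulated"
        elif above_cutoff:
            call = "expressed"
        else:
            call = "not_called"
        calls.append(EnrichmentCall(gene, folds, call))
    return calls


def ovary_set(calls: Sequence[EnrichmentCall]) -> list:
    """The ovary set: genes called upregulated or specific, in input order."""
    return [c.gene_id for c in calls if c.call in ("ovary_upregulated", "ovary_specific")]


def upregulated_in_any(
    table: ExpressionTable,
    tissue_samples: Sequence[str],
    reference_sample: str,
    cutoffs: CutoffPolicy,
    fold_threshold: float = 4.0,
) -> list:
    """Genes meeting the fold or specificity criterion in at least one but
    not all tissue samples (the ovary set itself is excluded)."""
    out = []
    ref_zero = {g: table.raw_total(g, reference_sample) == 0 for g in table.genes()}
    for gene in table.genes():
        ref_norm = table.normalized(gene, reference_sample)
        n_meeting = 0
        for s in tissue_samples:
            fc = fold_change(table.normalized(gene, s), ref_norm)
            enriched = fc is not None and fc > fold_threshold
            specific = ref_zero[gene] and table.dominant_count(gene, s) > cutoffs.threshold(s)
            if enriched or specific:
                n_meeting += 1
        if 1 <= n_meeting < len(tissue_samples):
            out.append(gene)
    return out


def rank_table(table: ExpressionTable, sample: str, n: int = 10) -> list:
    """Top-n gene groups by normalised total count, descending; ties
    broken lexicographically by id. n beyond the gene count returns all."""
    if n < 1:
        raise ValueError("n must be >= 1")
    df = table.raw[sample]
    ranked = sorted(df.index, key=lambda g: (-table.normalized(g, sample), g))
    return ranked[:n]


def calls_to_frame(calls: Sequence[EnrichmentCall], tissue_samples: Sequence[str]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"gene_id": c.gene_id, "call": c.call}
        for s in tissue_samples:
            fc = c.fold_changes.get(s)
            row[f"fold_{s}"] = "" if fc is None else f"{fc:.4g}"
        rows.append(row)
    return pd.DataFrame(rows)
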