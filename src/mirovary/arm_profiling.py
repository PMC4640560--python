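"""Mapping collapsed small-RNA reads onto hairpin precursors.

A miRNA hairpin yields up to two mature products, one per stem arm. Reads
are assigned to a precursor by exact substring match (T/U-normalised,
case-folded), then to an arm by the position of their 5' end relative to
the annotated mature intervals. Per gene and sample this produces arm read
counts, the dominant arm, and the 5'-start homogeneity of each arm — the
fraction of an arm's reads sharing the modal 5' start position — which is
what the isomiR heterogeneity filter downstream tests.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

_RNA_COMPLEMENT = str.maketrans("acgu", "ugca")


def normalize_rna(seq: str) -> str:
    """Lower-case RNA alphabet with T mapped to U."""
    return seq.strip().lower().replace("t", "u")


def reverse_complement(seq: str) -> str:
    return normalize_rna(seq).translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HairpinRecord:
    """A precursor with its two mature products and derived arm intervals.

    Intervals are 0-based half-open positions of each mature product within
    the precursor; the 5' product must end before the 3' product starts.
    """

    gene_id: str
    precursor: str
    mature_5p: str
    mature_3p: str

    def __post_init__(self):
        object.__setattr__(self, "precursor", normalize_rna(self.precursor))
        object.__setattr__(self, "mature_5p", normalize_rna(self.mature_5p))
        object.__setattr__(self, "mature_3p", normalize_rna(self.mature_3p))
        if self.mature_5p not in self.precursor:
            raise ValueError(f"{self.gene_id}: 5' mature product is not a substring of the precursor")
        s5 = self.precursor.find(self.mature_5p)
        s3 = self.precursor.find(self.mature_3p, s5 + len(self.mature_5p))
        if s3 < 0:
            raise ValueError(
                f"{self.gene_id}: 3' mature product does not occur downstream of the 5' product"
            )

    @property
    def arm5_interval(self) -> tuple[int, int]:
        s = self.precursor.find(self.mature_5p)
        return (s, s + len(self.mature_5p))

    @property
    def arm3_interval(self) -> tuple[int, int]:
        s = self.precursor.find(self.mature_3p, self.arm5_interval[1])
        return (s, s + len(self.mature_3p))


@dataclass
class ReadLibrary:
    """A sample's collapsed reads: unique sequence -> occurrence count."""

    sample_id: str
    reads: dict
    total_reads: int = 0

    def __post_init__(self):
        self.reads = {normalize_rna(s): int(c) for s, c in self.reads.items()}
        if any(not s for s in self.reads):
            raise ValueError("empty read sequence")
        self.total_reads = sum(self.reads.values())


@dataclass
class MappedRead:
    sequence: str
    start: int
    length: int
    count: float  # fractional when multi-mapping


@dataclass
class ArmProfile:
    """Per-precursor, per-sample arm quantification.

    Homogeneities are None when the corresponding arm has no reads.
    Counts may be fractional (multi-mapping reads split in equal shares);
    rounding happens only at report time.
    """

    gene_id: str
    sample_id: str
    count_5p: float = 0.0
    count_3p: float = 0.0
    homogeneity_5p: float | None = None
    homogeneity_3p: float | None = None
    mapped_positions: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.count_5p + self.count_3p

    @property
    def dominant_arm(self) -> str:
        return "3p" if self.count_3p > self.count_5p else "5p"

    @property
    def dominant_count(self) -> float:
        return max(self.count_5p, self.count_3p)


def collapse_reads(raw: Iterable[str], sample_id: str = "sample") -> ReadLibrary:
    """Collapse a read multiset into unique sequences with summed counts."""
    counts = Counter(normalize_rna(s) for s in raw)
    return ReadLibrary(sample_id, dict(counts))


def map_reads(
    library: ReadLibrary,
    hairpins: Sequence[HairpinRecord],
    min_len: int = 18,
    max_len: int = 26,
) -> dict:
    """Map collapsed reads onto precursors by exact substring match.

    A read maps to a gene iff its length is within [min_len, max_len] and
    it occurs in the precursor (first occurrence taken for the position).
    Reads occurring in k > 1 precursors contribute count/k to each gene, so
    total mapped count is conserved. Returns gene_id -> list of MappedRead.
    """
    if min_len > max_len:
        raise ValueError(f"min_len={min_len} exceeds max_len={max_len}")
    mapped: dict = defaultdict(list)
    for seq, count in library.reads.items():
        if not (min_len <= len(seq) <= max_len):
            continue
        hits = [(h.gene_id, h.precursor.find(seq)) for h in hairpins if seq in h.precursor]
        if not hits:
            continue
        share = count / len(hits)
        for gene_id, start in hits:
            mapped[gene_id].append(MappedRead(seq, start, len(seq), share))
    return dict(mapped)


def build_arm_profile(
    gene: HairpinRecord,
    mapped_reads: Iterable[MappedRead],
    sample_id: str = "sample",
    loop_tolerance: int = 3,
) -> ArmProfile:
    """Assign mapped reads to arms and compute counts and homogeneities.

    A read belongs to the arm whose mature interval its start position
    falls in, widened by ``loop_tolerance`` nt on each side (5' arm checked
    first where the widened intervals overlap). Reads starting strictly
    inside the loop, or outside both widened intervals, are discarded.
    Per-arm homogeneity = count at the modal 5' start / arm count.
    Dominant arm is the larger count, ties going to the 5' arm.
    """
    a5, a3 = gene.arm5_interval, gene.arm3_interval
    starts_5p: Counter = Counter()
    starts_3p: Counter = Counter()
    positions: Counter = Counter()
    for read in mapped_reads:
        s = read.start
        positions[(s, read.length)] += read.count
        if a5[0] - loop_tolerance <= s < a5[1] + loop_tolerance:
            starts_5p[s] += read.count
        elif a3[0] - loop_tolerance <= s < a3[1] + loop_tolerance:
            starts_3p[s] += read.count
        # else: loop/flank read, excluded from arm counts

    def _summarise(starts: Counter) -> tuple[float, float | None]:
        total = sum(starts.values())
        if total <= 0:
            return 0.0, None
        return total, max(starts.values()) / total

    c5, h5 = _summarise(starts_5p)
    c3, h3 = _summarise(starts_3p)
    return ArmProfile(gene.gene_id, sample_id, c5, c3, h5, h3, dict(positions))


def profile_library(
    library: ReadLibrary,
    hairpins: Sequence[HairpinRecord],
    min_len: int = 18,
    max_len: int = 26,
    loop_tolerance: int = 3,
) -> dict:
    """Map a library and build one ArmProfile per hairpin (zero-read
    profiles included). Returns gene_id -> ArmProfile."""
    mapped = map_reads(library, hairpins, min_len, max_len)
    return {
        h.gene_id: build_arm_profile(
            h, mapped.get(h.gene_id, []), library.sample_id, loop_tolerance
        )
        for h in hairpins
    }


# ---------------------------------------------------------------------------
# I/O: hairpin FASTA + mature-annotation TSV, collapsed FASTA/FASTQ, profiles
# ---------------------------------------------------------------------------

_COLLAPSED_HEADER = re.compile(r"^(?P<id>.+)_x(?P<count>\d+)$")


def read_hairpins(fasta_path, annotation_path) -> list:
    """Load hairpins from a precursor FASTA and a mature-annotation TSV
    with columns gene_id, mature_5p, mature_3p."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    for col in ("gene_id", "mature_5p", "mature_3p"):
        if col not in ann.columns:
            raise ValueError(f"annotation TSV missing column {col!r}")
    hairpins = []
    for row in ann.itertuples(index=False):
        if row.gene_id not in seqs:
            raise ValueError(f"annotated gene {row.gene_id!r} absent from FASTA")
        hairpins.append(HairpinRecord(row.gene_id, seqs[row.gene_id], row.mature_5p, row.mature_3p))
    return hairpins


def read_collapsed_fasta(path, sample_id: str | None = None) -> ReadLibrary:
    """Read a collapsed-read FASTA whose headers carry counts as
    ``>{id}_x{count}``; headers without the suffix count as 1."""
    counts: Counter = Counter()
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COLLAPSED_HEADER.match(rec.id)
        n = int(m.group("count")) if m else 1
        counts[normalize_rna(str(rec.seq))] += n
    return ReadLibrary(sample_id or Path(path).stem, dict(counts))


def read_fastq(path, sample_id: str | None = None) -> ReadLibrary:
    """Read a FASTQ file, one count per record, collapsing duplicates."""
    counts: Counter = Counter()
    for rec in SeqIO.parse(str(path), "fastq"):
        counts[normalize_rna(str(rec.seq))] += 1
    return ReadLibrary(sample_id or Path(path).stem, dict(counts))


def profiles_to_frame(profiles: Mapping[str, Mapping[str, ArmProfile]]) -> pd.DataFrame:
    """Flatten {sample_id: {gene_id: ArmProfile}} to the profile table
    (counts rounded half-up at this report boundary)."""

    def _round(x: float) -> int:
        return int(x + 0.5)

    rows = []
    for sample_id, by_gene in profiles.items():
        for gene_id, p in by_gene.items():
            rows.append(
                {
                    "gene_id": gene_id,
                    "sample_id": sample_id,
                    "count_5p": _round(p.count_5p),
                    "count_3p": _round(p.count_3p),
                    "total": _round(p.total),
                    "dominant_arm": p.dominant_arm,
                    "dominant_count": _round(p.dominant_count),
                    "homogeneity_5p": "" if p.homogeneity_5p is None else f"{p.homogeneity_5p:.6f}",
                    "homogeneity_3p": "" if p.homogeneity_3p is None else f"{p.homogeneity_3p:.6f}",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "sample_id",
            "count_5p",
            "count_3p",
            "total",
            "dominant_arm",
            "dominant_count",
            "homogeneity_5p",
            "homogeneity_3p",
        ],
    )


def frame_to_profiles(frame: pd.DataFrame) -> dict:
    """Inverse of profiles_to_frame (positions are not round-tripped)."""
    out: dict = defaultdict(dict)
    for row in frame.itertuples(index=False):
        out[row.sample_id][row.gene_id] = ArmProfile(
            gene_id=row.gene_id,
            sample_id=row.sample_id,
            count_5p=float(row.count_5p),
            count_3p=float(row.count_3p),
            homogeneity_5p=None if row.homogeneity_5p in ("", None) or pd.isna(row.homogeneity_5p) else float(row.homogeneity_5p),
            homogeneity_3p=None if row.homogeneity_3p in ("", None) or pd.isna(row.homogeneity_3p) else float(row.homogeneity_3p),
        )
    return dict(out)
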