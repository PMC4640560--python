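"""Candidate curation: the filter cascade, known-miRNA annotation, and
gene merging.

Candidate precursors are filtered in a fixed order — contaminant hit,
single-arm expression, low 5'-start homogeneity, then a per-sample
dominant-arm read-count cutoff — recording the first failing rule per
gene and sample. By default the contaminant/structural filters are
applied only to novel candidates (genes absent from the known catalogue),
while the expression cutoff gates every gene; a flag applies the full
cascade to all.

Known-miRNA annotation and the conservation module share one sequence
matcher: two mature products match when some end-to-end alignment at a
5' offset of at most +/-2 nt has no more than ``max_mismatches``
substitutions in the overlapping window.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .arm_profiling import ArmProfile, HairpinRecord, normalize_rna, reverse_complement

RULE_ORDER = ("contaminant", "single_arm", "low_homogeneity", "below_cutoff", "none")


@dataclass(frozen=True)
class CurationDecision:
    gene_id: str
    sample_id: str
    passed: bool
    failed_rule: str  # first failing rule, "none" when passed
    dominant_count: float

    def __post_init__(self):
        if self.failed_rule not in RULE_ORDER:
            raise ValueError(f"unknown rule {self.failed_rule!r}")
        if self.passed != (self.failed_rule == "none"):
            raise ValueError("passed must be equivalent to failed_rule == 'none'")


@dataclass(frozen=True)
class CutoffPolicy:
    """Per-sample dominant-arm read-count thresholds (strict greater-than).

    The study used >50 dominant-arm reads for the deeper library and >18
    for the shallower one, the two being equivalent after scaling for
    miRNA sequencing depth.
    """

    thresholds: Mapping[str, float]

    def __post_init__(self):
        if any(t < 0 for t in self.thresholds.values()):
            raise ValueError("cutoff thresholds must be >= 0")

    def threshold(self, sample_id: str) -> float:
        try:
            return self.thresholds[sample_id]
        except KeyError:
            raise KeyError(f"no cutoff configured for sample {sample_id!r}") from None


def matches_mature(a: str, b: str, max_mismatches: int = 2, max_offset: int = 2) -> bool:
    """End-to-end comparison of two mature sequences over equal-length
    windows at 5' offsets within +/-max_offset; True when the best window
    has <= max_mismatches substitutions."""
    a, b = normalize_rna(a), normalize_rna(b)
    best = None
    for off in range(-max_offset, max_offset + 1):
        mism = 0
        overlap = 0
        for i in range(len(a)):
            j = i + off
            if 0 <= j < len(b):
                overlap += 1
                if a[i] != b[j]:
                    mism += 1
        if overlap >= min(len(a), len(b)) - max_offset:
            best = mism if best is None else min(best, mism)
    return best is not None and best <= max_mismatches


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------


def contaminant_hit(hairpin: HairpinRecord, catalogue: Sequence[str], min_hit_len: int = 16) -> bool:
    """True when the precursor shares an exact substring of at least
    ``min_hit_len`` nt with any catalogue entry, on either strand of the
    entry."""
    prec = hairpin.precursor
    if len(prec) < min_hit_len:
        return False
    kmers = {prec[i: i + min_hit_len] for i in range(len(prec) - min_hit_len + 1)}
    for entry in catalogue:
        for strand in (normalize_rna(entry), reverse_complement(entry)):
            if len(strand) < min_hit_len:
                continue
            if any(strand[i: i + min_hit_len] in kmers for i in range(len(strand) - min_hit_len + 1)):
                return True
    return False


def filter_contaminants(
    hairpins: Sequence[HairpinRecord], catalogue: Sequence[str], min_hit_len: int = 16
) -> tuple:
    """Split hairpins into (survivors, set of contaminant gene_ids)."""
    flagged = {h.gene_id for h in hairpins if contaminant_hit(h, catalogue, min_hit_len)}
    return [h for h in hairpins if h.gene_id not in flagged], flagged


def apply_structural_filters(profile: ArmProfile, min_homogeneity: float = 0.95) -> CurationDecision:
    """Both-arm and 5'-homogeneity rules: fail(single_arm) when either arm
    has no reads, else fail(low_homogeneity) when either arm's modal
    5'-start fraction is below ``min_homogeneity`` (boundary inclusive)."""
    if profile.count_5p == 0 or profile.count_3p == 0:
        return CurationDecision(profile.gene_id, profile.sample_id, False, "single_arm", profile.dominant_count)
    for h in (profile.homogeneity_5p, profile.homogeneity_3p):
        if h is not None and h < min_homogeneity:
            return CurationDecision(profile.gene_id, profile.sample_id, False, "low_homogeneity", profile.dominant_count)
    return CurationDecision(profile.gene_id, profile.sample_id, True, "none", profile.dominant_count)


def apply_expression_cutoff(profile: ArmProfile, policy: CutoffPolicy) -> CurationDecision:
    """Pass iff dominant-arm count strictly exceeds the sample threshold."""
    thr = policy.threshold(profile.sample_id)
    ok = profile.dominant_count > thr
    return CurationDecision(
        profile.gene_id, profile.sample_id, ok, "none" if ok else "below_cutoff", profile.dominant_count
    )


def curate_profile(
    profile: ArmProfile,
    policy: CutoffPolicy,
    contaminant_ids: set | None = None,
    min_homogeneity: float = 0.95,
    is_known: bool = False,
    filter_known: bool = False,
) -> CurationDecision:
    """Run the cascade (contaminant -> single_arm -> low_homogeneity ->
    below_cutoff) for one gene/sample, recording the first failure.

    Known genes skip the contaminant/structural rules unless
    ``filter_known`` is set; the expression cutoff always applies.
    """
    structural = not is_known or filter_known
    if structural and contaminant_ids and profile.gene_id in contaminant_ids:
        return CurationDecision(profile.gene_id, profile.sample_id, False, "contaminant", profile.dominant_count)
    if structural:
        d = apply_structural_filters(profile, min_homogeneity)
        if not d.passed:
            return d
    return apply_expression_cutoff(profile, policy)


def curate_sample(
    profiles: Mapping[str, ArmProfile],
    policy: CutoffPolicy,
    contaminant_ids: set | None = None,
    min_homogeneity: float = 0.95,
    known_ids: set | None = None,
    filter_known: bool = False,
) -> dict:
    """Curate every profile of one sample. Returns gene_id -> CurationDecision."""
    known_ids = known_ids or set()
    return {
        g: curate_profile(p, policy, contaminant_ids, min_homogeneity, g in known_ids, filter_known)
        for g, p in profiles.items()
    }


# ---------------------------------------------------------------------------
# Known-miRNA annotation
# ---------------------------------------------------------------------------


def annotate_known(
    candidate: HairpinRecord,
    known_catalogue: Mapping[str, Sequence[str]],
    max_mismatches: int = 2,
) -> str | None:
    """Match a candidate against a catalogue of known mature products
    ({known_id: [mature sequences]}). Returns the matched id (fewest
    mismatching entry wins, ties by catalogue order) or None for novel."""
    for mature in (candidate.mature_5p, candidate.mature_3p):
        for known_id, seqs in known_catalogue.items():
            if any(matches_mature(mature, s, max_mismatches) for s in seqs):
                return known_id
    return None


# ---------------------------------------------------------------------------
# Shared-arm merging
# ---------------------------------------------------------------------------


@dataclass
class GeneGroup:
    """A merged group of genes sharing a mature product. Counts are the
    per-arm maximum over members, since shared-arm reads are the same
    molecules counted once per member."""

    group_id: str
    members: tuple


def merge_shared_arm(hairpins: Sequence[HairpinRecord]) -> list:
    """Group genes whose mature products (either arm) are identical, by
    transitive closure; group ids concatenate sorted member ids with '/'."""
    parent = {h.gene_id: h.gene_id for h in hairpins}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    by_mature: dict = {}
    for h in hairpins:
        for m in (h.mature_5p, h.mature_3p):
            if m in by_mature:
                ra, rb = find(by_mature[m]), find(h.gene_id)
                if ra != rb:
                    parent[rb] = ra
            else:
                by_mature[m] = h.gene_id
    groups: dict = {}
    for h in hairpins:
        groups.setdefault(find(h.gene_id), []).append(h.gene_id)
    return [GeneGroup("/".join(sorted(m)), tuple(sorted(m))) for m in groups.values()]


def merge_profiles(groups: Sequence[GeneGroup], profiles: Mapping[str, ArmProfile]) -> dict:
    """Collapse per-gene profiles to per-group profiles (max per arm).
    Returns group_id -> ArmProfile."""
    out = {}
    for grp in groups:
        members = [profiles[g] for g in grp.members if g in profiles]
        if not members:
            continue
        sample_id = members[0].sample_id
        c5 = max(p.count_5p for p in members)
        c3 = max(p.count_3p for p in members)
        h5 = next((p.homogeneity_5p for p in members if p.homogeneity_5p is not None), None)
        h3 = next((p.homogeneity_3p for p in members if p.homogeneity_3p is not None), None)
        out[grp.group_id] = ArmProfile(grp.group_id, sample_id, c5, c3, h5, h3)
    return out


# ---------------------------------------------------------------------------
# Cross-sample presence arithmetic
# ---------------------------------------------------------------------------


@dataclass
class PresenceSummary:
    """Set arithmetic over per-sample pass sets, split by known/novel."""

    per_sample: dict  # sample_id -> set of gene ids passing all filters
    known_union: int
    known_shared: int
    novel_union: int
    novel_shared: int
    expressed_total: int
    shared_total: int
    catalogue_total: int


def cross_sample_presence(
    decisions: Mapping[str, Mapping[str, CurationDecision]],
    known_ids: Iterable[str],
    n_previously_known: int | None = None,
) -> PresenceSummary:
    """Summarise which genes pass in which samples.

    ``known_ids`` are genes matching the prior catalogue;
    ``n_previously_known`` is that catalogue's size (defaults to
    len(known_ids)) and enters the combined catalogue total as
    previously-known + novel-union.
    """
    if len(decisions) < 2:
        raise ValueError("cross_sample_presence requires >= 2 curated samples")
    known_ids = set(known_ids)
    per_sample = {
        s: {g for g, d in by_gene.items() if d.passed} for s, by_gene in decisions.items()
    }
    sets = list(per_sample.values())
    union = set.union(*sets)
    shared = set.intersection(*sets)
    known_union = len(union & known_ids)
    novel_union = len(union - known_ids)
    if n_previously_known is None:
        n_previously_known = len(known_ids)
    return PresenceSummary(
        per_sample=per_sample,
        known_union=known_union,
        known_shared=len(shared & known_ids),
        novel_union=novel_union,
        novel_shared=len(shared - known_ids),
        expressed_total=known_union + novel_union,
        shared_total=len(shared),
        catalogue_total=n_previously_known + novel_union,
    )
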