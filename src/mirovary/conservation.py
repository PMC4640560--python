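"""Evolutionary age classification of miRNAs.

A miRNA is 'conserved' when either mature product matches a sequence in
at least one other species' catalogue (windowed comparison with a small
mismatch budget), and 'lineage-specific' when found only in the focal
species. Conserved genes additionally receive an origin category: the
clade label of the most inclusive clade containing a hit species, from
the butterfly lineage outward through Lepidoptera and Amphiesmenoptera
(Lepidoptera + caddisflies) to 'ancient' for pre-amphiesmenopteran
origins.

Catalogues of mature sequences stand in for genome scans: the interface
accepts any species-labelled sequence sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .arm_profiling import HairpinRecord
from .curation import matches_mature

logger = logging.getLogger(__name__)

#: clade order from innermost (species-specific) to outermost (ancient)
DEFAULT_CLADE_ORDER = (
    "species_specific",
    "butterfly_lineage",
    "lepidopteran",
    "amphiesmenopteran",
    "ancient",
)


@dataclass(frozen=True)
class SpeciesTreeConfig:
    """species -> clade label, plus the clade nesting order."""

    clades: Mapping[str, str]
    order: tuple = DEFAULT_CLADE_ORDER

    def __post_init__(self):
        unknown = {c for c in self.clades.values() if c not in self.order}
        if unknown:
            raise ValueError(f"clade labels not in nesting order: {sorted(unknown)}")

    def rank(self, clade: str) -> int:
        return self.order.index(clade)


@dataclass(frozen=True)
class ConservationAnnotation:
    gene_id: str
    age_class: str  # "conserved" | "lineage_specific"
    hit_species: frozenset = frozenset()
    origin: str | None = None

    def __post_init__(self):
        if (self.age_class == "conserved") != bool(self.hit_species):
            raise ValueError("conserved iff hit_species nonempty")


def classify_conservation(
    gene: HairpinRecord,
    species_catalogues: Mapping[str, Sequence[str]],
    max_mismatches: int = 2,
) -> ConservationAnnotation:
    """Age-class a gene by catalogue hits (either mature product, any
    species). An empty catalogue set logs a warning and yields
    lineage_specific."""
    if not species_catalogues:
        logger.warning("no species catalogues supplied; %s classed lineage_specific", gene.gene_id)
    hits = set()
    for species, seqs in species_catalogues.items():
        for mature in (gene.mature_5p, gene.mature_3p):
            if any(matches_mature(mature, s, max_mismatches) for s in seqs):
                hits.add(species)
                break
    age = "conserved" if hits else "lineage_specific"
    return ConservationAnnotation(gene.gene_id, age, frozenset(hits))


def assign_origin_node(annotation: ConservationAnnotation, tree: SpeciesTreeConfig) -> ConservationAnnotation:
    """Attach the origin category: the most inclusive clade containing a
    hit species; species_specific when there are no hits."""
    if not annotation.hit_species:
        return ConservationAnnotation(annotation.gene_id, annotation.age_class, annotation.hit_species, "species_specific")
    missing = [s for s in annotation.hit_species if s not in tree.clades]
    if missing:
        raise KeyError(f"hit species absent from species tree: {sorted(missing)}")
    origin = max((tree.clades[s] for s in annotation.hit_species), key=tree.rank)
    return ConservationAnnotation(annotation.gene_id, annotation.age_class, annotation.hit_species, origin)


def annotate_conservation(
    hairpins: Sequence[HairpinRecord],
    species_catalogues: Mapping[str, Sequence[str]],
    tree: SpeciesTreeConfig | None = None,
    max_mismatches: int = 2,
) -> dict:
    """classify + origin-assign a whole catalogue. Returns gene_id -> annotation."""
    out = {}
    for h in hairpins:
        ann = classify_conservation(h, species_catalogues, max_mismatches)
        if tree is not None:
            ann = assign_origin_node(ann, tree)
        out[h.gene_id] = ann
    return out


@dataclass
class AgeComposition:
    counts: dict = field(default_factory=dict)
    proportions: dict = field(default_factory=dict)
    n: int = 0


def age_composition(
    annotations: Mapping[str, ConservationAnnotation],
    subset: Sequence[str] | None = None,
    by: str = "age_class",
) -> AgeComposition:
    """Counts and proportions of age classes (or origins, by='origin')
    within a gene subset (default: all annotated genes)."""
    genes = list(subset) if subset is not None else list(annotations)
    if not genes:
        raise ValueError("age_composition requires a non-empty gene subset")
    missing = [g for g in genes if g not in annotations]
    if missing:
        raise KeyError(f"unannotated genes: {missing[:3]}")
    counts: dict = {}
    for g in genes:
        key = getattr(annotations[g], by)
        counts[key] = counts.get(key, 0) + 1
    n = len(genes)
    return AgeComposition(counts, {k: v / n for k, v in counts.items()}, n)
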