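"""Synthetic hairpin catalogues and small-RNA read libraries.

Generates ground-truthed inputs for every downstream stage: hairpin
precursors with embedded mature products, per-species mature catalogues
encoding a planted conserved/lineage-specific split, contaminant
sequences, and multinomially sampled read libraries with configurable arm
bias, 5'-start homogeneity (isomiR heterogeneity), contaminant load, a
log-normal spread of expression levels with an age-dependent shift, and a
planted subset of tissue-enriched genes.

Reads are length-preserving substrings of the precursor: the 5' end is
shifted by an offset drawn from ``offset_distribution`` with probability
``1 - homogeneity``, and the 3' end follows at the fixed product length.
Only 5' heterogeneity is modelled because only the 5'-start homogeneity
filter consumes it.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .arm_profiling import HairpinRecord, ReadLibrary, normalize_rna

_ALPHABET = np.array(list("acgu"))

#: species -> clade used for planted conservation hits; innermost to
#: outermost clade order is configured in the conservation module.
DEFAULT_SPECIES_CLADES = {
    "Heliconius_melpomene": "butterfly_lineage",
    "Danaus_plexippus": "butterfly_lineage",
    "Bombyx_mori": "lepidopteran",
    "Manduca_sexta": "lepidopteran",
    "Glyphotaelius_pellucidus": "amphiesmenopteran",
    "Drosophila_melanogaster": "ancient",
}

#: 5'-offset distribution for non-canonical starts: most isomiRs shift by
#: a single nucleotide, larger shifts are progressively rarer.
DEFAULT_OFFSET_DISTRIBUTION = {
    -1: 0.35, 1: 0.35, -2: 0.10, 2: 0.10, -3: 0.05, 3: 0.05,
}


@dataclass
class SimulationParams:
    """Study-condition knobs for the generator.

    Defaults mirror the study: a 150-gene catalogue with 83 conserved
    members, million-read libraries, near-homogeneous 5' starts, and a
    small planted set of ovary-enriched genes amplified 8-fold.
    """

    n_mirnas: int = 150
    conserved_fraction: float = 83 / 150
    depth: int = 1_000_000
    arm_bias: float = 0.5
    homogeneity: float = 0.98
    offset_distribution: dict = field(default_factory=lambda: dict(DEFAULT_OFFSET_DISTRIBUTION))
    contaminant_fraction: float = 0.05
    enrichment_factor: float = 8.0
    n_enriched: int = 5
    age_effect: float = 1.5
    log_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be > 0")
        for name in ("conserved_fraction", "arm_bias", "homogeneity", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1")
        if self.n_enriched < 0 or self.n_enriched > self.n_mirnas:
            raise ValueError("n_enriched must lie in [0, n_mirnas]")
        if self.log_sd < 0:
            raise ValueError("log_sd must be >= 0")
        total = sum(self.offset_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("offset_distribution probabilities must sum to 1")
        if any(not 1 <= abs(k) <= 3 for k in self.offset_distribution):
            raise ValueError("offset_distribution shifts must be within +/-1..3")


@dataclass
class SyntheticCatalog:
    """A generated hairpin catalogue with planted ground truth."""

    hairpins: list
    truth_age: dict  # gene_id -> "conserved" | "lineage_specific"
    truth_enriched: set
    species_catalogues: dict  # species -> list of mature sequences
    contaminants: list
    expression: dict  # gene_id -> relative expression weight (log-normal)

    def hairpin(self, gene_id: str) -> HairpinRecord:
        return next(h for h in self.hairpins if h.gene_id == gene_id)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def generate_catalog(params: SimulationParams) -> SyntheticCatalog:
    """Build a deterministic synthetic catalogue.

    Each hairpin is 60-120 nt with both mature products (20-24 nt) embedded
    as exact substrings, >=4 nt flanks, and a >=12 nt loop gap so that
    +/-3 nt isomiR offsets never fall off the precursor. Conserved genes
    have their 5' mature product planted verbatim in 1-3 species
    catalogues; lineage-specific genes appear in none.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_mirnas
    hairpins: list = []
    seen_matures: set = set()
    for i in range(n):
        gene_id = f"syn-mir-{i + 1:03d}"
        while True:
            len5, len3 = rng.integers(20, 25, size=2)
            m5, m3 = _random_seq(rng, int(len5)), _random_seq(rng, int(len3))
            if m5 == m3 or m5 in seen_matures or m3 in seen_matures:
                continue
            f5 = int(rng.integers(4, 13))
            gap = int(rng.integers(12, 41))
            f3 = int(rng.integers(4, 13))
            prec = _random_seq(rng, f5) + m5 + _random_seq(rng, gap) + m3 + _random_seq(rng, f3)
            # guard against chance duplicate occurrences, which would make
            # arm intervals ambiguous
            if prec.count(m5) == 1 and prec.count(m3) == 1:
                break
        seen_matures.update((m5, m3))
        hairpins.append(HairpinRecord(gene_id, prec, m5, m3))

    ids = [h.gene_id for h in hairpins]
    n_conserved = int(round(n * params.conserved_fraction))
    conserved = {str(g) for g in rng.choice(ids, size=n_conserved, replace=False)}
    truth_age = {g: ("conserved" if g in conserved else "lineage_specific") for g in ids}

    species = list(DEFAULT_SPECIES_CLADES)
    species_catalogues: dict = {s: [] for s in species}
    for h in hairpins:
        if truth_age[h.gene_id] == "conserved":
            k = int(rng.integers(1, 4))
            for s in rng.choice(species, size=k, replace=False):
                species_catalogues[s].append(h.mature_5p)

    contaminants = [_random_seq(rng, int(rng.integers(80, 301))) for _ in range(10)]

    log_expr = rng.normal(0.0, params.log_sd, size=n)
    expression = {
        g: float(np.exp(log_expr[i] + (params.age_effect if truth_age[g] == "conserved" else 0.0)))
        for i, g in enumerate(ids)
    }
    # enrichment is planted in the 50th-90th percentile band of base
    # expression: below the median a planted gene would be undetectable in
    # principle, while planting on library-dominating genes would shift the
    # per-million denominator itself and dilute every realized fold change
    by_expr = sorted(ids, key=expression.get)
    eligible = by_expr[int(0.5 * n): int(0.9 * n)]
    if len(eligible) < params.n_enriched:  # tiny catalogues: widen toward the top
        eligible = by_expr[-max(params.n_enriched, n - n // 2):]
    truth_enriched = {str(g) for g in rng.choice(eligible, size=params.n_enriched, replace=False)}
    return SyntheticCatalog(hairpins, truth_age, truth_enriched, species_catalogues, contaminants, expression)


def _library_rng(params: SimulationParams, sample_id: str) -> np.random.Generator:
    return np.random.default_rng([params.seed, zlib.crc32(sample_id.encode())])


def simulate_library(
    catalog: SyntheticCatalog,
    params: SimulationParams,
    sample_id: str,
    tissue: bool = False,
    rng: np.random.Generator | None = None,
) -> ReadLibrary:
    """Sample one collapsed read library by a single multinomial draw.

    Outcomes are (gene, arm, 5'-offset) read sequences plus contaminant
    sequences. Gene weights are the catalogue's log-normal expression
    values, multiplied by ``enrichment_factor`` for planted genes when the
    ``tissue`` flag is set; within a gene, ``arm_bias`` splits reads
    between arms and ``homogeneity`` is the probability of the canonical
    5' start. Contaminants take ``contaminant_fraction`` of the library,
    half random sequences and half fragments of catalogue contaminant
    entries.
    """
    params.validate()
    if rng is None:
        rng = _library_rng(params, sample_id)

    sequences: list = []
    weights: list = []
    for h in catalog.hairpins:
        w = catalog.expression[h.gene_id]
        if tissue and h.gene_id in catalog.truth_enriched:
            w *= params.enrichment_factor
        for interval, arm_w in ((h.arm5_interval, params.arm_bias), (h.arm3_interval, 1.0 - params.arm_bias)):
            start, end = interval
            length = end - start
            base = w * arm_w
            if base <= 0:
                continue
            sequences.append(h.precursor[start:end])
            weights.append(base * params.homogeneity)
            for off, p_off in params.offset_distribution.items():
                s = start + off
                sequences.append(h.precursor[s: s + length])
                weights.append(base * (1.0 - params.homogeneity) * p_off)

    weights = np.asarray(weights, dtype=float)
    if params.contaminant_fraction > 0:
        n_spec = 20
        cont_seqs = []
        for j in range(n_spec):
            if j % 2 == 0 or not catalog.contaminants:
                cont_seqs.append(_random_seq(rng, int(rng.integers(18, 27))))
            else:
                src = catalog.contaminants[int(rng.integers(len(catalog.contaminants)))]
                ln = int(rng.integers(18, 27))
                s = int(rng.integers(0, len(src) - ln + 1))
                cont_seqs.append(src[s: s + ln])
        mirna_mass = weights.sum()
        cont_each = (
            params.contaminant_fraction
            * mirna_mass
            / (1.0 - params.contaminant_fraction)
            / n_spec
        ) if params.contaminant_fraction < 1.0 else 1.0
        sequences.extend(cont_seqs)
        weights = np.concatenate([weights, np.full(len(cont_seqs), cont_each)])

    probs = weights / weights.sum()
    counts = rng.multinomial(params.depth, probs)
    reads: dict = {}
    for seq, c in zip(sequences, counts):
        if c > 0:
            reads[seq] = reads.get(seq, 0) + int(c)
    return ReadLibrary(sample_id, reads)


# ---------------------------------------------------------------------------
# Fixture serialization (plain-text formats only)
# ---------------------------------------------------------------------------


def _write_fasta(path: Path, records: Iterable[tuple]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_fixture(catalog: SyntheticCatalog, libraries: Iterable[ReadLibrary], out_dir) -> dict:
    """Write a catalogue + libraries as a self-contained fixture directory.

    Produces hairpins.fa, mature_annotations.tsv, per-sample collapsed
    FASTAs (``reads_{sample}.fa`` with ``>{id}_x{count}`` headers),
    per-species catalogues, species_clades.tsv, contaminants.fa and
    truth.tsv. Returns the written paths keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["hairpins"] = out / "hairpins.fa"
    _write_fasta(paths["hairpins"], ((h.gene_id, h.precursor) for h in catalog.hairpins))

    paths["annotations"] = out / "mature_annotations.tsv"
    pd.DataFrame(
        [(h.gene_id, h.mature_5p, h.mature_3p) for h in catalog.hairpins],
        columns=["gene_id", "mature_5p", "mature_3p"],
    ).to_csv(paths["annotations"], sep="\t", index=False)

    paths["truth"] = out / "truth.tsv"
    pd.DataFrame(
        [
            (
                h.gene_id,
                catalog.truth_age[h.gene_id],
                int(h.gene_id in catalog.truth_enriched),
                f"{catalog.expression[h.gene_id]:.17g}",
            )
            for h in catalog.hairpins
        ],
        columns=["gene_id", "age", "enriched", "expression"],
    ).to_csv(paths["truth"], sep="\t", index=False)

    paths["contaminants"] = out / "contaminants.fa"
    _write_fasta(paths["contaminants"], ((f"contaminant-{i+1}", s) for i, s in enumerate(catalog.contaminants)))

    paths["species_clades"] = out / "species_clades.tsv"
    pd.DataFrame(
        sorted(DEFAULT_SPECIES_CLADES.items()), columns=["species", "clade"]
    ).to_csv(paths["species_clades"], sep="\t", index=False)
    paths["species"] = {}
    for species, seqs in catalog.species_catalogues.items():
        p = out / f"species_{species}.fa"
        _write_fasta(p, ((f"{species}-mat-{i+1}", s) for i, s in enumerate(seqs)))
        paths["species"][species] = p

    paths["reads"] = {}
    for lib in libraries:
        p = out / f"reads_{lib.sample_id}.fa"
        _write_fasta(
            p,
            (
                (f"{lib.sample_id}-r{i+1}_x{count}", seq)
                for i, (seq, count) in enumerate(sorted(lib.reads.items()))
            ),
        )
        paths["reads"][lib.sample_id] = p
    return paths


def read_fixture(fixture_dir) -> tuple:
    """Load a fixture directory back into (SyntheticCatalog, {sample: ReadLibrary})."""
    from .arm_profiling import read_collapsed_fasta, read_hairpins
    from Bio import SeqIO

    d = Path(fixture_dir)
    hairpins = read_hairpins(d / "hairpins.fa", d / "mature_annotations.tsv")
    truth = pd.read_csv(d / "truth.tsv", sep="\t")
    truth_age = dict(zip(truth.gene_id, truth.age))
    truth_enriched = set(truth.gene_id[truth.enriched == 1])
    expression = dict(zip(truth.gene_id, truth.expression.astype(float)))
    contaminants = [normalize_rna(str(r.seq)) for r in SeqIO.parse(str(d / "contaminants.fa"), "fasta")]
    species_catalogues = {}
    for p in sorted(d.glob("species_*.fa")):
        species = p.stem.removeprefix("species_")
        species_catalogues[species] = [normalize_rna(str(r.seq)) for r in SeqIO.parse(str(p), "fasta")]
    catalog = SyntheticCatalog(hairpins, truth_age, truth_enriched, species_catalogues, contaminants, expression)
    libraries = {}
    for p in sorted(d.glob("reads_*.fa")):
        sample = p.stem.removeprefix("reads_")
        libraries[sample] = read_collapsed_fasta(p, sample)
    return catalog, libraries
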