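# Methods

## Quantification model

A miRNA hairpin yields reads from two arms. Mapping is exact substring
matching of collapsed reads (18–26 nt by default) against precursors, with
T↔U normalisation and case folding. Exact matching is deterministic and
reproducible; a mismatch-tolerant mapper changes counts only marginally for
miRNA-sized reads on a catalogue of this size. Reads found in k precursors
contribute 1/k of their count to each, which conserves total mapped counts;
fractional counts are rounded half-up only when tables are written.

A read is assigned to the arm whose mature interval contains its 5′ start,
with the interval widened by a ±3 nt tolerance (the usual isomiR window);
where the widened intervals would overlap, the 5′ arm is checked first.
Reads starting strictly inside the loop or outside both widened intervals
are dropped from arm counts. Per arm, **homogeneity** is the fraction of arm
reads sharing the modal 5′ start, computed on read counts (not distinct
sequences). The dominant arm is the one with the larger count; ties go to
the 5′ arm for determinism.

## Curation cascade

Rules run in a fixed order and the first failure is recorded:
`contaminant → single_arm → low_homogeneity → below_cutoff`.

* **contaminant**: the precursor shares an exact substring of ≥ 16 nt with
  any entry of an ncRNA/repeat catalogue, on either strand of the entry.
* **single_arm**: no reads on one arm. Genuine miRNA processing leaves both
  a mature and a star product; degradation fragments do not.
* **low_homogeneity**: either arm with reads has homogeneity < 0.95. The
  threshold is interpreted per arm ("each arm must be ≥ 95 % homogeneous");
  the boundary is inclusive (exactly 0.95 passes). Drosha/Dicer cleavage
  gives miRNAs a precise 5′ end; heterogeneous starts indicate degradation.
* **below_cutoff**: dominant-arm count must strictly exceed the per-sample
  threshold. Thresholds scale with each library's miRNA sequencing depth
  (the bundled study values are >18 and >50 for its two libraries).

By default the contaminant/structural rules apply only to novel candidates
(genes without a hit in the prior catalogue), mirroring a workflow where
known miRNAs were already curated once; the expression cutoff applies to
every gene. A `filter_known` flag applies the full cascade to all genes.

Known-miRNA annotation and cross-species matching share one comparator: two
mature sequences match when the best end-to-end alignment at a 5′ offset
within ±2 nt has ≤ 2 substitutions in the overlapping window (both knobs
configurable). Genes whose mature products are identical are merged by
transitive closure; merged counts take the per-arm maximum over members
because shared-arm reads are single molecules observed once per member.

## Conservation and origin

Age is inferred from species-labelled catalogues of mature sequences, which
stand in for genome scans: deterministic, download-free, and the interface
accepts any species → sequences mapping. A gene is conserved iff it hits at
least one other species. The origin category is the clade label of the most
inclusive clade containing a hit, with default nesting (innermost first)
`species_specific < butterfly_lineage < lepidopteran < amphiesmenopteran <
ancient`. Adding catalogues can only move genes toward older origins
(monotone).

## Enrichment calls

Normalisation is reads per million miRNA-mapped reads; the denominator is
each sample's total mapped miRNA count (overridable). Fold change divides
tissue RPM by reference RPM using total (both-arm) counts; a zero reference
yields an explicit *undefined* flag — no pseudocounts, no infinities. Calls:

* `ovary_upregulated`: fold > threshold (default 4, strict) in **all**
  tissue samples, and above the expression cutoff in all tissue samples;
* `ovary_specific`: zero reference reads and above cutoff in all tissue
  samples — any detection in the reference disqualifies;
* `expressed` / `not_called` otherwise.

The ovary set is the union of the first two classes. Calls are invariant to
rescaling any library (counts and denominator together).

In the published-table reconstruction (`datasets.reconstruct_ovary_set`)
the reference library's per-gene counts are implied from the printed
St Hubert fold changes (reference = total / fold on a common per-million
scale), because the reference's own counts were not republished. St Hubert
folds are therefore recovered exactly, while the other sample's recomputed
folds differ from print (its true normalisation denominator is unknown);
every classification is unaffected since both printed and recomputed folds
sit on the same side of the 4-fold threshold.

The mature products of the five previously known ovary-set genes were also
not republished; `datasets.ovary_set_matures` substitutes deterministic
synthetic placeholder sequences, encoding the one published constraint the
merge rule needs — Par-340 and Par-341 share their 3′ arm product.

## Statistics

* **Mann-Whitney U**, two-tailed, smaller-U convention (the published
  U values are far below n₁n₂/2, consistent with min-U reporting). Ties get
  average ranks; the variance is tie-corrected and a 0.5 continuity
  correction applied. For n₁+n₂ ≤ 12 the p-value is exact:
  P(min-U ≤ observed) over all C(n₁+n₂, n₁) group assignments.
* **Spearman's ρ** as the Pearson correlation of average ranks; p from the
  t approximation with n−2 df, standard at n ≈ 150. Zero rank variance is
  flagged undefined rather than propagating NaN.
* **χ² (2×2)** without continuity correction (both margins are large in the
  intended use); a flag can add it.

The age–expression report codes conserved = 1, lineage-specific = 0
(flipping the coding negates ρ exactly); an ordinal five-level origin coding
is available as an alternative through the composition utilities.

## Synthetic data

The generator emulates the study conditions and is the basis of all
recovery claims. Defaults: 150 hairpins, conserved fraction 83/150, depth
10⁶ reads/sample, arm bias 0.5, homogeneity 0.98, contaminant fraction
0.05, log-normal expression with σ = 2 (reproducing the large spread of
miRNA expression levels), age effect +1.5 on the log-mean of conserved
genes, 5 planted tissue-enriched genes at 8-fold enrichment. Non-canonical
5′ starts draw offsets from {±1: 0.35, ±2: 0.10, ±3: 0.05} — single-
nucleotide isomiR shifts dominate in real libraries. Reads are
length-preserving precursor substrings (3′ end tied to the product length):
only 5′ heterogeneity is modelled because only the 5′ filter consumes it.
Hairpins carry ≥ 4 nt flanks and ≥ 12 nt loops so ±3 offsets never leave
the precursor. One integer seed drives a single generator per call;
per-sample generators are derived deterministically from (seed, sample id).

Enrichment is planted in the 50th–90th percentile band of base expression:
below the median a planted gene can sit under the read-count cutoff at any
realistic depth (enrichment of an undetectable gene is unobservable in
principle), while planting on a library-dominating gene inflates the
per-million denominator itself and dilutes every realized fold change — a
known pathology of proportion-based normalisation, not of the caller.

What the generator does **not** model: sequencing error, adapter remnants
(inputs are assumed adapter-trimmed), 3′ isomiR heterogeneity, hairpin
secondary structure, cross-mapping between paralogues (mature sequences are
generated unique), or biological covariance of expression between samples
(each library is an independent multinomial draw around shared gene-level
weights). Passing recovery tests therefore demonstrate correctness of the
counting, filtering and calling logic under the stated noise model, not
robustness to alignment artefacts or paralogy in real libraries.

## Problem sizes and tolerances

The type-I error simulation uses 200 replicates of 150-gene transcriptomes
at depth 5×10⁴ (rejection-rate band 0.5–10 % around the nominal 5 %);
the Mann-Whitney/enumeration agreement check uses 200 random instances with
n₁+n₂ ≤ 10; planted-enrichment recovery runs at the full default depth of
10⁶ reads across 2 tissue + 1 reference libraries. Homogeneity assertions
on simulated arms use a ±0.01 band, several standard errors wide at the
depths used. Numerical comparisons of U and exact p-values use a 10⁻⁹
absolute guard when comparing against enumeration.

## Known limitations

* Exact-substring mapping undercounts reads carrying sequencing errors or
  untemplated additions; the cutoffs partially absorb this.
* The reconstruction of the published enrichment analysis is limited by
  what the study printed: one sample's fold changes anchor the implied
  reference, and placeholder matures stand in for unpublished sequences.
* Reproducing the published rank statistics (U = 802.5, ρ = 0.582, the
  58/57/52 cutoff funnel) requires the study's supplementary per-miRNA
  count table, which is not redistributable here; the corresponding test
  documents the required file schema (`data/mirna_read_counts.tsv`) and
  fails until it is supplied.
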