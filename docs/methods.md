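# Methods

## Scope and model

`panpav` implements the computational core of a pan-genome
presence/absence-variation (PAV) workflow for a resequenced crop cohort:

1. **Map-to-pan gene PAV calling** (`panpav.covpav`). Reads of each
   accession are aligned to the pan-genome (reference plus novel
   sequence); a gene is called *present* when the coverage **breadth** —
   the fraction of bases under at least one aligned read, depth ignored —
   exceeds 0.95 over the coding region and 0.85 over the gene body, both
   strictly. The premise is that at sequencing depth ≥ 20× essentially the
   whole genome is covered by at least one read, so a gene whose sequence
   is present in the sample cannot plausibly fall under these thresholds.
   Accession QC keeps samples with sequencing depth ≥ 20× and mapping
   depth ≥ 15× (mapping depth = total mapped bases / genome size). Family
   presence is the OR over member genes.
2. **Cohort SV consolidation** (`panpav.svpop`). Per-sample deletion /
   inversion / duplication / translocation calls pass a support filter
   (≥ 3 k-mer-supporting reads AND (> 4 split reads OR ≥ 3 discordant
   pairs at *both* breakpoints)) and a size filter (100 bp – 1 Mb
   inclusive; translocations have no size). Calls from all samples are
   pooled, canonically sorted, and clustered greedily: a call joins the
   first cluster whose *representative* (highest split+kmer support) it
   can merge with — both endpoints within 1 kb and overlap > half of the
   union extent ("total size" is read as the union interval, the stricter
   interpretation). Cohort variants seen in < 6 accessions or > 80% of
   the cohort are removed before the presence/absence matrix is written.
3. **Novel-sequence logic** (`panpav.novelseq`). Assembler k-mer size is
   planned from depth (`K = 2·int(0.38·depth + 10) + 1`, clamped to
   [15, 127]) and refined by a ±2 hill-climb on contig N50 that stops when
   the middle k of the evaluated triple is maximal (ties stop; each k is
   evaluated once). Scaffolds split into contigs at runs of > 10 Ns;
   contigs > 500 bp with no reference alignment block ≥ 65 bp at ≥ 90%
   identity are novel candidates; redundancy is removed by greedy
   length-sorted clustering at 90% identity (identity = global-alignment
   matches / shorter length, cd-hit-est semantics), re-clustering
   representatives to a fixed point (≤ 3 rounds); contigs whose best
   database hit (min e-value, ties by max identity) lies outside
   Viridiplantae are contaminants (no hit ⇒ kept). Survivors concatenate
   with 100-N spacers into one scaffold with an invertible offset map
   (TSV + AGP). Predicted genes deduplicate at 95% global protein
   identity: reference genes are never removed; a novel gene survives only
   as the representative of a reference-free cluster.
4. **Validation statistics** (`panpav.popgen`). Accession distances are
   mismatch proportions over 0/1 markers; trees are Saitou–Nei neighbor
   joining (deterministic tie-breaks, negative branches clamped to 0) and
   are scored by Fitch small parsimony; heuristic parsimony *search* is
   deliberately replaced by NJ topology + Fitch scoring, since the claim
   under test is group separation, not the optimal tree. Kinship is the
   frequency-standardized (Balding–Nichols-style) matrix adapted to binary
   presence markers: monomorphic markers dropped, marker contribution
   `(x_i−p)(x_j−p)/(p(1−p))`, averaged. Association uses the
   single-random-effect mixed model `y = Xβ + u + e`,
   `u ~ N(0, σg²K)`, `e ~ N(0, σe²I)`: REML is profiled over
   `δ = σe²/σg²` through the spectral decomposition of K projected off X
   (each δ costs O(n)), maximized on a 100-point grid over
   `log δ ∈ [−10, 10]` plus bounded refinement to 1e−6; the scan then
   fixes the variance components and tests each marker by GLS through the
   precomputed rotation (Wald t, df = n − p). Significance uses Bonferroni
   `α/m` with m recomputed from the markers actually tested.

## The synthetic cohort

`panpav.simdata` generates the study conditions every other module is
tested against. Defaults (all in `SimConfig`):

- **Genome**: two 600 kb chromosomes of uniform ACGT (configurable GC,
  no repeat model — threshold logic does not need repeat realism).
- **Genes**: 100 core + 200 dispensable genes, bodies 0.6–1.2 kb with 1–3
  CDS exons, non-overlapping, ≥ 200 bp apart, confined to the first ~65%
  of each chromosome.
- **Population**: 40 accessions in 2 groups; each dispensable gene gets a
  per-group presence frequency drawn from (0.75, 0.95) in one group and
  (0.15, 0.35) in the other, giving the strongly group-structured PAVs the
  validation statistics assume.
- **SVs**: a cohort pool of sites (2× the per-accession count per type;
  sizes 0.3–2 kb) in the gene-free chromosome tails, ≥ 2.5 kb apart so
  distinct sites can never satisfy the 1 kb merge rule. Carriers are
  group-structured like dispensable genes (~0.9 vs ~0.1), which keeps the
  expected per-accession count at the configured value and makes SV-based
  trees separate groups. Deletions/inversions/duplications are applied
  literally; a translocation is a reciprocal chromosome tail swap (at most
  one per chromosome pair per accession).
- **Reads**: error-free by default, 100 bp paired-end at 20×, insert
  normal(460, 50) clamped to ≥ 2 read lengths. Substitution errors at a
  configurable rate; no indel errors, quality model or diploidy.
- **Oracle alignments**: every accession base maps to the reference
  through the piecewise segment map built during realization, so
  alignments are exact by construction; reads crossing a breakpoint are
  clipped to their first aligned block, and reads from excised sequence
  are unmapped. Sequencing errors appear as mismatches, never as clips.
- **Phenotype**: trait = causal PAV marker + polygenic score over the
  remaining dispensable markers (inheriting group structure, hence
  confounding) + noise orthogonalized against the genetic score, mixed so
  the genetic share of variance equals the configured heritability
  (default 0.6) exactly in-sample, with the causal marker carrying
  `causal_share` (default 0.5) of the genetic part. `causal_gene="auto"`
  picks the dispensable gene nearest 50% frequency.

Everything is a pure function of `(inputs, seed)`; stage-specific RNG
streams are derived from the seed, so adding accessions does not reshuffle
the reference.

What passing on this cohort does **not** show: robustness to repeats and
mapping ambiguity, indel/quality error structure, heterozygosity, SV
breakpoint-estimation error beyond the injected ±25 bp jitter, or partial
gene presence. Those belong to the upstream aligner/caller, which this
package consumes as typed inputs.

## Numerical and design choices

- Coordinates are 0-based half-open internally; GFF3/AGP/VCF conversion
  happens only in the readers/writers. Touching half-open intervals merge.
- Breadth counts only aligned-block bases (CIGAR M/=/X); deletions/introns
  inside an alignment are not covered. Secondary/supplementary alignments
  count; duplicates and unmapped records do not.
- Representative transcript = maximal total CDS length, ties by
  transcript id.
- Greedy SV clustering against representatives (not transitive closure)
  prevents chaining drift; canonical sorting makes the result independent
  of input order.
- `plan_kmer` ties: the middle k wins (stops); on hitting a k-bound the
  best evaluated k is chosen, ties toward the current window middle.
- Pairwise identity via edlib global alignment; protein-cluster
  representative = longest sequence, ties by id.
- NJ Q-criterion ties go to the smallest index pair; the 3-taxon remainder
  is solved in closed form.
- REML grid-then-refine guards against local optima; `K = I` makes δ
  unidentifiable (flat profile) — detected and flagged, total variance
  still correct. Kinship PSD tolerance is −1e−8 (relative).
- Variance-component precision depends on kinship eigenvalue dispersion:
  with weakly structured K the null sampling spread of the genetic
  fraction is wide, so the zero-genetic-variance recovery check runs on
  family-structured markers, which give an informative K.
- Monomorphic markers are skipped in scans (counted); markers collinear
  with covariates are skipped with a flag; p-values are floored at the
  smallest positive double.

## Problem sizes

Tests and the acceptance script run at desk scale by design: 1 Mb genomes
for breadth, 40-accession cohorts for end-to-end PAV/SV recovery,
200-accession cohorts × 20 seeds for mixed-model recovery, 100 random
instances per brute-force oracle. The full suite completes in well under a
minute on one CPU.

## Known limitations

- Translocations are modeled as clean reciprocal tail swaps; multiple
  translocations sharing a source chromosome raise a placement error.
- The oracle aligner emits one block per mate (no split alignments), so
  coverage immediately downstream of a breakpoint decays over ~1 read
  length; gene/SV placement margins absorb this.
- `greedy_cluster` is O(n²) edlib alignments — appropriate for novel-contig
  sets of thousands, not millions.
- The k-mer planner's linear depth model constants (0.38, 10) are taken as
  given; refitting them requires raw assembly data out of scope here.
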