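# Methods

This note documents the models, conventions and numerical choices behind
`kdrseq`, in the order the pipeline applies them, together with what the
synthetic data does and does not emulate.

## Gene model and coordinates

A `GeneModel` is a forward-strand genomic sequence with an ordered list of
non-overlapping exons (0-based half-open intervals), the protein position of
the first encoded codon, and the amplified regions, each defined by a primer
pair and the inclusive span of fully sequenced codons. Protein positions are
1-based and follow the reference translation, so the canonical sites carry
their field names (S989P, V1016G, T1520I, F1534C/L). Validation at
construction enforces: exons sorted, disjoint and in bounds; exonic length a
multiple of three; no stop codon anywhere in the modelled segment (it is an
internal stretch of a much larger protein); each region's primers present
exactly once on the forward strand with every span codon inside the
primer-trimmed insert. Codons split by an intron (any phase) map to two
genomic intervals; the codon map is total and injective over the modelled
positions, and tests verify it against the independent full-translation
route.

The bundled reference (`kdrseq.bundled`, id `vgsc_synthetic`) is a
deterministic synthetic stand-in, not the real gene: it models protein
positions 950–1600 with the published primer sequences embedded, wild-type
residues at every surveyed site, and one GT..AG intron inside the DIII-S6
amplicon. The DIII forward primer (`AaNavEx31P`, an exon-anchored primer
name) spans the exon/intron junction — its first nine bases end the first
exon and the remainder reads into the intron — and the junction splits codon
1510 after its first base (phase 1). Intron placement in the real gene is
not claimed; it is a modelling choice that exercises every codon-mapping
code path (split codons, intronic alignment columns, intron-aware frameshift
logic). All unconstrained residues, the intron filler and the flanks come
from a fixed-seed random stream, so the model is byte-stable across runs and
machines. Region spans are DII-S6: 957–1024 and DIII-S6: 1511–1587; codons
overlapping the primer annealing sites (956, 1025+, 1510, 1588+) are outside
the spans and are never called.

The kdr catalogue lists per site the wild-type residue, known mutant
residues, domain and a validated-resistance flag: validated S989P, V1016G,
T1520I, F1534C/L; non-validated "watch" sites F1020S and E1553G, whose
association with resistance is unresolved. Any other observed substitution
is classified `other`. Catalogue and model are cross-validated (positions in
span, wild types agree).

## Synthetic cohorts

`simulate_cohort` expands a declarative `CohortSpec` — populations, groups
of individuals sharing a planted haplotype and optional extra mutations,
clones per individual, substitution noise rate, dropout counts, flank
padding, seed — into per-region clone FASTA files, a manifest and a truth
table. Defaults follow the emulated survey design: 3 clones per individual
per region (the surveys sequence "two to three"), noise 0 (clone sequences
are bidirectionally verified, so the per-mosquito sequence is effectively
error-free), 30 nt flanks, no dropout.

Mutations are planted by rewriting the reference codon to the
minimal-nucleotide-edit codon of the target residue (ties broken by the
lexicographically smallest codon), so amino-acid truth fully determines the
nucleotide sequence. Planted positions must fall inside a region's span —
anything else could never appear in an emitted read and is rejected. Clone
reads are the full primer-to-primer amplicon in random flanking context,
with i.i.d. per-base substitutions at `noise_rate` (a hit always changes the
base) and a fair coin for strand. Dropout individuals are drawn uniformly
without replacement; `one_fail` individuals lose one randomly chosen region,
`both_fail` individuals both (they still appear in the truth table, which is
how the pipeline knows the full collected roster). Identical specs produce
byte-identical outputs.

What the generator does *not* emulate: chromatogram-level artefacts, PCR
chimeras, heterozygote superposition in direct Sanger traces (cloned
amplicons are haploid-phase, so zygosity is out of scope), indel sequencing
errors by default, and primer-site polymorphism. Passing tests therefore
demonstrate correctness of the computational pipeline under the stated read
model, not robustness to every failure mode of wet-lab Sanger data.
Discordant clone sets — heterozygous mosquitoes yielding clones of both
alleles — arise naturally when `noise_rate > 0`; the consensus policy below
defines their arbitration.

The two study cohorts in `kdrseq.datasets` encode the published counts. The
394-individual cohort fixes per-township totals (139/130/83/30/12) and
carrier counts (S989P 216, V1016G 290, F1534C 274, T1520I 2, F1534L 2 in
Patheingyi, F1020S 50 and E1553G 10 with their published township
breakdown); per-township S989P counts follow the published percentages
(54/67/66/21/8). The townships' V1016G- and F1534C-only carriers are not
individually published; their allocation here keeps every township's V1016G
and F1534C frequency inside the published 50.4–92.8% band and puts wild-type
individuals only in the three townships reported to harbour H1. The
411-individual variant appends 17 wild-type individuals and dropout
{both: 5, one: 12} for the sample-filter arithmetic; dropout is random by
design, which is exactly why the frequency cohort carries no dropout — the
excluded mosquitoes contributed no sequence data to the published counts.

## Extraction and consensus

Primer matching is ungapped with a per-primer mismatch tolerance (default
2), degenerate-base-aware on both sides (letters match when their IUPAC base
sets intersect), on both strands. The unique placement with the fewest total
mismatches wins; equally good distinct placements raise an ambiguity error
rather than silently choosing. The amplicon is reported in forward-gene
orientation with primers trimmed.

Consensus (default policy `majority`): per position, a strict base majority
wins; top-count ties emit the IUPAC union of the tied bases; every
non-unanimous column is recorded as discordant. Clones of unequal length are
star-aligned to the longest clone with the same aligner as variant calling
(global mode) before voting; a strict gap majority deletes the column, and
an insertion column survives only on a strict base majority. The alternative
`first` policy returns the first clone verbatim while still reporting
discordance. Which arbitration real surveys used is generally unstated, so
both are provided; with verified clones the policies coincide.

## Alignment

Variant calling uses an explicit three-state Gotoh alignment (numpy
row-sweep, integer scores): match +2, mismatch −3, gap open −5 (the cost of
a length-1 gap), extend −2 per additional base. Consensus amplicons are
aligned semi-globally — the query end to end, reference overhangs free —
against the region's primer-trimmed insert, introns included. Ambiguity
codes score as matches when compatible. Tie-breaking is fixed: the end
column prefers the match state and the rightmost position; traceback prefers
diagonal continuation, then gap-in-query, then gap-in-reference, which
yields one canonical optimum (mismatches over gaps; gaps pushed to
deterministic positions — in repeat context the canonical gap may sit at an
equivalent offset a few bases from where it was "planted", which is
score-identical and handled by the coverage logic). Alignments below 80%
identity (configurable) are flagged unalignable and the individual is
excluded from that region's calls. Tests check score equality against
`Bio.Align.PairwiseAligner` as an independent dynamic-programming oracle on
random sequence pairs.

## Calling, classification, haplotypes

The alignment is projected onto the codon map. A codon is called only when
all three of its reference bases align to query bases, with no insertion
interrupting an intra-exon run; otherwise it is reported uncovered, never
imputed wild-type (this includes codons partially covered by the amplicon
and codons lost to deletions). A gap whose exonic length is not a multiple
of three frameshifts the amplicon: all codons from the gap onward are
uncovered and the individual is flagged for review; intronic gaps and
in-frame coding gaps do not. Observed codons containing ambiguity codes are
expanded; a residue set of size one is called normally, larger sets are
classified `ambiguous` and excluded from mutant counts. Synonymous codon
changes yield no call, and a call is never emitted where observed and
reference codons agree.

Classification: `validated_kdr` when the site is catalogued validated and
the residue is a known mutant; `watch` for known mutants at non-validated
catalogue sites; `other` for everything else. Calls are per-individual
presence/absence — one carrier counts once regardless of clones or calls.

Haplotypes are the residue tuples at (989, 1016, 1520, 1534), wild type
(S, V, T, F) where no call exists. The eleven recurrent combinations carry
fixed labels H1–H11; the single-mutant labels are assigned in position order
(H2 = S989P, H3 = V1016G, H4 = F1534C), a package convention — published
figures define these only graphically — that is configurable through a
naming-map JSON and emitted with every run. Novel tuples get
`N{k}:<mutations>` labels in first-seen order. An ambiguous call or an
uncovered codon at any canonical position makes the haplotype `incomplete`:
it is listed in its own table row and excluded from labelled percentages.
Non-canonical mutations never enter the tuple; they are reported alongside.
The two amplicons are separate molecules, so "haplotype" here means
co-occurrence within one mosquito, not molecular phase; statistical phasing
and linkage analysis are out of scope.

## Tables and rounding

The paired-amplicon filter retains exactly the individuals with both
regions present and reports every exclusion with the missing region(s).
Every percentage in every table is `100 * carriers / retained-n` of its
column, rounded half-up to one decimal via exact decimal arithmetic (this
reproduces all published values, e.g. 290/394 → 73.6, 2/83 → 2.4, and
avoids float-representation artefacts at ties such as 1/2000 → 0.1). The
`Total` column always equals the row-sum of the population counts, and
haplotype-table column counts sum to the column's retained-n; both
invariants are tested. One known divergence: a survey prints 38.9% for a
township value whose exact fraction is 54/139 = 38.849…% → 38.8% under any
single rounding; per-township cells with non-invertible printed counts are
not treated as targets. No inferential statistics are computed — the
reports are descriptive, as in the surveys they mirror.

## Determinism and problem sizes

All randomness flows from `numpy.random.default_rng` seeded by the cohort
spec; reruns of an identical pipeline configuration are byte-identical,
including output files. The shipped cohorts are desk-scale by construction
(411 individuals × 2 regions × 3 clones at most); a full survey run
completes in a few seconds on one CPU, and the property-based tests use
small random cohorts to keep the suite fast while covering the input space.
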