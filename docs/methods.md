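# Methods

This note documents the models, numerical choices and limitations behind
`specprime`: what each stage computes, which parameters matter, and what the
synthetic data generator does and does not emulate.

## Problem setting

Given one or more full-length protein-coding marker sequences per species
(the motivating marker is mitochondrial *COI*, ~1.5 kb, strongly AT-biased in
insects), the goal is a set of species-specific PCR assays: for each species,
a forward/reverse primer pair that amplifies a single product of a predicted
size from that species and nothing from any other species in the panel, even
when templates are mixed. Specificity is obtained by anchoring each primer's
3' terminus on a *diagnostic* site — an alignment column where the target
species carries one unambiguous base and all other species share a single,
different unambiguous base — so that every non-target template presents a
3'-terminal mismatch, which blocks polymerase extension.

## Codon-aware alignment

The marker is coding with a conserved reading frame, so indels between
species occur in codon units. Alignment therefore operates on codons:

- **Pairwise engine.** Global alignment (Gotoh, affine gaps) over codon
  lists. A codon-vs-codon match scores the summed per-nucleotide identity
  (+1 match / −1 mismatch, range −3…+3). A run of L gap codons costs
  `8 + 2·(L−1)`. These defaults make a single-codon indel (cost 8) cheaper
  than three scattered mismatches only when the flanking codons genuinely
  realign, which is the regime observed between full-length coding sequences
  of related species (e.g. a 12 nt length difference = 4 codons).
- **Progressive join.** The first input record seeds the profile; remaining
  records join in order of decreasing pairwise identity to that seed (ties:
  input order). A joining sequence is aligned against the running profile
  with the same gap costs; a profile column scores the mean codon score over
  its non-gap rows (gap rows score 0, so extending an existing gap region is
  not doubly penalised).
- **Frame handling.** A record's `frame_offset` prefix and any trailing
  partial codon are carried as flank columns (right-/left-aligned, gap
  padded), so ungapping any output row reproduces its input exactly.

The pairwise engine is verified against exhaustive enumeration of all
alignments on instances up to 5 codons. The progressive join is heuristic:
for three or more sequences it does not guarantee the sum-of-pairs optimum
(no practical aligner does), and it is validated on constructed indel cases
with a transparent optimum. It is a design aid, not a general-purpose MSA
competitor; pre-aligned FASTA is accepted wherever an alignment is consumed.

## Site profile, diagnostic sites, hypervariable windows

Per column: base counts per species, a polymorphism flag (≥ 2 distinct
unambiguous bases across rows), and a diagnostic call. Columns containing
any gap or ambiguity are never diagnostic — a conservative rule, since a
primer terminus over such a column could not guarantee a mismatch against
every non-target. A column is diagnostic for at most one species by
construction.

Hypervariable windows: sliding windows (default width 100 columns, step 10)
whose polymorphic-column density reaches `min_density` (default 0.15) are
kept, overlapping hits are merged and the merged span rescored over its full
width; output is sorted by descending density, then ascending start. At the
study divergence (p ≈ 0.19) the background polymorphism density itself
exceeds 0.15, so the default scan returns one window spanning most of the
gene — appropriate for *design* (candidates are filtered by diagnostic
anchoring anyway). To *localise* the hotspot against that background, raise
`min_density` above the background density (≈ 0.4 works for the default
generator); the acceptance checks do exactly that.

## Composition and distances

Base composition is computed per species over unambiguous A/C/G/T only
(ambiguity codes excluded from numerator and denominator), overall and per
codon position; positions are classed from each record's own frame offset on
the ungapped sequence, never from alignment columns, so alignment gaps
cannot shift the reading frame. Reported percentages are rounded to two
decimals; full precision is kept internally.

The distance is the uncorrected p-distance with pairwise deletion: for each
pair of rows, `p = mismatches / comparable sites` where a comparable site
has unambiguous non-gap bases in both rows. Gaps are missing data, not a
fifth state. By default each species is first collapsed to a majority-rule
consensus (ties become `N` and are thereby deleted pairwise); per-record
mode is available. Being uncorrected, p understates multiple substitutions;
it is used here as a descriptive divergence summary, not for phylogenetics.

## Melting temperature

Nearest-neighbour summation over the unified ten-dinucleotide ΔH/ΔS
parameter set with terminal initiation terms (A/T ends: +2.3 kcal/mol,
+4.1 cal/mol·K; G/C ends: +0.1, −2.8) and the duplex-symmetry entropy term
(−1.4 cal/mol·K) for self-complementary oligos. Monovalent salt enters as an
entropy correction `ΔS += 0.368·(N−1)·ln([Na+])` (Na+ in M), and the melting
condition uses a quarter of the total strand concentration:

    Tm = 1000·ΔH / (ΔS_salt + R·ln(C/4)) − 273.15   (R = 1.987 cal/mol·K)

Defaults: 50 mM monovalent salt, 500 nM primer. The test suite checks the
implementation to 0.01 °C against two independent oracles: a re-typed
term-by-term summation of the published table, and Biopython's `Tm_NN`
configured with the same parameter set and salt correction.

The default acceptance window for primer Tm is 50–62 °C. On a 70% A+T
template, 18–24-mers under this model and salt span roughly 42–57 °C, so the
window is deliberately placed on the model's own scale; tools that assume
1 M Na+ (Wallace-style) report systematically higher numbers for the same
oligos. The window, like every other constraint, is one config key away.

## Structure screening

Hairpin and dimer screening uses integer match-run heuristics, not
free-energy minimisation — design-stage screening is qualitative:

- `hairpin_score`: longest perfect Watson–Crick stem closable with a loop of
  ≥ 3 nt;
- `self_dimer_score` / `cross_dimer_score`: longest contiguous complementary
  run between the oligo and itself / its partner over all ungapped
  antiparallel offsets.

Default ceilings: hairpin ≤ 4, self-dimer ≤ 8, cross-dimer ≤ 8.

## Candidate enumeration, pairing, ranking

Candidates are substrings (18–24 nt by default, both orientations) of the
target species' majority consensus inside the hypervariable windows. A span
is disqualified outright if the consensus there contains a gap or ambiguity.
Filters, in order: diagnostic anchoring (≥ 1 diagnostic column within the
3'-terminal window of 5 nt, and the terminal base itself diagnostic under
the default `strict_terminal=True`); GC 35–65%; Tm in range; structure
ceilings; then specificity (worst-case over non-target rows: total
mismatches ≥ 2 and a mismatch within the 3' window against *every*
non-target). The 5 nt diagnostic window default reflects the region where
terminal mismatches still measurably impair extension.

Pairs are all forward×reverse combinations with non-overlapping spans,
amplicon length within 550–800 nt on the ungapped target consensus (both
primer footprints included), Tm difference ≤ 3 °C, and cross-dimer under the
ceiling. The published assays this workflow mirrors include validated
amplicons of 561 and 580 bp, which is why the default band opens at 550
rather than 600; the narrower band is a single config change. Ranking uses

    score = w_tm·(Tm closeness to window midpoint)
          + w_diag·(3'-window diagnostic count, both primers)
          + w_spec·(worst-case non-target mismatches)
          − w_struct·(hairpin + self-dimer + cross-dimer)

with weights 1 / 2 / 1 / 0.5, sorted by descending score, then ascending
amplicon start, then ascending length — a total order, so ranking is
invariant under input permutation. `top_n` (default 3) pairs are kept per
species, matching the screening depth of a typical wet-lab candidate round.

## In-silico PCR

A primer binds a template site iff total mismatches ≤ `max_mismatch`
(default 3) *and* the 3'-terminal `block_size` bases (default 2) match
perfectly; ambiguous template bases count as mismatches. Both strands are
scanned; coordinates are 1-based on the + strand. Amplicons are all
(+ forward site, − reverse site) combinations with a convergent geometry and
length ≤ 3000 nt. The block rule encodes the terminal-mismatch extension
block; 3 total mismatches tolerates minor haplotype drift between the design
template and real individuals. These two knobs are documented modelling
choices — no quantitative wet-lab mismatch-tolerance model exists to fit.

Semantics are strictly presence/absence. Mixture columns in the specificity
matrix (the all-species '+' community, the per-target '−' community of the
three non-targets, and 1:1:1:1 … 1:4:4:4 abundance gradients) carry their
copy counts as a dose annotation only: a mixture cell equals the union of
its member species' cells. Amplification efficiency, inhibition and
limit-of-detection behaviour are wet-lab phenomena outside this model's
scope.

## Synthetic family generator

The generator emulates the statistical structure of a four-species
coding-marker family: 515 codons (1545 nt), overall A+T ≈ 70% with the third
and first codon positions most AT-rich and the second most constrained, mean
pairwise p-distance calibrated to 0.19 with 70% of substitution events
concentrated in columns 600–1300, and 20 planted diagnostic columns per
species (disjoint, inside the hotspot). Substitutions never create an
in-frame stop codon (TAA/TAG/TGA).

Two expectation calibrations make the nominal parameters come out in the
realised data rather than merely in the sampling distribution:

- the per-position stationary frequencies are adjusted so that the A+T
  fraction *conditional on stop-free codons and after the expected
  substitution load* equals `at_fraction` (stop codons are AT-rich, so
  naive conditioning depresses A+T; forced-different redraws are
  GC-enriching);
- the per-site substitution probability is solved (bisection) so that the
  expected mean pairwise p — including the fixed 2/n_species contribution of
  every planted column — equals `target_p`, using the two-independent-hit
  mismatch probability `2q(1−q) + (2/3)q²`.

Sites evolve independently per lineage from a shared ancestor; there is no
rate matrix beyond the AT bias, no phylogenetic tree structure, and no
indels (alignment is exercised separately on constructed indel cases).
Consequently, passing tests on these families demonstrates the pipeline's
statistical and combinatorial correctness at realistic divergence and
composition — not robustness to real-data features such as heterogeneous
rates across lineages, within-species haplotype variation, length variation,
or sequencing artefacts. Sampling noise on a 1545 nt sequence gives each
species' A+T a spread of roughly ±1.2 percentage points around the
calibrated 70%, so individual seeds can realise a species slightly below the
marker's 68% floor; seeded checks use verified seeds.

## Determinism and degenerate inputs

Everything outside the generator is deterministic; the generator is fully
determined by its spec (including the seed). Ties are broken by ascending
alignment coordinate throughout. Report writers use fixed column orders and
fixed float formatting, so reruns are byte-identical. Degenerate inputs have
defined behaviour: no diagnostic sites for a species yields an empty
candidate set with a warning (not an error); an empty candidate set yields
an empty pair table; a species pair with zero comparable sites is an error
naming the pair; empty FASTA is a parse error.

## Problem sizes

Tests and the acceptance script run on the default family size (4 species ×
1545 nt), 50-seed generator sweeps, 1000 randomised small-alignment distance
fixtures, 200 randomised binding-site fixtures, and exhaustive alignment
oracles up to 5 codons — sizes at which every oracle comparison is exact and
the whole suite completes in well under a minute.
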