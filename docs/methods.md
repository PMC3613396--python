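# Methods

This note records the models, parameter choices and numerical conventions
behind `dpsevolve`, and what the synthetic world does and does not
establish.

## Coordinates and formats

All in-memory gene coordinates are 0-based half-open on the forward strand;
GFF3 on disk is 1-based inclusive and the conversion is an exact bijection
(round-trip tested). Gene families travel in a GFF `family=` attribute;
records without it get family `other`. Secondary-structure (SS) annotations
use a FASTA-like dialect: per-protein H/E/C state strings with the overall
prediction confidence in the header as `conf=<0-100>`. Ct tables are TSV
with columns `gene, condition, replicate, ct, efficiency, reference_flag`;
validation requires a reference (hrdB) row for every condition × replicate
and complete control/stress pairing per gene.

## Pairwise alignment and E-values

Protein comparison is optimal local (Smith–Waterman) alignment under
BLOSUM62 with BLAST-style affine gaps: a gap of length k costs
`open + k·extend`, defaults open = 10, extend = 1. Identity is the
percentage of identical columns over the full local alignment (gap columns
in the denominator). E-values use the Karlin–Altschul form
`E = K·m·n·e^{−λS}` with fixed gapped constants λ = 0.267, K = 0.041 and
search space m×n per pair. These constants are approximate — they exist to
reproduce the *thresholding behaviour* of a relaxed BLASTP search
(E ≤ 10⁻³), not calibrated statistics, and are documented as such. Best-hit
ties break to the lower E-value, then the lexicographically smaller subject
id, so all searches are deterministic.

Cluster membership follows the back-best-hit logic of a
query-retrieve-reblast search: any protein below the E-value cutoff whose
best reference is family R joins cluster R. This deliberately admits both
members of a recent within-genome duplication, which a strict one-to-one
reciprocal-best-hit pairing cannot (the reference has a single best hit per
genome); strict RBH is exposed separately (`reciprocal_best_hits`) and obeys
symmetry and self-identity properties.

## Structure classification

- Minimum helix run length: 3 residues (shorter H runs are noise).
- Dps signature: exactly five helices with the third *strictly* the
  shortest and ≤ 15 residues (the BC helix). Four-helix profiles are
  ferritin-like.
- Tail classes: a tail is "long" at ≥ 10 residues. The source analysis
  never quantifies short vs long; these values reproduce the qualitative
  classes on the synthetic fixtures and are exposed as parameters.
- Confidence filter: records with SS confidence strictly below 40% are
  dropped ("lower than 40%" is a strict inequality; 40 is retained). The
  filter is idempotent.

## Trees

Distances are p-distances (mismatches over compared columns, gap columns
excluded pairwise); no substitution-model correction is applied for the
discrimination tree — maximum-likelihood inference is out of scope and
delegated to external tools. Neighbor joining is the standard Saitou–Nei
agglomeration with the Studier–Keppler Q criterion; negative branch lengths
are clamped to zero; ties in Q break to the smallest current index pair.
On additive matrices the algorithm recovers topology and branch lengths
exactly (property-tested to 1e-9 on random trees of up to 8 taxa).

Bootstrap: alignment columns resampled with replacement, one NJ tree per
pseudoreplicate (default 500), bipartitions kept at strictly > 50%
frequency (a tie at exactly 50% is not a majority), supports reported as
percentages. Consensus construction inserts retained splits greedily in
order of decreasing frequency; splits above 50% are mutually compatible so
the construction cannot conflict.

Bacterioferritin exclusion roots a clone of the full-data NJ tree at the
midpoint, takes the smallest clade that joins the bacterioferritin
references with at least one other taxon ("grouped together with"), and
excludes a record only if it is in that clade *and* fails the Dps
signature — the conjunction matters: a structurally complete Dps is kept
wherever it sits in the tree. Consensus trees carry supports but no branch
lengths; when a consensus tree is passed directly, unit lengths are assumed
for midpoint rooting.

## Promoter scanning

The pattern grammar is `LEFT(N)min-maxRIGHT` in IUPAC code; the SigB
consensus is `GNNTN(N)14-16GGGYAY`. Scanning reports every admissible
(start, spacer) combination — one position can yield up to three
overlapping hits — on both strands, with reverse-strand hits mapped to
forward coordinates as the matched span. An `N` in the subject matches
nothing (masked regions cannot produce hits). The implementation compiles
one fixed-length lookahead regex per spacer length; an exhaustive
try-every-start-and-spacer oracle lives in the test suite and the two agree
on thousands of random sequences.

Per-gene calls scan the coding strand of a 2×200 nt upstream window (so
too-distant motifs are seen and rejected by the distance filter rather than
silently missed) and require: every base of the hit intergenic (overlapping
no annotated gene span on either strand), and the motif 3′ end within
200 nt of the start codon. "Distance" is 3′-end-to-ATG on the coding
strand — the biologically natural promoter-proximity anchor; the choice of
anchor and the coding-strand restriction (a promoter must be co-oriented
with its ORF) are explicit substitutes for an unstated convention.

## Chromosome context

Replicons are oriented by the *dnaA* strand: a minus-strand dnaA mirrors
all coordinates (s,e) → (L−e, L−s), flips strands and reverse-complements
the sequence; the operation is a fixed point afterwards. Gene position is
the midpoint in Mb ("approximate location"); compartment is arm iff the
midpoint's distance to the nearest end is strictly below the threshold
(default 2,000,000 bp — a single reproducible stand-in for per-species
published core boundaries). Neighbourhoods are offsets in gene-rank space
(−k..+k, k = 3), read in the focal gene's direction so profiles are
comparable across strands and genomes; synteny consensus reports the modal
family and its percentage among genomes with a defined entry per offset,
and a gene-level synteny score is the mean modal frequency over offsets.

## Expression

Pfaffl ratio `E_t^ΔCt_t / E_ref^ΔCt_ref` with ΔCt = Ct_control − Ct_stress,
computed per biological replicate and summarised as mean and sample (n−1)
SD. Induction is mean ≥ 2.0-fold — the source analysis says "significantly
upregulated" without naming a test, so a deterministic fold threshold is
the default (parameter-exposed). Efficiencies are per-amplicon inputs in
[1, 2]; a convenience estimator `E = 10^(−1/slope)` from a dilution series
is provided. Concordance between promoter calls and induction is a 2×2
table plus percentage agreement.

## The synthetic world

Defaults are the stated conditions of the emulated study wherever one
exists, otherwise a realistic choice made once:

| parameter | default | rationale |
|---|---|---|
| replicon length | 8 Mb | typical linear *Streptomyces* chromosome |
| GC content | 70% | *Streptomyces*-like; realistic chance-hit rates |
| dnaA position | central 10% | orientation calibration |
| arm threshold | 2 Mb | terminal lateral-transfer hot spots |
| cohort size | 17 genomes | the emulated genome comparison |
| annotated genes | 50 per replicon | scaled-down annotation; only gene-rank neighbourhoods and upstream windows matter downstream |
| paralog identity | N(97, 1.5) truncated to (85, 100) | reported pairwise similarity of duplicated dpsB |
| motif placement | intergenic, coding strand, 3′ end 20–160 nt upstream; spacer uniform {14,15,16}; degenerate positions uniform | exercises the full pattern space |
| member divergence | 5–10% from family ancestors | within the 15% envelope where family recovery is exact |
| family divergence | 30% from a common root (bfr 40%) | clean clades with a distinct outgroup |
| true induced ratio | 8 | strong induction; no numeric fold changes are printed in the emulated figures, value chosen once |
| Ct noise | Normal(0, 0.2) per well | no noise model is stated; assumption |
| qPCR replicates, E | 3, 2.0 | three biological replicates; ideal doubling |

All proteins are 170 residues and evolve by substitutions only, so the
stacked member/reference/bacterioferritin sequences *are* an ungapped
alignment — sequence, proteome and tree inputs stay mutually consistent,
and planted identities are analytically exact. Tails are planted per
protein (family base ± 2 residues, categories preserved); interior loops
absorb the length budget. Background genes get random proteins that are
rejection-sampled against chance reference hits below the E-value cutoff,
and scanned upstream windows are rejection-sampled free of chance motif
hits — so within-window sensitivity/false-positive statements and exact
family recovery hold *by construction*; scanner statistics elsewhere are
tested separately against the oracle. Decoy plants (17-nt spacer; motif
250 nt upstream) are negative controls a correct scanner must reject.
Replicons are emitted mirrored with probability 1/2 so orientation
calibration is always exercised.

What a green end-to-end test establishes: every stage recovers its planted
signal and the stages compose. What it does not establish: behaviour on
real annotations (overlapping genes, operons, pseudogenes), real protein
alignments (indels, domain rearrangements), promoter variants outside the
consensus, or qPCR pathologies (efficiency drift, outlier replicates).

Ct tables share one hrdB measurement per condition × replicate across the
panel, as in a real run; consequently panel-wide error statistics are
dominated by the shared reference draws, and error-distribution claims are
evaluated over independently simulated genes.

## Known limitations

- The Karlin–Altschul constants are fixed, not fitted; absolute E-values
  are approximate (thresholding behaviour is what is validated).
- NJ tie-breaking is index-based; bootstrap supports are
  permutation-invariant only when the data admit no distance ties.
- The compartment boundary is a single global threshold; per-species core
  coordinates would shift individual calls near 2 Mb.
- Tail-class proportions reported for real genera are not reproduced here:
  they depend on the external genome databases and on an overlapping-class
  convention that is not fully specified.
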