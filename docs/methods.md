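# Methods

This note documents the models and procedures `abrep` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Curation model

Repertoire sequencing reads are redundant (several mRNA molecules per
cell, PCR amplification) and noisy (polymerase errors, base miscalls).
Curation reduces them to one sequence per original transcript.

**Quality filter.** The expected number of miscalls in a read is
`E = Σ_b 10^(-Q_b/10)` over its Phred scores; reads with `E > 20` or
merged length < 300 nt are discarded. Both thresholds are exposed
(`QCThresholds`); 300 nt corresponds to the shortest read covering most of
a V(D)J region, and E ≤ 20 admits long reads while bounding the absolute
error load.

**UMI path.** Reads are grouped by identical UMI. Because PCR crossover
and UMI collisions can put molecules of different cells under one UMI,
each group is greedily subclustered at 97% identity before consensus;
97% comfortably separates distinct cells (which differ by junction
sequence plus SHM, typically > 5% apart) while keeping all error-bearing
copies of one molecule (errors at the ~0.1–1% scale) together. Each
subcluster is collapsed by star alignment to its most abundant member and
column-wise majority vote (abundance-weighted; ties resolved to the most
abundant member's base; majority-gap columns dropped). Exact-duplicate
consensus sequences — multiple mRNAs of one cell — are merged. Consensus
records with neither UMI duplicates (subcluster size 1) nor consensus
duplicates are singletons and are removed: a sequence seen exactly once in
the whole library is indistinguishable from a PCR artifact.

**Cluster path (no UMI).** Exact duplicates are collapsed first, so
abundance records sequencing depth. Records are then greedily clustered at
99% identity in abundance-descending order (ties: longer sequence, then
lexicographic), each record joining the first existing seed within
threshold. The assumption is that a real transcript is sequenced many
times, so the deepest record of a neighborhood is the error-free one;
sequencing errors sit a few edits from their seed and are absorbed, while
artifacts appear as clusters of total size 1 and are dropped
(`min_cluster_size = 2`). The procedure is deterministic and idempotent.

**Identity definition.** Pairwise identity between sequences is the
Levenshtein identity `1 − d/max(|a|, |b|)` with unit-cost edit distance
`d` (edlib backend). This is the deterministic definition used by the
USEARCH/vsearch family of greedy clusterers; unlike per-alignment
"matches/columns" measures it does not depend on which co-optimal
alignment an aligner happens to return. Consequence: a sequence that is a
clean prefix of another is penalized for the length difference; on
libraries mixing very different read spans a span-aware identity would be
preferable. The greedy clusterer's threshold test is computed with a
banded search (`d ≤ (1−t)·max len`), which is exactly equivalent to
thresholding the identity.

**Repertoire filter.** Repertoires with fewer than 1,700 unique
transcripts are flagged for exclusion from cross-repertoire statistics, as
small libraries bias frequency estimates.

## Annotation

Germline V/D/J assignment uses local alignment with nucleotide-BLAST-like
scores (+2 match, −3 mismatch, −5 gap open, −2 extend; all configurable).
Ties between equal-scoring alleles break by higher identity, then
lexicographic allele name, so runs are reproducible. J is searched
strictly 3′ of the V span; D (heavy chains) between V and J, with a call
withheld unless the best D alignment contains ≥ 5 contiguous matching
nucleotides — below that, short random matches masquerade as D genes.
Significance is summarized Karlin–Altschul style,
`evalue_like = K·m·n·exp(−λS)` with K = 0.41, λ = 0.625 (documented
constants, configurable); isotype (CH1) and sequence-search hits use a
1e-6 cutoff.

CDR3 runs strictly between the codon aligned to the germline V's 2nd
conserved Cys (IMGT 104) and the first Trp/Phe of the J WGXG/FGXG motif
(IMGT 118); it is reported absent when either anchor is unlocatable or
mutated away, or the interval is not a codon multiple (out-of-frame
junction). Productiveness additionally requires a stop-free V(D)J region
in the germline V frame. SHM is `100 × mismatched / aligned` V columns, N
bases excluded from both counts. Note that a cluster of adjacent
substitutions can admit a gapped alignment of equal or better score than
the mismatch-only one; SHM then reflects the returned alignment.

Numbering is IMGT-native: V columns map through the germline gene's
gapped coordinates; CDR3 residues are numbered 105–117 by the symmetric
fill rule (shorter loops omit 111, then 112, then 110, …; longer loops
gain 111.1/112.1 insertion codes). Kabat and Chothia labels are produced
by composing the IMGT map with a static per-gene translation table;
tables for the toy germline ship with the package (sequential renumbering
of the positions each toy gene occupies) and users can register tables
for real genes. Full HMM-based renumbering of arbitrary sequences is out
of scope.

## Clonotypes, GSSPs, rarity

Clones group transcripts with the same V gene, J gene and CDR3 length
whose CDR3 nucleotide identity to the clone seed is ≥ 90%. One
representative (highest abundance) per clone enters profile construction,
so clonal expansions contribute a single observation.

GSSP normalization defaults to `per_observed`: `freq(p, X)` divides the
representatives carrying non-germline residue `X` at `p` by all
representatives observing `p`, including unmutated ones. This makes the
rare-mutation threshold ("frequency < 0.5%") an unconditional probability
of seeing the substitution in a matured sequence. The alternative
`per_mutated` mode (conditioning on a mutation at the position, so
frequencies at a mutated position sum to 1) is provided behind a flag, and
serialized profiles carry their mode. Profiles built from fewer than 100
clones are withheld. Profiles are keyed by gene, not allele; each
transcript's substitutions are called against its own assigned allele, so
allelic differences are not counted as mutations. Rarity is exactly
`(1 − freq) × 100`%.

Profile comparison is the Pearson correlation over (position, residue)
cells at positions both profiles cover, with absent cells counted as 0.

## GSNPs

Transcripts with SHM > 1% are eligible (below that, too few mutations
exist for somatically introduced sites to be meaningful). For each
eligible transcript the numbered V-region residues are scanned for
N-X-S/T sequons with X ≠ Pro; a site counts only if no sequon exists at
the homologous numbered position of the transcript's germline V gene.
Frequencies divide by eligible transcripts per gene (not donors). The
sequon rule is a sequence-level necessary condition; a structure-aware
occupancy predictor would remove some sites, so these frequencies are an
upper bound on glycosylation. Sequons are reported at the Asn's IMGT
position and counted only when all three residues are numbered.

## Prevalence and rarefaction

The motif grammar is dash-separated slots: `X` any residue, `[...]` a
residue class, plain letters literal; motifs anchor over the full CDR3.
Position-mode queries fail on unnumbered or unobserved positions — an
unobserved position is evidence of absence of the signature, not missing
data to be forgiven. The frequency denominator is explicit: unique
transcripts of the query's germline gene when a gene constraint exists
(the natural reference class for "how often does this gene's rearrangement
carry the signature"), the whole repertoire otherwise; both are available
because a gene-origin signature with a same-gene denominator is trivially
1. Paired-chain prevalence multiplies two whole-repertoire chain
frequencies (random-pairing assumption) and reports per million B cells to
two significant figures.

Rarefaction draws, for each subset size `i`, `N = 20` random
subsets without replacement (independently across repeats, one seeded
generator) and reports `CV_i` = sample (n−1) SD of the repeat mean
frequencies over their mean. An `exhaustive` flag enumerates all
`C(n, i)` subsets instead, which makes small-panel results exactly
checkable against direct enumeration. Subset indices are sorted before
averaging so identical subsets give bit-identical means and a uniform
panel yields exactly CV = 0.

## Synthetic-data generator

The simulator emulates, per cell: uniform V/(D)/J choice, N-region
insertion (geometric length, mean 4 nt), junction padding to keep the J
anchor in frame, stop-codon-free redraws (bounded), then point SHM at a
configurable per-base rate with a multiplier inside WRC/GYW AID hotspot
motifs; per molecule: a UMI (collisions only at the configured rate —
uniqueness is enforced by rejection sampling at rate 0) and a PCR
duplicate count; per read: independent per-base PCR errors, Phred scores
from a clipped normal, and miscalls injected at the rate the emitted
quality string implies. One seeded generator drives all draws in a fixed
order (cells → molecules → copies → read noise → final shuffle), so a
config is a complete specification of its output.

Reference study conditions for curation recovery
(`sim.curation_study_config`): 1,000 cells, 3 mRNA per cell, 5 PCR
duplicates per molecule (fixed counts), PCR error 1e-3/base, ~Q40
sequencing, 12-nt UMIs, no collisions. Five duplicates per molecule: a
majority-vote consensus needs ≥ 3 copies, and at depth 3 two copies
sharing a same-position error still produce voting ties at a small but
non-negligible rate (~5 expected events per 1,000 cells at 1e-3); at
depth 5 the tie probability is negligible, so exact recovery is a
property of the method rather than luck. Three molecules per cell is a
conservative stand-in for the many immunoglobulin mRNAs of a real B cell
and gives the no-UMI path its depth margin.

What the generator does **not** emulate: indel SHM (the pipeline discards
frameshifted transcripts, so substitutions exercise every stage), clonal
lineage structure (cells are independent; clone recovery is tested on
separately constructed lineages), gene-usage and SHM-rate heterogeneity,
chimeric PCR crossover products, quality-by-position decay, and paired
heavy–light single cells. Passing recovery tests on this generator
therefore demonstrates correctness of the collapsing logic under the
stated error model, not performance on real libraries with structured
artifacts.

## Numerical choices and degenerate inputs

- All internal coordinates are 0-based half-open; IMGT labels 1-based.
- Read merging maximizes matches − mismatches over ungapped overlaps
  (ties to the longer overlap) and rejects below 80% overlap identity;
  disagreements resolve to the higher-Phred base with quality
  `|q1 − q2|`, agreements keep `max(q1, q2)`.
- Zero-denominator frequencies are reported absent (None), never 0.
- A rarefaction panel with zero mean frequency reports CV = 0.
- Duplicate germline allele names are a configuration error; an empty
  germline FASTA loads as an empty set with a warning.
- Curation is randomness-free; ordering ties break by abundance, length,
  then sequence, everywhere.

## Problem sizes

The bundled tests and the acceptance script run at desk scale: 1,000-cell
repertoires (~15,000 reads) for curation recovery, 1,000 clone
representatives for profile recovery, 200 randomized trials for the
clustering oracle, ~30,000 strings for the sequon oracle. These sizes give
binomial standard errors small enough for the stated checks while keeping
a full run in tens of seconds.

## Known limitations

- Kabat/Chothia numbering is table-driven and ships only for the toy
  germline; real genes need user-supplied tables.
- The Levenshtein identity slightly penalizes length differences between
  near-identical sequences of unequal span (see Curation model).
- GSNP frequencies are sequon-rule upper bounds, not occupancy
  predictions.
- Signature search is exact on annotations; it does not model annotation
  uncertainty.
- The non-UMI path cannot, by construction, recover a transcript whose
  every read is error-bearing and singleton; its recovery guarantee is
  statistical, tied to sequencing depth.
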