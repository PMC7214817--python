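# Methods

## Coordinate system

All positions are relative to the annotated start codon: position −k is the
k-th nucleotide 5′ of the A of the ATG, which itself starts at 0. A codon
starting at p is in the CDS reading frame iff p ≡ 0 (mod 3). This makes the
canonical *pgd1*-type geometry arithmetically consistent: a 27-nt
motif-encoding region at −39..−13 (9 codons ending immediately before the
last 4 upstream codons) and a 6-nt tandem start-codon pair at −63..−58, both
at in-frame positions. `upstream_index` maps p to the 0-based index
`utr_len + p` and is a bijection from [−utr_len, −1] onto [0, utr_len−1].

## PTS2 consensus matching

The PTS2 motif is modelled as four anchored residue classes with a free
spacer: class 1 {R,K}, class 2 {L,V,I}, spacer of `spacer_len` residues,
class 3 {H,Q}, class 4 {L,A}. The default `spacer_len` is 5, giving the
9-residue consensus (R/K)-(L/V/I)-x₅-(H/Q)-(L/A) that the worked nonapeptide
RISSLAAQL satisfies; setting `spacer_len=1` reproduces the compact
expression `[RK][LVI].[HQ][LA]` sometimes used for quick searches. Spacer
positions accept any of the 20 standard amino acids; `*` (stop) and `X`
(the translation of any N-containing codon) fail every position, including
the spacer. This is deliberately conservative: an undetermined base can
never create a motif hit.

Scanning translates the maximal in-frame suffix of the upstream sequence
(positions −3·⌊utr_len/3⌋ … −3) and reports every, possibly overlapping,
consensus window, mapped back to nucleotide coordinates. Hits may span
in-frame stop codons — reachability is a property of initiation candidates,
not of the motif. A hit is **cryptic** iff no in-frame ATG lies 5′ of it;
in-frame stops between the hit and the CDS are reported alongside. When
several cryptic hits exist the 3′-most (closest to the CDS) is treated as
primary; the tie-break is purely positional and deterministic.

## Initiation candidates and extensions

Near-cognate start codons are exactly the nine codons at Hamming distance 1
from ATG: CTG, GTG, TTG, AAG, ACG, AGG, ATA, ATC, ATT. Every in-frame
position from the motif start 5′-ward to the end of the supplied upstream
sequence is classified; near-cognate (and canonical ATG) codons become
candidates. Candidates strictly 3′ of the motif start are excluded, since
initiation there would leave the signal outside the protein; no
transcript-start inference is attempted beyond the supplied sequence.
A tandem pair is two near-cognate candidates at adjacent in-frame positions
(p and p+3). Ranking places tandem-pair members before singles and 3′-most
first — the validated biological site is the 3′-proximal tandem pair.

The predicted N-terminal extension translates from the candidate to the
annotated start. Its first residue is reported as M (initiator-tRNA
convention for near-cognate initiation); a `literal_initiator` flag gives
the literal codon translation instead. Candidates separated from the CDS by
an in-frame stop are flagged `blocked_by_stop` and refuse extension
prediction. In-silico mutagenesis (`substitute_codons`) replaces in-frame
upstream codons non-destructively, supporting knockout (GCA) and
canonical-start knock-in (ATG) comparisons at the sequence level.

## Conservation profiling

Because UTR 3′ ends are fixed by the annotation anchor, ortholog upstream
sequences are stacked **right-anchored** (position −1 column-aligned, 5′
padding treated as missing) rather than aligned; a Needleman–Wunsch global
aligner with linear gap penalty (defaults +1/−1/−2, deterministic traceback
with tie order diagonal > up > left) is provided for divergent families but
is not the default. Per-column identity is the modal-symbol fraction among
non-missing symbols (defined where coverage ≥ 2) — simple, monotone in
conservation, and permutation-invariant in rows; it is not a pairwise
identity and carries no phylogenetic correction. Conserved windows are
maximal runs of columns with identity ≥ `min_identity` (default 0.8) of
length ≥ `min_len` (default 6). Motif conservation is the fraction of
ortholog loci that retain at least one cryptic in-frame consensus match;
the peptide may vary between orthologs as long as it fits the consensus.

## Read evidence

The transcript-evidence filter asks whether any read supports a spliced
transcript placing an AUG upstream of (and in frame with) the tandem
near-cognate site. The chain is: exact k-mer matching of reads against the
300-nt region immediately 5′ of the CDS (k = 20, forward orientation by
default, reverse-complement matching behind a flag); exact-sequence
deduplication (first occurrence kept); then the literal pattern
`ATG(.)*AGGATT` — an ATG anywhere 5′ of an anchor occurrence within the
read, spacing unconstrained. A frame-aware mode additionally requires the
ATG-to-anchor spacing to be a multiple of 3; both counts are always
reported. The stage order match → dedup → pattern is fixed and the counts
obey the monotone chain n_pattern ≤ n_unique ≤ n_matching ≤ n_in. k-mer
matching deliberately stands in for read mapping; no spliced alignment or
assembly is attempted.

## Quantification

The initiation rate uses a dual-construct design: a wild-type reporter
(canonical start intact) and an M1A reporter (canonical start mutated, so
only upstream non-AUG initiation yields protein). Each lane is normalised
as gfp/loading (tubulin loading control) and the rate is
100 · mean(normalised M1A) / mean(normalised WT) percent — a declared
convention (mean-of-ratios); the per-replicate rates reported alongside are
each M1A lane against the mean WT signal, so their mean equals the headline
estimate and their SD is the dispersion. The estimator is invariant to
uniform rescaling, per-lane loading differences and lane order.
Co-localization is the fraction of marker-positive (mCherry-SKL) foci that
also contain reporter (GFP) signal; marker-negative foci never enter the
denominator. Box-plot summaries follow the standard convention: centre
line median, box limits first/third quartiles, whiskers the most extreme
points within 1.5 × IQR.

## Synthetic data: what it emulates, and what it does not

`generate_locus` draws an i.i.d. background at the configured GC content
(default 0.5), reverse-translates the motif peptide with uniform synonymous
codon choice, and plants the candidate codons literally (AGG at −63, ATT at
−60 by default). Rejection resampling (bounded at 10,000 attempts, with an
informative error on failure) enforces the cryptic study conditions:

1. no in-frame ATG upstream of the motif;
2. no in-frame stop between the 5′-most candidate and the start codon;
3. the planted motif is the *unique* in-frame consensus match;
4. transcript-evidence cleanliness: the anchor 6-mer occurs exactly once in
   the transcript (upstream + first 200 nt of CDS) and no ATG trigram, in
   any frame, lies within one read length 5′ of the anchor.

Constraints 3–4 make planted-recovery and negative-evidence tests exact:
only engineered contaminant reads can ever match the upstream-ATG pattern,
mirroring a locus whose read data genuinely carry no spliced-in upstream
start codon. With `cryptic=false` an in-frame ATG is planted instead
(default −72) as the designed counterexample.

`generate_ortholog_family` applies independent per-position substitutions
at a window-specific rate (default 0.02 inside the planted conserved block
at −68..−53, 0.3 elsewhere), indel-free. A repair pass reverts any codon
whose mutation would break the motif consensus (anchor residues must stay
in class; spacer residues must remain standard amino acids), create a new
in-frame upstream ATG, or place an in-frame stop between the 5′-most
candidate and the CDS — the family emulates orthologs in which the
*mechanism* is conserved even where individual bases are not, which is the
configuration whose recovery the conservation stage is meant to test.
Realized substitution rates at repaired codons are therefore slightly below
nominal.

Reads are sampled uniformly from the transcript with per-base substitution
errors (default read length 75 nt, error rate 0, 2,000 reads); a
configurable fraction comes from a variant transcript with an in-frame ATG
planted at −75, within read range of the anchor. Densitometry lanes use
WT latent expression fixed at 100 arbitrary units, M1A at the true rate
(default 2%), mean-one lognormal expression and loading-control noise
(default cv 0.1, 6 lanes per construct) and a shared per-lane loading
factor (lognormal, cv 0.2) that cancels under normalisation; at cv 0 the
estimator recovers the true rate exactly. Foci are independent Bernoulli
draws at the true co-localization fraction (default 0.7, 200 foci).

Not emulated: indels, coverage bias, quality scores, realistic splicing
(beyond the single engineered contaminant isoform), codon-usage bias in the
background, or phylogenetic structure among orthologs (substitutions are
i.i.d., not tree-correlated). Passing tests therefore demonstrate correct
recovery of planted signals under these idealised conditions, not
performance on real genomes, where GC composition, repeat content and
annotation errors add failure modes the generator does not model.

## Problem sizes and determinism

Every generator is deterministic in `(seed, configuration)`; derived
replicate seeds stay below 2³¹. The recovery studies use 200 replicate
densitometry tables and 100 replicate ortholog families — enough for the
mean estimate's standard error (≈0.01 percentage points) and the modal
window boundary to be stable, while keeping the full suite in seconds on
one CPU. Genome-scale tests use 50–200 synthetic genes, half planted, with
exact (zero false positive/negative) recovery required.

## Known limitations

- Crypticity considers only in-frame ATGs within the supplied upstream
  sequence; an ATG beyond it (longer 5′ UTR than supplied) would be missed.
- No initiation-context (Kozak-like) scoring: candidate ranking is
  structural (tandem > single, 3′-most first), not a rate prediction.
- The conservation statistic assumes anchored, indel-free comparability;
  families with real indels should be pre-aligned (the provided global
  aligner is a building block, not a pipeline stage).
- The published read-evidence pattern is frame-blind by design; the
  frame-aware count is the biologically intended test and both are
  reported.
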