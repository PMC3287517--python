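# Methods

## Amplicon and read model

An amplicon is modelled on GS FLX Titanium chemistry after adaptor
trimming: the sequencer-visible read begins with the 4 bp library key
(`TCAG`), a 6 bp sample-specific MID, and the PCR primer, followed by the
16S insert.  The full double-tagged molecule on the forward strand is

    key + mid_fwd + primer_fwd + insert + revcomp(key + mid_rev + primer_rev)

A-end reads present the forward block and a 5′ prefix of the insert;
B-end reads present the reverse block and a reverse-complemented 3′
suffix.  Insert lengths are Normal(430, 25) bp, clamped to
[100, template length]; the clamp at the template length is what
produces full-length reads and lets assemblies reach both amplicon ends.
The published universal primer pair is the default
(`MGAGTTTGATCCTGGCTCAG` / `GCTGCCTCCCGTAGGAGT`); the degenerate M is
resolved uniformly at random per read, as in a real degenerate primer
pool.

### Error model

454's dominant error mode is homopolymer length miscalls.  Each maximal
run of length *k* gains or loses one base (equiprobably) with probability
`min(0.5, hp_indel_base * hp_scale**(k-1))`; defaults
`hp_indel_base = 0.01`, `hp_scale = 1.6` give ~1 % per-base indel weight
on typical 16S sequence, consistent with published Titanium error
profiles.  A uniform substitution rate (`sub_rate = 0.004`) is layered
on first.  Reads carry a constant Phred 35; the model does not simulate
per-base quality decay, so quality filtering on simulated data is
exercised only through its interface, not its discrimination.

Probabilities like the run-length law are exposed directly
(`ErrorModel.hp_indel_prob`) and checked against closed form and Monte
Carlo in the tests.

### What the simulator does not emulate

PCR chimeras, per-cycle amplification bias, per-individual substructure
within a species pool (the study pooled 7 larvae per species equimolar —
the pool is modelled as a single community), flowgram-level signal, and
quality-correlated errors.  Passing tests therefore demonstrate the
pipeline's correctness against this generative model, not robustness to
chimeric or heavily quality-degraded real data.

## Demultiplexing

Assignment requires an exact (0-mismatch) key at position 0 and an exact
6 bp MID at positions 4–9, in either orientation, then an IUPAC-aware
primer match (0 mismatches by default, configurable).  "Exact" is the
conservative reading of accurate tag matching; with 6 bp MIDs a single
substitution always demotes a read to UNASSIGNED rather than risking
cross-sample bleed.  Sheet validation rejects duplicated MIDs across
rows and orientations, so assignment can never tie.  Quality gating
(mean Phred ≥ 20, ≤ 0 N bases by default) runs before assignment and
quarantines failures into QC_FAIL; the three-way outcome is a strict
partition of the input.

Reverse-orientation reads are reverse-complemented into the insert's
forward frame before pooling, leaving their framing block
reverse-complemented at the read's 3′ end; the assigner also recognises
that tail layout, which makes demultiplexing idempotent on its own
output pools.

## Window-match seed-extension assembly

Parameters follow the published run settings: minimum seed 200 bp,
window 60 bp, anchor = key + first 20 bp of the forward primer, and a
500 kb per-tag budget.  The anchor is applied as an IUPAC pattern with
N wildcards over the 6 bp MID positions, since the MID sits between key
and primer on the read and has already been verified by demultiplexing.

The extension mechanics are this package's design (the original
algorithm's internals are unpublished):

- **Seeding.** Anchored reads ≥ 200 bp, longest first (id as
  tie-break).  The longest read maximises single-seed coverage but is
  also enriched for homopolymer insertions; the polish step (below)
  compensates.
- **Extension.** Each round takes the contig's terminal 60 bp window and
  finds its leftmost occurrence in every available read by banded edit
  distance with budget `floor((1 − min_window_identity) · 60)` — at the
  default `min_window_identity = 1.0` this is exact containment; at 0.95
  it tolerates 3 edits, which (unlike Hamming matching) also bridges a
  homopolymer indel inside the window.  Reads whose match leaves a 3′
  overhang vote column-wise on up to one window of new bases; ties
  become IUPAC codes.  A read joins the member list the first round it
  matches and keeps voting afterwards.
- **Tip erosion.** If no read matches the terminal window, the window
  slides back up to 30 bp and the majority overhang replaces the eroded
  tip.  This prevents a cluster of seed errors near the 3′ end from
  terminating assembly (observed failure mode: the contig stops ~28 bp
  short, and every reverse-frame read — all of which carry the reverse
  framing block — then fails containment).
- **Recruitment.** After extension, remaining reads that align within
  the contig (edlib infix mode, edit budget `(1 − min_window_identity) ·
  read length`) are recruited as members, so a contig's support counts
  every read it explains, not only the reads that happened to extend its
  tip.  Membership is exclusive across contigs.
- **Polish.** The contig is re-called as the pileup majority of its
  members (capped at 100 reads, longest first — ample coverage for a
  majority).  Polish runs once on the extension members *before*
  recruitment (an unpolished contig can carry enough seed errors to push
  honest reads past the recruitment budget) and again on the full
  membership.  Ties keep the existing contig base, so zero-noise contigs
  pass through byte-identical.
- **Framing canonicalisation.** Where the contig matches the known
  key/MID/primer framing, those positions are rewritten to the IUPAC
  pattern (restoring M at the degenerate primer position), and edlib is
  given the corresponding ambiguity equalities.  Without this, reads
  carrying the two primer variants split each template's support into
  two contigs.

Assembly stops when no seed remains or the cumulative bases of
extension-consumed reads reach `max_bases` (checked between seeds);
recruitment does not count against the budget, which keeps the budget a
measure of assembly work rather than of community size.  Contigs with
support < 2 are discarded.  On zero-noise pools the contigs equal the
true full amplicons byte-for-byte and support equals the simulator's
per-template read counts (tested over 50 random communities).

The bundled end-to-end configuration raises `max_bases` to 10 Mb: at the
study's per-sample read counts (≈ 6000–8600 reads × ~480 bp ≈ 3–4 Mb) a
500 kb cap would truncate assembly after the dominant template.  The
500 kb default is retained as the published setting for single runs.

## OTU calling and the abundance table

Contigs of one sample are clustered greedily around highest-support
centroids at 0.97 global-alignment identity — the conventional
species-level 16S radius; the recovery results are insensitive to the
exact radius because the synthetic clades are ≥ 10 % divergent.
Identity is matches / alignment columns excluding terminal gaps, under
match +1, mismatch −1, gap open −2, gap extend −0.5 (Biopython
`PairwiseAligner`).  Cluster consensus is support-weighted majority per
centroid column (ties → IUPAC; insertions emitted only with > 50 %
weight), after which the key/MID/primer framing is stripped from both
ends.  Read counts per OTU are the summed assembler support of the
cluster's contigs; percentages are reported to 2 decimals of the
sample's total, matching the conventional survey-table format.

## Phylogenetics

- **Nearest reference**: maximal pairwise identity, ties to the
  lexicographically smallest accession.
- **Distances**: pairwise-deletion p-distance over columns where both
  sequences have a concrete base; JC69 correction
  `−(3/4)·ln(1 − 4p/3)`, with p ≥ 0.75 raised as saturated.
- **Neighbour joining**: Saitou–Nei Q-criterion, ties broken by the
  smallest label pair; negative branch lengths clamped to zero with the
  deficit moved to the sister branch (pair sum preserved).  Exact on
  additive matrices (tested: topology and path lengths recovered on
  random 4–12-leaf trees).
- **Fitch parsimony**: bitmask dynamic program over all columns at once;
  gaps and N are wildcards.  Multifurcating roots are rooted to binary
  first (the score is rooting-invariant).
- **Placement**: the query is profile-aligned to the reference
  alignment's majority consensus (insertions relative to the profile are
  dropped), then scored on every branch exhaustively; ties go to the
  first branch in preorder.  Exhaustive evaluation is exact and entirely
  feasible at the tens-of-references scale this package targets; it
  replaces the heuristic insertion of large-database tools.

## Synthetic reference set

`synthetic_references()` generates 13 sequences of 450 bp in three
endosymbiont-like clades (Rickettsia-like, Nardonella-like,
Neoehrlichia-like) plus two environmental outliers: clade ancestors
diverge ~15 % from a common root, leaves ~2 % within a clade.  The
sequences are synthetic — they share no homology with real 16S data —
and exist so that simulation, assembly, classification and placement are
testable offline.  The demo communities draw each sample's dominant and
minor templates from *different* clades; within-clade (~4 %) template
mixtures would sit at the assembler's recruitment resolution
(`min_window_identity = 0.95` → 5 % edit budget) and are outside the
demo's scope — a real caveat for closely related strains.

## Demo configuration

The bundled demo mirrors the four-species study design: pools of
6073 / 8584 / 6412 / 6311 reads (scalable), dominant fractions
0.9083 / 0.9087 / 0.9916 / 0.9349, minor mass split 60/40 (or 50/30/20)
over 2–3 templates, default error model, `min_window_identity = 0.95`,
`max_bases = 10 Mb`.  All stage seeds derive from one global seed via a
CRC32 hash of the stage name, so adding a stage never perturbs earlier
stages' random streams and reruns are checksum-identical.

## Numerical and determinism notes

- Coordinates are 0-based half-open throughout; quality encoding is
  Phred+33 only.
- Sequences are uppercased on input, U→T, any non-IUPAC character is an
  error.
- Every stochastic component takes an explicit seed or Generator; pool
  order, sort keys and tie-breaks are all specified, so identical inputs
  give byte-identical outputs.
- Majority-vote ties in assembly become IUPAC codes during extension but
  keep the existing base during polish; cluster-consensus gap/base ties
  keep the base; all-gap columns are dropped.

## Known limitations

- Exact-match demultiplexing discards every read with an error in the
  first 10 bases (~30–45 % at the default noise level — comparable to
  the attrition a real run of this design reports); no Hamming-1 MID
  rescue is attempted by design.
- The assembler is greedy and reference-free; it resolves community
  members down to roughly its window-identity radius and cannot separate
  strains within ~5 % identity under the noisy configuration.
- Chimera detection, rarefaction/diversity statistics, bootstrap
  support, and likelihood-based phylogenetics are out of scope.
- Placement assumes the query is alignable to the reference profile;
  heavily gapped or partial queries degrade to missing-data columns.
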