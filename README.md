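# amplitag

Multitag 454-style 16S rDNA amplicon analysis for insect endosymbiont
surveys: simulation of barcoded pyrosequencing read pools, exact key/MID
demultiplexing, window-match seed-extension consensus assembly, OTU
abundance tables, and desk-scale phylogenetic placement.

## The problem

Tag-encoded FLX amplicon pyrosequencing lets several samples share one
sequencing run: each sample's PCR amplicons are framed with the fixed
4 bp library key (`TCAG`), a sample-specific 6 bp multiplex identifier
(MID), and a universal 16S primer (V1–V2 region, ~450 bp insert).  A
typical application is profiling the intracellular bacteria
(endosymbionts such as *Rickettsia*, "*Candidatus* Blochmannia" /
"*Candidatus* Nardonella", "*Candidatus* Neoehrlichia") of insect hosts
— here the design is modelled on a survey of larvae of four
*Otiorhynchus* weevil species, where each species' pool is heavily
dominated (90–99 %) by a single endosymbiont plus a tail of rare taxa.

`amplitag` implements the full analysis path as a reusable, tested
library and CLI:

1. **simulate** — generate 454-style read pools with known ground truth:
   amplicons `key + MID + primer + insert` (reverse-strand reads carry the
   reverse MID/primer and the reverse-complemented insert), Normal insert
   lengths, substitution noise, and run-length-dependent homopolymer
   indels — a maximal run of length *k* gains or loses one base with
   probability `min(0.5, p₁·sᵏ⁻¹)`.
2. **demux** — assign reads to samples by *exact* key and MID match
   (primers matched IUPAC-aware), quality-gate on mean Phred and N count,
   and emit per-sample pools in a common forward frame.  Assignment is a
   partition: every read lands in exactly one of
   {samples} ∪ {UNASSIGNED, QC_FAIL}.
3. **assemble** — greedy window-match seed-extension assembly per tag
   pool: the longest anchored read (key + 20 bp of primer, ≥ 200 bp)
   seeds a contig that grows 3′-ward by majority vote over all reads
   matching its terminal 60 bp window; reads contained in the finished
   contig are recruited as members and the contig is polished by pileup
   majority.  Defaults: 200 bp minimum seed, 60 bp window, 500 kb
   per-tag base budget.
4. **otu** — greedy centroid clustering of contigs at 0.97 identity,
   support-weighted cluster consensus, removal of the key/MID/primer
   framing, and a per-sample abundance table
   (`read_count`, `pct_of_total` to 2 decimals).
5. **classify / tree / place** — nearest reference by global-alignment
   identity; Saitou–Nei neighbour joining on p- or Jukes–Cantor (JC69)
   distances; and parsimony placement of a query on the branch of a
   reference tree minimising the Fitch score, evaluated exhaustively over
   every branch.

A bundled synthetic reference set (three endosymbiont-like 16S clades
plus outliers, generated deterministically) makes the whole pipeline
runnable and testable without any database download.

## Worked example

The bundled demo simulates the four-species design (per-sample dominant
OTU fractions 0.9083 / 0.9087 / 0.9916 / 0.9349, the published MID pairs,
default noise model) and runs every stage:

```bash
amplitag run --outdir demo --seed 42 --scale 0.25
```

prints the recovered abundance table (`demo/otu_table.tsv`):

```
sample            otu_id                  read_count  pct_of_total  closest_match
O_salicicola      O_salicicola_OTU01             938         90.54  SYN00005 (1.0000)
O_salicicola      O_salicicola_OTU02              56          5.41  SYN00009 (1.0000)
O_salicicola      O_salicicola_OTU03              42          4.05  SYN00012 (1.0000)
O_rugosostriatus  O_rugosostriatus_OTU01        1322         91.24  SYN00001 (1.0000)
...
O_sulcatus        O_sulcatus_OTU01              1074         98.99  SYN00002 (1.0000)
O_armadillo       O_armadillo_OTU01              964         93.59  SYN00006 (1.0000)
```

Each sample's dominant OTU is recovered at its configured share (90.54 %
observed vs 90.83 % configured for *O. salicicola*, and so on, within
binomial sampling error of the ~1000-read pools), the consensus
sequences classify to their true templates at identity 1.0000, and
`demo/manifest.tsv` records a SHA-256 per artefact — rerunning the same
config reproduces identical checksums.  At `--scale 1.0` the pools match
the study's read counts (6073 / 8584 / 6412 / 6311).

Individual stages are available as `amplitag simulate | demux | assemble
| otu | classify | tree | place`, all driven by a TSV sample sheet
(`sample, key, mid_fwd, mid_rev, primer_fwd, primer_rev`) and plain
FASTA/FASTQ/TSV/Newick files.

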