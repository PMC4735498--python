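# Methods

## Scope and model

`virinflux` analyses host-to-virus DNA influx in deep-sequenced populations
of a circular dsDNA virus. The observable unit is the host–virus junction:
a position where viral sequence abuts host-derived sequence in a sequenced
viral genome. Two mechanisms generate junctions: cut-and-paste
transposition of host DNA transposons into family-specific target motifs
(leaving a target-site duplication and junctions exactly at the terminal
inverted repeats of the element), and recombination joins — typically
microhomology-mediated — that can place any host fragment at any viral
position. The analysis assumes junctions are rare per genome (a few
percent of genomes carry one insertion), so each chimeric read reflects one
junction, and that insertions per genome are Poisson distributed.

## Chimeric-read detection

Reads are aligned to the viral reference and to the host reference set
(assembled contigs and transcripts). For each read, the best-scoring
alignment is retained per reference class, with exact score ties broken by
a seeded uniform draw. A read is an intra-read junction when

- the virus-only and host-only aligned portions are each ≥ 16 bp,
- the two alignments cover ≥ 95 read bases in total for 101-bp reads
  (130 for 151-bp reads), and
- the signed overlap between the alignments is in [−2, 20] bp.

The total is counted as `virus_only + host_only + overlap`, so an
untemplated gap (negative overlap) reduces it. Negative overlaps denote
1–2 junction bases matching neither molecule; overlaps above 20 bp mark
viral regions merely similar to host sequence and are rejected. A junction
falling between the two mates of a pair is accepted when one mate is
virus-only and the other host-only, each over the total-length threshold;
such inter-read junctions have an interval rather than a breakpoint and do
not enter offset-based collapsing.

Host references are vetted iteratively to a fixed point: assembled contigs
must be corroborated by independent transcript evidence, transcripts
sharing a chimeric read with a retained contig are redundant candidates for
the same insertion and are dropped, and references with fewer than three
chimeric reads or under 75 bp of cumulative chimeric alignment are
discarded. Fixed-point iteration (rather than one pass) was chosen because
dropping a contig can re-qualify a transcript; a single-pass mode is
available.

PCR duplicates (identical outer fragment coordinates on virus and host) and
junctions sequenced by both overlapping mates of one pair collapse to one
evidence item, but the raw chimeric count is preserved because the
frequency estimator needs duplicates on both sides of its ratio.

## Junction identity and collapsing

A junction is identified by the strand-aware offset between the viral and
host coordinates aligned to the same read base — a quantity invariant
across all reads covering the junction — together with the viral strand and
the host contig. Reads sharing this identity are treated as amplification
of a single original insertion through viral replication and collapse to
one junction (the representative read has the best host alignment score).
When libraries come from independently infected host lineages, the library
is part of the identity: identical junctions cannot be inherited across
lineages that share no ancestor on that host. Junctions across the
circular origin use modular coordinates; offsets are computed on the
unrolled frame of the alignments.

## Mechanism classification

Junctions of one contig clustering at one or two contig positions mark the
ends of a mobile element. Positions chain into a cluster when within
± 5 bp (the tolerance is configurable); a group qualifies when it contains
at least 10 distinct viral sites. For each cluster a 30-bp sequence logo
is built from the viral windows around the member insertion sites (15 bp
each side of the breakpoint, reverse-complemented for minus-strand
junctions so logos of opposite element ends are comparable). Information
content is 2 − H(p) bits per position with no small-sample correction; the
≥ 10-member threshold bounds the bias.

Junctions that do not cluster are scattered recombination joins. Their
microhomology is the stretch of junction sequence attributable to both
molecules. Operationally the viral and host sequences are reconstructed
through the two alignments' coordinate frames, anchored at the inner
host-alignment boundary and read through the junction in the same
direction; their common prefix equals the alignment overlap on error-free
data (0 = blunt join; −1/−2 = untemplated bases). The null distribution of
microhomology lengths is sampled per the same geometry: for each junction's
20-bp host-side terminal sequence, the terminal identity against 20 random
20-bp windows of the viral genome is recorded and the aggregate rescaled to
the observed junction count. Observed and expected length distributions
(0–20 bp) are compared with a Pearson chi-square test; with all 21 bins the
equal-total constraint gives 20 degrees of freedom. By default adjacent
tail bins are merged until each expected count reaches 5 (Cochran's rule),
reducing the degrees of freedom accordingly; `min_expected=0` keeps the
full 21-bin statistic. The default keeps the test calibrated — on
null-simulated data 200 replicate p-values pass a Kolmogorov–Smirnov
uniformity check — while the merged and unmerged statistics agree on the
drastic excess produced by genuine microhomology.

## Insertion frequency

With `Nc` chimeric reads (duplicates included), `N` viral reads, read
length `Lr`, genome length `Lg` and mean junction overlap `Ov`,

    Pj = (Nc / N) · Lg / (Lr − 2·d + Ov),   d = 28 bp

where `d` is the aligner's minimum reportable similarity, kept symbolic so
non-default alignment thresholds propagate. The fraction of genomes with
at least one insertion is `1 − exp(−Pj/2)` under the Poisson-per-genome
assumption (one insertion in a circular genome yields two junctions). `N`
is counted as reads with a best-hit viral alignment; `Ov` is the
per-library mean of evidence overlaps (a global mode is available);
inter-read evidence is excluded from `Nc` by default since the window
geometry is intra-read.

The detectable-window term is an approximation: the exact window for a
junction with overlap k is `Lr − 55 + k` for k ≤ 12 and saturates beyond,
and a maximal-scoring aligner occasionally extends through an isolated
mismatch, widening its effective window further. At the suite's test
conditions the estimator consequently runs a few percent high of the
realized rate (about +4% at 10-kb genomes and ~800 chimeric reads) — well
inside the 15% recovery band the validation demands, and faithful to the
published estimator rather than a recalibration of it.

## Insertion landscape

Junction positions are binned in contiguous windows anchored at reference
position 0 — 500 bp for maps, 1,500 bp for models, both configurable; a
final short window merges with the first (circularity). Counts are taken
either once per unique junction ("independent") or weighted by supporting
reads ("all"). Motif covariates count overlapping occurrences of TTAA,
TTA, TAA and TA on the forward strand only (TTAA and TA are palindromic,
TTA/TAA are each other's reverse complements, so two-strand counting would
double-count). Counts are modelled with a log-link Poisson GLM (IRLS,
convergence 1e−8, 100-iteration cap, via statsmodels); covariate subsets
are ranked by AICc = AIC + 2k(k+1)/(n−k−1), rank-deficient or
under-determined subsets are skipped and flagged, and the chosen model gets
a sequential (type-I) analysis of deviance in the stated covariate order.

## Horizontal-transfer screen

A TE integrated into viral genomes is a horizontal-transfer candidate in
another species when it aligns there at ≥ 85% nucleotide identity over
≥ 100 bp. Reported per candidate: the best qualifying hit identity (the
headline value; the mean is also kept), the number of hits ≥ 100 bp and the
longest hit. The neutral expectation is the per-species-pair mean of
non-corrected Nei–Gojobori synonymous distances over conserved genes,
expressed as `(1 − dS) × 100` percent similarity; a candidate whose
identity exceeds it (margin configurable, default 0) is inconsistent with
vertical inheritance.

NG86 here: per codon, each position contributes the fraction of its three
single-base changes that are synonymous, with changes to stop codons
excluded from the denominator; site counts are averaged between the two
sequences, so S + N = 3 × (codon count). Multi-position codon differences
are averaged over all minimal substitution pathways, excluding pathways
through stop codons and falling back to all pathways when every one is
blocked. Codon pairs containing gaps, ambiguous bases or stop codons are
dropped pairwise and counted. dS is the raw proportion Sd/S with no
multiple-hit correction. The implementation is checked against an
independent exhaustive-enumeration oracle on 10,000 random codon pairs.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes — it
is the package's ground-truth instrument, not a sequencing simulator.

- **Genome**: i.i.d. bases at the configured GC content (default 0.41, the
  AcMNPV value) on a circular reference (default 133,926 bp), with a map of
  all target-motif occurrences.
- **Host contigs**: DNA-transposon contigs of 1.5 kb with terminal inverted
  repeats (the 5' TIR is the reverse complement of the 3' TIR), a
  family-specific target motif (piggyBac/TTAA, Harbinger/TAA, Mariner/TA),
  and a stop-free open-reading-frame placeholder; plus unannotated contigs
  of unknown class.
- **Insertions**: each genome receives Poisson(λ) insertions (default
  λ = 0.05, matching the ~5% occupancy regime of deep-sequenced baculovirus
  populations). With probability 0.93 (the study regime: most independent
  junctions arise from transposition) an event is a transposition into a
  uniformly chosen motif occurrence, with target-site duplication on by
  default. Otherwise it is a recombination join: blunt with weight 0.19,
  untemplated 1–2 bp insertion with weight 0.16, else microhomology of
  geometric length (p = 0.5, truncated to [1, 20]) — weights proportional
  to the reported 87/71/298 support for the three junction classes. A
  homology-k join uses a host fragment whose first k bases equal the viral
  flank's last k, spliced so the shared bases appear once; the realized
  junction geometry (including chance extensions) is recorded in the truth
  table. Events that cannot be placed are redrawn and counted.
- **Reads**: paired 101-bp (or 151-bp) reads from fragments drawn uniformly
  on each circular genome (origin-crossing fragments by rotation; truth
  stays on the reference frame), normal insert size (default 300 ± 25),
  i.i.d. substitution errors, and exact PCR duplicates at a configured
  rate. Fixed Q30 placeholder qualities. Every junction-spanning read is
  recorded with its expected maximal alignment boundaries, which makes
  sensitivity and false-discovery oracles exact.
- **Determinism**: one seed per run; per-stage substreams derived from it.

What the generator does not emulate — real quality-score profiles, indel
errors, coverage biases, co-infection or recombination between viral
genotypes, host-genome repeat structure, assembly artefacts in the host
reference set. Passing tests therefore demonstrate the correctness of the
analysis logic under its stated model, not robustness to every artefact of
real libraries; the retention filters that target such artefacts are tested
on constructed cases instead.

## Validation problem sizes

The validation suite runs end-to-end recovery on a 50-kb genome at 2,000×
total coverage (≈ one million reads) with error-free 101-bp pairs, where
every planted junction far enough from the read ends must be found and
nothing else; estimator recovery at λ ∈ {0.02, 0.05, 0.2} on 10-kb genomes
with coverage scaled so each run yields roughly 800 chimeric reads
(recovery within 15%); chi-square calibration with 200 replicates of 800
junctions; logo recovery from ≈ 300 transposition events; and the NG86 and
GLM checks described above. These sizes keep each validation step within
tens of seconds while leaving the statistical checks well powered.

## Known limitations

- The internal ungapped aligner serves synthetic data and testing;
  production runs can ingest external 12-column tabular alignments, which
  the pipeline treats identically. No gapped alignment, no E-values.
- Detected overlaps (and hence microhomology lengths) can exceed the
  planted value when a maximal-scoring alignment extends through an
  isolated mismatch — a property shared with any scored local aligner.
- The frequency estimator inherits the published detectable-window
  approximation (small positive bias, quantified above).
- Inter-read junctions carry positional intervals only and are excluded
  from junction collapsing and (by default) from `Nc`.
- The clustering tolerance (± 5 bp) is a declared choice; the analysis it
  supports is insensitive to values of similar magnitude.
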