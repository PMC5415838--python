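# Methods

`mirstage` re-implements, as a tested library, the analysis chain used to
profile miRNAs in small-RNA sequencing libraries from differentiating
muscle-derived satellite cells (three stages: proliferating, day 1 and
day 3 of differentiation): read cleaning, genome annotation, conserved and
novel miRNA identification, two-library differential expression, and
seed-based target prediction.  Because no sequencing data are distributed
with the package, a first-class synthetic-data generator plants every
signal the pipeline is supposed to detect and records exact per-read
provenance; the tests and the acceptance script measure the pipeline
against that planted truth.

## Read cleaning

A read is *high quality* when it contains no `N`, at most 4 bases below
Q10 and at most 6 bases below Q13.  High-quality reads then pass a fixed
cascade, each read landing in exactly one bucket so that the bucket counts
plus clean reads add back to the high-quality total:

1. **no 3' adapter** — the leftmost adapter occurrence is searched with
   one tolerated mismatch per 10 nt of compared adapter; a terminal
   partial match needs at least a 6 nt adapter prefix.  This mirrors
   standard small-RNA trimmer behaviour; the tolerance values are package
   choices since trimming tools differ here.
2. **null insert** — adapter found at position 0.
3. **5' adapter contaminant** — insert head matches the 5' adapter over
   `min(|insert|, |adapter5|)` bases with at most one mismatch.  The
   comparison spans the full overlap rather than a short prefix so that
   random 18–30-mers essentially never trip it.
4. **shorter than 18 nt**.
5. **polyA** — at least 80 % A (no published definition exists; 80 % is
   the package's own rule).
6. inserts longer than 30 nt go to a `larger_than_30nt` bucket that is
   reported only when non-empty.

Percentages are reported against high-quality reads, rounded half-up to
two decimals, matching the conventional QC-table layout.  Clean inserts
are collapsed to unique tags carrying per-library counts.

## Annotation cascade

Tags are mapped exactly (18-mer seed + verification; a `--mismatches`
option switches to a sliding-window scan) on both genome strands.  Each
tag receives exactly one category by a fixed priority:

    miRNA > rRNA > tRNA > snRNA > snoRNA > scRNA > srpRNA > repeat >
    exon_sense > exon_antisense > intron_sense > intron_antisense > unann

The priority is a package decision: miRNA dominance in small-RNA
libraries implies the miRNA class must outrank the structural classes,
and the remaining order follows common annotation practice.  A
multi-locus tag contributes its whole read count once, to its winning
category, so category read counts partition the clean total; locus counts
are reported separately.  Unmapped tags count as `unann`.

## Conserved miRNAs

A tag is a conserved miRNA when, after T→U normalisation, it occurs in a
reference precursor with zero mismatches at a position within ±2 nt of
the annotated mature start (the shift tolerance admits 5'/3' length
variants that strict equality would discard; configurable).  Tags failing
the perfect-match rule feed the base-edit detector, which reports tags at
Hamming distance exactly 1 from a mature over the 5'-anchored common
prefix (length difference ≤ 2); ties between matures go to the
lexicographically smallest name.  Family assignment strips the species
prefix, arm suffixes, variant letters and duplicate-locus numerals
(`bta-miR-2284x → miR-2284`, `bta-let-7a-5p → let-7`).  Positional
nucleotide bias is the count-weighted base fraction per position over
matched tags.

## Novel miRNA screen

Unannotated tags with at most 10 genomic loci and at least 3 supporting
reads seed candidate windows of tag ± 150 nt (the read floor is a
Mireap-style noise filter: background and sequencing-error tags are
dominated by singletons, and it keeps the number of folded windows
proportional to real signal).  Each window is folded; the mature must

* be 20–22 nt long,
* lie entirely within one arm (all pairing partners on one side, the
  loop-proximal mature base paired, no second stem inside the terminal
  loop, no internal unpaired run longer than 3 nt — the package's
  concrete reading of "no loop or break"),
* have fewer than 6 unpaired positions against the star arm,
* have AU content within 30–70 %,
* come from a precursor with MFE < −20 kcal/mol and MFEI ≤ −0.85
  (AMFE = MFE·100/length; MFEI = AMFE/GC%).  −0.85 is the conventional
  pre-miRNA MFEI cutoff; energies are evaluated on the refolded
  mature..star span, not the 322-nt window, because pre-miRNA energy
  thresholds are meaningless for a long window that always folds below
  −20 kcal/mol,
* show Dicer-consistent processing: ≥ 80 % of the window's (filtered)
  read support starting within ±2 nt of the mature 5' end.

All criterion flags are recorded; the verdict is their conjunction, so
tightening any threshold can only turn passes into failures.
Overlapping windows merge, the highest-count tag defining the mature.

## Folding engine

The reference engine minimises a small fixed energy model over
pseudoknot-free structures: pair terms GC −3.0, AU −2.0, GU −1.0
kcal/mol; loop terms charged to the closing pair — hairpin +4.0,
bulge/internal +3.0 (searched up to 30 unpaired bases), multibranch
+4.0; hairpin loops span ≥ 3 bases; external bases are free.  The
dynamic program (numba-compiled) fills pair/multiloop/external tables and
a traceback reconstructs one optimal dot-bracket.  The model is
deliberately simple so tests can verify the DP against exhaustive
enumeration of all structures on short sequences with an independent
direct structure scorer, and so the generator and screen share exactly
the same energies.  ViennaRNA can be plugged in through the same
interface where thermodynamic energies are wanted; thresholds are always
interpreted under the engine in use, and the synthetic truth is generated
with the same engine that screens it.

## Expression and the two-library exact test

Normalized expression is transcripts per million clean reads with a 0.01
TPM floor (the floor is what makes a 0 → 7 count pair produce a finite,
reproducible fold change).  Fold change is `log2(NE_B / NE_A)`.

Without replicates, differences are scored by the Audic–Claverie
statistic: given count *x* in library 1 (clean total *N1*), the
probability of count *y* in library 2 (total *N2*) is

    p(y|x) = (N2/N1)^y · (x+y)! / ( x! y! · (1 + N2/N1)^(x+y+1) )

which is the negative-binomial mass NB(y; x+1, N1/(N1+N2)); the
implementation evaluates it in log-gamma space and is stable for counts
to 1e7.  For the two-sided p-value the lower tail C includes the observed
y and the upper tail D = 1 − C excludes it, p = min(1, 2·min(C, D)).
Partitioning the mass this way (rather than counting the observed point
in both tails) is what makes the p-value exactly invariant under swapping
the libraries and near-uniform under a Poisson null (measured KS ≈ 0.03
at rate 100); the double-counting variant is conservative by 2·p(y) and
asymmetric by the same amount.  With equal totals and x = y the point
mass straddles the distribution median, so p ≈ 1 as expected.  The
shorter tail is accumulated outward from y in log space with a
negligible-increment stop.

The DE class follows the NE ratio alone — up if > 2, down if ≤ ½, equal
otherwise — with the p-value reported alongside; an optional `p_max`
intersects the two.  Heatmap-style preparation log2-transforms, median-
centres and unit-norm-scales each row and builds an average-linkage tree
on 1 − Pearson distance; rows constant after transformation get zero
distance to all rows.

## Target prediction and qPCR

Sites are scanned ungapped over every transcript window of miRNA length:
match 0, G:U wobble 0.5, mismatch 1.0, doubled across miRNA positions
2–13; hits need score ≤ 4.0 and an intermolecular duplex energy ≤ −10
kcal/mol under the engine pair terms (no intramolecular folding, no
bulges — a deliberate simplification keeping scores reproducible).  The
qPCR utility computes N = 2^−ΔΔCt against a reference gene and control
condition.

## Synthetic data: what it emulates, and what it does not

The generator plants, on a random genome (default 200 kb, GC 0.42):
known miRNA hairpins (annotated and entered in the miRBase-style
reference), novel hairpins (absent from annotation and reference), and
decoy features for every annotation class.  Three libraries (default 1e5
reads each) mix, at the rates of a typical QC table, low-quality reads
and the five contaminant classes with clean reads whose class composition
follows a miRNA-dominant profile (≈ 82.5 % miRNA); insert lengths peak at
22 nt.  Reads are insert + 3' adapter + random filler cut to 50 cycles,
with per-base substitution errors (default 1e-3) and Gaussian Phred
scores.  Known-miRNA abundances are heavy-tailed (log-normal, σ = 1.5,
single-miRNA share capped at 20 %).

Determinism: one master seed, fixed substream offsets per operation
(genome 101, reads 201+stage, transcripts 301, abundances 501), so
identical configs give byte-identical FASTQ.

*Planted fold changes.*  DE miRNAs get expected counts scaled by exactly
2^lfc versus stage 0; non-DE miRNAs keep their baseline expectation; the
read-mass difference is absorbed by the unannotated background budget
(floored at 20 % of baseline, any remainder spread over non-DE miRNAs).
The default design interleaves +2/−2 entries on mid-to-low-abundance
miRNAs so the background always absorbs the shift.

*Planted novels.*  Each novel precursor is constructed by rejection —
mature with forced 5' U and AU in limits, reverse-complement star with
1–3 non-pairing substitutions, low-pairing loop — and re-rolled until its
*genomic* 150 nt-flanked window passes the full screen under the
configured engine, so generator closure holds by construction.  Novel
abundance weights are floored at 2 % of the novel budget (≈ 58 expected
reads per stage at defaults): a novel miRNA is only discoverable with
adequate depth, and below it the Dicer read-concentration criterion is
at the mercy of star-count fluctuations.

The generator does **not** emulate: indels or realistic error spectra,
isomiR end-heterogeneity, multi-lane or batch effects, replicate pooling
variance (configurable stages are single pools, as in the emulated
design), RNA-editing signal beyond substitution errors, or genome
repetitiveness (decoy repeats are single-copy intervals).  Passing tests
therefore demonstrate the pipeline's correctness against its stated
rules, not robustness to those real-data phenomena.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at the
study-scale conditions of a 200 kb genome, 20 known + 10 novel
precursors and three libraries of 1e5 reads, plus a compact 150 kb /
6 + 2 / 3×2000-read dataset for unit tests; the exact-test calibration
uses 1e4 Poisson draws at rate 100.  Decoy specificity is measured on 10
dinucleotide-preserving shuffles (Eulerian-walk rejection sampling) of
each novel window.  Energies compare with `<` at thresholds (MFE −20 is
a failure), percentages round half-up to 2 decimals, DE ratio
boundaries are `> 2` and `≤ ½`, and p-values are floored at the smallest
positive double so they remain in (0, 1].

## Known limitations

* The built-in energy model ignores stacking context, dangles and
  temperature; absolute energies differ from thermodynamic folders, so
  thresholds are calibrated per engine (the defaults are stated for the
  built-in model, under which they behave like their conventional
  counterparts).
* Exact mapping only by default; the mismatch option scans naively and
  is intended for toy genomes.
* Base-edit detection cannot distinguish editing from SNPs or
  sequencing error; on synthetic data the truth labels resolve this.
* The two-library exact test models sampling noise only; with biological
  replicates a dispersion-aware model would be preferred (out of scope
  for the emulated pooled design).
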