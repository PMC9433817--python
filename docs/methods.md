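# Methods

## Overview

`repsat` studies how the sampled blood volume limits in-silico
reconstitution of the B-cell receptor (BCR) heavy-chain repertoire.  The
package couples a ground-truth simulator (clone population → blood draw →
UMI-tagged sequencing) to an analysis pipeline (quality filter → UMI
consensus → germline annotation → FUS collapse → saturation statistics).
Every stochastic step is driven by a seed derived deterministically from
one master seed, so any run is reproducible byte for byte.

## Generative model

**Clone frequencies.**  Clone weights are drawn from a Pareto distribution
with shape $\alpha - 1$ (density $\propto w^{-\alpha}$) and normalized;
$\alpha = 2.2$ by default.  A power law is the simplest family that yields
repertoires dominated by the lowest observable frequency class (singleton
reads), which is the empirical shape of peripheral-blood BCR repertoires.
The exponent, and every other population parameter, is configurable —
there is no donor-level generative model to copy, so all defaults are
explicit stand-ins.

**Isotypes and class switching.**  The baseline isotype mixture is
IgM-dominant (IgM 0.70, IgD 0.12, IgG 0.10, IgA 0.07, IgE 0.01).  The
probability that a clone is class-switched follows a logistic curve in its
centred log10 frequency with slope `switch_bias` (default 1.0 per decade),
so expanded clones are preferentially switched — the structure seen when
antigen-driven expansion and class-switch recombination co-occur.
Conditional on the naive/switched split, the isotype is drawn from the
renormalized mixture.

**Somatic hypermutation.**  SHM counts are Poisson: mean 0.5 substitutions
for naive IgM/IgD clones, 8.0 for class-switched clones, applied at
distinct random positions of the clone's V segment (substitutions only, to
a different base, so the truth SHM count equals the Hamming distance to
germline).

**Germline segments.**  A toy germline library stands in for a curated
database: by default 5 V genes of 300 nt carrying fixed CDR1/CDR2 spans,
3 J genes of 48 nt, and five 30-nt constant-region tags, one per isotype.
Random draws are accepted only if pairwise Hamming distances are ≥ 10% of
the segment length (≥ 3 positions for tags), which makes best-identity
assignment unambiguous at the simulator's error rates.  Full clone
sequences are V (with SHM) + a 9–21 nt random junction + J + isotype tag;
the junction is redrawn if a (sequence, isotype) pair would collide.

**Blood draws.**  A draw of $v$ mL captures
$n = \mathrm{round}(v \cdot \text{cells\_per\_ml})$ cells as one
multinomial sample from the clone frequencies.  Draws from the two arms
are independent samples from the same population: venous homogeneity is an
assumption of the generator and a property the analysis then measures.

**Sequencing.**  Each sampled cell contributes
$1 + \mathrm{Poisson}(t - 1)$ mRNA molecules (`transcripts_per_cell`
$t = 3$ by default; $t = 1$ gives exactly one molecule per cell).  Each
molecule receives a random UMI (12 nt default, placed in the first bases
of the FASTQ record and echoed in the header) and is read
$1 + \mathrm{Poisson}(m - 1)$ times ($m = 3$ default), with i.i.d.
substitution errors at `error_rate` per base.  A `lowq_fraction` of reads
is degraded — a random ≥ 5% of positions drop to Phred 10 — so the quality
filter has something to reject; all other bases carry Phred 37.

The per-cell transcript count is the load-bearing modelling choice.  With
exactly one molecule per cell, a multinomial cell draw followed by
without-replacement read sampling is *exactly* a fixed-depth multinomial
from the population (the draws compose), so every fixed-depth repertoire
would be statistically identical regardless of volume and no saturation
could exist.  With several molecules per cell, reads can resample
molecules of the same cell, the finite cell count becomes a genuine
bottleneck, and diversity and coverage acquire the volume dependence the
analysis is built to measure.  The effective number of distinct cells
reachable by $n$ reads from $N$ sampled cells scales as
$N(1 - e^{-n/N})$, which increases — with shrinking increments — in the
volume: the saturation pattern.

## Pipeline conventions

* **Quality filter**: a read survives iff strictly more than 95% of its
  bases exceed Phred 20 (both comparisons strict; boundary semantics are
  pinned by tests).  Empty reads are rejected with a warning.
* **UMI clustering** is exact-match; reads with non-ACGT UMIs are dropped
  and counted.  Mismatch-tolerant UMI networks are out of scope.
* **Cluster selection**: ≥ 3 reads ("more than two"), configurable.
* **Consensus**: modal read length (ties → shorter); per position,
  plurality vote among reads of that length, then highest summed Phred,
  then the alphabetically smallest base.  The chain exists purely for
  determinism.
* **Annotation** is gapless best-identity assignment over all offsets
  (ties → first gene in germline order, then smallest offset), with a 0.8
  identity floor — far above the 0.25 random baseline, below worst-case
  SHM load.  The upstream channel produces substitutions only, so gapless
  alignment is exact here; indel-aware tools should replace this stage for
  real data, which can enter the pipeline as AIRR tables at the repertoire
  stage.  CDR1/2 come from the assigned V gene's recorded spans; CDR3 is a
  fixed-flank junction window (V end − 6 to J start + 6).  The isotype is
  the best-matching constant-region tag at the 3′ end (identity ≥ 0.8,
  ties → undetermined).  V mutation counts are Hamming mismatches over the
  aligned V region only.
* **Repertoire**: functional reads are downsampled without replacement to
  a fixed depth (190 000 in the motivating study; 19 000 at the package's
  test scale) and collapsed by exact (sequence, isotype) key.  On count
  vectors the same law is drawn as a multivariate hypergeometric.
* **Hill q = 1** uses the entropy-limit formula, never a numerical limit.
  Rarefaction is empirical subsampling (mean Hill number over
  without-replacement subsamples); no Chao-type extrapolation.
* **Sections**: 10 log10-equidistant bins between the reference minimum
  and maximum frequency, half-open with a closed top bin, indexed 1
  (lowest) to 10 (highest).  Binning adds 1e-9 in log10 space before the
  floor so that frequencies sitting on a boundary land in the upper bin
  regardless of floating-point representation.  A degenerate range (all
  frequencies equal) populates only the top section.  The representative
  frequency of a section is the geometric mean of its member frequencies
  (member-based, not boundary-based: it degrades gracefully for sparse
  sections); empty sections are reported as undefined (NaN), never as 0.
* **Threshold scans** walk sections from the top; undefined sections do
  not break a run of qualifying sections.  The detection threshold demands
  coverage 1.0, the 50% cutoff demands ≥ 0.5.
* **Correlations** are computed on log10 frequencies by default (raw scale
  available), restricted to FUSs present in both repertoires; frequency
  strata are evaluated on the larger-volume repertoire's frequencies.
  Fewer than two pairs, or zero variance, yields an undefined result with
  a reason, not an exception.

## The replicated volume study

`volume_study` draws, per replicate: one left-arm sample per volume analog
(5, 10, 20, 40), plus two independent right-arm 40 analogs.  The first
right-arm draw is the reference for coverage, thresholds and the
volume-pair correlations (mirroring the two-arm design); the second exists
only so that cross-arm statistics can be compared against genuinely
same-arm replicate statistics.  Defaults: 10⁴ clones, α = 2.2,
2×10⁴ cells per mL analog, depth 19 000, 10 replicates — sizes chosen so
the study runs in seconds while the saturation pattern is well resolved
against replicate noise.

One scale interaction deserves note.  At these sizes the repertoire holds
roughly two reads per clone, so even the lowest-frequency section of the
reference is more than 50% covered by the 5 mL analog; the 50%-coverage
cutoff then collapses to the repertoire minimum and the lower-frequency
stratum under it is empty (in deep donor repertoires, with far less than
one read per clone, the cutoff falls mid-axis).  For the stratified
correlation comparison, `volume_study` therefore uses the first cutoff
that actually splits the repertoire — the 50% cutoff where possible,
otherwise the detection threshold — requiring at least two distinct
frequency levels on each side.  `cutoff_50` itself always implements the
plain 50% rule.

## What the simulation does and does not show

The generator reproduces the structural features the analysis depends on:
singleton-dominated frequency distributions, an IgM/D-dominant low-SHM
naive compartment, class-switched clones concentrated at higher
frequencies, volume-proportional cell capture, UMI-resolvable sequencing
error, and arm-independent sampling.  It deliberately omits: paired-end
merging artefacts, PCR chimeras and amplification bias, indels, UMI
collisions beyond random tag coincidence, per-cell transcript heterogeneity
between B-cell subsets (plasmablasts vs naive cells), and clone-count /
depth regimes of real donors (~10⁶⁺ clones at 1.9×10⁵ reads).  Passing
tests therefore certify the pipeline's correctness and the qualitative
saturation phenomenology, not quantitative agreement with any donor; the
printed statistics of real repertoires depend on the donor's clone-size
distribution, which is not identifiable from this simulation.

## Numerical and testing conventions

Monte-Carlo comparisons in the test suite use pre-registered allowances:
3-standard-error bands where a closed-form moment oracle exists
(binomial/hypergeometric means), a 1% relative allowance on Hill-mean
monotonicity across volumes (≈ 1.7 standard errors of a 10-replicate mean
difference), and 0.02 absolute on coverage monotonicity.  Exact claims —
consensus tie-breaks, boundary semantics, section arithmetic, the
noiseless round-trip identity, byte-level reproducibility — are asserted
with no tolerance.  Pearson r is checked against the textbook
covariance formula to 1e-12 and Hill q = 1 against an independent entropy
computation to 1e-12.
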