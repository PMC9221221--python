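# Methods

`topochron` analyses the growth cycle of a bacterial batch culture as the
interplay of two gradients on a circular chromosome: a **temporal**
gradient of global DNA superhelical density σ(t) — negative supercoiling
rises sharply after nutritional shift-up and relaxes toward stationary
phase — and a **spatial** gradient of duplex thermodynamic stability,
G/C-rich (stable) DNA near the replication origin (OriC) grading into
A/T-rich DNA near the terminus (Ter) along both replichores. Coupling the
two orders gene activation in space and time: as the chromosome relaxes,
maximal activity sweeps from OriC-proximal genes with very negative
optimal superhelical densities toward Ter-proximal genes that prefer
relaxed DNA.

## Melting-energy profile (`thermo`)

The free melting energy (fME) of a window is the mean nearest-neighbor
stacking free energy ΔG°₃₇ of its base steps, using the unified
ten-parameter duplex table (values from −0.58 kcal/mol for TA to
−2.24 kcal/mol for GC; reverse-complement symmetric). Duplex initiation
and symmetry corrections are omitted: they are O(1) per duplex and
irrelevant to windows of 10⁵ steps. Whether a ΔG, ΔH or melting-
temperature proxy best matches published genome wheels is not decidable
from the figure conventions alone; ΔG°₃₇ is the assumption here and the
parameter table is swappable (`NNParameterSet`).

Windows wrap the circle, are centered every `step` bp (default 1 kb), and
are normalized per step so different window widths are comparable. The
default width is 500 kb for full-size genomes and genome_length/9
(rounded to 1 kb) for smaller synthetic genomes, preserving the
window:genome ratio of the 500 kb : ~4.6 Mb convention. The sliding
computation is a cumulative-sum difference; it agrees with naive
per-window summation to 1e-9 (tested), and with `step=1` the profile mean
equals the whole-genome per-step mean exactly (every step covered equally
often).

Per-gene values use the strand-aware transcription start (+: `start`,
−: `end−1`) as the promoter proxy and take the circularly nearest window
center (ties to the lower coordinate).

Superhelical density converts to total superhelical turns per kb as
|σ|·1000/h with helical repeat h = 10.5 bp/turn: σ = −0.08 gives 7.6 (~8)
turns/kb, σ = −0.03 gives 2.9 (~3).

## TCDS scores (`tcds`)

Transcription generates negative supercoils upstream and positive
supercoils downstream of the translocating polymerase (twin-domain
geometry); the supercoils diffuse into neighboring promoters. The score
at a focal promoter p is

    TCDS(p, t) = Σ_n sign(p, n) · E_n(t) · exp(−d_n / λ),   d_n ≤ R

over neighbors n within range R = 10 kb. `sign(p, n)` is −1 when the
neighbor end facing p along the shorter arc is its 5′ end (p sits in the
upstream negative domain), +1 for the 3′ end. `d_n` is the circular
distance from p to that facing end — supercoils emanate from the unit's
boundaries, not its midpoint. The decay length λ = 2.5 kb is a package
choice (only the 10 kb range is conventional); it puts the weight at the
cutoff at exp(−4) ≈ 0.018, so the hard cutoff discards ~2% effects.
Neighbors that contain the focal promoter are skipped (the sign is
undefined inside a transcribed unit). Expression columns are used as
given — the score is linear in abundance, and group curves are meant to
reflect abundance dynamics; unit-sum column normalization is available
but off by default.

The ori/mid/ter partition ranks genes by circular promoter distance to
OriC and cuts the ranks into three contiguous blocks, remainders joining
ori then mid.

## Trajectory summaries (`trajectories`)

Group-relative expression is the set mean divided by the all-gene mean
per timepoint (mean, not median — configurable upstream of the call by
passing a different statistic). Expression-weighted means of per-gene
properties (fME, distance to OriC) are Σ prop·E / Σ E per timepoint —
invariant to column rescaling. Curves are computed on the raw minutes
grid; smoothing is a plotting concern and is not applied.

For joint plotting, curves are min–max normalized to (0;1); a constant
curve maps to 0.5 with a logged warning (no dynamic range to rescale).

The **remapping envelope** quantifies how much a curve depends on which
gene carries which expression profile: each replicate draws ⌈fraction·G⌉
genes uniformly without replacement and permutes their expression rows
among themselves (derangement not enforced), recomputes the statistic,
and the per-timepoint SD over replicates (ddof = 1) is the envelope.
"Remap 10% of the expression patterns" is read as within-subset
permutation; reassignment to arbitrary genes would be an alternative
reading, so the scheme is parameterized and flagged. fraction = 0 is
short-circuited to exact zeros (identical replicates; avoids float dust
from the mean subtraction).

The promoter-optimum trend statistic takes a table of promoters with
known optimal superhelical density ranges and distances from OriC
(five characterized promoters — hisR, rrnAP1, fis, tyrT, osmE — ship as
`REFERENCE_PROMOTER_OPTIMA`), reduces each σ range to its midpoint, and
reports the Spearman rank correlation of distance vs. signed midpoint.
On the reference table ρ = +1: the optimum rises monotonically (toward
relaxation) with distance from the origin. Midpoints rather than range
endpoints keep the statistic single-valued; the endpoints remain in the
type for sensitivity runs.

## Synthetic growth cycle (`simulate`)

The generator emulates a time-resolved batch-culture expression data set
on a scaled-down chromosome. Defaults are the study conditions: L = 1 Mb,
400 genes, G/C fraction declining linearly 0.60 → 0.40 from OriC
(position 0) to Ter (L/2) along both replichores, σ(t) piecewise linear
from −0.03 at inoculation to a single minimum of −0.075 at 60 min and
back to −0.03 at 420 min, sampled every 10 min (43 timepoints). The σ
schedule is an assumption — no quantitative σ(t) curve exists to copy —
so its shape and knots are configurable, and all pattern-recovery results
on synthetic data are conditional on it.

Each gene's optimal superhelical density (σ\*) is an affine function of
its local fME (interval midpoint, strand-independent): the most stable
gene maps to σ_peak, the least stable to σ_stat. The min–max map is used
instead of a z-score-plus-clip because it hits both boundary conditions
exactly for any fME distribution and leaves no clipped mass of genes
sharing σ\* = σ_stat (which would scramble peak-time ranks). Labels:
σ\* ≤ −0.060 → `hyp` (activated by hyper-negative supercoiling),
σ\* ≥ −0.045 → `rel` (activated by relaxation), buffer zone unlabeled.

Expression follows a Gaussian response in σ with common width w = 0.012
(symmetric unimodal response — activity declines on both sides of the
optimum), times a lognormal per-gene baseline (log-sd 0.5), times
multiplicative lognormal noise (log-sd 0.2; `noise=0` gives the noiseless
mean). The noiseless argmax is recorded as the gene's peak time; ties
resolve to the **latest** timepoint, since σ(0) = σ(t_end) makes the
response of stationary-tuned genes symmetric and the early tie-point
reflects the inoculum, not the response. 1 kb gene bodies, no operons, no
length variation: genome-scale realism is deliberately sacrificed for
testability.

Genes are placed as adjacent pairs (200 bp within a pair, ≥401 bp plus
randomly distributed slack between pairs) so that each gene's nearest
neighbor is provably its partner. Orientation then couples to the labels:
with probability `orientation_bias` (default 0.8) a hyp gene's pair is
made divergent (it receives negative TCDS from its partner's 5′ end) and
a rel gene's pair convergent (positive TCDS); conflicting desires in a
mixed pair resolve in favor of the hyp member, undecided pairs get random
strands. Pairing is what makes the bias-1 guarantee ("every hyp gene
divergent with its nearest neighbor") satisfiable: with genes placed
independently, nearest-neighbor orientation constraints can chain and
contradict.

All stages draw from per-stage child generators of a single seed
(`default_rng([seed, stream])`), so the bundle is bit-reproducible and
stages can be rerun in isolation.

### What the generator does and does not emulate

It reproduces the coupled-gradient logic: G/C (hence fME) gradients,
σ-dependent activation order, hyp/rel classes, orientation-coupled TCDS
signs, multiplicative measurement noise. It does **not** emulate
regulator dynamics (NAPs, ppGpp, sigma-factor competition), operon
structure, gene-length or expression-level covariates, replication-
associated dosage, or count-level sampling (a negative-binomial count
mode would sit on top of the mean model; values here are treated as
normalized abundances). Passing pattern-recovery tests therefore shows
the analysis chain is sound and self-consistent — not that real data
must exhibit the pattern.

## Numerical and degenerate-input choices

- Circular distances are exact integers; window sums use float cumsums
  (agreement with naive summation to 1e-9 on 100 kb scales).
- Nearest-center and facing-end ties resolve to the lower coordinate /
  start edge, deterministically.
- Genes spanning the linearization point are rejected on input; rotate
  the sequence first.
- Degenerate (constant) fME profiles yield equal σ\*, no labels, and a
  warning; constant curves normalize to 0.5 with a warning; zero total
  expression weight and empty gene sets raise errors rather than NaN.

## Pipeline problem sizes

The default pipeline and the reproduction script run the generator at
its native study conditions (1 Mb, 400 genes, 43 timepoints) with
100-replicate envelopes; a full run takes a few seconds on one core.
Unit and property suites use 40–120-gene genomes of 60–300 kb, chosen to
exercise every code path with brute-force-checkable sizes.
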