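# Methods

This note documents the models, parameter choices and numerical
conventions behind cobindseq, and what the synthetic benchmark does and
does not establish about real data.

## Coordinate and track conventions

All coordinates are 0-based, half-open (BED-native); any 1-based input
would have to be converted at the boundary. Coverage and occupancy are
dense per-base numpy vectors per chromosome. This is deliberate: the
package targets desk-scale genomes (tens of Mb), where dense vectors
keep every operation exact and trivially comparable to per-base
brute-force oracles in the test suite. Reads flagged as non-uniquely
mapped are dropped (with a logged count) before extension; extended
reads are clipped at chromosome ends rather than discarded.

## Consensus regions

Caller agreement is evaluated per base: each caller's peak set becomes a
0/1 occupancy vector, the vectors are summed, and maximal runs with
sum ≥ `min_support` (default 2) and length ≥ `min_length` (default
150 bp) are the candidate regions. The region set is invariant under
caller order, and on any instance the interval sweep is identical to a
per-base recomputation (tested on random jittered instances).

## Negative-binomial background and scoring

The "background" is everything not claimed by any caller. Both tracks
are cut into `bin_size` = 1 kb bins; a bin's read count is the summed
per-base coverage divided by the extended read length (exact when reads
lie inside bins, a mild smoothing across boundaries otherwise). Three
quantities are fitted on background bins only:

* **scale** — least-squares slope through the origin of sample on
  control counts. With noisy, independent bin counts this slope is
  attenuated below the ratio of means (by E[x]²/E[x²]); the scoring
  floor below makes this conservative rather than anticonservative, and
  the slope matches the exact-proportionality cases by construction.
* **mean** — average sample background count per bin.
* **dispersion** — method of moments, α = max(0, (Var − μ)/μ²), so
  Var = μ + αμ². α = 0 falls back to an exact Poisson tail; the
  equivalence is tested to 1e-10 relative error.

A region of length L with sample count k (reads overlapping by ≥ 1 bp,
each read once — the region is the full consensus run, not a fixed
window) and control count c is scored with the NB upper tail at expected
mean max(scale·c, μ·L/bin_size). The floor keeps empty-control regions
held to the genome-wide background rate. Fold change is
(k + 1)/(scale·c + 1); the pseudocount of 1 avoids division by zero and
is recorded in the output metadata. BH adjustment is applied once across
all candidates of a factor (not per chromosome), and the default filters
are k ≥ 10, FC ≥ 2, q ≤ 0.01. Regions abutting chromosome ends are
scored like any other.

Null calibration: with sample and control drawn from the same NB
background (planted sites at zero enrichment, so candidates exist but
carry no signal), the measured fraction of candidates passing all three
filters is ~0 over 20 seeds, far below the 2 % tolerance asserted in the
tests.

## Co-binding classification

Two site sets are merged by center distance: pairs within
`pairing_distance` = 250 bp become one combined site at the midpoint
(greedy nearest-center matching resolves multi-overlaps; each input site
is used exactly once, so |A-only| + |B-only| + 2·|paired| = |A| + |B|).
The profile matrix averages control-subtracted coverage
(max(0, sample − scale·control); clamping is the default because
negative ChIP signal has no physical meaning, and an unclamped mode
exists for checks) in 25-bp sub-windows across ±500 bp — 40 sub-windows
per factor, 80 columns. Windows running past a chromosome end are
zero-padded.

**Standardization.** Two z-scoring modes are implemented and switchable
(`zscore_mode`):

* `"column"` (classifier default): each 25-bp sub-window column is
  standardized across sites. This preserves the relative amplitude
  between the two factor tracks of a site.
* `"site"`: each site × track segment is standardized independently
  (population SD; zero-variance segments become zero), making profile
  shape, not ChIP efficiency, the clustering signal.

Column mode is the default because per-site standardization normalizes
every segment to the same norm, after which a single stray background
read near the window center of the silent track is indistinguishable
from a genuine peak; under the default simulation conditions this caps
class agreement at ARI ≈ 0.84 and biases the shared fraction upward by
about +0.05, while column mode recovers the planted classes at
ARI ≥ 0.98. Both readings of "z-scores in each sub-window" are
defensible; the package makes the better-identified one the default and
keeps the other a flag.

Clustering is Lloyd's K-means (K = 3, k-means++ initialization, best of
10 restarts, explicit seed recorded in output metadata). The three
clusters get semantic labels deterministically: clusters are ranked by
mean raw (un-z-scored) signal difference between the two tracks —
highest → A-only, lowest → B-only, middle → shared — replacing the
visual heatmap labeling with a rule that is symmetric under swapping the
factors. Ties are flagged as ambiguous and broken by cluster id. Paired
sites' profiles are centered on the midpoint of the two peak centers.

## Motif scanning

The bundled pattern is the composite E-box/GATA element
CTG–N(6–8)–WGATAR; any bipartite IUPAC pattern with a variable
unconstrained spacer is accepted. Matching is case-insensitive
(soft-masked lowercase is still matchable; maskedness is handled by the
site filter, not the scanner), and an N in the subject matches only a
pattern N, so hard-masked runs cannot fabricate composite hits. Minus
strand hits are matches of the reverse-complemented pattern on the
forward sequence, reported in forward coordinates. Every
(offset, spacer, strand) triple is reported; the site-level proportion
counts a site once regardless of hit multiplicity, and a minimum-support
reporting threshold (`min_sites`) can blank fractions backed by too few
sites. Site preparation fetches 200-bp windows centered on each site
(N-padded at chromosome ends by default), counts lowercase + N as
masked, and removes sites with ≥ 150 masked bases (inclusive bound).
Uniform subsampling of large classes is deterministic per seed.

## TSS annotation

The TSS is the gene interval's start on + and end − 1 on − (strand "."
is rejected — the TSS is undefined). Each site's center is assigned to
the single nearest TSS on its chromosome when within 1 Mb; ties break to
the smaller TSS coordinate, then the lexicographically smaller gene id.
The signed distance is center − TSS, set to 0 when the site interval
spans the TSS; |distance| < 5 kb is proximal, the rest distal,
out-of-range sites are unassigned. Gene-set outputs stop at per-class
gene lists; ontology/pathway enrichment is intentionally out of scope.

## Synthetic data: what it emulates, and what it does not

The generator plants everything the pipeline later has to find:

* genome — uniform random A/C/G/T, 2 × 5 Mb by default, with contiguous
  soft-masked stretches (exponential lengths, mean 500 bp) covering
  ≈ 10 % of the sequence;
* sites — 1,500 centers, uniform with ≥ 2 kb spacing, classes drawn
  from (shared, A-only, B-only) = (0.6, 0.2, 0.2), echoing the
  predominance of co-occupied sites in the motivating system;
* motif — a concrete CTG + N(6–8) + WGATAR instance written into the
  sequence at A-bound sites with probability 0.9 (B-only sites never),
  so the factor-specificity of the composite element is reproducible;
* coverage — NB(1 read/kb, α = 0.2) background with uniform positions,
  plus Poisson(30) reads per bound site with midpoints Normal(center,
  60 bp); IgG receives background only; all reads are emitted directly
  as 200-bp extended intervals because alignment is out of scope;
* callers — three independent callers, each reporting a bound site with
  probability 0.9 as center ± 300 bp with Normal(0, 30 bp) edge jitter,
  plus Poisson(5/Mb) false peaks (flagged in the truth files);
* genes — 200 non-overlapping genes, 2–10 kb, random strand, uniform
  placement.

Every artifact is a pure function of (config, seed); per-artifact RNG
streams make each file reproducible in isolation, and truth tables
round-trip losslessly through TSV.

What passing these benchmarks does **not** show: real ChIP-seq has
GC- and mappability-driven background structure, fragment-length
artifacts, duplicate reads and caller-specific systematic biases, none
of which the generator emulates. Recovery and calibration here establish
the internal correctness and statistical sanity of the pipeline, not its
field accuracy on any particular organism. Headline real-data figures
(co-occupancy percentage, distal binding fraction) require the original
sequencing data and are deliberately outside the benchmark, although the
synthetic defaults were chosen so that the same qualitative pattern
(majority shared sites, mostly distal, motif confined to A-bound
classes) emerges.

## Problem sizes and determinism

The default benchmark sizes — 10-Mb genomes, 1,500 sites, 10 seeds for
recovery/class checks, 20 seeds for null calibration — were chosen as
the smallest instances at which the binomial/multinomial noise on the
measured rates is clearly below the asserted tolerances. The end-to-end
pipeline writes a manifest of per-output SHA-256 checksums; re-running
any config reproduces it byte for byte, which the test suite asserts on
the bundled demo.

## Known limitations

* The NB fit assumes a homogeneous background rate; no local (sliding)
  background as in some callers.
* The scale estimator's attenuation under low-count bins (noted above)
  under-subtracts control in `subtract_control`; z-scoring downstream
  absorbs the residual flat background.
* Exactly two factors; K ≠ 3 clusterings run but are not semantically
  labeled.
* Caller emulation is interval-level; it does not model any specific
  caller's scoring.
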