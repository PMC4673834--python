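# cobindseq

Consensus ChIP-seq binding-site detection with negative-binomial
significance against an IgG control, two-factor co-occupancy
classification, composite E-box/GATA motif scanning, and nearest-TSS
annotation — with a fully ground-truthed synthetic-data generator so the
whole pipeline is testable end to end without any downloads.

## Who this is for

Groups analysing ChIP-seq of transcription-factor complexes (the
motivating system is the erythroid LDB1 complex and its co-repressors)
who want the classic multi-caller workflow as a reusable, tested
library: call binding sites supported by several peak callers, test them
against an immunoglobulin (IgG) control, ask where two factors co-bind,
whether the co-bound sites carry the complex's composite DNA signature,
and which genes they likely regulate.

## The method

**Consensus regions.** Each peak caller's output is turned into a binary
per-base occupancy vector; vectors are summed and maximal runs with sum
≥ 2 and length ≥ 150 bp become candidate consensus-binding regions.

**Significance.** Uniquely mapped reads are extended to 200 bp in the 3′
direction and piled into coverage. In background bins (1 kb, away from
any caller peak) the model fits a control-to-sample scale factor *s*
(least-squares slope), a background mean *μ* per bin and a
negative-binomial overdispersion *α* by the method of moments
(Var = μ + αμ²; α = 0 is the Poisson limit). A region with read count
*k* and control count *c* gets the upper-tail p-value
P(X ≥ k) under NB(max(*s·c*, *μ*·len/bin), *α*), Benjamini–Hochberg
adjustment across all candidates, and is kept when
k ≥ 10, fold change (k+1)/(s·c+1) ≥ 2 and q ≤ 0.01.

**Co-binding classes.** The two factors' site sets are merged (centers
within 250 bp pair up, midpoint center). Around each combined site the
background-equalized, control-subtracted coverage of both factors is
averaged in 25-bp sub-windows across ±0.5 kb, standardized to z-scores,
and clustered with K-means (K = 3); clusters are labeled
A-only / B-only / shared from their mean per-track signal.

**Motif and genes.** 200-bp repeat-masked sequences centered on each
site (sites with ≥ 150 bp masked removed) are scanned for the composite
E-box/GATA motif `CTG N(6–8) WGATAR` on both strands, and every site is
assigned to the single nearest TSS within 1 Mb (proximal < 5 kb,
distal otherwise).

The library is organised as scikit-learn-style estimators —
`ConsensusPeakCaller` and `CoBindingClassifier` expose
`fit`/`get_params` and trailing-underscore fitted attributes — with
plain functions for every individual step.

## Worked example

The bundled demo config simulates a 2 × 500-kb genome with 150 planted
sites (60 % bound by both factors) and runs every stage:

```bash
cobindseq run -c src/cobindseq/data/demo.cfg -o demo_out
```

The run manifest (`demo_out/manifest.json`) records, per stage, the
record counts actually produced:

```
simulate    {'n_genes': 60, 'n_sites': 150}
consensus   {'A_candidates': 119, 'A_passing': 119, 'B_candidates': 120, 'B_passing': 120}
cobinding   {'n_combined': 146, 'shared': 95, 'A_only': 26, 'B_only': 25}
annotation  {'proximal': 75, 'distal': 71, 'unassigned': 0}
```

and `demo_out/motif_summary.tsv` gives the per-class motif proportions:

```
class   n_total n_with_motif  fraction
shared  89      79            0.88764
A_only  24      22            0.916667
B_only  24      0             0
```

Reading: of 150 planted sites, 119/120 factor-A/B consensus sites pass
the read-count, fold-change and q-value filters; merging yields 146
combined sites whose K-means classes recover the planted 95/26/25
shared/A-only/B-only structure; the composite motif appears in ~90 % of
shared and A-only sites and in none of the B-only sites (the generator
embeds it only at A-bound sites), mirroring how a factor-specific
composite element behaves in real data. Each stage is also available as
a standalone subcommand (`simulate`, `consensus`, `cobind`, `motif`,
`annotate`) operating on ordinary BED/FASTA/TSV files.

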