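# Methods

## Duplex energy model

Binding sites are scored with an intermolecular nearest-neighbor free
energy at 37 °C. A duplex structure is a chain of canonical base pairs
(Watson–Crick plus G:U wobble) monotone along both strands, read 5'→3'
on the miRNA and 3'→5' on the target. Its energy is

    ΔG = ΔG_init + Σ_junctions ΔG(junction) + Σ_ends ΔG_end

where a junction between consecutive pairs is a stack (tabulated doublet
energy), a bulge (one-sided gap, length-dependent initiation), or an
internal loop (two-sided gap, size-dependent initiation plus a Ninio
asymmetry term of 0.6 kcal/mol per unpaired-length difference, capped at
3.0). Terminal AU or G:U pairs each add 0.45 kcal/mol; duplex initiation
is 4.09 kcal/mol. Stack and loop constants are the published Turner 2004
RNA parameters (Watson–Crick stacks at published precision, wobble
stacks at 0.1 kcal/mol). Two simplifications relative to full Turner
2004: 1×1, 1×2 and 2×2 internal loops use the generic size-dependent
initiation rather than tandem-mismatch tables, and no dangling-end or
coaxial terms are applied. Both choices keep the grammar minimal; the
exhaustive enumeration oracle shares the same table, so the dynamic
program is verified against an independent implementation of the same
physical model rather than against a vendored tool.

The DP computes, for every pair (i, j), the best duplex whose 3'-most
pair is (i, j), looking back at most `max_loop + 1 = 16` positions on
each strand (bulges and internal-loop sides are capped at 15 nt). Cost is
O(M·N·16²) per window; the backtrace yields the pairing string. If no
canonical pair exists the function returns the "no duplex" sentinel
(`None`) rather than an energy. Because the reported ΔG is a minimum
over structures, adding window context can only lower it (tested as a
property).

## Site scanning

A site must be seed-anchored: the reverse complement of miRNA positions
2–7 (6mer), 2–8 (7mer-m8), or 2–7 plus a target adenine opposite
position 1 (7mer-A1) must occur exactly (G:U disallowed in the seed,
allowed elsewhere in the helix). Each anchor defines a window of miRNA
length + 15 nt extending 5' on the target (where the miRNA 3' region
pairs), bounded at 40 nt, on which the duplex MFE is evaluated. Sites
with ΔG strictly below the threshold (−20 kcal/mol by default) are
retained; overlapping sites are resolved greedily from the lowest ΔG,
and hits are reported sorted by ΔG, with 0-based half-open coordinates
(1-based only in report columns). When a circRNA carries conserved
sub-intervals, scanning is restricted to them; conserved regions are an
input, not something the package infers. AGO-occupancy intervals (e.g.
PAR-CLIP-derived BED) can optionally flag hits as AGO-supported; they do
not change scoring.

## Vote filter, scoring, ranking

miRNA→mRNA evidence uses five per-algorithm site counts; a record is
kept when the sum is ≥ 5 (inclusive — one site from each algorithm
suffices). A circRNA's sponge score aggregates the feature classes of
the disease miRNAs with at least one retained site. The class multiset
summed per miRNA (`sum_classes`) is the default, chosen because a
sponge can meaningfully "harbor" more than five classes only if classes
are counted per miRNA and summed; `union_classes` (bounded by 5) is
provided for sensitivity analyses, and the policy used is recorded in
every output. Whether the five features should carry unequal weights is
left open deliberately; `evidence_count` is carried unweighted by
default with an optional multiplier. Ranking is by descending score with
a deterministic tie cascade: more distinct sponged miRNAs, more retained
hits, then lexicographic id.

## Expression screen

Differential expression is a Welch two-sample t test per feature on the
log2 scale, log2FC = mean(A) − mean(B). The pass rule is strict on both
sides (|log2FC| > 1.5 AND p < 0.05), so a fold change of exactly 1.5
fails; "log2FC > 1.5" is read as an absolute-value rule with direction
reported, since both higher and lower features are of interest. Raw p
values are used by default to mirror the screening practice this
pipeline emulates; a moderated-variance option (per-feature variances
shrunk halfway toward their grand mean) exists behind a flag, off by
default. Features with zero variance in both groups and equal means get
p = 1 by convention, logged. Co-expression edges use the Pearson
product-moment correlation over shared samples, kept iff r > 0.1
(strict); constant vectors have undefined r and are never kept, and a
warning is always logged when only three samples are shared, the minimum
allowed — correlations at n = 3 are reported as specified but are
statistically fragile.

## Clinical statistics

Markers are dichotomized at the cohort mean with ties to low
(configurable). The 2×2 layer computes the Pearson chi-square without
continuity correction — required for the statistic to reproduce the
reference value 7.119 from the Ki-67 counts — the exact two-sided
Fisher p, and the odds ratio oriented row2-vs-row1, OR = (a·d)/(b·c).
The reference table labels this column "RR" (relative risk); all eleven
printed values match the odds-ratio formula and none match a risk
ratio, so the package computes the odds ratio and documents the label
discrepancy rather than resolving it. Zero cells yield ±∞/0 with an
explicit flag; an optional Haldane (+0.5) correction is off by default.
Survival uses the product-limit estimator and the two-group log-rank
test (via lifelines). Multivariate Cox regression is out of scope: it
is an off-the-shelf model and the patient-level covariates needed to
fit it are not part of the package's inputs.

## Synthetic data: what it emulates, what it does not

The generators define the study conditions under which the pipeline is
tested:

- **Sequences** — circRNA conserved regions are uniform random RNA
  (25% per base; no composition bias is assumed) with planted sites
  that are exact reverse complements of a full miRNA (strongest signal)
  or of its 8-nt 5' end (`plant_mode="seed"`, for specificity tests).
  Placement uses an exact combinatorial bijection, so non-overlap is
  guaranteed and infeasible requests fail loudly.
- **Expression** — group mean plus i.i.d. Gaussian noise on the log2
  scale. Defaults mirror the emulated contrast: 3 vs 4 samples (the
  three TNBC vs four luminal/HER2+ cell lines; a choice, since per-group
  sizes beyond the cell-line counts are not specified), planted log2FC
  2.0, noise sd 0.3 (0.2 in the demo; typical residual microarray sd).
  No probe-level effects, batch structure, or correlation between
  features — so passing tests demonstrate threshold semantics and
  operating characteristics under clean noise, not robustness to array
  artifacts.
- **Cohort** — 136 patients (98 low / 38 high) whose per-variable 2×2
  crosstabs reproduce the reference-table counts exactly (levels are
  permuted within marker group, so variables are conditionally
  independent given the marker — real covariates are not). Survival is
  exponential per group: baseline hazard 0.01/month (low group), hazard
  ratio 9.114 by default (the reference multivariate estimate), with
  administrative uniform censoring on (12, 72) months matching a
  2010–2015 enrollment window. This is the simplest model supporting
  log-rank size and power checks; it does not emulate non-proportional
  hazards or informative censoring.

Every generator returns ground truth next to the data and is
deterministic per seed (one substream per generator).

## Problem sizes and numerical choices

The test suite and acceptance script use: 500 random pairs of 4–10 nt
for DP-vs-enumeration equivalence (the enumeration oracle is exponential
and only feasible at this scale); 10 seeded 3-circRNA instances (50
planted sites) for recovery; 100 seeded 20-feature matrices (4 vs 4,
sd 0.1) for DE operating characteristics; 1000 null cohorts for log-rank
type-I error and 500 at hazard ratio 4 for power; a 6-circRNA, 8-miRNA
demo for the end-to-end screen. Energy comparisons use an absolute
tolerance of 1e-9 kcal/mol; correlation oracles 1e-12. Ties in ranking
and de-overlap are broken deterministically as described above, so
identical seeds give byte-identical outputs.

## Known limitations

- The duplex grammar omits multibranch structures, intramolecular
  folding and target accessibility (PITA-style ΔΔG), like the
  hybridization-only tools it models.
- Seed tiers stop at 7mer-m8 (no separate 8mer tier); an m8 match with
  an A1 adenine is reported as 7mer-m8.
- Inventory-scale results (hundreds of circRNAs, tens of thousands of
  interactions) depend on external database snapshots and are not
  reproduced; the synthetic benchmark substitutes planted-truth checks
  at desk scale.
- Real conserved-region definitions are an input; the package does not
  compute sequence conservation.
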