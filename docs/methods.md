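# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the simulator does and does not emulate, and
the numerical choices a maintainer should know about.

## The measurement model

Each hybridization compares a Cy5-labelled sample against a Cy3-labelled
common reference on the same array. Per spot the scanner reports an
intensity pair; the analysis works on

- **M** = log2(sample / reference), the quantity of interest, and
- **A** = ½·log2(sample · reference), the mean log intensity,

after background correction. Because the reference is the same cDNA pool on
every array, a treatment effect for gene *g* appears as a shift of its M
values on treated arrays relative to control arrays, and the per-gene test
is a two-sample comparison of M between array groups.

## Preprocessing

Fixed stage order, recorded in the matrix provenance:

1. **Background correction.** A per-array, per-channel constant is
   subtracted; by default it is estimated as the median of the lowest 5% of
   intensities in that channel (`bg_quantile`), a robust stand-in when no
   per-spot background accompanies the scan. Fixed values can be supplied
   instead. Corrected intensities are floored at 1 (`floor`) so log ratios
   stay finite; the low-intensity filter removes most spots the floor would
   otherwise distort.
2. **Spot filtering.** Flagged spots are dropped, as are spots with *both*
   channels below 100 units (`low_threshold`); a spot bright in either
   channel survives. These are the only steps that remove spots.
3. **Log ratios.** M and A per retained spot.
4. **Lowess normalization.** Per array, a locally weighted regression of M
   on A (span 0.3 of the spots, 3 robustness iterations, a small `delta`
   for speed) is subtracted from M. This removes the smooth
   intensity-dependent dye bias produced by unequal Cy3/Cy5 labelling
   efficiencies. The span trades curvature bias against variance: narrower
   spans track a steep bias more faithfully (the tests use 0.2 on
   noise-free data) while 0.3 is a stable default for noisy triplicates.
   Arrays with fewer than 50 spots are rejected. Like any local-window
   smoother, the fit is least constrained at the sparse ends of the
   intensity range; re-normalizing an already normalized array changes the
   interior by <0.01 but the extreme tails by up to a few hundredths.
5. **Presence filter.** Genes must carry values on strictly more than 50%
   of arrays (`min_fraction`); the boundary (exactly half) is excluded.

## Upregulation calling

Per gene and treatment, a two-sided two-sample Student's t-test
(equal-variance pooled by default; Welch via `equal_var=False`; a one-sample
test of treated ratios against zero via `one_sample=True` for
control-normalized designs) on the available replicates, requiring at least
two per group. No multiple-testing correction is applied: the workflow is
defined by raw p-value cutoffs, strict 0.001 and relaxed 0.01, and
*upregulated* additionally requires a positive mean log2 fold change.
`fold_change = 2^mean_log2fc` exactly, so adding a constant to both groups
leaves it unchanged. Genes whose groups are both constant get p = 1 when the
means agree (and a p underflowing to the smallest positive float when they
do not, so they sort first rather than dropping out). Top-k summaries rank
upregulated-tested genes by ascending p, ties by descending fold change,
then gene id — fully deterministic.

## Recruitment accounting

With strict-cutoff sets A, B (single ligands) and C (combination):
`n_overlap = |C ∩ (A ∪ B)|`, `n_unique_combo = |C \ (A ∪ B)|` (these
partition C), and the *recruited* genes are the unique-combo genes
upregulated in A **or** B at the relaxed cutoff. Nestedness of significance
sets in the cutoff guarantees recruits are disjoint from the strict sets;
the report asserts this on every run. Because the share of monostimulation
genes found in the combination set can be quoted against either |A ∪ B| or
|A| + |B|, the report carries both ratios. Percentages round to whole
percent.

## Synergy classification

The synergy ratio is `FC_combo / (FC_A + FC_B)` on linear fold changes over
the untreated control; a gene is synergistic when the ratio is at least
1.5, boundary inclusive (the packaged panel contains rows printed at
exactly 1.5). By default only genes in the strict-cutoff combination set
are scored — published synergy lists are drawn from that set — with
`eligible=None` widening to every tested gene.

Numerical choices: reported ratios are rounded half-up to one decimal in
two stages (first to 9 decimals, ties-to-even, then to 1 decimal, half-up)
so that fold changes parsed from decimal text behave like exact decimals —
4.2/(1.1+1.7) is stored as 1.4999999999999996 yet rounds to 1.5 — and the
threshold comparison tolerates 1e-9 for the same reason. The packaged
62-gene panel validates within ±0.1 of the published ratios; the residual
0.1 discrepancies (e.g. the IL-6 row, 14.7/5.8 = 2.534 → 2.5 vs printed
2.6) trace to the published fold-change inputs being rounded themselves.

## Network hub classification

Over a directed regulator → target edge list restricted to a gene universe
(typically the combination-upregulated set), a node's coverage is the
fraction of the *other* universe members it regulates — its out-neighbours
(`direct`, the default, matching how curated upstream-regulator networks
draw edges) or its directed reachable set (`reachable`, allowing cascades).
Self-loops never count and a node is excluded from its own denominator.
Classes: coverage > 30% → major; 10% ≤ coverage ≤ 30% → minor (exactly 30%
is not "more than 30%"); otherwise none. `set_coverage` reports the joint
coverage of a node set against the residual universe (universe minus the
set); with that denominator the joint coverage dominates each member's own
coverage, and grows with the set, only when the queried nodes do not
regulate one another — the typical situation for hub panels, and the one
the property tests exercise.

## The synthetic-data generator

The generator emulates a triplicate two-colour costimulation experiment
(control, weak ligand A, potent ligand B, combination) with known latent
truth, so recovery can be measured exactly.

**Truth.** Each gene is supra-additive with probability `frac_supra`
(default 2.5%), otherwise ligand-responsive with probabilities
`frac_regulated_a` (0.15%) and `frac_regulated_b` (1.1%). Log2 effect sizes
are normal (mean 2.0, sd 0.9 — linear fold changes mostly 2–15, covering
the 1.1–126 span of published panels only through the combination step).
Non-supra combination responses add on the linear scale
(`fc_combo = fc_a + fc_b − 1`, so a gene driven by one ligand keeps its
single-ligand fold change; a multiplicative `log_additive` rule is
available). Supra-additive genes set `fc_combo = s · (fc_a + fc_b)` with
`s ~ U[1.5, 5]`, guaranteeing the class invariant by construction, and are
themselves ligand-responsive with elevated conditional probabilities
(5% / 30%): in the emulated study most synergistic genes show a clear
response to the potent ligand alone. Each gene also receives a baseline
log2 reference abundance (normal, mean 9, sd 1.5): the reference channel is
the same material on every array, so a gene's reference intensity is a gene
property, not an independent per-array draw — without this, a gene can sit
near background on a single replicate and its ratio variance explodes.

**Arrays.** Per array: reference = 2^(baseline + jitter), sample =
reference · fold change · 2^noise (replicate noise sd 0.1 on the log2
scale, the low level typical of cell-line triplicates — and required for
genes with fold changes near 2 to clear p < 0.001 with n = 3, as in the
emulated study); the sample channel is then bent by a smooth
intensity-dependent dye bias (a slow sinusoid of A, amplitude 0.3, exposed
as `dye_bias_profile` so tests can subtract it analytically); both channels
receive an additive scanner background (80 units, the target of the
background-correction stage); 2% of spots are flagged and 2% are forced
below the 100-unit threshold in both channels. A single global seed drives
everything through documented substreams (stream 0: truth; stream 1+i:
array i), with a fixed draw order per stream so any individual quantity can
be re-derived independently.

**What the defaults represent.** They place the experiment in the regime of
the emulated study: strict-cutoff counts on the order of ~20 / ~150 / ~310
(weak ligand / potent ligand / combination), ~90% of monostimulation genes
contained in the combination set, and top-50 mean fold changes ordered
combination > potent ligand > weak ligand at roughly 3 / 8 / 18. Simulation
sizes in the tests (800–10,000 genes) were chosen as the smallest that make
the binomial noise on these quantities negligible.

**What is not emulated.** Probe-level or duplicate-spot structure, spatial
artifacts, gene–gene correlation, per-gene variance heterogeneity,
between-array scale differences, and cross-hybridization. Passing tests
therefore show that the chain recovers truth under idealized independent
log-normal noise with realistic nuisance structure (background, dye bias,
flags, dropouts) — not that it is robust to correlated or heavy-tailed
noise in real scans.

**Network generator.** Planted major hubs receive exactly
⌈coverage · N⌉ distinct out-edges (0.40 by default), minors 0.15, remaining
nodes sparse out-edges capped below the 10% minor threshold, so planted
classes are recoverable exactly.

## Known limitations

- The equal-variance t-test with n = 3 per group is fragile to per-gene
  variance heterogeneity, which the simulator does not generate; real-data
  use may prefer the Welch flag.
- Raw p-value cutoffs are part of the workflow's definition; at 10,000
  genes the strict cutoff still admits ~5 false positives per contrast,
  which bounds the achievable containment and synergy specificity.
- The lowess normalization is unconstrained at the extreme intensity tails;
  quantities that depend on single spots there inherit that uncertainty.
- Fold-change estimates for genes whose signal sits near the additive
  background are compressed or inflated by imperfect background estimates;
  such genes are mostly removed by the both-channels-below-100 filter.
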