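# Methods

## Problem and model

Antarctic notothenioid fishes carry large families of freezing-avoidance
genes — antifreeze glycoproteins (AFGP) and the ice-melt-promoting zona
pellucida subfamilies ZPAX1 and ZPC5. The working model is that these
families expanded in *waves* paced by Quaternary glacial cycles: each
glacial advance favors duplication, each retreat allows redundant copies
to degenerate. This package implements the computational side of that
analysis on synthetic data with the same statistical structure:

1. **Duplication dating.** Paralog ages are read from synonymous
   divergence. For a duplication of age `t` under a neutral clock with
   per-site per-year rate `mu`, the expected synonymous distance between
   the two copies is `dS = 2*mu*t`, hence `t = dS / (2*mu)`. The default
   `mu` is 4e-9 /site/yr (the value used for the wave dating); the
   divergence-derived 4.07e-9 is carried as a second named constant.
2. **Waves.** The per-duplication-node dS values of a family are smoothed
   with a Gaussian KDE; prominent modes are duplication waves, and the
   inter-peak spacing Δds converts to a wave period via the clock.
3. **Periodicity.** Wave evenness is summarized as `R = 1 − CV(spacings)`
   and compared against a burst-free null in which the same number of dS
   values is drawn from a gamma fit to the observed values.
4. **Copy number.** Family abundance per sample is read depth normalized
   to gene length and library size, divided by the mean normalized depth
   of single-copy controls (atraid, rgs20); populations are compared with
   the Kruskal–Wallis rank-sum test.
5. **Sweeps.** Composite-likelihood-ratio (CLR) selection scans are
   post-processed by top-1% thresholding, strict <1000 bp merging,
   three-way intersection (two within-species matchups plus an
   outgroup-polarized scan), and any-overlap gene assignment.

## Estimators and numerical choices

**NG86 distances.** dN and dS are computed by Nei–Gojobori (1986)
counting: per-codon synonymous site fractions `s = Σ_pos f_syn(pos)` with
mutations to stops excluded from both site and difference counts;
multi-hit codons resolved by averaging over all minimal mutational
pathways that avoid stops (with a fallback to all pathways when every
pathway is blocked); Jukes–Cantor correction `d = −3/4·ln(1 − 4p/3)`.
Proportions `p ≥ 3/4` are flagged saturated and the distance is reported
as missing, never as a number. Counting replaces maximum-likelihood
free-ratio branch estimates; in the low-divergence regime this pipeline
targets (dS ≈ 0.002–0.05) the two agree closely and counting is
dependency-free and exactly testable against enumeration oracles.

**Trees.** The family guide tree is neighbor-joining on the dS matrix.
Negative branch lengths are clamped to zero with the deficit moved to
the sibling branch. Missing (saturated) entries are imputed with the
matrix maximum so extreme pairs are placed far apart rather than
aborting. The tree is midpoint-rooted — a single family offers no
outgroup — and every internal node receives the mean pairwise dS over
all cross-child-clade leaf pairs (defined entries only), which under the
clock estimates `2*mu*t` for the node's duplication age.

**KDE and peaks.** Gaussian kernels on a ≥512-point uniform grid over
`[0, max + 3h]`, renormalized to unit trapezoid integral (kernels
truncated below dS = 0 would otherwise lose mass). `bandwidth="auto"` is
Silverman's rule `0.9·min(sd, IQR/1.34)·n^(−1/5)`. Peaks are local
maxima with topographic prominence at least 5% of the density maximum;
the global maximum counts its full height as prominence, so a positive
density always yields at least one peak; grid-boundary maxima are
eligible.

**Periodicity test.** `R = 1 − CV` of the inter-peak spacings, undefined
(reported as non-significant, p = 1) with fewer than three peaks. The
null refits a gamma distribution to the positive observed values
(floc = 0 for stability), resamples the same sample size, re-runs the
identical KDE + peak pipeline, and reports `p` as the fraction of null
replicates with `R` at least the observed. Null replicates with an
undefined `R` count as non-exceeding. The test's type-I error is checked
empirically (≤0.1 at nominal 0.05 over 100 gamma samples).

**Glacial overlay.** δ¹⁸O is linearly interpolated at each wave time
(the curve is densely sampled relative to wave spacing); enrichment at
glacial maxima is a permutation p-value against uniformly random
placements of the same number of ages within the curve range.

**Intervals.** All genomic coordinates are 0-based half-open internally;
GFF3 converts at the I/O boundary. CLR grid positions are 1-based
single-base test sites (SweepFinder2 convention). The top-quantile
threshold uses linear interpolation and includes ties (≥); an all-equal
track therefore degenerates to one chromosome-spanning region
(documented, tested). "Distant less than 1000 bp" is read strictly, with
distance `start₂ − end₁`. Gene membership is any-overlap (≥1 bp), with a
`contained` flag for the stricter reading. Merged-then-intersect order is
the default for the three-way comparison.

**Rate arithmetic.** Two conventions for a per-year rate from
interspecies divergence: `per_divergence_time` (`mu = dS/T`, the
arithmetic that reproduces the printed 4.07e-9 at T = 3.3 Myr) and
`per_total_branch` (`mu = dS/2T`, the standard clock relation). The
choice is surfaced in output metadata, never silently resolved.

## Synthetic data: what it emulates, and what it does not

**Burst families.** Codon sequences evolve as a per-lineage Poisson jump
process: proposals arrive per nucleotide site at rate `mu` (times
`max(1, ω)` for acceptance thinning), uniform among the three
alternative bases; synonymous changes are accepted at relative rate 1,
nonsynonymous at relative rate ω, stop-creating changes rejected. With
this parametrization the synonymous substitution rate per synonymous
site equals `mu` exactly, so a copy pair of age `t` has expected
`dS = 2*mu*t` (verified against replicate means). Duplication bursts add
`copies_per_burst` copies at each burst time, parents drawn without
replacement while the pool lasts. No indels are simulated, so families
are aligned by construction — deliberately bypassing alignment error,
which real data would add. Pseudogenization is an optional per-copy
per-year hazard (default 0) after which premature stops are accepted.

**Constant-rate null.** A Yule tree (dendropy pure-birth, rescaled to a
given root-to-tip depth in expected substitutions per site) with a
Muse–Gaut-style codon model: mutation targets drawn from
π = (0.2, 0.3, 0.4, 0.1) identically at all three codon positions,
ω = 2.0, stops rejected, root drawn from the stationary sense-codon
distribution (∝ products of π). Realized base composition matches π
within 2% and the NG86 dN/dS on long sequences is 2.0 ± 0.2 (both
tested). Duplication times on a Yule tree have no periodic structure,
which is the property the control needs.

**Copy-number counts.** Poisson reads with mean
`CN × gene length × library size × depth_scale`; single-copy controls
have CN 1. The estimator is unbiased within Poisson ratio error
(true CN 12 recovered at 12 ± 1 over 100 replicates).

**CLR tracks.** i.i.d. exponential background on a SweepFinder-style
grid with triangular sweep bumps; no linkage, recombination-map, or
background-selection structure.

**Glacial curve.** A two-regime sinusoid — 100-kyr cycles within the
last 1 Myr, 40-kyr cycles beyond (the stated "about 40 kyr / cycle"
reading), phase-continuous at the 1 Mya switch. It has the right
periods, not the real stack's amplitude modulation or asymmetric
sawtooth shape.

## The resolution limit of wave detection

The central caveat of the whole method, quantified here because the
tests expose it. At the glacial pacing, one wave interval is
`Δds = 2*mu*P ≈ 0.0021` (P = 2.6e5 yr). A gene of 650 codons has
S ≈ 490 synonymous sites, so one interval corresponds to
`Δds × S ≈ 1.0` synonymous substitutions, and the Poisson sampling noise
of a node's dS is `sqrt(j)` substitutions for the j-th wave —
*comparable to the spacing itself*. No density estimate can separate
clusters whose spread equals their separation. Independently, Silverman's
global bandwidth on a k-wave comb scales with the between-wave spread
(≈0.61×spacing for five equal waves at n = 40), which over-smooths a
five-wave structure even for noise-free values. Consequently:

* At the study's gene scale the pipeline typically reports 1–3 broad
  modes rather than five ZPAX1-like waves, and the recovered mean
  spacing is unstable. The analysis drivers and the acceptance script
  report these outcomes as computed.
* Waves are cleanly recovered once `Δds × S >> 1`: the bundled
  "resolvable" configuration (bursts every 2 Myr, 6000 codons, 16
  duplications per burst, so `Δds × S ≈ 73`) yields the full contrast —
  three peaks at the true multiples, periodicity p ≤ 0.005, while the
  constant-rate null gives p = 1. The periodicity acceptance test runs
  at this scale; the scale is a statistical-power requirement of the
  method, stated here as the package's own design choice.

Equivalently: passing tests at the resolvable scale show the pipeline is
correct; they do not show that 650-codon genes contain enough synonymous
information to resolve glacial-pacing waves — they demonstrably do not.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `mu_year` | 4e-9 | subs/site/yr | wave-dating clock rate |
| `MU_YEAR_DIVERGENCE` | 4.07e-9 | subs/site/yr | divergence-derived rate (demography) |
| `g` | 7 | years | generation time |
| ω (null) | 2.0 | — | dN/dS of the constant-rate control |
| π (null) | 0.2/0.3/0.4/0.1 | — | base frequencies A/C/G/T |
| KDE bandwidth | Silverman | dS | exposed; see resolution limit |
| peak prominence | 0.05 | fraction of max density | wave-calling threshold |
| `q` | 0.01 | — | CLR top-quantile |
| `gap` | 1000 | bp | strict sweep-merging distance |
| controls | atraid, rgs20 | — | single-copy depth denominators |
| `n_null` | 200 | replicates | periodicity null resamples |

## Known limitations

* NG86 counting underestimates distances under strong
  transition/transversion or codon-usage bias; neither is simulated.
* Neighbor-joining topologies are unreliable when pairwise distances
  carry ~1-substitution noise; node dS values inherit that instability.
* The gamma null of the periodicity test assumes a smooth unimodal age
  distribution; age distributions that are non-gamma but still
  burst-free could inflate significance.
* Per-sample library normalization is implemented (per-population
  pooling is a documented alternative reading of the normalization).
* The sweep stage consumes CLR tracks; it does not recompute CLR,
  recombination maps, or background selection.

Problem sizes used by the test suite and acceptance script (41–49
copies, 650–6000 codons, 200-replicate nulls) keep the full run within a
few minutes on one CPU while leaving every conclusion above unchanged at
larger sizes.
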