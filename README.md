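# glacierpace

Toolkit for studying **glacier-paced gene-family evolution** in Antarctic
notothenioid fishes: dating paralog duplication waves from synonymous
divergence, testing the periodicity of those waves against a
constant-rate null, overlaying wave times on a glacial δ¹⁸O proxy curve,
profiling relative copy number of antifreeze-related gene families from
mapped-read depth, and post-processing composite-likelihood-ratio (CLR)
selection scans into population-specific sweep regions and gene lists.

The scientific core is the molecular-clock reading of paralog ages: for
a duplication of age *t* under a neutral per-site per-year rate *μ*, the
synonymous distance between the copies satisfies E[dS] = 2*μt*, so

```
t = dS / (2 μ),        μ = 4×10⁻⁹ /site/yr (dating default)
```

A family's per-duplication-node dS values (Nei–Gojobori 1986 counting
with Jukes–Cantor correction, on a midpoint-rooted neighbor-joining
tree) are smoothed with a Gaussian KDE; prominent density modes are
duplication *waves*, and the inter-peak spacing Δds converts to the wave
period in years. Wave evenness R = 1 − CV(spacings) is tested against a
gamma-resampled burst-free null. All inputs (codon families with
implanted bursts, a Muse–Gaut ω = 2 null, Poisson read counts, CLR
tracks, a two-regime glacial curve) are generated by the seeded
`synthetic_data` module, so the entire analysis runs without downloads.

## Worked example

Date the duplications of a simulated family expanding in bursts every
2 Myr and test wave periodicity:

```python
from glacierpace import synthetic_data as synth, molevo, periodicity

cfg = synth.BurstSimConfig(seed=1, n_codons=6000, mu_year=4e-9, omega=0.0,
                           burst_times=(6e6, 4e6, 2e6), copies_per_burst=16)
records, history = synth.simulate_burst_family(cfg)
dup, tree, matrix = molevo.family_dup_ds(records)

est = periodicity.kde(dup, "auto")
peaks = periodicity.detect_peaks(est)
mean_sp, sd_sp = periodicity.spacing_stats(peaks)
R, p = periodicity.periodicity_test(dup, n_null=200, seed=1)
print(peaks.n_peaks, round(mean_sp, 5),
      [round(periodicity.ds_to_time(d, 4e-9) / 1e6, 2) for d in peaks.peak_ds],
      round(p, 3))
```

prints

```
3 0.01476 [2.09, 3.94, 5.78] 0.0
```

three detected waves at 2.09, 3.94 and 5.78 Myr (true burst ages 2, 4
and 6 Myr) whose mean dS spacing 0.01476 corresponds to a 1.8-Myr period
(true interval 2 Myr), with periodicity p ≈ 0 — while the same
pipeline on `simulate_null_family(...)` output (constant-rate codon
model, dN/dS = 2.0, base frequencies 0.2/0.3/0.4/0.1) detects no
significant periodicity (p = 1). At the real glacial pacing
(Δds ≈ 0.0021) a 650-codon gene carries only ~1 synonymous substitution
per wave interval, which is the method's resolution floor — see
`docs/methods.md` for the full analysis.

The numbered scripts under `analysis/` run the complete study on
synthetic inputs (`python analysis/01_simulate_inputs.py`, then 02–06),
writing tables under `results/`. A thin CLI mirrors the stages:
`glacierpace simulate family ...`, `glacierpace date-dups ...`,
`glacierpace periodicity ...`, `glacierpace cnv ...`,
`glacierpace sweeps ...`, `glacierpace rates ...`.

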