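#!/usr/bin/env python
"""Generate every synthetic input for the downstream analyses.

Produces, under results/synthetic/:
  * zpax1_like.fasta / zpc5_like.fasta — codon families duplicating in
    periodic bursts at the glacial pacing (2.6e5-yr and 6.6e5-yr wave
    periods, neutral rate 4e-9 per site per year) plus their true
    duplication histories (JSON)
  * resolvable.fasta — a burst family at a coarser pacing and longer
    sequence where the waves are well separated from substitution noise
    (used for the periodicity significance analysis)
  * null_family.fasta — constant-rate codon-model control (dN/dS = 2.0,
    base frequencies 0.2/0.3/0.4/0.1, Yule tree): no burst structure
  * glacial_curve.csv — two-regime d18O-like oscillation (100-kyr cycles
    in the last 1 Myr, 40-kyr cycles beyond)
  * cnv_counts.tsv (+ gene_lengths.tsv, library_sizes.tsv) — Poisson
    read counts for three antifreeze-related families over four
    populations against single-copy controls atraid and rgs20
  * clr_<pop>_{m1,m2,pol}.tsv — CLR selection-scan tracks with a sweep
    implanted at a population-specific locus
  * genes.bed — gene annotations overlapping the implanted sweeps
"""

import json
import sys
from pathlib import Path

import pandas as pd

from glacierpace import io_formats, synthetic_data as synth

SEED = 20260926
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    fams = {
        # study pacing: five waves every 2.6e5 yr (ZPAX1-like),
        # three waves every 6.6e5 yr (ZPC5-like)
        "zpax1_like": synth.BurstSimConfig(
            seed=SEED, n_codons=650, mu_year=4e-9, omega=0.0,
            burst_times=(1.3e6, 1.04e6, 7.8e5, 5.2e5, 2.6e5), copies_per_burst=8),
        "zpc5_like": synth.BurstSimConfig(
            seed=SEED + 1, n_codons=650, mu_year=4e-9, omega=0.0,
            burst_times=(1.98e6, 1.32e6, 6.6e5), copies_per_burst=12),
        # coarser pacing at longer sequences: waves far above the
        # single-substitution resolution floor
        "resolvable": synth.BurstSimConfig(
            seed=SEED + 2, n_codons=6000, mu_year=4e-9, omega=0.0,
            burst_times=(6e6, 4e6, 2e6), copies_per_burst=16),
    }
    for name, cfg in fams.items():
        records, history = synth.simulate_burst_family(cfg)
        io_formats.write_fasta(records, OUT / f"{name}.fasta")
        (OUT / f"{name}_history.json").write_text(json.dumps(
            {"events": [list(e) for e in history.events],
             "tip_ids": list(history.tip_ids)}, indent=1))
        print(f"{name}: {len(records)} copies, "
              f"{len(set(history.event_times))} burst ages")

    null_records = synth.simulate_null_family(seed=SEED + 3, n_tips=49,
                                              n_codons=6000, tree_depth=0.024)
    io_formats.write_fasta(null_records, OUT / "null_family.fasta")
    print(f"null_family: {len(null_records)} tips, constant-rate MG model")

    curve = synth.synthetic_glacial_curve()
    io_formats.write_glacial_curve(curve, OUT / "glacial_curve.csv", unit="ka")
    print(f"glacial_curve: {curve.age.size} points, 0-1.8 Myr")

    # CNV: copy ranges mirroring the profiled antifreeze-related families
    # (AFGP ~10-18, ZPAX1 ~33-36, ZPC5 ~40-45), AFGP elevated in ZD2
    pops = {"RS1": 13, "RS2": 12, "ZD1": 11, "ZD2": 17}
    samples = {f"{p}_{i}": p for p in pops for i in range(8)}
    true_cn = {}
    for p, afgp in pops.items():
        true_cn[(p, "afgp")] = float(afgp)
        true_cn[(p, "zpax1")] = 34.0
        true_cn[(p, "zpc5")] = 42.0
    design = synth.CnvDesign(
        samples=samples,
        true_cn=true_cn,
        gene_lengths={"afgp": 2500, "zpax1": 3000, "zpc5": 1400,
                      "atraid": 1200, "rgs20": 1100},
        library_sizes={s: 1e6 for s in samples},
    )
    table = synth.simulate_cnv_counts(SEED + 4, design)
    table.counts.to_csv(OUT / "cnv_counts.tsv", sep="\t", index=False)
    pd.DataFrame(table.gene_lengths.items(), columns=["gene", "length_bp"]).to_csv(
        OUT / "gene_lengths.tsv", sep="\t", index=False)
    pd.DataFrame(table.library_sizes.items(), columns=["sample", "total_reads"]).to_csv(
        OUT / "library_sizes.tsv", sep="\t", index=False)
    print(f"cnv_counts: {len(samples)} samples x {len(design.gene_lengths)} genes")

    # CLR tracks: SweepFinder-style grid every 2 kb over 10 Mb; each
    # population has its own sweep locus present in both matchups and the
    # polarized scan
    sweep_loci = {"RS1": 2_000_000, "RS2": 5_000_000, "ZD1": 8_000_000}
    kw = dict(n_positions=5000, step=2000, sweep_height=80.0, sweep_halfwidth=8000)
    from glacierpace import sweeps as sweeps_mod

    s = SEED + 10
    for pop, locus in sweep_loci.items():
        for tag in ("m1", "m2", "pol"):
            track = synth.simulate_clr_track(seed=s, sweep_centers=(locus,), **kw)
            sweeps_mod.write_clr_track(track, OUT / f"clr_{pop}_{tag}.tsv")
            s += 1
    genes = [io_formats.GeneAnnotation(f"sweepgene_{p}", "chr1", locus - 3000,
                                       locus + 3000)
             for p, locus in sweep_loci.items()]
    genes += [io_formats.GeneAnnotation(f"bystander_{k}", "chr1",
                                        k * 1_000_000 + 400_000,
                                        k * 1_000_000 + 410_000)
              for k in range(9)]
    with open(OUT / "genes.bed", "w") as fh:
        for g in sorted(genes, key=lambda g: g.start):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    print(f"clr tracks: {len(sweep_loci) * 3}; genes.bed: {len(genes)} genes")


if __name__ == "__main__":
    sys.exit(main())
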