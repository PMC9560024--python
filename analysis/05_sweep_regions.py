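#!/usr/bin/env python
"""Population-specific selective-sweep regions and genes from CLR tracks.

For each population: top-1% CLR sites in both within-species matchups
and the outgroup-polarized scan, strict <1000 bp merging, three-way
intersection, and any-overlap gene assignment.  Writes per-population
BED files and gene lists under results/sweeps/.
"""

import sys
from pathlib import Path

from glacierpace import io_formats, sweeps

ROOT = Path(__file__).resolve().parent.parent / "results"
POPULATIONS = ["RS1", "RS2", "ZD1"]


def main() -> None:
    out = ROOT / "sweeps"
    out.mkdir(parents=True, exist_ok=True)
    syn = ROOT / "synthetic"
    annotations = io_formats.read_annotations(syn / "genes.bed", "bed")
    for pop in POPULATIONS:
        tracks = [sweeps.read_clr_track(syn / f"clr_{pop}_{tag}.tsv")
                  for tag in ("m1", "m2", "pol")]
        genes, table = sweeps.population_sweep_genes(*tracks, annotations,
                                                     q=0.01, gap=1000)
        io_formats.write_bed(table["final"], out / f"{pop}_sweep_regions.bed")
        (out / f"{pop}_sweep_genes.txt").write_text(
            "".join(g + "\n" for g in genes))
        print(f"{pop}: {len(table['final'])} sweep regions, genes: {genes}")


if __name__ == "__main__":
    sys.exit(main())
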