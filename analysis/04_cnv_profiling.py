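#!/usr/bin/env python
"""Relative copy number of the antifreeze-related families per population.

Normalizes mapped-read counts to gene length and library size, divides
by the mean depth of the single-copy controls (atraid, rgs20), and
compares populations with the Kruskal-Wallis rank sum test.  Writes
results/cnv/relative_cn.tsv and a test-summary TSV.
"""

import sys
from pathlib import Path

import pandas as pd

from glacierpace import cnv

ROOT = Path(__file__).resolve().parent.parent / "results"
FAMILIES = {"AFGP": ["afgp"], "ZPAX1": ["zpax1"], "ZPC5": ["zpc5"]}


def main() -> None:
    out = ROOT / "cnv"
    out.mkdir(parents=True, exist_ok=True)
    syn = ROOT / "synthetic"
    counts = pd.read_csv(syn / "cnv_counts.tsv", sep="\t")
    lengths = pd.read_csv(syn / "gene_lengths.tsv", sep="\t") \
        .set_index("gene")["length_bp"].to_dict()
    libs = pd.read_csv(syn / "library_sizes.tsv", sep="\t") \
        .set_index("sample")["total_reads"].to_dict()
    table = cnv.ReadCountTable(counts, lengths, libs)

    rows, tests = [], []
    for fam, genes in FAMILIES.items():
        vals = cnv.relative_cn(table, genes, family_id=fam)
        rows += [(v.sample_id, v.population, v.family_id, v.value) for v in vals]
        df = pd.DataFrame([(v.population, v.value) for v in vals],
                          columns=["population", "value"])
        groups = [g["value"].tolist() for _, g in df.groupby("population")]
        h, p = cnv.kruskal_wallis(groups)
        tests.append((fam, h, p))
        means = df.groupby("population")["value"].mean().round(1).to_dict()
        print(f"{fam}: population means {means}; Kruskal-Wallis H={h:.2f} p={p:.3g}")

    pd.DataFrame(rows, columns=["sample", "population", "family", "relative_cn"]) \
        .to_csv(out / "relative_cn.tsv", sep="\t", index=False)
    pd.DataFrame(tests, columns=["family", "H", "p"]) \
        .to_csv(out / "kruskal_wallis.tsv", sep="\t", index=False)


if __name__ == "__main__":
    sys.exit(main())
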