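"""Relative copy number of gene families from mapped-read depth.

Per-gene mapped-read counts are normalized to gene length and library
size (reads per kb per billion mapped reads); a family's relative copy
number in a sample is the sum of its members' normalized depths divided
by the mean normalized depth of single-copy control genes (atraid and
rgs20 in the study this emulates).  Populations are compared with the
Kruskal–Wallis rank sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("glacierpace")

DEFAULT_CONTROLS = ("atraid", "rgs20")

#: cosmetic scale of normalized depth: reads per kb per billion mapped
NORM_SCALE = 1.0e9


@dataclass(frozen=True)
class ReadCountTable:
    """Per-sample per-gene mapped-read counts with gene lengths and
    per-sample library sizes."""

    counts: pd.DataFrame  # columns: sample, population, gene, mapped_reads
    gene_lengths: dict[str, int]
    library_sizes: dict[str, float]

    def __post_init__(self) -> None:
        required = {"sample", "population", "gene", "mapped_reads"}
        missing = required - set(self.counts.columns)
        if missing:
            raise ValueError(f"count table missing columns {sorted(missing)}")
        if (self.counts["mapped_reads"] < 0).any():
            raise ValueError("mapped_reads must be >= 0")
        for gene in self.counts["gene"].unique():
            if self.gene_lengths.get(gene, 0) <= 0:
                raise ValueError(f"unknown or zero-length gene {gene!r}")
        for sample in self.counts["sample"].unique():
            if self.library_sizes.get(sample, 0) <= 0:
                raise ValueError(f"unknown or zero library size for sample {sample!r}")


@dataclass(frozen=True)
class RelativeCN:
    sample_id: str
    population: str
    family_id: str
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("relative copy number must be >= 0")


def normalize_abundance(table: ReadCountTable) -> pd.DataFrame:
    """Normalized depth per (sample, gene): reads / (length * library) * 1e9."""
    df = table.counts.copy()
    lengths = df["gene"].map(table.gene_lengths)
    libs = df["sample"].map(table.library_sizes)
    df["normalized"] = df["mapped_reads"] / (lengths * libs) * NORM_SCALE
    return df


def relative_cn(
    table: ReadCountTable,
    target_family: list[str],
    family_id: str = "family",
    controls: tuple[str, ...] = DEFAULT_CONTROLS,
    control_mean: str = "arithmetic",
) -> list[RelativeCN]:
    """Family relative copy number per sample.

    value(sample) = sum of the family members' normalized depths divided
    by the mean normalized depth of the controls, so the value estimates
    the total copy count of the family.  Samples whose control depth is 0
    are excluded with a warning.
    """
    if control_mean not in {"arithmetic", "geometric"}:
        raise ValueError(f"unknown control_mean {control_mean!r}")
    df = normalize_abundance(table)
    present = set(df["gene"].unique())
    for c in controls:
        if c not in present:
            raise ValueError(f"control gene {c!r} absent from count table")
    out: list[RelativeCN] = []
    for (sample, pop), grp in df.groupby(["sample", "population"], sort=True):
        depth = grp.set_index("gene")["normalized"]
        ctrl_depths = np.array([depth.get(c, np.nan) for c in controls], float)
        if np.isnan(ctrl_depths).any():
            raise ValueError(f"control gene missing for sample {sample!r}")
        if control_mean == "arithmetic":
            ctrl = float(ctrl_depths.mean())
        else:
            ctrl = float(np.exp(np.log(np.clip(ctrl_depths, 1e-300, None)).mean()))
        if ctrl <= 0:
            logger.warning("relative_cn: control depth 0 for sample %s; excluded", sample)
            continue
        fam = float(sum(depth.get(g, 0.0) for g in target_family))
        out.append(RelativeCN(str(sample), str(pop), family_id, fam / ctrl))
    return out


def per_gene_cn(
    table: ReadCountTable,
    genes: list[str],
    controls: tuple[str, ...] = DEFAULT_CONTROLS,
) -> pd.DataFrame:
    """Per-gene relative copy number (each gene as its own family)."""
    frames = []
    for g in genes:
        vals = relative_cn(table, [g], family_id=g, controls=controls)
        frames.append(pd.DataFrame(
            [(v.sample_id, v.population, v.family_id, v.value) for v in vals],
            columns=["sample", "population", "gene", "relative_cn"],
        ))
    return pd.concat(frames, ignore_index=True)


def kruskal_wallis(groups: list[list[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H with the standard tie correction and chi-square p.

    All observations identical is a degenerate case: H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    total_n = sum(len(g) for g in groups)
    if total_n < 5:
        raise ValueError("need at least 5 observations in total")
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
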