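"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based half-open internally; conversions from
1-based formats (GFF3) happen here and only here.  Glacial-curve ages are
stored in years before present regardless of the input unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("glacierpace")

_SEQ_ALPHABET = set("ACGTN-")


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence (alphabet A, C, G, T, N, -)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - _SEQ_ALPHABET
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class GlacialCurve:
    """A glacial proxy curve: benthic d18O against age in years before present.

    High d18O marks large ice volume (cold, glacial periods).  Ages are
    strictly increasing toward the past.
    """

    age: np.ndarray
    d18o: np.ndarray

    def __post_init__(self) -> None:
        age = np.asarray(self.age, dtype=float)
        d18o = np.asarray(self.d18o, dtype=float)
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "d18o", d18o)
        if age.shape != d18o.shape or age.ndim != 1:
            raise ValueError("age and d18o must be equal-length 1-D arrays")
        if age.size < 2:
            raise ValueError("glacial curve needs at least 2 points")
        if not np.all(np.diff(age) > 0):
            raise ValueError("ages not increasing")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval for {self.gene_id!r}: [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased, whitespace stripped).

    Raises on duplicate ids and on empty files.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_glacial_curve(path: str | Path, unit: str = "ka") -> GlacialCurve:
    """Read a two-column CSV (age, d18O) into a GlacialCurve in years BP.

    ``unit`` declares the age unit of the file: ``"ka"`` (thousand years,
    the LR04 convention) or ``"years"``.  A header row is detected and
    skipped if its first field is non-numeric.
    """
    if unit not in {"ka", "years"}:
        raise ValueError(f"unknown age unit {unit!r}")
    df = pd.read_csv(path, header=None, comment="#")
    first = df.iloc[0, 0]
    try:
        float(first)
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if df.shape[0] < 2:
        raise ValueError("glacial curve needs at least 2 rows")
    age = df.iloc[:, 0].astype(float).to_numpy()
    d18o = df.iloc[:, 1].astype(float).to_numpy()
    if unit == "ka":
        age = age * 1.0e3
    return GlacialCurve(age=age, d18o=d18o)


def write_glacial_curve(curve: GlacialCurve, path: str | Path, unit: str = "years") -> None:
    age = curve.age / 1e3 if unit == "ka" else curve.age
    pd.DataFrame({"age": age, "d18O": curve.d18o}).to_csv(path, index=False, header=False)


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, _, v = part.partition("=")
            out[k.strip()] = v.strip()
    return out


def read_annotations(path: str | Path, format: str = "bed") -> list[GeneAnnotation]:
    """Read gene annotations from BED (0-based half-open) or GFF3 (1-based closed).

    GFF3 coordinates are converted to the internal 0-based half-open
    convention (start-1, end).  Gene ids come from BED column 4 or the
    GFF3 ``ID``/``gene_id`` attribute; missing ids are autogenerated as
    ``gene_<n>`` with a warning.
    """
    if format not in {"bed", "gff3"}:
        raise ValueError(f"unknown annotation format {format!r}")
    annotations: list[GeneAnnotation] = []
    n_auto = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if format == "bed":
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                gene_id = fields[3] if len(fields) > 3 and fields[3] else ""
                strand = fields[5] if len(fields) > 5 else "."
            else:
                if len(fields) < 9:
                    raise ValueError(f"malformed GFF3 line: {line!r}")
                chrom = fields[0]
                start, end = int(fields[3]) - 1, int(fields[4])
                strand = fields[6] if fields[6] in {"+", "-"} else "."
                attrs = _parse_gff3_attributes(fields[8])
                gene_id = attrs.get("ID") or attrs.get("gene_id") or ""
            if not gene_id:
                n_auto += 1
                gene_id = f"gene_{n_auto}"
                logger.warning("annotation without id at %s:%d-%d; using %s",
                               chrom, start, end, gene_id)
            annotations.append(GeneAnnotation(gene_id, chrom, start, end, strand))
    return annotations


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def load_config(path: str | Path) -> dict:
    """Load a plain YAML key-value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def setup_logging(quiet: bool = False) -> None:
    """Route structured log lines to standard error."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.ERROR if quiet else logging.INFO)
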