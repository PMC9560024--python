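"""Codon-level evolutionary distances and per-duplication-node dS extraction.

dN and dS are estimated by the Nei–Gojobori (1986) counting method:
per-codon synonymous/nonsynonymous site fractions, minimal mutational
pathways averaged for multi-hit codons (pathways through stop codons
excluded), and the Jukes–Cantor multiple-hit correction
d = -3/4 * ln(1 - 4p/3).  Counting is accurate in the low-divergence
regime this pipeline targets (dS ~ 0.002-0.03) and is used here in place
of maximum-likelihood branch estimates.

A family's duplication nodes are obtained from a neighbor-joining tree of
the pairwise dS matrix, midpoint-rooted (a single family has no
outgroup); each internal node is assigned the mean pairwise dS across its
child clades, which under a molecular clock estimates 2*mu*t for a
duplication of age t.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import dendropy
import numpy as np

from .io_formats import SequenceRecord

logger = logging.getLogger("glacierpace")

_BASES = "ACGT"

# standard genetic code, DNA codons; '*' marks stops
GENETIC_CODE: dict[str, str] = {}
_aa = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(itertools.product("TCAG", repeat=3)):
    GENETIC_CODE[_b1 + _b2 + _b3] = _aa[_i]

STOP_CODONS = frozenset(c for c, a in GENETIC_CODE.items() if a == "*")
SENSE_CODONS = tuple(sorted(c for c, a in GENETIC_CODE.items() if a != "*"))


def is_sense_codon(codon: str) -> bool:
    return codon in GENETIC_CODE and GENETIC_CODE[codon] != "*"


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) of a sense codon.

    Each position contributes 1/3 per single-nucleotide neighbor that is a
    synonymous (to s) or nonsynonymous (to n) sense codon; mutations to
    stop codons count toward neither, so s + n <= 3.
    """
    if not is_sense_codon(codon):
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    s = n = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1:]
            nb_aa = GENETIC_CODE[nb]
            if nb_aa == "*":
                continue
            if nb_aa == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return s, n


@lru_cache(maxsize=None)
def codon_path_differences(a: str, b: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts (sd, nd) between two
    sense codons, averaged over all minimal mutational pathways.

    Pathways passing through a stop codon are discarded; if every pathway
    is blocked by stops (possible only for 2-3 hit codon pairs), all
    pathways are used as a fallback so the pair still contributes.
    """
    if not (is_sense_codon(a) and is_sense_codon(b)):
        raise ValueError(f"not sense codons: {a!r}, {b!r}")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = a
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                return None
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    orders = list(itertools.permutations(diff_pos))
    valid = [r for r in (walk(o) for o in orders) if r is not None]
    if not valid:
        # fall back to stop-traversing paths rather than dropping the codon
        def walk_any(order: tuple[int, ...]) -> tuple[float, float]:
            cur = a
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1:]
                same = GENETIC_CODE[nxt] == GENETIC_CODE[cur] and GENETIC_CODE[nxt] != "*"
                if same:
                    sd += 1.0
                else:
                    nd += 1.0
                cur = nxt
            return sd, nd

        valid = [walk_any(o) for o in orders]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class PairwiseRates:
    """NG86 pairwise estimates between two in-frame codon sequences.

    dN/dS are substitutions per nonsynonymous/synonymous site after the
    Jukes–Cantor correction; they are None when the corresponding
    uncorrected proportion is saturated (p >= 3/4).
    """

    dn: float | None
    ds: float | None
    pn: float
    ps: float
    n_sites: float
    s_sites: float
    n_codons_used: int
    saturated_s: bool = False
    saturated_n: bool = False


def _usable_codon(codon: str) -> bool:
    return len(codon) == 3 and is_sense_codon(codon)


def ng86_pairwise(a: str, b: str) -> PairwiseRates:
    """Nei–Gojobori (1986) dN and dS between two aligned codon sequences.

    Codons containing gaps, ambiguous bases, or stops in either sequence
    are skipped pairwise.  Site counts are averaged over the two
    sequences; multi-hit codons are resolved by minimal-pathway averaging.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be equal length")
    if len(a) % 3:
        raise ValueError("sequence length not a multiple of 3")
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    used = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if not (_usable_codon(ca) and _usable_codon(cb)):
            continue
        used += 1
        sa, na = codon_site_counts(ca)
        sb, nb = codon_site_counts(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        d_s, d_n = codon_path_differences(ca, cb)
        sd += d_s
        nd += d_n
    if used == 0:
        raise ValueError("no comparable codons between the two sequences")
    s_sites = 0.5 * (s_a + s_b)
    n_sites = 0.5 * (n_a + n_b)
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    return PairwiseRates(
        dn=dn, ds=ds, pn=pn, ps=ps,
        n_sites=n_sites, s_sites=s_sites, n_codons_used=used,
        saturated_s=ds is None, saturated_n=dn is None,
    )


@dataclass(frozen=True)
class CodonAlignment:
    """An aligned in-frame codon family (equal lengths, multiple of 3)."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        recs = tuple(self.records)
        object.__setattr__(self, "records", recs)
        if len(recs) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        lengths = {len(r.seq) for r in recs}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        (length,) = lengths
        if length % 3:
            raise ValueError("alignment length must be a multiple of 3")
        ids = [r.id for r in recs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_codons(self) -> int:
        return len(self.records[0].seq) // 3


def ds_matrix(aln: CodonAlignment) -> np.ndarray:
    """Symmetric matrix of pairwise dS; saturated entries are NaN."""
    n = len(aln.records)
    mat = np.zeros((n, n))
    n_missing = 0
    for i in range(n):
        for j in range(i + 1, n):
            rates = ng86_pairwise(aln.records[i].seq, aln.records[j].seq)
            if rates.ds is None:
                mat[i, j] = mat[j, i] = np.nan
                n_missing += 1
            else:
                mat[i, j] = mat[j, i] = rates.ds
    if n_missing:
        logger.info("ds_matrix: %d saturated pairs recorded as missing", n_missing)
    return mat


def nj_tree(matrix: np.ndarray, ids: list[str]) -> str:
    """Neighbor-joining tree (newick, unrooted) from a distance matrix.

    Negative branch lengths are clamped to 0 with the deficit moved to the
    sibling branch.  Missing (NaN) entries are imputed with the matrix
    maximum so that saturated pairs are placed far apart rather than
    aborting the join.
    """
    d = np.array(matrix, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(ids):
        raise ValueError("matrix/ids shape mismatch")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if np.isnan(d).any():
        fill = np.nanmax(d)
        d = np.where(np.isnan(d), fill, d)
        logger.info("nj_tree: imputed missing distances with matrix max %.4g", fill)
    nodes = [f"{_quote(t)}" for t in ids]
    if n == 2:
        return f"({nodes[0]}:{d[0, 1] / 2:.10g},{nodes[1]}:{d[0, 1] / 2:.10g});"
    active = list(range(n))
    d = d.copy()
    labels = dict(enumerate(nodes))
    next_idx = n
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}

    def get(i: int, j: int) -> float:
        return 0.0 if i == j else dist[frozenset((i, j))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active) for i in active}
        best, best_q = None, math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * get(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = get(i, j) - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = next_idx
        next_idx += 1
        labels[new] = f"({labels[i]}:{li:.10g},{labels[j]}:{lj:.10g})"
        for k in active:
            if k in (i, j):
                continue
            dist[frozenset((new, k))] = 0.5 * (get(i, k) + get(j, k) - get(i, j))
        active.remove(i)
        active.remove(j)
        active.append(new)
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (get(i, j) + get(i, k) - get(j, k))
        lj = 0.5 * (get(i, j) + get(j, k) - get(i, k))
        lk = 0.5 * (get(i, k) + get(j, k) - get(i, j))
        li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
        return f"({labels[i]}:{li:.10g},{labels[j]}:{lj:.10g},{labels[k]}:{lk:.10g});"
    i, j = active
    lij = get(i, j)
    return f"({labels[i]}:{lij / 2:.10g},{labels[j]}:{lij / 2:.10g});"


def _quote(taxon: str) -> str:
    if any(c in taxon for c in " ()[]:;,'"):
        return "'" + taxon.replace("'", "''") + "'"
    return taxon


@dataclass(frozen=True)
class DupDsSet:
    """Per-duplication-node dS values of one gene family."""

    values: tuple[float, ...]
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.node_ids):
            raise ValueError("values/node_ids length mismatch")
        if any(v < 0 for v in self.values):
            raise ValueError("dS values must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def duplication_node_ds(tree_newick: str, matrix: np.ndarray, ids: list[str]) -> DupDsSet:
    """dS value per internal node of the midpoint-rooted family tree.

    Each internal node receives the mean of pairwise dS over all leaf
    pairs drawn from two different child clades (defined entries only);
    nodes with no defined cross-clade pair are dropped with a logged
    count.  Under a clock this statistic estimates 2*mu*t for a
    duplication at age t.
    """
    tree = dendropy.Tree.get(data=tree_newick, schema="newick",
                             preserve_underscores=True)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    idx = {t: i for i, t in enumerate(ids)}
    missing = [t for t in leaves if t not in idx]
    if missing:
        raise ValueError(f"tree leaves not in matrix ids: {missing}")
    if len(leaves) == 2:
        # midpoint rooting is degenerate: the lone split is the one node
        v = matrix[idx[leaves[0]], idx[leaves[1]]]
        if np.isnan(v):
            return DupDsSet(values=(), node_ids=())
        return DupDsSet(values=(float(v),), node_ids=("node_1",))
    tree.reroot_at_midpoint(update_bipartitions=True)
    values: list[float] = []
    node_ids: list[str] = []
    n_dropped = 0
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        child_leaf_sets = [
            [idx[lf.taxon.label] for lf in child.leaf_iter()]
            for child in node.child_nodes()
        ]
        if len(child_leaf_sets) < 2:
            continue
        pair_vals: list[float] = []
        for a_set, b_set in itertools.combinations(child_leaf_sets, 2):
            for ia in a_set:
                for ib in b_set:
                    v = matrix[ia, ib]
                    if not np.isnan(v):
                        pair_vals.append(float(v))
        counter += 1
        if not pair_vals:
            n_dropped += 1
            continue
        values.append(float(np.mean(pair_vals)))
        node_ids.append(f"node_{counter}")
    if n_dropped:
        logger.info("duplication_node_ds: dropped %d nodes with no defined cross pair",
                    n_dropped)
    return DupDsSet(values=tuple(values), node_ids=tuple(node_ids))


def family_dup_ds(records: list[SequenceRecord]) -> tuple[DupDsSet, str, np.ndarray]:
    """Full dating pipeline for one family: dS matrix -> NJ tree -> node dS.

    Returns the per-node dS set, the newick tree, and the dS matrix.
    """
    aln = CodonAlignment(records=tuple(records))
    mat = ds_matrix(aln)
    tree = nj_tree(mat, aln.ids)
    return duplication_node_ds(tree, mat, aln.ids), tree, mat
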