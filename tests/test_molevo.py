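import itertools

import dendropy
import numpy as np
import pytest
from Bio.Seq import Seq

from glacierpace import molevo
from glacierpace.io_formats import SequenceRecord
from glacierpace.molevo import (
    CodonAlignment,
    codon_path_differences,
    codon_site_counts,
    ds_matrix,
    duplication_node_ds,
    ng86_pairwise,
    nj_tree,
)


def oracle_site_counts(codon):
    """Independent enumeration of the 9 single-nucleotide neighbors,
    classifying with Biopython's translation table."""
    aa = str(Seq(codon).translate())
    s = n = 0.0
    for pos, alt in itertools.product(range(3), "ACGT"):
        if alt == codon[pos]:
            continue
        nb = codon[:pos] + alt + codon[pos + 1:]
        nb_aa = str(Seq(nb).translate())
        if nb_aa == "*":
            continue
        s += (nb_aa == aa) / 3
        n += (nb_aa != aa) / 3
    return s, n


class TestSiteCounts:
    @pytest.mark.parametrize("codon,expected", [
        ("GCT", (1.0, 2.0)),        # fourfold Ala
        ("TTT", (1 / 3, 8 / 3)),    # twofold Phe
        ("TGG", (0.0, 7 / 3)),      # Trp: synonymous-position neighbors are stops
    ])
    def test_hand_enumerated_codons(self, codon, expected):
        s, n = codon_site_counts(codon)
        assert s == pytest.approx(expected[0])
        assert n == pytest.approx(expected[1])

    def test_matches_enumeration_oracle_for_all_sense_codons(self):
        for codon in molevo.SENSE_CODONS:
            s, n = codon_site_counts(codon)
            es, en = oracle_site_counts(codon)
            assert s == pytest.approx(es), codon
            assert n == pytest.approx(en), codon

    def test_sites_total_three_minus_stop_share(self):
        for codon in molevo.SENSE_CODONS:
            s, n = codon_site_counts(codon)
            stop_share = sum(
                str(Seq(codon[:p] + b + codon[p + 1:]).translate()) == "*"
                for p, b in itertools.product(range(3), "ACGT")
                if b != codon[p]
            ) / 3
            assert s + n == pytest.approx(3.0 - stop_share)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_site_counts("TAA")


def oracle_path_differences(a, b):
    """Brute-force pathway averaging, independent permutation walk."""
    diff = [i for i in range(3) if a[i] != b[i]]
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            ta, tb = str(Seq(cur).translate()), str(Seq(nxt).translate())
            if tb == "*":
                ok = False
                break
            sd += ta == tb
            nd += ta != tb
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    return (np.mean([r[0] for r in results]), np.mean([r[1] for r in results]))


class TestNG86:
    def test_identical_sequences(self):
        r = ng86_pairwise("ATGGCT", "ATGGCT")
        assert r.ds == 0 and r.dn == 0

    def test_hand_computed_single_synonymous_change(self):
        # 10 Ala codons, one synonymous third-position difference
        a, b = "GCT" * 10, "GCT" * 9 + "GCC"
        r = ng86_pairwise(a, b)
        assert r.s_sites == pytest.approx(10.0)
        assert r.ps == pytest.approx(0.1)
        assert r.ds == pytest.approx(-0.75 * np.log(1 - 0.4 / 3))
        assert r.ds == pytest.approx(0.10732, abs=1e-5)
        assert r.dn == 0

    def test_saturation_flagged_not_numeric(self):
        # AAA vs AAG: one synonymous difference over S = 1/3 -> pS = 3
        r = ng86_pairwise("AAA", "AAG")
        assert r.ps == pytest.approx(3.0)
        assert r.saturated_s and r.ds is None

    def test_multi_hit_pathway_averaging_matches_oracle(self):
        rng = np.random.default_rng(0)
        sense = molevo.SENSE_CODONS
        for _ in range(300):
            a, b = rng.choice(len(sense), 2)
            a, b = sense[a], sense[b]
            expected = oracle_path_differences(a, b)
            got = codon_path_differences(a, b)
            if expected is not None:
                assert got[0] == pytest.approx(expected[0]), (a, b)
                assert got[1] == pytest.approx(expected[1]), (a, b)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        sense = molevo.SENSE_CODONS
        for _ in range(20):
            seq1 = "".join(rng.choice(sense, 30))
            seq2 = "".join(rng.choice(sense, 30))
            r1, r2 = ng86_pairwise(seq1, seq2), ng86_pairwise(seq2, seq1)
            assert r1.ps == pytest.approx(r2.ps)
            assert r1.pn == pytest.approx(r2.pn)

    def test_ds_monotone_in_synonymous_differences(self):
        base = "GCT" * 40
        prev = -1.0
        for k in range(0, 8):
            other = "GCC" * k + "GCT" * (40 - k)
            ds = ng86_pairwise(base, other).ds
            assert ds > prev
            prev = ds

    def test_gap_and_stop_codons_skipped_pairwise(self):
        # second codon has a gap in a, third is a stop in b: both skipped
        a = "GCTGC-AAAGGG"
        b = "GCTGCCTAAGGG"
        r = ng86_pairwise(a, b)
        assert r.n_codons_used == 2
        assert r.ds == 0 and r.dn == 0


class TestDsMatrix:
    def test_identical_pair_and_symmetry(self):
        aln = CodonAlignment(records=(
            SequenceRecord("a", "GCTGCT"), SequenceRecord("b", "GCTGCT"),
            SequenceRecord("c", "GCCGCT"),
        ))
        m = ds_matrix(aln)
        assert np.all(np.diag(m) == 0)
        assert np.array_equal(m, m.T)
        assert m[0, 1] == 0

    def test_two_copy_family_recovers_2mut(self, two_copy_family):
        records, history = two_copy_family
        aln = CodonAlignment(records=tuple(records))
        m = ds_matrix(aln)
        t = history.events[0][0]
        # one realization: within 4 Poisson sd of 2*mu*t
        expect = 2 * 4e-9 * t
        s_sites = ng86_pairwise(records[0].seq, records[1].seq).s_sites
        sd = np.sqrt(expect * s_sites) / s_sites
        assert abs(m[0, 1] - expect) < 4 * sd


class TestNJ:
    def test_three_taxa_topology_and_lengths(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        nwk = nj_tree(d, ["a", "b", "c"])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["a"], taxa["b"]) == pytest.approx(3.0)
        assert pdm.distance(taxa["a"], taxa["c"]) == pytest.approx(4.0)
        assert pdm.distance(taxa["b"], taxa["c"]) == pytest.approx(5.0)

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) -> additive distances
        ids = ["A", "B", "C", "D"]
        d = np.array([
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ], dtype=float)
        nwk = nj_tree(d, ids)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, j in itertools.combinations(range(4), 2):
            assert pdm.distance(taxa[ids[i]], taxa[ids[j]]) == pytest.approx(d[i, j])

    def test_matches_scikit_bio_topology_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        ids = ["A", "B", "C", "D", "E"]
        # caterpillar tree distances (additive)
        d = np.array([
            [0, 2, 6, 8, 9],
            [2, 0, 6, 8, 9],
            [6, 6, 0, 6, 7],
            [8, 8, 6, 0, 5],
            [9, 9, 7, 5, 0],
        ], dtype=float)
        ours = dendropy.Tree.get(data=nj_tree(d, ids), schema="newick")
        theirs = dendropy.Tree.get(
            data=str(skbio.tree.nj(skbio.DistanceMatrix(d, ids))), schema="newick",
            taxon_namespace=ours.taxon_namespace)
        ours.encode_bipartitions()
        theirs.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(ours, theirs) == 0

    def test_ultrametric_cherries_recovered(self):
        ids = ["a", "b", "c", "d"]
        d = np.array([
            [0, 0.001, 0.005, 0.005],
            [0.001, 0, 0.005, 0.005],
            [0.005, 0.005, 0, 0.001],
            [0.005, 0.005, 0.001, 0],
        ])
        tree = dendropy.Tree.get(data=nj_tree(d, ids), schema="newick")
        # in the unrooted quartet exactly one cherry is an explicit clade;
        # either cherry certifies the ab|cd split
        sisters = set()
        for node in tree.preorder_node_iter():
            leaves = [lf.taxon.label for lf in node.leaf_iter()]
            if len(leaves) == 2:
                sisters.add(frozenset(leaves))
        assert sisters & {frozenset({"a", "b"}), frozenset({"c", "d"})}
        assert not sisters - {frozenset({"a", "b"}), frozenset({"c", "d"})}

    def test_no_negative_branch_lengths_on_noisy_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 6
            d = rng.uniform(0.001, 0.02, (n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            tree = dendropy.Tree.get(data=nj_tree(d, [f"t{i}" for i in range(n)]),
                                     schema="newick")
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    assert edge.length >= 0


class TestDuplicationNodeDs:
    def test_two_leaf_family_single_value(self):
        d = np.array([[0.0, 0.004], [0.004, 0.0]])
        nwk = nj_tree(d, ["a", "b"])
        dup = duplication_node_ds(nwk, d, ["a", "b"])
        assert len(dup.values) == 1
        assert dup.values[0] == pytest.approx(0.004)

    def test_two_cherries_hand_computed(self):
        ids = ["a", "b", "c", "d"]
        d = np.full((4, 4), 0.005)
        np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = 0.001
        d[2, 3] = d[3, 2] = 0.001
        nwk = nj_tree(d, ids)
        dup = duplication_node_ds(nwk, d, ids)
        assert sorted(np.round(dup.values, 6)) == [0.001, 0.001, 0.005]

    def test_burst_family_nodes_cluster_near_burst_ages(self, resolvable_burst_ds):
        values = resolvable_burst_ds.as_array()
        expected = np.array([2 * 4e-9 * t for t in (2e6, 4e6, 6e6)])
        # every node should sit within half an inter-wave spacing of a wave
        dist = np.min(np.abs(values[:, None] - expected[None, :]), axis=1)
        assert np.median(dist) < 0.004
        # and each wave should attract a sizable share of the nodes
        nearest = np.argmin(np.abs(values[:, None] - expected[None, :]), axis=1)
        assert all((nearest == k).sum() >= 5 for k in range(3))

    def test_leaf_mismatch_raises(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError):
            duplication_node_ds("(x:1,y:1);", d, ["a", "b"])
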