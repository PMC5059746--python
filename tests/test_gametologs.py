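"""Alignment cleaning, divergence models, ORF scanning, NJ trees and the
chromosome-clustering test."""

import numpy as np
import pytest

from strataviper import pipeline, simzw
from strataviper import gametologs as gm
from strataviper.errors import InputError, SaturationError


class TestCleanAlignment:
    def test_gapless_unchanged(self):
        seqs = ["ACGTACGT", "ACGAACGT"]
        assert gm.clean_alignment(seqs) == seqs

    def test_columns_removed_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        chars = np.array(list("ACGT-N"))
        aln = ["".join(rng.choice(chars, 200)) for _ in range(3)]
        cleaned = gm.clean_alignment(aln)
        keep = [i for i in range(200)
                if all(s[i] in "ACGT" for s in aln)]
        assert cleaned == ["".join(s[i] for i in keep) for s in aln]

    def test_length_filter_after_cleaning(self):
        # 400 bp with 150 gapped columns -> 250 bp <= 300: rejected
        a = "A" * 250 + "-" * 150
        b = "A" * 400
        cleaned = gm.clean_alignment([a, b])
        assert len(cleaned[0]) == 250
        assert not gm.passes_length_filter(cleaned)
        assert gm.passes_length_filter(["A" * 301, "C" * 301])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InputError):
            gm.clean_alignment(["ACGT", "ACG"])


class TestDivergence:
    def test_identical(self):
        assert gm.pairwise_divergence("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_p_distance(self):
        a = "A" * 100
        b = "A" * 95 + "C" * 5
        assert gm.pairwise_divergence(a, b) == pytest.approx(0.05)

    def test_k2p_at_least_p(self):
        rng = np.random.default_rng(1)
        bases = "ACGT"
        for _ in range(20):
            a = "".join(rng.choice(list(bases), 500))
            b = "".join(
                c if rng.random() > 0.15 else rng.choice(list(bases))
                for c in a
            )
            p = gm.pairwise_divergence(a, b, "p")
            k = gm.pairwise_divergence(a, b, "k2p")
            assert k >= p - 1e-12

    def test_k2p_saturation_flagged(self):
        # transversion-saturated pair: Q = 1
        with pytest.raises(SaturationError):
            gm.pairwise_divergence("A" * 50, "C" * 50, "k2p")


class TestScanOrf:
    def _orf(self, n_codons=20):
        rng = np.random.default_rng(42)
        inner = []
        while len(inner) < n_codons - 2:
            c = "".join(rng.choice(list("ACGT"), 3))
            if c not in ("TAA", "TAG", "TGA"):
                inner.append(c)
        return "ATG" + "".join(inner) + "TAA"

    def test_single_deletion_is_frameshift(self):
        z = self._orf()
        pos = 9 * 3 + 1  # inside codon 10
        w = z[:pos] + "-" + z[pos + 1:]
        (d,) = gm.scan_orf(z, w)
        assert d.kind == "frameshift"
        assert d.z_pos == pos

    def test_midframe_stop_detected(self):
        z = self._orf()
        w = z[:30] + "TAA" + z[33:]
        (d,) = gm.scan_orf(z, w)
        assert d.kind == "premature_stop"
        assert d.z_pos == 30

    def test_intact_is_clean(self):
        z = self._orf()
        assert gm.scan_orf(z, z) == []

    def test_frame_restoring_pair_not_flagged_downstream(self):
        """A 3-bp deletion keeps the frame; no frameshift is called."""
        z = self._orf()
        w = z[:12] + "---" + z[15:]
        assert all(d.kind != "frameshift" for d in gm.scan_orf(z, w))

    def test_invalid_reference_rejected(self):
        with pytest.raises(InputError, match="reference ORF"):
            gm.scan_orf("CCCAAATAA", "CCCAAATAA")  # no ATG start
        with pytest.raises(InputError, match="reference ORF"):
            gm.scan_orf("ATGTAAAAATAA", "ATGTAAAAATAA")  # internal stop

    def test_simulated_disruptions_recovered_exactly(self, small_bundle):
        """Ground-truth disruption positions and types recovered for every
        simulated W gene of every species."""
        cfg = small_bundle.config
        for gene in small_bundle.gametologs.genes:
            for sp, _ in cfg.species:
                truth = sorted(
                    [(d.kind, d.z_pos) for d in gene.disruptions[sp]],
                    key=lambda t: t[1],
                )
                found = [(d.kind, d.z_pos) for d in gm.scan_orf(
                    gene.seqs[f"{sp}_Z"], gene.seqs[f"{sp}_W"])]
                assert found == truth

    def test_reverting_disruptions_restores_intact(self, small_bundle):
        """Replacing each disrupted W with its pre-disruption sequence leaves
        an intact ORF; the generator's disruptions are the only lesions."""
        cfg = pipeline.small_preset(seed=21, w_disruption_rate=0.0)
        gs = simzw.simulate_gametologs(cfg)
        for gene in gs.genes:
            for sp, _ in cfg.species:
                assert gm.scan_orf(gene.seqs[f"{sp}_Z"],
                                   gene.seqs[f"{sp}_W"]) == []


class TestPseudogeneFraction:
    def test_printed_counts(self):
        res = gm.pseudogene_fraction(["pseudogene"] * 62 + ["intact"] * 75)
        assert res == {"n_total": 137, "n_pseudo": 62, "percent": 45.26}

    def test_zero(self):
        assert gm.pseudogene_fraction(["intact"] * 10)["percent"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            gm.pseudogene_fraction([])

    def test_matches_direct_count_on_bundle(self, small_bundle):
        statuses = []
        direct = 0
        for gene in small_bundle.gametologs.genes:
            z, w = gene.seqs["viper_Z"], gene.seqs["viper_W"]
            statuses.append("pseudogene" if gm.scan_orf(z, w) else "intact")
            direct += bool(gene.disruptions["viper"])
        assert gm.pseudogene_fraction(statuses)["n_pseudo"] == direct


class TestTrees:
    def test_three_taxa_unique_topology(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        t = gm.nj_tree(["a", "b", "c"], D)
        assert t.count("(") == 1  # single unrooted trichotomy

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):3,C:4,D:5): additive distances
        D = np.array([
            [0, 3, 8, 9],
            [3, 0, 9, 10],
            [8, 9, 0, 9],
            [9, 10, 9, 0]], float)
        t = gm.nj_tree(["A", "B", "C", "D"], D)
        assert "(A:1.000000,B:2.000000)" in t

    def test_permutation_invariant(self):
        D = np.array([
            [0, 3, 8, 9],
            [3, 0, 9, 10],
            [8, 9, 0, 9],
            [9, 10, 9, 0]], float)
        labels = ["A", "B", "C", "D"]
        t1 = gm.nj_tree(labels, D)
        perm = [2, 0, 3, 1]
        t2 = gm.nj_tree([labels[i] for i in perm], D[np.ix_(perm, perm)])
        assert t1 == t2

    def test_matches_biopython_nj_topology(self):
        """Independent NJ implementation (Bio.Phylo) yields the same splits
        on a random additive matrix."""
        import itertools
        from io import StringIO

        import networkx as nx
        from Bio import Phylo
        from Bio.Phylo.TreeConstruction import (DistanceMatrix,
                                                DistanceTreeConstructor)

        # additive distances: path lengths on an explicit 6-taxon tree
        g = nx.Graph()
        g.add_weighted_edges_from([
            ("a", "X1", 1.0), ("b", "X1", 1.5), ("X1", "X2", 0.7),
            ("c", "X2", 0.8), ("X2", "X3", 0.6), ("d", "X3", 1.2),
            ("X3", "X4", 0.4), ("e", "X4", 0.9), ("f", "X4", 1.1),
        ])
        names = list("abcdef")
        D = np.zeros((6, 6))
        for i, j in itertools.combinations(range(6), 2):
            D[i, j] = D[j, i] = nx.shortest_path_length(
                g, names[i], names[j], weight="weight")
        mine = gm.nj_tree(names, D)
        lower = [[float(D[i, j]) for j in range(i + 1)] for i in range(6)]
        ref_tree = DistanceTreeConstructor().nj(DistanceMatrix(names, lower))

        def splits(newick):
            import dendropy
            t = dendropy.Tree.get(data=newick, schema="newick",
                                  preserve_underscores=True)
            t.encode_bipartitions()
            out = set()
            for e in t.preorder_edge_iter():
                if e.head_node and e.head_node.parent_node:
                    side = frozenset(l.taxon.label
                                     for l in e.head_node.leaf_iter())
                    if 1 < len(side) < 5:
                        side = min(side, frozenset(set(names) - side),
                                   key=sorted)
                        out.add(side)
            return out

        buf = StringIO()
        Phylo.write(ref_tree, buf, "newick")
        assert splits(mine) == splits(buf.getvalue())

    def test_nonsymmetric_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], float)
        with pytest.raises(InputError):
            gm.nj_tree(["a", "b", "c"], D)

    def test_ultrametric_recovery_up_to_8_taxa(self):
        """NJ recovers the generating topology for simulated clock-like
        gametolog distances (4-8 taxa)."""
        cfg = pipeline.small_preset(seed=13, species=(
            ("sp1", 0.004), ("sp2", 0.006), ("sp3", 0.010), ("sp4", 0.010)))
        gs = simzw.simulate_gametologs(cfg)
        for gene in gs.genes[:6]:
            names = sorted(gene.seqs)
            cleaned = gm.clean_alignment([gene.seqs[n] for n in names])
            labels, D = gm.distance_matrix(dict(zip(names, cleaned)))
            tree = gm.nj_tree(labels, D)
            res = gm.cluster_by_chromosome_test(
                tree, {n: tuple(n.rsplit("_", 1)) for n in names})
            assert res.clustering == "by_chromosome"


class TestClusterTest:
    LBL = {"A_Z": ("A", "Z"), "B_Z": ("B", "Z"),
           "A_W": ("A", "W"), "B_W": ("B", "W")}

    def test_by_chromosome(self):
        res = gm.cluster_by_chromosome_test(
            "((A_Z:1,B_Z:1):1,(A_W:1,B_W:1):1);", self.LBL)
        assert res.clustering == "by_chromosome"

    def test_by_species(self):
        res = gm.cluster_by_chromosome_test(
            "((A_Z:1,A_W:1):1,(B_Z:1,B_W:1):1);", self.LBL)
        assert res.clustering == "by_species"

    def test_unresolved(self):
        lbl = dict(self.LBL)
        lbl.update({"C_Z": ("C", "Z"), "C_W": ("C", "W")})
        res = gm.cluster_by_chromosome_test(
            "((A_Z:1,C_W:1):1,(B_Z:1,(A_W:1,(B_W:1,C_Z:1):1):1):1);", lbl)
        assert res.clustering == "unresolved"

    def test_missing_labels_rejected(self):
        with pytest.raises(InputError):
            gm.cluster_by_chromosome_test(
                "((A_Z:1,B_Z:1):1,(A_W:1,B_W:1):1);",
                {"A_Z": ("A", "Z"), "B_Z": ("B", "Z"), "A_W": ("A", "W"),
                 "B_W": ("B", "X")})

    def test_shared_strata_preset_clusters_by_chromosome(self, small_bundle):
        """>=95% of simulated shared-strata genes (Z-W divergence at least
        twice the deepest species split) cluster by chromosome."""
        n_ok = 0
        genes = small_bundle.gametologs.genes
        for gene in genes:
            names = sorted(gene.seqs)
            cleaned = gm.clean_alignment([gene.seqs[n] for n in names])
            if not gm.passes_length_filter(cleaned):
                continue
            labels, D = gm.distance_matrix(dict(zip(names, cleaned)))
            tree = gm.nj_tree(labels, D)
            res = gm.cluster_by_chromosome_test(
                tree, {n: tuple(n.rsplit("_", 1)) for n in names})
            n_ok += res.clustering == "by_chromosome"
        assert n_ok / len(genes) >= 0.95
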