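import itertools

import numpy as np
import pandas as pd
import pytest

from mirnet.data_io import (DataError, ExpressionMatrix, MotifSet, PromoterSet,
                            TargetPairSet, load_fixture_table, reverse_complement)
from mirnet.networks import (FeedbackLoop, MotifHit, RegulatoryNetwork,
                             build_bipartite_network, build_tf_mirna_network,
                             core_tfs, find_feedback_loops, hub_nodes,
                             scan_promoters, _iupac_revcomp)
from mirnet.data_io import IUPAC_CODES


def naive_scan(seq, motif, max_mismatch=0, both_strands=True):
    """Sliding-window oracle with literal IUPAC set membership checks."""
    hits = []
    L = len(motif)
    for strand, m in (("+", motif), ("-", _iupac_revcomp(motif))):
        if strand == "-" and not both_strands:
            continue
        for pos in range(len(seq) - L + 1):
            window = seq[pos:pos + L]
            mism = sum(1 for w, c in zip(window, m) if w not in IUPAC_CODES[c])
            if mism <= max_mismatch:
                hits.append((pos, strand))
    return set(hits)


class TestBipartiteNetwork:
    def test_degree_counting(self):
        net = build_bipartite_network(TargetPairSet(frozenset(
            {("m1", "g1"), ("m1", "g2"), ("m1", "g3")})))
        assert net.degree("m1") == 3
        assert all(net.degree(g) == 1 for g in ("g1", "g2", "g3"))

    def test_empty_input(self):
        net = build_bipartite_network(TargetPairSet(frozenset()))
        assert net.n_edges == 0 and not list(net.graph.nodes)

    def test_published_target_table_degree(self):
        """The 21 printed targets of hsa-miR-34c-5p give it degree 21."""
        t2 = load_fixture_table("table2")
        net = build_bipartite_network(TargetPairSet(frozenset(zip(t2["mirna"], t2["gene"]))))
        assert net.degree("hsa-miR-34c-5p") == 21

    def test_degree_sum_is_twice_edges(self):
        rng = np.random.default_rng(4)
        pairs = {(f"m{rng.integers(20)}", f"g{rng.integers(40)}") for _ in range(150)}
        net = build_bipartite_network(TargetPairSet(frozenset(pairs)))
        assert sum(d for _, d in net.graph.degree()) == 2 * net.n_edges

    def test_mirna_self_loop_rejected(self):
        net = RegulatoryNetwork()
        with pytest.raises(DataError, match="self-loop"):
            net.add_edge("x", "x", "mirna_targets_gene")


class TestHubs:
    def test_star_center(self):
        net = build_bipartite_network(TargetPairSet(frozenset(
            {("hub", f"g{i}") for i in range(12)})))
        assert hub_nodes(net, 10) == [("hub", 12)]

    def test_all_below_threshold(self):
        net = build_bipartite_network(TargetPairSet(frozenset({("m", "g")})))
        assert hub_nodes(net, 10) == []

    def test_strict_gt_excludes_exact_threshold(self):
        net = build_bipartite_network(TargetPairSet(frozenset(
            {("hub", f"g{i}") for i in range(10)})))
        assert hub_nodes(net, 10) == [("hub", 10)]
        assert hub_nodes(net, 10, strict_gt=True) == []

    def test_matches_brute_force_on_random_graph(self):
        rng = np.random.default_rng(12)
        pairs = {(f"m{rng.integers(15)}", f"g{rng.integers(30)}") for _ in range(200)}
        net = build_bipartite_network(TargetPairSet(frozenset(pairs)))
        brute = sorted(((n, d) for n, d in net.graph.degree() if d >= 5),
                       key=lambda nd: (-nd[1], nd[0]))
        assert hub_nodes(net, 5) == brute


class TestMotifScan:
    def _promoters(self, **seqs):
        window = max(len(s) for s in seqs.values())
        trunc = frozenset(k for k, s in seqs.items() if len(s) < window)
        return PromoterSet(sequences=seqs, window_bp=window, truncated=trunc)

    def test_planted_site_found_exactly(self):
        rng = np.random.default_rng(7)
        bases = list("ACGT")
        seq = "".join(rng.choice(bases, 100))
        motif = "GGGCGG"
        planted = seq[:37] + motif + seq[37 + 6:]
        # remove chance occurrences elsewhere for an exact-count assertion
        if naive_scan(planted, motif) != {(37, "+")}:
            pytest.skip("chance second occurrence in random background")
        hits = scan_promoters(self._promoters(m1=planted), MotifSet({"TF1": motif}), 0)
        assert [(h.position, h.strand) for h in hits] == [(37, "+")]

    def test_absent_motif_zero_hits(self):
        hits = scan_promoters(self._promoters(m1="AAAAAAAAAA"), MotifSet({"TF1": "GGGCGG"}), 0)
        assert hits == []

    def test_iupac_degenerate_match(self):
        hits = scan_promoters(
            PromoterSet(sequences={"m1": "ACGT"}, window_bp=4),
            MotifSet({"TF1": "RYGT"}), 0, both_strands=False)
        assert [(h.position, h.strand, h.matched) for h in hits] == [(0, "+", "ACGT")]

    def test_mismatch_budget(self):
        hits = scan_promoters(
            PromoterSet(sequences={"m1": "AACGTAA"}, window_bp=7),
            MotifSet({"TF1": "ACGG"}), 1, both_strands=False)
        assert any(h.position == 1 for h in hits)

    @pytest.mark.parametrize("max_mismatch", [0, 1])
    def test_matches_naive_oracle_on_random_sequences(self, max_mismatch):
        rng = np.random.default_rng(100)
        bases = list("ACGT")
        motifs = MotifSet({"TF1": "GGRYGG", "TF2": "TAWAAT"})
        for _ in range(100):
            seq = "".join(rng.choice(bases, 60))
            hits = scan_promoters(PromoterSet(sequences={"m": seq}, window_bp=60),
                                  motifs, max_mismatch)
            for tf, motif in motifs.motifs.items():
                got = {(h.position, h.strand) for h in hits if h.tf_name == tf}
                assert got == naive_scan(seq, motif, max_mismatch)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(31)
        bases = list("ACGT")
        motif = MotifSet({"TF": "GGATCY"})
        for _ in range(25):
            seq = "".join(rng.choice(bases, 50))
            fwd = scan_promoters(PromoterSet(sequences={"m": seq}, window_bp=50), motif, 0)
            rev = scan_promoters(
                PromoterSet(sequences={"m": reverse_complement(seq)}, window_bp=50), motif, 0)
            L = len(motif.motifs["TF"])
            mapped = {(len(seq) - h.position - L, "+-"["+-".index(h.strand) - 1]) for h in rev}
            assert {(h.position, h.strand) for h in fwd} == mapped

    def test_invalid_iupac_named(self):
        motifs = MotifSet({"TF1": "ACGT"})
        object.__setattr__(motifs, "motifs", {"TF1": "ACXT"})  # bypass constructor check
        with pytest.raises(DataError, match="X"):
            scan_promoters(PromoterSet(sequences={"m": "ACGTACGT"}, window_bp=8), motifs, 0)


class TestTFNetwork:
    def _hits(self, pairs):
        return [MotifHit(tf, m, 0, "+", "ACGT") for tf, m in pairs]

    def test_edge_and_degree_counts(self):
        hits = self._hits([(tf, m) for tf in ("TF1", "TF2") for m in ("a", "b", "c")])
        net = build_tf_mirna_network(hits)
        assert net.n_edges == 6
        assert net.degree("TF1") == net.degree("TF2") == 3

    def test_identical_series_weight_one(self):
        samples = list("abcdef")
        x = np.arange(6, dtype=float)
        te = ExpressionMatrix(pd.DataFrame([x], index=["TF1"], columns=samples), "mRNA")
        me = ExpressionMatrix(pd.DataFrame([x], index=["m1"], columns=samples), "miRNA")
        net = build_tf_mirna_network(self._hits([("TF1", "m1")]), te, me)
        assert net.graph.edges["TF1", "m1"]["weight"] == pytest.approx(1.0)

    def test_weights_match_hand_pearson(self):
        samples = list("abcdef")
        x = np.array([1.0, 3, 2, 5, 4, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        te = ExpressionMatrix(pd.DataFrame([x], index=["TF1"], columns=samples), "mRNA")
        me = ExpressionMatrix(pd.DataFrame([y], index=["m1"], columns=samples), "miRNA")
        net = build_tf_mirna_network(self._hits([("TF1", "m1")]), te, me)
        assert net.graph.edges["TF1", "m1"]["weight"] == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_too_few_shared_samples_for_weighting(self):
        te = ExpressionMatrix(pd.DataFrame([[1.0, 2]], index=["TF1"], columns=["a", "b"]), "mRNA")
        me = ExpressionMatrix(pd.DataFrame([[1.0, 2]], index=["m1"], columns=["a", "b"]), "miRNA")
        with pytest.raises(DataError, match="shared samples"):
            build_tf_mirna_network(self._hits([("TF1", "m1")]), te, me)

    def test_core_tfs_match_brute_force(self):
        rng = np.random.default_rng(9)
        pairs = {(f"TF{rng.integers(6)}", f"m{rng.integers(25)}") for _ in range(80)}
        net = build_tf_mirna_network(self._hits(sorted(pairs)))
        brute = sorted(
            ((tf, deg) for tf, deg in net.graph.degree()
             if tf.startswith("TF") and deg >= 8),
            key=lambda nd: (-nd[1], nd[0]))
        assert core_tfs(net, 8) == brute

    def test_published_core_tf_intersection(self):
        """The TFs called at every stage are exactly the seven named regulators."""
        t5 = load_fixture_table("table5")
        assert {len(v) for v in t5.values()} == {7, 8, 14, 21}
        inter = set.intersection(*(set(v) for v in t5.values()))
        assert inter == {"ETS2", "MYB", "Sp1", "KLF6", "NFE2", "PCBP1", "TMEM54"}


class TestFeedbackLoops:
    def _tf_net(self, binding):
        net = RegulatoryNetwork()
        for tf, m in binding:
            net.add_edge(tf, m, "tf_binds_mirna")
        return net

    def test_published_example_loops(self):
        net = self._tf_net([("SP1", "hsa-miR-1"), ("ETS2", "hsa-miR-429"), ("SP1", "hsa-miR-99a")])
        pairs = TargetPairSet(frozenset({("hsa-miR-1", "SP1"), ("hsa-miR-429", "ETS2")}))
        loops = find_feedback_loops(net, pairs)
        assert [(l.tf_name, l.mirna_id) for l in loops] == [
            ("ETS2", "hsa-miR-429"), ("SP1", "hsa-miR-1")]
        assert all(l.target_gene == l.tf_name for l in loops)

    def test_disjoint_name_spaces_empty(self):
        net = self._tf_net([("TFA", "m1")])
        assert find_feedback_loops(net, TargetPairSet(frozenset({("m1", "geneB")}))) == []

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(2)
        tfs = [f"TF{i}" for i in range(10)]
        mirnas = [f"m{i}" for i in range(30)]
        binding = {(t, m) for t in tfs for m in mirnas if rng.random() < 0.2}
        targeting = {(m, t) for t in tfs for m in mirnas if rng.random() < 0.2}
        net = self._tf_net(sorted(binding))
        loops = find_feedback_loops(net, TargetPairSet(frozenset(targeting)))
        brute = sorted((t, m) for t, m in itertools.product(tfs, mirnas)
                       if (t, m) in binding and (m, t) in targeting)
        assert [(l.tf_name, l.mirna_id) for l in loops] == brute

    def test_published_loop_table_has_three_tfs(self):
        t6 = load_fixture_table("table6")
        net = self._tf_net(list(zip(t6["tf"], t6["mirna"])))
        pairs = TargetPairSet(frozenset(zip(t6["mirna"], t6["target_gene"])))
        loops = find_feedback_loops(net, pairs)
        assert len(loops) == len(t6)
        assert {l.tf_name for l in loops} == {"ETS2", "SP1", "KLF6"}
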