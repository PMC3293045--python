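"""Regulatory networks: bipartite miRNA-gene graph, TF-miRNA net, feedback loops.

Three parts: (i) the published coordinate-expression table becomes the
miRNA-gene bipartite network with degree-based hub calling; (ii) the published
TF table's per-stage counts and across-stage core are recomputed; (iii) the
synthetic regulome is scanned for planted TF binding sites, the TF-miRNA
network is built with Pearson "regulatory ability" weights, and planted
feedback loops are mined and scored.
"""

from pathlib import Path

import pandas as pd

from mirnet import data_io, networks

BENCH = Path("results/benchmark")
OUT = Path("results")


def main() -> None:
    # (i) bipartite network of the published coordinate pairs
    t2 = data_io.load_fixture_table("table2")
    bip = networks.build_bipartite_network(
        data_io.TargetPairSet(frozenset(zip(t2["mirna"], t2["gene"]))))
    hubs = networks.hub_nodes(bip, min_degree=10)
    print(f"published miRNA-gene network: {bip.n_edges} edges; hubs (degree >= 10):")
    for n, d in hubs:
        print(f"  {n}: degree {d}")
    data_io.write_network_edgelist(bip, OUT / "mirna_gene_network.tsv")

    # (ii) published TF table recounts
    t5 = data_io.load_fixture_table("table5")
    core = set.intersection(*(set(v) for v in t5.values()))
    counts = {s: len(v) for s, v in t5.items()}
    print(f"TF counts per stage {counts}; across-stage core ({len(core)}): {sorted(core)}")

    # (iii) synthetic regulome scan -> TF net -> loops
    promoters = data_io.read_promoters_fasta(BENCH / "promoters.fasta")
    motifs = data_io.read_motifs_tsv(BENCH / "motifs.tsv")
    hits = networks.scan_promoters(promoters, motifs, max_mismatch=0)
    mirna_expr = data_io.read_expression_tsv(BENCH / "regulome_mirna_expression.tsv", "miRNA")
    mrna_expr = data_io.read_expression_tsv(BENCH / "regulome_mrna_expression.tsv", "mRNA")
    tf_net = networks.build_tf_mirna_network(hits, tf_expr=mrna_expr, mirna_expr=mirna_expr)
    data_io.write_network_edgelist(tf_net, OUT / "tf_mirna_network.tsv")

    pairs = data_io.read_target_pairs_tsv(BENCH / "target_pairs.tsv")
    loops = networks.find_feedback_loops(tf_net, pairs)
    truth = pd.read_csv(BENCH / "truth_loops.tsv", sep="\t")
    planted = set(zip(truth["tf"], truth["mirna"]))
    found = {(l.tf_name, l.mirna_id) for l in loops}
    print(f"synthetic regulome: {len(hits)} motif hits, {tf_net.n_edges} TF->miRNA edges, "
          f"{len(loops)} feedback loops ({len(found & planted)}/{len(planted)} planted recovered)")
    networks.loops_to_frame(loops).to_csv(OUT / "feedback_loops.tsv", sep="\t", index=False)
    print(f"wrote {OUT}/mirna_gene_network.tsv, tf_mirna_network.tsv, feedback_loops.tsv")


if __name__ == "__main__":
    main()
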