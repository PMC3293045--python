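"""Generate the study-scale synthetic benchmark and write its input files.

Emulates the 22-sample staged design (6 normal, 4 per tumour stage I-II / III /
IV, 4 lymph-node metastasis) with 766 detected miRNAs, 48 planted
differentially expressed features spread over the six stage-trend patterns,
plus a planted regulome (target pairs, TF motifs, promoters, paired
expression). Everything downstream (02-07) reads from results/benchmark/.
"""

from pathlib import Path

import pandas as pd

from mirnet import data_io, synthetic

SEED = 20120119
OUT = Path("results/benchmark")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = data_io.study_design()
    matrix, truth = synthetic.generate_staged_expression(seed=SEED, design=design)
    data_io.write_expression_tsv(matrix, OUT / "mirna_expression.tsv")
    data_io.write_design_tsv(design, OUT / "design.tsv")
    pd.DataFrame(
        [(f, p, *e) for f, (p, e) in truth.de_features.items()],
        columns=["feature_id", "pattern_id", *[f"effect_{s}" for s in design.stages]],
    ).to_csv(OUT / "truth_de_features.tsv", sep="\t", index=False)

    pairs, motifs, promoters, mirna_expr, mrna_expr, reg_truth = synthetic.generate_regulome(seed=SEED)
    data_io.write_target_pairs_tsv(pairs, OUT / "target_pairs.tsv")
    data_io.write_motifs_tsv(motifs, OUT / "motifs.tsv")
    data_io.write_promoters_fasta(promoters, OUT / "promoters.fasta")
    data_io.write_expression_tsv(mirna_expr, OUT / "regulome_mirna_expression.tsv")
    data_io.write_expression_tsv(mrna_expr, OUT / "regulome_mrna_expression.tsv")
    pd.DataFrame(reg_truth.loops, columns=["tf", "mirna"]).to_csv(
        OUT / "truth_loops.tsv", sep="\t", index=False)
    pd.DataFrame(reg_truth.target_pairs, columns=["mirna", "gene", "mirna_direction"]).to_csv(
        OUT / "truth_anticorrelated_pairs.tsv", sep="\t", index=False)

    print(f"benchmark (seed {SEED}) written to {OUT}/")
    print(f"  {len(matrix.feature_ids)} miRNAs x {len(matrix.sample_ids)} samples, "
          f"{len(truth.de_features)} planted DE")
    print(f"  regulome: {len(pairs)} predicted pairs, {len(reg_truth.loops)} planted loops")


if __name__ == "__main__":
    main()
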