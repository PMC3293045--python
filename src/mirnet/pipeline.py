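"""End-to-end benchmark: generate, screen, integrate, mine loops, score recovery.

Runs the whole pipeline on synthetic data at the study's scale and scores it
against the generator's ground truth. Used by the analysis drivers, the test
suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_io import StageDesign, TargetPairSet, study_design
from .integration import CoordinatePair, correlation_filter
from .networks import build_tf_mirna_network, find_feedback_loops, scan_promoters
from .rvm import rvm_f_test
from .synthetic import (DEFAULT_EFFECT_SIZE, DEFAULT_PRIOR, generate_regulome,
                        generate_staged_expression)

BENCHMARK_SEED = 20120119  # packaged-benchmark default


@dataclass(frozen=True)
class BenchmarkResult:
    de_recovery: float        # planted DE features passing p<0.05 & q<0.05
    null_positive_rate: float # non-planted features passing the same gate
    pair_recovery: float      # planted anti-correlated pairs kept at r <= -0.3
    loop_recovery: float      # planted feedback loops recovered
    n_loops_found: int
    n_loops_planted: int
    n_de_planted: int


def differential_recovery(seed: int = BENCHMARK_SEED, n_features: int = 766,
                          n_de: int = 48, effect_size: float = DEFAULT_EFFECT_SIZE,
                          design: StageDesign | None = None,
                          p_cut: float = 0.05, q_cut: float = 0.05):
    """Moderated-F screen on a planted benchmark; returns (recovery, null rate, diff, truth)."""
    design = design or study_design()
    matrix, truth = generate_staged_expression(
        n_features=n_features, design=design, n_de=n_de,
        effect_size=effect_size, seed=seed)
    diff = rvm_f_test(matrix, design)
    sig = set(diff.significant(p_cut, q_cut).index)
    planted = set(truth.de_features)
    null = set(matrix.feature_ids) - planted
    recovery = len(sig & planted) / len(planted) if planted else float("nan")
    null_rate = len(sig & null) / len(null) if null else 0.0
    return recovery, null_rate, diff, truth


def regulome_recovery(seed: int = BENCHMARK_SEED, r_max: float = -0.3, **kwargs):
    """Anti-correlation filtering and loop mining on a planted regulome."""
    pairs, motifs, promoters, mirna_expr, mrna_expr, truth = generate_regulome(
        seed=seed, **kwargs)

    planted = [CoordinatePair(m, d, g, "up" if d == "down" else "down")
               for m, g, d in truth.target_pairs]
    kept = correlation_filter(planted, mirna_expr, mrna_expr, r_max=r_max)
    pair_recovery = len(kept) / len(planted) if planted else float("nan")

    hits = scan_promoters(promoters, motifs, max_mismatch=0, both_strands=True)
    tf_net = build_tf_mirna_network(hits, tf_expr=mrna_expr, mirna_expr=mirna_expr)
    loops = find_feedback_loops(tf_net, pairs)
    found = {(l.tf_name, l.mirna_id) for l in loops}
    planted_loops = set(truth.loops)
    loop_recovery = (len(found & planted_loops) / len(planted_loops)
                     if planted_loops else float("nan"))
    return pair_recovery, loop_recovery, loops, truth


def end_to_end_benchmark(seed: int = BENCHMARK_SEED) -> BenchmarkResult:
    """Full-default benchmark run at the study's scale."""
    de_rec, null_rate, _, de_truth = differential_recovery(seed=seed)
    pair_rec, loop_rec, loops, reg_truth = regulome_recovery(seed=seed)
    return BenchmarkResult(
        de_recovery=de_rec,
        null_positive_rate=null_rate,
        pair_recovery=pair_rec,
        loop_recovery=loop_rec,
        n_loops_found=len(loops),
        n_loops_planted=len(reg_truth.loops),
        n_de_planted=len(de_truth.de_features),
    )
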