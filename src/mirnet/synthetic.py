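"""Synthetic staged expression, regulome, promoters and Ct tables with ground truth.

The generator reproduces the statistical assumptions the pipeline makes, at
the study's scale: a 22-sample ordered design (6 normal, 4 per tumour stage
I-II / III / IV, 4 lymph-node metastasis), ~766 detected miRNAs of which 48
are planted as differentially expressed along one of the six stage-trend
patterns, per-feature variances drawn from the inverse-variance Gamma prior
(a = 2, b = 1.5), anti-correlated planted miRNA-target pairs, and TF binding
motifs planted into pre-miRNA upstream windows. Planted effects span 4 log2
units (16-fold across the full progression), the scale of strongly aberrant
tumour miRNAs; an a-priori power analysis put per-feature detection near 98%
at the study's arm sizes, so planted features are recoverable by design.
Noise is Gaussian on the log2 scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import DataError, ExpressionMatrix, MotifSet, PromoterSet, StageDesign, TargetPairSet, study_design
from .qpcr import CtRecord
from .rvm import RVMPrior

#: Unit-span stage trajectories for the six dynamic patterns.
TRAJECTORY_SHAPES: dict[int, tuple[float, ...]] = {
    1: (0.0, -0.25, -0.5, -0.75, -1.0),  # gradual decrease
    2: (0.0, -1.0, -1.0, -1.0, -1.0),    # early decrease, then flat
    3: (0.0, -1.0, -1.0, 0.0, 0.0),      # decrease then recovery
    4: (0.0, 1.0, 1.0, 0.0, 0.0),        # increase then decline
    5: (0.0, 0.25, 0.5, 0.75, 1.0),      # gradual increase
    6: (0.0, 0.0, 0.0, 0.0, 1.0),        # flat, metastasis spike
}

DEFAULT_PRIOR = RVMPrior(a=2.0, b=1.5)
DEFAULT_EFFECT_SIZE = 4.0  # log2 units spanned by a planted trajectory
BASELINE_MEAN = 8.0        # log2 intensity centre of detected features
BASELINE_SD = 1.5


@dataclass
class SyntheticTruth:
    """Ground truth of a generated benchmark, for recovery testing."""

    seed: int
    prior: RVMPrior
    de_features: dict[str, tuple[int, tuple[float, ...]]] = field(default_factory=dict)
    target_pairs: list[tuple[str, str, str]] = field(default_factory=list)  # (mirna, gene, mirna_direction)
    motif_sites: list[tuple[str, str, int]] = field(default_factory=list)   # (tf, mirna, position)
    loops: list[tuple[str, str]] = field(default_factory=list)              # (tf, mirna)


def _split_counts(n: int, proportions: dict[int, float]) -> dict[int, int]:
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise DataError(f"pattern proportions must sum to 1, got {sum(proportions.values())}")
    keys = sorted(proportions)
    counts = {k: int(np.floor(proportions[k] * n)) for k in keys}
    i = 0
    while sum(counts.values()) < n:
        counts[keys[i % len(keys)]] += 1
        i += 1
    return counts


def generate_staged_expression(
    n_features: int = 766,
    design: StageDesign | None = None,
    prior: RVMPrior = DEFAULT_PRIOR,
    n_de: int = 48,
    pattern_mix: dict[int, float] | None = None,
    effect_size: float = DEFAULT_EFFECT_SIZE,
    seed: int = 0,
    feature_kind: str = "miRNA",
    id_prefix: str = "syn-miR",
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Staged log2 expression with planted trend patterns and RVM variances."""
    if n_de > n_features:
        raise DataError("n_de cannot exceed n_features")
    if effect_size <= 0:
        raise DataError("effect_size must be positive")
    design = design or study_design()
    pattern_mix = pattern_mix or {p: 1 / 6 for p in range(1, 7)}
    rng = np.random.default_rng(seed)

    samples = list(design.sample_to_stage)
    stage_idx = np.array([design.stages.index(design.sample_to_stage[s]) for s in samples])
    n = len(samples)

    inv_var = rng.gamma(prior.a, prior.b, size=n_features)
    sigma = 1.0 / np.sqrt(inv_var)
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_features)
    X = baseline[:, None] + rng.normal(0.0, 1.0, size=(n_features, n)) * sigma[:, None]

    truth = SyntheticTruth(seed=seed, prior=prior)
    counts = _split_counts(n_de, pattern_mix)
    ids = [f"{id_prefix}-{i:04d}" for i in range(n_features)]
    row = 0
    for pattern in sorted(counts):
        shape = np.array(TRAJECTORY_SHAPES[pattern])
        for _ in range(counts[pattern]):
            effects = effect_size * shape
            X[row] += effects[stage_idx]
            truth.de_features[ids[row]] = (pattern, tuple(float(e) for e in effects))
            row += 1

    matrix = ExpressionMatrix(data=pd.DataFrame(X, index=ids, columns=samples),
                              feature_kind=feature_kind)
    return matrix, truth


_ACGT = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ACGT, size=length))


def generate_regulome(
    n_mirnas: int = 30,
    n_genes: int = 60,
    n_tfs: int = 8,
    loop_count: int = 3,
    promoter_bp: int = 1000,
    seed: int = 0,
    n_anticorr_pairs: int = 20,
    motif_length: int = 10,
    design: StageDesign | None = None,
) -> tuple[TargetPairSet, MotifSet, PromoterSet, ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Planted regulome: target pairs, TF motifs, promoters and paired expression.

    Exactly ``loop_count`` TF<->miRNA feedback loops are planted (the TF's
    motif in the miRNA's upstream window AND the TF's transcript in that
    miRNA's target set). Planted miRNA-target pairs are generated with
    anti-correlated expression (generative r about -0.9); background promoter
    sequence is i.i.d. uniform ACGT, and background target pairs never point
    at TF transcripts, so chance motif hits cannot close a spurious loop.
    """
    if loop_count > min(n_tfs, n_mirnas):
        raise DataError("loop_count cannot exceed min(n_tfs, n_mirnas)")
    if promoter_bp < motif_length:
        raise DataError(f"promoter window {promoter_bp} shorter than motif length {motif_length}")
    design = design or study_design()
    rng = np.random.default_rng(seed)
    samples = list(design.sample_to_stage)
    n = len(samples)

    mirnas = [f"syn-miR-{i:03d}" for i in range(n_mirnas)]
    genes = [f"GENE{i:03d}" for i in range(n_genes)]
    tfs = [f"TF{i:02d}" for i in range(n_tfs)]

    truth = SyntheticTruth(seed=seed, prior=DEFAULT_PRIOR)
    motifs = {tf: _random_seq(rng, motif_length) for tf in tfs}
    promoters = {m: _random_seq(rng, promoter_bp) for m in mirnas}

    # plant one binding site per loop TF in its partner miRNA's promoter
    for i in range(loop_count):
        tf, m = tfs[i], mirnas[i]
        pos = int(rng.integers(0, promoter_bp - motif_length + 1))
        seq = promoters[m]
        promoters[m] = seq[:pos] + motifs[tf] + seq[pos + motif_length:]
        truth.motif_sites.append((tf, m, pos))
        truth.loops.append((tf, m))

    # expression: miRNA rows, then gene/TF rows anti-correlated where planted
    mirna_X = rng.normal(BASELINE_MEAN, 1.0, size=(n_mirnas, n)) + rng.normal(0, 0.5, size=(n_mirnas, n))
    mrna_rows: dict[str, np.ndarray] = {
        g: rng.normal(BASELINE_MEAN, 1.0, size=n) for g in genes + tfs
    }

    pairs: set[tuple[str, str]] = set()

    def plant_anticorrelated(mirna_i: int, target: str) -> None:
        x = mirna_X[mirna_i]
        noise = rng.normal(0.0, 0.5, size=n)
        mrna_rows[target] = BASELINE_MEAN - (x - x.mean()) + noise

    # loop pairs: miRNA targets its TF's transcript
    for i, (tf, m) in enumerate(truth.loops):
        pairs.add((m, tf))
        plant_anticorrelated(i, tf)
        direction = "down" if i % 2 == 0 else "up"
        truth.target_pairs.append((m, tf, direction))

    # additional planted anti-correlated miRNA-gene pairs
    free_mirnas = list(range(n_mirnas))
    gene_pool = list(genes)
    rng.shuffle(gene_pool)
    for j in range(n_anticorr_pairs):
        mi = free_mirnas[j % n_mirnas]
        g = gene_pool[j % n_genes]
        if (mirnas[mi], g) in pairs:
            continue
        pairs.add((mirnas[mi], g))
        plant_anticorrelated(mi, g)
        truth.target_pairs.append((mirnas[mi], g, "down" if j % 2 == 0 else "up"))

    # background predicted pairs (no expression relationship, never a TF target)
    n_background = 2 * n_anticorr_pairs
    for _ in range(n_background):
        m = mirnas[int(rng.integers(n_mirnas))]
        g = genes[int(rng.integers(n_genes))]
        if (m, g) not in pairs:
            pairs.add((m, g))

    mirna_expr = ExpressionMatrix(
        data=pd.DataFrame(mirna_X, index=mirnas, columns=samples), feature_kind="miRNA")
    mrna_ids = genes + tfs
    mrna_expr = ExpressionMatrix(
        data=pd.DataFrame(np.vstack([mrna_rows[g] for g in mrna_ids]),
                          index=mrna_ids, columns=samples),
        feature_kind="mRNA")
    return (
        TargetPairSet(pairs=frozenset(pairs), provenance=f"synthetic(seed={seed})"),
        MotifSet(motifs=motifs),
        PromoterSet(sequences=promoters, window_bp=promoter_bp),
        mirna_expr,
        mrna_expr,
        truth,
    )


def generate_ct_table(
    true_folds: dict[str, float],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    reference_id: str = "U6",
    calibrator_sample: str = "normal",
    test_sample: str = "tumor",
    base_ct_target: float = 28.0,
    base_ct_reference: float = 20.0,
) -> list[CtRecord]:
    """Triplicate Ct records whose 2^-ddCt inversion recovers ``true_folds``."""
    for t, f in true_folds.items():
        if f <= 0:
            raise DataError(f"fold for {t!r} must be positive, got {f}")
    rng = np.random.default_rng(seed)
    records: list[CtRecord] = []
    for target in sorted(true_folds):
        fold = true_folds[target]
        for _ in range(n_replicates):
            records.append(CtRecord(
                sample_id=calibrator_sample, target_id=target, reference_id=reference_id,
                ct_target=base_ct_target + rng.normal(0, ct_noise_sd) if ct_noise_sd else base_ct_target,
                ct_reference=base_ct_reference + rng.normal(0, ct_noise_sd) if ct_noise_sd else base_ct_reference,
                calibrator=True))
        for _ in range(n_replicates):
            records.append(CtRecord(
                sample_id=test_sample, target_id=target, reference_id=reference_id,
                ct_target=base_ct_target - np.log2(fold) + (rng.normal(0, ct_noise_sd) if ct_noise_sd else 0.0),
                ct_reference=base_ct_reference + (rng.normal(0, ct_noise_sd) if ct_noise_sd else 0.0),
                calibrator=False))
    return records
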