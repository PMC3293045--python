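"""Domain types and file I/O shared by all pipeline stages.

Expression matrices are log2-scale feature-by-sample tables; the staged design
(normal epithelium, tumour stages I-II / III / IV, lymph-node metastasis) is a
mapping of sample ids to ordered stage labels. Predicted miRNA-target pairs,
GMT gene-set annotation, IUPAC consensus motifs and upstream promoter sequences
all arrive as plain-text files so that every analysis step is reproducible
without live database queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from importlib import resources

logger = logging.getLogger("mirnet")

#: IUPAC nucleotide codes and the base sets they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

STAGE_LABELS: tuple[str, ...] = ("normal", "I-II", "III", "IV", "MET")


class DataError(ValueError):
    """Malformed input file or violated domain invariant."""


@dataclass(frozen=True)
class StageDesign:
    """Ordered clinical-stage design with a reference (normal) stage."""

    stages: tuple[str, ...]
    sample_to_stage: Mapping[str, str]
    reference_stage: str = "normal"

    def __post_init__(self) -> None:
        if self.reference_stage not in self.stages:
            raise DataError(f"reference stage {self.reference_stage!r} not among stages {self.stages}")
        unknown = {s for s in self.sample_to_stage.values() if s not in self.stages}
        if unknown:
            raise DataError(f"samples mapped to unknown stages: {sorted(unknown)}")
        sizes = self.stage_sizes()
        small = [s for s, c in sizes.items() if c < 2]
        if small:
            raise DataError(f"stages with <2 samples (variance not estimable): {small}")

    def stage_sizes(self) -> dict[str, int]:
        sizes = {s: 0 for s in self.stages}
        for st in self.sample_to_stage.values():
            sizes[st] += 1
        return sizes

    def samples_in(self, stage: str) -> list[str]:
        return [s for s, st in self.sample_to_stage.items() if st == stage]

    @property
    def non_reference_stages(self) -> tuple[str, ...]:
        return tuple(s for s in self.stages if s != self.reference_stage)


def study_design() -> StageDesign:
    """The study's 22-sample arm structure: 6 normal, 4 per tumour stage, 4 metastasis."""
    sizes = {"normal": 6, "I-II": 4, "III": 4, "IV": 4, "MET": 4}
    mapping: dict[str, str] = {}
    for stage, n in sizes.items():
        for i in range(n):
            mapping[f"{stage}_{i + 1}"] = stage
    return StageDesign(stages=STAGE_LABELS, sample_to_stage=mapping)


@dataclass
class ExpressionMatrix:
    """Log2 feature-by-sample expression values with a declared feature kind."""

    data: pd.DataFrame  # features x samples, float, NaN = missing
    feature_kind: str  # "miRNA" or "mRNA"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("miRNA", "mRNA"):
            raise DataError(f"feature_kind must be 'miRNA' or 'mRNA', got {self.feature_kind!r}")
        dup_f = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_f:
            raise DataError(f"duplicate feature ids: {dup_f}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_s:
            raise DataError(f"duplicate sample ids: {dup_s}")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.data.to_numpy(dtype=float, na_value=np.nan)).any():
                raise DataError("expression values must be finite or missing")

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float, na_value=np.nan)


@dataclass(frozen=True)
class TargetPairSet:
    """Predicted miRNA -> target-gene pairs (e.g. a TargetScan export)."""

    pairs: frozenset[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for m, g in self.pairs:
            if not m or not g:
                raise DataError(f"empty id in pair {(m, g)!r}")

    def __len__(self) -> int:
        return len(self.pairs)

    def genes(self) -> set[str]:
        return {g for _, g in self.pairs}

    def mirnas(self) -> set[str]:
        return {m for m, _ in self.pairs}


@dataclass(frozen=True)
class AnnotationSet:
    """Gene-set annotation: term id -> (name, member genes), optional background."""

    terms: Mapping[str, tuple[str, frozenset[str]]]
    background: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise DataError(f"term {tid!r} has an empty gene set")

    def universe(self) -> frozenset[str]:
        if self.background is not None:
            return self.background
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return frozenset(out)


@dataclass(frozen=True)
class MotifSet:
    """TF name -> IUPAC consensus binding sequence."""

    motifs: Mapping[str, str]

    def __post_init__(self) -> None:
        for tf, cons in self.motifs.items():
            bad = [c for c in cons.upper() if c not in IUPAC_CODES]
            if bad:
                raise DataError(f"motif for {tf!r} contains non-IUPAC characters: {bad}")
            if len(cons) < 4:
                raise DataError(f"motif for {tf!r} shorter than 4 bases: {cons!r}")


@dataclass(frozen=True)
class PromoterSet:
    """Upstream (promoter) sequence per pre-miRNA locus."""

    sequences: Mapping[str, str]
    window_bp: int
    truncated: frozenset[str] = frozenset()  # ids shorter than window_bp

    def __post_init__(self) -> None:
        for mid, seq in self.sequences.items():
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise DataError(f"promoter {mid!r} has non-ACGTN characters: {sorted(bad)}")
            if len(seq) > self.window_bp:
                raise DataError(f"promoter {mid!r} longer than declared window {self.window_bp}")
            if len(seq) < self.window_bp and mid not in self.truncated:
                raise DataError(f"promoter {mid!r} shorter than window but not flagged truncated")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, feature_kind: str) -> ExpressionMatrix:
    """Read a tab-separated matrix: first row sample ids, first column feature ids.

    Empty cells become missing values; non-numeric cells raise with the
    row/column address; duplicated ids raise naming the duplicate.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup = raw.index[raw.index.duplicated()].unique().tolist()
    if dup:
        raise DataError(f"{path}: duplicate feature id(s) {dup}")
    dup = raw.columns[raw.columns.duplicated()].unique().tolist()
    if dup:
        raise DataError(f"{path}: duplicate sample id(s) {dup}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna() & (raw.astype(str).apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"{path}: non-numeric cell {raw.iat[i, j]!r} at feature {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    n_missing = int(numeric.isna().to_numpy().sum())
    if n_missing:
        logger.info("%s: %d missing cells recorded as missing", path, n_missing)
    return ExpressionMatrix(data=numeric.astype(float), feature_kind=feature_kind)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id")


def read_design_tsv(path: str | Path, reference_stage: str = "normal") -> StageDesign:
    """Read a two-column sample<TAB>stage table; stage order = first appearance."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: design needs columns sample, stage")
    df = df.iloc[:, :2]
    df.columns = ["sample", "stage"]
    stages = tuple(dict.fromkeys(df["stage"]))
    return StageDesign(stages=stages, sample_to_stage=dict(zip(df["sample"], df["stage"])),
                       reference_stage=reference_stage)


def write_design_tsv(design: StageDesign, path: str | Path) -> None:
    rows = [(s, st) for s, st in design.sample_to_stage.items()]
    pd.DataFrame(rows, columns=["sample", "stage"]).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> AnnotationSet:
    """Read GMT annotation: term_id TAB description TAB gene TAB gene ..."""
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            tid, desc, *genes = fields
            genes = [g for g in genes if g]
            terms[tid] = (desc, frozenset(genes))
    if not terms:
        logger.warning("%s: empty GMT file, no terms loaded", path)
        return AnnotationSet(terms={})
    return AnnotationSet(terms=terms)


def read_target_pairs_tsv(path: str | Path, provenance: str = "") -> TargetPairSet:
    """Read predicted miRNA->gene pairs: mirna TAB gene, optional header."""
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataError(f"{path}:{lineno}: need mirna TAB gene")
            if lineno == 1 and fields[0].lower() in ("mirna", "mirna_id"):
                continue
            pairs.add((fields[0], fields[1]))
    return TargetPairSet(pairs=frozenset(pairs), provenance=provenance or str(path))


def write_target_pairs_tsv(pairs: TargetPairSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tgene\n")
        for m, g in sorted(pairs.pairs):
            fh.write(f"{m}\t{g}\n")


def read_motifs_tsv(path: str | Path) -> MotifSet:
    """Read TF motifs: tf_name TAB IUPAC consensus, optional header."""
    motifs: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataError(f"{path}:{lineno}: need tf_name TAB consensus")
            if lineno == 1 and fields[1].lower() in ("consensus", "motif", "iupac"):
                continue
            motifs[fields[0]] = fields[1].upper()
    return MotifSet(motifs=motifs)


def write_motifs_tsv(motifs: MotifSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\tconsensus\n")
        for tf, cons in sorted(motifs.motifs.items()):
            fh.write(f"{tf}\t{cons}\n")


def read_promoters_fasta(path: str | Path, window_bp: int | None = None) -> PromoterSet:
    """Read promoter FASTA; window defaults to the longest sequence present."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise DataError(f"{path}: no FASTA records")
    if window_bp is None:
        window_bp = max(len(s) for s in seqs.values())
    truncated = frozenset(m for m, s in seqs.items() if len(s) < window_bp)
    if truncated:
        logger.info("%s: %d promoters shorter than window %d", path, len(truncated), window_bp)
    return PromoterSet(sequences=seqs, window_bp=window_bp, truncated=truncated)


def write_promoters_fasta(promoters: PromoterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for mid in sorted(promoters.sequences):
            fh.write(f">{mid}\n{promoters.sequences[mid]}\n")


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# packaged fixture tables
# ---------------------------------------------------------------------------

_FIXTURE_NAMES = ("table1", "table2", "table5", "table6")


def _fixture_path(name: str):
    return resources.files("mirnet.fixtures").joinpath(f"{name}.tsv")


def load_fixture_table(name: str):
    """Load one of the packaged published tables.

    table1 -> {stage: {"down": [...], "up": [...]}} (aberrant miRNAs per stage)
    table2 -> DataFrame (mirna, aliases, mirna_direction, gene, gene_direction)
    table5 -> {stage: [TF, ...]} (promoter-binding TFs with degree >= 10)
    table6 -> DataFrame (tf, mirna, target_gene) self-repression feedback loops
    """
    if name not in _FIXTURE_NAMES:
        raise DataError(f"unknown fixture {name!r}; valid names: {_FIXTURE_NAMES}")
    with resources.as_file(_fixture_path(name)) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    if name == "table1":
        out: dict[str, dict[str, list[str]]] = {}
        for stage, sub in df.groupby("stage", sort=False):
            out[stage] = {
                "down": sub.loc[sub["direction"] == "down", "mirna"].tolist(),
                "up": sub.loc[sub["direction"] == "up", "mirna"].tolist(),
            }
        return out
    if name == "table5":
        return {stage: sub["tf"].tolist() for stage, sub in df.groupby("stage", sort=False)}
    return df  # table2, table6 as row tables


# ---------------------------------------------------------------------------
# network edge lists (definition of RegulatoryNetwork lives in networks.py)
# ---------------------------------------------------------------------------

EDGELIST_HEADER = "source\ttarget\tedge_type\tweight"


def write_network_edgelist(network, path: str | Path, graphml: str | Path | None = None) -> None:
    """Write a deterministic tab-separated edge list (and optional GraphML)."""
    rows = []
    for u, v, d in network.graph.edges(data=True):
        w = d.get("weight")
        rows.append((u, v, d.get("edge_type", ""), "" if w is None else f"{w:.6g}"))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write(EDGELIST_HEADER + "\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    if graphml is not None:
        g = network.graph.copy()
        for _, _, d in g.edges(data=True):
            if d.get("weight") is None:
                d.pop("weight", None)
        nx.write_graphml(g, graphml)


def read_network_edgelist(path: str | Path):
    """Re-read an edge list written by :func:`write_network_edgelist`."""
    from .networks import RegulatoryNetwork  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    net = RegulatoryNetwork()
    for _, row in df.iterrows():
        w = row.get("weight")
        weight = None if pd.isna(w) else float(w)
        net.add_edge(str(row["source"]), str(row["target"]), row["edge_type"], weight=weight)
    return net
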