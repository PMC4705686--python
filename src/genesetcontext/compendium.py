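"""Annotated expression compendium: data model, TSV I/O, synthesis, ordering.

A compendium is a dense genes x samples matrix of consistently normalized
expression scores (z-score-like: values near zero mean the gene is absent or
lowly expressed) together with a sample annotation that assigns every sample
to exactly one biological context -- a free-text label such as a cell type,
tissue, or disease condition. Real compendia of this shape are built from
thousands of public microarray samples normalized on a single platform; the
:func:`synthesize_compendium` generator emulates that situation with a
Gaussian baseline and context-specific implanted signal, so the rest of the
pipeline can be exercised and validated without the (large, external) real
data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from ._errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionCompendium",
    "ContextSummary",
    "SyntheticDesign",
    "read_compendium",
    "write_compendium",
    "summarize_contexts",
    "synthesize_compendium",
    "cluster_sample_order",
]


@dataclass
class ExpressionCompendium:
    """Genes x samples score matrix plus per-sample context labels.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers (e.g. ENTREZ gene IDs). Must be unique.
    sample_ids : list of str
        Column identifiers. Must be unique.
    scores : ndarray, shape (n_genes, n_samples)
        Finite expression scores.
    annotations : dict
        ``sample_id -> context label``; every sample carries exactly one label.
    platform : str
        Free-text tag describing the score provenance (e.g. array platform).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    scores: np.ndarray
    annotations: dict[str, str]
    platform: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        validate_compendium(self)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def context_labels(self) -> list[str]:
        """Context label of every sample, in sample order."""
        return [self.annotations[s] for s in self.sample_ids]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass(frozen=True)
class ContextSummary:
    context: str
    n_samples: int


@dataclass
class SyntheticDesign:
    """Recipe for a synthetic annotated compendium.

    The generated gene universe is ``g1 .. g<n_genes>``. ``contexts`` lists
    ``(label, size)`` pairs; ``implants`` lists ``(context, gene_ids, delta)``
    triples adding a constant shift ``delta`` to the named genes in every
    sample of that context. ``baseline_sd`` is the i.i.d. Gaussian noise SD
    around zero, matching the near-zero behaviour of normalized scores for
    unexpressed genes.
    """

    n_genes: int
    contexts: list[tuple[str, int]]
    implants: list[tuple[str, list[str], float]] = field(default_factory=list)
    baseline_sd: float = 1.0
    seed: int = 0

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i}" for i in range(1, self.n_genes + 1)]

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("design needs at least one gene")
        if not self.contexts:
            raise ValidationError("design needs at least one context")
        labels = [c for c, _ in self.contexts]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate context labels in design")
        for label, size in self.contexts:
            if size < 1:
                raise ValidationError(f"context {label!r} has non-positive size {size}")
        if self.baseline_sd < 0:
            raise ValidationError("baseline_sd must be >= 0")
        universe = set(self.gene_ids)
        known = set(labels)
        for ctx, genes, _delta in self.implants:
            if ctx not in known:
                raise ValidationError(f"implant references unknown context {ctx!r}")
            missing = sorted(set(genes) - universe)
            if missing:
                raise ValidationError(
                    f"implant genes not in generated universe: {missing[:5]}"
                )


def validate_compendium(comp: ExpressionCompendium) -> None:
    """Check all structural invariants; raise :class:`ValidationError`."""
    if len(comp.gene_ids) == 0 or len(comp.sample_ids) == 0:
        raise ValidationError("compendium requires >=1 gene and >=1 sample")
    if len(set(comp.gene_ids)) != len(comp.gene_ids):
        dupes = _dupes(comp.gene_ids)
        raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
    if len(set(comp.sample_ids)) != len(comp.sample_ids):
        dupes = _dupes(comp.sample_ids)
        raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
    if comp.scores.shape != (len(comp.gene_ids), len(comp.sample_ids)):
        raise ValidationError(
            f"score matrix shape {comp.scores.shape} does not match "
            f"({len(comp.gene_ids)}, {len(comp.sample_ids)})"
        )
    if not np.all(np.isfinite(comp.scores)):
        raise ValidationError("score matrix contains non-finite values")
    unannotated = [s for s in comp.sample_ids if s not in comp.annotations]
    if unannotated:
        raise ValidationError(
            f"samples missing a context annotation: {unannotated[:10]}"
        )


def _dupes(items: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in items:
        if x in seen:
            out.append(x)
        seen.add(x)
    return out


def read_compendium(matrix_path, annotation_path) -> ExpressionCompendium:
    """Read a tab-delimited score matrix and 2-column annotation table.

    The matrix file has a header row of sample IDs and a first column of gene
    IDs. The annotation file has two tab-separated columns (sample_id,
    context) and no header; it may annotate a superset of the matrix samples.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{matrix_path}: empty score matrix")
    try:
        scores = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"{matrix_path}: non-numeric cell: {exc}") from exc

    ann = pd.read_csv(
        annotation_path, sep="\t", header=None, names=["sample_id", "context"],
        dtype=str,
    )
    if ann["sample_id"].duplicated().any():
        dupes = ann.loc[ann["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{annotation_path}: duplicate sample ids {dupes[:5]}")
    if ann.isna().any().any():
        raise ValidationError(f"{annotation_path}: malformed rows (expected 2 columns)")
    lookup = dict(zip(ann["sample_id"], ann["context"]))

    sample_ids = [str(s) for s in df.columns]
    missing = [s for s in sample_ids if s not in lookup]
    if missing:
        raise ValidationError(
            f"{annotation_path}: no context annotation for samples {missing[:10]}"
        )
    annotations = {s: lookup[s] for s in sample_ids}
    return ExpressionCompendium(
        gene_ids=[str(g) for g in df.index],
        sample_ids=sample_ids,
        scores=scores,
        annotations=annotations,
    )


def write_compendium(comp: ExpressionCompendium, matrix_path, annotation_path) -> None:
    """Write matrix + annotation TSVs readable by :func:`read_compendium`.

    Scores are written with 12 significant digits. Identifiers and labels
    must not contain tab or newline characters (no quoting is performed).
    """
    for name in (*comp.gene_ids, *comp.sample_ids, *comp.annotations.values()):
        if "\t" in name or "\n" in name:
            raise ValidationError(
                f"identifier/label {name!r} contains a delimiter character"
            )
    df = pd.DataFrame(comp.scores, index=comp.gene_ids, columns=comp.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(matrix_path, sep="\t", float_format="%.12g")
    with open(annotation_path, "w", encoding="utf-8") as fh:
        for s in comp.sample_ids:
            fh.write(f"{s}\t{comp.annotations[s]}\n")


def summarize_contexts(comp: ExpressionCompendium) -> list[ContextSummary]:
    """One entry per distinct context label, in lexicographic label order."""
    counts: dict[str, int] = {}
    for label in comp.context_labels():
        counts[label] = counts.get(label, 0) + 1
    return [ContextSummary(c, n) for c, n in sorted(counts.items())]


def synthesize_compendium(design: SyntheticDesign) -> ExpressionCompendium:
    """Generate a compendium from a :class:`SyntheticDesign`.

    Baseline scores are i.i.d. Normal(0, baseline_sd^2); each implant adds
    its ``delta`` to the listed genes in that context's samples. The same
    seed yields a bit-identical matrix.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    sample_ids: list[str] = []
    annotations: dict[str, str] = {}
    ctx_columns: dict[str, list[int]] = {}
    i = 0
    for label, size in design.contexts:
        cols = []
        for _ in range(size):
            i += 1
            sid = f"s{i}"
            sample_ids.append(sid)
            annotations[sid] = label
            cols.append(i - 1)
        ctx_columns[label] = cols

    scores = rng.normal(0.0, design.baseline_sd, size=(design.n_genes, len(sample_ids)))
    gene_idx = {g: j for j, g in enumerate(design.gene_ids)}
    for ctx, genes, delta in design.implants:
        rows = [gene_idx[g] for g in genes]
        scores[np.ix_(rows, ctx_columns[ctx])] += delta
    return ExpressionCompendium(
        gene_ids=design.gene_ids,
        sample_ids=sample_ids,
        scores=scores,
        annotations=annotations,
        platform="synthetic",
    )


def cluster_sample_order(act) -> np.ndarray:
    """Leaf order of complete-linkage hierarchical clustering of samples.

    Samples are clustered on Euclidean distance between their gene-set
    activity vectors; the returned permutation is the dendrogram leaf order,
    the conventional column ordering for activity heat maps.

    Parameters
    ----------
    act : ActivityMatrix
        Activity values (sets x samples); needs >=2 samples.
    """
    values = np.asarray(act.values, dtype=float)
    if values.shape[1] < 2:
        raise ValidationError("clustering requires at least 2 samples")
    dist = pdist(values.T, metric="euclidean")
    tree = linkage(dist, method="complete")
    return np.asarray(leaves_list(tree))
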