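"""Gene-set activity: weighted average of member-gene expression per sample.

The activity of gene set *s* in sample *i* is

    y_si = sum_g w_g * x_gi / sum_g |w_g|

summed over the member genes present in the compendium. With all weights 1
this is the arithmetic mean of member-gene expression. Signed weights let a
single score track regulatory activity: a transcription factor that is
actively working drives its activated targets (w=+1) up and its repressed
targets (w=-1) down, both of which push y upward.

Member genes absent from the compendium are excluded from numerator and
denominator alike (the score renormalizes naturally) and reported per set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .compendium import ExpressionCompendium
from .genesets import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityMatrix",
    "GeneUsage",
    "compute_activity",
    "activity_moments",
    "write_activity_table",
    "read_activity_table",
]


@dataclass(frozen=True)
class GeneUsage:
    """Per-set accounting of which member genes the compendium provided."""

    n_used: int
    missing: tuple[str, ...]


@dataclass
class ActivityMatrix:
    """Gene-set x sample activity values, sample order as in the compendium."""

    set_names: list[str]
    sample_ids: list[str]
    values: np.ndarray
    usage: dict[str, GeneUsage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.set_names), len(self.sample_ids)):
            raise ValidationError(
                f"activity shape {self.values.shape} does not match "
                f"({len(self.set_names)}, {len(self.sample_ids)})"
            )
        if len(set(self.set_names)) != len(self.set_names):
            raise ValidationError("duplicate set names in activity matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("activity matrix contains non-finite values")

    @property
    def n_sets(self) -> int:
        return len(self.set_names)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, set_name: str) -> np.ndarray:
        """Activity values of one gene set across all samples."""
        try:
            i = self.set_names.index(set_name)
        except ValueError:
            raise ValidationError(f"unknown gene set {set_name!r}") from None
        return self.values[i]


def compute_activity(
    comp: ExpressionCompendium, sets: list[GeneSet]
) -> ActivityMatrix:
    """Score every gene set in every compendium sample.

    Raises :class:`ValidationError` if a set has no member gene present in
    the compendium, or if the present members carry zero total absolute
    weight (the denominator would vanish).
    """
    if not sets:
        raise ValidationError("no gene sets given")
    gene_index = comp.gene_index()
    values = np.empty((len(sets), comp.n_samples), dtype=float)
    usage: dict[str, GeneUsage] = {}
    for si, gs in enumerate(sets):
        rows, weights, missing = [], [], []
        for gene, w in gs.members:
            idx = gene_index.get(gene)
            if idx is None:
                missing.append(gene)
            else:
                rows.append(idx)
                weights.append(w)
        if not rows:
            raise ValidationError(
                f"gene set {gs.name!r}: no member gene present in the compendium"
            )
        w_arr = np.asarray(weights, dtype=float)
        denom = np.abs(w_arr).sum()
        if denom == 0:
            raise ValidationError(
                f"gene set {gs.name!r}: present members have zero total |weight|"
            )
        values[si] = w_arr @ comp.scores[rows] / denom
        usage[gs.name] = GeneUsage(n_used=len(rows), missing=tuple(missing))
        if missing:
            logger.info(
                "gene set %r: %d/%d member genes absent from compendium",
                gs.name, len(missing), len(gs),
            )
    return ActivityMatrix(
        set_names=[gs.name for gs in sets],
        sample_ids=list(comp.sample_ids),
        values=values,
        usage=usage,
    )


def activity_moments(act: ActivityMatrix, set_name: str) -> tuple[float, float]:
    """Mean and sample SD (N-1 denominator) of a set's activity over samples."""
    row = act.row(set_name)
    if row.size < 2:
        raise ValidationError("standard deviation needs at least 2 samples")
    return float(row.mean()), float(row.std(ddof=1))


def write_activity_table(act: ActivityMatrix, path) -> None:
    """Export activities as TSV (sets x samples, header row of sample ids)."""
    df = pd.DataFrame(act.values, index=act.set_names, columns=act.sample_ids)
    df.index.name = "set_name"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_activity_table(path) -> ActivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ActivityMatrix(
        set_names=[str(s) for s in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )
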