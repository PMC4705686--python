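"""Weighted gene sets: parsing, cross-species conversion, noise perturbation.

A gene set is a named list of gene identifiers with signed real weights.
Weight +1/-1 is the common case (activated vs repressed targets of a
transcription factor), but any finite nonzero weighting is allowed. Two file
formats are read: a 3-column tab-delimited format (set name, gene id,
weight) that can hold several sets in one file, and standard GMT, in which
case every gene receives unit weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import math

from ._errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "HomologMap",
    "ConversionReport",
    "parse_geneset_file",
    "write_geneset_file",
    "parse_gmt",
    "geneset_from_signed_lists",
    "parse_homolog_map",
    "convert_species",
    "perturb_gene_set",
    "remove_shared_genes",
]


@dataclass
class GeneSet:
    """Named gene set with signed per-gene weights.

    ``members`` is an ordered list of ``(gene_id, weight)`` pairs. Gene ids
    must be unique within the set, weights finite, and the total absolute
    weight positive (it is the denominator of the activity score).
    """

    name: str
    members: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")
        genes = [g for g, _ in self.members]
        if len(set(genes)) != len(genes):
            seen, dupes = set(), []
            for g in genes:
                if g in seen:
                    dupes.append(g)
                seen.add(g)
            raise ValidationError(
                f"gene set {self.name!r} has duplicate genes: {dupes[:5]}"
            )
        for g, w in self.members:
            if not math.isfinite(w):
                raise ValidationError(f"gene set {self.name!r}: non-finite weight for {g}")
        if sum(abs(w) for _, w in self.members) == 0:
            raise ValidationError(
                f"gene set {self.name!r}: total absolute weight is zero"
            )

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.members]

    @property
    def weights(self) -> dict[str, float]:
        return dict(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class HomologMap:
    """Ordered (source gene, target gene) pairs linking homologs across species.

    One source may map to several targets (one-to-many homology); exact
    duplicate pairs are rejected.
    """

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("homolog map contains duplicate pairs")

    def targets(self, source: str) -> list[str]:
        return [t for s, t in self.pairs if s == source]


@dataclass
class ConversionReport:
    """What happened during a cross-species conversion."""

    unmapped: list[str] = field(default_factory=list)
    # (target, kept_weight, discarded_weight) for duplicate-target collisions
    conflicts: list[tuple[str, float, float]] = field(default_factory=list)


def parse_geneset_file(path) -> list[GeneSet]:
    """Parse a 3-column TSV (set_name, gene_id, weight); multiple sets allowed.

    Sets are returned in first-appearance order. A first row whose third
    field is non-numeric is treated as a header and skipped with a logged
    notice; a non-numeric weight on any later row is an error, as is a
    duplicated (set, gene) pair.
    """
    groups: dict[str, list[tuple[str, float]]] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValidationError(f"{path}: empty gene-set file")
    for lineno, line in enumerate(lines, start=1):
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValidationError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        name, gene, weight_text = (p.strip() for p in parts)
        try:
            weight = float(weight_text)
        except ValueError:
            if lineno == 1:
                logger.info("%s: skipping header row %r", path, line)
                continue
            raise ValidationError(
                f"{path}:{lineno}: non-numeric weight {weight_text!r}"
            ) from None
        members = groups.setdefault(name, [])
        if any(g == gene for g, _ in members):
            raise ValidationError(
                f"{path}:{lineno}: duplicate gene {gene!r} in set {name!r}"
            )
        members.append((gene, weight))
    if not groups:
        raise ValidationError(f"{path}: no data rows")
    return [GeneSet(name, members) for name, members in groups.items()]


def write_geneset_file(sets: list[GeneSet], path) -> None:
    """Write gene sets in the 3-column TSV format read by :func:`parse_geneset_file`."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            for gene, weight in gs.members:
                fh.write(f"{gs.name}\t{gene}\t{weight:.12g}\n")


def parse_gmt(path) -> list[GeneSet]:
    """Parse a standard GMT file (name, description, genes...); unit weights."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, _description, *genes = parts
            genes = [g.strip() for g in genes if g.strip()]
            if not genes:
                raise ValidationError(f"{path}:{lineno}: GMT set {name!r} has no genes")
            if name in names:
                raise ValidationError(f"{path}:{lineno}: duplicate GMT set {name!r}")
            names.add(name)
            sets.append(GeneSet(name, [(g, 1.0) for g in genes]))
    if not sets:
        raise ValidationError(f"{path}: empty GMT file")
    return sets


def geneset_from_signed_lists(
    name: str, positive_ids: list[str], negative_ids: list[str]
) -> GeneSet:
    """Build a set from keyed-in gene lists: positives weight +1, negatives -1."""
    overlap = sorted(set(positive_ids) & set(negative_ids))
    if overlap:
        raise ValidationError(
            f"genes appear in both positive and negative lists: {overlap[:5]}"
        )
    members = [(g, 1.0) for g in positive_ids] + [(g, -1.0) for g in negative_ids]
    return GeneSet(name, members)


def parse_homolog_map(path) -> HomologMap:
    """Parse a 2-column TSV (source_gene, target_gene) homolog table."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated fields"
                )
            pairs.append((parts[0], parts[1]))
    return HomologMap(pairs)


def convert_species(
    gs: GeneSet, homolog_map: HomologMap
) -> tuple[GeneSet, ConversionReport]:
    """Map every member to its homolog(s) in another species.

    Each member is replaced by all of its mapped targets, each inheriting
    the source weight (one-to-many homology expands the set). If two sources
    map to the same target the first-seen weight is kept and the collision
    logged. Unmapped genes are dropped and listed in the report; if nothing
    maps (or total absolute weight becomes zero) the conversion fails.
    """
    by_source: dict[str, list[str]] = {}
    for s, t in homolog_map.pairs:
        by_source.setdefault(s, []).append(t)

    report = ConversionReport()
    members: list[tuple[str, float]] = []
    index: dict[str, int] = {}
    for gene, weight in gs.members:
        targets = by_source.get(gene)
        if not targets:
            report.unmapped.append(gene)
            continue
        for t in targets:
            if t in index:
                kept = members[index[t]][1]
                if kept != weight:
                    logger.warning(
                        "conversion of %r: target %r already present with weight "
                        "%g; discarding weight %g", gs.name, t, kept, weight,
                    )
                report.conflicts.append((t, members[index[t]][1], weight))
                continue
            index[t] = len(members)
            members.append((t, weight))
    if not members:
        raise ValidationError(
            f"conversion of {gs.name!r} dropped every gene (none mapped)"
        )
    if sum(abs(w) for _, w in members) == 0:
        raise ValidationError(
            f"conversion of {gs.name!r} left zero total absolute weight"
        )
    return GeneSet(gs.name, members), report


def perturb_gene_set(
    gs: GeneSet, fraction: float, gene_universe: list[str], seed: int
) -> GeneSet:
    """Replace a fraction of members by random genes from a universe.

    Exactly ``int(fraction * len(gs) + 0.5)`` members (half-up rounding),
    chosen uniformly at random, are swapped for distinct random universe
    genes not already in the set; each replacement inherits the weight of
    the member it displaces, so the set size and the multiset of weights are
    preserved. This emulates a noisy or partially wrong gene set.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError(f"fraction must be in [0, 1], got {fraction}")
    import numpy as np

    n_replace = int(fraction * len(gs) + 0.5)
    if n_replace == 0:
        return GeneSet(gs.name, list(gs.members))
    current = set(gs.genes)
    candidates = [g for g in dict.fromkeys(gene_universe) if g not in current]
    if len(candidates) < n_replace:
        raise ValidationError(
            f"universe has only {len(candidates)} genes outside the set; "
            f"{n_replace} replacements needed"
        )
    rng = np.random.default_rng(seed)
    replace_idx = set(rng.choice(len(gs), size=n_replace, replace=False).tolist())
    new_genes = rng.choice(len(candidates), size=n_replace, replace=False)
    new_iter = iter(candidates[i] for i in new_genes.tolist())
    members = [
        (next(new_iter), w) if i in replace_idx else (g, w)
        for i, (g, w) in enumerate(gs.members)
    ]
    return GeneSet(gs.name, members)


def remove_shared_genes(sets: list[GeneSet]) -> list[GeneSet]:
    """Drop genes appearing in more than one of the given sets.

    Utility for multi-pathway analyses where shared genes would couple the
    activity scores; applied only on request, never silently.
    """
    counts: dict[str, int] = {}
    for gs in sets:
        for g in gs.genes:
            counts[g] = counts.get(g, 0) + 1
    out = []
    for gs in sets:
        members = [(g, w) for g, w in gs.members if counts[g] == 1]
        if not members:
            raise ValidationError(
                f"removing shared genes empties gene set {gs.name!r}"
            )
        out.append(GeneSet(gs.name, members))
    return out
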