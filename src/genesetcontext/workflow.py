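"""End-to-end pipeline functions: analyze, activity export, simulation, plots.

These tie the modules together the way a full analysis runs: score gene-set
activities, select samples with a pattern of interest, test contexts for
enrichment, and write/plot the results. They are ordinary functions raising
:class:`~genesetcontext._errors.ValidationError` on bad input; scripts in
``examples/`` show typical invocations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # file output only; no display required
import matplotlib.pyplot as plt
import numpy as np

from ._errors import ValidationError
from .activity import ActivityMatrix, compute_activity, write_activity_table
from .compendium import (
    ExpressionCompendium,
    SyntheticDesign,
    cluster_sample_order,
    read_compendium,
    synthesize_compendium,
    write_compendium,
)
from .enrichment import EnrichmentReport, run_enrichment, write_ranking_table
from .genesets import GeneSet, parse_geneset_file, write_geneset_file
from .poi import POI, load_poi, match_samples

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_analysis",
    "run_activity_export",
    "run_simulation",
    "plot_activity",
]

_PLOT_EXTENSIONS = {".png", ".pdf", ".svg", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass
class RunConfig:
    """Paths and thresholds for a full analysis run."""

    compendium_path: str
    annotation_path: str
    geneset_path: str
    poi_path: str
    out_dir: str
    p_cutoff: float = 0.05
    fc_cutoff: float = 1.5
    plot: bool = False

    def validate(self) -> None:
        if not 0.0 < self.p_cutoff <= 1.0:
            raise ValidationError(f"p_cutoff must be in (0, 1], got {self.p_cutoff}")
        if self.fc_cutoff < 0:
            raise ValidationError(f"fc_cutoff must be >= 0, got {self.fc_cutoff}")
        for label, p in [
            ("compendium", self.compendium_path),
            ("annotations", self.annotation_path),
            ("gene sets", self.geneset_path),
            ("POI", self.poi_path),
        ]:
            if not Path(p).is_file():
                raise ValidationError(f"{label} file not found: {p}")


def run_analysis(config: RunConfig) -> EnrichmentReport:
    """Full pipeline: activity -> POI match -> enrichment -> ranking tables.

    Writes ``ranking_table.tsv`` (filtered, ranked) and ``full_table.tsv``
    (all contexts) into ``config.out_dir``, plus ``activity_plot.png`` when
    ``config.plot`` is set. Returns the in-memory report.
    """
    config.validate()
    comp = read_compendium(config.compendium_path, config.annotation_path)
    sets = parse_geneset_file(config.geneset_path)
    poi = load_poi(config.poi_path)

    act = compute_activity(comp, sets)
    n_missing = sum(len(u.missing) for u in act.usage.values())
    report = run_enrichment(comp, act, poi, config.p_cutoff, config.fc_cutoff)
    logger.info(
        "analysis: N=%d, K=%d, C=%d, %d member genes missing from compendium",
        report.n_total, report.n_selected, report.n_contexts, n_missing,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ranking_table(report.reported, out / "ranking_table.tsv")
    write_ranking_table(report.full, out / "full_table.tsv")
    if config.plot:
        try:
            plot_activity(act, poi, report, out / "activity_plot.png",
                          annotations=comp.annotations)
        except Exception:  # plotting must never corrupt tabular outputs
            logger.exception("plotting failed; tables were written")
    return report


def run_activity_export(
    compendium_path, annotation_path, geneset_path, out_path
) -> ActivityMatrix:
    """Compute activities only and write them as a sets x samples TSV."""
    comp = read_compendium(compendium_path, annotation_path)
    sets = parse_geneset_file(geneset_path)
    act = compute_activity(comp, sets)
    write_activity_table(act, out_path)
    return act


def run_simulation(design, out_prefix) -> ExpressionCompendium:
    """Generate a synthetic compendium and write analysis-ready input files.

    ``design`` is a :class:`SyntheticDesign` or the path of a JSON file with
    its fields. Writes ``<prefix>_matrix.tsv``, ``<prefix>_annotations.tsv``
    and ``<prefix>_genesets.tsv`` (the implanted gene sets, unit weights).
    """
    if not isinstance(design, SyntheticDesign):
        with open(design, encoding="utf-8") as fh:
            d = json.load(fh)
        design = SyntheticDesign(
            n_genes=int(d["n_genes"]),
            contexts=[(str(c), int(n)) for c, n in d["contexts"]],
            implants=[
                (str(ctx), [str(g) for g in genes], float(delta))
                for ctx, genes, delta in d.get("implants", [])
            ],
            baseline_sd=float(d.get("baseline_sd", 1.0)),
            seed=int(d.get("seed", 0)),
        )
    comp = synthesize_compendium(design)
    prefix = str(out_prefix)
    write_compendium(comp, f"{prefix}_matrix.tsv", f"{prefix}_annotations.tsv")
    sets = [
        GeneSet(f"implant_{ctx}", [(g, 1.0) for g in genes])
        for ctx, genes, _delta in design.implants
    ]
    if sets:
        write_geneset_file(sets, f"{prefix}_genesets.tsv")
    return comp


def plot_activity(
    act: ActivityMatrix,
    poi: POI | None,
    report: EnrichmentReport | None,
    path,
    annotations: dict[str, str] | None = None,
) -> None:
    """Export an activity figure; layout depends on the number of gene sets.

    One set: histogram of activities. Two sets: scatter plot with the
    POI-selected samples outlined and samples of the top (up to 5) reported
    contexts color-highlighted. More than two sets: heat map with samples
    ordered by complete-linkage hierarchical clustering.
    """
    path = Path(path)
    if path.suffix.lower() not in _PLOT_EXTENSIONS:
        raise ValidationError(f"unsupported image extension {path.suffix!r}")

    mask = None
    if poi is not None:
        mask = np.asarray(match_samples(poi, act), dtype=bool)

    fig, ax = plt.subplots(figsize=(7, 5))
    try:
        if act.n_sets == 1:
            _plot_histogram(ax, act, mask)
        elif act.n_sets == 2:
            _plot_scatter(ax, act, mask, report, annotations)
        else:
            _plot_heatmap(fig, ax, act)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
    finally:
        plt.close(fig)


def _plot_histogram(ax, act: ActivityMatrix, mask) -> None:
    row = act.values[0]
    ax.hist(row, bins=40, color="steelblue", alpha=0.8, label="all samples")
    if mask is not None and mask.any():
        ax.hist(row[mask], bins=40, color="firebrick", alpha=0.8, label="selected")
        ax.legend()
    ax.set_xlabel(f"{act.set_names[0]} activity")
    ax.set_ylabel("samples")


def _plot_scatter(ax, act: ActivityMatrix, mask, report, annotations) -> None:
    x, y = act.values[0], act.values[1]
    ax.scatter(x, y, s=8, c="lightgray", label="all samples")
    if mask is not None and mask.any():
        ax.scatter(x[mask], y[mask], s=14, facecolors="none",
                   edgecolors="black", linewidths=0.6, label="selected")
    if report is not None and report.reported and annotations is not None:
        labels = np.asarray([annotations[s] for s in act.sample_ids])
        cmap = plt.get_cmap("tab10")
        for i, res in enumerate(report.reported[:5]):
            in_ctx = labels == res.context
            ax.scatter(x[in_ctx], y[in_ctx], s=14, color=cmap(i),
                       label=f"{res.context} (k={res.k_c}/{res.n_c})")
    ax.set_xlabel(f"{act.set_names[0]} activity")
    ax.set_ylabel(f"{act.set_names[1]} activity")
    ax.legend(fontsize=7, loc="best")


def _plot_heatmap(fig, ax, act: ActivityMatrix) -> None:
    order = cluster_sample_order(act)
    im = ax.imshow(act.values[:, order], aspect="auto", cmap="RdBu_r",
                   interpolation="nearest")
    ax.set_yticks(range(act.n_sets), act.set_names, fontsize=7)
    ax.set_xlabel("samples (clustered)")
    fig.colorbar(im, ax=ax, label="activity")
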