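"""File-based pipeline: simulate -> write inputs -> analyze -> plot.

Everything the analysis needs lives in plain text files (score matrix,
annotations, gene sets, POI JSON), so this is the shape of a scripted,
reproducible run: simulate a compendium to disk, save a POI, run the full
analysis, and read back the ranking table it wrote.
"""

import tempfile
from pathlib import Path

from genesetcontext import (
    RunConfig,
    SyntheticDesign,
    default_poi,
    read_ranking_table,
    run_analysis,
    run_simulation,
    save_poi,
)

design = SyntheticDesign(
    n_genes=800,
    contexts=[("muscle", 30), ("liver", 60), ("brain", 60), ("blood", 50)],
    implants=[("muscle", [f"g{i}" for i in range(1, 61)], 2.0)],
    seed=5,
)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    run_simulation(design, tmp / "sim")
    save_poi(default_poi(["implant_muscle"]), tmp / "poi.json")

    report = run_analysis(RunConfig(
        compendium_path=str(tmp / "sim_matrix.tsv"),
        annotation_path=str(tmp / "sim_annotations.tsv"),
        geneset_path=str(tmp / "sim_genesets.tsv"),
        poi_path=str(tmp / "poi.json"),
        out_dir=str(tmp / "out"),
        plot=True,
    ))

    print(f"selected {report.n_selected}/{report.n_total} samples; "
          f"{len(report.reported)} enriched context(s):")
    for r in read_ranking_table(tmp / "out" / "ranking_table.tsv"):
        print(f"  {r.context}: k={r.k_c}/{r.n_c}, "
              f"fold={r.fold_change:.2f}, p_adj={r.p_adj:.3g}")
    plot = tmp / "out" / "activity_plot.png"
    print(f"histogram written: {plot.name} ({plot.stat().st_size} bytes)")
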