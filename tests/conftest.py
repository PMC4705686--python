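import numpy as np
import pytest

from genesetcontext import (
    ActivityMatrix,
    ExpressionCompendium,
    GeneSet,
    SyntheticDesign,
    synthesize_compendium,
)


def make_activity(set_names, values, sample_ids=None) -> ActivityMatrix:
    values = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(1, values.shape[1] + 1)]
    return ActivityMatrix(set_names=list(set_names), sample_ids=sample_ids,
                          values=values)


def point_in_polygon_raycast(x: float, y: float, vertices) -> bool:
    """Independent even-odd ray-casting oracle; boundary counts as inside."""
    n = len(vertices)
    # boundary check: point on any edge segment
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12:
            if min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 and \
               min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
                return True
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def random_simple_polygon(rng, n_vertices: int):
    """Random simple polygon: radial construction, rejection-sampled.

    Vertices at sorted angles around a center with varying radii are usually
    but not always simple; candidates are re-drawn until non-self-
    intersecting (validity check is input filtering only, not the oracle).
    """
    import shapely

    while True:
        angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, size=n_vertices))
        radii = rng.uniform(0.5, 2.0, size=n_vertices)
        cx, cy = rng.uniform(-1.0, 1.0, size=2)
        verts = [
            (cx + r * np.cos(a), cy + r * np.sin(a))
            for r, a in zip(radii, angles)
        ]
        if shapely.Polygon(verts).is_valid:
            return verts


@pytest.fixture
def toy_compendium() -> ExpressionCompendium:
    """3 genes x 4 samples, two contexts, hand-written scores."""
    return ExpressionCompendium(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        scores=np.array(
            [
                [10.0, 1.0, 0.5, -1.0],
                [-2.0, 9.0, 0.25, 2.0],
                [3.0, -3.0, 1.0, 0.0],
            ]
        ),
        annotations={"s1": "tumor", "s2": "tumor", "s3": "normal", "s4": "normal"},
    )


@pytest.fixture
def signed_set() -> GeneSet:
    """Activated (+1) and repressed (-1) target, as for a TF signature."""
    return GeneSet("tf_targets", [("g1", 1.0), ("g2", -1.0)])


@pytest.fixture
def implant_design() -> SyntheticDesign:
    """Small compendium with one context carrying strong implanted signal."""
    return SyntheticDesign(
        n_genes=200,
        contexts=[("hot", 15), ("bg1", 25), ("bg2", 25), ("bg3", 25)],
        implants=[("hot", [f"g{i}" for i in range(1, 31)], 3.0)],
        baseline_sd=1.0,
        seed=7,
    )


@pytest.fixture
def implant_compendium(implant_design) -> ExpressionCompendium:
    return synthesize_compendium(implant_design)
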