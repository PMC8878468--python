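"""Labeled feature datasets produced by the full synthetic pipeline.

Fields are rendered, segmented and featurized exactly as real data
would be; extracted cells are then matched back to generator truth by
centroid proximity. The resulting tables train and evaluate the gating
nodes without any archived screen data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..features import extract_features
from ..gating import CLASS_ORDERS, GatingModel, MODE_NODES, train_node
from ..segmentation import SegmentationParams, segment_cell_bodies, segment_nuclei
from .render import RenderParams, cell_for_viability, random_layout, render_field
from .truth import CellTruth


def dataset_render_params(separability: float = 1.0) -> RenderParams:
    """Small, fast fields for dataset generation (3 z-slices suffice for
    a max projection)."""
    return RenderParams(shape=(360, 360), n_z=3, z_focus=1, separability=separability)


def _segment_and_extract(field, mode: str, seg_params: SegmentationParams):
    hoechst = field.projection("hoechst")
    nuclei = segment_nuclei(hoechst, seg_params)
    bf = field.projection("brightfield")
    bodies = segment_cell_bodies(bf, nuclei, seg_params)
    channels = {ch: field.projection(ch) for ch in field.channels}
    return extract_features(nuclei, bodies, channels, mode=mode)


def _match_truth(features: pd.DataFrame, cells: list[CellTruth], tol: float = 10.0) -> pd.Series:
    """Nearest-centroid matching of extracted cells to truth cells;
    returns the truth index per feature row (NaN if unmatched)."""
    if features.empty or not cells:
        return pd.Series(np.nan, index=features.index)
    centers = np.array([c.center for c in cells])  # (x, y)
    tree = cKDTree(centers)
    pts = features[["centroid_x", "centroid_y"]].to_numpy()
    dist, idx = tree.query(pts)
    matched = pd.Series(np.where(dist <= tol, idx, np.nan), index=features.index)
    # enforce one-to-one: keep the closest claim per truth cell
    order = np.argsort(dist)
    seen: set[int] = set()
    for i in order:
        t = matched.iloc[i]
        if np.isnan(t):
            continue
        if int(t) in seen:
            matched.iloc[i] = np.nan
        else:
            seen.add(int(t))
    return matched


def render_labeled_fields(
    field_cells: list[list[CellTruth]],
    mode: str,
    seed: int,
    render_params: RenderParams | None = None,
    seg_params: SegmentationParams | None = None,
    match_tol: float = 10.0,
) -> pd.DataFrame:
    """Render each cell list as one field, run segmentation + features,
    and return the concatenated feature table with truth columns
    (``nucleus_class``, ``viability_class``, ...) for matched cells."""
    render_params = render_params or dataset_render_params()
    seg_params = seg_params or SegmentationParams()
    frames = []
    for i, cells in enumerate(field_cells):
        field, _ = render_field(cells, mode=mode, params=render_params, seed=seed + 1000 * i)
        feats = _segment_and_extract(field, mode, seg_params)
        match = _match_truth(feats, cells, match_tol)
        feats = feats[match.notna()].copy()
        matched_cells = [cells[int(t)] for t in match.dropna()]
        feats["nucleus_class"] = [c.nucleus_class for c in matched_cells]
        feats["pyknosed_subclass"] = [c.pyknosed_subclass for c in matched_cells]
        feats["viability_class"] = [c.viability_class for c in matched_cells]
        feats["fucci_state"] = [c.fucci_state for c in matched_cells]
        feats["tubulin_effect"] = [c.tubulin_effect for c in matched_cells]
        feats["mito_mass_increased"] = [c.mito_mass_increased for c in matched_cells]
        feats["membrane_permeable"] = [c.membrane_permeable for c in matched_cells]
        feats["field"] = i
        frames.append(feats.reset_index(drop=True))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def _mixed_fields(
    cell_factories,
    n_per_class: int,
    seed: int,
    render_params: RenderParams,
    cells_per_field: int = 45,
) -> list[list[CellTruth]]:
    """Interleave classes into fields of ``cells_per_field`` cells each.

    ``cell_factories`` is a list of callables (cell_id, center) -> CellTruth.
    """
    rng = np.random.default_rng(seed)
    n_classes = len(cell_factories)
    total = n_per_class * n_classes
    assignments = np.repeat(np.arange(n_classes), n_per_class)
    rng.shuffle(assignments)
    min_dist = max(render_params.min_center_distance, 2.5 * render_params.nucleus_radius)
    fields: list[list[CellTruth]] = []
    pos = 0
    while pos < total:
        k = min(cells_per_field, total - pos)
        centers = random_layout(k, render_params.shape, min_dist, rng,
                                margin=render_params.margin)
        cells = [
            cell_factories[assignments[pos + j]](j, (float(centers[j][0]), float(centers[j][1])))
            for j in range(k)
        ]
        fields.append(cells)
        pos += k
    return fields


def nucleus_class_dataset(
    n_per_class: int,
    seed: int = 0,
    separability: float = 1.0,
    render_params: RenderParams | None = None,
) -> pd.DataFrame:
    """Healthy / pyknosed / fragmented cells with ``label`` =
    nucleus class (the NUCLEI3 training distribution)."""
    rp = render_params or dataset_render_params(separability)

    # each nuclear class spans its viability-driven rendering variants so
    # the node generalizes to dying cells (mirrors training on reference
    # compound wells rather than on pristine cells)
    def cycling(variants):
        state = {"k": 0}

        def make(i, c):
            v = variants[state["k"] % len(variants)]
            state["k"] += 1
            return v(i, c)

        return make

    factories = [
        cycling([lambda i, c: CellTruth(i, c, nucleus_class="healthy")]),
        cycling([
            lambda i, c: CellTruth(i, c, nucleus_class="pyknosed",
                                   pyknosed_subclass="mitotic"),
            lambda i, c: cell_for_viability(i, c, "early_apoptotic"),
            lambda i, c: cell_for_viability(i, c, "lysed"),
        ]),
        cycling([
            lambda i, c: CellTruth(i, c, nucleus_class="fragmented"),
            lambda i, c: cell_for_viability(i, c, "late_apoptotic"),
            lambda i, c: cell_for_viability(i, c, "necrotic"),
        ]),
    ]
    df = render_labeled_fields(_mixed_fields(factories, n_per_class, seed, rp),
                               "viability", seed, rp)
    df["label"] = df["nucleus_class"]
    return df


def viability_dataset(
    n_per_class: int,
    seed: int = 0,
    separability: float = 1.0,
    render_params: RenderParams | None = None,
) -> pd.DataFrame:
    """Five viability classes with ``label`` = viability class."""
    rp = render_params or dataset_render_params(separability)
    factories = [
        (lambda v: (lambda i, c: cell_for_viability(i, c, v)))(v)
        for v in CLASS_ORDERS["VIA5"]
    ]
    df = render_labeled_fields(_mixed_fields(factories, n_per_class, seed, rp),
                               "viability", seed, rp)
    df["label"] = df["viability_class"]
    return df


def pyknosed_dataset(
    n_per_class: int,
    seed: int = 0,
    separability: float = 1.0,
    render_params: RenderParams | None = None,
) -> pd.DataFrame:
    """Pyknosed cells, mitotic vs apoptotic (Annexin ring)."""
    rp = render_params or dataset_render_params(separability)
    factories = [
        lambda i, c: CellTruth(i, c, nucleus_class="pyknosed", pyknosed_subclass="mitotic"),
        lambda i, c: CellTruth(i, c, nucleus_class="pyknosed", pyknosed_subclass="apoptotic"),
    ]
    df = render_labeled_fields(_mixed_fields(factories, n_per_class, seed, rp),
                               "multiplex", seed, rp)
    df["label"] = df["pyknosed_subclass"]
    return df


_PHENOTYPE_FLAGS = {
    "TUBULIN": ("tubulin_effect", ("no_effect", "effect")),
    "MITO": ("mito_mass_increased", ("not_increased", "increased")),
    "MEMBRANE": ("membrane_permeable", ("normal", "permeable")),
}


def phenotype_dataset(
    node_id: str,
    n_per_class: int,
    seed: int = 0,
    separability: float = 1.0,
    render_params: RenderParams | None = None,
) -> pd.DataFrame:
    """Healthy-nucleus cells with one phenotype flag off/on."""
    flag, (neg, pos) = _PHENOTYPE_FLAGS[node_id]
    rp = render_params or dataset_render_params(separability)
    factories = [
        lambda i, c: CellTruth(i, c, **{flag: False}),
        lambda i, c: CellTruth(i, c, **{flag: True}),
    ]
    df = render_labeled_fields(_mixed_fields(factories, n_per_class, seed, rp),
                               "multiplex", seed, rp)
    df["label"] = df[flag].map({False: neg, True: pos})
    return df


def fucci_dataset(
    n_per_class: int,
    seed: int = 0,
    separability: float = 1.0,
    render_params: RenderParams | None = None,
) -> pd.DataFrame:
    """Healthy cells in red / green / yellow / unlabeled FUCCI states."""
    rp = render_params or dataset_render_params(separability)
    factories = [
        (lambda s: (lambda i, c: CellTruth(i, c, fucci_state=s)))(s)
        for s in ("red", "green", "yellow", "unlabeled")
    ]
    df = render_labeled_fields(_mixed_fields(factories, n_per_class, seed, rp),
                               "fucci", seed, rp)
    df["label"] = df["fucci_state"]
    return df


def train_default_model(
    mode: str,
    seed: int = 0,
    n_per_class: int = 80,
    separability: float = 1.0,
) -> GatingModel:
    """Train every trainable node of ``mode`` on generator data.

    This is how a pipeline run bootstraps a model when no archived
    training set is available; provenance records the dataset sizes.
    """
    nodes = {}
    nodes["NUCLEI3"] = train_node(
        "NUCLEI3", nucleus_class_dataset(n_per_class, seed, separability), seed
    )
    if mode == "viability":
        nodes["VIA5"] = train_node(
            "VIA5", viability_dataset(n_per_class, seed + 1, separability), seed
        )
        nodes["PYKNOSED2"] = train_node(
            "PYKNOSED2", pyknosed_dataset(n_per_class, seed + 2, separability), seed
        )
    elif mode == "multiplex":
        nodes["PYKNOSED2"] = train_node(
            "PYKNOSED2", pyknosed_dataset(n_per_class, seed + 2, separability), seed
        )
        for i, node_id in enumerate(("TUBULIN", "MITO", "MEMBRANE")):
            nodes[node_id] = train_node(
                node_id, phenotype_dataset(node_id, n_per_class, seed + 3 + i, separability),
                seed,
            )
    elif mode == "fucci":
        nodes["FUCCI"] = train_node(
            "FUCCI", fucci_dataset(n_per_class, seed + 6, separability), seed
        )
    model = GatingModel(mode=mode, nodes=nodes)
    model.provenance = {
        "training": "synthetic generator",
        "n_per_class": n_per_class,
        "seed": seed,
        "separability": separability,
    }
    return model
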