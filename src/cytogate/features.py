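"""Per-cell feature extraction feeding every gating node.

Two versioned feature sets are defined: ``NUCLEUS_SET`` (13 features of
the nucleus / nuclear fragments) and ``BODY_SET`` (19 features of the
cell body and dye channels). Units are pixels, squared pixels and raw
intensity counts; intensity features are background-subtracted using the
field's 5th percentile per channel.

Fragmented nuclei are handled here, not in the segmenter: nucleus
objects are grouped into cells either by the cell-body label that
contains them or, absent a body mask, by centroid proximity.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops

from .segmentation import LabelMask

FEATURE_SET_VERSION = "1"

NUCLEUS_SET = [
    "nucleus_area",
    "nucleus_equivalent_diameter",
    "nucleus_perimeter",
    "nucleus_compactness",
    "nucleus_eccentricity",
    "nucleus_solidity",
    "hoechst_mean",
    "hoechst_sd",
    "hoechst_max",
    "hoechst_cv",
    "fragment_count",
    "fragment_area_fraction",
    "radial_intensity_ratio",
]

BODY_SET = [
    "body_area",
    "body_diameter",
    "body_compactness",
    "body_eccentricity",
    "body_solidity",
    "nucleus_body_ratio",
    "f488_mean",
    "f488_sd",
    "f488_p90",
    "f561_mean",
    "f561_sd",
    "f561_p90",
    "f640_mean",
    "f640_sd",
    "f640_p90",
    "ring_annexin_mean",
    "bf_texture_sd",
    "contrast_mean",
    "border_irregularity",
]

#: auxiliary nuclear-channel features used by the FUCCI gate
FUCCI_EXTRA = ["nuc488_mean", "nuc561_mean"]

MODE_REQUIRED_CHANNELS = {
    "viability": ("ch488", "ch561", "ch640"),
    "multiplex": ("ch488", "ch561", "ch640"),
    "fucci": ("ch488", "ch561"),
}
#: which channel carries the Annexin membrane signal per mode
MODE_ANNEXIN_CHANNEL = {"viability": "ch488", "multiplex": "ch640", "fucci": None}


class FeatureError(ValueError):
    pass


def _background_subtract(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    return np.clip(img - np.percentile(img, 5), 0, None)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def group_nuclei(
    nuclei: LabelMask,
    body: LabelMask | None = None,
    grouping_radius: float = 15.0,
) -> dict[int, int]:
    """Map each nucleus label to a cell id, merging nuclear fragments.

    Fragments are merged when they share a cell-body label or when their
    centroids lie within ``grouping_radius`` pixels. Cell ids are
    1..N_cells in order of the smallest member label.
    """
    n = nuclei.n_objects
    if n == 0:
        return {}
    uf = _UnionFind(n + 1)
    props = regionprops(nuclei.labels)
    centroids = {p.label: np.array(p.centroid) for p in props}

    if body is not None:
        by_body: dict[int, list[int]] = defaultdict(list)
        for p in props:
            yx = tuple(np.round(p.centroid).astype(int))
            yx = (min(yx[0], body.labels.shape[0] - 1), min(yx[1], body.labels.shape[1] - 1))
            b = int(body.labels[yx])
            if b == 0:
                vals, cnts = np.unique(
                    body.labels[nuclei.labels == p.label], return_counts=True
                )
                nz = vals > 0
                b = int(vals[nz][np.argmax(cnts[nz])]) if nz.any() else 0
            if b > 0:
                by_body[b].append(p.label)
        for labels in by_body.values():
            for lbl in labels[1:]:
                uf.union(labels[0], lbl)

    labels = sorted(centroids)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if np.linalg.norm(centroids[a] - centroids[b]) <= grouping_radius:
                uf.union(a, b)

    roots = sorted({uf.find(lbl) for lbl in labels})
    root_to_cell = {r: i + 1 for i, r in enumerate(roots)}
    return {lbl: root_to_cell[uf.find(lbl)] for lbl in labels}


def _shape_stats(mask: np.ndarray) -> dict:
    lab = mask.astype(np.int32)
    props = regionprops(lab)
    if not props:
        return {"perimeter": 0.0, "eccentricity": 0.0, "solidity": 0.0}
    p = max(props, key=lambda q: q.area)
    return {
        "perimeter": sum(q.perimeter for q in props),
        "eccentricity": p.eccentricity,
        "solidity": p.solidity,
    }


def nuclear_features(
    nuclei: LabelMask,
    hoechst_projection: np.ndarray,
    body: LabelMask | None = None,
    grouping_radius: float = 15.0,
    background_subtract: bool = True,
) -> pd.DataFrame:
    """One row per cell (grouped nuclear fragments) with ``NUCLEUS_SET``
    features plus centroid columns. Empty masks give an empty table."""
    img = np.asarray(hoechst_projection, dtype=float)
    if img.shape != nuclei.labels.shape:
        raise FeatureError("hoechst projection / nuclei mask shape mismatch")
    if background_subtract:
        img = _background_subtract(img)

    mapping = group_nuclei(nuclei, body, grouping_radius)
    if not mapping:
        return pd.DataFrame(columns=["cell_id", "centroid_x", "centroid_y", *NUCLEUS_SET]).set_index(
            "cell_id"
        )

    members: dict[int, list[int]] = defaultdict(list)
    for lbl, cid in mapping.items():
        members[cid].append(lbl)

    objects = ndi.find_objects(nuclei.labels)
    rows = []
    for cid in sorted(members):
        lbls = members[cid]
        # union bounding box
        slices = [objects[l - 1] for l in lbls if objects[l - 1] is not None]
        y0 = min(s[0].start for s in slices)
        y1 = max(s[0].stop for s in slices)
        x0 = min(s[1].start for s in slices)
        x1 = max(s[1].stop for s in slices)
        sub_lab = nuclei.labels[y0:y1, x0:x1]
        sub_img = img[y0:y1, x0:x1]
        union = np.isin(sub_lab, lbls)

        areas = {l: int(np.sum(sub_lab == l)) for l in lbls}
        total_area = sum(areas.values())
        vals = sub_img[union]
        mean_i = float(vals.mean())
        sd_i = float(vals.std())
        max_i = float(vals.max())
        cv = sd_i / mean_i if mean_i > 0 else 0.0

        shape = _shape_stats(union)
        perim = shape["perimeter"]
        compactness = 4 * math.pi * total_area / perim**2 if perim > 0 else 0.0

        # intensity-weighted centroid and radial profile
        yy, xx = np.nonzero(union)
        w = vals if vals.sum() > 0 else np.ones_like(vals)
        cy = float(np.average(yy, weights=w)) + y0
        cx = float(np.average(xx, weights=w)) + x0
        r_eq = math.sqrt(total_area / math.pi)
        d = np.hypot(yy + y0 - cy, xx + x0 - cx)
        inner = vals[d < 0.5 * r_eq]
        outer = vals[d >= 0.5 * r_eq]
        if inner.size and outer.size and outer.mean() > 0:
            radial = float(inner.mean() / outer.mean())
        else:
            radial = 1.0

        rows.append(
            {
                "cell_id": cid,
                "centroid_x": cx,
                "centroid_y": cy,
                "nucleus_area": float(total_area),
                "nucleus_equivalent_diameter": 2 * r_eq,
                "nucleus_perimeter": float(perim),
                "nucleus_compactness": min(compactness, 1.5),
                "nucleus_eccentricity": float(shape["eccentricity"]),
                "nucleus_solidity": float(shape["solidity"]),
                "hoechst_mean": mean_i,
                "hoechst_sd": sd_i,
                "hoechst_max": max_i,
                "hoechst_cv": cv,
                "fragment_count": float(len(lbls)),
                "fragment_area_fraction": 1.0 - max(areas.values()) / total_area,
                "radial_intensity_ratio": radial,
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def cell_features(
    body: LabelMask,
    nuclei: LabelMask,
    channels: dict[str, np.ndarray],
    mode: str = "viability",
    grouping_radius: float = 15.0,
    ring_width: int = 3,
    background_subtract: bool = True,
) -> pd.DataFrame:
    """One row per cell with ``BODY_SET`` features (plus FUCCI extras in
    fucci mode). ``channels`` maps channel-id to a 2-D projection;
    ``brightfield`` and ``contrast`` are optional.

    Cytoplasm is body minus nucleus; the membrane ring is the body
    boundary band of ``ring_width`` px. A cell whose body equals its
    nucleus gets zero cytoplasmic intensities and ``no_cytoplasm=True``.
    """
    if mode not in MODE_REQUIRED_CHANNELS:
        raise FeatureError(f"bad mode {mode!r}")
    for ch in MODE_REQUIRED_CHANNELS[mode]:
        if ch not in channels:
            raise FeatureError(f"mode {mode!r} requires channel {ch!r}")
    imgs = {}
    for ch, arr in channels.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape != body.labels.shape:
            raise FeatureError(f"channel {ch!r} shape mismatch with body mask")
        imgs[ch] = _background_subtract(arr) if background_subtract and ch not in (
            "brightfield",
            "contrast",
        ) else arr

    mapping = group_nuclei(nuclei, body, grouping_radius)
    cols = ["cell_id", *BODY_SET, "no_cytoplasm"] + (FUCCI_EXTRA if mode == "fucci" else [])
    if not mapping:
        return pd.DataFrame(columns=cols).set_index("cell_id")

    members: dict[int, list[int]] = defaultdict(list)
    for lbl, cid in mapping.items():
        members[cid].append(lbl)

    # nucleus label -> owning body label (majority vote over pixels)
    nuc_to_body: dict[int, int] = {}
    for lbl in mapping:
        vals, cnts = np.unique(body.labels[nuclei.labels == lbl], return_counts=True)
        nz = vals > 0
        nuc_to_body[lbl] = int(vals[nz][np.argmax(cnts[nz])]) if nz.any() else 0

    annexin_ch = MODE_ANNEXIN_CHANNEL[mode]
    rows = []
    for cid in sorted(members):
        lbls = members[cid]
        body_lbls = sorted({nuc_to_body[l] for l in lbls if nuc_to_body[l] > 0})
        body_mask = np.isin(body.labels, body_lbls) if body_lbls else np.zeros_like(
            body.labels, dtype=bool
        )
        nuc_mask = np.isin(nuclei.labels, lbls)
        if not body_mask.any():
            body_mask = nuc_mask
        cyto = body_mask & ~(nuclei.labels > 0)
        eroded = ndi.binary_erosion(body_mask, iterations=ring_width)
        ring = body_mask & ~eroded
        no_cyto = not cyto.any()

        area = float(body_mask.sum())
        shape = _shape_stats(body_mask)
        perim = shape["perimeter"]
        compactness = 4 * math.pi * area / perim**2 if perim > 0 else 0.0
        diameter = 2 * math.sqrt(area / math.pi)
        irregularity = perim / (2 * math.sqrt(math.pi * area)) if area > 0 else 0.0

        row = {
            "cell_id": cid,
            "body_area": area,
            "body_diameter": diameter,
            "body_compactness": min(compactness, 1.5),
            "body_eccentricity": float(shape["eccentricity"]),
            "body_solidity": float(shape["solidity"]),
            "nucleus_body_ratio": float(nuc_mask.sum()) / area if area > 0 else 0.0,
            "no_cytoplasm": no_cyto,
        }
        for ch in ("ch488", "ch561", "ch640"):
            prefix = f"f{ch[2:]}"
            if ch in imgs and not no_cyto:
                vals = imgs[ch][cyto]
                row[f"{prefix}_mean"] = float(vals.mean())
                row[f"{prefix}_sd"] = float(vals.std())
                row[f"{prefix}_p90"] = float(np.percentile(vals, 90))
            else:
                row[f"{prefix}_mean"] = row[f"{prefix}_sd"] = row[f"{prefix}_p90"] = 0.0
        if annexin_ch and annexin_ch in imgs and ring.any():
            row["ring_annexin_mean"] = float(imgs[annexin_ch][ring].mean())
        else:
            row["ring_annexin_mean"] = 0.0
        row["bf_texture_sd"] = (
            float(imgs["brightfield"][body_mask].std())
            if "brightfield" in imgs and body_mask.any()
            else 0.0
        )
        row["contrast_mean"] = (
            float(imgs["contrast"][body_mask].mean())
            if "contrast" in imgs and body_mask.any()
            else 0.0
        )
        row["border_irregularity"] = irregularity
        if mode == "fucci":
            for ch, name in (("ch488", "nuc488_mean"), ("ch561", "nuc561_mean")):
                row[name] = float(imgs[ch][nuc_mask].mean()) if nuc_mask.any() else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_id")


def extract_features(
    nuclei: LabelMask,
    body: LabelMask,
    channels: dict[str, np.ndarray],
    mode: str = "viability",
    grouping_radius: float = 15.0,
) -> pd.DataFrame:
    """Joined nucleus + body feature table (one row per cell)."""
    hoechst = channels.get("hoechst")
    if hoechst is None:
        raise FeatureError("channel 'hoechst' is required")
    nuc = nuclear_features(nuclei, hoechst, body, grouping_radius)
    bod = cell_features(body, nuclei, channels, mode, grouping_radius)
    return nuc.join(bod, how="inner")
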