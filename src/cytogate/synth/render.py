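"""Render synthetic multi-channel z-stack fields with exact ground truth.

Cells are drawn as 2-D Gaussian/disk primitives onto per-channel
in-focus planes; the z dimension is emulated by progressively blurring
the in-focus plane away from the focal slice; Poisson-Gaussian noise is
added last. This is deliberately simple optics — the analysis only
consumes projections and the contrast between two focal slices.

Channel semantics depend on the simulation mode:

========== =============== ================= ===================
channel     viability  multiplex         fucci
========== =============== ================= ===================
hoechst     nuclei          nuclei            nuclei
ch488       Annexin (ring)  tubulin dye       GFP (S/G2/M)
ch561       permeability    MitoTracker red   RFP (G1)
ch640       mito far-red    Annexin (ring)    unused (background)
brightfield cell bodies     cell bodies       cell bodies
========== =============== ================= ===================
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from ..segmentation import ImageField, LabelMask
from .truth import ArtifactTruth, CellTruth, TruthError

ALL_CHANNELS = ("hoechst", "ch488", "ch561", "ch640", "brightfield")

#: mode -> semantic role -> channel id
MODE_CHANNEL_ROLES = {
    "viability": {"annexin": "ch488", "permeability": "ch561", "mito": "ch640"},
    "multiplex": {"tubulin": "ch488", "mito": "ch561", "annexin": "ch640"},
    "fucci": {"gfp": "ch488", "rfp": "ch561"},
}


@dataclass
class RenderParams:
    """Geometry, intensity and noise knobs of the generator.

    ``separability`` scales every phenotype effect size; 1.0 is the
    default difficulty used throughout the test-suite, 0 makes all
    classes identical.
    """

    shape: tuple[int, int] = (1000, 1000)  # (y, x)
    n_z: int = 7
    z_focus: int = 2  # 0-based index of the in-focus slice (slice 3, 1-based)
    z_blur: float = 1.8  # px of extra Gaussian blur per slice away from focus
    nucleus_sigma: float = 4.0
    nucleus_amp: float = 8000.0
    body_radius: float = 14.0
    hoechst_background: float = 400.0
    channel_background: float = 300.0
    brightfield_background: float = 20000.0
    brightfield_body_depth: float = 4000.0
    read_noise: float = 25.0
    poisson_noise: bool = True
    crosstalk: float = 0.0  # single coefficient ch561 -> ch640
    separability: float = 1.0
    min_center_distance: float = 6.0  # packing limit: closer pairs -> rejection
    margin: float = 20.0

    @property
    def nucleus_radius(self) -> float:
        return 2.0 * self.nucleus_sigma


def _stamp_gaussian(img: np.ndarray, cx: float, cy: float, sigma: float, amp: float) -> None:
    r = max(1, int(math.ceil(4 * sigma)))
    y0, y1 = int(cy) - r, int(cy) + r + 1
    x0, x1 = int(cx) - r, int(cx) + r + 1
    sy0, sy1 = max(0, y0), min(img.shape[0], y1)
    sx0, sx1 = max(0, x0), min(img.shape[1], x1)
    if sy0 >= sy1 or sx0 >= sx1:
        return
    yy = np.arange(sy0, sy1)[:, None] - cy
    xx = np.arange(sx0, sx1)[None, :] - cx
    img[sy0:sy1, sx0:sx1] += amp * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))


def _stamp_ring(img: np.ndarray, cx: float, cy: float, radius: float, width: float, amp: float) -> None:
    r = int(math.ceil(radius + 3 * width))
    y0, y1 = int(cy) - r, int(cy) + r + 1
    x0, x1 = int(cx) - r, int(cx) + r + 1
    sy0, sy1 = max(0, y0), min(img.shape[0], y1)
    sx0, sx1 = max(0, x0), min(img.shape[1], x1)
    if sy0 >= sy1 or sx0 >= sx1:
        return
    yy = np.arange(sy0, sy1)[:, None] - cy
    xx = np.arange(sx0, sx1)[None, :] - cx
    d = np.sqrt(yy**2 + xx**2)
    img[sy0:sy1, sx0:sx1] += amp * np.exp(-((d - radius) ** 2) / (2 * width**2))


def _stamp_disk(mask: np.ndarray, cx: float, cy: float, radius: float, value: int) -> None:
    r = int(math.ceil(radius))
    y0, y1 = int(cy) - r, int(cy) + r + 1
    x0, x1 = int(cx) - r, int(cx) + r + 1
    sy0, sy1 = max(0, y0), min(mask.shape[0], y1)
    sx0, sx1 = max(0, x0), min(mask.shape[1], x1)
    if sy0 >= sy1 or sx0 >= sx1:
        return
    yy = np.arange(sy0, sy1)[:, None] - cy
    xx = np.arange(sx0, sx1)[None, :] - cx
    sel = (yy**2 + xx**2) <= radius**2
    region = mask[sy0:sy1, sx0:sx1]
    region[sel] = value


def _fragment_offsets(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    angles = rng.uniform(0, 2 * np.pi, n) + np.arange(n) * 2 * np.pi / n
    radii = rng.uniform(0.55 * radius, radius, n)
    return np.stack([radii * np.cos(angles), radii * np.sin(angles)], axis=1)


def random_layout(
    n: int,
    shape: tuple[int, int],
    min_distance: float,
    rng: np.random.Generator,
    margin: float = 20.0,
    max_tries: int = 20000,
) -> np.ndarray:
    """Dart-throwing placement of ``n`` centers (x, y) with a minimum
    pairwise distance; raises if the field cannot accommodate them."""
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(placed) < n:
        if tries > max_tries:
            raise TruthError(
                f"could not place {n} cells at min_distance={min_distance} "
                f"in field {shape} (packing too dense)"
            )
        x = rng.uniform(margin, shape[1] - margin)
        y = rng.uniform(margin, shape[0] - margin)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_distance**2 for px, py in placed):
            placed.append((x, y))
        tries += 1
    return np.array(placed)


def make_cells(
    n: int,
    rng: np.random.Generator,
    params: RenderParams | None = None,
    nucleus_class: str = "healthy",
    viability_class: str = "healthy",
    fucci_state: str = "n/a",
    min_distance: float | None = None,
    **phenotypes,
) -> list[CellTruth]:
    """Convenience constructor: ``n`` cells of one phenotype on a random
    non-touching layout."""
    params = params or RenderParams()
    if min_distance is None:
        min_distance = 4.5 * params.nucleus_sigma + 2 * params.body_radius * 0
        min_distance = max(min_distance, 2.5 * params.nucleus_radius)
    centers = random_layout(n, params.shape, min_distance, rng, margin=params.margin)
    pyk = "mitotic" if nucleus_class == "pyknosed" else "n/a"
    cells = []
    for i, (x, y) in enumerate(centers):
        kw = dict(phenotypes)
        if nucleus_class != "healthy":
            kw = {}
        cells.append(
            CellTruth(
                cell_id=i,
                center=(float(x), float(y)),
                nucleus_class=nucleus_class,
                pyknosed_subclass=phenotypes.get("pyknosed_subclass", pyk)
                if nucleus_class == "pyknosed"
                else "n/a",
                viability_class=viability_class,
                fucci_state=fucci_state,
                **{
                    k: v
                    for k, v in kw.items()
                    if k in ("tubulin_effect", "mito_mass_increased", "membrane_permeable")
                },
            )
        )
    return cells


#: viability class -> consistent nuclear morphology class (mirrors the
#: strong correlation between whole-cell and nuclear phenotypes)
VIABILITY_TO_NUCLEUS = {
    "healthy": ("healthy", "n/a"),
    "early_apoptotic": ("pyknosed", "apoptotic"),
    "late_apoptotic": ("fragmented", "n/a"),
    "necrotic": ("fragmented", "n/a"),
    "lysed": ("pyknosed", "apoptotic"),
}


def cell_for_viability(cell_id: int, center: tuple[float, float], viability: str,
                       fucci_state: str = "n/a") -> CellTruth:
    nuc, pyk = VIABILITY_TO_NUCLEUS[viability]
    return CellTruth(
        cell_id=cell_id,
        center=center,
        nucleus_class=nuc,
        pyknosed_subclass=pyk,
        viability_class=viability,
        fucci_state=fucci_state,
    )


def make_precipitate(
    shape: tuple[int, int],
    center: tuple[float, float],
    rng: np.random.Generator,
    intensity_scale: float = 8.0,
    n_steps: int = 40,
    stamp_radius: float = 3.0,
) -> ArtifactTruth:
    """Irregular (random-walk union-of-disks) precipitate blob."""
    mask = np.zeros(shape, dtype=np.int32)
    x, y = center
    for _ in range(n_steps):
        _stamp_disk(mask, x, y, stamp_radius, 1)
        step = rng.normal(0, stamp_radius, 2)
        x = float(np.clip(x + step[0], 1, shape[1] - 2))
        y = float(np.clip(y + step[1], 1, shape[0] - 2))
    return ArtifactTruth("precipitate", mask > 0, intensity_scale)


def make_autofluorescence(
    shape: tuple[int, int],
    rng: np.random.Generator,
    intensity_scale: float = 3.0,
    coverage: float = 0.75,
    n_blobs: int = 8,
) -> ArtifactTruth:
    """Broad elevated fluorescent background (soluble auto-fluorescent
    compound): a union of large disks covering roughly ``coverage`` of
    the field, so the 5th-percentile background estimate still comes
    from clean pixels."""
    mask = np.zeros(shape, dtype=np.int32)
    target = coverage * mask.size
    radius = math.sqrt(target / (n_blobs * math.pi)) * 1.4
    while mask.sum() < target:
        x = rng.uniform(0, shape[1])
        y = rng.uniform(0, shape[0])
        _stamp_disk(mask, x, y, radius, 1)
    return ArtifactTruth("autofluorescence", mask > 0, intensity_scale)


def _viability_modifiers(cell: CellTruth, p: RenderParams) -> dict:
    """Per-cell rendering modifiers derived from viability state."""
    s = p.separability
    mods = {
        "nuc_amp_scale": 1.0,
        "nuc_sigma_scale": 1.0,
        "body_radius_scale": 1.0,
        "annexin": False,
        "permeable": False,
        "mito_scale": 1.0,
    }
    v = cell.viability_class
    if v == "early_apoptotic":
        mods["annexin"] = True
        mods["mito_scale"] = 1.0 + 0.8 * s
    elif v == "late_apoptotic":
        mods.update(annexin=True, permeable=True)
        mods["nuc_amp_scale"] = 1.0 + 0.3 * s
        mods["body_radius_scale"] = 1.0 - 0.25 * s
    elif v == "necrotic":
        mods.update(permeable=True)
        mods["nuc_amp_scale"] = 1.0 - 0.45 * s
        mods["nuc_sigma_scale"] = 1.0 + 0.4 * s
        mods["body_radius_scale"] = 1.0 + 0.2 * s
        mods["mito_scale"] = 1.0 - 0.6 * s
    elif v == "lysed":
        mods.update(permeable=True)
        mods["nuc_amp_scale"] = 1.0 - 0.4 * s
        mods["nuc_sigma_scale"] = 1.0 - 0.2 * s
        mods["body_radius_scale"] = 1.0 - 0.5 * s
        mods["mito_scale"] = 1.0 - 0.8 * s
    if cell.pyknosed_subclass == "apoptotic":
        mods["annexin"] = True
    if cell.membrane_permeable:
        mods["permeable"] = True
    return mods


def render_field(
    truth: list[CellTruth],
    artifacts: list[ArtifactTruth] | None = None,
    mode: str = "viability",
    params: RenderParams | None = None,
    seed: int = 0,
    channels: tuple[str, ...] = ALL_CHANNELS,
) -> tuple[ImageField, dict[str, LabelMask]]:
    """Render one field and its ground-truth instance masks.

    Returns ``(field, masks)`` where ``masks['nuclei']`` and
    ``masks['cell_body']`` carry one label per input cell (fragments of
    a fragmented nucleus share their cell's label). Identical inputs and
    seed give bit-identical pixels.
    """
    params = params or RenderParams()
    artifacts = artifacts or []
    if mode not in MODE_CHANNEL_ROLES:
        raise TruthError(f"bad mode {mode!r}")
    rng = np.random.default_rng(seed)
    shape = params.shape
    s = params.separability

    for c in truth:
        x, y = c.center
        if not (0 <= x < shape[1] and 0 <= y < shape[0]):
            raise TruthError(f"cell {c.cell_id} center {c.center} outside field {shape}")
    if len(truth) >= 2:
        centers = np.array([c.center for c in truth])
        tree = cKDTree(centers)
        pairs = tree.query_pairs(params.min_center_distance)
        if pairs:
            raise TruthError(
                f"{len(pairs)} nucleus pairs closer than the packing limit "
                f"({params.min_center_distance} px); reduce density or spread cells"
            )

    roles = MODE_CHANNEL_ROLES[mode]
    planes = {ch: np.zeros(shape, dtype=np.float64) for ch in channels}
    nuclei_mask = np.zeros(shape, dtype=np.int32)
    body_mask = np.zeros(shape, dtype=np.int32)

    nuclear_amps: list[float] = []
    for idx, cell in enumerate(truth):
        label = idx + 1
        cx, cy = cell.center
        mods = _viability_modifiers(cell, params)

        # --- nuclear morphology on the Hoechst channel ---
        sigma = params.nucleus_sigma * mods["nuc_sigma_scale"]
        amp = params.nucleus_amp * mods["nuc_amp_scale"]
        if cell.nucleus_class == "pyknosed":
            sigma *= 1.0 - 0.38 * s
            amp *= 1.0 + 1.0 * s
        frag_centers = [(cx, cy)]
        frag_sigma = sigma
        if cell.nucleus_class == "fragmented":
            n_frag = int(rng.integers(3, 7))
            offsets = _fragment_offsets(rng, n_frag, 2.6 * params.nucleus_sigma)
            frag_centers = [(cx + dx, cy + dy) for dx, dy in offsets]
            frag_sigma = sigma * 0.45
            amp *= 1.1
        nuclear_amps.append(amp)
        if "hoechst" in planes:
            for fx, fy in frag_centers:
                _stamp_gaussian(planes["hoechst"], fx, fy, frag_sigma, amp)
        for fx, fy in frag_centers:
            _stamp_disk(nuclei_mask, fx, fy, 2.0 * frag_sigma, label)

        body_r = params.body_radius * mods["body_radius_scale"]
        _stamp_disk(body_mask, cx, cy, body_r, label)
        if "brightfield" in planes:
            _stamp_gaussian(
                planes["brightfield"], cx, cy, body_r / 1.6, -params.brightfield_body_depth
            )

        # --- dye channels by mode ---
        cyto_sigma = body_r / 1.8
        if mode == "fucci":
            red_amp = 6000.0 * s if cell.fucci_state in ("red", "yellow") else 0.0
            green_amp = 6000.0 * s if cell.fucci_state in ("green", "yellow") else 0.0
            if cell.fucci_state == "yellow":
                red_amp *= 0.75
                green_amp *= 0.75
            if red_amp and "ch561" in planes:
                _stamp_gaussian(planes["ch561"], cx, cy, sigma, red_amp)
            if green_amp and "ch488" in planes:
                _stamp_gaussian(planes["ch488"], cx, cy, sigma, green_amp)
        else:
            mito_ch = roles["mito"]
            mito_amp = 2200.0 * mods["mito_scale"]
            if cell.mito_mass_increased:
                mito_amp *= 1.0 + 1.6 * s
            if mito_ch in planes:
                _stamp_gaussian(planes[mito_ch], cx, cy, cyto_sigma, mito_amp)

            annexin_ch = roles["annexin"]
            if mods["annexin"] and annexin_ch in planes:
                _stamp_ring(planes[annexin_ch], cx, cy, body_r, 2.0, 4500.0 * s)

            if mode == "viability":
                perm_ch = roles["permeability"]
                if mods["permeable"] and perm_ch in planes:
                    _stamp_gaussian(planes[perm_ch], cx, cy, sigma * 1.2, 5500.0 * s)
            else:  # multiplex: tubulin dye doubles as permeability readout
                tub_ch = roles["tubulin"]
                if tub_ch in planes:
                    _stamp_gaussian(planes[tub_ch], cx, cy, cyto_sigma, 2500.0)
                    if cell.tubulin_effect:
                        n_puncta = int(rng.integers(6, 12))
                        for _ in range(n_puncta):
                            ang = rng.uniform(0, 2 * np.pi)
                            rad = rng.uniform(0.3, 0.9) * body_r
                            _stamp_gaussian(
                                planes[tub_ch],
                                cx + rad * np.cos(ang),
                                cy + rad * np.sin(ang),
                                1.3,
                                3500.0 * s,
                            )
                    if mods["permeable"]:
                        _stamp_gaussian(planes[tub_ch], cx, cy, sigma * 1.2, 4000.0 * s)

    # --- artifacts ---
    median_nuc_amp = float(np.median(nuclear_amps)) if nuclear_amps else params.nucleus_amp
    for art in artifacts:
        if art.footprint.shape != shape:
            raise TruthError("artifact footprint shape mismatch")
        if art.kind == "precipitate":
            if "hoechst" in planes:
                planes["hoechst"][art.footprint] += art.intensity_scale * median_nuc_amp
        else:  # autofluorescence: broad background in hoechst + 488,
            # scaled against the median nuclear amplitude so affected
            # nuclei read as high-intensity objects
            add = (art.intensity_scale - 1.0) * median_nuc_amp
            for ch in ("hoechst", "ch488"):
                if ch in planes:
                    planes[ch][art.footprint] += add

    if params.crosstalk > 0 and "ch561" in planes and "ch640" in planes:
        planes["ch640"] += params.crosstalk * planes["ch561"]

    backgrounds = {
        "hoechst": params.hoechst_background,
        "ch488": params.channel_background,
        "ch561": params.channel_background,
        "ch640": params.channel_background,
        "brightfield": params.brightfield_background,
    }

    # --- z-stacks + noise (fixed channel order for determinism) ---
    stacks: dict[str, np.ndarray] = {}
    for ch in channels:
        plane = planes[ch] + backgrounds[ch]
        stack = np.empty((params.n_z,) + shape, dtype=np.uint16)
        for k in range(params.n_z):
            blur = params.z_blur * abs(k - params.z_focus)
            z_plane = ndi.gaussian_filter(plane, blur) if blur > 0 else plane
            if params.poisson_noise:
                noisy = rng.poisson(np.clip(z_plane, 0, None)).astype(np.float64)
            else:
                noisy = z_plane.copy()
            noisy += rng.normal(0.0, params.read_noise, shape)
            stack[k] = np.clip(noisy, 0, 65535).astype(np.uint16)
        stacks[ch] = stack

    field = ImageField(
        channels=stacks,
        pixel_depth=16,
        metadata={"mode": mode, "seed": seed, "n_cells": len(truth)},
    )
    masks = {
        "nuclei": LabelMask(nuclei_mask, "nuclei"),
        "cell_body": LabelMask(body_mask, "cell_body"),
    }
    return field, masks
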