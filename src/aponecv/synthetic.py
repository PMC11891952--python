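"""Seeded generator of three-channel test scenes with ground-truth labels.

The generator emulates the staining logic of the Annexin V-Cy3 / 6-CFDA
cell-death kit as it appears in two-channel fluorescence micrographs:

* viable cells — a bright disk in the green (6-CF) channel only;
* apoptotic cells — co-localised disks in green and red (AnnCy3 bound to
  externalised phosphatidylserine while the membrane is still intact);
* necrotic cells — red signal only, rendered as overlapping punctate
  Gaussian foci inside the cell footprint (membrane rupture concentrates
  the dye in smaller formations), with no green signal.

Cells are flat-top disks with 2-px Gaussian edge feathering on a dim
background with optional low-frequency shading and Gaussian noise; the
transmitted-light plane shows all footprints at mid-gray on a bright
field.  All channels are rendered 16-bit.  Every cell draws from its own
spawned random stream, so adding a cell never reshuffles the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "SceneSpec",
    "CellTruth",
    "GroundTruth",
    "PlacementError",
    "generate_scene",
    "score_against_truth",
]

VIABLE, APOPTOTIC, NECROTIC = "viable", "apoptotic", "necrotic"


class PlacementError(RuntimeError):
    """Raised when the requested cells cannot be placed on the canvas."""

    def __init__(self, placed: int, requested: int):
        super().__init__(
            f"could only place {placed} of {requested} cells; "
            "enlarge the canvas or relax min_separation")
        self.placed = placed
        self.requested = requested


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field of view.

    ``min_separation`` is the minimum gap between cell rims in px; a
    negative value *forces touching*: cells of the classes listed in
    ``touching_classes`` are laid down as pairs whose rims overlap by
    ``|min_separation|`` px, producing fused blobs a watershed must
    split.  Touching defaults to viable cells only: fused cytoplasmic
    disks are what the green-channel watershed separates, while punctate
    necrotic signal does not optically fuse and co-localised apoptotic
    blobs are never re-split after the merge dilation.  Intensities are
    16-bit counts; the defaults give signal-to-background 10 and
    signal-to-noise well above 5, the regime the pipeline is validated
    in.
    """

    shape: tuple[int, int] = (512, 512)
    n_viable: int = 5
    n_apoptotic: int = 2
    n_necrotic: int = 3
    radius_range: tuple[float, float] = (9.0, 13.0)
    min_separation: float = 6.0
    background_level: float = 300.0
    signal_level: float = 3000.0
    noise_sd: float = 40.0
    shading_amplitude: float = 0.15
    necrotic_foci: int = 7
    touching_classes: tuple[str, ...] = (VIABLE,)
    seed: int = 0


@dataclass(frozen=True)
class CellTruth:
    center: tuple[float, float]  # (row, col)
    radius: float
    cls: str


@dataclass(frozen=True)
class GroundTruth:
    cells: tuple[CellTruth, ...]

    @property
    def counts(self) -> dict[str, int]:
        c = {VIABLE: 0, APOPTOTIC: 0, NECROTIC: 0}
        for cell in self.cells:
            c[cell.cls] += 1
        c["total"] = len(self.cells)
        return c

    def to_json(self) -> str:
        return json.dumps([asdict(c) for c in self.cells], indent=1)


def _soft_disk(shape: tuple[int, int], center: tuple[float, float],
               radius: float, feather: float = 2.0) -> np.ndarray:
    """Flat-top disk with Gaussian-feathered rim, values in [0, 1]."""
    h, w = shape
    r0 = max(int(center[0] - radius - 4 * feather), 0)
    r1 = min(int(center[0] + radius + 4 * feather) + 1, h)
    c0 = max(int(center[1] - radius - 4 * feather), 0)
    c1 = min(int(center[1] + radius + 4 * feather) + 1, w)
    out = np.zeros(shape)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(yy - center[0], xx - center[1])
    prof = np.where(d <= radius, 1.0,
                    np.exp(-0.5 * ((d - radius) / feather) ** 2))
    out[r0:r1, c0:c1] = prof
    return out


def _necrotic_profile(shape: tuple[int, int], center: tuple[float, float],
                      radius: float, n_foci: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Punctate red signal: overlapping Gaussian foci inside the footprint.

    One focus sits at the centre; the rest are spread on an inner ring,
    densely enough that neighbouring foci overlap and threshold into a
    single accumulation whose footprint approximates the cell (one
    countable object, not a scatter of specks).
    """
    sigma = max(radius / 2.8, 2.0)
    out = np.zeros(shape)
    spots = [(center[0], center[1])]
    ring_r = radius * 0.45
    n_ring = max(n_foci - 1, 0)
    phase = rng.uniform(0, 2 * np.pi)
    for i in range(n_ring):
        ang = phase + 2 * np.pi * i / n_ring
        jitter = rng.uniform(-0.1, 0.1, size=2) * radius
        spots.append((center[0] + ring_r * np.sin(ang) + jitter[0],
                      center[1] + ring_r * np.cos(ang) + jitter[1]))
    h, w = shape
    for (cy, cx) in spots:
        r0 = max(int(cy - 4 * sigma), 0)
        r1 = min(int(cy + 4 * sigma) + 1, h)
        c0 = max(int(cx - 4 * sigma), 0)
        c1 = min(int(cx + 4 * sigma) + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        out[r0:r1, c0:c1] += np.exp(-0.5 * d2 / sigma ** 2)
    peak = out.max()
    if peak > 0:
        out = out / peak
    return out


def _place_cells(spec: SceneSpec, rng: np.random.Generator,
                 radii_streams: list[np.random.Generator]
                 ) -> list[tuple[tuple[float, float], float, str]]:
    """Choose centres and radii honouring the separation policy."""
    h, w = spec.shape
    classes = ([VIABLE] * spec.n_viable + [APOPTOTIC] * spec.n_apoptotic
               + [NECROTIC] * spec.n_necrotic)
    placed: list[tuple[tuple[float, float], float, str]] = []
    touching = spec.min_separation < 0
    gap = spec.min_separation
    margin_extra = 6.0  # keep rims clear of the border (edge exclusion)

    i = 0
    while i < len(classes):
        cls = classes[i]
        stream = radii_streams[i]
        radius = stream.uniform(*spec.radius_range)
        margin = radius + margin_extra
        ok = False
        for _ in range(4000):
            cy = stream.uniform(margin, h - margin)
            cx = stream.uniform(margin, w - margin)
            min_gap = 2.0 if touching else gap
            if all(np.hypot(cy - pc[0], cx - pc[1]) >= radius + pr + min_gap
                   for (pc, pr, _) in placed):
                ok = True
                break
        if not ok:
            raise PlacementError(len(placed), len(classes))
        placed.append(((cy, cx), radius, cls))
        i += 1
        # touching mode: drop the partner right next to the cell just placed
        if (touching and cls in spec.touching_classes
                and i < len(classes) and classes[i] == cls):
            stream2 = radii_streams[i]
            radius2 = stream2.uniform(*spec.radius_range)
            for _ in range(400):
                ang = stream2.uniform(0, 2 * np.pi)
                dist = radius + radius2 + gap  # gap < 0: rims overlap
                cy2 = cy + dist * np.sin(ang)
                cx2 = cx + dist * np.cos(ang)
                m2 = radius2 + margin_extra
                if not (m2 <= cy2 <= h - m2 and m2 <= cx2 <= w - m2):
                    continue
                if all(np.hypot(cy2 - pc[0], cx2 - pc[1]) >= radius2 + pr + 2.0
                       for (pc, pr, _) in placed[:-1]):
                    placed.append(((cy2, cx2), radius2, cls))
                    break
            else:
                raise PlacementError(len(placed), len(classes))
            i += 1
    return placed


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene.

    Returns ``(stack, truth)`` where ``stack`` is a (3, H, W) uint16 array
    in channel order green, red, transmitted, and ``truth`` carries every
    cell's centre, radius and class.  Fully reproducible from
    ``spec.seed``; each cell consumes its own spawned substream.
    """
    n_cells = spec.n_viable + spec.n_apoptotic + spec.n_necrotic
    root = np.random.SeedSequence(spec.seed)
    # fixed stream layout: [scene noise, shading] + one stream per cell
    children = root.spawn(2 + n_cells)
    noise_rng = np.random.default_rng(children[0])
    shade_rng = np.random.default_rng(children[1])
    cell_rngs = [np.random.default_rng(c) for c in children[2:]]

    placed = _place_cells(spec, np.random.default_rng(root), cell_rngs)

    h, w = spec.shape
    green = np.zeros((h, w))
    red = np.zeros((h, w))
    footprints = np.zeros((h, w))
    cells = []
    for (center, radius, cls), rng in zip(placed, cell_rngs):
        disk = _soft_disk(spec.shape, center, radius)
        footprints = np.maximum(footprints, disk)
        amp = spec.signal_level * rng.uniform(0.85, 1.15)
        if cls == VIABLE:
            green += amp * disk
        elif cls == APOPTOTIC:
            green += amp * disk
            # the annexin signal decorates the rounding apoptotic cell and
            # does not extend beyond the cytoplasmic 6-CF footprint; its
            # disk is rendered slightly smaller so that the thresholded red
            # footprint stays nested inside the green one, which is the
            # geometry the subtraction logic assumes
            red_disk = _soft_disk(spec.shape, center, max(radius - 3.0, 3.0))
            red += spec.signal_level * rng.uniform(0.85, 1.15) * red_disk
        else:  # necrotic: punctate red, no green
            prof = _necrotic_profile(spec.shape, center, radius,
                                     spec.necrotic_foci, rng)
            red += amp * prof
        cells.append(CellTruth(center=(float(center[0]), float(center[1])),
                               radius=float(radius), cls=cls))

    def finish(signal: np.ndarray, rng_n: np.random.Generator) -> np.ndarray:
        img = signal + spec.background_level
        if spec.shading_amplitude > 0:
            ny, nx = shade_rng.uniform(-1, 1, 2)
            yy, xx = np.mgrid[0:h, 0:w]
            shade = np.sin(np.pi * (yy / h) + ny) * np.sin(np.pi * (xx / w) + nx)
            img = img * (1.0 + spec.shading_amplitude * 0.5 * shade)
        if spec.noise_sd > 0:
            img = img + rng_n.normal(0, spec.noise_sd, size=img.shape)
        return np.clip(np.round(img), 0, 65535).astype(np.uint16)

    green16 = finish(green, noise_rng)
    red16 = finish(red, noise_rng)
    trans = np.full((h, w), 52000.0)
    trans = np.where(footprints > 0.5, 30000.0, trans)
    trans16 = np.clip(np.round(trans), 0, 65535).astype(np.uint16)

    return np.stack([green16, red16, trans16]), GroundTruth(cells=tuple(cells))


def score_against_truth(counts, truth: GroundTruth) -> dict[str, dict[str, float]]:
    """Absolute and relative count errors per class and in total.

    ``counts`` is any object with viable/apoptotic/necrotic/total
    attributes (the pipeline's ClassCounts).
    """
    true = truth.counts
    out = {}
    for key in (VIABLE, APOPTOTIC, NECROTIC, "total"):
        pred = getattr(counts, key)
        t = true[key]
        abs_err = abs(pred - t)
        rel_err = abs_err / t if t else (0.0 if abs_err == 0 else float("inf"))
        out[key] = {"true": t, "predicted": pred,
                    "abs_error": abs_err, "rel_error": rel_err}
    return out
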