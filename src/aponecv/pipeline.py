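"""The cell-death classification pipeline.

Each field of view is a three-plane stack: green (6-CF, viable signal),
red (AnnCy3, death signal) and transmitted light.  Both fluorescence
channels are background-subtracted (rolling ball), deconvolved with the
channel's diffraction PSF, smoothed twice and auto-thresholded; the
resulting binary masks are combined by set arithmetic:

    Merge    = Green AND Red          (co-localised -> apoptotic)
    MergeD   = dilate(Merge, 1)
    Viable   = Green  minus MergeD    (green only)
    Necrotic = Red    minus MergeD    (red only)
    MergeE   = erode(MergeD, 1)

The dilation before subtraction over-covers the apoptotic halos so no
thin green or red fragments survive around them; the merge mask is eroded
back to size before its particles are counted.  Each of the three masks
is then analysed with its class-specific size/circularity gate and the
headline counts are the three accepted-particle counts, with
total = viable + apoptotic + necrotic.

Two presets exist: mode C for control/healthy samples (green-dominant;
intermeans threshold on green, watershed on both channels) and mode TR
for treated/dying samples (red-dominant; Otsu on green, and no watershed
on red because the punctate AnnCy3 signal does not fuse cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import imageops, thresholds
from .particles import GateParams, ParticleRecord, ParticleSummary, analyze_particles
from .psf_deconv import DeconvSettings, OpticsParams, deconvolve, generate_psf

__all__ = [
    "MODE_C",
    "MODE_TR",
    "PipelineConfig",
    "ClassCounts",
    "ChannelResult",
    "RunArtifacts",
    "default_gates",
    "process_channel",
    "classify",
    "total_cells",
    "SUMMARY_ROW_LABELS",
]

MODE_C = "C"
MODE_TR = "TR"

#: canonical summary-sheet row label per analysed class
SUMMARY_ROW_LABELS = {
    "green_only": "6-CF subt Merge",
    "red_only": "AnnCy3 subt Merge",
    "merge": "Merge",
}

# class-specific gates per mode: (circ_min, circ_max, size_min, size_max)
_TABLE_GATES = {
    MODE_C: {
        "merge": (0.2, 1.0, 100.0, np.inf),
        "red_only": (0.3, 1.0, 100.0, np.inf),
        "green_only": (0.2, 1.0, 100.0, np.inf),
    },
    MODE_TR: {
        "merge": (0.1, 1.0, 50.0, np.inf),
        "red_only": (0.3, 1.0, 100.0, np.inf),
        "green_only": (0.6, 1.0, 100.0, np.inf),
    },
}


def default_gates(mode: str) -> dict[str, GateParams]:
    """The validated per-class gates for a mode (10x air objective, px^2)."""
    if mode not in _TABLE_GATES:
        raise ValueError(f"unknown mode {mode!r}; expected 'C' or 'TR'")
    return {cls: GateParams(size_min=s0, size_max=s1, circ_min=c0, circ_max=c1)
            for cls, (c0, c1, s0, s1) in _TABLE_GATES[mode].items()}


@dataclass(frozen=True)
class PipelineConfig:
    """Full run configuration; defaults are the validated settings."""

    mode: str = MODE_C
    rolling_radius_green: int = 50
    rolling_radius_red: int = 30
    optics_green: OpticsParams = field(
        default_factory=lambda: OpticsParams(wavelength=488.0))
    optics_red: OpticsParams = field(
        default_factory=lambda: OpticsParams(wavelength=561.0))
    deconv: DeconvSettings = field(default_factory=DeconvSettings)
    gates: dict[str, GateParams] | None = None  # None -> default_gates(mode)
    smooth_passes: int = 2
    manual_thresholds: dict[str, float] | None = None  # channel -> intensity
    watershed_tolerance: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in (MODE_C, MODE_TR):
            raise ValueError(f"unknown mode {self.mode!r}; expected 'C' or 'TR'")
        if self.gates is not None:
            missing = {"merge", "red_only", "green_only"} - set(self.gates)
            if missing:
                raise ValueError(f"gates missing for classes: {sorted(missing)}")

    def resolved_gates(self) -> dict[str, GateParams]:
        return self.gates if self.gates is not None else default_gates(self.mode)

    def threshold_algorithm(self, channel: str) -> str:
        """Auto-threshold algorithm per channel and mode."""
        if channel == "green":
            return "default" if self.mode == MODE_C else "otsu"
        if channel == "red":
            return "triangle"
        raise ValueError(f"unknown channel {channel!r}")

    def watershed_enabled(self, channel: str) -> bool:
        """Watershed splits green in both modes, red only in mode C."""
        if channel == "green":
            return True
        if channel == "red":
            return self.mode == MODE_C
        raise ValueError(f"unknown channel {channel!r}")


@dataclass(frozen=True)
class ClassCounts:
    viable: int
    apoptotic: int
    necrotic: int

    def __post_init__(self) -> None:
        if min(self.viable, self.apoptotic, self.necrotic) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.viable + self.apoptotic + self.necrotic


@dataclass
class ChannelResult:
    """Binary mask of one processed channel plus its provenance."""

    mask: np.ndarray
    deconvolved: np.ndarray
    stages: list[tuple[str, dict]]
    threshold_algorithm: str
    threshold_intensity: float
    deconv_iterations: int


@dataclass
class RunArtifacts:
    """Everything one classified field of view produces."""

    counts: ClassCounts
    green: ChannelResult
    red: ChannelResult
    masks: dict[str, np.ndarray]        # merge, merge_dilated, merge_eroded,
                                        # viable, necrotic
    overlays: dict[str, np.ndarray]     # green_only, red_only, merge (RGB)
    summaries: dict[str, ParticleSummary]
    records: dict[str, list[ParticleRecord]]
    config: PipelineConfig


_THRESHOLDERS = {
    "default": thresholds.threshold_default,
    "otsu": thresholds.threshold_otsu,
    "triangle": thresholds.threshold_triangle,
}


def _fit_psf(optics: OpticsParams, shape: tuple[int, int]) -> np.ndarray:
    """Generate the channel PSF, shrunk (odd) if the image is small."""
    limit = min(shape)
    size = optics.psf_size
    if size > limit:
        size = limit if limit % 2 == 1 else limit - 1
        size = max(size, 15)
        optics = replace(optics, psf_size=size)
    return generate_psf(optics)


def process_channel(img: np.ndarray, channel: str,
                    cfg: PipelineConfig) -> ChannelResult:
    """Run one fluorescence channel through to its binary mask.

    Stage order: rolling-ball background subtraction, Richardson-Lucy
    deconvolution with the channel PSF, mean smoothing (``smooth_passes``
    times), auto-threshold (green: intermeans in mode C, Otsu in mode TR;
    red: triangle — unless manually overridden), binarisation, and
    watershed splitting where the mode calls for it.  Every stage is
    appended to the result's stage log with its parameters.
    """
    if channel not in ("green", "red"):
        raise ValueError(f"unknown channel {channel!r}")
    stages: list[tuple[str, dict]] = []
    radius = (cfg.rolling_radius_green if channel == "green"
              else cfg.rolling_radius_red)
    optics = cfg.optics_green if channel == "green" else cfg.optics_red

    try:
        plane = imageops.subtract_background(img, radius)
        stages.append(("subtract_background", {"radius": radius}))

        psf = _fit_psf(optics, plane.shape)
        plane, n_iter = deconvolve(plane, psf, cfg.deconv, full_output=True)
        deconvolved = plane
        stages.append(("deconvolve", {"iterations": n_iter,
                                      "psf_size": psf.shape[0],
                                      "wavelength_nm": optics.wavelength}))

        for _ in range(cfg.smooth_passes):
            plane = imageops.smooth(plane)
        stages.append(("smooth", {"passes": cfg.smooth_passes}))

        manual = (cfg.manual_thresholds or {}).get(channel)
        if manual is not None:
            algorithm = "manual"
            t_intensity = float(manual)
        else:
            algorithm = cfg.threshold_algorithm(channel)
            hist = thresholds.histogram256(plane)
            t_bin = _THRESHOLDERS[algorithm](hist)
            t_intensity = hist.bin_to_intensity(t_bin)
        stages.append(("threshold", {"algorithm": algorithm,
                                     "intensity": t_intensity}))

        mask = thresholds.apply_threshold(plane, t_intensity)
        stages.append(("binarise", {}))

        if cfg.watershed_enabled(channel):
            mask = imageops.watershed_split(mask, cfg.watershed_tolerance)
            stages.append(("watershed", {"tolerance": cfg.watershed_tolerance}))
    except Exception as exc:
        stage = stages[-1][0] if stages else "subtract_background"
        raise type(exc)(f"[{channel}/{stage}] {exc}") from exc

    return ChannelResult(mask=mask, deconvolved=deconvolved, stages=stages,
                         threshold_algorithm=algorithm,
                         threshold_intensity=t_intensity,
                         deconv_iterations=n_iter)


def classify(stack: np.ndarray, cfg: PipelineConfig) -> RunArtifacts:
    """Classify one field of view into viable / apoptotic / necrotic counts.

    ``stack`` is (3, H, W) in channel order green, red, transmitted (the
    transmitted plane is carried but not used by the computation).
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("expected a (>=2, H, W) stack: green, red[, transmitted]")
    green_img, red_img = stack[0], stack[1]
    if green_img.shape != red_img.shape:
        raise ValueError("green and red planes must share one shape")

    g = process_channel(green_img, "green", cfg)
    r = process_channel(red_img, "red", cfg)

    merge = imageops.mask_and(g.mask, r.mask)
    merge_d = imageops.dilate(merge, 1)
    viable_mask = imageops.mask_subtract(g.mask, merge_d)
    necrotic_mask = imageops.mask_subtract(r.mask, merge_d)
    merge_e = imageops.erode(merge_d, 1)

    # the subtracted masks can never intersect each other or the merge
    assert not (viable_mask & necrotic_mask).any()
    assert not (viable_mask & merge_d).any()
    assert not (necrotic_mask & merge_d).any()

    gates = cfg.resolved_gates()
    analyses = {
        "green_only": (viable_mask, gates["green_only"], g.deconvolved),
        "red_only": (necrotic_mask, gates["red_only"], r.deconvolved),
        "merge": (merge_e, gates["merge"], g.deconvolved),
    }
    records: dict[str, list[ParticleRecord]] = {}
    summaries: dict[str, ParticleSummary] = {}
    overlays: dict[str, np.ndarray] = {}
    for cls, (mask, gate, reference) in analyses.items():
        recs, summary, overlay = analyze_particles(
            mask, gate, exclude_edges=True, include_holes=True,
            reference=reference)
        records[cls] = recs
        summaries[cls] = summary
        overlays[cls] = overlay

    counts = ClassCounts(viable=summaries["green_only"].count,
                         apoptotic=summaries["merge"].count,
                         necrotic=summaries["red_only"].count)
    masks = {"green": g.mask, "red": r.mask, "merge": merge,
             "merge_dilated": merge_d, "merge_eroded": merge_e,
             "viable": viable_mask, "necrotic": necrotic_mask}
    return RunArtifacts(counts=counts, green=g, red=r, masks=masks,
                        overlays=overlays, summaries=summaries,
                        records=records, config=cfg)


def total_cells(viable: int, necrotic: int, apoptotic: int) -> int:
    """Total cells = green-only + red-only + co-localised counts."""
    if min(viable, necrotic, apoptotic) < 0:
        raise ValueError("counts must be non-negative")
    return viable + necrotic + apoptotic
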