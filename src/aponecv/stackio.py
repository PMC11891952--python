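"""Reading channel stacks and writing run outputs.

A field of view travels as a multi-page grayscale TIFF with pages in the
order green (6-CF), red (AnnCy3), transmitted light.  Outputs of a run go
to a user directory: the two deconvolved planes as TIFF, the three
overlay images as PNG, a summary table as CSV and XLSX (one row per
analysed class, in the canonical order and with the canonical labels),
and a JSON run log with every parameter needed to reproduce the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .pipeline import RunArtifacts, SUMMARY_ROW_LABELS
from .synthetic import GroundTruth

__all__ = ["ChannelStack", "StackFormatError", "read_stack", "write_scene",
           "write_outputs", "summary_frame"]

_CLASS_ORDER = ("green_only", "red_only", "merge")


class StackFormatError(ValueError):
    """The file is not a usable green/red/transmitted stack."""


@dataclass(frozen=True)
class ChannelStack:
    green: np.ndarray
    red: np.ndarray
    transmitted: np.ndarray
    source_path: str = ""
    pixel_spacing: float | None = None  # nm/px, optional metadata

    @property
    def planes(self) -> np.ndarray:
        return np.stack([self.green, self.red, self.transmitted])


def read_stack(path, channel_order: tuple[int, int, int] = (0, 1, 2)
               ) -> ChannelStack:
    """Read a multi-page TIFF as a green/red/transmitted channel stack.

    ``channel_order`` gives the page index of green, red and transmitted
    respectively, for stacks saved in a different page order.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        planes = []
        for page in tif.pages:
            arr = page.asarray()
            if arr.ndim != 2:
                raise StackFormatError(
                    f"{path.name}: page {len(planes)} is not single-channel "
                    f"grayscale (shape {arr.shape}); RGB pages are not "
                    "supported")
            planes.append(arr)
    if len(planes) < 3:
        raise StackFormatError(
            f"{path.name}: {len(planes)} page(s); a stack of green, red "
            "and transmitted light channels is required")
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise StackFormatError(f"{path.name}: pages have mixed shapes {shapes}")
    dtypes = {p.dtype for p in planes}
    if not dtypes <= {np.dtype(np.uint8), np.dtype(np.uint16)}:
        raise StackFormatError(
            f"{path.name}: unsupported dtype {dtypes}; "
            "8- or 16-bit grayscale required")
    g, r, t = (planes[i] for i in channel_order)
    return ChannelStack(green=g, red=r, transmitted=t, source_path=str(path))


def write_scene(stack: np.ndarray, truth: GroundTruth | None,
                out: Path | str, stem: str = "scene") -> dict[str, Path]:
    """Write a generated scene as the pipeline's TIFF dialect (+ truth JSON)."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    tiff_path = out / f"{stem}.tif"
    # one grayscale page per channel (never planar RGB)
    tifffile.imwrite(tiff_path, np.asarray(stack), photometric="minisblack")
    manifest = {"stack": tiff_path}
    if truth is not None:
        truth_path = out / f"{stem}.truth.json"
        truth_path.write_text(truth.to_json())
        manifest["truth"] = truth_path
    return manifest


def summary_frame(artifacts: RunArtifacts) -> pd.DataFrame:
    """The run's summary table: one row per analysed class."""
    rows = []
    for cls in _CLASS_ORDER:
        s = artifacts.summaries[cls]
        rows.append({
            "Slice": SUMMARY_ROW_LABELS[cls],
            "Count": s.count,
            "Total Area": s.total_area,
            "Average Size": s.average_size,
            "%Area": s.percent_area,
            "Mean": s.mean,
            "IntDen": s.integrated_density,
        })
    return pd.DataFrame(rows)


def _run_log(artifacts: RunArtifacts) -> dict:
    cfg = artifacts.config
    return {
        "mode": cfg.mode,
        "rolling_radius_green": cfg.rolling_radius_green,
        "rolling_radius_red": cfg.rolling_radius_red,
        "smooth_passes": cfg.smooth_passes,
        "deconv": {
            "wiener_gamma": cfg.deconv.wiener_gamma,
            "lowpass_xy": cfg.deconv.lowpass_xy,
            "max_iterations": cfg.deconv.max_iterations,
            "termination_change": cfg.deconv.termination_change,
        },
        "channels": {
            name: {
                "threshold_algorithm": ch.threshold_algorithm,
                "threshold_intensity": ch.threshold_intensity,
                "deconv_iterations": ch.deconv_iterations,
                "stages": [{"stage": s, **params} for s, params in ch.stages],
            }
            for name, ch in (("green", artifacts.green), ("red", artifacts.red))
        },
        "gates": {
            cls: {"size_min": g.size_min,
                  "size_max": ("inf" if np.isinf(g.size_max) else g.size_max),
                  "circ_min": g.circ_min, "circ_max": g.circ_max}
            for cls, g in cfg.resolved_gates().items()
        },
        "counts": {
            "viable": artifacts.counts.viable,
            "apoptotic": artifacts.counts.apoptotic,
            "necrotic": artifacts.counts.necrotic,
            "total": artifacts.counts.total,
        },
    }


def write_outputs(artifacts: RunArtifacts, outdir, stem: str = "run"
                  ) -> dict[str, Path]:
    """Write all artifacts of a classified field of view.

    Everything is rendered in memory before the first byte is written, so
    an unwritable directory fails before any partial output exists.
    Returns the manifest of created files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not outdir.is_dir():
        raise IOError(f"not a writable directory: {outdir}")

    # render everything first
    frame = summary_frame(artifacts)
    csv_text = frame.to_csv(index=False)
    log_text = json.dumps(_run_log(artifacts), indent=1)

    manifest: dict[str, Path] = {}
    for name, ch in (("green", artifacts.green), ("red", artifacts.red)):
        p = outdir / f"{stem}_deconvolved_{name}.tif"
        tifffile.imwrite(p, np.asarray(ch.deconvolved))
        manifest[f"deconvolved_{name}"] = p
    for cls in _CLASS_ORDER:
        p = outdir / f"{stem}_overlay_{cls}.png"
        iio.imwrite(p, artifacts.overlays[cls])
        manifest[f"overlay_{cls}"] = p
    csv_path = outdir / f"{stem}_summary.csv"
    csv_path.write_text(csv_text)
    manifest["summary_csv"] = csv_path
    xlsx_path = outdir / f"{stem}_summary.xlsx"
    frame.to_excel(xlsx_path, index=False)
    manifest["summary_xlsx"] = xlsx_path
    log_path = outdir / f"{stem}_log.json"
    log_path.write_text(log_text)
    manifest["log"] = log_path
    return manifest
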