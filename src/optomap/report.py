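"""Rendering, persistence and logging of mapping experiments.

* heat maps: regions overlaid on the field-of-view image, colored with
  an alpha ramp proportional to heat (sharing the evaluator's clip
  rule), with a sidecar JSON linking each region to its exported
  waveform file — the portable stand-in for clicking a region in an
  interactive figure;
* per-region waveform exports (overlaid trials + mean, plus raw CSV);
* the experiment archive: every input and output of an analysis in one
  directory with a content-hash manifest, so the analysis can be
  reproduced bit-for-bit from the archive alone;
* an append-only, timestamped experiment log.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from types import SimpleNamespace

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Ellipse as MplEllipse
from matplotlib.patches import Polygon as MplPolygon
from matplotlib.patches import Rectangle as MplRectangle

from . import epochs as _epochs
from . import geometry as _geometry
from . import rigsim as _rigsim
from .evaluate import aggregate, clip_heat
from .protocol import Protocol

__all__ = [
    "HeatMapFigure",
    "ExperimentLog",
    "ArchiveError",
    "heat_to_alpha",
    "render_heatmap",
    "export_waveforms",
    "save_results",
    "save_archive",
    "load_archive",
    "verify_archive",
    "reanalyze_archive",
    "log_open",
    "log_append",
]

#: Conventional clip level (mV) for presentation, keeping action
#: potentials from dwarfing subthreshold responses on the map.
DEFAULT_RENDER_CLIP = 30.0


class ArchiveError(RuntimeError):
    """Archive missing files or failing its manifest integrity check."""


# ---------------------------------------------------------------------------
# Heat maps
# ---------------------------------------------------------------------------

def heat_to_alpha(heat: float, scale_min: float, scale_max: float,
                  clip: float | None = None) -> float:
    """Affine-monotone alpha mapping with the evaluator's clip rule:
    ``(min(heat, clip) - scale_min) / (scale_max - scale_min)``,
    clamped to [0, 1]; ``nan`` for undefined heats."""
    if scale_min == scale_max:
        raise ValueError("scale_min and scale_max must differ")
    if heat is None or math.isnan(heat):
        return float("nan")
    a = (clip_heat(heat, clip) - scale_min) / (scale_max - scale_min)
    return float(min(1.0, max(0.0, a)))


def _region_patch(region, **style):
    """Build a matplotlib patch from a region geometry: an ROI, a
    SmartGrid cell, or a plain bounds tuple."""
    if hasattr(region, "kind"):  # ROI
        if region.kind == "rectangle":
            x0, y0, x1, y1 = region.params
            return MplRectangle((x0, y0), x1 - x0, y1 - y0, **style)
        if region.kind == "ellipse":
            cx, cy, rx, ry = region.params
            return MplEllipse((cx, cy), 2 * rx, 2 * ry, **style)
        return MplPolygon(np.asarray(region.params), closed=True, **style)
    bounds = region.bounds if hasattr(region, "bounds") else tuple(region)
    x0, y0, x1, y1 = bounds
    return MplRectangle((x0, y0), x1 - x0, y1 - y0, **style)


@dataclass
class HeatMapFigure:
    path: str | None
    alphas: dict
    scale: tuple
    clip: float | None
    units: str
    sidecar_path: str | None = None
    waveform_index: dict = field(default_factory=dict)


def render_heatmap(heat_results, regions: dict, background=None,
                   scale=(0.0, DEFAULT_RENDER_CLIP),
                   clip: float | None = DEFAULT_RENDER_CLIP,
                   units: str = "mV", out_path=None,
                   color=(1.0, 0.0, 0.0), waveform_index: dict | None = None,
                   ) -> HeatMapFigure:
    """Render a heat map over the field-of-view image.

    Each region is filled with a single hue whose alpha is the
    normalized, clipped heat; undefined heats are hatched and
    transparent.  A color bar is drawn in the evaluator's units.  A
    sidecar JSON next to ``out_path`` records per-region heat, alpha
    and (optionally) the path of the region's waveform export.
    """
    scale_min, scale_max = scale
    missing = [hr.pattern_id for hr in heat_results if hr.pattern_id not in regions]
    if missing:
        raise KeyError(f"no region geometry for pattern(s): {missing}")
    alphas = {hr.pattern_id: heat_to_alpha(hr.heat, scale_min, scale_max, clip)
              for hr in heat_results}

    fig, ax = plt.subplots(figsize=(7, 6))
    if background is not None:
        bg = _geometry.load_image(background) if isinstance(background, (str, Path)) \
            else np.asarray(background)
        ax.imshow(bg, cmap="gray", origin="upper")
    for hr in heat_results:
        a = alphas[hr.pattern_id]
        if math.isnan(a):
            patch = _region_patch(regions[hr.pattern_id], facecolor="none",
                                  edgecolor="gray", hatch="//", linewidth=0.5)
        else:
            patch = _region_patch(regions[hr.pattern_id],
                                  facecolor=(*color, a),
                                  edgecolor=(*color, 0.4), linewidth=0.5)
        ax.add_patch(patch)
    ax.autoscale_view()
    if background is None:
        ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_xlabel("x (camera px)")
    ax.set_ylabel("y (camera px)")
    cmap = matplotlib.colors.LinearSegmentedColormap.from_list(
        "heat", [(*color, 0.0), (*color, 1.0)])
    sm = matplotlib.cm.ScalarMappable(
        norm=matplotlib.colors.Normalize(scale_min, scale_max), cmap=cmap)
    fig.colorbar(sm, ax=ax, label=units)

    sidecar_path = None
    if out_path is not None:
        out_path = Path(out_path)
        fig.savefig(out_path, dpi=120)
        sidecar_path = out_path.with_suffix(".regions.json")
        sidecar = {
            hr.pattern_id: {
                "heat": None if math.isnan(hr.heat) else hr.heat,
                "alpha": None if math.isnan(alphas[hr.pattern_id])
                else alphas[hr.pattern_id],
                "n_trials": hr.n_trials,
                "n_rejected": hr.n_rejected,
                "waveforms": (waveform_index or {}).get(hr.pattern_id),
            }
            for hr in heat_results
        }
        sidecar_path.write_text(json.dumps(sidecar, indent=2))
        sidecar_path = str(sidecar_path)
    plt.close(fig)
    return HeatMapFigure(path=str(out_path) if out_path else None,
                         alphas=alphas, scale=(scale_min, scale_max),
                         clip=clip, units=units, sidecar_path=sidecar_path,
                         waveform_index=waveform_index or {})


# ---------------------------------------------------------------------------
# Waveform export
# ---------------------------------------------------------------------------

def export_waveforms(epochs, pattern_id: str, out_path,
                     stim_duration: float | None = None) -> dict:
    """Export the per-trial waveforms behind one region's heat value.

    Writes a PNG with every trial overlaid (thin) plus the mean trace
    (bold), the stimulation window shaded when ``stim_duration`` is
    given, and a CSV of time (s, zero at onset) versus per-trial mV.
    """
    group = [e for e in epochs if e.pattern_id == pattern_id]
    if not group:
        raise KeyError(f"no epochs for pattern {pattern_id!r}")
    out_path = Path(out_path)
    t = group[0].time
    traces = np.stack([e.samples for e in group])
    mean = traces.mean(axis=0)

    fig, ax = plt.subplots(figsize=(6, 4))
    for tr in traces:
        ax.plot(t, tr, color="0.6", linewidth=0.7)
    ax.plot(t, mean, color="k", linewidth=1.6, label=f"mean of {len(group)}")
    if stim_duration is not None:
        ax.axvspan(0.0, stim_duration, color="tab:blue", alpha=0.15)
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel("membrane potential (mV)")
    ax.set_title(pattern_id)
    ax.legend(frameon=False)
    png_path = out_path.with_suffix(".png")
    fig.savefig(png_path, dpi=120)
    plt.close(fig)

    csv_path = out_path.with_suffix(".csv")
    df = pd.DataFrame({"time_s": t})
    for i, tr in enumerate(traces):
        df[f"trial_{i}"] = tr
    df["mean"] = mean
    df.to_csv(csv_path, index=False)
    return {"pattern_id": pattern_id, "n_trials": len(group),
            "png": str(png_path), "csv": str(csv_path)}


def save_results(heat_results, json_path=None, csv_path=None) -> None:
    """Emit aggregated results as JSON records and/or a flat CSV."""
    if json_path is not None:
        Path(json_path).write_text(json.dumps(
            [hr.to_dict() for hr in heat_results], indent=2))
    if csv_path is not None:
        pd.DataFrame([{"pattern_id": hr.pattern_id,
                       "heat": hr.heat,
                       "n_trials": hr.n_trials,
                       "n_rejected": hr.n_rejected}
                      for hr in heat_results]).to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# Experiment archive
# ---------------------------------------------------------------------------

_ARCHIVE_FILES = {
    "recording": "recording.h5",
    "masks_tiff": "masks.tif",
    "masks_json": "masks.json",
    "protocol": "protocol.json",
    "results_json": "results.json",
    "results_csv": "results.csv",
    "params": "params.json",
}
_MANIFEST = "manifest.json"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def save_archive(protocol, masks, recording, heat_results, params: dict,
                 out_dir, epochs=None, transform=None) -> dict:
    """Write the full experiment to a directory with a hash manifest.

    The manifest is written last (atomically via rename), so a partial
    write leaves no manifest and the archive is detectably incomplete.
    Re-running the analysis from the archive alone
    (:func:`reanalyze_archive`) reproduces the heats bit-for-bit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _rigsim.save_recording(recording, out_dir / _ARCHIVE_FILES["recording"])
    _geometry.save_masks(list(masks.values()) if isinstance(masks, dict) else masks,
                         out_dir / _ARCHIVE_FILES["masks_tiff"],
                         out_dir / _ARCHIVE_FILES["masks_json"],
                         transform=transform)
    protocol.to_json(out_dir / _ARCHIVE_FILES["protocol"])
    save_results(heat_results, out_dir / _ARCHIVE_FILES["results_json"],
                 out_dir / _ARCHIVE_FILES["results_csv"])
    (out_dir / _ARCHIVE_FILES["params"]).write_text(json.dumps(params, indent=2))
    files = list(_ARCHIVE_FILES.values())
    if epochs is not None:
        _epochs.save_epochs(epochs, out_dir / "epochs.h5")
        files.append("epochs.h5")

    manifest = {"files": {name: _sha256(out_dir / name) for name in files},
                "created": datetime.now().isoformat()}
    tmp = out_dir / (_MANIFEST + ".tmp")
    tmp.write_text(json.dumps(manifest, indent=2))
    os.replace(tmp, out_dir / _MANIFEST)
    return manifest


def verify_archive(archive_dir) -> dict:
    """Check the manifest and every content hash; raise
    :class:`ArchiveError` naming the offending file otherwise."""
    archive_dir = Path(archive_dir)
    mpath = archive_dir / _MANIFEST
    if not mpath.exists():
        raise ArchiveError(f"archive manifest missing: {mpath}")
    manifest = json.loads(mpath.read_text())
    for name, digest in manifest["files"].items():
        fpath = archive_dir / name
        if not fpath.exists():
            raise ArchiveError(f"archive file missing: {fpath}")
        if _sha256(fpath) != digest:
            raise ArchiveError(f"archive integrity failure: {fpath} does not "
                               "match its manifest hash")
    return manifest


def load_archive(archive_dir):
    """Verify and load an archive; returns a namespace with protocol,
    masks, transform, recording, params and results."""
    archive_dir = Path(archive_dir)
    verify_archive(archive_dir)
    protocol = Protocol.from_json(archive_dir / _ARCHIVE_FILES["protocol"])
    masks, transform = _geometry.load_masks(
        archive_dir / _ARCHIVE_FILES["masks_tiff"],
        archive_dir / _ARCHIVE_FILES["masks_json"])
    recording = _rigsim.load_recording(archive_dir / _ARCHIVE_FILES["recording"])
    params = json.loads((archive_dir / _ARCHIVE_FILES["params"]).read_text())
    results = json.loads((archive_dir / _ARCHIVE_FILES["results_json"]).read_text())
    return SimpleNamespace(protocol=protocol, masks={m.id: m for m in masks},
                           transform=transform, recording=recording,
                           params=params, results=results)


def reanalyze_archive(archive_dir):
    """Re-run segmentation + aggregation purely from archive contents."""
    a = load_archive(archive_dir)
    p = a.params
    eps = _epochs.segment(a.recording, a.protocol,
                          pre=p.get("pre", 0.05), post=p.get("post", 0.5))
    return aggregate(eps, evaluator=p.get("evaluator", "max_depolarization"),
                     params=p.get("evaluator_params", {}),
                     reject=p.get("reject", True),
                     reject_params=p.get("reject_params", {}),
                     group_by=p.get("group_by", "pattern_id"))


# ---------------------------------------------------------------------------
# Experiment log
# ---------------------------------------------------------------------------

@dataclass
class ExperimentLog:
    """Append-only plain-text log: one ISO-8601-stamped entry per line.

    Appending never rewrites prior content and the file is flushed
    after every entry, so the log survives crashes mid-experiment.
    """

    path: str


def log_open(path) -> ExperimentLog:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:  # fail now, not at first append
        with open(path, "a", encoding="utf-8"):
            pass
    except OSError as exc:
        raise OSError(f"log path not writable: {path}") from exc
    return ExperimentLog(path=str(path))


def log_append(log: ExperimentLog, text: str, source: str = "user") -> None:
    entry = f"{datetime.now().isoformat()} [{source}] {text}\n"
    with open(log.path, "a", encoding="utf-8") as f:
        f.write(entry)
        f.flush()
        os.fsync(f.fileno())
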