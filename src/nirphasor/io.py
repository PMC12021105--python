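"""File I/O: spectra as CSV, frames and result planes as TIFF with JSON
sidecars, gates as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .camera import IntensityImage
from .phasor import PhasorImage
from .synth import Spectrum

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "write_frame_stack",
    "read_frame_stack",
    "write_phasor_image",
    "read_phasor_image",
    "write_histogram_csv",
    "write_gates_json",
    "read_gates_json",
]

FRAME_KINDS = ("sine", "cosine", "total")


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    pd.DataFrame({
        "wavelength_nm": spectrum.wavelengths,
        "intensity": spectrum.intensity,
    }).to_csv(path, index=False)


def read_spectrum_csv(path) -> Spectrum:
    """Two-column CSV (wavelength_nm, intensity); the header is optional."""
    first = pd.read_csv(path, nrows=1, header=None)
    try:
        float(first.iloc[0, 0])
        header = None
    except (TypeError, ValueError):
        header = 0
    df = pd.read_csv(path, header=header)
    if df.shape[1] < 2:
        raise ValueError("spectrum CSV needs two columns")
    return Spectrum(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_frame_stack(path, frames: dict, metadata: dict | None = None) -> None:
    """Write the sine/cosine/total frames as a 3-page 16-bit TIFF.

    A JSON sidecar (``<path>.json``) records the page order, filter
    settings and camera parameters.  Frame kinds must be exactly
    {sine, cosine, total}.
    """
    if set(frames) != set(FRAME_KINDS):
        raise ValueError(f"frame kinds must be exactly {set(FRAME_KINDS)}")
    arrays = []
    for kind in FRAME_KINDS:
        data = np.asarray(getattr(frames[kind], "data", frames[kind]))
        arrays.append(np.clip(np.rint(data), 0, 65535).astype(np.uint16))
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError("the three frames must share a shape")
    tifffile.imwrite(path, np.stack(arrays), photometric="minisblack",
                     planarconfig="separate")
    sidecar = {"pages": list(FRAME_KINDS), "metadata": metadata or {}}
    for kind in FRAME_KINDS:
        frame = frames[kind]
        if isinstance(frame, IntensityImage):
            sidecar.setdefault("frames", {})[kind] = {
                "exposure_s": frame.exposure,
                **{k: v for k, v in frame.meta.items() if k == "filter"},
            }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_frame_stack(path) -> tuple[dict, dict]:
    """Read a three-frame TIFF stack; returns (frames, sidecar)."""
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    pages = sidecar.get("pages", [])
    if set(pages) != set(FRAME_KINDS):
        raise ValueError(f"sidecar frame kinds must be exactly {set(FRAME_KINDS)}")
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError("expected a 3-page frame stack")
    frames = {kind: stack[i].astype(float) for i, kind in enumerate(pages)}
    return frames, sidecar


def write_phasor_image(path, phasor: PhasorImage) -> None:
    """Persist (G, S, mask) as a 3-plane 32-bit float TIFF + provenance JSON."""
    planes = np.stack([
        phasor.g.astype(np.float32),
        phasor.s.astype(np.float32),
        phasor.valid.astype(np.float32),
    ])
    tifffile.imwrite(path, planes, photometric="minisblack",
                     planarconfig="separate")
    with open(_sidecar_path(path), "w") as fh:
        json.dump({"planes": ["G", "S", "mask"],
                   "provenance": _jsonable(phasor.provenance)}, fh, indent=2)


def read_phasor_image(path) -> PhasorImage:
    planes = tifffile.imread(path)
    if planes.ndim != 3 or planes.shape[0] != 3:
        raise ValueError("expected a 3-plane phasor TIFF")
    sidecar_path = _sidecar_path(path)
    provenance = {}
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            provenance = json.load(fh).get("provenance", {})
    return PhasorImage(planes[0].astype(float), planes[1].astype(float),
                       planes[2] > 0.5, provenance)


def write_histogram_csv(path, counts, g_edges, s_edges) -> None:
    g_centers = 0.5 * (g_edges[:-1] + g_edges[1:])
    s_centers = 0.5 * (s_edges[:-1] + s_edges[1:])
    gg, ss = np.meshgrid(g_centers, s_centers, indexing="ij")
    pd.DataFrame({
        "G": gg.ravel(), "S": ss.ravel(), "count": np.asarray(counts).ravel(),
    }).to_csv(path, index=False)


def write_gates_json(path, polygons) -> None:
    with open(path, "w") as fh:
        json.dump([{"label": int(label),
                    "vertices": np.asarray(verts, dtype=float).tolist()}
                   for label, verts in polygons], fh, indent=2)


def read_gates_json(path) -> list[tuple[int, np.ndarray]]:
    with open(path) as fh:
        gates = json.load(fh)
    return [(int(g["label"]), np.asarray(g["vertices"], dtype=float))
            for g in gates]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
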