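"""File I/O: frame sequences (TIFF/PNG + JSON sidecar), masks (PNG 0/255), tables (CSV)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .phantom import CavityShape, FrameSequence, PhantomConfig


def _config_to_dict(config: PhantomConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cavity"] = dataclasses.asdict(config.cavity)
    return d


def _config_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    d["cavity"] = CavityShape(**d["cavity"])
    d["av_plane"] = tuple(tuple(p) for p in d["av_plane"])
    return PhantomConfig(**d)


def save_sequence(seq: FrameSequence, outdir, stem: str = "sequence") -> Path:
    """Write frames as a multi-page float32 TIFF, truth masks as 0/255 PNGs
    and a JSON sidecar (timestamps, AV plane, config echo). Returns the
    sidecar path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tiff_path = outdir / f"{stem}.tif"
    tifffile.imwrite(tiff_path, np.stack(seq.frames).astype(np.float32))
    mask_path = outdir / f"{stem}_truth.png"
    save_mask_png(seq.truth_mask, mask_path)
    sidecar = {
        "frames": tiff_path.name,
        "truth_mask": mask_path.name,
        "timestamps": [float(t) for t in seq.timestamps],
        "av_plane": [list(map(float, p)) for p in seq.av_plane],
        "config": _config_to_dict(seq.meta),
    }
    sidecar_path = outdir / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return sidecar_path


def load_sequence(sidecar_path) -> FrameSequence:
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    frames = [
        np.asarray(f, dtype=float)
        for f in tifffile.imread(sidecar_path.parent / meta["frames"])
    ]
    truth = load_mask_png(sidecar_path.parent / meta["truth_mask"])
    return FrameSequence(
        timestamps=np.asarray(meta["timestamps"], dtype=float),
        frames=frames,
        truth_masks=[truth] * len(frames),
        av_plane=tuple(tuple(p) for p in meta["av_plane"]),
        meta=_config_from_dict(meta["config"]),
    )


def save_mask_png(mask: np.ndarray, path) -> None:
    Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)


def load_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def save_frame_png(frame: np.ndarray, path, vmax: float = 1.0) -> None:
    arr = np.clip(frame / vmax, 0.0, 1.0)
    Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(path)
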