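"""File formats and run manifests.

Arrays travel as NPY with JSON sidecars (geometry, phantom specs, scaling),
encodings as CSV, previews as 16-bit PNG with the linear scaling recorded in
the sidecar.  Every command writes a manifest naming the config hash, the
seed, and the files it produced.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .encoding import ProjectionEncoding
from .phantoms import Image, PhantomSpec
from .tomography import Geometry, Sinogram

__all__ = [
    "save_image", "load_image", "save_png16", "save_sinogram",
    "load_sinogram", "save_encoding_csv", "load_encoding_csv",
    "write_manifest", "config_hash",
]


def save_image(path: Path, image: Image) -> None:
    np.save(path, image.pixels)


def load_image(path: Path) -> Image:
    return Image(np.load(path))


def save_png16(path: Path, pixels: np.ndarray) -> None:
    """16-bit PNG preview, linearly scaled; scaling goes in a JSON sidecar."""
    lo, hi = float(pixels.min()), float(pixels.max())
    scale = (hi - lo) or 1.0
    data = np.round((pixels - lo) / scale * 65535).astype(np.uint16)
    iio.imwrite(path, data)
    Path(str(path) + ".json").write_text(
        json.dumps({"offset": lo, "scale": scale, "dtype": "uint16"}))


def save_sinogram(path: Path, sino: Sinogram) -> None:
    np.save(path, sino.values)
    Path(str(path) + ".json").write_text(json.dumps({
        "m1": sino.geometry.m1, "m2": sino.geometry.m2,
        "detector_spacing": sino.geometry.detector_spacing}))


def load_sinogram(path: Path) -> Sinogram:
    meta = json.loads(Path(str(path) + ".json").read_text())
    return Sinogram(np.load(path), Geometry(**meta))


def save_encoding_csv(path: Path, encoding: ProjectionEncoding) -> None:
    lines = ["index,e"] + [f"{j},{v:.10g}" for j, v in enumerate(encoding.e)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_encoding_csv(path: Path) -> ProjectionEncoding:
    rows = Path(path).read_text().strip().splitlines()[1:]
    return ProjectionEncoding(np.array([float(r.split(",")[1]) for r in rows]))


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(outdir: Path, config_dict: dict, seed: int,
                   files: list[str]) -> None:
    (Path(outdir) / "manifest.json").write_text(json.dumps({
        "config_hash": config_hash(config_dict),
        "seed": seed,
        "files": sorted(files),
    }, indent=2))
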