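"""Reading and writing contrast stacks, raw frames, and parameter maps.

Stacks travel as 32-bit float multi-page TIFFs (one page per exposure,
page order = exposure order) with a JSON sidecar carrying the exposure
times in seconds; parameter maps are written one TIFF per parameter plus
a manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .contrast import ContrastStack, RawFrameStack
from .lsq import FitResult
from .models import ExposureSet

__all__ = [
    "read_exposures",
    "write_contrast_stack",
    "read_contrast_stack",
    "read_raw_stack",
    "write_fit_result",
    "read_fit_result",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def read_exposures(path) -> ExposureSet:
    """Exposure times from a JSON file ({"times_s": [...]}) or a plain
    text file with one duration (seconds) per line."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        times = json.loads(text)["times_s"]
    else:
        times = [float(line) for line in text.split() if line.strip()]
    return ExposureSet(np.asarray(times))


def write_contrast_stack(path, stack: ContrastStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.k2.astype(np.float32))
    meta = {
        "times_s": stack.exposure_set.times.tolist(),
        "quantity": "squared speckle contrast",
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_contrast_stack(path, exposures: ExposureSet | None = None) -> ContrastStack:
    path = Path(path)
    k2 = tifffile.imread(path).astype(float)
    if exposures is None:
        meta = json.loads(_sidecar(path).read_text())
        exposures = ExposureSet(np.asarray(meta["times_s"]))
    return ContrastStack(k2, exposures)


def read_raw_stack(
    path, exposures: ExposureSet, replicates: int = 1
) -> RawFrameStack:
    frames = tifffile.imread(Path(path))
    if frames.ndim == 2:
        frames = frames[None]
    return RawFrameStack(frames, exposures, replicates)


def write_fit_result(out_dir, fit: FitResult, manifest: dict | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    maps = {"tau_c": fit.tau_c, "beta": fit.beta, "rho": fit.rho}
    if fit.d_mu is not None:
        maps["d_mu"] = fit.d_mu
    maps["valid"] = fit.valid.astype(np.float32)
    for name, arr in maps.items():
        tifffile.imwrite(out / f"{name}.tif", np.asarray(arr, dtype=np.float32))
    info = dict(manifest or {})
    info.setdefault("maps", sorted(maps))
    info.setdefault("units", {"tau_c": "s"})
    (out / "manifest.json").write_text(json.dumps(info, indent=1))


def read_fit_result(out_dir) -> FitResult:
    out = Path(out_dir)
    read = lambda name: tifffile.imread(out / f"{name}.tif").astype(float)
    d_mu = (out / "d_mu.tif").exists()
    return FitResult(
        beta=read("beta"),
        rho=read("rho"),
        tau_c=read("tau_c"),
        d_mu=read("d_mu") if d_mu else None,
        rss=np.full_like(read("beta"), np.nan),
        converged=read("valid") > 0,
        n_iter=np.zeros_like(read("beta"), dtype=int),
        valid=read("valid") > 0,
    )
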