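"""Readers and writers for the pipeline's container formats.

* decay stacks: multi-page TIFF (page axis = time, increasing) plus a JSON
  sidecar carrying the time base (n_bins, bin_width_s, rep_rate_hz);
* 2-D intensity images and parameter maps: TIFF;
* label masks: 16-bit unsigned TIFF, with negative exclusion codes mapped
  into a reserved high range (TIFF stores unsigned);
* IRFs and tables: CSV;
* configs, QC reports, manifests: JSON.

All writes are atomic (temp file + rename), so a crashed run never leaves
a truncated output behind.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .containers import DecayStack
from .decay_model import IRFCurve, TimeGrid

__all__ = [
    "atomic_write",
    "read_decay_stack",
    "write_decay_stack",
    "read_image",
    "write_image",
    "read_label_mask",
    "write_label_mask",
    "read_irf_csv",
    "write_irf_csv",
    "write_json",
    "read_json",
    "write_manifest",
]

# label masks are stored unsigned; negative exclusion codes -1..-4095 map
# to 61441..65535 (65536 + code)
_NEG_LABEL_BASE = 65536
_NEG_LABEL_MIN = 61441


def atomic_write(path: str | Path, writer) -> Path:
    """Write via a temp file in the destination directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix + ".tmp")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_decay_stack(stack: DecayStack, path: str | Path) -> Path:
    """Write a decay stack as multi-page TIFF + JSON metadata sidecar."""
    path = Path(path)
    counts = stack.counts
    dtype = np.uint16 if counts.max() < 2**16 else np.uint32
    # metadata=None forces plain multi-page layout: one page per time bin
    atomic_write(
        path,
        lambda p: tifffile.imwrite(p, counts.astype(dtype), photometric="minisblack", metadata=None),
    )
    write_json(_sidecar_path(path), stack.grid.to_dict())
    return path


def read_decay_stack(path: str | Path, expected_grid: TimeGrid | None = None) -> DecayStack:
    """Read a decay stack; the JSON sidecar with the time base is required."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"decay stack {path} has no metadata sidecar {sidecar.name}; "
            "required keys: n_bins, bin_width_s, rep_rate_hz"
        )
    grid = TimeGrid.from_dict(read_json(sidecar))
    counts = tifffile.imread(path)
    if not np.issubdtype(np.asarray(counts).dtype, np.integer):
        raise ValueError(f"{path}: photon counts must be integer-typed, got {counts.dtype}")
    if expected_grid is not None and grid != expected_grid:
        raise ValueError(
            f"{path}: sidecar time base {grid.to_dict()} does not match the configured "
            f"{expected_grid.to_dict()}"
        )
    return DecayStack(counts=np.asarray(counts), grid=grid)


def write_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    arr = np.asarray(image)
    atomic_write(path, lambda p: tifffile.imwrite(p, arr))
    return path


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path))


def write_label_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write an integer label mask as uint16 TIFF (negatives -> high range)."""
    mask = np.asarray(mask).astype(np.int64)
    if mask.max() >= _NEG_LABEL_MIN or mask.min() < -(_NEG_LABEL_BASE - _NEG_LABEL_MIN):
        raise ValueError(
            f"labels must be in [-{_NEG_LABEL_BASE - _NEG_LABEL_MIN}, {_NEG_LABEL_MIN - 1}]"
        )
    enc = np.where(mask < 0, mask + _NEG_LABEL_BASE, mask).astype(np.uint16)
    return write_image(enc, path)


def read_label_mask(path: str | Path) -> np.ndarray:
    enc = read_image(path).astype(np.int64)
    return np.where(enc >= _NEG_LABEL_MIN, enc - _NEG_LABEL_BASE, enc).astype(np.int32)


def write_irf_csv(irf: IRFCurve, path: str | Path) -> Path:
    """IRF as 2-column CSV (time_s, counts)."""
    df = pd.DataFrame({"time_s": irf.grid.bin_centers, "counts": irf.values})
    atomic_write(path, lambda p: df.to_csv(p, index=False))
    return path


def read_irf_csv(path: str | Path, grid: TimeGrid, fwhm: float | None = None) -> IRFCurve:
    df = pd.read_csv(path)
    for col in ("time_s", "counts"):
        if col not in df.columns:
            raise ValueError(f"IRF CSV {path} is missing the '{col}' column")
    if len(df) != grid.n_bins:
        raise ValueError(f"IRF CSV has {len(df)} rows but the grid has {grid.n_bins} bins")
    return IRFCurve(values=df["counts"].to_numpy(dtype=float), grid=grid, fwhm=fwhm)


def write_json(path: str | Path, obj: Any) -> Path:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    return atomic_write(
        path, lambda p: p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default))
    )


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: dict, outputs: list[str | Path], seed: int | None = None) -> Path:
    """Record beside the outputs everything needed to reproduce them."""
    from . import __version__

    out_dir = Path(out_dir)
    entries = {}
    for p in outputs:
        p = Path(p)
        if p.exists():
            entries[p.name] = _checksum(p)
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config": config,
        "output_checksums": entries,
    }
    return write_json(out_dir / "manifest.json", manifest)
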