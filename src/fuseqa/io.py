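"""Image and manifest I/O.

A *gray image* is a square 2-D float64 array with intensities in [0, 1].
PNG (8/16-bit) and TIFF are read; color inputs are reduced to ITU-R 601
luminance; PNGs are written at 8 bits.  Datasets are described by a CSV
manifest with columns ``mi1,mi2,fused,mos``: two registered source-modality
images, their fused image, and the fused image's mean opinion score (MOS)
normalized to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

log = logging.getLogger("fuseqa")

MANIFEST_COLUMNS = ("mi1", "mi2", "fused", "mos")


def load_image(path) -> np.ndarray:
    """Read a grayscale image as a square float64 array in [0, 1].

    8-bit data is scaled by 1/255, 16-bit by 1/65535; RGB(A) inputs are
    converted to luminance (ITU-R 601 weights) first.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("I;16", "I;16B", "I;16L"):
                arr = np.asarray(im, dtype=np.float64) / 65535.0
            elif im.mode == "I":
                arr = np.asarray(im, dtype=np.float64)
                arr = arr / 65535.0 if arr.max() > 255 else arr / 255.0
            elif im.mode == "F":
                arr = np.asarray(im, dtype=np.float64)
            elif im.mode == "L":
                arr = np.asarray(im, dtype=np.float64) / 255.0
            else:  # color and palette images -> luminance
                arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
    except FileNotFoundError:
        raise IOError(f"image file not found: {path}") from None
    except OSError as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise IOError(f"image {path} is not a single-plane grayscale image")
    if arr.shape[0] != arr.shape[1]:
        raise IOError(f"image {path} is not square: {arr.shape[0]}x{arr.shape[1]}")
    return np.clip(arr, 0.0, 1.0)


def save_image(img: np.ndarray, path) -> None:
    """Write a [0, 1] gray image as an 8-bit PNG."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("save_image expects a 2-D array")
    data = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(data, mode="L").save(Path(path), format="PNG")


def resize(img: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize to ``side`` x ``side``; values clipped back to [0, 1]."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("resize expects a square 2-D array")
    if side == img.shape[0]:
        return img.copy()
    if side < 8:
        raise ValueError("target side must be at least 8")
    out = _sk_resize(img, (side, side), order=1, anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class ManifestRecord:
    mi1: Path
    mi2: Path
    fused: Path
    mos: float


@dataclass
class Manifest:
    """Ordered list of fusion samples; the empirical training distribution."""

    records: list[ManifestRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(str(r.mi1), str(r.mi2), str(r.fused), r.mos) for r in self.records],
            columns=list(MANIFEST_COLUMNS),
        )


def load_manifest(path) -> Manifest:
    """Load and validate a CSV manifest; paths are resolved relative to it.

    Raises ``ValueError`` naming the offending data row (1-based) for an
    out-of-range MOS or an unresolvable path, and on duplicate fused paths.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    base = path.parent
    records: list[ManifestRecord] = []
    seen_fused: set[Path] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        mos = float(row.mos)
        if not 0.0 <= mos <= 1.0:
            raise ValueError(f"manifest row {i}: mos={mos} outside [0, 1]")
        paths = {}
        for col in ("mi1", "mi2", "fused"):
            p = Path(getattr(row, col))
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise ValueError(f"manifest row {i}: {col} path does not exist: {p}")
            paths[col] = p
        if paths["fused"] in seen_fused:
            raise ValueError(f"manifest row {i}: duplicate fused path {paths['fused']}")
        seen_fused.add(paths["fused"])
        records.append(ManifestRecord(paths["mi1"], paths["mi2"], paths["fused"], mos))
    if not records:
        log.warning("manifest %s contains no data rows", path)
    return Manifest(records)


def save_manifest(manifest: Manifest, path) -> None:
    manifest.to_frame().to_csv(Path(path), index=False)
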