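"""File I/O: images, masks, model archives, and run configuration."""

from __future__ import annotations

import pickle
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .training import FullViewModel, ZoomViewModel

MODEL_FORMAT_VERSION = 1

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF as a 2-D uint8 grid.

    RGB(A) inputs are collapsed by luminosity with a warning; 16-bit inputs
    are linearly rescaled to 8 bits with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        warnings.warn(f"{path.name}: multi-channel image collapsed by luminosity",
                      stacklevel=2)
        arr = arr[..., :3] @ _LUMA
    if arr.dtype == np.uint16:
        warnings.warn(f"{path.name}: 16-bit image rescaled to 8-bit", stacklevel=2)
        arr = arr.astype(np.float64) / 257.0
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def write_image(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), image.astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask; any nonzero pixel is foreground (warned when the
    file contains values other than 0 and 255)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    vals = np.unique(arr)
    if not set(vals.tolist()) <= {0, 255}:
        warnings.warn(f"{path.name}: mask has values other than 0/255; "
                      "treating any nonzero as foreground", stacklevel=2)
    return arr != 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.where(mask, 255, 0).astype(np.uint8))


def write_probability_map(p: np.ndarray, path: str | Path) -> None:
    """16-bit PNG encoding of probabilities in [0, 1]."""
    iio.imwrite(Path(path), np.round(p * 65535).astype(np.uint16))


# ---------------------------------------------------------------------------
# Model archives
# ---------------------------------------------------------------------------

def save_models(full: FullViewModel, zoom: ZoomViewModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "full": full,
        "zoom": zoom,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_models(path: str | Path) -> tuple[FullViewModel, ZoomViewModel]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except (pickle.UnpicklingError, EOFError) as exc:
        raise IOError(f"corrupted model archive: {path}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise IOError(f"not a model archive: {path}")
    version = payload["format_version"]
    if version != MODEL_FORMAT_VERSION:
        raise IOError(
            f"model archive {path} has format version {version}, "
            f"this build reads version {MODEL_FORMAT_VERSION}"
        )
    return payload["full"], payload["zoom"]


# ---------------------------------------------------------------------------
# Run configuration / manifests
# ---------------------------------------------------------------------------

def write_manifest(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
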