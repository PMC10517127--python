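"""Image and table readers/writers.

File conventions: one single-channel 8-bit grayscale TIFF or PNG per
modality per eye, named ``<eye_id>_struct.<ext>`` / ``<eye_id>_octa.<ext>``
(optional ``<eye_id>_faz.<ext>`` binary mask), plus one covariate CSV with
an ``eye_id`` column.  Output CSVs carry the resolved run configuration as
``#``-prefixed header comments for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import InputError
from .images import EnFaceImage, Modality
from .vascular import FazMask

_MODALITY_SUFFIX = {"struct": Modality.STRUCTURAL, "octa": Modality.ANGIOGRAPHY}


def _load_array(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        raise InputError(
            f"{path.name}: expected a single-channel grayscale image, got "
            f"{arr.shape[-1]} channels; convert to 8-bit grayscale first"
        )
    if arr.dtype != np.uint8:
        raise InputError(
            f"{path.name}: expected 8-bit pixels, got dtype {arr.dtype}; "
            "rescale to uint8 before analysis"
        )
    return arr


def read_enface(
    path: str | Path,
    modality: Modality | str | None = None,
    extent_mm: float = 3.0,
    quality: float | None = None,
) -> EnFaceImage:
    """Read one en-face image; modality inferred from the filename if absent.

    Filenames ending in ``_struct`` / ``_octa`` (before the extension) map
    to structural / angiography.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    arr = _load_array(path)
    eye_id = None
    if modality is None:
        stem = path.stem
        for suffix, mod in _MODALITY_SUFFIX.items():
            if stem.endswith("_" + suffix):
                modality = mod
                eye_id = stem[: -len(suffix) - 1]
                break
        else:
            raise InputError(
                f"{path.name}: cannot infer modality; name the file "
                "'<eye_id>_struct.*' or '<eye_id>_octa.*' or pass modality="
            )
    return EnFaceImage(
        arr, Modality(modality), extent_mm=extent_mm, quality=quality, eye_id=eye_id
    )


def write_enface(image: EnFaceImage, path: str | Path) -> None:
    """Write an en-face image as 8-bit grayscale TIFF or PNG."""
    path = Path(path)
    arr = np.asarray(image.pixels)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="L").save(path)


def read_faz_mask(path: str | Path) -> FazMask:
    """Read a binary FAZ mask image (nonzero pixels = FAZ)."""
    arr = _load_array(Path(path))
    return FazMask(arr > 0, provenance="supplied")


def write_faz_mask(faz: FazMask, path: str | Path) -> None:
    Image.fromarray((faz.mask * np.uint8(255)), mode="L").save(Path(path))


def write_table(
    df: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    """Write a CSV with the resolved configuration as comment header lines."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if provenance is not None:
            fh.write("# perivasc run configuration:\n")
            for line in json.dumps(provenance, indent=None, sort_keys=True).split("\n"):
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comment lines skipped)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"table not found: {path}")
    return pd.read_csv(path, comment="#")
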