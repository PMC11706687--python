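"""Multichannel image, mask and metadata-table I/O.

Images travel as OME-TIFF (channel names and physical pixel size in the
OME-XML) or plain multi-page TIFF, in which case the standard acquisition
channel order is assumed: (1) fluorescence 405 nm, (2) brightfield 405 nm,
(3) fluorescence 458 nm, (4) brightfield 458 nm.  Derived analysis layers
(segmentation, ratio, uncertainty, attribution) are appended as extra named
channels of a float32 result stack.
"""

from __future__ import annotations

import hashlib
import uuid
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CHANNEL_ROLES",
    "CLASS_NAMES",
    "DEFAULT_PIXEL_SIZE_UM",
    "MultiChannelImage",
    "SegmentationMask",
    "SampleRecord",
    "FormatError",
    "SchemaError",
    "ValidationError",
    "read_image",
    "write_image",
    "write_result_image",
    "read_result_image",
    "read_metadata_table",
    "write_metadata_table",
]

#: Fixed acquisition channel order.
CHANNEL_ROLES = ("fl405", "bf405", "fl458", "bf458")

#: Segmentation class identifiers.
CLASS_NAMES = ["background", "root", "EEZ", "LEZ", "MZ"]
N_CLASSES = len(CLASS_NAMES)

#: Physical pixel size of the acquisition setup, in micrometres.
DEFAULT_PIXEL_SIZE_UM = 0.415133


class FormatError(ValueError):
    """The file on disk does not match the expected image layout."""


class SchemaError(ValueError):
    """The metadata table lacks a required column."""


class ValidationError(ValueError):
    """The metadata table content is inconsistent."""


@dataclass
class MultiChannelImage:
    """A 4-channel 2-D image with channel-role labels and pixel size."""

    pixels: np.ndarray  # (4, H, W), non-negative intensities
    channel_roles: tuple = CHANNEL_ROLES
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != len(self.channel_roles):
            raise FormatError(
                f"expected ({len(self.channel_roles)}, H, W) pixels, "
                f"got shape {self.pixels.shape}"
            )

    def channel(self, role: str) -> np.ndarray:
        """Return the 2-D plane for a channel role, e.g. ``"bf405"``."""
        try:
            idx = self.channel_roles.index(role)
        except ValueError:
            raise KeyError(f"no channel with role {role!r}") from None
        return self.pixels[idx]

    @property
    def shape(self):
        return self.pixels.shape[1:]


@dataclass
class SegmentationMask:
    """Per-pixel integer labels: background 0, root 1, EEZ 2, LEZ 3, MZ 4."""

    labels: np.ndarray
    class_names: tuple = tuple(CLASS_NAMES)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("mask must be 2-D")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_names)
        ):
            raise FormatError("mask labels outside the 0..4 class range")
        self.labels = self.labels.astype(np.uint8)


@dataclass
class SampleRecord:
    """One row of the metadata table."""

    sample_id: str
    line: str
    treatment: str
    file: str


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def _ome_channel_names(tif: tifffile.TiffFile) -> list[str] | None:
    if not tif.is_ome:
        return None
    try:
        meta = tifffile.xml2dict(tif.ome_metadata)
        image = meta["OME"]["Image"]
        if isinstance(image, list):
            image = image[0]
        channels = image["Pixels"]["Channel"]
        if isinstance(channels, dict):
            channels = [channels]
        names = [c.get("Name") for c in channels]
        if all(n is not None for n in names):
            return [str(n) for n in names]
    except (KeyError, TypeError):
        pass
    return None


def _ome_pixel_size(tif: tifffile.TiffFile) -> float | None:
    if not tif.is_ome:
        return None
    try:
        meta = tifffile.xml2dict(tif.ome_metadata)
        image = meta["OME"]["Image"]
        if isinstance(image, list):
            image = image[0]
        size = image["Pixels"].get("PhysicalSizeX")
        return None if size is None else float(size)
    except (KeyError, TypeError):
        return None


def _read_stack(path: str | Path) -> tuple[np.ndarray, list[str] | None, float | None]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            names = _ome_channel_names(tif)
            pixel_size = _ome_pixel_size(tif)
    except (tifffile.TiffFileError, OSError) as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a (C, H, W) stack, got {data.shape}")
    return data, names, pixel_size


def read_image(path: str | Path) -> MultiChannelImage:
    """Read a 4-channel acquisition image from OME-TIFF or plain TIFF.

    OME channel names are honoured when they cover the four expected roles;
    otherwise page order is assumed to follow the acquisition convention.
    Extra pages (e.g. a stored mask channel) are ignored here.
    """
    data, names, pixel_size = _read_stack(path)
    if data.shape[0] < 4:
        raise FormatError(
            f"{path}: needs >= 4 channels, found {data.shape[0]}"
        )
    if names and all(role in names for role in CHANNEL_ROLES):
        order = [names.index(role) for role in CHANNEL_ROLES]
        pixels = data[order]
    else:
        pixels = data[:4]
    return MultiChannelImage(
        pixels=pixels,
        channel_roles=CHANNEL_ROLES,
        pixel_size_um=pixel_size if pixel_size is not None else DEFAULT_PIXEL_SIZE_UM,
    )


def read_mask(path: str | Path) -> SegmentationMask | None:
    """Read a ground-truth mask stored as the channel named ``"mask"``."""
    data, names, _ = _read_stack(path)
    if names and "mask" in names:
        return SegmentationMask(data[names.index("mask")])
    if data.shape[0] == len(CHANNEL_ROLES) + 1:
        return SegmentationMask(data[-1])
    return None


def _write_ome(path: Path, stack: np.ndarray, names: list[str], pixel_size: float):
    # Deterministic OME UUID derived from the content, so identical data
    # yields byte-identical files (a reproducibility contract of the tool).
    digest = hashlib.sha1()
    digest.update(np.ascontiguousarray(stack).tobytes())
    digest.update("|".join(names).encode())
    uid = uuid.UUID(bytes=digest.digest()[:16], version=5)
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        metadata={
            "axes": "CYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": pixel_size,
            "PhysicalSizeYUnit": "µm",
            "UUID": f"urn:uuid:{uid}",
            "Creator": "phroot",
        },
    )


def write_image(
    image: MultiChannelImage, path: str | Path, mask: SegmentationMask | None = None
) -> Path:
    """Write an acquisition image (optionally with its mask as a 5th channel).

    Intensities are stored losslessly in their native integer dtype.
    """
    path = Path(path)
    stack = image.pixels
    names = list(image.channel_roles)
    if mask is not None:
        if mask.labels.shape != image.shape:
            raise FormatError("mask shape does not match image")
        stack = np.concatenate(
            [stack, mask.labels.astype(stack.dtype)[None]], axis=0
        )
        names = names + ["mask"]
    _write_ome(path, stack, names, image.pixel_size_um)
    return path


def write_result_image(
    image: MultiChannelImage,
    path: str | Path,
    extra_layers: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write the original channels plus named derived layers as float32.

    The result stack shares one dtype, so integer layers (e.g. segmentation
    labels 0–4) remain exactly representable.
    """
    path = Path(path)
    extra_layers = extra_layers or {}
    h, w = image.shape
    layers = [image.pixels.astype(np.float32)]
    names = list(image.channel_roles)
    for name, layer in extra_layers.items():
        layer = np.asarray(layer)
        if layer.shape != (h, w):
            raise FormatError(
                f"layer {name!r} has shape {layer.shape}, expected {(h, w)}"
            )
        layers.append(layer.astype(np.float32)[None])
        names.append(name)
    _write_ome(path, np.concatenate(layers, axis=0), names, image.pixel_size_um)
    return path


def read_result_image(path: str | Path) -> tuple[np.ndarray, list[str], float]:
    """Read back a result stack: (C × H × W array, channel names, pixel size)."""
    data, names, pixel_size = _read_stack(path)
    if names is None:
        names = [f"channel_{i}" for i in range(data.shape[0])]
    return data, names, pixel_size if pixel_size is not None else DEFAULT_PIXEL_SIZE_UM


# ---------------------------------------------------------------------------
# metadata table
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("sample_id", "line", "treatment", "file")


def read_metadata_table(
    path: str | Path, check_files: bool = True
) -> list[SampleRecord]:
    """Read the tab- or comma-separated sample table.

    Requires columns sample_id, line, treatment, file; sample ids must be
    unique and, when ``check_files`` is set, every referenced image must
    exist (relative paths resolve against the table's directory).
    """
    path = Path(path)
    table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    dupes = table["sample_id"][table["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate sample_id values {sorted(set(dupes))}")
    records = []
    for row in table.itertuples(index=False):
        file = Path(row.file)
        if not file.is_absolute():
            file = path.parent / file
        if check_files and not file.exists():
            raise ValidationError(f"{path}: image file not found for {row.sample_id}: {file}")
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                line=str(row.line),
                treatment=str(row.treatment),
                file=str(file),
            )
        )
    return records


def write_metadata_table(records: list[SampleRecord], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "line": r.line,
                "treatment": r.treatment,
                "file": r.file,
            }
            for r in records
        ]
    )
    frame.to_csv(path, sep="\t", index=False)
    return path
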