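"""Calibrated multichannel volumes: TIFF/OME-TIFF I/O and tidy result tables.

Conventions used throughout the package:

* arrays are indexed ``(channel, z, y, x)``, 0-based;
* the physical coordinate of voxel index ``i`` along an axis is
  ``i * voxel_size_nm[axis]`` (voxel centers on a regular grid starting at 0);
* every distance is expressed in nanometres and computed with per-axis voxel
  sizes, so anisotropic sampling (typical 3D-SIM stacks have a much coarser
  axial pitch than lateral pitch) is handled uniformly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "KNOWN_CHANNELS",
    "MultiChannelVolume",
    "ValidationError",
    "read_volume",
    "write_volume",
    "write_records",
    "write_run_metadata",
]

#: channel labels with a defined meaning in this package
KNOWN_CHANNELS = ("lamin", "lap2a", "trf1", "dapi", "stain_a", "stain_b")


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass
class MultiChannelVolume:
    """A calibrated multichannel image volume.

    Parameters
    ----------
    data:
        Non-negative intensities, shape ``(n_channels, nz, ny, nx)``.  2-D
        fields are stored with ``nz == 1``.
    channel_names:
        Ordered channel labels; one per channel plane.
    voxel_size_nm:
        ``(dz, dy, dx)`` voxel pitch in nanometres, all positive.
    """

    data: np.ndarray
    channel_names: list[str]
    voxel_size_nm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # single channel convenience
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValidationError(
                f"expected 4-D (channel, z, y, x) data, got ndim={self.data.ndim}"
            )
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValidationError("intensities must be finite")
        if self.data.min() < 0:
            raise ValidationError("intensities must be non-negative")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        self.voxel_size_nm = tuple(float(v) for v in self.voxel_size_nm)
        if len(self.voxel_size_nm) != 3 or any(v <= 0 for v in self.voxel_size_nm):
            raise ValidationError("voxel_size_nm must be three positive reals")

    # -- accessors ---------------------------------------------------------
    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the 3-D array for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ValidationError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names


# ---------------------------------------------------------------------------
# TIFF / OME-TIFF reading
# ---------------------------------------------------------------------------

def _ome_voxel_size_nm(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Extract (dz, dy, dx) in nm from OME-XML metadata, if present."""
    if not tif.is_ome or tif.ome_metadata is None:
        return None
    import xml.etree.ElementTree as ET

    try:
        root = ET.fromstring(tif.ome_metadata)
    except ET.ParseError:
        return None
    # unit conversion to nm; OME default unit is micron
    scale = {"nm": 1.0, "µm": 1000.0, "um": 1000.0, "micron": 1000.0, "mm": 1e6}
    for pixels in root.iter():
        if not pixels.tag.endswith("Pixels"):
            continue
        out = []
        for axis in ("Z", "Y", "X"):
            value = pixels.get(f"PhysicalSize{axis}")
            if value is None:
                return None
            unit = pixels.get(f"PhysicalSize{axis}Unit", "µm")
            out.append(float(value) * scale.get(unit, 1000.0))
        return tuple(out)  # type: ignore[return-value]
    return None


def read_volume(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    voxel_size_nm: Sequence[float] | None = None,
    layout: str = "channel_major",
) -> MultiChannelVolume:
    """Read a TIFF / OME-TIFF stack into a :class:`MultiChannelVolume`.

    Parameters
    ----------
    channel_map:
        Mapping from channel label to channel index in the stack.  Required
        for plain multi-page TIFFs; for OME-TIFF with a channel axis it
        defaults to positional labels ``ch0, ch1, ...`` when omitted.
    voxel_size_nm:
        Caller-supplied ``(dz, dy, dx)`` calibration.  Caller values take
        precedence over OME metadata; if neither is available a
        :class:`ValidationError` is raised.
    layout:
        For plain (non-OME) multi-page TIFFs: ``"channel_major"`` means pages
        are ordered ``c0z0..c0zN, c1z0..``, ``"interleaved"`` means
        ``z0c0, z0c1, z1c0, ...``.  Ignored when the file axes already carry
        a channel dimension.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            meta_calibration = _ome_voxel_size_nm(tif)
    except (OSError, tifffile.TiffFileError):
        raise
    except Exception as exc:  # corrupt content surfaces as I/O problem
        raise OSError(f"could not read TIFF stack {path}: {exc}") from exc

    # normalize to (C, Z, Y, X)
    axes = axes.replace("S", "C").replace("I", "Q").replace("Q", "Z")
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        if "C" in axes and "Z" not in axes:
            data = data[:, None] if axes.startswith("C") else np.moveaxis(data, -1, 0)[:, None]
        else:
            # plain z-stack of pages; channel structure given by channel_map
            n_channels = max(channel_map.values()) + 1 if channel_map else 1
            if data.shape[0] % n_channels:
                raise ValidationError(
                    f"{data.shape[0]} pages not divisible by {n_channels} channels"
                )
            nz = data.shape[0] // n_channels
            if layout == "channel_major":
                data = data.reshape(n_channels, nz, *data.shape[1:])
            elif layout == "interleaved":
                data = data.reshape(nz, n_channels, *data.shape[1:]).swapaxes(0, 1)
            else:
                raise ValidationError(f"unknown layout {layout!r}")
    elif data.ndim == 4:
        order = [axes.index(a) for a in "CZYX" if a in axes]
        if len(order) == 4:
            data = np.transpose(data, order)
        elif axes.index("C") > axes.index("Z"):  # ZCYX without full labels
            data = data.swapaxes(0, 1)
    else:
        raise ValidationError(f"unsupported stack dimensionality {data.ndim}")

    if channel_map:
        n_stack = data.shape[0]
        bad = {k: i for k, i in channel_map.items() if not 0 <= i < n_stack}
        if bad:
            raise ValidationError(
                f"channel indices out of range for {n_stack}-channel stack: {bad}"
            )
        names_idx = sorted(channel_map.items(), key=lambda kv: kv[1])
        data = data[[i for _, i in names_idx]]
        names = [k for k, _ in names_idx]
    else:
        names = [f"ch{i}" for i in range(data.shape[0])]

    if voxel_size_nm is not None:
        calibration = tuple(float(v) for v in voxel_size_nm)
    elif meta_calibration is not None:
        calibration = meta_calibration
    else:
        raise ValidationError(
            "no voxel calibration: pass voxel_size_nm or use OME-TIFF with "
            "PhysicalSize metadata"
        )
    return MultiChannelVolume(data, names, calibration)


def write_volume(volume: MultiChannelVolume, path: str | Path) -> None:
    """Write a volume as OME-TIFF with physical voxel sizes (in µm)."""
    dz, dy, dx = volume.voxel_size_nm
    tifffile.imwrite(
        Path(path),
        volume.data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz / 1000.0,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy / 1000.0,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx / 1000.0,
            "PhysicalSizeXUnit": "µm",
        },
    )


# ---------------------------------------------------------------------------
# result tables / metadata
# ---------------------------------------------------------------------------

def write_records(records: Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Write keyed measurement rows to CSV.

    All rows must share one key set; column order follows the first record.
    Floats are rendered with 9 significant digits so a write/read round trip
    preserves values to well below 1e-6 relative.
    """
    import pandas as pd

    records = list(records)
    if records:
        keys = list(records[0].keys())
        for i, rec in enumerate(records):
            if list(rec.keys()) != keys and set(rec.keys()) != set(keys):
                raise ValidationError(
                    f"record {i} keys {sorted(rec.keys())} differ from "
                    f"{sorted(keys)}"
                )
        frame = pd.DataFrame(records, columns=keys)
    else:
        frame = pd.DataFrame()
    frame.to_csv(Path(path), index=False, float_format="%.9g")


def write_run_metadata(path: str | Path, **metadata: object) -> None:
    """Write run metadata (parameters, seed, software version) as JSON."""
    from telolamina import __version__

    payload = {"software": "telolamina", "version": __version__, **metadata}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
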