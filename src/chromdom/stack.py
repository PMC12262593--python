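"""Multi-channel 3D stack container and TIFF/OME-TIFF input/output.

The in-memory unit of the whole pipeline is a :class:`MultiChannelStack`:
a set of equally shaped ``(z, y, x)`` intensity grids (one per fluorescence
channel) plus the physical voxel spacing and a per-slide flag telling real
microscope slides apart from slides inserted by Z-interpolation.

Coordinate convention: 0-based ``(z, y, x)`` everywhere; spacing is given in
micrometres as ``spacing_xy`` (isotropic in-plane) and ``spacing_z``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: per-slide provenance flags
REAL = "real"
INTERP = "interp"

#: acquisition defaults for 3D-SIM reconstructions (micrometres)
DEFAULT_SPACING_XY = 0.06
DEFAULT_SPACING_Z = 0.15


@dataclass
class MultiChannelStack:
    """Per-channel 3D intensity grids sharing one voxel geometry.

    Parameters
    ----------
    channels
        Mapping channel label -> 3D array ``(slide, row, col)``. All
        channels must share one shape.
    spacing_xy, spacing_z
        Voxel pitch in micrometres.
    slide_flags
        One flag (``"real"`` or ``"interp"``) per slide. Defaults to all
        real, as produced by acquisition.
    """

    channels: dict[str, np.ndarray]
    spacing_xy: float = DEFAULT_SPACING_XY
    spacing_z: float = DEFAULT_SPACING_Z
    slide_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack needs at least one channel")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 3:
            raise ValueError(f"channels must be 3D (z, y, x); got shape {first}")
        for name, shp in shapes.items():
            if shp != first:
                raise ValueError(
                    f"mismatched channel shapes: {name} has {shp}, expected {first}"
                )
        if not self.slide_flags:
            self.slide_flags = [REAL] * first[0]
        if len(self.slide_flags) != first[0]:
            raise ValueError(
                f"{len(self.slide_flags)} slide flags for {first[0]} slides"
            )
        bad = set(self.slide_flags) - {REAL, INTERP}
        if bad:
            raise ValueError(f"unknown slide flags: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_slides(self) -> int:
        return self.shape[0]

    @property
    def n_real_slides(self) -> int:
        return sum(1 for f in self.slide_flags if f == REAL)

    @property
    def is_enhanced(self) -> bool:
        return any(f == INTERP for f in self.slide_flags)

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel pitch as an ``(z, y, x)`` triple in micrometres."""
        return (self.spacing_z, self.spacing_xy, self.spacing_xy)

    @property
    def voxel_volume_um3(self) -> float:
        return self.spacing_z * self.spacing_xy**2

    def copy(self) -> "MultiChannelStack":
        return MultiChannelStack(
            channels={k: v.copy() for k, v in self.channels.items()},
            spacing_xy=self.spacing_xy,
            spacing_z=self.spacing_z,
            slide_flags=list(self.slide_flags),
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: MultiChannelStack, path: str | Path) -> Path:
    """Write a stack as one multi-channel OME-TIFF plus a JSON sidecar.

    The sidecar records channel order, spacing and slide flags so a
    round trip through :func:`read_stack` is lossless.
    """
    path = Path(path)
    names = list(stack.channels)
    arrays = [np.asarray(stack.channels[n]) for n in names]
    dtype = np.result_type(*[a.dtype for a in arrays])
    data = np.stack([a.astype(dtype, copy=False) for a in arrays])  # (C, Z, Y, X)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        metadata={"axes": "CZYX", "Channel": {"Name": names}},
    )
    sidecar = {
        "channels": names,
        "spacing_xy_um": stack.spacing_xy,
        "spacing_z_um": stack.spacing_z,
        "slide_flags": list(stack.slide_flags),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(
    path: str | Path,
    channel_map: dict[str, int] | None = None,
    axes_override: str | None = None,
    default_spacing: tuple[float, float] = (DEFAULT_SPACING_XY, DEFAULT_SPACING_Z),
) -> MultiChannelStack:
    """Read a multi-channel Z-stack TIFF into a :class:`MultiChannelStack`.

    Axis order is auto-detected from TIFF/OME metadata; ``axes_override``
    (a string such as ``"CZYX"`` or ``"ZCYX"``) takes precedence. Channel
    names come from ``channel_map`` (name -> index along the channel axis)
    or, failing that, from the JSON sidecar written by :func:`write_stack`;
    unnamed channels are called ``ch0, ch1, ...``.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = axes_override or series.axes
    axes = axes.upper().replace("S", "C").replace("Q", "Z")
    if len(axes) != data.ndim:
        raise ValueError(f"axes {axes!r} do not match array rank {data.ndim}")
    if data.ndim == 3:
        # single channel stack
        if set(axes) != {"Z", "Y", "X"}:
            raise ValueError(
                f"cannot interpret 3D axes {axes!r}; pass axes_override"
            )
        data = data[np.newaxis]
        axes = "C" + axes
    if sorted(axes) != ["C", "X", "Y", "Z"]:
        raise ValueError(
            f"unknown axis layout {axes!r}; pass axes_override with C, Z, Y, X"
        )
    order = [axes.index(a) for a in "CZYX"]
    data = np.transpose(data, order)

    sidecar = None
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())

    n_ch = data.shape[0]
    if channel_map is not None:
        names = sorted(channel_map, key=channel_map.get)
        if len(names) != n_ch or sorted(channel_map.values()) != list(range(n_ch)):
            raise ValueError(
                f"channel_map must cover indices 0..{n_ch - 1}, got {channel_map}"
            )
    elif sidecar is not None and len(sidecar.get("channels", [])) == n_ch:
        names = sidecar["channels"]
    else:
        names = [f"ch{i}" for i in range(n_ch)]

    if sidecar is not None:
        spacing_xy = float(sidecar["spacing_xy_um"])
        spacing_z = float(sidecar["spacing_z_um"])
        flags = list(sidecar["slide_flags"])
    else:
        spacing_xy, spacing_z = default_spacing
        flags = []
        logger.warning(
            "%s: no spacing metadata, falling back to %.3g/%.3g um",
            path.name, spacing_xy, spacing_z,
        )

    return MultiChannelStack(
        channels={name: data[i] for i, name in enumerate(names)},
        spacing_xy=spacing_xy,
        spacing_z=spacing_z,
        slide_flags=flags,
    )
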