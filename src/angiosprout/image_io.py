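"""Reading multi-channel confocal z-stacks and computing maximal projections.

The OrganoPlate angiogenesis assay is imaged as confocal z-stacks (typically
40 planes at a 5 µm step, spanning the full 200 µm chip depth) with one
Hoechst/nuclear channel and one phalloidin/F-actin channel.  All downstream
analysis operates on the per-channel maximal projection, so this module only
needs to read stacks, carry the physical calibration, and collapse z.

Calibration (pixel size, z-step) is mandatory configuration and is never
guessed from TIFF tags: tag dialects vary between acquisition systems.  If
resolution tags are present and disagree with the configured pixel size by
more than 1 %, a warning is logged and the configured value wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Channel roles every analysis needs.
REQUIRED_ROLES = ("nuclear", "actin")


class ChannelConfigError(ValueError):
    """The channel map does not cover the required nuclear/actin roles."""


class StackFormatError(ValueError):
    """The TIFF file cannot be interpreted as a multi-channel stack."""


@dataclass(frozen=True)
class ChipStack:
    """A raw multi-channel z-stack of one chip field with physical calibration.

    Parameters
    ----------
    pixels
        Intensity array indexed ``(z, channel, y, x)``; native integer depth
        is preserved (conversion to float happens inside detection operators).
    channel_roles
        Role per channel axis entry; must contain exactly one ``"nuclear"``
        and one ``"actin"``.
    pixel_size_um
        Micrometres per pixel, isotropic in x/y.
    z_step_um
        Micrometres between consecutive planes.
    chip_id
        Opaque identifier carried through to reports.
    """

    pixels: np.ndarray
    channel_roles: tuple[str, ...]
    pixel_size_um: float
    z_step_um: float
    chip_id: str

    def __post_init__(self) -> None:
        if self.pixels.ndim != 4:
            raise StackFormatError(
                f"expected (z, channel, y, x) array, got ndim={self.pixels.ndim}"
            )
        if self.pixels.shape[0] < 1:
            raise StackFormatError("stack must contain at least one z-plane")
        if np.issubdtype(self.pixels.dtype, np.floating) and np.any(self.pixels < 0):
            raise StackFormatError("intensities must be non-negative")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be positive")
        if len(self.channel_roles) != self.pixels.shape[1]:
            raise ChannelConfigError(
                f"{len(self.channel_roles)} roles given for "
                f"{self.pixels.shape[1]} channels"
            )
        for role in REQUIRED_ROLES:
            if self.channel_roles.count(role) != 1:
                raise ChannelConfigError(
                    f"exactly one channel must carry the {role!r} role; "
                    f"got roles {self.channel_roles}"
                )

    @property
    def n_planes(self) -> int:
        return self.pixels.shape[0]

    @property
    def depth_um(self) -> float:
        """Axial extent spanned by the stack (plane count × z-step)."""
        return self.n_planes * self.z_step_um

    def channel_index(self, role: str) -> int:
        try:
            return self.channel_roles.index(role)
        except ValueError:
            raise ChannelConfigError(f"no channel carries role {role!r}") from None


@dataclass(frozen=True)
class Projection:
    """A 2-D maximal projection of one channel of a :class:`ChipStack`."""

    image: np.ndarray
    channel_role: str
    pixel_size_um: float
    chip_id: str

    def __post_init__(self) -> None:
        if self.image.ndim != 2:
            raise StackFormatError("projection image must be 2-D (y, x)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


def planes_for_depth(depth_um: float, z_step_um: float) -> int:
    """Number of z-planes needed to span ``depth_um`` at ``z_step_um``.

    With a 5 µm step, spanning the full 200 µm chip depth takes 40 planes.
    """
    if z_step_um <= 0:
        raise ValueError("z_step_um must be positive")
    return int(np.ceil(depth_um / z_step_um))


def read_stack(
    path: str | Path,
    *,
    pixel_size_um: float,
    z_step_um: float,
    channel_map: Mapping[str, str],
    chip_id: str | None = None,
) -> ChipStack:
    """Read a multi-page TIFF as a :class:`ChipStack`.

    Parameters
    ----------
    path
        Multi-page TIFF laid out ``(z, channel, y, x)`` or ``(channel, y, x)``
        for single-plane acquisitions.  OME-TIFF axis metadata is honoured
        when present.
    channel_map
        Maps channel labels (in storage order, e.g. ``{"w1": "nuclear",
        "w2": "actin"}``) to roles.  Roles are always assigned through this
        mapping, never guessed from intensity statistics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    for role in REQUIRED_ROLES:
        if role not in channel_map.values():
            raise ChannelConfigError(
                f"channel_map {dict(channel_map)} has no entry for role {role!r}"
            )

    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. "ZCYX", "CYX", "QYX"
        _check_tag_calibration(tif, pixel_size_um)

    data = _reshape_to_zcyx(data, axes)
    if data.shape[1] < 2:
        raise StackFormatError(
            f"{path.name}: found {data.shape[1]} channel(s); at least a "
            "nuclear and an actin channel are required"
        )
    labels = list(channel_map.keys())
    if len(labels) != data.shape[1]:
        raise ChannelConfigError(
            f"channel_map has {len(labels)} entries for {data.shape[1]} channels"
        )
    roles = tuple(channel_map[label] for label in labels)
    return ChipStack(
        pixels=data,
        channel_roles=roles,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        chip_id=chip_id or path.stem,
    )


def read_projection_pair(
    nuclear_path: str | Path,
    actin_path: str | Path,
    *,
    pixel_size_um: float,
    chip_id: str,
) -> dict[str, Projection]:
    """Read pre-computed 2-D projections stored one TIFF per channel.

    Supports the ``<chip_id>_<role>.tif`` naming convention used when
    projections are exported directly by the acquisition software.
    """
    out: dict[str, Projection] = {}
    for role, p in (("nuclear", nuclear_path), ("actin", actin_path)):
        img = tifffile.imread(p)
        if img.ndim != 2:
            raise StackFormatError(f"{p}: expected a 2-D projection")
        out[role] = Projection(
            image=img, channel_role=role, pixel_size_um=pixel_size_um, chip_id=chip_id
        )
    return out


def max_project(stack: ChipStack, role: str) -> Projection:
    """Pixel-wise maximum over z for the channel carrying ``role``.

    Projecting a single-plane stack returns that plane unchanged, and the
    result is invariant to any permutation of the z-planes.
    """
    idx = stack.channel_index(role)
    image = np.max(stack.pixels[:, idx], axis=0)
    return Projection(
        image=image,
        channel_role=role,
        pixel_size_um=stack.pixel_size_um,
        chip_id=stack.chip_id,
    )


def _reshape_to_zcyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Normalise a TIFF series to the (z, channel, y, x) convention."""
    axes = axes.upper()
    if data.ndim == 2:
        raise StackFormatError("single-channel 2-D image; need a multi-channel stack")
    if data.ndim == 3:
        # (C, Y, X) single-plane or ambiguous (Q/I leading axis): treat the
        # leading axis as channels for a single z-plane.
        return data[np.newaxis, ...]
    if data.ndim == 4:
        if axes in ("ZCYX", "TCYX", "QCYX", "ICYX"):
            return data
        if axes in ("CZYX",):
            return np.swapaxes(data, 0, 1)
        return data  # assume (z, c, y, x) when axes metadata is uninformative
    raise StackFormatError(f"cannot interpret array of ndim={data.ndim} as a stack")


def _check_tag_calibration(tif: tifffile.TiffFile, pixel_size_um: float) -> None:
    """Warn when TIFF resolution tags disagree with configured pixel size >1 %."""
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is None or unit is None:
            return
        num, den = xres.value
        if num == 0:
            return
        # ResolutionUnit 3 = centimetre
        per_unit_um = 10_000.0 if getattr(unit.value, "value", unit.value) == 3 else 25_400.0
        tag_px_um = per_unit_um * den / num
    except Exception:  # malformed tags are ignored, config wins regardless
        return
    if abs(tag_px_um - pixel_size_um) / pixel_size_um > 0.01:
        logger.warning(
            "TIFF tags imply %.4f um/px but config says %.4f um/px; using config",
            tag_px_um,
            pixel_size_um,
        )
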