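"""Choriocapillaris slab definitions and en-face extraction.

A slab is an axial window below the Bruch's-membrane (BM) surface,
measured along the axial axis with positive offsets pointing deeper into
the choroid.  Five slabs are analysed: the device's automatic slab
(device-dependent: 0-20 um below BM on the swept-source instrument,
9-31 um on the spectral-domain instrument) plus four fixed windows
(11-21, 21-31, 31-41 and 16-31 um below BM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .devices import DeviceProfile

__all__ = ["SlabSpec", "FIXED_SLABS", "AUTOMATIC_SLABS", "slab_catalog",
           "resolve_slab", "extract_enface"]


@dataclass(frozen=True)
class SlabSpec:
    """Axial window below BM defining one choriocapillaris slab."""

    name: str
    z_inner_um: float
    z_outer_um: float

    def __post_init__(self) -> None:
        if not (0 <= self.z_inner_um < self.z_outer_um):
            raise ValueError(
                f"slab {self.name!r}: need 0 <= z_inner < z_outer, got "
                f"({self.z_inner_um}, {self.z_outer_um})"
            )

    @property
    def thickness_um(self) -> float:
        return self.z_outer_um - self.z_inner_um


FIXED_SLABS: dict[str, tuple[float, float]] = {
    "11-21": (11.0, 21.0),
    "21-31": (21.0, 31.0),
    "31-41": (31.0, 41.0),
    "16-31": (16.0, 31.0),
}

# The SD mapping applies to both the V1 and V4 acquisition modes.
AUTOMATIC_SLABS: dict[str, tuple[float, float]] = {
    "SS": (0.0, 20.0),
    "SD_V1": (9.0, 31.0),
    "SD_V4": (9.0, 31.0),
}


def slab_catalog(device: DeviceProfile | str) -> list[SlabSpec]:
    """The five analysed slabs for one device, automatic slab first."""
    name = device.name if isinstance(device, DeviceProfile) else str(device)
    key = name.upper()
    if key not in AUTOMATIC_SLABS:
        raise KeyError(
            f"unknown device {name!r}; automatic slab defined for "
            f"{sorted(AUTOMATIC_SLABS)}"
        )
    auto = SlabSpec("automatic", *AUTOMATIC_SLABS[key])
    return [auto] + [SlabSpec(n, *zz) for n, zz in FIXED_SLABS.items()]


def resolve_slab(name: str, device: DeviceProfile | str) -> SlabSpec:
    """Look up one slab by name for a given device."""
    for slab in slab_catalog(device):
        if slab.name == name:
            return slab
    raise KeyError(
        f"unknown slab {name!r}; known slabs: "
        f"{[s.name for s in slab_catalog(device)]}"
    )


def extract_enface(
    volume: np.ndarray,
    bm_depth_map: np.ndarray,
    slab: SlabSpec,
    axial_step_um: float,
    statistic: str = "mean",
) -> np.ndarray:
    """Project a 3-D volume over a slab window below the BM surface.

    For every lateral pixel the volume is sampled at depths
    ``bm + z_inner, bm + z_inner + step, ..., bm + z_outer`` (inclusive
    bounds; the outer bound is always included) with linear interpolation
    at fractional sample depths, and reduced with ``statistic`` (``mean``,
    the default, or ``max``).

    Raises
    ------
    ValueError
        If the slab window exits the volume for any lateral pixel; the
        message reports the offending pixel count.
    """
    if volume.ndim != 3:
        raise ValueError("volume must be 3-D (depth, y, x)")
    if bm_depth_map.shape != volume.shape[1:]:
        raise ValueError("bm_depth_map shape does not match the volume's lateral grid")
    if statistic not in ("mean", "max"):
        raise ValueError(f"unknown projection statistic {statistic!r}")

    offsets = np.arange(slab.z_inner_um, slab.z_outer_um + 1e-9, axial_step_um)
    if offsets[-1] < slab.z_outer_um - 1e-9:
        offsets = np.append(offsets, slab.z_outer_um)

    nz = volume.shape[0]
    depth_max = (nz - 1) * axial_step_um
    depths = bm_depth_map[None, :, :] + offsets[:, None, None]
    bad = (depths < -1e-9) | (depths > depth_max + 1e-9)
    if bad.any():
        n_bad = int(bad.any(axis=0).sum())
        raise ValueError(
            f"slab {slab.name!r} window exits the volume for {n_bad} "
            f"lateral pixel(s) (volume depth range 0..{depth_max:g} um)"
        )

    idx = depths / axial_step_um
    lo = np.clip(np.floor(idx).astype(int), 0, nz - 2)
    frac = idx - lo
    v0 = np.take_along_axis(volume, lo, axis=0)
    v1 = np.take_along_axis(volume, lo + 1, axis=0)
    samples = v0 * (1.0 - frac) + v1 * frac
    if statistic == "mean":
        return samples.mean(axis=0)
    return samples.max(axis=0)
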