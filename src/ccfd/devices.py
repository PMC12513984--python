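"""OCTA instrument profiles.

A :class:`DeviceProfile` captures the scan geometry and sampling of one
acquisition mode: the swept-source instrument (``SS``, 3 x 3 mm at
1024 x 1024 px) and the spectral-domain instrument in its non-averaged
(``SD_V1``) and four-volume-averaged (``SD_V4``) modes (3 x 3 mm at
400 x 400 px).  Volume averaging is modelled purely as a reduction of the
additive noise standard deviation by the square root of the number of
averaged volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["DeviceProfile", "SS", "SD_V1", "SD_V4", "DEVICES", "get_device"]


@dataclass(frozen=True)
class DeviceProfile:
    """Scan geometry and sampling of one OCTA instrument/mode.

    Parameters
    ----------
    name : str
        Device label (``SS``, ``SD_V1`` or ``SD_V4``).
    scan_extent_mm : float
        Physical width/height of the square scan, millimetres.
    grid_px : int
        Pixels per side of the en-face grid.
    noise_sd : float
        Additive noise scale for one acquired volume, in normalized
        intensity units.
    n_averaged_volumes : int
        Number of independently acquired volumes averaged per scan
        (1 for SS and SD_V1, 4 for SD_V4).
    """

    name: str
    scan_extent_mm: float
    grid_px: int
    noise_sd: float = 0.03
    n_averaged_volumes: int = 1

    def __post_init__(self) -> None:
        if self.grid_px <= 0:
            raise ValueError(f"grid_px must be positive, got {self.grid_px}")
        if self.scan_extent_mm <= 0:
            raise ValueError(
                f"scan_extent_mm must be positive, got {self.scan_extent_mm}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.n_averaged_volumes < 1:
            raise ValueError("n_averaged_volumes must be >= 1")

    @property
    def pixel_size_um(self) -> float:
        """Physical pixel pitch in micrometres."""
        return 1000.0 * self.scan_extent_mm / self.grid_px

    def without_noise(self) -> "DeviceProfile":
        """Copy of this profile with the noise turned off."""
        return replace(self, noise_sd=0.0)


# Default profiles.  Grid sizes are the instruments' 3 x 3 mm grids; the
# noise scales are generator defaults (the SD instrument images the
# choriocapillaris through more RPE scattering, hence the larger value).
SS = DeviceProfile("SS", 3.0, 1024, noise_sd=0.03, n_averaged_volumes=1)
SD_V1 = DeviceProfile("SD_V1", 3.0, 400, noise_sd=0.06, n_averaged_volumes=1)
SD_V4 = DeviceProfile("SD_V4", 3.0, 400, noise_sd=0.06, n_averaged_volumes=4)

DEVICES: dict[str, DeviceProfile] = {d.name: d for d in (SS, SD_V1, SD_V4)}


def get_device(name: str) -> DeviceProfile:
    """Look up a default device profile by label (case-insensitive)."""
    key = name.upper()
    if key not in DEVICES:
        raise KeyError(
            f"unknown device {name!r}; known devices: {sorted(DEVICES)}"
        )
    return DEVICES[key]
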