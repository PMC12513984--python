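"""End-to-end orchestration: simulate → slab extract → compensate →
binarize → quantify → compare.

A run is fully described by a :class:`RunConfig` (YAML-serializable);
given fixed seeds the outputs are byte-identical between reruns, and every
output row carries a short hash of the processing parameters so tables
from different settings cannot be mixed silently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binarize import PhansalkarParams, phansalkar_threshold
from .compensate import CompensationParams, compensate
from .devices import DEVICES, DeviceProfile, get_device
from .quantify import quantify_fd
from .slabs import extract_enface, resolve_slab, slab_catalog
from .stats import build_comparison_tables, mixed_factorial_anova
from .synthetic import (
    REFERENCE_EXTENT_MM,
    REFERENCE_GRID_PX,
    GroundTruth,
    ShadowField,
    VesselNetworkParams,
    gaussian_band_profile,
    generate_cc_pattern,
    generate_volume,
    render_device_image,
)

__all__ = ["RunConfig", "run_pipeline", "process_pair", "recovery_scene"]

METRIC_CSV_COLUMNS = [
    "eye_id", "device", "slab", "fd_percent", "fd_count",
    "mean_fd_size_um2", "total_fd_area_mm2", "pixel_size_um", "params_hash",
]


@dataclass
class RunConfig:
    """Configuration of one synthetic cohort run."""

    n_eyes: int = 5
    devices: tuple = ("SS", "SD_V1", "SD_V4")
    slabs: tuple = ("automatic", "11-21", "21-31", "31-41", "16-31")
    seed: int = 0
    target_fd_range: tuple = (0.3, 0.6)
    n_drusen: int = 8
    drusen_radius_um: float = 100.0
    min_attenuation: float = 0.4
    blur_sigma_um: float = 15.0
    radius_px: int = 4
    connectivity: int = 8
    min_size_um2: float = 0.0
    use_volume: bool = True
    axial_step_um: float = 2.0
    bm_depth_um: float = 10.0
    extra_device_profiles: dict = field(default_factory=dict)

    def validate(self) -> None:
        for dev in self.devices:
            if dev not in DEVICES and dev not in self.extra_device_profiles:
                raise ValueError(f"unknown device {dev!r} in config")
        known = {s.name for s in slab_catalog("SS")}
        for slab in self.slabs:
            if slab not in known:
                raise ValueError(f"unknown slab {slab!r} in config")
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        lo, hi = self.target_fd_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("target_fd_range must be an increasing range in [0, 1]")

    def device(self, name: str) -> DeviceProfile:
        if name in self.extra_device_profiles:
            return DeviceProfile(**self.extra_device_profiles[name])
        return get_device(name)

    def params_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("devices", "slabs", "target_fd_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("devices", "slabs", "target_fd_range"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def process_pair(
    flow: np.ndarray,
    structural: np.ndarray,
    pixel_size_um: float,
    blur_sigma_um: float = 15.0,
    radius_px: int = 4,
    connectivity: int = 8,
    min_size_um2: float = 0.0,
    apply_compensation: bool = True,
):
    """Compensate, binarize and quantify one registered en-face pair."""
    img = (
        compensate(flow, structural, CompensationParams(blur_sigma_um), pixel_size_um)
        if apply_compensation
        else flow
    )
    mask = phansalkar_threshold(img, pixel_size_um, PhansalkarParams(radius_px))
    return quantify_fd(mask, min_size_um2=min_size_um2, connectivity=connectivity)


def recovery_scene(
    seed: int,
    target_fd_fraction: float,
    device: DeviceProfile | None = None,
    with_noise: bool = False,
    with_drusen: bool = False,
    apply_compensation: bool = True,
    radius_px: int = 4,
    blur_sigma_um: float = 15.0,
    n_drusen: int = 8,
    drusen_radius_um: float = 100.0,
    min_attenuation: float = 0.4,
) -> tuple[float, float]:
    """One synthetic scene through the whole pipeline.

    Returns ``(measured fd_percent, 100 * true deficit fraction)``.  The
    default device is the swept-source profile, whose grid matches the
    reference grid so geometry is not degraded by resampling.
    """
    if device is None:
        device = get_device("SS")
    if not with_noise:
        device = device.without_noise()
    truth = generate_cc_pattern(
        VesselNetworkParams(target_fd_fraction=target_fd_fraction, seed=seed)
    )
    if with_drusen:
        shadow = ShadowField.generate(
            REFERENCE_GRID_PX, REFERENCE_EXTENT_MM, n_drusen,
            drusen_radius_um, min_attenuation, seed=seed + 10_000,
        )
    else:
        shadow = ShadowField.uniform(REFERENCE_GRID_PX)
    pair = render_device_image(truth, shadow, device, seed=seed + 20_000)
    metrics = process_pair(
        pair.flow, pair.structural, pair.pixel_size_um,
        blur_sigma_um=blur_sigma_um, radius_px=radius_px,
        apply_compensation=apply_compensation,
    )
    return metrics.fd_percent, 100.0 * truth.fd_fraction_true


def _eye_volume(truth: GroundTruth, config: RunConfig, eye_seed: int):
    """CC band plus a coarser inner-choroid layer, below a flat BM."""
    bm = np.full(truth.flow_field.shape, config.bm_depth_um)
    cc_vol = generate_volume(
        truth, bm, config.axial_step_um,
        gaussian_band_profile(16.0, 9.0), dtype=np.float32,
    )
    choroid_truth = generate_cc_pattern(
        VesselNetworkParams(
            vessel_diameter_um=(40.0, 60.0),
            edge_gap_um=(20.0, 40.0),
            target_fd_fraction=0.35,
            planted_void_radius_um=100.0,
            seed=eye_seed + 7,
        )
    )
    cc_vol += generate_volume(
        choroid_truth, bm, config.axial_step_um,
        gaussian_band_profile(42.0, 10.0), dtype=np.float32,
    )
    np.clip(cc_vol, 0.0, 1.0, out=cc_vol)
    return cc_vol, bm


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run the full synthetic cohort and write metrics + comparison tables.

    Produces ``metrics.csv`` (one row per eye x device x slab),
    ``table1_analogue.csv``, ``table2_analogue.csv``, ``icc.csv`` and a
    ``report.json`` with the config, seeds and the two-way within-subject
    ANOVA over the device and slab factors.  Deterministic for fixed
    seeds.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phash = config.params_hash()

    rows = []
    for eye in range(config.n_eyes):
        eye_seed = int((config.seed * 1009 + eye * 13) % (2**31))
        rng = np.random.default_rng(eye_seed)
        target = rng.uniform(*config.target_fd_range)
        truth = generate_cc_pattern(
            VesselNetworkParams(target_fd_fraction=target, seed=eye_seed)
        )
        if config.n_drusen > 0:
            shadow = ShadowField.generate(
                REFERENCE_GRID_PX, REFERENCE_EXTENT_MM, config.n_drusen,
                config.drusen_radius_um, config.min_attenuation,
                seed=eye_seed + 1,
            )
        else:
            shadow = ShadowField.uniform(REFERENCE_GRID_PX)

        slab_fields: dict[tuple[float, float], GroundTruth] = {}
        if config.use_volume:
            volume, bm = _eye_volume(truth, config, eye_seed)
            # The same axial window yields the same en-face field for every
            # device; extract each distinct window once per eye.
            for dev_name in config.devices:
                for slab_name in config.slabs:
                    slab = resolve_slab(slab_name, dev_name)
                    key = (slab.z_inner_um, slab.z_outer_um)
                    if key in slab_fields:
                        continue
                    field2d = np.clip(
                        extract_enface(volume, bm, slab, config.axial_step_um)
                        .astype(np.float64),
                        0.0, 1.0,
                    )
                    slab_fields[key] = GroundTruth(
                        field2d, field2d == 0, float((field2d == 0).mean()),
                        truth.pixel_size_um,
                    )
            del volume

        for di, dev_name in enumerate(config.devices):
            device = config.device(dev_name)
            for si, slab_name in enumerate(config.slabs):
                slab = resolve_slab(slab_name, dev_name)
                if config.use_volume:
                    slab_truth = slab_fields[(slab.z_inner_um, slab.z_outer_um)]
                else:
                    slab_truth = truth
                pair = render_device_image(
                    slab_truth, shadow, device,
                    seed=int((eye_seed + 131 * di + 17 * si + 1) % (2**31)),
                )
                metrics = process_pair(
                    pair.flow, pair.structural, pair.pixel_size_um,
                    blur_sigma_um=config.blur_sigma_um,
                    radius_px=config.radius_px,
                    connectivity=config.connectivity,
                    min_size_um2=config.min_size_um2,
                )
                rows.append({
                    "eye_id": f"eye{eye:02d}",
                    "device": dev_name,
                    "slab": slab_name,
                    "fd_percent": metrics.fd_percent,
                    "fd_count": metrics.fd_count,
                    "mean_fd_size_um2": metrics.mean_fd_size_um2,
                    "total_fd_area_mm2": metrics.total_fd_area_mm2,
                    "pixel_size_um": metrics.pixel_size_um,
                    "params_hash": phash,
                })

    df = pd.DataFrame(rows, columns=METRIC_CSV_COLUMNS)
    df.to_csv(out / "metrics.csv", index=False)

    report = {"config": asdict(config), "params_hash": phash,
              "n_rows": len(df)}
    if config.n_eyes >= 5 and len(config.devices) >= 2 and len(config.slabs) >= 3:
        tables = build_comparison_tables(df)
        tables.to_csv(out)
        anova = mixed_factorial_anova(df)
        report["anova_device_slab"] = {
            factor: {
                "F": float(anova.loc[factor, "F Value"]),
                "p": float(anova.loc[factor, "Pr > F"]),
            }
            for factor in anova.index
        }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str)
    )
    return out
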