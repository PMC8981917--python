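"""Synthetic inputs with known ground truth for every pipeline stage.

The tensile generator produces J-shaped load-extension traces from an
explicit constitutive law — a quadratic toe joining the linear region with
continuous value and slope, followed by a single-sample rupture drop — so
the mechanics stage can be validated by parameter recovery: the linear
modulus, peak stress and rupture strain that generated a trace are exactly
known.  Companion generators emulate gripper-drag baselines, annulus images
with an angularly varying thickness, linear assay standard curves and
long-format dose-response tables.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .morphometry import SpecimenGeometry
from .traceio import TensileTrace, TestProtocol

__all__ = [
    "ConstitutiveParams",
    "gen_trace",
    "gen_drag_baseline",
    "gen_ring_image",
    "gen_dose_response",
    "gen_standard_series",
    "constant_thickness",
    "two_level_thickness",
    "sinusoidal_thickness",
    "write_cohort",
]


@dataclass(frozen=True)
class ConstitutiveParams:
    """Ground-truth parameters of one synthetic specimen.

    The model stress is a C1 piecewise law: a quadratic toe of extent
    ``toe_strain`` whose end slope equals ``linear_modulus`` (MPa), then a
    line of that slope until the stress reaches ``uts`` (MPa), then a
    single-sample drop to (1 - post_peak_drop_fraction) of the peak.  With
    ``failure_strain`` left None the rupture strain is derived so the peak
    stress equals ``uts`` exactly (toe/2 + uts/E); an explicit value
    truncates the pull early.  ``noise_sd`` and ``drag_amplitude`` are in mN;
    ``slack_mm`` is crosshead travel before the specimen engages.
    """

    linear_modulus: float  # MPa
    uts: float  # MPa
    toe_strain: float = 0.05
    failure_strain: float | None = None
    post_peak_drop_fraction: float = 0.6
    noise_sd: float = 0.0  # mN
    drag_amplitude: float = 0.0  # mN
    slack_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.linear_modulus <= 0:
            raise ValueError(f"linear_modulus must be positive, got {self.linear_modulus}")
        if self.uts <= 0:
            raise ValueError(f"uts must be positive, got {self.uts}")
        if self.toe_strain < 0:
            raise ValueError("toe_strain must be non-negative")
        if not 0.0 <= self.post_peak_drop_fraction <= 1.0:
            raise ValueError("post_peak_drop_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.drag_amplitude < 0:
            raise ValueError("noise_sd and drag_amplitude must be non-negative")
        if self.slack_mm < 0:
            raise ValueError("slack_mm must be non-negative")
        if self.failure_strain is not None and self.failure_strain <= self.toe_strain:
            raise ValueError(
                f"failure_strain {self.failure_strain} must exceed toe_strain "
                f"{self.toe_strain}"
            )

    @property
    def rupture_strain(self) -> float:
        """Strain at the rupture sample (derived from uts if not given)."""
        derived = self.toe_strain / 2.0 + self.uts / self.linear_modulus
        return derived if self.failure_strain is None else min(self.failure_strain, derived)

    def model_stress(self, strain) -> np.ndarray:
        """Noise-free model stress (MPa) at the given strain(s)."""
        eps = np.asarray(strain, dtype=float)
        E, toe = self.linear_modulus, self.toe_strain
        if toe > 0:
            toe_part = E / (2.0 * toe) * eps**2
        else:
            toe_part = np.zeros_like(eps)
        lin_part = E * (eps - toe / 2.0)
        sigma = np.where(eps < toe, toe_part, lin_part)
        return np.clip(sigma, 0.0, None)


def _drag_load(extension: np.ndarray, amplitude_mn: float, grip_distance: float) -> np.ndarray:
    """Smooth monotone drag profile bounded by the amplitude (returned in N)."""
    return amplitude_mn / 1000.0 * np.tanh(2.0 * np.asarray(extension) / grip_distance)


def gen_trace(
    params: ConstitutiveParams,
    geometry: SpecimenGeometry,
    protocol: TestProtocol | None = None,
    specimen_id: str = "synthetic",
) -> TensileTrace:
    """Simulate one pull-to-failure trace at the protocol's rate and speed.

    Load in N is drag(extension) + 2*A0*sigma_model(strain) + Gaussian noise,
    with strain measured from the end of the slack region over the true
    gauge length (initial grip distance + slack).  The trace ends one sample
    after the peak with the post-peak drop applied, so the 40%-drop
    termination rule fires on the final sample.
    """
    protocol = protocol or TestProtocol()
    a0 = geometry.a0_min
    if a0 <= 0:
        raise ValueError("geometry area must be positive")
    rng = np.random.default_rng(params.seed)
    dt = protocol.sampling_interval
    speed = protocol.crosshead_speed  # mm/s
    gauge_true = protocol.initial_grip_distance + params.slack_mm
    e_rupture = params.slack_mm + params.rupture_strain * gauge_true
    n_to_peak = int(math.ceil(e_rupture / (speed * dt)))
    t = np.arange(n_to_peak + 2) * dt
    ext = speed * t
    strain = np.clip((ext - params.slack_mm) / gauge_true, 0.0, None)
    stress = params.model_stress(strain)
    # first sample at/after the rupture strain is the peak; next sample drops
    k = int(np.searchsorted(strain, params.rupture_strain))
    k = min(k, len(strain) - 2)
    stress = stress[: k + 2]
    stress[k + 1] = (1.0 - params.post_peak_drop_fraction) * stress[k]
    t, ext = t[: k + 2], ext[: k + 2]
    load = _drag_load(ext, params.drag_amplitude, protocol.initial_grip_distance)
    load = load + 2.0 * a0 * stress
    if params.noise_sd > 0:
        load = load + rng.normal(0.0, params.noise_sd / 1000.0, size=load.shape)
    return TensileTrace(time=t, extension=ext, load=load, specimen_id=specimen_id)


def gen_drag_baseline(
    protocol: TestProtocol | None = None,
    drag_amplitude: float = 2.0,
    seed: int = 0,
    max_extension: float = 2.5,
    noise_sd: float = 0.0,
) -> TensileTrace:
    """Specimen-free baseline: the drag profile alone, over the full travel."""
    protocol = protocol or TestProtocol()
    if drag_amplitude < 0:
        raise ValueError("drag_amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    dt = protocol.sampling_interval
    speed = protocol.crosshead_speed
    n = int(math.ceil(max_extension / (speed * dt))) + 1
    t = np.arange(n) * dt
    ext = speed * t
    load = _drag_load(ext, drag_amplitude, protocol.initial_grip_distance)
    if noise_sd > 0:
        load = load + rng.normal(0.0, noise_sd / 1000.0, size=load.shape)
    return TensileTrace(
        time=t, extension=ext, load=load, specimen_id="baseline", is_baseline=True
    )


def constant_thickness(t_px: float):
    return lambda theta: np.full_like(np.asarray(theta, dtype=float), t_px)


def two_level_thickness(t1_px: float, t2_px: float):
    """t1 on [0, pi), t2 on [pi, 2*pi)."""

    def fn(theta):
        theta = np.mod(np.asarray(theta, dtype=float), 2.0 * np.pi)
        return np.where(theta < np.pi, t1_px, t2_px)

    return fn


def sinusoidal_thickness(mean_px: float, amplitude_px: float, lobes: int = 2):
    def fn(theta):
        return mean_px + amplitude_px * np.cos(lobes * np.asarray(theta, dtype=float))

    return fn


def gen_ring_image(
    inner_radius_px: float,
    thickness_fn,
    image_size: int = 256,
    seed: int = 0,
    noise_sd: float = 4.0,
    n_speckles: int = 0,
    foreground: int = 200,
    background: int = 30,
) -> np.ndarray:
    """Rasterize an annulus whose thickness at angle theta is thickness_fn(theta).

    Returns an 8-bit grayscale image with the ring centered in the frame,
    optional Gaussian intensity noise and small off-ring speckles.
    """
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    dy, dx = yy - c, xx - c
    r = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    t = np.asarray(thickness_fn(theta), dtype=float)
    t_probe = np.asarray(thickness_fn(np.linspace(0, 2 * np.pi, 720, endpoint=False)))
    if np.any(t_probe < 0.5):
        raise ValueError(
            "thickness_fn must be positive (>= 0.5 px, the rasterization floor) "
            f"at every angle; got min {float(t_probe.min()):.3g} px"
        )
    if inner_radius_px + float(t_probe.max()) >= image_size / 2.0:
        raise ValueError("ring exceeds the image frame")
    mask = (r >= inner_radius_px) & (r <= inner_radius_px + t)
    img = np.full((image_size, image_size), float(background))
    img[mask] = foreground
    rng = np.random.default_rng(seed)
    for _ in range(n_speckles):
        sy, sx = rng.integers(2, image_size - 4, size=2)
        if r[sy, sx] > inner_radius_px + t_probe.max() + 6 or r[sy, sx] < inner_radius_px - 6:
            img[sy : sy + 2, sx : sx + 2] = foreground
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def save_ring_image(img: np.ndarray, path) -> None:
    Image.fromarray(img, mode="L").save(path, format="PNG")


def gen_dose_response(
    group_means,
    group_sds,
    n_per_group: int,
    seed: int = 0,
    group_labels=None,
    endpoint: str = "value",
    day: int = 0,
) -> pd.DataFrame:
    """Long-format table of Gaussian samples, one block per group."""
    means = np.asarray(group_means, dtype=float)
    sds = np.asarray(group_sds, dtype=float)
    if means.shape != sds.shape:
        raise ValueError("group_means and group_sds must have equal length")
    if np.any(sds < 0):
        raise ValueError("standard deviations must be non-negative")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    labels = group_labels or [f"g{i}" for i in range(len(means))]
    rng = np.random.default_rng(seed)
    rows = []
    for g, mu, sd in zip(labels, means, sds):
        for i, v in enumerate(rng.normal(mu, sd, size=n_per_group)):
            rows.append(
                {
                    "specimen_id": f"{g}_{i:02d}",
                    "group": g,
                    "day": day,
                    "endpoint": endpoint,
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows)


def gen_standard_series(
    slope: float = 0.02,
    intercept: float = 0.0,
    masses_ug=(0.0, 5.0, 10.0, 20.0, 30.0, 50.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Absorbance standards on a known line, optionally with read noise."""
    rng = np.random.default_rng(seed)
    masses = np.asarray(masses_ug, dtype=float)
    absorbance = intercept + slope * masses
    if noise_sd > 0:
        absorbance = absorbance + rng.normal(0.0, noise_sd, size=masses.shape)
    return pd.DataFrame({"standard_ug": masses, "absorbance": absorbance})


def write_cohort(
    out_dir,
    group_moduli: dict[str, float],
    uts_over_modulus: float = 0.13,
    n_per_group: int = 8,
    seed: int = 0,
    noise_sd_fraction: float = 0.01,
    drag_amplitude: float = 2.0,
    width_mm: float = 0.6,
    height_mm: float = 0.6,
    protocol: TestProtocol | None = None,
) -> Path:
    """Write a complete synthetic experiment (traces, baseline, geometry, config).

    Each group gets ``n_per_group`` specimens with the group's linear modulus
    and a proportional peak stress (``uts = uts_over_modulus * E``); load
    noise is ``noise_sd_fraction`` of each specimen's peak load.  Returns the
    path of the experiment YAML consumed by the pipeline.
    """
    from . import traceio
    from .morphometry import write_geometry

    protocol = protocol or TestProtocol()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    geometry = SpecimenGeometry(widths=[width_mm], heights=[height_mm])
    baseline = gen_drag_baseline(
        protocol, drag_amplitude=drag_amplitude, seed=int(rng.integers(2**31))
    )
    traceio.write_trace(baseline, out_dir / "baseline.csv")
    groups_cfg = []
    for label, modulus in group_moduli.items():
        traces, geoms = [], []
        for i in range(n_per_group):
            uts = uts_over_modulus * modulus
            peak_load_mn = 2.0 * geometry.a0_min * uts * 1000.0
            params = ConstitutiveParams(
                linear_modulus=modulus,
                uts=uts,
                noise_sd=noise_sd_fraction * peak_load_mn,
                drag_amplitude=drag_amplitude,
                slack_mm=0.02,
                seed=int(rng.integers(2**31)),
            )
            sid = f"{label}_{i:02d}"
            trace = gen_trace(params, geometry, protocol, specimen_id=sid)
            tpath = out_dir / f"trace_{sid}.csv"
            gpath = out_dir / f"geom_{sid}.yaml"
            traceio.write_trace(trace, tpath)
            write_geometry(geometry, gpath)
            traces.append(tpath.name)
            geoms.append(gpath.name)
        groups_cfg.append({"label": label, "traces": traces, "geometries": geoms})
    traceio.write_protocol(protocol, out_dir / "protocol.yaml")
    config = {
        "protocol": "protocol.yaml",
        "baseline": "baseline.csv",
        "area_convention": "minimum",
        "stress_convention": "engineering",
        "groups": groups_cfg,
        "seed": seed,
    }
    cfg_path = out_dir / "experiment.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return cfg_path
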