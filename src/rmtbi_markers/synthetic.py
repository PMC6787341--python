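"""Synthetic-data generators with known ground truth.

Every input the analysis layers consume can be generated here:

* RPPM slides — serial 1:1 dilution series responding through a 5PL
  curve with multiplicative log-normal noise, plus planted sub-threshold
  and outlier spots;
* streamline bundles with analytic length and curvature (line, circle,
  helix phantoms);
* diffusion-tensor volumes with a specified eigenstructure;
* factorial behavioral tables (injury x recovery day) with specified
  cell means.

Each generator returns ``(data, GroundTruth)`` where the ground truth
records every planted parameter and label, and is bit-reproducible for a
given seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rmtbi_markers.fivepl import FivePL, eval_5pl

#: Default slide-wide 5PL: a 2.5-decade dynamic range (100 AU floor to
#: ~32k AU saturation over a 50 AU background), Hill slope and asymmetry
#: chosen so the 8-step 1:1 dilution window covers the full transition —
#: the regime in which all five parameters are statistically
#: identifiable from one slide.
DEFAULT_5PL = FivePL(A=2.0, D=4.5, C=-3.5, B=1.2, G=1.5)


class ConfigError(ValueError):
    """Invalid simulator configuration."""


@dataclass
class GroundTruth:
    """Planted simulator parameters and labels, JSON-serializable."""

    kind: str
    payload: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, FivePL):
                return {"A": o.A, "D": o.D, "C": o.C, "B": o.B, "G": o.G}
            raise TypeError(f"not JSON-serializable: {type(o)}")
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, **self.payload}, fh,
                      indent=2, default=_default)


def _check_finite(name: str, value) -> None:
    arr = np.asarray(value, float)
    if not np.isfinite(arr).all():
        raise ConfigError(f"non-finite value for {name}: {value}")


# ---------------------------------------------------------------------------
# RPPM slides

@dataclass
class SlideSimConfig:
    """Configuration of a simulated RPPM slide.

    ``true_abundance`` is the per-sample relative protein amount in
    arbitrary units (all ones by default); ``noise_sigma`` is the SD of
    the multiplicative log-normal noise in log10 units; proportions of
    planted outlier / sub-threshold spots are converted to counts by
    ``floor(fraction * n_spots)``.
    """

    n_samples: int = 16
    n_dilutions: int = 8
    depositions_per_spot: int = 2
    samples_per_block: int = 4
    true_5pl: FivePL = DEFAULT_5PL
    true_abundance: Sequence[float] | None = None
    noise_sigma: float = 0.02
    background_mean: float = 50.0
    outlier_fraction: float = 0.0
    outlier_scale: float = 10.0
    subthreshold_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dilutions < 4:
            raise ConfigError(f"n_dilutions must be >= 4, got {self.n_dilutions}")
        if self.n_samples < 1 or self.depositions_per_spot < 1:
            raise ConfigError("n_samples and depositions_per_spot must be >= 1")
        for name in ("noise_sigma", "background_mean", "outlier_scale"):
            _check_finite(name, getattr(self, name))
        for name in ("outlier_fraction", "subthreshold_fraction"):
            v = getattr(self, name)
            _check_finite(name, v)
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        if self.true_abundance is None:
            self.true_abundance = np.ones(self.n_samples)
        self.true_abundance = np.asarray(self.true_abundance, float)
        if len(self.true_abundance) != self.n_samples:
            raise ConfigError("true_abundance length must equal n_samples")
        _check_finite("true_abundance", self.true_abundance)
        if (self.true_abundance <= 0).any():
            raise ConfigError("abundances must be > 0")


def simulate_rppm_slide(config: SlideSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one slide: a spot row per (sample, dilution step, deposition).

    The expected net intensity of sample i at step k is the 5PL evaluated
    at log2(abundance_i * 2**-k); noise multiplies the net intensity
    log-normally (additive Gaussian in log10).  Planted outlier spots are
    multiplied by ``outlier_scale``; planted sub-threshold spots get an
    SNR drawn uniformly from [0.5, 1.9] so the SNR < 2 filter removes
    exactly them.  The ground truth records everything planted.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples * config.n_dilutions * config.depositions_per_spot
    sample_idx = np.repeat(np.arange(config.n_samples),
                           config.n_dilutions * config.depositions_per_spot)
    step = np.tile(np.repeat(np.arange(config.n_dilutions),
                             config.depositions_per_spot), config.n_samples)
    depo = np.tile(np.arange(config.depositions_per_spot),
                   config.n_samples * config.n_dilutions)

    x = np.log2(config.true_abundance[sample_idx]) - step
    expected_log10 = eval_5pl(x, config.true_5pl)
    log10_net = expected_log10 + rng.normal(0.0, config.noise_sigma, n) \
        if config.noise_sigma > 0 else expected_log10.copy()
    net = 10.0 ** log10_net

    # planted labels: floor(fraction * n), disjoint, by seeded shuffle
    n_out = int(math.floor(config.outlier_fraction * n))
    n_sub = int(math.floor(config.subthreshold_fraction * n))
    shuffled = rng.permutation(n)
    outlier_idx = np.sort(shuffled[:n_out])
    sub_idx = np.sort(shuffled[n_out:n_out + n_sub])
    net[outlier_idx] *= config.outlier_scale

    background = np.full(n, config.background_mean)
    raw = net + background
    snr = raw / background
    snr[sub_idx] = rng.uniform(0.5, 1.9, n_sub)

    table = pd.DataFrame({
        "sample_id": np.array([f"S{i:03d}" for i in range(config.n_samples)])[sample_idx],
        "block_id": np.array([f"B{i // config.samples_per_block:02d}"
                              for i in range(config.n_samples)])[sample_idx],
        "dilution_step": step,
        "deposition": depo,
        "raw": raw,
        "background": background,
        "snr": snr,
    })
    truth = GroundTruth(kind="rppm_slide", payload={
        "true_5pl": config.true_5pl,
        "true_abundance": {f"S{i:03d}": float(a)
                           for i, a in enumerate(config.true_abundance)},
        "expected_log10_net": expected_log10,
        "outlier_rows": outlier_idx,
        "subthreshold_rows": sub_idx,
        "noise_sigma": config.noise_sigma,
        "seed": config.seed,
    })
    return table, truth


def spread_abundances(n_samples: int, fold_range: float = 8.0) -> np.ndarray:
    """Log-spaced abundances spanning ``fold_range`` (geometric, centred
    on 1), emulating the inter-animal spread of a plasma protein."""
    half = 0.5 * math.log2(fold_range)
    return 2.0 ** np.linspace(-half, half, n_samples)


# ---------------------------------------------------------------------------
# streamline bundles

@dataclass
class TractSimConfig:
    """Analytic streamline-bundle phantom (line, circle or helix)."""

    geometry: str = "line"
    radius: float = 10.0      # mm (circle, helix)
    pitch: float = 1.0        # mm: helix rises 2*pi*pitch per turn
    length: float = 20.0      # mm (line); arc/axial extent handled per geometry
    n_streamlines: int = 10
    step_size: float = 0.2    # mm between consecutive points
    jitter_sigma: float = 0.0  # mm, perpendicular offset of whole centerline
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 1.0   # mm, isotropic
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("line", "circle", "helix"):
            raise ConfigError(f"unknown geometry {self.geometry!r}")
        if self.step_size <= 0 or self.voxel_size <= 0:
            raise ConfigError("step_size and voxel_size must be > 0")
        if self.n_streamlines < 1:
            raise ConfigError("n_streamlines must be >= 1")
        scale = self.length if self.geometry == "line" else self.radius
        if self.step_size > scale:
            raise ConfigError(
                f"step_size {self.step_size} exceeds geometry scale {scale}")


def _centerline(config: TractSimConfig) -> tuple[np.ndarray, float, float]:
    """Return (points, analytic_length, analytic_curvature)."""
    h = config.step_size
    if config.geometry == "line":
        n = max(int(round(config.length / h)) + 1, 2)
        t = np.linspace(0.0, config.length, n)
        pts = np.column_stack([t, np.zeros(n), np.zeros(n)])
        return pts, config.length, 0.0
    if config.geometry == "circle":
        r = config.radius
        circumference = 2 * math.pi * r
        n = max(int(round(circumference / h)), 8)
        theta = np.linspace(0.0, 2 * math.pi, n + 1)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta),
                               np.zeros(n + 1)])
        return pts, circumference, 1.0 / r
    # helix: x = r cos t, y = r sin t, z = c t; curvature r/(r^2 + c^2)
    r, c = config.radius, config.pitch
    speed = math.hypot(r, c)
    t_max = config.length / speed
    n = max(int(round(config.length / h)), 8)
    t = np.linspace(0.0, t_max, n + 1)
    pts = np.column_stack([r * np.cos(t), r * np.sin(t), c * t])
    return pts, config.length, r / (r * r + c * c)


def simulate_bundle(config: TractSimConfig) -> tuple[list[np.ndarray], GroundTruth]:
    """Sample ``n_streamlines`` copies of the analytic centerline, each
    optionally offset rigidly by a Gaussian perpendicular jitter (the
    rigid offset preserves the analytic length and curvature of the
    centerline in expectation)."""
    rng = np.random.default_rng(config.seed)
    center, true_len, true_curv = _centerline(config)
    # recentre into the middle of the grid
    grid_center = (np.asarray(config.grid_shape, float) - 1) / 2 * config.voxel_size
    offset0 = grid_center - center.mean(axis=0)
    streamlines = []
    for _ in range(config.n_streamlines):
        jitter = np.zeros(3)
        if config.jitter_sigma > 0:
            jitter = rng.normal(0.0, config.jitter_sigma, 3)
            if config.geometry == "line":
                jitter[0] = 0.0  # offsets perpendicular to the line axis
        streamlines.append(center + offset0 + jitter)
    truth = GroundTruth(kind="bundle", payload={
        "geometry": config.geometry,
        "length_mm": true_len,
        "curvature_per_mm": true_curv,
        "n_streamlines": config.n_streamlines,
        "seed": config.seed,
    })
    return streamlines, truth


# ---------------------------------------------------------------------------
# tensor volumes

@dataclass
class TensorSimConfig:
    """Homogeneous diffusion-tensor field with known eigenstructure."""

    grid_shape: tuple[int, int, int] = (8, 8, 8)
    eigenvalues: tuple[float, float, float] = (1.5e-3, 0.4e-3, 0.4e-3)
    principal_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    noise_sigma: float = 0.0   # additive on tensor elements, mm^2/s
    voxel_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, float)
        _check_finite("eigenvalues", ev)
        if not (ev[0] >= ev[1] >= ev[2]):
            raise ConfigError(f"eigenvalues must be descending, got {tuple(ev)}")
        d = np.asarray(self.principal_direction, float)
        if np.linalg.norm(d) == 0:
            raise ConfigError("principal_direction must be non-zero")


def _rotation_to(v: np.ndarray) -> np.ndarray:
    """Orthonormal matrix whose first column is v (normalized)."""
    v = v / np.linalg.norm(v)
    a = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u1 = np.cross(v, a)
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(v, u1)
    return np.column_stack([v, u1, u2])


def simulate_tensor_volume(config: TensorSimConfig) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Return (tensor volume, affine, truth).

    The tensor volume is shaped ``grid_shape + (6,)`` in lower-triangular
    order (dxx, dxy, dyy, dxz, dyz, dzz); the truth carries closed-form
    FA/RD/AD/trace maps.
    """
    from rmtbi_markers.dwi import fa_from_eigenvalues

    rng = np.random.default_rng(config.seed)
    ev = np.asarray(config.eigenvalues, float)
    R = _rotation_to(np.asarray(config.principal_direction, float))
    tensor = R @ np.diag(ev) @ R.T
    lower = np.array([tensor[0, 0], tensor[0, 1], tensor[1, 1],
                      tensor[0, 2], tensor[1, 2], tensor[2, 2]])
    vol = np.broadcast_to(lower, config.grid_shape + (6,)).copy()
    if config.noise_sigma > 0:
        vol = vol + rng.normal(0.0, config.noise_sigma, vol.shape)
    affine = np.diag([config.voxel_size] * 3 + [1.0])

    fa = fa_from_eigenvalues(ev)
    truth = GroundTruth(kind="tensor_volume", payload={
        "eigenvalues": ev,
        "FA": fa,
        "AD": float(ev[0]),
        "RD": float((ev[1] + ev[2]) / 2),
        "TR": float(ev.sum()),
        "seed": config.seed,
    })
    return vol, affine, truth


# ---------------------------------------------------------------------------
# factorial behavioral data

@dataclass
class BehaviorSimConfig:
    """2 (injury) x k (recovery day) between-subjects design.

    ``cell_means`` maps (injury, day) -> mean; ``n_per_cell`` maps the
    same keys to per-cell counts (unbalanced designs allowed, e.g.
    sham = 8 vs injured = 10).
    """

    cell_means: Mapping[tuple[str, str], float] = None
    residual_sd: float = 1.0
    n_per_cell: Mapping[tuple[str, str], int] | int = 8
    measure: str = "search_time"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_means is None:
            days = ("D1", "D3", "D5", "D7", "D30")
            self.cell_means = {(g, d): 0.0 for g in ("sham", "rmtbi") for d in days}
        if self.residual_sd < 0 or not math.isfinite(self.residual_sd):
            raise ConfigError(f"residual_sd must be finite >= 0, got {self.residual_sd}")
        if isinstance(self.n_per_cell, int):
            self.n_per_cell = {k: self.n_per_cell for k in self.cell_means}
        for k, n in self.n_per_cell.items():
            if n < 2:
                raise ConfigError(f"cell {k}: n must be >= 2, got {n}")


def simulate_factorial_data(config: BehaviorSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Independent normal observations per cell at the specified means."""
    rng = np.random.default_rng(config.seed)
    rows = []
    subj = 0
    for (injury, day), mu in sorted(config.cell_means.items()):
        n = config.n_per_cell[(injury, day)]
        vals = mu + rng.normal(0.0, config.residual_sd, n) \
            if config.residual_sd > 0 else np.full(n, float(mu))
        for v in vals:
            rows.append({"subject_id": f"R{subj:03d}", "injury": injury,
                         "recovery_day": day, "measure": config.measure,
                         "value": float(v)})
            subj += 1
    obs = pd.DataFrame(rows)
    means = {f"{g}|{d}": float(m) for (g, d), m in config.cell_means.items()}
    truth = GroundTruth(kind="factorial", payload={
        "cell_means": means,
        "residual_sd": config.residual_sd,
        "seed": config.seed,
    })
    return obs, truth
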