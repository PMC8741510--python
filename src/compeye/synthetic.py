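"""Synthetic data with embedded ground truth for every pipeline stage.

Generators emulate the study's raw inputs so each analysis stage can be
benchmarked against a known answer:

* a textured spherical-cap focus stack whose per-pixel sharpest layer
  lies exactly on the true surface, carrying a hexagonal facet lattice
  of known spacing and count;
* featureless (speckle-textured) bead stacks of known radius for the
  sphere-fit calibration;
* trait tables drawn from Y = a X^b with lognormal noise;
* dWBA trial sets with a saturating (Hill-form) contrast response,
  steep low-pass spatial tuning, band-pass temporal tuning, and per-fly
  Gaussian noise, together with the threshold values those tuning
  curves imply on the tested grids.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ValidationError
from .psychophysics import SAMPLING_RATE, STILL_PERIOD, WBATrial, temporal_acuity
from .stack import FocusStack

__all__ = [
    "EyeStackSpec",
    "WBASimSpec",
    "make_lattice_image",
    "make_eye_stack",
    "make_bead_stack",
    "make_allometry_table",
    "make_wba_dataset",
]


# --------------------------------------------------------------------------
# lattice images (flat benchmark for the facet detector)

def hex_lattice(spacing: float, extent: float,
                center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Hexagonal lattice points (row, col) covering a square of half-side
    ``extent`` around ``center``; nearest-neighbor distance = spacing."""
    dy = spacing * np.sqrt(3.0) / 2.0
    n_rows = int(np.ceil(extent / dy)) + 1
    n_cols = int(np.ceil(extent / spacing)) + 1
    pts = []
    for i in range(-n_rows, n_rows + 1):
        offset = (i % 2) * spacing / 2.0
        for j in range(-n_cols, n_cols + 1):
            pts.append((center[0] + i * dy, center[1] + j * spacing + offset))
    return np.asarray(pts)


def make_lattice_image(spacing: float = 20.0, n_spots: int = 500,
                       shape: tuple[int, int] | None = None,
                       noise_sd: float = 0.0, spot_sigma: float | None = None,
                       lattice: str = "hex",
                       seed: int | None = None) -> dict:
    """Flat image of bright lattice spots with known centers.

    The ``n_spots`` lattice points nearest the image center are rendered
    as Gaussian spots of width ``spot_sigma`` (default spacing/5).
    Returns image, centers (row, col), mask (disk hull of the spots),
    spacing.
    """
    rng = np.random.default_rng(seed)
    if spot_sigma is None:
        spot_sigma = spacing / 5.0
    # disk area needed for n_spots hexagonal (or square) cells
    cell = spacing**2 * (np.sqrt(3.0) / 2.0 if lattice == "hex" else 1.0)
    r_disk = np.sqrt(n_spots * cell / np.pi)
    if shape is None:
        side = int(2 * (r_disk + 3 * spacing))
        shape = (side, side)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    if lattice == "hex":
        pts = hex_lattice(spacing, r_disk + 2 * spacing)
    else:
        grid = np.arange(-r_disk - 2 * spacing, r_disk + 2 * spacing, spacing)
        pts = np.array([(y, x) for y in grid for x in grid])
    order = np.argsort(np.hypot(pts[:, 0], pts[:, 1]))
    centers = pts[order[:n_spots]] + [cy, cx]

    image = np.zeros(shape)
    yy, xx = np.indices(shape)
    # render by splatting into a fine grid then blurring once
    ridx = np.round(centers).astype(int)
    ok = ((ridx[:, 0] >= 0) & (ridx[:, 0] < shape[0])
          & (ridx[:, 1] >= 0) & (ridx[:, 1] < shape[1]))
    if not ok.all():
        raise ValidationError("lattice spots fall outside the image frame")
    image[ridx[:, 0], ridx[:, 1]] = 1.0
    image = ndimage.gaussian_filter(image, spot_sigma)
    image /= image.max()
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, shape)
    r_hull = np.hypot(centers[:, 0] - cy, centers[:, 1] - cx).max() + spacing
    mask = np.hypot(yy - cy, xx - cx) <= r_hull
    return {"image": image, "centers": centers, "mask": mask,
            "spacing": spacing, "count": len(centers)}


# --------------------------------------------------------------------------
# focus stacks of spherical caps

@dataclass
class EyeStackSpec:
    """Parameters of a rendered spherical-cap focus stack.

    Defaults emulate a fly eye: radius ~250 um, 30-degree cap, ~20 um
    facets, ~20 focal layers.
    """

    radius: float = 250.0                 # um
    half_angle_v: float = 30.0            # degrees (vertical, image rows)
    half_angle_h: float = 30.0            # degrees (horizontal, image cols)
    facet_spacing: float = 20.0           # um
    n_layers: int = 20
    delta_h: float = 6.0                  # um
    pixel_scale: float = 1.0              # um per pixel
    noise_sd: float = 0.005
    blur_per_layer: float = 4.0           # defocus blur (px of sigma) per delta_h
    speckle_amplitude: float = 0.5
    speckle_corr: float = 0.0             # correlation length of the speckle, px
    spot_sigma_frac: float = 0.2          # spot width as a fraction of spacing
    seed: int = 0
    margin: int = 12                      # background border, pixels

    def __post_init__(self) -> None:
        for name in ("radius", "facet_spacing", "delta_h", "pixel_scale"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 < self.half_angle_v <= 90 and 0 < self.half_angle_h <= 90):
            raise ValidationError("half-angles must be in (0, 90] degrees")
        if self.n_layers < 2:
            raise ValidationError("need at least 2 layers")


@dataclass
class WBASimSpec:
    """Parameters of the simulated wingbeat-analyzer experiment.

    Tuning defaults are steep so every tested grid value is clearly sub-
    or super-threshold: a Hill contrast response (C50, exponent q), an
    exponent-8 spatial low-pass at ``spatial_corner`` CPD, and a
    band-pass in temporal frequency (high-pass corner ``temporal_lo``,
    steep low-pass at ``temporal_hi``).  ``fly_sd`` is the per-fly
    response variability (normalized response units) that dominates the
    detection statistics.
    """

    n_flies: int = 20
    contrasts: tuple = (0.05, 0.09, 0.15, 0.25, 0.35, 0.45,
                        0.55, 0.70, 0.85, 0.98)
    spatial_frequencies: tuple = (0.01, 0.02, 0.03, 0.04, 0.05,
                                  0.06, 0.08, 0.10, 0.13, 0.16)
    temporal_frequencies: tuple = (1.0, 2.0, 3.0, 5.0, 7.0,
                                   10.0, 15.0, 20.0, 30.0, 45.0)
    gain: float = 1.0
    c50: float = 0.24
    hill_exponent: float = 5.0
    spatial_corner: float = 0.12    # CPD
    spatial_exponent: float = 8.0
    temporal_lo: float = 2.0        # Hz, high-pass corner
    temporal_hi: float = 25.0       # Hz, low-pass corner
    temporal_exponent: float = 4.0
    fly_sd: float = 0.06
    gain_sd: float = 0.15
    trace_noise_sd: float = 0.25
    duration: float = 3.0           # s
    lighting: float = 35.0
    detection_z: float = 2.576      # criterion used to derive truth thresholds
    seed: int = 0

    def __post_init__(self) -> None:
        for grid in (self.contrasts, self.spatial_frequencies,
                     self.temporal_frequencies):
            if len(grid) == 0:
                raise ValidationError("stimulus grids must be non-empty")
            if np.any(np.diff(grid) <= 0):
                raise ValidationError("stimulus grids must be ascending")
        if self.fly_sd < 0 or self.trace_noise_sd < 0:
            raise ValidationError("noise SDs must be >= 0")

    # tuning curves -------------------------------------------------------
    def contrast_response(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        num = (c / self.c50) ** self.hill_exponent
        return num / (1.0 + num)

    def spatial_response(self, nu) -> np.ndarray:
        nu = np.asarray(nu, dtype=float)
        return np.exp(-((nu / self.spatial_corner) ** self.spatial_exponent))

    def temporal_response(self, f) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        hp = (f / self.temporal_lo) ** 2 / (1.0 + (f / self.temporal_lo) ** 2)
        lp = np.exp(-((f / self.temporal_hi) ** self.temporal_exponent))
        return hp * lp

    def expected_response(self, contrast, nu_s, nu_t) -> np.ndarray:
        return (self.gain * self.contrast_response(contrast)
                * self.spatial_response(nu_s) * self.temporal_response(nu_t))

    @property
    def detection_criterion(self) -> float:
        """Expected response at which the group mean clears the 99% CI rule."""
        return self.detection_z * self.fly_sd / np.sqrt(self.n_flies)


def _speckle(shape: tuple[int, int], corr: float,
             rng: np.random.Generator) -> np.ndarray:
    """Zero-mean random field; ``corr`` = 0 gives per-pixel grain."""
    f = rng.normal(size=shape)
    if corr > 0:
        f = ndimage.gaussian_filter(f, corr)
    return f / (np.abs(f).max() + 1e-12)


def _render_cap_stack(radius: float, half_angle_v: float, half_angle_h: float,
                      n_layers: int, delta_h: float, pixel_scale: float,
                      scene_texture, noise_sd: float, blur_per_layer: float,
                      margin: int, rng: np.random.Generator) -> dict:
    """Shared dome renderer.

    The cap footprint is the ellipse with semi-axes R sin(theta_h),
    R sin(theta_v); height above the footprint plane's lowest rim point
    is sqrt(R^2 - d^2) - z_ref.  Layer k shows the scene blurred by a
    defocus proportional to |height - k delta_h| (quantized to the layer
    grid so the per-pixel sharpest layer is exactly the nearest one).
    """
    a = radius * np.sin(np.radians(half_angle_h)) / pixel_scale  # px, cols
    b = radius * np.sin(np.radians(half_angle_v)) / pixel_scale  # px, rows
    W = int(2 * a) + 2 * margin + 1
    H = int(2 * b) + 2 * margin + 1
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.indices((H, W))
    dx = (xx - cx) * pixel_scale
    dy = (yy - cy) * pixel_scale
    mask = (dx / (a * pixel_scale)) ** 2 + (dy / (b * pixel_scale)) ** 2 <= 1.0
    r2 = dx**2 + dy**2
    z_sphere = np.sqrt(np.maximum(radius**2 - r2, 0.0))
    theta_max = max(half_angle_v, half_angle_h)
    z_ref = radius * np.cos(np.radians(theta_max))
    heights = np.where(mask, z_sphere - z_ref, np.nan)
    h_max = np.nanmax(heights)
    if h_max > (n_layers - 1) * delta_h:
        raise ValidationError(
            f"cap height span {h_max:.1f} um exceeds the stack depth "
            f"{(n_layers - 1) * delta_h:.1f} um; increase n_layers or delta_h"
        )

    scene = scene_texture((H, W), mask, (cy, cx))
    # blur bank: one blurred scene per integer layer distance; per-pixel
    # defocus interpolates linearly between bank levels so focus decays
    # continuously (and monotonically) with distance from the surface
    bank = np.stack([
        scene if j == 0 else ndimage.gaussian_filter(scene, blur_per_layer * j)
        for j in range(n_layers)
    ])
    h_filled = np.where(mask, heights, 0.0)
    rows, cols = np.indices((H, W))
    layers = np.empty((n_layers, H, W))
    for k in range(n_layers):
        d = np.abs(h_filled - k * delta_h) / delta_h
        d = np.clip(d, 0.0, n_layers - 1 - 1e-9)
        j0 = d.astype(int)
        w = d - j0
        lo = bank[j0, rows, cols]
        hi = bank[np.minimum(j0 + 1, n_layers - 1), rows, cols]
        layers[k] = (1.0 - w) * lo + w * hi
    # background outside the cap: featureless
    layers = np.where(mask[None], layers, scene[mask].mean())
    if noise_sd > 0:
        layers = layers + rng.normal(0.0, noise_sd, layers.shape)
    stack = FocusStack(layers=layers, delta_h=delta_h, pixel_scale=pixel_scale)
    return {"stack": stack, "heights": heights, "mask": mask,
            "center_px": (cy, cx), "footprint_semiaxes_px": (b, a)}


def make_eye_stack(spec: EyeStackSpec) -> dict:
    """Spherical-cap focus stack with a hexagonal facet lattice.

    Returns the stack plus embedded truth: per-pixel surface heights and
    footprint mask, facet centers (row, col) and count, lattice spacing
    in pixels, eye radius, and the angular FOV (2 x half-angles).
    """
    rng = np.random.default_rng(spec.seed)
    spacing_px = spec.facet_spacing / spec.pixel_scale
    truth: dict = {}

    def texture(shape, mask, center):
        cy, cx = center
        pts = hex_lattice(spacing_px, max(shape)) + [cy, cx]
        ridx = np.round(pts).astype(int)
        ok = ((ridx[:, 0] >= 0) & (ridx[:, 0] < shape[0])
              & (ridx[:, 1] >= 0) & (ridx[:, 1] < shape[1]))
        pts, ridx = pts[ok], ridx[ok]
        inside = mask[ridx[:, 0], ridx[:, 1]]
        pts, ridx = pts[inside], ridx[inside]
        spots = np.zeros(shape)
        spots[ridx[:, 0], ridx[:, 1]] = 1.0
        spots = ndimage.gaussian_filter(spots,
                                        spec.spot_sigma_frac * spacing_px)
        spots /= spots.max()
        scene = (0.2 + 0.8 * spots
                 + spec.speckle_amplitude
                 * _speckle(shape, spec.speckle_corr, rng))
        truth["facet_centers"] = pts
        truth["facet_count"] = len(pts)
        return np.clip(scene, 0.0, None)

    out = _render_cap_stack(
        spec.radius, spec.half_angle_v, spec.half_angle_h, spec.n_layers,
        spec.delta_h, spec.pixel_scale, texture, spec.noise_sd,
        spec.blur_per_layer, spec.margin, rng,
    )
    truth.update({
        "heights": out["heights"],
        "mask": out["mask"],
        "radius": spec.radius,
        "lattice_spacing_px": spacing_px,
        "facet_spacing_um": spec.facet_spacing,
        "fov_vertical": 2.0 * spec.half_angle_v,
        "fov_horizontal": 2.0 * spec.half_angle_h,
    })
    return {"stack": out["stack"], "truth": truth}


def make_bead_stack(radius: float, n_layers: int = 20,
                    half_angle: float = 40.0, frame: int = 320,
                    noise_sd: float = 0.005, blur_per_layer: float = 2.0,
                    seed: int = 0) -> dict:
    """Speckle-textured spherical bead focus stack of known radius.

    The pixel scale and depth step adapt to the radius so the bead fills
    a fixed fraction of the frame at any nominal size.
    """
    if not radius > 0:
        raise ValidationError("bead radius must be positive")
    rng = np.random.default_rng(seed)
    footprint = radius * np.sin(np.radians(half_angle))
    pixel_scale = footprint / (0.42 * frame)
    delta_h = radius * (1.0 - np.cos(np.radians(half_angle))) / (n_layers - 1)

    def texture(shape, mask, center):
        return 0.5 + 0.45 * _speckle(shape, 1.5, rng)

    out = _render_cap_stack(radius, half_angle, half_angle, n_layers,
                            delta_h, pixel_scale, texture, noise_sd,
                            blur_per_layer, 10, rng)
    return {"stack": out["stack"],
            "truth": {"radius": radius, "heights": out["heights"],
                      "mask": out["mask"]}}


# --------------------------------------------------------------------------
# allometry tables

def make_allometry_table(a: float = 2.0, b: float = 0.7, n: int = 30,
                         sigma_log: float = 0.05,
                         x_range: tuple[float, float] = (1500.0, 3000.0),
                         groups: dict | None = None,
                         seed: int = 0) -> dict:
    """Trait table drawn from Y = a X^b with lognormal noise.

    ``groups`` optionally maps genotype label -> (a, b); otherwise a
    single group "g0" with the top-level (a, b) is produced.  X (body
    length, um) is log-uniform over ``x_range``.
    """
    rng = np.random.default_rng(seed)
    if groups is None:
        groups = {"g0": (a, b)}
    rows = []
    truth = {}
    for label, (ga, gb) in groups.items():
        x = np.exp(rng.uniform(np.log(x_range[0]), np.log(x_range[1]), n))
        y = ga * x**gb * np.exp(rng.normal(0.0, sigma_log, n))
        for xi, yi in zip(x, y):
            rows.append({"genotype": label, "body_length": xi,
                         "eye_length": yi})
        truth[label] = {"a": ga, "b": gb}
    return {"table": pd.DataFrame(rows), "truth": truth}


# --------------------------------------------------------------------------
# dWBA trial sets

def _make_trace(mu: float, n: int, fs: float, still: float,
                rng: np.random.Generator) -> np.ndarray:
    """Response envelope: zero through the still period, ramping to the
    plateau ``mu`` by 0.4 s (inside the 0.5-2 s analysis window)."""
    t = np.arange(n) / fs
    env = np.clip((t - still) / 0.2, 0.0, 1.0)
    return mu * env


def make_wba_dataset(spec: WBASimSpec,
                     experiment: str = "contrast") -> dict:
    """Simulated trials for one experiment plus implied truth thresholds.

    Per fly x condition x direction a 3 s, 1 kHz left/right trace pair
    is produced: zero-mean during the still period, then a plateau at
    gain_f * expected_response + a per-(fly, condition) deviation, plus
    white trace noise.  Truth thresholds are the grid values at which
    the expected responses cross the generator's detection criterion
    (and, for temporal acuity, the >50% drop rule applied to the
    expected means).
    """
    rng = np.random.default_rng(spec.seed)
    fs = SAMPLING_RATE
    n_samples = int(round(spec.duration * fs))

    base = {"contrast": max(spec.contrasts),
            "spatial": 0.04, "temporal": 10.0}
    if experiment == "contrast":
        grid = np.asarray(spec.contrasts)
        expected = spec.expected_response(grid, base["spatial"],
                                          base["temporal"])
    elif experiment == "spatial":
        grid = np.asarray(spec.spatial_frequencies)
        expected = spec.expected_response(base["contrast"], grid,
                                          base["temporal"])
    elif experiment == "temporal":
        grid = np.asarray(spec.temporal_frequencies)
        expected = spec.expected_response(base["contrast"], base["spatial"],
                                          grid)
    else:
        raise ValidationError(f"unknown experiment kind {experiment!r}")

    fly_gain = np.maximum(rng.normal(1.0, spec.gain_sd, spec.n_flies), 0.0)
    trials: list[WBATrial] = []
    for fi in range(spec.n_flies):
        fly_id = f"fly{fi:03d}"
        wba_base = 60.0 + 5.0 * rng.normal()  # arbitrary wingbeat units
        for ci, cond in enumerate(grid):
            mu = expected[ci] * fly_gain[fi] + rng.normal(0.0, spec.fly_sd)
            for direction in ("left", "right"):
                signed = mu if direction == "left" else -mu
                d_env = _make_trace(signed, n_samples, fs, STILL_PERIOD, rng)
                noise_l = rng.normal(0.0, spec.trace_noise_sd, n_samples)
                noise_r = rng.normal(0.0, spec.trace_noise_sd, n_samples)
                kwargs = {"contrast": base["contrast"],
                          "spatial_frequency": base["spatial"],
                          "temporal_frequency": base["temporal"]}
                key = {"contrast": "contrast", "spatial": "spatial_frequency",
                       "temporal": "temporal_frequency"}[experiment]
                kwargs[key] = float(cond)
                trials.append(WBATrial(
                    fly_id=fly_id,
                    left=wba_base + d_env / 2.0 + noise_l,
                    right=wba_base - d_env / 2.0 + noise_r,
                    direction=direction,
                    lighting=spec.lighting,
                    experiment=experiment,
                    **kwargs,
                ))

    crit = spec.detection_criterion
    detected = expected >= crit
    truth: dict = {"grid": grid.tolist(),
                   "expected_response": expected.tolist(),
                   "detected": detected.tolist(),
                   "detection_criterion": crit}
    if experiment == "contrast":
        truth["c_min"] = float(grid[detected].min()) if detected.any() else None
    elif experiment == "spatial":
        truth["spatial_acuity"] = (float(grid[detected].max())
                                   if detected.any() else None)
    else:
        if detected.any():
            ta = temporal_acuity(grid, expected / expected.max(), detected)
            truth["temporal_acuity"] = ta["acuity"]
            truth["temporal_censored"] = ta["censored"]
        else:
            truth["temporal_acuity"] = None
    return {"trials": trials, "truth": truth, "spec": spec}
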