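"""Seeded synthetic-data generators for every analysis stage.

Each generator is a pure function of its parameters and a seed, and
returns the artifact together with a machine-readable ground-truth record,
so round-trip tests compare analysis output against truth rather than
hard-coded numbers.  The generators emulate the structures the analyses
assume in real transmission images of wrinkled colonies:

* radially striped colony images whose stripe count follows
  ``N(r) = round(2 pi r / lambda)`` — stripes bifurcate as the radius
  grows so the local spacing stays within ``[lambda/sqrt(2), lambda sqrt(2)]``;
* expanding colony contours with a velocity break at ``t_c`` and petal
  modulation afterwards;
* blister side profiles that narrow and heighten towards a contact stage
  whose half-height width is twice the film thickness;
* ``(G_f/G_s, lambda/h_f)`` wavelength datasets drawn from the trilayer
  stability model with multiplicative log-normal noise.

Intensity conventions match the normalisation contract (bright background
whose histogram mode maps to 0.9), so ``normalize_and_segment`` runs on
generated images unmodified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mechanics import LayerStack
from .metrics import BlisterProfile
from .theory import ModelValidityError, StiffnessScan, solve_wrinkling

__all__ = [
    "SyntheticScene",
    "gen_radial_pattern_image",
    "gen_colony_series",
    "gen_blister_series",
    "gen_stiffness_dataset",
]


@dataclass(frozen=True)
class SyntheticScene:
    """Parameterisation shared by the image/contour generators.

    Lengths are millimetres, times hours.  Defaults are sized like a
    day-old wrinkled colony: ~6 mm radius, ~1 mm intrinsic wavelength,
    50 um pixels.
    """

    seed: int = 0
    pixel_size_mm: float = 0.05
    image_shape: tuple[int, int] = (300, 300)
    colony_radius_mm: float = 6.0
    lambda_mm: float = 1.0             #: intrinsic wavelength of radial features
    pattern_inner_mm: float = 1.5      #: R_p: radius where the pattern begins
    pattern_amplitude: float = 0.2     #: angular intensity modulation depth
    colony_level: float = 0.45         #: mean normalised intensity inside colony
    background_level: float = 0.9
    noise_sigma: float = 0.0           #: additive Gaussian sigma on intensity
    times_hr: tuple[float, ...] = tuple(float(t) for t in range(12, 72, 2))
    radius0_mm: float = 1.0            #: colony radius at the first frame
    v_before: float = 0.12             #: expansion speed before t_c (mm/hr)
    v_after: float = 0.05              #: expansion speed after t_c (mm/hr)
    t_c_hr: float = 40.0               #: velocity-break (wrinkling-onset) time
    petal_count: int = 6
    petal_amplitude_max: float = 0.15
    blister_arcs: tuple[tuple[float, float, float], ...] = ()  #: (r_mm, theta0, dtheta)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _polar_grids(scene: SyntheticScene) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = scene.image_shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    y, x = np.mgrid[0:ny, 0:nx]
    dx = (x - cx) * scene.pixel_size_mm
    dy = (y - cy) * scene.pixel_size_mm
    return np.hypot(dx, dy), np.arctan2(dy, dx)


def gen_radial_pattern_image(scene: SyntheticScene) -> tuple[np.ndarray, dict]:
    """Radially striped colony image with a fixed intrinsic wavelength.

    The stripe count at radius r is ``N(r) = round(2 pi r / lambda)``;
    where the count increments a stripe bifurcates, keeping the local
    spacing ``2 pi r / N(r)`` within a factor sqrt(2) of ``lambda``.
    Optional dark blister arcs and additive Gaussian noise are applied
    last.  Returns ``(image, truth)``.
    """
    if scene.lambda_mm < 4 * scene.pixel_size_mm:
        raise ValueError(
            f"wavelength {scene.lambda_mm} mm is below 4 pixels "
            f"({4 * scene.pixel_size_mm} mm)")
    r, theta = _polar_grids(scene)
    rng = scene.rng()
    img = np.full(scene.image_shape, scene.background_level)
    inside = r <= scene.colony_radius_mm
    img[inside] = scene.colony_level

    patterned = inside & (r >= scene.pattern_inner_mm) \
        & (r <= scene.colony_radius_mm - 2 * scene.pixel_size_mm)
    N_of_r = np.rint(2.0 * np.pi * r / scene.lambda_mm)
    phase = rng.uniform(0, 2 * np.pi)
    img[patterned] += scene.pattern_amplitude * np.cos(
        N_of_r[patterned] * theta[patterned] + phase)

    for (rb, t0, dth) in scene.blister_arcs:
        band = (np.abs(r - rb) < 1.5 * scene.pixel_size_mm) \
            & (((theta - t0) % (2 * np.pi)) < dth)
        img[band] = max(0.05, scene.colony_level - 0.3)

    if scene.noise_sigma > 0:
        img = img + rng.normal(0.0, scene.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.2)
    ny, nx = scene.image_shape
    truth = {
        "lambda_true_mm": scene.lambda_mm,
        "colony_radius_mm": scene.colony_radius_mm,
        "pattern_inner_mm": scene.pattern_inner_mm,
        "pattern_amplitude": scene.pattern_amplitude,
        "center_px": ((nx - 1) / 2.0, (ny - 1) / 2.0),
        "pixel_size_mm": scene.pixel_size_mm,
        "noise_sigma": scene.noise_sigma,
        "phase": phase,
        "seed": scene.seed,
    }
    return img, truth


def _radius_law(scene: SyntheticScene, t: float) -> float:
    if t <= scene.t_c_hr:
        return scene.radius0_mm + scene.v_before * (t - scene.times_hr[0])
    r_c = scene.radius0_mm + scene.v_before * (scene.t_c_hr - scene.times_hr[0])
    return r_c + scene.v_after * (t - scene.t_c_hr)


def gen_colony_series(scene: SyntheticScene, images: bool = False
                      ) -> tuple[list[np.ndarray], dict]:
    """Time series of colony masks (or images) with a velocity break.

    The mean radius grows piecewise-linearly with slopes ``v_before`` /
    ``v_after`` breaking at ``t_c``; after ``t_c`` the boundary develops a
    petal modulation ``r(theta) = R(t)(1 + a(t) cos(k theta))`` whose
    amplitude ramps linearly to ``petal_amplitude_max`` by the final frame.
    Returns ``(frames, truth)`` where frames are boolean masks, or
    background/colony intensity images when ``images=True``.
    """
    times = np.asarray(scene.times_hr, dtype=float)
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    r, theta = _polar_grids(scene)
    t_end = times[-1]
    frames: list[np.ndarray] = []
    R_series, a_series = [], []
    for t in times:
        R = _radius_law(scene, t)
        if t <= scene.t_c_hr or t_end == scene.t_c_hr:
            a = 0.0
        else:
            a = scene.petal_amplitude_max * (t - scene.t_c_hr) / (t_end - scene.t_c_hr)
        boundary = R * (1.0 + a * np.cos(scene.petal_count * theta))
        mask = r <= boundary
        R_series.append(R)
        a_series.append(a)
        if images:
            img = np.full(scene.image_shape, scene.background_level)
            img[mask] = scene.colony_level
            if scene.noise_sigma > 0:
                img = img + scene.rng().normal(0, scene.noise_sigma, img.shape)
            frames.append(np.clip(img, 0, 1.2))
        else:
            frames.append(mask)
    ny, nx = scene.image_shape
    truth = {
        "times_hr": times.tolist(),
        "t_c_hr": scene.t_c_hr,
        "v_before_mm_hr": scene.v_before,
        "v_after_mm_hr": scene.v_after,
        "petal_count": scene.petal_count,
        "petal_amplitude_series": a_series,
        "mean_radius_series_mm": R_series,
        "center_px": ((nx - 1) / 2.0, (ny - 1) / 2.0),
        "pixel_size_mm": scene.pixel_size_mm,
        "seed": scene.seed,
    }
    return frames, truth


def gen_blister_series(hf: float = 0.1, n_stages: int = 5,
                       initial_width: float | None = None,
                       initial_height: float | None = None,
                       final_height: float | None = None,
                       n_samples: int = 801, seed: int = 0,
                       ) -> tuple[list[BlisterProfile], dict]:
    """Side-view blister profiles narrowing towards wall contact.

    Stage 0 is a wide, low cosine bump; later stages are flat-topped
    profiles with tanh walls whose half-height width shrinks to exactly
    ``2 hf`` (the contact stage, where the two film walls meet) while the
    height grows monotonically.  Lengths share the unit of ``hf``
    (millimetres in the examples).  Returns ``(profiles, truth)``.
    """
    if hf <= 0:
        raise ValueError("film thickness must be positive")
    if n_stages < 2:
        raise ValueError("need at least two stages")
    W0 = 10.0 * hf if initial_width is None else initial_width
    H0 = 0.8 * hf if initial_height is None else initial_height
    H1 = 4.0 * hf if final_height is None else final_height
    if W0 <= 2 * hf:
        raise ValueError("initial width must exceed the contact width 2 hf")
    span = 1.5 * W0      # leaves flat flanks outside the widest bump
    x = np.linspace(-span, span, n_samples)
    profiles: list[BlisterProfile] = []
    H_series, W_series = [], []
    for j in range(n_stages):
        s = j / (n_stages - 1)
        H = H0 + (H1 - H0) * s
        W = W0 + (2.0 * hf - W0) * s
        if j == 0:
            z = np.where(np.abs(x) < W0, 0.5 * H0 * (1 + np.cos(np.pi * x / W0)), 0.0)
        else:
            wall = max(0.02 * hf, 0.02 * W)
            d = W / 2.0
            z = 0.5 * (np.tanh((x + d) / wall) - np.tanh((x - d) / wall))
            z *= H / z.max()
        profiles.append(BlisterProfile(x=x.copy(), z=z))
        H_series.append(float(H))
        W_series.append(float(W))
    truth = {
        "hf": hf,
        "H_series": H_series,
        "W_series": W_series,
        "final_W_over_hf": W_series[-1] / hf,
        "seed": seed,
    }
    return profiles, truth


def gen_stiffness_dataset(stack_template: LayerStack, gr_true: float,
                          ratios: np.ndarray, noise_sigma: float = 0.0,
                          seed: int = 0) -> tuple[StiffnessScan, dict]:
    """Wavelength-vs-stiffness dataset drawn from the trilayer model.

    For each stiffness contrast ``G_f/G_s`` the normalised wavelength
    ``lambda_cr/h_f`` is computed with the residual modulus set to
    ``gr_true x G_f`` and multiplied by log-normal noise
    ``exp(N(0, sigma))``.  Ratios where the solver fails are dropped and
    recorded.  Returns ``(scan, truth)``.
    """
    if not 0 < gr_true <= 1:
        raise ValueError("gr_true must lie in (0, 1]")
    ratios = np.sort(np.asarray(ratios, dtype=float))
    if np.any(ratios <= 0):
        raise ValueError("stiffness ratios must be positive")
    from dataclasses import replace
    rng = np.random.default_rng(seed)
    kept, lam, failures = [], [], []
    for r in ratios:
        gs = stack_template.substrate.G
        stk = replace(stack_template, film=replace(stack_template.film, G=r * gs))
        stk = replace(stk, residual=replace(stk.residual, G=gr_true * stk.film.G))
        try:
            sol = solve_wrinkling(stk)
        except (ModelValidityError, ValueError) as exc:
            failures.append((float(r), str(exc)))
            continue
        noise = math.exp(rng.normal(0.0, noise_sigma)) if noise_sigma > 0 else 1.0
        kept.append(float(r))
        lam.append(sol.lambda_cr / stk.film.h * noise)
    scan = StiffnessScan(ratios=np.array(kept), normalized_wavelengths=np.array(lam),
                         failures=failures)
    truth = {"gr_true": gr_true, "noise_sigma": noise_sigma, "seed": seed,
             "n_points": len(kept), "n_dropped": len(failures)}
    return scan, truth
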