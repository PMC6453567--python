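"""Plane-strain finite-element simulation of growth-induced wrinkling.

The trilayer (film / residual / substrate) occupies the rectangle
``[0, L] x [0, h_f + h_r + h_s]`` in the undeformed reference frame.  The
film and residual layers grow uniaxially in ``X_1`` via the multiplicative
decomposition ``F = F_e F_g`` with ``F_g = diag(1+g, 1)``; the substrate
does not grow (``F_g = I``).  Each layer is a compressible neo-Hookean
solid with energy density

    Psi(F_e) = (mu_e/2)(I_C - 2 - 2 ln J) + (lambda_e/2)(ln J)^2,

``I_C = tr(F_e^T F_e)``, ``J = det F_e``, and Lamé parameters from the
layer's shear modulus and Poisson ratio.  At each growth increment the
total energy ``Pi = sum_e area_e Psi(F_e) J_g`` is minimised over nodal
displacements subject to ``u_1 = 0`` on the side walls and ``u_2 = 0`` on
the bottom (laterally confined, bottom-supported domain).  Growth is
stepped in increments ``dg`` (default 0.002); wrinkle onset is the first
step at which the surface deflection — the deviation of the top-surface
vertical displacement from its mean, which excludes the uniform Poisson
thickening of the flat state — exceeds ``0.01 h_f``.

The mesh is a structured crossed-triangle mesh (four first-order triangles
per quad around a centre node, which mitigates volumetric locking at
``nu = 0.45``); layer interfaces coincide with element rows and substrate
rows coarsen geometrically with depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import eigsh, splu

from .mechanics import LayerStack, growth_strain, lame_parameters
from .theory import solve_wrinkling

__all__ = [
    "FemConfig",
    "Mesh",
    "DeformationState",
    "SimulationResult",
    "build_mesh",
    "neo_hookean_energy_density",
    "total_energy",
    "minimize_energy",
    "run_growth",
    "strain_fields",
    "dominant_surface_wavelength",
]

_LABELS = {"film": 0, "residual": 1, "substrate": 2}


@dataclass(frozen=True)
class FemConfig:
    """Parameters of a growth simulation (normalised units: h_f = G_s = 1)."""

    L: float                        #: domain length (m)
    hf: float = 1.0                 #: film thickness (m)
    hr_over_hf: float = 0.3
    hs_over_hf: float = 10.0
    gf_over_gs: float = 10.0
    gr_over_gf: float = 0.1
    gs: float = 1.0                 #: substrate shear modulus (Pa)
    nu: float = 0.45                #: Poisson ratio, all layers
    dg: float = 0.002               #: growth increment
    g_max: float = 0.4
    onset_threshold: float = 0.01   #: deflection threshold, fraction of h_f
    perturbation_amplitude: float = 1e-4  #: surface perturbation, fraction of h_f
    seed: int = 0
    elements_per_hf: int = 4        #: element rows through the film
    elements_per_wavelength: int = 12  #: horizontal resolution target
    steps_past_onset: int = 10      #: extra increments simulated after onset
    gtol_scale: float = 1e-8        #: projected-gradient tol, x G_f h_f^2
    max_iter: int = 60              #: Newton iterations per growth step

    def __post_init__(self) -> None:
        if self.dg <= 0:
            raise ValueError("growth increment must be positive")
        if self.g_max > 1:
            raise ValueError("g_max must not exceed 1")
        if self.hr_over_hf <= 0:
            raise ValueError("residual layer thickness ratio must be positive")
        if not 0 < self.nu < 0.5:
            raise ValueError("FEM requires 0 < nu < 0.5")
        if self.elements_per_hf < 1:
            raise ValueError("need at least one element row through the film")

    @property
    def stack(self) -> LayerStack:
        return LayerStack.from_ratios(
            gf_over_gs=self.gf_over_gs, gr_over_gf=self.gr_over_gf,
            hr_over_hf=self.hr_over_hf, hs_over_hf=self.hs_over_hf,
            hf=self.hf, gs=self.gs, nu=self.nu,
        )

    @classmethod
    def for_stack(cls, stack: LayerStack, wavelengths: float = 10.0, **kw) -> "FemConfig":
        """Config sized from the theory prediction: ``L = wavelengths x lambda_cr``."""
        lam = solve_wrinkling(stack).lambda_cr
        return cls(
            L=wavelengths * lam,
            hf=stack.film.h,
            hr_over_hf=stack.residual.h / stack.film.h,
            hs_over_hf=stack.substrate.h / stack.film.h,
            gf_over_gs=stack.film.G / stack.substrate.G,
            gr_over_gf=stack.residual.G / stack.film.G,
            gs=stack.substrate.G,
            **kw,
        )


@dataclass
class Mesh:
    """Structured crossed-triangle mesh with layer labels.

    ``coords`` are undeformed node positions (n_nodes, 2); ``triangles``
    (n_elem, 3) are positively oriented; ``labels`` maps each element to
    film (0) / residual (1) / substrate (2).
    """

    coords: np.ndarray
    triangles: np.ndarray
    labels: np.ndarray
    top_nodes: np.ndarray      #: surface node ids, sorted by X_1
    fixed_x: np.ndarray        #: node ids with u_1 = 0 (side walls)
    fixed_y: np.ndarray        #: node ids with u_2 = 0 (bottom)

    # assembly caches, built lazily
    _grads: np.ndarray | None = field(default=None, repr=False)
    _areas: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def element_geometry(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-element shape-function gradients (n_e, 3, 2) and areas."""
        if self._grads is None:
            X = self.coords[self.triangles]            # (ne, 3, 2)
            e1 = X[:, 1] - X[:, 0]
            e2 = X[:, 2] - X[:, 0]
            det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
            if np.any(det <= 0):
                raise ValueError("mesh contains non-positively-oriented triangles")
            inv = np.empty((len(det), 2, 2))
            inv[:, 0, 0] = e2[:, 1] / det
            inv[:, 0, 1] = -e2[:, 0] / det
            inv[:, 1, 0] = -e1[:, 1] / det
            inv[:, 1, 1] = e1[:, 0] / det
            dN = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # d(N)/d(xi,eta)
            self._grads = np.einsum("ak,ekj->eaj", dN, inv)
            self._areas = 0.5 * det
        return self._grads, self._areas


@dataclass
class DeformationState:
    """Per-element kinematic and strain fields at one growth state."""

    u: np.ndarray           #: nodal displacements (n_nodes, 2)
    F: np.ndarray           #: deformation gradient (n_e, 2, 2)
    F_e: np.ndarray         #: elastic part F F_g^{-1}
    J: np.ndarray           #: det F_e
    I_C: np.ndarray         #: tr(F_e^T F_e)
    green_lagrange: np.ndarray   #: e = (F_e^T F_e - I)/2, (n_e, 2, 2)
    deviatoric: np.ndarray       #: e' = e - (tr e / 2) I
    von_mises: np.ndarray        #: (2 e'_ij e'_ij / 3)^{1/2}


@dataclass
class SimulationResult:
    """Trajectory of an incremental growth simulation."""

    config: FemConfig
    mesh: Mesh
    g_series: np.ndarray
    deflection_series: np.ndarray   #: max |u_2,top - mean| per step (m)
    energy_series: np.ndarray
    onset_g: float | None           #: first g with deflection > threshold
    onset_strain: float | None      #: g/(1+g) at onset, None if no onset
    u_final: np.ndarray
    surface_x: np.ndarray           #: undeformed X_1 of surface nodes
    surface_u2: np.ndarray          #: final surface vertical displacement
    measured_wavelength: float | None  #: dominant FFT wavelength of u_2,top

    @property
    def no_onset(self) -> bool:
        return self.onset_g is None

    def final_state(self) -> DeformationState:
        g = float(self.g_series[-1]) if self.g_series.size else 0.0
        return strain_fields(self.u_final, self.mesh, self.config, g)


# ---------------------------------------------------------------------------
# meshing

def _graded_thicknesses(total: float, first: float, ratio: float = 2.0) -> list[float]:
    """Row thicknesses coarsening geometrically until ``total`` is filled,
    then rescaled to fit exactly."""
    rows, t = [], first
    while sum(rows) < total:
        rows.append(t)
        t *= ratio
    scale = total / sum(rows)
    return [r * scale for r in rows]


def build_mesh(config: FemConfig) -> Mesh:
    """Structured crossed-triangle mesh conforming to the layer interfaces."""
    hf = config.hf
    hr = config.hr_over_hf * hf
    hs = config.hs_over_hf * hf
    config.stack.require_thick_substrate()

    dy_f = hf / config.elements_per_hf
    n_res_rows = max(2, round(hr / dy_f))
    sub_rows = _graded_thicknesses(hs, dy_f)[::-1]  # coarse at bottom

    y_levels = [0.0]
    for t in sub_rows:
        y_levels.append(y_levels[-1] + t)
    y_levels[len(sub_rows)] = hs  # exact interface
    for i in range(n_res_rows):
        y_levels.append(hs + hr * (i + 1) / n_res_rows)
    for i in range(config.elements_per_hf):
        y_levels.append(hs + hr + hf * (i + 1) / config.elements_per_hf)
    y = np.array(y_levels)

    # horizontal resolution from the predicted wavelength
    lam = solve_wrinkling(config.stack).lambda_cr
    dx_target = lam / config.elements_per_wavelength
    nx = max(8, int(round(config.L / dx_target)))
    x = np.linspace(0.0, config.L, nx + 1)

    ny = len(y) - 1
    corner = np.arange((nx + 1) * (ny + 1)).reshape(ny + 1, nx + 1)
    xx, yy = np.meshgrid(x, y)
    coords = np.column_stack([xx.ravel(), yy.ravel()])

    # centre nodes, one per quad
    cx = 0.5 * (x[:-1] + x[1:])
    cy = 0.5 * (y[:-1] + y[1:])
    cxx, cyy = np.meshgrid(cx, cy)
    centre = np.arange(nx * ny).reshape(ny, nx) + coords.shape[0]
    coords = np.vstack([coords, np.column_stack([cxx.ravel(), cyy.ravel()])])

    # element row labels
    row_label = np.empty(ny, dtype=np.int8)
    row_label[: len(sub_rows)] = _LABELS["substrate"]
    row_label[len(sub_rows): len(sub_rows) + n_res_rows] = _LABELS["residual"]
    row_label[len(sub_rows) + n_res_rows:] = _LABELS["film"]

    tris, labels = [], []
    for j in range(ny):
        bl, br = corner[j, :-1], corner[j, 1:]
        tl, tr = corner[j + 1, :-1], corner[j + 1, 1:]
        c = centre[j]
        # four CCW triangles per quad: bottom, right, top, left
        tris.append(np.stack([bl, br, c], axis=1))
        tris.append(np.stack([br, tr, c], axis=1))
        tris.append(np.stack([tr, tl, c], axis=1))
        tris.append(np.stack([tl, bl, c], axis=1))
        labels.extend([row_label[j]] * (4 * nx))
    triangles = np.vstack(tris)
    labels = np.asarray(labels, dtype=np.int8)

    top = corner[-1, :]
    sides = np.concatenate([corner[:, 0], corner[:, -1]])
    bottom = corner[0, :]
    return Mesh(coords=coords, triangles=triangles, labels=labels,
                top_nodes=top, fixed_x=np.unique(sides), fixed_y=bottom)


# ---------------------------------------------------------------------------
# constitutive law and energy

def neo_hookean_energy_density(F_e: np.ndarray, mu_e: float, lam_e: float) -> float:
    """Compressible neo-Hookean energy density for a single 2x2 F_e."""
    F_e = np.asarray(F_e, dtype=float)
    J = F_e[0, 0] * F_e[1, 1] - F_e[0, 1] * F_e[1, 0]
    if J <= 0:
        raise ValueError(f"inverted configuration: det F_e = {J}")
    I_C = float(np.sum(F_e * F_e))
    lnJ = math.log(J)
    return 0.5 * mu_e * (I_C - 2.0 - 2.0 * lnJ) + 0.5 * lam_e * lnJ**2


def _material_arrays(mesh: Mesh, config: FemConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-element (mu_e, lambda_e, grows) arrays."""
    stack = config.stack
    mus = np.array([stack.film.G, stack.residual.G, stack.substrate.G])
    lams = np.array([lame_parameters(G, config.nu)[1] for G in mus])
    grows = np.array([True, True, False])
    lab = mesh.labels
    return mus[lab], lams[lab], grows[lab]


def _deformation(u: np.ndarray, mesh: Mesh, g: float, grows: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-element F, F_e, J, a_g (growth stretch) for displacement field u."""
    grads, _ = mesh.element_geometry()
    U = u[mesh.triangles]                       # (ne, 3, 2)
    F = np.einsum("eai,eaj->eij", U, grads)
    F[:, 0, 0] += 1.0
    F[:, 1, 1] += 1.0
    a_g = np.where(grows, 1.0 + g, 1.0)         # F_g = diag(a_g, 1)
    F_e = F.copy()
    F_e[:, :, 0] /= a_g[:, None]                # F F_g^{-1}: first column scaled
    J = F_e[:, 0, 0] * F_e[:, 1, 1] - F_e[:, 0, 1] * F_e[:, 1, 0]
    return F, F_e, J, a_g


def _energy_and_gradient(u_flat: np.ndarray, mesh: Mesh, config: FemConfig,
                         g: float, cache: dict) -> tuple[float, np.ndarray]:
    """Total energy and its analytic nodal gradient, vectorised."""
    mu, lam, grows = cache["materials"]
    grads, areas = mesh.element_geometry()
    u = u_flat.reshape(-1, 2)
    _, F_e, J, a_g = _deformation(u, mesh, g, grows)
    if np.any(J <= 0):
        # barrier: line search backs off an inverted trial step
        return 1e8 * config.gs * config.hf**2 * (1 + int(np.sum(J <= 0))), np.zeros_like(u_flat)
    lnJ = np.log(J)
    I_C = np.einsum("eij,eij->e", F_e, F_e)
    psi = 0.5 * mu * (I_C - 2.0 - 2.0 * lnJ) + 0.5 * lam * lnJ**2
    w = areas * a_g                              # J_g = a_g in plane strain
    energy = float(np.sum(w * psi))

    # P = dPsi/dF_e = mu (F_e - F_e^{-T}) + lam lnJ F_e^{-T}
    FinvT = np.empty_like(F_e)
    FinvT[:, 0, 0] = F_e[:, 1, 1]
    FinvT[:, 0, 1] = -F_e[:, 1, 0]
    FinvT[:, 1, 0] = -F_e[:, 0, 1]
    FinvT[:, 1, 1] = F_e[:, 0, 0]
    FinvT /= J[:, None, None]
    P = mu[:, None, None] * (F_e - FinvT) + (lam * lnJ)[:, None, None] * FinvT
    # dPsi/dF = P F_g^{-T}: first column scaled by 1/a_g
    P[:, :, 0] /= a_g[:, None]
    # per-node force contributions: w * P_ij grad_aj
    f = np.einsum("e,eij,eaj->eai", w, P, grads)
    grad = np.zeros_like(u)
    np.add.at(grad, mesh.triangles.ravel(), f.reshape(-1, 2))
    grad[cache["fixed_mask"]] = 0.0
    return energy, grad.ravel()


def _make_cache(mesh: Mesh, config: FemConfig) -> dict:
    fixed_mask = np.zeros((mesh.n_nodes, 2), dtype=bool)
    fixed_mask[mesh.fixed_x, 0] = True
    fixed_mask[mesh.fixed_y, 1] = True
    free = np.flatnonzero(~fixed_mask.ravel())
    # sparse assembly index pattern: element dof (a, i) -> global dof
    edof = (2 * mesh.triangles[:, :, None] + np.arange(2)[None, None, :]).reshape(-1, 6)
    rows = np.repeat(edof, 6, axis=1).ravel()
    cols = np.tile(edof, (1, 6)).ravel()
    return {"materials": _material_arrays(mesh, config), "fixed_mask": fixed_mask,
            "free": free, "hess_rows": rows, "hess_cols": cols}


def _assemble_hessian(u: np.ndarray, mesh: Mesh, config: FemConfig, g: float,
                      cache: dict) -> sparse.csr_matrix:
    """Analytic tangent stiffness d^2 Pi / du^2 as a sparse matrix.

    The material tangent of the neo-Hookean law, with Q = F_e^{-T}, is
    D_ijkl = mu d_ik d_jl + (mu - lam lnJ) Q_il Q_kj + lam Q_ij Q_kl;
    the growth map enters by scaling the shape-function gradients
    columnwise with F_g^{-1} (exact for F constant per element).
    """
    mu, lam, grows = cache["materials"]
    grads, areas = mesh.element_geometry()
    _, F_e, J, a_g = _deformation(u, mesh, g, grows)
    lnJ = np.log(J)
    Q = np.empty_like(F_e)                       # F_e^{-T}
    Q[:, 0, 0] = F_e[:, 1, 1]
    Q[:, 0, 1] = -F_e[:, 1, 0]
    Q[:, 1, 0] = -F_e[:, 0, 1]
    Q[:, 1, 1] = F_e[:, 0, 0]
    Q /= J[:, None, None]

    eye = np.eye(2)
    D = (mu[:, None, None, None, None] * np.einsum("ik,jl->ijkl", eye, eye)
         + (mu - lam * lnJ)[:, None, None, None, None]
         * np.einsum("eil,ekj->eijkl", Q, Q)
         + lam[:, None, None, None, None] * np.einsum("eij,ekl->eijkl", Q, Q))
    # chain rule through F_e = F F_g^{-1}: scale gradient columns by 1/a_g
    Bp = grads.copy()
    Bp[:, :, 0] /= a_g[:, None]
    w = areas * a_g
    Ke = np.einsum("e,eijkl,eaj,ebl->eaibk", w, D, Bp, Bp)
    H = sparse.coo_matrix(
        (Ke.reshape(-1), (cache["hess_rows"], cache["hess_cols"])),
        shape=(2 * mesh.n_nodes, 2 * mesh.n_nodes)).tocsr()
    return H


def total_energy(u: np.ndarray, mesh: Mesh, config: FemConfig, g: float) -> float:
    """Total elastic energy Pi of displacement field ``u`` at growth ``g``.

    Exact for affine displacements (F is constant per linear triangle).
    """
    if g < 0:
        raise ValueError("growth parameter must be non-negative")
    mu, lam, grows = _material_arrays(mesh, config)
    _, F_e, J, a_g = _deformation(np.asarray(u, dtype=float), mesh, g, grows)
    if np.any(J <= 0):
        bad = int(np.argmax(J <= 0))
        raise ValueError(f"inverted element {bad}: det F_e = {J[bad]:.3g}")
    _, areas = mesh.element_geometry()
    lnJ = np.log(J)
    I_C = np.einsum("eij,eij->e", F_e, F_e)
    psi = 0.5 * mu * (I_C - 2.0 - 2.0 * lnJ) + 0.5 * lam * lnJ**2
    return float(np.sum(areas * a_g * psi))


def _apply_bcs(u: np.ndarray, mesh: Mesh) -> np.ndarray:
    u = u.copy()
    u[mesh.fixed_x, 0] = 0.0
    u[mesh.fixed_y, 1] = 0.0
    return u


def _smallest_mode(H: sparse.csc_matrix) -> tuple[float, np.ndarray | None]:
    """Smallest eigenvalue (nearest zero) of the reduced tangent and its mode."""
    try:
        vals, vecs = eigsh(H, k=1, sigma=0.0, which="LM")
        return float(vals[0]), vecs[:, 0]
    except (RuntimeError, ValueError, ArithmeticError):
        return 0.0, None


def minimize_energy(u_init: np.ndarray, mesh: Mesh, config: FemConfig,
                    g: float, cache: dict | None = None) -> np.ndarray:
    """Minimise Pi over nodal displacements at fixed growth ``g``.

    Damped Newton descent on the BC-reduced unknowns: the analytic sparse
    tangent is factorised each iteration and the Newton step is safeguarded
    by Levenberg damping (added when the step is not a descent direction)
    and an Armijo backtracking line search on the energy.  Because plain
    Newton converges to *stationary* points, a converged iterate is
    accepted only if the tangent is positive semi-definite there; at an
    unstable (saddle) equilibrium — the flat branch above the wrinkling
    threshold — the smallest-eigenvalue mode is followed downhill instead
    and the iteration continues, which is what lets the solver leave the
    flat branch for the wrinkled one.  Raises if the projected-gradient
    norm does not reach tolerance.
    """
    cache = cache or _make_cache(mesh, config)
    u = _apply_bcs(np.asarray(u_init, dtype=float), mesh)
    free = cache["free"]
    gtol = config.gtol_scale * config.gf_over_gs * config.gs * config.hf**2
    energy, grad = _energy_and_gradient(u.ravel(), mesh, config, g, cache)
    tau = 0.0
    mu_scale = config.gf_over_gs * config.gs
    escapes = 0
    for _ in range(config.max_iter):
        gf = grad[free]
        gnorm = float(np.max(np.abs(gf))) if gf.size else 0.0
        if gnorm <= gtol:
            if config.perturbation_amplitude <= 0 or escapes >= 5:
                return u
            H_conv = _assemble_hessian(u, mesh, config, g, cache)[free][:, free].tocsc()
            lam_min, v = _smallest_mode(H_conv)
            if v is None or lam_min >= -1e-8 * float(np.max(H_conv.diagonal())):
                return u  # stable equilibrium
            # saddle: follow the unstable mode downhill
            v = v / np.max(np.abs(v))
            stepped = False
            for s in config.hf * np.geomspace(0.3, 1e-3, 7):
                for sign in (1.0, -1.0):
                    trial = u.ravel().copy()
                    trial[free] += sign * s * v
                    e_t, g_t = _energy_and_gradient(trial, mesh, config, g, cache)
                    if e_t < energy - abs(energy) * 1e-14:
                        u = trial.reshape(-1, 2)
                        energy, grad = e_t, g_t
                        stepped = True
                        break
                if stepped:
                    break
            if not stepped:
                return u  # unstable mode is energetically flat at this resolution
            escapes += 1
            continue
        H = _assemble_hessian(u, mesh, config, g, cache)[free][:, free].tocsc()
        d = None
        while True:
            try:
                Hd = H if tau == 0.0 else (H + tau * sparse.identity(H.shape[0], format="csc"))
                d = splu(Hd).solve(-gf)
            except RuntimeError:
                d = None
            if d is not None and np.dot(d, gf) < 0 and np.all(np.isfinite(d)):
                break
            tau = max(10.0 * tau, 1e-6 * mu_scale)
            if tau > 1e12 * mu_scale:
                raise RuntimeError(
                    f"Newton direction unusable at g={g:.4f} despite damping")
        # Armijo backtracking
        slope = float(np.dot(d, gf))
        alpha, accepted = 1.0, False
        for _ in range(40):
            trial = u.ravel().copy()
            trial[free] += alpha * d
            e_t, g_t = _energy_and_gradient(trial, mesh, config, g, cache)
            if e_t <= energy + 1e-4 * alpha * slope:
                u = trial.reshape(-1, 2)
                energy, grad = e_t, g_t
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            tau = max(10.0 * tau, 1e-6 * mu_scale)
            if tau > 1e12 * mu_scale:
                raise RuntimeError(
                    f"line search failed at g={g:.4f}: gradient norm {gnorm:.3e}")
            continue
        tau *= 0.25  # relax damping after a successful step
        if tau < 1e-10 * mu_scale:
            tau = 0.0
    gf = grad[free]
    gnorm = float(np.max(np.abs(gf)))
    if gnorm > 50 * gtol:
        raise RuntimeError(
            f"energy minimisation did not converge at g={g:.4f}: "
            f"projected-gradient norm {gnorm:.3e} > {50 * gtol:.3e}")
    return u


def _surface_perturbation(mesh: Mesh, config: FemConfig, rng: np.random.Generator
                          ) -> np.ndarray:
    """Fixed multi-sine vertical perturbation of the film surface nodes.

    Breaks the symmetry of the flat branch so the minimiser can leave it;
    the random phases are seeded, so runs are reproducible.
    """
    x = mesh.coords[mesh.top_nodes, 0]
    n_modes = min(40, max(4, len(x) // 4))
    amps = rng.uniform(0.5, 1.0, n_modes)
    phases = rng.uniform(0, 2 * np.pi, n_modes)
    prof = np.zeros_like(x)
    for k in range(1, n_modes + 1):
        prof += amps[k - 1] * np.sin(2 * np.pi * k * x / config.L + phases[k - 1])
    if np.max(np.abs(prof)) > 0:
        prof *= 1.0 / np.max(np.abs(prof))
    return config.perturbation_amplitude * config.hf * prof


def dominant_surface_wavelength(x: np.ndarray, u2: np.ndarray, L: float) -> float | None:
    """Dominant nonzero-mode FFT wavelength of a surface profile.

    Returns None when no mode clearly dominates (flat surface).
    """
    h = u2 - np.mean(u2)
    if np.max(np.abs(h)) == 0:
        return None
    # drop the duplicated right-edge sample for an exactly periodic grid
    power = np.abs(np.fft.rfft(h[:-1])) ** 2
    power[0] = 0.0
    k = int(np.argmax(power))
    if k == 0 or power[k] < 1e-12 * np.sum(power):
        return None
    return L / k


def run_growth(config: FemConfig) -> SimulationResult:
    """Incremental growth simulation g = dg, 2 dg, ... with onset detection.

    Each step warm-starts from the previous equilibrium plus the seeded
    surface perturbation.  The run stops ``steps_past_onset`` increments
    after onset (or at ``g_max``); the final surface is Fourier-analysed
    for the dominant wrinkle wavelength.
    """
    mesh = build_mesh(config)
    cache = _make_cache(mesh, config)
    rng = np.random.default_rng(config.seed)
    pert = _surface_perturbation(mesh, config, rng)

    u = np.zeros((mesh.n_nodes, 2))
    g_list, defl_list, en_list = [], [], []
    onset_g: float | None = None
    steps_after = 0
    n_steps = int(round(config.g_max / config.dg))
    for step in range(1, n_steps + 1):
        g = step * config.dg
        u_start = u.copy()
        u_start[mesh.top_nodes, 1] += pert
        u = minimize_energy(u_start, mesh, config, g, cache)
        u2_top = u[mesh.top_nodes, 1]
        defl = float(np.max(np.abs(u2_top - np.mean(u2_top))))
        g_list.append(g)
        defl_list.append(defl)
        en_list.append(total_energy(u, mesh, config, g))
        if onset_g is None and defl > config.onset_threshold * config.hf:
            onset_g = g
        if onset_g is not None:
            steps_after += 1
            if steps_after > config.steps_past_onset:
                break

    surface_x = mesh.coords[mesh.top_nodes, 0]
    surface_u2 = u[mesh.top_nodes, 1]
    lam = dominant_surface_wavelength(surface_x, surface_u2, config.L) \
        if onset_g is not None else None
    return SimulationResult(
        config=config, mesh=mesh,
        g_series=np.array(g_list),
        deflection_series=np.array(defl_list),
        energy_series=np.array(en_list),
        onset_g=onset_g,
        onset_strain=growth_strain(onset_g) if onset_g is not None else None,
        u_final=u, surface_x=surface_x, surface_u2=surface_u2,
        measured_wavelength=lam,
    )


def strain_fields(u: np.ndarray, mesh: Mesh, config: FemConfig, g: float
                  ) -> DeformationState:
    """Per-element Green-Lagrange, deviatoric and von Mises strain fields.

    e = (F_e^T F_e - I)/2;  e'_ij = e_ij - (e_kk/2) delta_ij;
    eps_vM = sqrt(2 e'_ij e'_ij / 3).
    """
    _, _, grows = _material_arrays(mesh, config)
    u = np.asarray(u, dtype=float)
    F, F_e, J, _ = _deformation(u, mesh, g, grows)
    if np.any(J <= 0):
        bad = int(np.argmax(J <= 0))
        raise ValueError(f"inverted element {bad}: det F_e = {J[bad]:.3g}")
    C = np.einsum("eki,ekj->eij", F_e, F_e)
    e = 0.5 * (C - np.eye(2))
    tr = e[:, 0, 0] + e[:, 1, 1]
    dev = e.copy()
    dev[:, 0, 0] -= 0.5 * tr
    dev[:, 1, 1] -= 0.5 * tr
    vm = np.sqrt(2.0 / 3.0 * np.einsum("eij,eij->e", dev, dev))
    I_C = np.einsum("eij,eij->e", F_e, F_e)
    return DeformationState(u=u, F=F, F_e=F_e, J=J, I_C=I_C,
                            green_lagrange=e, deviatoric=dev, von_mises=vm)
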