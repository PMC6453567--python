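"""Trilayer film-on-substrate wrinkling linear-stability solver.

A growing stiff film (shear modulus ``G_f``, thickness ``h_f``) bonded to a
thin compliant residual layer (``G_r``, ``h_r``) on a thick substrate
(``G_s``) buckles into wrinkles once the growth-induced compressive stress
reaches a critical value.  Assuming a sinusoidal surface undulation of
wavenumber ``n``, the longitudinal film stress required to sustain it is

    S(n) = G_f h_f^2 n^2 / 3  +  K(n) / (h_f n^2),

where ``K(n) = 4 G_s n / (n h_r (G_s/G_r - 1) + 2)`` is the combined
stiffness of the residual layer and substrate.  The first term (film
bending) grows with ``n``, the second (substrate deformation) diverges as
``n -> 0``, so ``S`` has an interior minimum: its minimiser ``n_cr`` is the
critical wavenumber, ``lambda_cr = 2 pi / n_cr`` the onset wavelength,
``S_cr = S(n_cr)`` the critical stress and ``eps_cr = S_cr / (3 G_f)`` the
critical mismatch strain.

Setting ``G_r = G_s`` collapses the model to the classical bilayer, with
closed form ``lambda_cr / h_f = 2 pi (G_f / 3 G_s)^(1/3)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .mechanics import LayerStack

__all__ = [
    "ModelValidityError",
    "WrinkleSolution",
    "StiffnessScan",
    "ResidualFit",
    "composite_stiffness",
    "film_stress",
    "solve_wrinkling",
    "bilayer_wavelength",
    "classical_bilayer_critical_strain",
    "effective_substrate_modulus",
    "normalized_adhesion",
    "scan_and_slope",
    "fit_residual_stiffness",
]

#: Dimensionless search bracket for the minimiser, in units of n*h_f.
NHF_BRACKET = (1e-3, 1e3)

#: Stiffness-contrast bounds from the wrinkling/creasing phase diagram of the
#: bilayer literature, quoted (not derived) by the source analysis: a bilayer
#: with G_f/G_s below ~1.3 is too compliant for a flat-to-wrinkle transition,
#: and the bilayer solution branch requires log-strain coordinates > 4.75.
#: Stored as documented constants only; nothing in this module computes them.
BILAYER_VALIDITY_GF_OVER_GS = 1.3
BILAYER_VALIDITY_X_BOUND = 4.75


class ModelValidityError(ValueError):
    """The requested parameters leave the model's validity region."""


@dataclass(frozen=True)
class WrinkleSolution:
    """Critical point of the trilayer stability problem.

    Invariants: ``lambda_cr * n_cr == 2 pi`` and
    ``eps_cr * 3 G_f == S_cr`` exactly (by construction).
    """

    n_cr: float          #: critical wavenumber (1/m)
    lambda_cr: float     #: onset wavelength (m)
    S_cr: float          #: film stress at onset (Pa)
    eps_cr: float        #: critical mismatch strain, S_cr / (3 G_f)
    G_s_eff: float       #: effective substrate modulus K(n_cr) * h'_s (Pa)
    strained_depth: float  #: h'_s used for G_s_eff (m)

    def normalized_adhesion(self, Gamma: float, film_h: float) -> float:
        return normalized_adhesion(Gamma, film_h, self.G_s_eff)


@dataclass
class StiffnessScan:
    """Normalised wavelength versus stiffness contrast, Fig-2-style."""

    ratios: np.ndarray                 #: G_f/G_s values, strictly increasing
    normalized_wavelengths: np.ndarray  #: lambda_cr / h_f per ratio
    eps_cr: np.ndarray | None = None
    S_cr_over_Gf: np.ndarray | None = None
    failures: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.normalized_wavelengths = np.asarray(self.normalized_wavelengths, dtype=float)
        if self.ratios.shape != self.normalized_wavelengths.shape:
            raise ValueError("ratios and wavelengths must have equal length")
        if self.ratios.size > 1 and not np.all(np.diff(self.ratios) > 0):
            raise ValueError("ratios must be strictly increasing")


@dataclass(frozen=True)
class ResidualFit:
    """Result of fitting the residual-layer stiffness to wavelength data."""

    gr_over_gf: float
    sse: float
    iterations: int
    boundary_solution: bool = False


def composite_stiffness(n: float, substrate_G: float, residual_G: float,
                        residual_h: float) -> float:
    """Combined stiffness K(n) of residual layer + substrate (Pa/m).

    K = 4 G_s n / (n h_r (G_s/G_r - 1) + 2).  Reduces to 2 G_s n for
    ``G_r = G_s`` or ``h_r = 0`` (no distinct interlayer).  A stiff
    interlayer (G_r > G_s) can drive the denominator non-positive at large
    ``n h_r``; that is outside the model's validity and raises.
    """
    if n <= 0:
        raise ValueError(f"wavenumber must be positive, got {n}")
    if substrate_G <= 0 or residual_G <= 0:
        raise ValueError("moduli must be positive")
    if residual_h < 0:
        raise ValueError("residual thickness must be non-negative")
    denom = n * residual_h * (substrate_G / residual_G - 1.0) + 2.0
    if denom <= 0:
        raise ModelValidityError(
            "composite-stiffness denominator is non-positive "
            f"(n={n}, h_r={residual_h}, G_s/G_r={substrate_G / residual_G:.3g}); "
            "the trilayer formula assumes a compliant interlayer"
        )
    return 4.0 * substrate_G * n / denom


def film_stress(n: float, stack: LayerStack) -> float:
    """Longitudinal film stress S(n) sustaining a sinusoidal wrinkle (Pa)."""
    K = composite_stiffness(n, stack.substrate.G, stack.residual.G, stack.residual.h)
    hf = stack.film.h
    return stack.film.G * hf**2 * n**2 / 3.0 + K / (hf * n**2)


def bilayer_wavelength(film_G: float, substrate_G: float, film_h: float) -> float:
    """Closed-form bilayer wrinkling wavelength 2 pi h_f (G_f / 3 G_s)^(1/3)."""
    if film_G <= 0 or substrate_G <= 0 or film_h <= 0:
        raise ValueError("all inputs must be positive")
    return 2.0 * math.pi * film_h * (film_G / (3.0 * substrate_G)) ** (1.0 / 3.0)


def classical_bilayer_critical_strain(film_G: float, substrate_G: float) -> float:
    """Classical bilayer onset strain (1/4)(3 G_s / G_f)^(2/3).

    Exposed alongside :func:`solve_wrinkling`'s ``eps_cr = S_cr/(3 G_f)``
    convention, which differs by a constant factor in the bilayer limit.
    """
    if film_G <= 0 or substrate_G <= 0:
        raise ValueError("moduli must be positive")
    return 0.25 * (3.0 * substrate_G / film_G) ** (2.0 / 3.0)


def _dS_dn(n: float, stack: LayerStack) -> float:
    """Analytic derivative of the film stress S(n)."""
    hf, Gf = stack.film.h, stack.film.G
    Gs, Gr, hr = stack.substrate.G, stack.residual.G, stack.residual.h
    c = hr * (Gs / Gr - 1.0)
    denom = c * n + 2.0
    if denom <= 0:
        raise ModelValidityError("outside model validity (denominator <= 0)")
    # S = Gf hf^2 n^2/3 + 4 Gs / (hf n (c n + 2))
    return (2.0 * Gf * hf**2 * n / 3.0
            - 4.0 * Gs * (2.0 * c * n + 2.0) / (hf * (n * denom) ** 2))


def solve_wrinkling(stack: LayerStack, strained_depth: float | None = None) -> WrinkleSolution:
    """Find the critical wrinkling point by minimising S(n).

    The stress is minimised over ``log n`` on the bracket
    ``n h_f in [1e-3, 1e3]`` (direct bracketed minimisation is equivalent to
    solving dS/dn = 0 at the stationary point and more robust for flat
    minima); the minimiser is then polished with the analytic derivative.
    The stationarity residual ``|dS/dn| n / S`` of the returned minimiser is
    verified below 1e-8.

    Parameters
    ----------
    stack : LayerStack
        Trilayer parameters; only G_f, h_f, G_r, h_r, G_s enter.
    strained_depth : float, optional
        Depth ``h'_s`` of the strained substrate region used to convert the
        composite stiffness into the effective substrate modulus
        ``G'_s = K(n_cr) h'_s``.  Defaults to ``1/n_cr``, the natural decay
        depth of a sinusoidal surface load.
    """
    hf = stack.film.h
    if hf <= 0:
        raise ValueError("film thickness must be positive")

    def stress_of_log_nhf(t: float) -> float:
        n = math.exp(t) / hf
        try:
            return film_stress(n, stack)
        except ModelValidityError:
            return math.inf

    lo, hi = math.log(NHF_BRACKET[0]), math.log(NHF_BRACKET[1])
    res = minimize_scalar(stress_of_log_nhf, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    if not res.success or not math.isfinite(res.fun):
        raise ModelValidityError(
            f"no interior stress minimum found on n*h_f in {NHF_BRACKET}: {res}"
        )
    n_cr = math.exp(res.x) / hf
    # polish with the analytic derivative in a local bracket
    n_lo, n_hi = n_cr * 0.9, n_cr / 0.9
    try:
        if _dS_dn(n_lo, stack) < 0 < _dS_dn(n_hi, stack):
            n_cr = brentq(_dS_dn, n_lo, n_hi, args=(stack,), xtol=1e-15 * n_cr,
                          rtol=8.9e-16)
    except ModelValidityError:
        pass
    S_cr = film_stress(n_cr, stack)

    dS = _dS_dn(n_cr, stack)
    if abs(dS) * n_cr / S_cr > 1e-8:
        raise ModelValidityError(
            f"minimiser failed stationarity check: |dS/dn| n/S = {abs(dS) * n_cr / S_cr:.2e}"
        )
    if not (math.exp(lo) * 1.01 < n_cr * hf < math.exp(hi) * 0.99):
        raise ModelValidityError(
            f"stress minimum sits at the bracket edge (n h_f = {n_cr * hf:.3g})"
        )

    h_eff = 1.0 / n_cr if strained_depth is None else float(strained_depth)
    if h_eff <= 0:
        raise ValueError("strained depth must be positive")
    K_cr = composite_stiffness(n_cr, stack.substrate.G, stack.residual.G,
                               stack.residual.h)
    return WrinkleSolution(
        n_cr=n_cr,
        lambda_cr=2.0 * math.pi / n_cr,
        S_cr=S_cr,
        eps_cr=S_cr / (3.0 * stack.film.G),
        G_s_eff=K_cr * h_eff,
        strained_depth=h_eff,
    )


def effective_substrate_modulus(solution: WrinkleSolution, stack: LayerStack,
                                strained_depth: float) -> float:
    """Effective substrate modulus G'_s = K(n_cr) * h'_s (Pa)."""
    if strained_depth <= 0:
        raise ValueError("strained depth must be positive")
    K_cr = composite_stiffness(solution.n_cr, stack.substrate.G,
                               stack.residual.G, stack.residual.h)
    return K_cr * strained_depth


def normalized_adhesion(Gamma: float, film_h: float, effective_G: float) -> float:
    """Dimensionless adhesion Gamma* = Gamma / (h_f G'_s).

    Small values (<< 1) mark the delamination-prone regime; large values
    favour wrinkling over blister formation.  ``Gamma = 0`` (adhesion below
    detection in matrix mutants) is allowed and returns 0.
    """
    if film_h <= 0 or effective_G <= 0:
        raise ValueError("film thickness and effective modulus must be positive")
    if Gamma < 0:
        raise ValueError("adhesion energy must be non-negative")
    return Gamma / (film_h * effective_G)


def _stack_at_ratio(template: LayerStack, gf_over_gs: float,
                    residual_tie: str = "film") -> LayerStack:
    """Template stack with the film modulus reset to gf_over_gs * G_s.

    ``residual_tie`` controls how the residual modulus follows the scan:
    ``"film"`` preserves the template's G_r/G_f (the trilayer convention,
    where the fit parameter is G_r/G_f), ``"substrate"`` preserves G_r/G_s
    (so a template with G_r = G_s stays an exact bilayer at every ratio).
    """
    from dataclasses import replace
    gf = gf_over_gs * template.substrate.G
    if residual_tie == "film":
        gr = template.residual.G / template.film.G * gf
    elif residual_tie == "substrate":
        gr = template.residual.G
    else:
        raise ValueError(f"residual_tie must be 'film' or 'substrate', got {residual_tie!r}")
    return replace(template, film=replace(template.film, G=gf),
                   residual=replace(template.residual, G=gr))


def scan_and_slope(
    stack_template: LayerStack,
    ratios: np.ndarray,
    slope_window: tuple[float, float],
    residual_tie: str = "film",
) -> tuple[StiffnessScan, float]:
    """Scan lambda_cr/h_f over G_f/G_s and fit the log-log slope in a window.

    The 1/3 scaling law holds only asymptotically at large stiffness
    contrast, so the fit window is always explicit.  Solver failures at
    individual ratios are recorded on the scan and excluded from the fit.
    See :func:`_stack_at_ratio` for how the residual modulus tracks the
    scanned film modulus (``residual_tie``).
    """
    ratios = np.sort(np.asarray(ratios, dtype=float))
    if np.any(ratios <= 0):
        raise ValueError("stiffness ratios must be positive")
    lam, eps, s_over_gf = [], [], []
    failures: list[tuple[float, str]] = []
    kept = []
    for r in ratios:
        stk = _stack_at_ratio(stack_template, r, residual_tie)
        try:
            sol = solve_wrinkling(stk)
        except (ModelValidityError, ValueError) as exc:
            failures.append((float(r), str(exc)))
            continue
        kept.append(r)
        lam.append(sol.lambda_cr / stk.film.h)
        eps.append(sol.eps_cr)
        s_over_gf.append(sol.S_cr / stk.film.G)
    if failures:
        warnings.warn(
            f"wrinkling solver failed at {len(failures)} ratio(s); excluded from scan",
            stacklevel=2,
        )
    scan = StiffnessScan(
        ratios=np.array(kept),
        normalized_wavelengths=np.array(lam),
        eps_cr=np.array(eps),
        S_cr_over_Gf=np.array(s_over_gf),
        failures=failures,
    )
    lo, hi = slope_window
    sel = (scan.ratios >= lo) & (scan.ratios <= hi)
    if sel.sum() < 5:
        raise ValueError(
            f"slope window [{lo}, {hi}] contains only {int(sel.sum())} scan points (need >= 5)"
        )
    slope = np.polyfit(np.log(scan.ratios[sel]),
                       np.log(scan.normalized_wavelengths[sel]), 1)[0]
    return scan, float(slope)


def fit_residual_stiffness(
    data: StiffnessScan,
    stack_template: LayerStack,
    bracket: tuple[float, float] = (1e-3, 1.0),
    rel_tol: float = 1e-3,
) -> ResidualFit:
    """Fit G_r/G_f to measured (G_f/G_s, lambda/h_f) wavelength data.

    The residual-layer modulus is the model's only free parameter; it is
    found by minimising the sum of squared errors between the predicted and
    measured normalised wavelengths.  Bisection on the sign of the SSE
    derivative (on log G_r/G_f) converges in ~10 iterations; if the SSE is
    not unimodal on the bracket a golden-section (bounded scalar) fallback
    is used.  A minimum at a bracket edge is flagged as a boundary solution.
    """
    if data.ratios.size < 3:
        raise ValueError(f"need >= 3 data points to fit, got {data.ratios.size}")
    lo, hi = bracket
    if not (0 < lo < hi <= 1.0):
        raise ValueError(f"bracket must lie within (0, 1], got {bracket}")

    gf_ratios = data.ratios
    lam_data = data.normalized_wavelengths
    from dataclasses import replace

    def sse(gr_over_gf: float) -> float:
        total = 0.0
        for r, lam_obs in zip(gf_ratios, lam_data):
            stk = _stack_at_ratio(stack_template, r, "film")
            stk = replace(stk, residual=replace(stk.residual, G=gr_over_gf * stk.film.G))
            try:
                sol = solve_wrinkling(stk)
            except (ModelValidityError, ValueError):
                return math.inf
            total += (sol.lambda_cr / stk.film.h - lam_obs) ** 2
        return total

    def dsse(t: float) -> float:
        # derivative sign of SSE on the log axis
        dt = 1e-4
        return sse(math.exp(t + dt)) - sse(math.exp(t - dt))

    a, b = math.log(lo), math.log(hi)
    da, db = dsse(a), dsse(b)
    iterations = 0
    if da < 0 < db:  # unimodal with interior minimum: bisection on slope sign
        while b - a > rel_tol and iterations < 60:
            m = 0.5 * (a + b)
            if dsse(m) < 0:
                a = m
            else:
                b = m
            iterations += 1
        x = math.exp(0.5 * (a + b))
        boundary = False
    else:
        res = minimize_scalar(lambda t: sse(math.exp(t)), bounds=(a, b),
                              method="bounded", options={"xatol": rel_tol / 2})
        x = math.exp(res.x)
        iterations = int(res.nfev)
        boundary = not (lo * (1 + 2 * rel_tol) < x < hi * (1 - 2 * rel_tol))
    return ResidualFit(gr_over_gf=x, sse=sse(x), iterations=iterations,
                       boundary_solution=boundary)
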