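"""Mechanical domain types and elementary constitutive conversions.

The trilayer system — a stiff growing biofilm *film* on a thin soft
*residual* (matrix polysaccharide) layer on a thick agar *substrate* — is
described by per-layer shear moduli ``G``, thicknesses ``h`` and Poisson
ratios ``nu``.  Internal units are strict SI (Pa, m); all dimensionless
results (``G_f/G_s``, ``lambda/h_f``) are invariant to consistent rescaling,
so tests and examples freely use normalised units with ``h_f = 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "ElasticLayer",
    "LayerStack",
    "GrowthState",
    "InterfacialEnergySet",
    "growth_strain",
    "lame_parameters",
    "poisson_from_moduli",
    "read_layer_table",
    "write_layer_table",
]


@dataclass(frozen=True)
class ElasticLayer:
    """A homogeneous isotropic elastic layer.

    Parameters
    ----------
    G : float
        Shear modulus in Pa.  Must be positive.
    h : float
        Thickness in m.  Non-negative (zero = absent layer).
    nu : float
        Poisson ratio.  ``nu = 0.5`` (incompressible) is allowed for
        theory-only use; the FEM requires ``nu < 0.5``.
    """

    G: float
    h: float
    nu: float = 0.5

    def __post_init__(self) -> None:
        if not self.G > 0:
            raise ValueError(f"shear modulus must be positive, got {self.G}")
        if self.h < 0:
            raise ValueError(f"thickness must be non-negative, got {self.h}")
        if not 0 <= self.nu <= 0.5:
            raise ValueError(f"Poisson ratio must lie in [0, 0.5], got {self.nu}")


@dataclass(frozen=True)
class LayerStack:
    """Film / residual / substrate trilayer."""

    film: ElasticLayer
    residual: ElasticLayer
    substrate: ElasticLayer

    @classmethod
    def from_ratios(
        cls,
        gf_over_gs: float,
        gr_over_gf: float = 0.1,
        hr_over_hf: float = 0.3,
        hs_over_hf: float = 10.0,
        hf: float = 1.0,
        gs: float = 1.0,
        nu: float = 0.5,
    ) -> "LayerStack":
        """Build a stack from the dimensionless ratios the results are
        reported in, with substrate modulus and film thickness as the
        free scales."""
        gf = gf_over_gs * gs
        return cls(
            film=ElasticLayer(G=gf, h=hf, nu=nu),
            residual=ElasticLayer(G=gr_over_gf * gf, h=hr_over_hf * hf, nu=nu),
            substrate=ElasticLayer(G=gs, h=hs_over_hf * hf, nu=nu),
        )

    def require_thick_substrate(self) -> None:
        """FEM precondition: the substrate must dwarf the film."""
        if self.substrate.h < 5 * self.film.h:
            raise ValueError(
                "substrate thickness must be at least 5x the film thickness "
                f"for the thick-substrate assumption (h_s={self.substrate.h}, "
                f"h_f={self.film.h})"
            )


@dataclass(frozen=True)
class GrowthState:
    """Uniaxial growth state of the film + residual layers.

    ``g`` is the growth parameter (relative length increase of the free
    layer), ``epsilon = g/(1+g)`` the induced mismatch strain, and
    ``J_g = 1+g`` the growth volume factor.
    """

    g: float

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError(f"growth parameter must be non-negative, got {self.g}")

    @property
    def epsilon(self) -> float:
        return growth_strain(self.g)

    @property
    def J_g(self) -> float:
        return 1.0 + self.g


@dataclass(frozen=True)
class InterfacialEnergySet:
    """Interfacial energies (J/m^2) governing blister development.

    ``Gamma`` is the film–substrate adhesion energy, ``gamma_fl`` the
    film–liquid and ``gamma_fa`` the film–air surface energy.  Zero is
    allowed (adhesion below the detection limit in matrix mutants).
    """

    Gamma: float
    gamma_fl: float
    gamma_fa: float

    def __post_init__(self) -> None:
        for name in ("Gamma", "gamma_fl", "gamma_fa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def growth_strain(g: float) -> float:
    """Mismatch strain induced by uniaxial growth ``g``: eps = g/(1+g).

    Strictly increasing in ``g`` and bounded above by 1.
    """
    if g < 0:
        raise ValueError(f"growth parameter must be non-negative, got {g}")
    return g / (1.0 + g)


def lame_parameters(G: float, nu: float) -> tuple[float, float]:
    """Lamé parameters (mu_e, lambda_e) from shear modulus and Poisson ratio.

    mu_e = G and lambda_e = 2 G nu / (1 - 2 nu); lambda_e diverges in the
    incompressible limit nu -> 0.5, which is therefore rejected.
    """
    if not G > 0:
        raise ValueError(f"shear modulus must be positive, got {G}")
    if not 0 <= nu < 0.5:
        raise ValueError(
            f"Poisson ratio must lie in [0, 0.5) for a finite Lame parameter, got {nu}"
        )
    return G, 2.0 * G * nu / (1.0 - 2.0 * nu)


def poisson_from_moduli(K: float, G: float) -> float:
    """Poisson ratio from bulk modulus K and (storage) shear modulus G.

    nu = (3K - 2G) / (2 (3K + G)).  Approaches 0.5 as G/K -> 0
    (incompressible limit).  ``G = 0`` is accepted and returns exactly 0.5.
    """
    if not K > 0:
        raise ValueError(f"bulk modulus must be positive, got {K}")
    if G < 0:
        raise ValueError(f"shear modulus must be non-negative, got {G}")
    return (3.0 * K - 2.0 * G) / (2.0 * (3.0 * K + G))


# ---------------------------------------------------------------------------
# parameter-table I/O  (CSV header: layer,G_Pa,h_m,nu)

_LAYER_ORDER = ("film", "residual", "substrate")


def write_layer_table(stack: LayerStack, path: str | Path) -> None:
    """Write a stack as CSV (``layer,G_Pa,h_m,nu``) or JSON by extension."""
    path = Path(path)
    rows = [
        {"layer": name, "G_Pa": lay.G, "h_m": lay.h, "nu": lay.nu}
        for name, lay in zip(_LAYER_ORDER, (stack.film, stack.residual, stack.substrate))
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
    else:
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_layer_table(path: str | Path) -> LayerStack:
    """Read a stack from the CSV/JSON written by :func:`write_layer_table`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = {r["layer"]: r for r in json.loads(path.read_text())}
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        rows = {r["layer"]: r for r in df.to_dict("records")}
    missing = set(_LAYER_ORDER) - set(rows)
    if missing:
        raise ValueError(f"layer table missing rows: {sorted(missing)}")
    layers = {
        name: ElasticLayer(G=float(rows[name]["G_Pa"]), h=float(rows[name]["h_m"]),
                           nu=float(rows[name]["nu"]))
        for name in _LAYER_ORDER
    }
    return LayerStack(film=layers["film"], residual=layers["residual"],
                      substrate=layers["substrate"])
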