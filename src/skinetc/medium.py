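"""Monte Carlo construction of heterogeneous one- and three-layer skin domains.

Each grid cell of a porous layer receives one pore diameter drawn from the
layer's fractal size distribution; the per-cell diameter, the layer's
conductivity and the capillary flow model combine into a per-cell
dimensionless effective conductivity field

    k_eff*(cell) = [(1-phi) + (Pe(lam)/2)(k_b/k_layer) Lambda(lam)]
                   * k_layer / k_ref,

normalized by the single reference tissue conductivity that also defines
the thermal diffusivity of the dimensionless heat equation.  Skin is
resolved as epidermis (avascular), dermis (densest capillary bed) and
hypodermis, stacked top-down with thickness fractions 0.04/0.48/0.48.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conductivity import fractal_geometry_factor
from .flow import BloodRheology, calibrate_pressure_gradient, mean_velocity, peclet
from .fractal import PoreNetworkSpec, pore_cdf_max, invert_pore_cdf, rev_geometry

__all__ = [
    "TissueLayer",
    "TissueProperties",
    "ETCField",
    "one_layer",
    "skin_three_layer",
    "default_rheology",
    "build_layer_stack",
    "sample_pore_field",
    "build_etc_field",
    "wj_etc_field",
    "write_field",
]

#: Reference tissue thermophysical defaults (density kg/m^3, specific heat
#: J/kg·°C, conductivity W/m·°C, metabolic heat W/m^3).
TISSUE_DENSITY = 1200.0
TISSUE_SPECIFIC_HEAT = 3600.0
TISSUE_CONDUCTIVITY = 0.293
METABOLIC_HEAT = 368.1

#: Per-layer conductivities (W/m·°C) for epidermis, dermis, hypodermis.
K_EPIDERMIS, K_DERMIS, K_HYPODERMIS = 0.25, 0.45, 0.2

#: Pore-diameter range of the skin capillary bed (m).
LAMBDA_MIN, LAMBDA_MAX = 5e-6, 5e-4

#: Peclet number of the largest pore under the Newtonian validation
#: settings; pins the default pressure gradient.
REFERENCE_PECLET = 16.3


@dataclass(frozen=True)
class TissueProperties:
    """Bulk tissue properties entering the bioheat nondimensionalization."""

    density: float = TISSUE_DENSITY
    specific_heat: float = TISSUE_SPECIFIC_HEAT
    conductivity: float = TISSUE_CONDUCTIVITY
    metabolic_heat: float = METABOLIC_HEAT

    def __post_init__(self) -> None:
        if min(self.density, self.specific_heat, self.conductivity) <= 0:
            raise ValueError("tissue properties must be positive")
        if self.metabolic_heat < 0:
            raise ValueError("metabolic heat must be non-negative")

    @property
    def diffusivity(self) -> float:
        """Thermal diffusivity ``alpha = k / (rho Cp)`` (m^2/s)."""
        return self.conductivity / (self.density * self.specific_heat)


@dataclass(frozen=True)
class TissueLayer:
    """One tissue layer: thickness fraction, conductivity and pore network.

    ``pore_spec`` is ``None`` exactly when the layer is avascular
    (``porosity == 0``), e.g. the epidermis.
    """

    name: str
    fraction: float
    conductivity: float
    pore_spec: PoreNetworkSpec | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.conductivity <= 0:
            raise ValueError("conductivity must be positive")
        if self.pore_spec is not None and self.pore_spec.porosity == 0.0:
            raise ValueError("a pore spec with zero porosity is meaningless")

    @property
    def porosity(self) -> float:
        return 0.0 if self.pore_spec is None else self.pore_spec.porosity


def one_layer(
    porosity: float = 0.1,
    tortuosity_dim: float = 1.0,
    conductivity: float = TISSUE_CONDUCTIVITY,
    name: str = "tissue",
) -> list[TissueLayer]:
    """Homogeneous single-layer tissue with uniform porosity."""
    spec = (
        None
        if porosity == 0.0
        else PoreNetworkSpec.from_porosity(
            porosity, LAMBDA_MIN, LAMBDA_MAX, tortuosity_dim
        )
    )
    return [TissueLayer(name, 1.0, conductivity, spec)]


def skin_three_layer(
    porosities: tuple[float, float, float] = (0.0, 0.5, 0.05),
    tortuosity_dim: float = 1.05,
    fractions: tuple[float, float, float] = (0.04, 0.48, 0.48),
    conductivities: tuple[float, float, float] = (
        K_EPIDERMIS,
        K_DERMIS,
        K_HYPODERMIS,
    ),
) -> list[TissueLayer]:
    """Epidermis/dermis/hypodermis stack, listed top-down.

    Defaults are the headline skin configuration: avascular epidermis,
    highly perfused dermis (phi = 0.5), weakly perfused hypodermis
    (phi = 0.05), with slightly tortuous capillaries.
    """
    names = ("epidermis", "dermis", "hypodermis")
    layers = []
    for name, frac, k, phi in zip(names, fractions, conductivities, porosities):
        spec = (
            None
            if phi == 0.0
            else PoreNetworkSpec.from_porosity(
                phi, LAMBDA_MIN, LAMBDA_MAX, tortuosity_dim
            )
        )
        layers.append(TissueLayer(name, frac, k, spec))
    return layers


def default_rheology(power_law_index: float = 1.0) -> BloodRheology:
    """Blood rheology with the pressure gradient pinned by ``Pe = 16.3``.

    The gradient is calibrated once, under the Newtonian validation settings
    (phi = 0.05, straight capillaries, largest pore), and then held fixed
    across power-law index and porosity sweeps so that only rheology and
    geometry vary.
    """
    base = BloodRheology(power_law_index=1.0)
    spec = PoreNetworkSpec.from_porosity(0.05, LAMBDA_MIN, LAMBDA_MAX, 1.0)
    L0 = rev_geometry(spec).side_length
    G = calibrate_pressure_gradient(REFERENCE_PECLET, LAMBDA_MAX, base, L0, 1.0)
    return BloodRheology(
        power_law_index=power_law_index, pressure_gradient=G
    )


@dataclass(frozen=True)
class ETCField:
    """Per-cell dimensionless effective conductivity over the domain grid.

    ``values[j, i]`` is ``k_eff*`` at row ``j`` (depth fraction ``y_bar``
    increasing from the body core at 0 to the skin surface at 1) and column
    ``i``.  Regeneration with the same seed and configuration is
    bit-identical.
    """

    values: np.ndarray
    layer_map: np.ndarray
    seed: int
    pore_diameters: np.ndarray | None = field(default=None, compare=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_layer_stack(layers: list[TissueLayer], ny: int) -> np.ndarray:
    """Assign each of ``ny`` grid rows (y_bar in [0, 1]) a layer index.

    ``layers`` are listed top-down (first layer adjacent to the heated
    surface ``y_bar = 1``); interface rows belong to the lower layer.
    Returns indices into ``layers``.
    """
    fractions = np.array([lay.fraction for lay in layers], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-12:
        raise ValueError(f"layer fractions must sum to 1, got {fractions.sum()}")
    y = np.linspace(0.0, 1.0, ny)
    # bottom-up cumulative interface depths; boundary rows go to the lower layer
    bottom_up = fractions[::-1]
    bounds = np.cumsum(bottom_up)[:-1]
    idx_bottom_up = np.searchsorted(bounds, y, side="left")
    return len(layers) - 1 - idx_bottom_up


def sample_pore_field(
    grid_shape: tuple[int, int], layers: list[TissueLayer], seed: int
) -> np.ndarray:
    """Per-cell pore diameters (m); NaN in avascular layers.

    One uniform draw per cell is made for the whole grid, then inverted
    through the owning layer's size distribution, so a single-layer stack
    and a multi-layer stack with identical specs produce identical fields
    for the same seed.
    """
    ny, nx = grid_shape
    layer_map = build_layer_stack(layers, ny)
    rng = np.random.default_rng(seed)
    uniforms = rng.uniform(size=(ny, nx))
    lam = np.full((ny, nx), np.nan)
    for idx, lay in enumerate(layers):
        if lay.pore_spec is None:
            continue
        rows = layer_map == idx
        r = uniforms[rows] * pore_cdf_max(lay.pore_spec)
        lam[rows] = invert_pore_cdf(r, lay.pore_spec)
    return lam


def build_etc_field(
    grid_shape: tuple[int, int],
    layers: list[TissueLayer],
    tissue: TissueProperties,
    rheology: BloodRheology,
    seed: int,
    peclet_exponent: int = 1,
) -> ETCField:
    """Monte Carlo dimensionless ETC field over the domain grid.

    Avascular layers get the uniform value ``k_layer / k_ref``; porous
    layers add the perfusion enhancement of each cell's sampled capillary.
    """
    ny, nx = grid_shape
    layer_map = build_layer_stack(layers, ny)
    lam = sample_pore_field(grid_shape, layers, seed)
    values = np.empty((ny, nx))
    kb = rheology.conductivity
    k_ref = tissue.conductivity
    for idx, lay in enumerate(layers):
        rows = layer_map == idx
        if lay.pore_spec is None:
            values[rows] = lay.conductivity / k_ref
            continue
        spec = lay.pore_spec
        L0 = rev_geometry(spec).side_length
        lam_cells = lam[rows]
        u = mean_velocity(lam_cells, rheology, L0, spec.tortuosity_dim)
        pe = peclet(lam_cells, u, rheology)
        factor = fractal_geometry_factor(lam_cells, spec, L0)
        keff_star = (1.0 - spec.porosity) + (
            pe**peclet_exponent / 2.0
        ) * (kb / lay.conductivity) * factor
        values[rows] = keff_star * lay.conductivity / k_ref
    layer_grid = np.repeat(layer_map[:, None], nx, axis=1)
    return ETCField(values=values, layer_map=layer_grid, seed=seed,
                    pore_diameters=lam)


def wj_etc_field(grid_shape: tuple[int, int], ref=None) -> np.ndarray:
    """Depth-dependent Weinbaum–Jiji ``k_eff*`` field on the same grid.

    The WJ conductivity varies only with depth fraction; each row takes the
    polynomial value at its ``y_bar``.
    """
    from .conductivity import WJReference, wj_reference_etc

    ny, nx = grid_shape
    if ref is None:
        ref = WJReference()
    y = np.linspace(0.0, 1.0, ny)
    profile = wj_reference_etc(y, ref)
    return np.repeat(np.asarray(profile)[:, None], nx, axis=1)


def write_field(path, field: np.ndarray, header: str = "") -> None:
    """Write a grid field as a delimited-text matrix (row = y index)."""
    np.savetxt(path, np.asarray(field), header=header, fmt="%.8e")
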