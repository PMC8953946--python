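"""Fractal pore-size statistics of the representative elementary volume (REV).

A perfused tissue cross-section is modelled as a bundle of capillary pores
whose diameters follow the fractal scaling law

    N(>= lam) = (lam_max / lam) ** Df,

with ``Df`` the (cross-sectional) pore-area fractal dimension.  From this
single law follow the pore-size probability density, its cumulative form,
inverse-transform Monte Carlo sampling, the tortuous capillary length
``L(lam) = L0**DT * lam**(1 - DT)``, the total pore area of the REV
cross-section and the REV side length ``L0 = sqrt(Ac / phi)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PoreNetworkSpec",
    "REVGeometry",
    "fractal_dimension_from_porosity",
    "check_fractal_criterion",
    "pore_count_above",
    "pore_pdf",
    "pore_cdf",
    "sample_pore_diameters",
    "tortuous_length",
    "total_pore_area",
    "rev_side_length",
    "rev_geometry",
    "write_pore_ensemble",
]


def fractal_dimension_from_porosity(
    phi: float, ratio: float, euclidean_dim: int = 2
) -> float:
    """Pore-area fractal dimension implied by porosity.

    Uses the porosity relation ``phi = ratio ** (DE - Df)`` with
    ``ratio = lam_min / lam_max``, i.e. ``Df = DE - ln(phi) / ln(ratio)``.

    Parameters
    ----------
    phi : float
        Porosity, in ``(0, 1]``.  ``phi == 1`` gives ``Df == DE`` exactly
        (the cross-section fully occupied by pores).
    ratio : float
        Diameter ratio ``lam_min / lam_max``, in ``(0, 1)``.
    euclidean_dim : int
        Embedding dimension ``DE`` (2 for a cross-section, 3 for a volume).
    """
    if not 0.0 < phi <= 1.0:
        raise ValueError(f"porosity must be in (0, 1], got {phi}")
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"diameter ratio must be in (0, 1), got {ratio}")
    if euclidean_dim not in (2, 3):
        raise ValueError(f"euclidean_dim must be 2 or 3, got {euclidean_dim}")
    return euclidean_dim - math.log(phi) / math.log(ratio)


@dataclass(frozen=True)
class PoreNetworkSpec:
    """Fractal/pore parameters of one porous tissue layer.

    ``fractal_dim`` must be consistent with the porosity through
    ``Df = DE - ln(phi) / ln(lam_min / lam_max)`` (checked at construction);
    use :meth:`from_porosity` to derive it.

    Attributes
    ----------
    lambda_min, lambda_max : float
        Smallest and largest capillary diameter in the REV cross-section (m).
    porosity : float
        Areal fraction of the cross-section occupied by capillary lumens.
    fractal_dim : float
        Pore-area fractal dimension ``Df``.
    tortuosity_dim : float
        Tortuosity fractal dimension ``DT`` (1 = straight capillaries).
    euclidean_dim : int
        Embedding dimension ``DE``.
    criterion_threshold : float
        Construction warns when ``(lam_min/lam_max)**Df`` exceeds this,
        meaning the medium is a poor candidate for fractal description.
    """

    lambda_min: float
    lambda_max: float
    porosity: float
    fractal_dim: float
    tortuosity_dim: float = 1.0
    euclidean_dim: int = 2
    criterion_threshold: float = field(default=0.01, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_min < self.lambda_max:
            raise ValueError(
                f"need 0 < lambda_min < lambda_max, got "
                f"({self.lambda_min}, {self.lambda_max})"
            )
        if not 0.0 <= self.porosity <= 1.0:
            raise ValueError(f"porosity must be in [0, 1], got {self.porosity}")
        if not 0.0 < self.fractal_dim <= self.euclidean_dim:
            raise ValueError(
                f"fractal_dim must be in (0, {self.euclidean_dim}], "
                f"got {self.fractal_dim}"
            )
        if self.tortuosity_dim < 1.0:
            raise ValueError(f"tortuosity_dim must be >= 1, got {self.tortuosity_dim}")
        if self.porosity > 0.0:
            implied = fractal_dimension_from_porosity(
                self.porosity, self.ratio, self.euclidean_dim
            )
            if abs(self.fractal_dim - implied) > 1e-12:
                raise ValueError(
                    f"fractal_dim {self.fractal_dim} inconsistent with porosity "
                    f"{self.porosity} (implied Df = {implied})"
                )
        value = self.criterion
        if value > self.criterion_threshold:
            warnings.warn(
                f"fractal criterion (lam_min/lam_max)**Df = {value:.4g} exceeds "
                f"{self.criterion_threshold}: the medium is marginal for a "
                "fractal description",
                stacklevel=2,
            )

    @classmethod
    def from_porosity(
        cls,
        porosity: float,
        lambda_min: float = 5e-6,
        lambda_max: float = 5e-4,
        tortuosity_dim: float = 1.0,
        euclidean_dim: int = 2,
        criterion_threshold: float = 0.01,
    ) -> "PoreNetworkSpec":
        """Build a spec with ``Df`` derived from the porosity relation."""
        df = fractal_dimension_from_porosity(
            porosity, lambda_min / lambda_max, euclidean_dim
        )
        return cls(
            lambda_min=lambda_min,
            lambda_max=lambda_max,
            porosity=porosity,
            fractal_dim=df,
            tortuosity_dim=tortuosity_dim,
            euclidean_dim=euclidean_dim,
            criterion_threshold=criterion_threshold,
        )

    @property
    def ratio(self) -> float:
        """Diameter ratio ``lam_min / lam_max``."""
        return self.lambda_min / self.lambda_max

    @property
    def criterion(self) -> float:
        """Fractal criterion value ``(lam_min/lam_max)**Df`` (should be ~0)."""
        return self.ratio**self.fractal_dim


@dataclass(frozen=True)
class REVGeometry:
    """Cross-sectional geometry of the REV: pore area, total area, side."""

    pore_area: float  # Ac (m^2)
    total_area: float  # AT = L0^2 (m^2)
    side_length: float  # L0 (m)

    def __post_init__(self) -> None:
        if self.pore_area <= 0 or self.side_length <= 0:
            raise ValueError("pore_area and side_length must be positive")
        if not math.isclose(self.total_area, self.side_length**2, rel_tol=1e-12):
            raise ValueError("total_area must equal side_length**2")

    @property
    def porosity(self) -> float:
        """Areal porosity ``Ac / AT`` implied by the stored geometry."""
        return self.pore_area / self.total_area


def check_fractal_criterion(
    spec: PoreNetworkSpec, threshold: float = 0.01
) -> tuple[float, bool]:
    """Return ``((ratio)**Df, value <= threshold)``.

    A value close to zero means the pore population spans enough scales for
    the fractal scaling law (and the pdf normalization) to hold.
    """
    value = spec.criterion
    return value, value <= threshold


def _check_range(lam, spec: PoreNetworkSpec) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < spec.lambda_min) or np.any(lam > spec.lambda_max):
        raise ValueError(
            f"diameter outside [{spec.lambda_min}, {spec.lambda_max}]"
        )
    return lam


def pore_count_above(lam, spec: PoreNetworkSpec):
    """Number of pores with diameter >= ``lam``: ``(lam_max/lam)**Df``.

    Equals 1 at ``lam = lam_max`` (exactly one largest pore) and the total
    pore count ``NT = (lam_max/lam_min)**Df`` at ``lam = lam_min``.
    """
    lam = _check_range(lam, spec)
    out = (spec.lambda_max / lam) ** spec.fractal_dim
    return out if out.ndim else float(out)


def pore_pdf(lam, spec: PoreNetworkSpec):
    """Pore-size probability density ``Df * lam_min**Df * lam**(-Df-1)`` (1/m)."""
    lam = _check_range(lam, spec)
    df = spec.fractal_dim
    out = df * spec.lambda_min**df * lam ** (-df - 1.0)
    return out if out.ndim else float(out)


def pore_cdf(lam, spec: PoreNetworkSpec):
    """Cumulative pore-size distribution ``R = 1 - (lam_min/lam)**Df``.

    Note ``R(lam_max) = 1 - (ratio)**Df`` is slightly below 1; the deficit is
    the fractal criterion value and vanishes when scales are well separated.
    """
    lam = _check_range(lam, spec)
    out = 1.0 - (spec.lambda_min / lam) ** spec.fractal_dim
    return out if out.ndim else float(out)


def pore_cdf_max(spec: PoreNetworkSpec) -> float:
    """Upper end of the cdf range, ``R(lam_max) = 1 - ratio**Df``."""
    return 1.0 - spec.criterion


def invert_pore_cdf(r, spec: PoreNetworkSpec):
    """Diameter at cumulative probability ``r``: ``lam_min * (1-r)**(-1/Df)``."""
    r = np.asarray(r, dtype=float)
    out = spec.lambda_min * (1.0 - r) ** (-1.0 / spec.fractal_dim)
    return out if out.ndim else float(out)


def sample_pore_diameters(
    count: int, spec: PoreNetworkSpec, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Monte Carlo pore diameters by inverse-transform sampling.

    Uniform draws are rescaled to ``[0, 1 - ratio**Df]`` before inversion so
    every sampled diameter lies in ``[lam_min, lam_max]`` (a raw uniform near
    1 would overshoot ``lam_max``).  The same seed reproduces the same
    diameters bit for bit.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    r = rng.uniform(size=count) * pore_cdf_max(spec)
    return invert_pore_cdf(r, spec)


def tortuous_length(lam, L0: float, DT: float):
    """Tortuous capillary length ``L(lam) = L0**DT * lam**(1-DT)`` (m).

    ``DT = 1`` gives a straight capillary of length ``L0``; for ``DT > 1``
    narrower capillaries are longer (more tortuous).
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0) or L0 <= 0:
        raise ValueError("lam and L0 must be positive")
    if DT < 1.0:
        raise ValueError(f"DT must be >= 1, got {DT}")
    out = L0**DT * lam ** (1.0 - DT)
    return out if out.ndim else float(out)


def total_pore_area(spec: PoreNetworkSpec) -> float:
    """Total pore area ``Ac`` of the REV cross-section (m^2).

    Closed-form value of ``-integral (pi lam^2 / 4) dN(lam)`` over
    ``[lam_min, lam_max]``; the removable ``Df -> 2`` singularity is handled
    by its analytic log limit ``(pi/2) lam_max^2 ln(lam_max/lam_min)``.
    """
    df = spec.fractal_dim
    lmin, lmax = spec.lambda_min, spec.lambda_max
    if abs(2.0 - df) < 1e-9:
        return 0.5 * math.pi * lmax**2 * math.log(lmax / lmin)
    return (
        math.pi
        * df
        * lmax**df
        * (lmax ** (2.0 - df) - lmin ** (2.0 - df))
        / (4.0 * (2.0 - df))
    )


def rev_side_length(Ac: float, phi: float) -> float:
    """REV side length ``L0 = sqrt(Ac / phi)`` (m)."""
    if Ac <= 0:
        raise ValueError(f"pore area must be positive, got {Ac}")
    if not 0.0 < phi <= 1.0:
        raise ValueError(f"porosity must be in (0, 1], got {phi}")
    return math.sqrt(Ac / phi)


def rev_geometry(spec: PoreNetworkSpec) -> REVGeometry:
    """REV geometry (Ac, AT, L0) implied by a pore-network spec."""
    if spec.porosity <= 0.0:
        raise ValueError("REV geometry undefined for zero porosity")
    ac = total_pore_area(spec)
    l0 = rev_side_length(ac, spec.porosity)
    return REVGeometry(pore_area=ac, total_area=l0**2, side_length=l0)


def write_pore_ensemble(
    path, diameters: np.ndarray, spec: PoreNetworkSpec, seed: int | None = None
) -> None:
    """Write sampled diameters as two-column text (index, lam in m)."""
    header = (
        f"pore diameter ensemble; seed={seed} phi={spec.porosity} "
        f"Df={spec.fractal_dim} DT={spec.tortuosity_dim} "
        f"lambda_min={spec.lambda_min} lambda_max={spec.lambda_max}"
    )
    idx = np.arange(len(diameters))
    np.savetxt(path, np.column_stack([idx, diameters]), header=header,
               fmt=("%d", "%.10e"))
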