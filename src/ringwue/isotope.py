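"""Farquhar-model formula chain: δ13C → Δ13C → ci → Wi.

Intrinsic water-use efficiency Wi ≡ A/gw is derived from wood δ13C via the
simple (two-term) discrimination model for C3 photosynthesis:

    Δ13C = (δ13C_air − δ13C_plant) / (1 + δ13C_plant/1000)
    Δ13C = a (1 − ci/ca) + b (ci/ca)
    Wi   = (ca − ci) / 1.6 = ca (b − Δ13C) / (1.6 (b − a))

with a = 4.4 ‰ (stomatal diffusion fractionation), b = 27 ‰ (Rubisco
carboxylation fractionation) and 1.6 the H2O:CO2 molecular diffusivity
ratio. Mesophyll conductance and post-photosynthetic offsets are deliberately
not modelled; the constants are configurable for sensitivity checks.

All functions accept scalars or numpy arrays. Δ outside the physical open
interval (a, b) yields ci/Wi values outside (0, ca) / (0, ca/1.6); these are
flagged, never clipped, so downstream trend fits can exclude them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ring_data import AtmosphericRecord

__all__ = [
    "IsotopeConstants",
    "GasExchangeState",
    "delta13c_from_ratio",
    "discrimination",
    "invert_discrimination",
    "ci_from_discrimination",
    "wi_from_discrimination",
    "gas_exchange_state",
    "atmos_lookup",
]


@dataclass(frozen=True)
class IsotopeConstants:
    """Fractionation constants of the simple discrimination model."""

    a_permil: float = 4.4
    b_permil: float = 27.0
    diffusivity_ratio: float = 1.6

    def __post_init__(self) -> None:
        if not (self.b_permil > self.a_permil > 0):
            raise ValueError(
                f"need b > a > 0, got a={self.a_permil}, b={self.b_permil}"
            )
        if not self.diffusivity_ratio > 1:
            raise ValueError(
                f"diffusivity_ratio must be > 1, got {self.diffusivity_ratio}"
            )


DEFAULT_CONSTANTS = IsotopeConstants()


@dataclass(frozen=True)
class GasExchangeState:
    """Per-observation gas-exchange diagnostics derived from one δ13C value.

    ``out_of_range`` marks Δ13C outside the open interval (a, b), where the
    inferred ci and Wi leave their physical ranges.
    """

    year: int
    ca_ppm: float
    d13c_air_permil: float
    d13c_plant_permil: float
    big_delta_permil: float
    ci_ppm: float
    ci_over_ca: float
    ca_minus_ci_ppm: float
    wi_ppm: float
    out_of_range: bool = False


def delta13c_from_ratio(r_sample, r_standard):
    """δ13C (‰ vs V-PDB) from 13C/12C abundance ratios."""
    r_sample = np.asarray(r_sample, dtype=float)
    r_standard = np.asarray(r_standard, dtype=float)
    if np.any(r_sample <= 0) or np.any(r_standard <= 0):
        raise ValueError("abundance ratios must be > 0")
    out = (r_sample / r_standard - 1.0) * 1000.0
    return out.item() if out.ndim == 0 else out


def discrimination(d13c_plant, d13c_air):
    """Plant-to-air isotope discrimination Δ13C (‰)."""
    d13c_plant = np.asarray(d13c_plant, dtype=float)
    d13c_air = np.asarray(d13c_air, dtype=float)
    denom = 1.0 + d13c_plant / 1000.0
    if np.any(denom <= 0):
        raise ValueError("1 + d13c_plant/1000 must be > 0")
    out = (d13c_air - d13c_plant) / denom
    return out.item() if out.ndim == 0 else out


def invert_discrimination(big_delta, d13c_air):
    """δ13C_plant that would produce discrimination ``big_delta``.

    Exact algebraic inverse of :func:`discrimination`; used by the synthetic
    generator to render wood δ13C from a prescribed Wi.
    """
    big_delta = np.asarray(big_delta, dtype=float)
    d13c_air = np.asarray(d13c_air, dtype=float)
    denom = 1.0 + big_delta / 1000.0
    if np.any(denom <= 0):
        raise ValueError("1 + big_delta/1000 must be > 0")
    out = (d13c_air - big_delta) / denom
    return out.item() if out.ndim == 0 else out


def ci_from_discrimination(big_delta, ca, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Leaf-intercellular CO2 ci (ppm) implied by Δ13C at atmospheric ca.

    ci = ca (Δ − a)/(b − a). For Δ outside (a, b) the result leaves [0, ca];
    callers flag such states rather than clipping.
    """
    big_delta = np.asarray(big_delta, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("ca must be > 0")
    out = ca * (big_delta - constants.a_permil) / (constants.b_permil - constants.a_permil)
    return out.item() if out.ndim == 0 else out


def wi_from_discrimination(big_delta, ca, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Intrinsic water-use efficiency Wi (ppm ≡ µmol mol⁻¹) from Δ13C.

    Wi = ca (b − Δ)/(1.6 (b − a)), identically (ca − ci)/1.6.
    """
    big_delta = np.asarray(big_delta, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("ca must be > 0")
    # factored so the limits are exact: Δ=b → 0, Δ=a → ca/1.6
    out = (ca / constants.diffusivity_ratio) * (
        (constants.b_permil - big_delta) / (constants.b_permil - constants.a_permil)
    )
    return out.item() if out.ndim == 0 else out


def discrimination_from_wi(wi, ca, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Δ13C implied by a prescribed Wi; inverse of :func:`wi_from_discrimination`."""
    wi = np.asarray(wi, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("ca must be > 0")
    out = constants.b_permil - (
        wi * constants.diffusivity_ratio * (constants.b_permil - constants.a_permil) / ca
    )
    return out.item() if out.ndim == 0 else out


def atmos_lookup(year: int | float, atmos: AtmosphericRecord) -> tuple[float, float]:
    """(ca ppm, δ13C_air ‰) at ``year``; interpolating, never extrapolating."""
    return atmos.lookup(year)


def gas_exchange_state(
    d13c_plant: float,
    year: int,
    atmos: AtmosphericRecord,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
    *,
    ca_override: float | None = None,
    d13c_air_override: float | None = None,
) -> GasExchangeState:
    """Full diagnostic state (Δ13C, ci, ci/ca, ca−ci, Wi) for one δ13C value.

    Source air comes from ``atmos`` at ``year`` unless explicit overrides are
    given (used by the below-canopy correction, which replaces the source air
    with the profile value at crown uptake height).
    """
    if ca_override is not None or d13c_air_override is not None:
        if ca_override is None or d13c_air_override is None:
            raise ValueError("ca_override and d13c_air_override go together")
        ca, d13c_air = float(ca_override), float(d13c_air_override)
    else:
        ca, d13c_air = atmos.lookup(year)
    delta = discrimination(d13c_plant, d13c_air)
    ci = ci_from_discrimination(delta, ca, constants)
    wi = wi_from_discrimination(delta, ca, constants)
    return GasExchangeState(
        year=int(year),
        ca_ppm=ca,
        d13c_air_permil=d13c_air,
        d13c_plant_permil=float(d13c_plant),
        big_delta_permil=delta,
        ci_ppm=ci,
        ci_over_ca=ci / ca,
        ca_minus_ci_ppm=ca - ci,
        wi_ppm=wi,
        out_of_range=not (constants.a_permil < delta < constants.b_permil),
    )
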