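"""Below-canopy source-air model and its correction of gas-exchange states.

Soil-respired CO2 (dead plant material, isotopically light) accumulates near
the forest floor during the day: CO2 concentration is elevated and δ13C_air
depleted in the first metres above the ground, decaying towards above-canopy
air with height. The excess CO2 is modelled as a negative exponential of
height; δ13C_air follows from exact two-member (Keeling-type) mass balance
between above-canopy air and respired CO2, which keeps the concentration and
isotope profiles internally consistent.

A tree's effective CO2 uptake is placed slightly below its top, at
0.9 × total height. Open-grown trees (forest_type "open") bypass the
correction entirely — their crowns sample well-mixed air.

Default profile amplitudes (temperate: 25 ppm ground excess, e-folding 2 m;
tropical: 40 ppm, 3 m; δ13C of respired CO2 −28 ‰) are package defaults
chosen to be realistic for daytime climatology, with tropical effects the
larger; all are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .isotope import GasExchangeState, IsotopeConstants, DEFAULT_CONSTANTS, gas_exchange_state
from .ring_data import AtmosphericRecord, TreeRecord

__all__ = [
    "CanopyProfileParams",
    "DEFAULT_PROFILES",
    "effective_uptake_height",
    "below_canopy_air",
    "corrected_gas_exchange",
    "correction_impact",
]


@dataclass(frozen=True)
class CanopyProfileParams:
    """Negative-exponential below-canopy CO2/δ13C_air profile.

    ``co2_excess_ground_ppm`` is the excess CO2 at the forest floor relative
    to above-canopy air; it decays with e-folding height
    ``e_folding_height_m``. ``d13c_respired_permil`` is the isotopic
    signature of soil-respired CO2 entering the mass balance.
    """

    forest_type: str
    co2_excess_ground_ppm: float
    e_folding_height_m: float
    d13c_respired_permil: float = -28.0

    def __post_init__(self) -> None:
        if self.co2_excess_ground_ppm < 0:
            raise ValueError(
                f"co2_excess_ground_ppm must be >= 0, got {self.co2_excess_ground_ppm}"
            )
        if not self.e_folding_height_m > 0:
            raise ValueError(
                f"e_folding_height_m must be > 0, got {self.e_folding_height_m}"
            )


DEFAULT_PROFILES: dict[str, CanopyProfileParams] = {
    "temperate": CanopyProfileParams("temperate", 25.0, 2.0, -28.0),
    "tropical": CanopyProfileParams("tropical", 40.0, 3.0, -28.0),
}


def effective_uptake_height(total_height_m: float) -> float:
    """Height of mean canopy CO2 uptake: 0.9 × total tree height."""
    if not total_height_m > 0:
        raise ValueError(f"total_height_m must be > 0, got {total_height_m}")
    return 0.9 * total_height_m


def below_canopy_air(
    height_m,
    params: CanopyProfileParams,
    ca_above: float,
    d13c_air_above: float,
):
    """Source air (ca ppm, δ13C_air ‰) at ``height_m`` above the floor.

    excess(h) = excess₀ · exp(−h/λ); ca(h) = ca_above + excess(h);
    δ13C_air(h) is the concentration-weighted mixture of above-canopy air and
    respired CO2 (exact two-member mass balance), so
    ca(h)·δ13C_air(h) = ca_above·δ_above + excess(h)·δ_resp identically.
    """
    if ca_above <= 0:
        raise ValueError(f"ca_above must be > 0, got {ca_above}")
    h = np.asarray(height_m, dtype=float)
    if np.any(h < 0):
        raise ValueError("height_m must be >= 0")
    excess = params.co2_excess_ground_ppm * np.exp(-h / params.e_folding_height_m)
    ca_h = ca_above + excess
    d13c_h = (ca_above * d13c_air_above + excess * params.d13c_respired_permil) / ca_h
    if ca_h.ndim == 0:
        return ca_h.item(), d13c_h.item()
    return ca_h, d13c_h


def corrected_gas_exchange(
    tree: TreeRecord,
    atmos: AtmosphericRecord,
    profiles: dict[str, CanopyProfileParams] | None = None,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
) -> GasExchangeState:
    """Gas-exchange state with source air taken at crown uptake height.

    ``profiles`` maps forest_type → profile (defaults to
    :data:`DEFAULT_PROFILES`). Open-grown trees bypass the correction and
    get the plain above-canopy state; a closed-forest tree whose forest type
    has no profile is a configuration error.
    """
    if tree.forest_type == "open":
        return gas_exchange_state(
            tree.d13c_outer_permil, tree.sampling_year, atmos, constants
        )
    profiles = DEFAULT_PROFILES if profiles is None else profiles
    profile = profiles.get(tree.forest_type)
    if profile is None:
        raise KeyError(
            f"no canopy profile configured for forest_type "
            f"{tree.forest_type!r} (tree {tree.tree_id})"
        )
    ca_above, d13c_above = atmos.lookup(tree.sampling_year)
    ca_h, d13c_h = below_canopy_air(
        effective_uptake_height(tree.height_m), profile, ca_above, d13c_above
    )
    return gas_exchange_state(
        tree.d13c_outer_permil,
        tree.sampling_year,
        atmos,
        constants,
        ca_override=ca_h,
        d13c_air_override=d13c_h,
    )


def correction_impact(slope_uncorrected: float, slope_corrected: float) -> float:
    """Percent reduction of a trend slope due to the source-air correction.

    100 × (uncorrected − corrected) / uncorrected; positive when the
    correction lowers the inferred developmental trend.
    """
    if slope_uncorrected == 0:
        raise ValueError("correction impact undefined for zero uncorrected slope")
    return 100.0 * (slope_uncorrected - slope_corrected) / slope_uncorrected
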