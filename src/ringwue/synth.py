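"""Synthetic stands and dominant-tree ring series with known ground truth.

The generator emulates a size-stratified isotope sampling campaign: trees of
all ages sampled in one year, so every outer ring formed under the same
atmosphere. Each tree's *true* intrinsic water-use efficiency is prescribed
as a linear function of height and crown illumination,

    Wi* = β0 + β_height · (H / 10 m) + β_light · (CII − 1) + ε,

and the wood δ13C such a tree would record is rendered by inverting the
Farquhar chain against the tree's source air (optionally the below-canopy
profile at 0.9 × its height). Because the truth is retained, every pipeline
stage is testable end to end, and the study's central confound — a purely
developmental Wi increase masquerading as a CO2/climate time trend when read
backwards along a dominant tree's rings under constant CO2 — can be made
quantitative: with σ = 0 the apparent time trend equals β_height · dH/dt by
the chain rule.

Height growth is monomolecular (von Bertalanffy), H(t) = Hmax (1 − e^(−kt)),
with defaults Hmax = 30 m, k = 0.02 yr⁻¹ so mid-life growth is 0.3 m yr⁻¹.
Crown illumination rises monotonically (stochastically for stands,
stepwise-deterministically for dominant-tree histories) with height relative
to the canopy; ``open_grown`` forces full exposure for all years, emulating
plantation-style open early growth. All randomness flows from one explicit
seed; identical seeds give identical output, byte-identical once written.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .canopy import CanopyProfileParams, below_canopy_air, effective_uptake_height
from .isotope import (
    DEFAULT_CONSTANTS,
    IsotopeConstants,
    discrimination_from_wi,
    invert_discrimination,
)
from .ring_data import (
    AtmosphericRecord,
    RingObservation,
    SoftRangeWarning,
    TreeRecord,
)

__all__ = [
    "StandConfig",
    "generate_atmosphere",
    "generate_stand",
    "render_d13c",
    "simulate_size_stratified_sample",
    "simulate_dominant_tree_series",
]

DEFAULT_SEED = 20170818


@dataclass(frozen=True)
class StandConfig:
    """Study conditions for a synthetic size-stratified stand.

    Defaults are the reference conditions used throughout: 150 trees spanning
    seedling to dominant, true Wi rising 18 ppm per 10 m of height and 5 ppm
    per crown-illumination step around a 35 ppm baseline, 8 ppm residual
    scatter, constant pre-industrial atmosphere.
    """

    n_trees: int = 150
    age_min_years: int = 3
    age_max_years: int = 120
    hmax_m: float = 30.0
    growth_rate_per_year: float = 0.02
    height_noise_sd: float = 0.10  # sd of multiplicative lognormal noise
    canopy_height_m: float = 30.0
    cii_noise_sd: float = 0.7  # ordered-category latent noise
    beta0_ppm: float = 35.0
    beta_height_ppm_per_10m: float = 18.0
    beta_light_ppm_per_step: float = 5.0
    sigma_ppm: float = 8.0
    species: str = "Synthetica exemplaris"
    site_id: str = "SYN1"
    forest_type: str = "temperate"
    sampling_year: int = 1900
    atmosphere_mode: str = "constant_preindustrial"  # or "ramp"
    profile: CanopyProfileParams | None = None
    open_grown: bool = False
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (self.hmax_m > 0 and self.growth_rate_per_year > 0):
            raise ValueError("hmax_m and growth_rate_per_year must be > 0")
        if self.sigma_ppm < 0:
            raise ValueError("sigma_ppm must be >= 0")

    def height_at(self, age_years):
        """Deterministic growth-curve height H(t) = Hmax (1 − e^(−kt))."""
        t = np.asarray(age_years, dtype=float)
        return self.hmax_m * (1.0 - np.exp(-self.growth_rate_per_year * t))

    def growth_rate_at(self, age_years):
        """Analytic dH/dt (m yr⁻¹) of the growth curve."""
        t = np.asarray(age_years, dtype=float)
        return self.hmax_m * self.growth_rate_per_year * np.exp(
            -self.growth_rate_per_year * t
        )

    def midlife_age_years(self) -> float:
        """Age at which growth has fallen to half its initial rate."""
        return float(np.log(2.0) / self.growth_rate_per_year)


def generate_atmosphere(
    mode: str,
    year_start: int,
    year_end: int,
    seed: int = 0,
    ca_endpoints: tuple[float, float] = (280.0, 400.0),
    d13c_endpoints: tuple[float, float] = (-6.4, -8.5),
) -> AtmosphericRecord:
    """Tabulated atmospheric record over a year span.

    ``constant_preindustrial`` gives 280 ppm / −6.4 ‰ at every year (and
    marks the record constant-mode, so lookups never refuse a year); ``ramp``
    gives a linear, strictly monotone CO2 rise with matching δ13C_air
    decline between the endpoint values. Both are deterministic; ``seed`` is
    accepted for interface symmetry.
    """
    if year_end < year_start:
        raise ValueError("year_end must be >= year_start")
    years = np.arange(year_start, year_end + 1)
    if mode == "constant_preindustrial":
        return AtmosphericRecord(
            years,
            np.full(len(years), AtmosphericRecord.PREINDUSTRIAL_CA_PPM),
            np.full(len(years), AtmosphericRecord.PREINDUSTRIAL_D13C_AIR),
            constant=True,
        )
    if mode == "ramp":
        frac = (
            np.zeros(len(years))
            if len(years) == 1
            else (years - year_start) / (year_end - year_start)
        )
        ca = ca_endpoints[0] + frac * (ca_endpoints[1] - ca_endpoints[0])
        d13c = d13c_endpoints[0] + frac * (d13c_endpoints[1] - d13c_endpoints[0])
        return AtmosphericRecord(years, ca, d13c)
    raise ValueError(f"unknown atmosphere mode {mode!r}")


def render_d13c(
    true_wi_ppm: float,
    year: int,
    atmos: AtmosphericRecord,
    height_m: float | None = None,
    profile: CanopyProfileParams | None = None,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
) -> float:
    """Wood δ13C a tree with intrinsic efficiency ``true_wi_ppm`` would record.

    Inverts the formula chain: Δ = b − 1.6·Wi·(b−a)/ca, then
    δ13C_plant = (δ13C_air − Δ)/(1 + Δ/1000), using the tree's source air —
    the below-canopy profile value at 0.9 × its height when a profile is
    active, otherwise the above-canopy atmosphere. Analysing the rendered
    δ13C under the same source-air assumptions returns ``true_wi_ppm``
    exactly (to floating-point round-off).
    """
    ca, d13c_air = atmos.lookup(year)
    if profile is not None:
        if height_m is None:
            raise ValueError("height_m required when a canopy profile is active")
        ca, d13c_air = below_canopy_air(
            effective_uptake_height(height_m), profile, ca, d13c_air
        )
    wi_max = ca / constants.diffusivity_ratio
    if not 0.0 <= true_wi_ppm <= wi_max:
        raise ValueError(
            f"true Wi {true_wi_ppm:.3f} ppm outside physical range "
            f"[0, {wi_max:.3f}] at ca = {ca:.1f} ppm"
        )
    delta = discrimination_from_wi(true_wi_ppm, ca, constants)
    return float(invert_discrimination(delta, d13c_air))


def _default_atmosphere(config: StandConfig) -> AtmosphericRecord:
    start = config.sampling_year - config.age_max_years - 1
    return generate_atmosphere(config.atmosphere_mode, start, config.sampling_year)


def _draw_cii(rng: np.random.Generator, rel_height: np.ndarray, noise_sd: float) -> np.ndarray:
    latent = 1.0 + 7.0 * np.clip(rel_height, 0.0, 1.0)
    if noise_sd > 0:
        latent = latent + rng.normal(0.0, noise_sd, size=latent.shape)
    return np.clip(np.rint(latent), 1, 8).astype(int)


_ORDINAL_TO_CII = {i + 1: c for i, c in enumerate(("1", "2a", "2b", "2c", "3a", "3b", "4", "5"))}


def generate_stand(
    config: StandConfig, atmos: AtmosphericRecord | None = None
) -> tuple[list[TreeRecord], pd.DataFrame]:
    """Generate a size-stratified stand and its hidden truth table.

    Ages are uniform over the configured range (even coverage of size
    classes); heights follow the growth curve with multiplicative lognormal
    noise; crown illumination is a monotone stochastic function of height
    relative to the canopy. Returns the TreeRecords (with rendered outer-ring
    δ13C) and a truth DataFrame holding each tree's true Wi — for testing
    only, never consumed by the analysis.
    """
    rng = np.random.default_rng(config.seed)
    atmos = _default_atmosphere(config) if atmos is None else atmos
    n = config.n_trees

    ages = np.rint(
        rng.uniform(config.age_min_years, config.age_max_years, size=n)
    ).astype(int)
    ages = np.maximum(ages, 1)
    heights = config.height_at(ages)
    if config.height_noise_sd > 0:
        heights = heights * np.exp(rng.normal(0.0, config.height_noise_sd, size=n))
    cii = (
        np.full(n, 8, dtype=int)
        if config.open_grown
        else _draw_cii(rng, heights / config.canopy_height_m, config.cii_noise_sd)
    )
    eps = rng.normal(0.0, config.sigma_ppm, size=n) if config.sigma_ppm > 0 else np.zeros(n)
    true_wi = (
        config.beta0_ppm
        + config.beta_height_ppm_per_10m * heights / 10.0
        + config.beta_light_ppm_per_step * (cii - 1)
        + eps
    )
    ca0, _ = atmos.lookup(config.sampling_year)
    lo, hi = 1.0, ca0 / DEFAULT_CONSTANTS.diffusivity_ratio - 1.0
    n_clip = int(np.sum((true_wi < lo) | (true_wi > hi)))
    if n_clip:
        warnings.warn(
            f"clipped {n_clip} true Wi value(s) into the physical range", stacklevel=2
        )
        true_wi = np.clip(true_wi, lo, hi)

    # dbh from a simple height allometry; seedlings below coring height have none
    dbh = 0.8 * heights**1.5 * np.exp(rng.normal(0.0, 0.05, size=n))
    records: list[TreeRecord] = []
    rows = []
    with warnings.catch_warnings():
        # rendered δ13C of high-Wi trees legitimately exceeds the conservative
        # field-data plausibility band; the advisory is for measured data
        warnings.simplefilter("ignore", SoftRangeWarning)
        for i in range(n):
            d13c = render_d13c(
                float(true_wi[i]),
                config.sampling_year,
                atmos,
                height_m=float(heights[i]),
                profile=config.profile,
            )
            tid = f"T{i + 1:04d}"
            records.append(
                TreeRecord(
                    tree_id=tid,
                    species=config.species,
                    site_id=config.site_id,
                    forest_type=config.forest_type,
                    sampling_year=config.sampling_year,
                    age_years=int(ages[i]),
                    dbh_cm=float(dbh[i]) if heights[i] >= 1.3 else None,
                    height_m=float(heights[i]),
                    cii_class=_ORDINAL_TO_CII[int(cii[i])],
                    d13c_outer_permil=d13c,
                )
            )
            rows.append(
                {
                    "tree_id": tid,
                    "age_years": int(ages[i]),
                    "height_m": float(heights[i]),
                    "cii_ordinal": int(cii[i]),
                    "true_wi_ppm": float(true_wi[i]),
                }
            )
    return records, pd.DataFrame(rows)


def simulate_size_stratified_sample(
    config: StandConfig,
    atmos: AtmosphericRecord | None = None,
    out_dir=None,
) -> tuple[list[TreeRecord], pd.DataFrame]:
    """Generate a stand and optionally write its tree table + truth table.

    The tree table uses the standard CSV schema; the truth table is written
    with a ``truth_`` prefix. Output is deterministic per seed.
    """
    from pathlib import Path

    from .ring_data import write_tree_table

    records, truth = generate_stand(config, atmos)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tree_table(records, out / "trees.csv")
        truth.to_csv(out / "truth_trees.csv", index=False, lineterminator="\n")
    return records, truth


def simulate_dominant_tree_series(
    config: StandConfig,
    n_dominant: int = 4,
    dominant_age_years: int | None = None,
    atmos: AtmosphericRecord | None = None,
    out_dir=None,
) -> tuple[list[RingObservation], pd.DataFrame]:
    """Annual pith-to-bark δ13C series for dominant trees, with truth.

    Each dominant tree's per-year height follows the growth curve (one
    multiplicative height factor per tree), its crown illumination rises
    stepwise with relative height (forced to maximum when ``open_grown``),
    and its per-year true Wi and rendered δ13C follow the stand model. Under
    a constant atmosphere any apparent "time trend" in the analysed series
    is purely developmental.
    """
    rng = np.random.default_rng(config.seed + 1)
    atmos = _default_atmosphere(config) if atmos is None else atmos
    age = config.age_max_years if dominant_age_years is None else dominant_age_years
    obs: list[RingObservation] = []
    rows = []
    for j in range(n_dominant):
        tid = f"D{j + 1:03d}"
        factor = (
            float(np.exp(rng.normal(0.0, config.height_noise_sd)))
            if config.height_noise_sd > 0
            else 1.0
        )
        t = np.arange(1, age + 1)
        years = config.sampling_year - age + t
        heights = config.height_at(t) * factor
        if config.open_grown:
            cii = np.full(age, 8, dtype=int)
        else:
            cii = np.clip(
                np.rint(1.0 + 7.0 * np.clip(heights / config.canopy_height_m, 0, 1)),
                1,
                8,
            ).astype(int)
        eps = (
            rng.normal(0.0, config.sigma_ppm, size=age)
            if config.sigma_ppm > 0
            else np.zeros(age)
        )
        true_wi = (
            config.beta0_ppm
            + config.beta_height_ppm_per_10m * heights / 10.0
            + config.beta_light_ppm_per_step * (cii - 1)
            + eps
        )
        for i in range(age):
            d13c = render_d13c(
                float(true_wi[i]),
                int(years[i]),
                atmos,
                height_m=float(heights[i]),
                profile=config.profile,
            )
            obs.append(
                RingObservation(
                    tree_id=tid,
                    calendar_year=int(years[i]),
                    ring_index=int(t[i]),
                    d13c_permil=d13c,
                    block_span_years=1,
                )
            )
            rows.append(
                {
                    "tree_id": tid,
                    "calendar_year": int(years[i]),
                    "age_years": int(t[i]),
                    "height_m": float(heights[i]),
                    "cii_ordinal": int(cii[i]),
                    "true_wi_ppm": float(true_wi[i]),
                    "growth_rate_m_per_yr": float(config.growth_rate_at(t[i]) * factor),
                }
            )
    truth = pd.DataFrame(rows)
    if out_dir is not None:
        from pathlib import Path

        from .ring_data import write_ring_table

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_ring_table(obs, out / "rings.csv")
        truth.to_csv(out / "truth_rings.csv", index=False, lineterminator="\n")
    return obs, truth
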