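"""Weighting conversions, normalisation and replicate aggregation.

The Coulter principle counts particles; the field plots *volume*-weighted
distributions, where each granule contributes in proportion to the volume of
the sphere with its equivalent diameter.  Conversions here move between the
two representations on a fixed bin grid using the geometric bin midpoint as
the representative diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sizedist import DiameterGrid, ReplicateSet, SizeDistribution, Weighting

__all__ = [
    "sphere_volume",
    "number_to_volume",
    "volume_to_number",
    "normalize_percent",
    "granules_per_mg",
    "binned_mass_mg",
    "AggregateCurve",
    "aggregate_replicates",
]

#: Density of starch in g cm⁻³ (literature value for native granules).
STARCH_DENSITY_G_CM3 = 1.5


def sphere_volume(d):
    """Volume (μm³) of a sphere of diameter ``d`` μm: π·d³/6."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    out = np.pi * d**3 / 6.0
    return float(out) if out.ndim == 0 else out


def number_to_volume(d: SizeDistribution) -> SizeDistribution:
    """Convert per-bin counts to relative volume %, normalised to sum 100."""
    if d.weighting is not Weighting.NUMBER_COUNTS:
        raise ValueError("number_to_volume expects a number_counts distribution")
    if not np.any(d.values > 0):
        raise ValueError("cannot volume-weight an all-zero count distribution")
    vol = d.values * sphere_volume(d.grid.midpoints)
    pct = 100.0 * vol / vol.sum()
    return d.with_values(
        pct,
        weighting=Weighting.RELATIVE_VOLUME_PCT,
        normalized=True,
        n_particles=float(d.values.sum()),
    )


def volume_to_number(d: SizeDistribution, total_count: float) -> SizeDistribution:
    """Invert volume weighting: counts ∝ value/midpoint³, scaled to ``total_count``.

    Counts are real-valued; rounding is the caller's choice.
    """
    if d.weighting is not Weighting.RELATIVE_VOLUME_PCT:
        raise ValueError("volume_to_number expects a relative_volume_pct distribution")
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if d.values.sum() <= 0:
        raise ValueError("cannot invert a zero-sum volume distribution")
    raw = d.values / d.grid.midpoints**3
    counts = total_count * raw / raw.sum()
    return d.with_values(
        counts, weighting=Weighting.NUMBER_COUNTS, normalized=False, n_particles=None
    )


def normalize_percent(d: SizeDistribution) -> SizeDistribution:
    """Scale values to sum exactly 100 and flag the result normalised."""
    total = float(d.values.sum())
    if total <= 0:
        raise ValueError("cannot normalise a distribution with non-positive sum")
    return d.with_values(
        100.0 * d.values / total,
        weighting=Weighting.RELATIVE_VOLUME_PCT,
        normalized=True,
    )


def binned_mass_mg(
    d: SizeDistribution, density_g_cm3: float = STARCH_DENSITY_G_CM3
) -> float:
    """Starch mass (mg) implied by per-bin counts at the given density.

    1 μm³ = 1e-12 cm³, so mass_mg = ρ[g cm⁻³] · V[μm³] · 1e-9.
    """
    if d.weighting is not Weighting.NUMBER_COUNTS:
        raise ValueError("binned_mass_mg expects a number_counts distribution")
    total_um3 = float(np.sum(d.values * sphere_volume(d.grid.midpoints)))
    return density_g_cm3 * total_um3 * 1e-9


def granules_per_mg(d: SizeDistribution, mass_mg: float | None = None) -> float:
    """Total granule count divided by the starch mass analysed (mg)."""
    if d.weighting is not Weighting.NUMBER_COUNTS:
        raise ValueError("granules_per_mg expects a number_counts distribution")
    mass = mass_mg if mass_mg is not None else d.mass_mg
    if mass is None:
        raise ValueError(
            "no starch mass available: set mass_mg on the distribution or pass it"
        )
    if mass <= 0:
        raise ValueError("mass_mg must be positive")
    return float(d.values.sum()) / mass


@dataclass(frozen=True)
class AggregateCurve:
    """Per-bin mean ± standard error over biological replicates."""

    grid: DiameterGrid
    mean: np.ndarray
    se: np.ndarray
    n: int
    genotype: str = ""
    timepoint: str = ""


def aggregate_replicates(rs: ReplicateSet) -> AggregateCurve:
    """Arithmetic per-bin mean and standard error (sd/√n, n−1 denominator).

    Requires ≥ 2 normalised volume-% replicates on a common grid, mirroring
    how mean ± SE curves of biological replicates are plotted.
    """
    if len(rs) < 2:
        raise ValueError("aggregation needs at least two replicates")
    for d in rs:
        if d.weighting is not Weighting.RELATIVE_VOLUME_PCT or not d.normalized:
            raise ValueError(
                f"replicate {d.replicate} of {d.sample_id!r} is not a "
                "normalised relative_volume_pct distribution"
            )
    stack = np.vstack([d.values for d in rs])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(n)
    return AggregateCurve(
        grid=rs.grid,
        mean=mean,
        se=se,
        n=n,
        genotype=rs.genotype,
        timepoint=rs.timepoint,
    )
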