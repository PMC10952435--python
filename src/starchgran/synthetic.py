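"""Seeded synthetic granule populations emulating Coulter-counter runs.

Presets parameterise the *volume-weighted* mixture directly — that is the
representation the instrument software plots and the decomposition fits —
so the generative truth and the fitted model share one parameterisation.
The number-weighted view needed for multinomial particle sampling is derived
by dividing the per-bin volume density by the midpoint diameter cubed.

Preset anchors (mature wild type: A peak near 19 μm, B volume-mean 6 μm,
B content 40%; mature mutant: 23 μm / 8.75 μm / 70%; 12 DAF unimodal A-only
at 14.0 / 14.4 μm; 16 DAF with 5% A-diameter and 98% B-content increases in
the mutant) sit at the midpoints of the reported "circa" ranges.  Spread
defaults (σ_A = 3.5 μm, s_B = 0.35) are implementer-chosen to reproduce the
visual width and valley structure of mature wheat-type distributions and
are configurable per spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .decompose import MixtureParams, mixture_bin_percent
from .sizedist import DiameterGrid, ReplicateSet, SizeDistribution, Weighting
from .transforms import STARCH_DENSITY_G_CM3, binned_mass_mg, number_to_volume

__all__ = [
    "PopulationSpec",
    "PRESET_NAMES",
    "make_preset",
    "expected_volume_density",
    "sample_binned_counts",
    "simulate_replicate_set",
]

DEFAULT_GRID = DiameterGrid.log_spaced(2.0, 60.0, 300)
DEFAULT_TOTAL_GRANULES = 100_000
DEFAULT_JITTER_CV = 0.03


@dataclass(frozen=True)
class PopulationSpec:
    """Generative parameters for one synthetic granule population."""

    params: MixtureParams
    total_granules: int = DEFAULT_TOTAL_GRANULES
    grid: DiameterGrid = field(default_factory=lambda: DEFAULT_GRID)
    replicate_jitter_cv: float = DEFAULT_JITTER_CV
    density_g_cm3: float = STARCH_DENSITY_G_CM3
    genotype: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.params.validate()
        if self.total_granules < 1_000:
            raise ValueError("total_granules must be at least 10³")
        if not (0.0 <= self.replicate_jitter_cv <= 0.2):
            raise ValueError("replicate_jitter_cv must lie in [0, 0.2]")
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")


def _mlog_for_mean(b_mean: float, slog: float) -> float:
    """Log-normal location giving mean diameter ``b_mean`` at scale ``slog``."""
    return math.log(b_mean) - slog**2 / 2.0


_SIGMA_A = 3.5
_SLOG_B = 0.35

# Mature-grain anchors: WT A peak c. 19 μm / B peak c. 6 μm, B content 40%;
# mutant A 23 μm (22–24 range midpoint), B 8.75 μm (8–9.5), B content 70%
# (67–73).  12 DAF is unimodal (A-only, 14.0 vs 14.4 μm).  16 DAF applies
# the reported relative differences (A +5%, B content +98%) to WT bases of
# 16 μm and 0.15.
_PRESETS: dict[str, dict] = {
    "WT_mature": dict(a_mean=19.0, b_mean=6.0, w_b=0.40, genotype="WT", timepoint="mature"),
    "parc6_mature": dict(a_mean=23.0, b_mean=8.75, w_b=0.70, genotype="parc6", timepoint="mature"),
    "WT_12DAF": dict(a_mean=14.0, b_mean=None, w_b=0.0, genotype="WT", timepoint="12DAF"),
    "parc6_12DAF": dict(a_mean=14.4, b_mean=None, w_b=0.0, genotype="parc6", timepoint="12DAF"),
    "WT_16DAF": dict(a_mean=16.0, b_mean=6.0, w_b=0.15, genotype="WT", timepoint="16DAF"),
    "parc6_16DAF": dict(
        a_mean=16.0 * 1.05, b_mean=6.5, w_b=0.15 * 1.98, genotype="parc6", timepoint="16DAF"
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def make_preset(name: str, **overrides) -> PopulationSpec:
    """Build the fully specified PopulationSpec for a named preset.

    Keyword overrides replace any PopulationSpec field (e.g. total_granules,
    grid, replicate_jitter_cv, density_g_cm3).
    """
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    cfg = _PRESETS[name]
    if cfg["w_b"] > 0:
        params = MixtureParams(
            w_B=cfg["w_b"],
            mu_A=cfg["a_mean"],
            sigma_A=_SIGMA_A,
            mlog_B=_mlog_for_mean(cfg["b_mean"], _SLOG_B),
            slog_B=_SLOG_B,
        )
    else:
        params = MixtureParams(w_B=0.0, mu_A=cfg["a_mean"], sigma_A=_SIGMA_A)
    spec = PopulationSpec(
        params=params, genotype=cfg["genotype"], timepoint=cfg["timepoint"]
    )
    return replace(spec, **overrides) if overrides else spec


def expected_volume_density(spec: PopulationSpec) -> SizeDistribution:
    """Noiseless per-bin volume %: the binned mixture, normalised to 100.

    Raises if a component peak sits more than three spreads outside the grid,
    where truncation would distort the normalised curve.
    """
    p = spec.params
    edges = spec.grid.edges
    if not (edges[0] - 3 * p.sigma_A <= p.mu_A <= edges[-1] + 3 * p.sigma_A):
        raise ValueError(
            f"A peak at {p.mu_A:g} μm lies more than 3σ outside the grid "
            f"[{edges[0]:g}, {edges[-1]:g}] μm"
        )
    if p.has_b:
        lo, hi = math.log(edges[0]), math.log(edges[-1])
        if not (lo - 3 * p.slog_B <= p.mlog_B <= hi + 3 * p.slog_B):
            raise ValueError(
                f"B peak at {math.exp(p.mlog_B):g} μm lies more than 3 log-spreads "
                f"outside the grid [{edges[0]:g}, {edges[-1]:g}] μm"
            )
    raw = mixture_bin_percent(spec.grid, p)
    values = 100.0 * raw / raw.sum()
    return SizeDistribution(
        grid=spec.grid,
        values=values,
        weighting=Weighting.RELATIVE_VOLUME_PCT,
        sample_id=f"{spec.genotype}_{spec.timepoint}_expected",
        genotype=spec.genotype,
        timepoint=spec.timepoint,
        normalized=True,
    )


def sample_binned_counts(spec: PopulationSpec, seed: int) -> SizeDistribution:
    """One multinomial Coulter run: ``total_granules`` particles over the bins.

    The expected volume density is converted to expected number proportions
    (divide by midpoint³, renormalise) and a single multinomial draw is
    taken.  Deterministic per (spec, seed); the seed is mandatory so no
    global random state is ever consulted.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    expected = expected_volume_density(spec)
    mids = spec.grid.midpoints
    number_prop = expected.values / mids**3
    number_prop = number_prop / number_prop.sum()
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    counts = rng.multinomial(spec.total_granules, number_prop).astype(float)
    dist = SizeDistribution(
        grid=spec.grid,
        values=counts,
        weighting=Weighting.NUMBER_COUNTS,
        sample_id=f"{spec.genotype}_{spec.timepoint}_s{seed}",
        genotype=spec.genotype,
        timepoint=spec.timepoint,
        normalized=False,
    )
    mass = binned_mass_mg(dist, spec.density_g_cm3)
    return replace(dist, mass_mg=mass)


def _jittered(spec: PopulationSpec, rng: np.random.Generator) -> PopulationSpec:
    """Multiply the two location parameters by independent log-normal factors.

    The jitter has unit mean and coefficient of variation replicate_jitter_cv,
    emulating plant-to-plant variation in granule size; w_B is left alone.
    """
    cv = spec.replicate_jitter_cv
    if cv == 0:
        return spec
    s = math.sqrt(math.log1p(cv**2))
    f_a, f_b = np.exp(rng.normal(-s**2 / 2.0, s, size=2))
    p = spec.params
    if p.has_b:
        new = MixtureParams(
            w_B=p.w_B,
            mu_A=p.mu_A * f_a,
            sigma_A=p.sigma_A,
            mlog_B=p.mlog_B + math.log(f_b),
            slog_B=p.slog_B,
        )
    else:
        new = MixtureParams(w_B=0.0, mu_A=p.mu_A * f_a, sigma_A=p.sigma_A)
    return replace(spec, params=new)


def simulate_replicate_set(
    spec: PopulationSpec,
    n_reps: int = 3,
    seed: int = 0,
    as_counts: bool = False,
) -> ReplicateSet:
    """Simulate ``n_reps`` biological replicates from one population spec.

    Each replicate gets its own sub-seed spawned from (seed, replicate
    index) by fixed arithmetic, so increasing ``n_reps`` never perturbs
    earlier replicates.  Location parameters receive seeded log-normal
    jitter; counts are then drawn and, unless ``as_counts``, converted to
    normalised relative volume %.
    """
    if n_reps < 2:
        raise ValueError("need at least two replicates")
    if seed is None:
        raise ValueError("an explicit seed is required")
    dists = []
    for r in range(1, n_reps + 1):
        ss = np.random.SeedSequence(entropy=(int(seed), r))
        jitter_rng = np.random.default_rng(ss)
        rep_spec = _jittered(spec, jitter_rng)
        sub_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        counts = sample_binned_counts(rep_spec, seed=sub_seed)
        counts = replace(
            counts,
            sample_id=f"{spec.genotype}_{spec.timepoint}_rep{r}",
            replicate=r,
        )
        if as_counts:
            dists.append(counts)
        else:
            vol = number_to_volume(counts)
            dists.append(replace(vol, mass_mg=counts.mass_mg))
    return ReplicateSet(tuple(dists))
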