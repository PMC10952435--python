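"""End-to-end orchestration: data in, per-replicate fits, metrics, group
statistics, aggregate curves, tables and plots.

The pipeline fits each biological replicate separately and summarises
genotypes as means over per-replicate metrics (never a fit to the mean
curve), then compares genotypes within each timepoint with the comparison
scheme of :mod:`starchgran.groupstats`.  All outputs are deterministic
functions of the configuration (and master seed in synthetic mode); every
output file carries a provenance header with the config hash, seed and
package version.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decompose import (
    FitResult,
    GranuleMetrics,
    derive_metrics,
    select_model,
)
from .groupstats import ComparisonResult, GroupSample, TestKind, compare_groups
from .sizedist import (
    ReplicateSet,
    SizeDistribution,
    Weighting,
    read_sizedist_table,
    write_sizedist_table,
)
from .synthetic import make_preset, simulate_replicate_set
from .transforms import (
    AggregateCurve,
    aggregate_replicates,
    granules_per_mg,
    normalize_percent,
    number_to_volume,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "render_report"]

#: Metrics compared across genotypes, in output order.
METRIC_COLUMNS = (
    "a_mean_diameter",
    "b_mean_diameter",
    "b_content_pct",
    "granules_per_mg",
)


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "from_files"
    presets: tuple[tuple[str, int], ...] = ()  # (preset name, n_reps)
    inputs: tuple[str, ...] = ()
    total_granules: int | None = None  # override for synthetic presets
    prominence_frac: float = 0.05
    alpha: float = 0.05
    alpha_assumption: float = 0.05
    outdir: str = "starchgran_out"
    seed: int | None = None
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "from_files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic":
            if self.seed is None:
                raise ValueError("synthetic mode requires a master seed")
            if not self.presets:
                raise ValueError("synthetic mode requires at least one preset")
        if self.mode == "from_files" and not self.inputs:
            raise ValueError("from_files mode requires at least one input path")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "presets" in raw:
            raw["presets"] = tuple(
                (str(p[0]), int(p[1])) if isinstance(p, (list, tuple)) else (str(p), 3)
                for p in raw["presets"]
            )
        if "inputs" in raw:
            raw["inputs"] = tuple(str(p) for p in raw["inputs"])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class RunReport:
    """In-memory result of a pipeline run."""

    config: RunConfig
    metrics: pd.DataFrame
    comparisons: dict[tuple[str, str], ComparisonResult] = field(default_factory=dict)
    curves: tuple[AggregateCurve, ...] = ()


def _collect_synthetic(cfg: RunConfig) -> list[tuple[ReplicateSet, ReplicateSet]]:
    """(volume replicates, count replicates) per preset entry, seeded."""
    out = []
    for idx, (name, n_reps) in enumerate(cfg.presets):
        overrides = {}
        if cfg.total_granules is not None:
            overrides["total_granules"] = cfg.total_granules
        spec = make_preset(name, **overrides)
        sub = int(
            np.random.SeedSequence(entropy=(int(cfg.seed), 1000 + idx))
            .generate_state(1)[0]
            % (2**31 - 1)
        )
        vol = simulate_replicate_set(spec, n_reps=n_reps, seed=sub)
        cnt = simulate_replicate_set(spec, n_reps=n_reps, seed=sub, as_counts=True)
        out.append((vol, cnt))
    return out


def _collect_from_files(cfg: RunConfig) -> list[tuple[ReplicateSet, ReplicateSet | None]]:
    by_group: dict[tuple[str, str], list[tuple[SizeDistribution, SizeDistribution | None]]] = {}
    for path in cfg.inputs:
        for dist in read_sizedist_table(path):
            counts = dist if dist.weighting is Weighting.NUMBER_COUNTS else None
            vol = (
                number_to_volume(dist)
                if dist.weighting is Weighting.NUMBER_COUNTS
                else (dist if dist.normalized else normalize_percent(dist))
            )
            if counts is not None:
                vol = replace(vol, mass_mg=counts.mass_mg)
            by_group.setdefault((dist.genotype, dist.timepoint), []).append((vol, counts))
    out = []
    for pairs in by_group.values():
        vols = ReplicateSet(tuple(v for v, _ in pairs))
        cnts = (
            ReplicateSet(tuple(c for _, c in pairs))
            if all(c is not None for _, c in pairs)
            else None
        )
        out.append((vols, cnts))
    return out


def _fit_row(
    dist: SizeDistribution,
    counts: SizeDistribution | None,
    prominence_frac: float,
) -> dict:
    fit: FitResult = select_model(dist, prominence_frac=prominence_frac)
    gpm = None
    if counts is not None and counts.mass_mg:
        gpm = granules_per_mg(counts)
    metrics: GranuleMetrics | None = None
    if fit.converged:
        metrics = derive_metrics(fit, granules_per_mg=gpm)
    p = fit.params
    return {
        "sample_id": dist.sample_id,
        "genotype": dist.genotype,
        "timepoint": dist.timepoint,
        "replicate": dist.replicate,
        "n_components": fit.n_components,
        "w_B": p.w_B,
        "mu_A": p.mu_A,
        "sigma_A": p.sigma_A,
        "mlog_B": p.mlog_B if fit.n_components == 2 else None,
        "slog_B": p.slog_B if fit.n_components == 2 else None,
        "rss": fit.rss,
        "converged": fit.converged,
        "a_mean_diameter": metrics.a_mean_diameter if metrics else None,
        "b_mean_diameter": metrics.b_mean_diameter if metrics else None,
        "b_content_pct": metrics.b_content_pct if metrics else None,
        "granules_per_mg": metrics.granules_per_mg if metrics else None,
    }


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every stage and return the in-memory report.

    Every sample appears exactly once in the metrics table; non-converged
    fits are reported with empty metric fields, never dropped.
    """
    if cfg.mode == "synthetic":
        groups = _collect_synthetic(cfg)
    else:
        groups = _collect_from_files(cfg)

    rows = []
    curves = []
    for vol_set, cnt_set in groups:
        cnt_by_rep = {c.replicate: c for c in cnt_set} if cnt_set is not None else {}
        for dist in vol_set:
            rows.append(
                _fit_row(dist, cnt_by_rep.get(dist.replicate), cfg.prominence_frac)
            )
        if len(vol_set) >= 2:
            curves.append(aggregate_replicates(vol_set))
    metrics = pd.DataFrame(rows)

    comparisons: dict[tuple[str, str], ComparisonResult] = {}
    for timepoint, sub in metrics.groupby("timepoint", sort=False):
        genotypes = list(dict.fromkeys(sub["genotype"]))
        if len(genotypes) < 2:
            continue
        for metric in METRIC_COLUMNS:
            samples = []
            for g in genotypes:
                obs = sub.loc[sub["genotype"] == g, metric].dropna().to_numpy(float)
                if obs.size >= 2:
                    samples.append(GroupSample(label=g, observations=obs))
            if len(samples) < 2:
                continue
            comparisons[(str(timepoint), metric)] = compare_groups(
                samples, alpha=cfg.alpha, alpha_assumption=cfg.alpha_assumption
            )
    return RunReport(
        config=cfg, metrics=metrics, comparisons=comparisons, curves=tuple(curves)
    )


def _provenance(cfg: RunConfig) -> str:
    return (
        f"# starchgran v{__version__}\tconfig_hash={cfg.hash()}\t"
        f"seed={cfg.seed}\n"
    )


def _write_tsv(frame: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        frame.to_csv(fh, sep="\t", index=False, na_rep="na", lineterminator="\n")


def _comparison_frame(report: RunReport) -> pd.DataFrame:
    rows = []
    for (timepoint, metric), comp in report.comparisons.items():
        sub = report.metrics[report.metrics["timepoint"] == timepoint]
        for i, label in enumerate(comp.labels):
            obs = sub.loc[sub["genotype"] == label, metric].dropna().to_numpy(float)
            row = {
                "timepoint": timepoint,
                "metric": metric,
                "test": comp.test_used.value,
                "omnibus_statistic": comp.omnibus.statistic,
                "omnibus_p": comp.omnibus.pvalue,
                "group": label,
                "n": obs.size,
                "mean": obs.mean() if obs.size else None,
                "se": (obs.std(ddof=1) / np.sqrt(obs.size)) if obs.size > 1 else None,
                "letters": comp.letters[label],
            }
            for j, other in enumerate(comp.labels):
                if other != label:
                    row[f"p_vs_{other}"] = comp.pairwise_p[i, j]
            rows.append(row)
    return pd.DataFrame(rows)


def _curve_distributions(report: RunReport) -> list[SizeDistribution]:
    dists = []
    for curve in report.curves:
        dists.append(
            SizeDistribution(
                grid=curve.grid,
                values=curve.mean,
                weighting=Weighting.RELATIVE_VOLUME_PCT,
                sample_id=f"{curve.genotype}_{curve.timepoint}_mean",
                genotype=curve.genotype,
                timepoint=curve.timepoint,
                replicate=0,
            )
        )
    return dists


def _plot_timepoint(curves, timepoint: str, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.0, 3.4))
    for curve in curves:
        mids = curve.grid.midpoints
        ax.plot(mids, curve.mean, label=curve.genotype)
        ax.fill_between(
            mids, curve.mean - curve.se, curve.mean + curve.se, alpha=0.3, lw=0
        )
    ax.set_xscale("log")
    ax.set_xlabel("Granule diameter (μm)")
    ax.set_ylabel("Relative volume (%)")
    ax.set_title(f"Granule size distribution, {timepoint}")
    ax.legend(frameon=False)
    fig.tight_layout()
    paths = []
    for ext in ("svg", "png"):
        p = outdir / f"distribution_{timepoint}.{ext}"
        fig.savefig(p)
        paths.append(p)
    plt.close(fig)
    return paths


def render_report(report: RunReport, outdir=None) -> dict[str, list[Path]]:
    """Write metrics, comparison and aggregate-curve TSVs plus one plot per
    timepoint (SVG + PNG).  Plotting failures downgrade to warnings; the
    tables are the contract.  Returns the written paths by kind.
    """
    cfg = report.config
    out = Path(outdir) if outdir is not None else Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[Path]] = {"tables": [], "plots": []}

    metrics_path = out / "metrics.tsv"
    _write_tsv(report.metrics, metrics_path, cfg)
    written["tables"].append(metrics_path)

    comp_path = out / "comparisons.tsv"
    comp_frame = _comparison_frame(report)
    if comp_frame.empty:
        comp_frame = pd.DataFrame(
            columns=["timepoint", "metric", "test", "omnibus_statistic",
                     "omnibus_p", "group", "n", "mean", "se", "letters"]
        )
    _write_tsv(comp_frame, comp_path, cfg)
    written["tables"].append(comp_path)

    curves_path = out / "aggregate_curves.tsv"
    dists = _curve_distributions(report)
    if dists:
        with open(curves_path, "w") as fh:
            fh.write(_provenance(cfg))
            write_sizedist_table(dists, fh, sep="\t")
    else:
        with open(curves_path, "w") as fh:
            fh.write(_provenance(cfg))
    written["tables"].append(curves_path)

    by_tp: dict[str, list[AggregateCurve]] = {}
    for curve in report.curves:
        by_tp.setdefault(curve.timepoint, []).append(curve)
    for timepoint, curves in by_tp.items():
        try:
            written["plots"].extend(_plot_timepoint(curves, timepoint, out))
        except Exception as exc:  # tables are the contract, plots best-effort
            warnings.warn(f"plotting failed for {timepoint}: {exc}", stacklevel=2)
    return written
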