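"""Binned granule size distributions and their CSV/TSV serialisation.

A Coulter counter reports one equivalent spherical diameter per particle,
accumulated on a fixed (log-spaced) grid of diameter bins.  This module
defines the in-memory containers for such binned distributions — a
:class:`DiameterGrid`, a per-sample :class:`SizeDistribution` and a
:class:`ReplicateSet` of biological replicates — plus reading, writing and
validation of a long-format CSV/TSV dialect with explicit bin edges.

Dialect
-------
One row per (sample, bin).  Mandatory columns: ``sample_id``, ``genotype``,
``timepoint``, ``replicate``, ``weighting``, ``bin_lower_um``,
``bin_upper_um``, ``value``; optional ``mass_mg``.  Units are fixed to μm,
the decimal separator is ``.`` and the field separator is ``,`` (or a tab
when ``sep="\\t"`` is passed).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Weighting",
    "DiameterGrid",
    "SizeDistribution",
    "ReplicateSet",
    "FormatError",
    "read_sizedist_table",
    "write_sizedist_table",
    "validate_distribution",
]

_NORM_TOL = 1e-6  # tolerance on sum == 100 for normalised volume %


class FormatError(ValueError):
    """A table violates the size-distribution dialect."""


class Weighting(str, Enum):
    """How each particle contributes to a bin's value."""

    NUMBER_COUNTS = "number_counts"
    RELATIVE_VOLUME_PCT = "relative_volume_pct"


@dataclass(frozen=True)
class DiameterGrid:
    """Strictly increasing diameter bin edges (μm) with geometric midpoints.

    Geometric midpoints match the log-spaced grids of particle-sizing
    instruments: on a log axis they sit exactly halfway across each bin.
    """

    edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("grid needs at least two bin edges")
        if not np.all(edges > 0):
            raise ValueError("bin edges must be positive diameters (μm)")
        if not np.all(np.diff(edges) > 0):
            bad = int(np.flatnonzero(np.diff(edges) <= 0)[0])
            raise ValueError(
                f"bin edges must be strictly increasing; edge {bad + 1} "
                f"({edges[bad + 1]:g} μm) does not exceed edge {bad} ({edges[bad]:g} μm)"
            )

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def midpoints(self) -> np.ndarray:
        """Geometric mean of adjacent edges, one per bin."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @classmethod
    def log_spaced(cls, d_min: float, d_max: float, n_bins: int) -> "DiameterGrid":
        """A grid of ``n_bins`` bins log-uniform between ``d_min`` and ``d_max`` μm."""
        if d_min <= 0 or d_max <= d_min:
            raise ValueError("need 0 < d_min < d_max")
        return cls(np.geomspace(d_min, d_max, n_bins + 1))

    def same_edges(self, other: "DiameterGrid", rtol: float = 1e-9) -> bool:
        return self.edges.size == other.edges.size and np.allclose(
            self.edges, other.edges, rtol=rtol, atol=0.0
        )


@dataclass(frozen=True)
class SizeDistribution:
    """One sample's binned size distribution with its metadata.

    ``values`` holds either particle counts per bin or relative volume
    percentages, as declared by ``weighting``.  ``normalized`` marks a
    volume-% distribution whose values sum to 100.
    """

    grid: DiameterGrid
    values: np.ndarray
    weighting: Weighting = Weighting.RELATIVE_VOLUME_PCT
    sample_id: str = "sample"
    genotype: str = ""
    timepoint: str = ""
    replicate: int = 1
    mass_mg: float | None = None
    normalized: bool = False
    n_particles: float | None = None  # total particles, if known for a volume dist

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "weighting", Weighting(self.weighting))

    def with_values(self, values: np.ndarray, **changes) -> "SizeDistribution":
        return replace(self, values=np.asarray(values, dtype=float), **changes)


@dataclass(frozen=True)
class ReplicateSet:
    """Biological replicates of one (genotype, timepoint) on a common grid."""

    distributions: tuple[SizeDistribution, ...]

    def __post_init__(self) -> None:
        dists = tuple(self.distributions)
        object.__setattr__(self, "distributions", dists)
        if not dists:
            raise ValueError("a ReplicateSet needs at least one distribution")
        ref = dists[0]
        for d in dists[1:]:
            if not d.grid.same_edges(ref.grid):
                raise ValueError("replicates must share identical grid edges")
            if d.weighting is not ref.weighting:
                raise ValueError("replicates must share one weighting")
            if (d.genotype, d.timepoint) != (ref.genotype, ref.timepoint):
                raise ValueError("replicates must share genotype and timepoint")
        reps = [d.replicate for d in dists]
        if len(set(reps)) != len(reps):
            raise ValueError(f"replicate indices must be unique, got {reps}")

    def __len__(self) -> int:
        return len(self.distributions)

    def __iter__(self):
        return iter(self.distributions)

    @property
    def grid(self) -> DiameterGrid:
        return self.distributions[0].grid

    @property
    def genotype(self) -> str:
        return self.distributions[0].genotype

    @property
    def timepoint(self) -> str:
        return self.distributions[0].timepoint


def validate_distribution(d: SizeDistribution) -> list[str]:
    """Check every invariant; return human-readable violations (empty = valid)."""
    violations: list[str] = []
    if d.values.size != d.grid.n_bins:
        violations.append(
            f"value count {d.values.size} does not match bin count {d.grid.n_bins}"
        )
    neg = np.flatnonzero(d.values < 0)
    for i in neg:
        violations.append(f"negative value {d.values[i]:g} in bin {int(i)}")
    if (
        d.weighting is Weighting.RELATIVE_VOLUME_PCT
        and d.normalized
        and d.values.size
        and abs(float(d.values.sum()) - 100.0) > _NORM_TOL
    ):
        violations.append(
            f"flagged normalized but values sum to {float(d.values.sum()):.9g}, not 100"
        )
    if d.mass_mg is not None and d.mass_mg <= 0:
        violations.append(f"mass_mg must be positive, got {d.mass_mg:g}")
    return violations


_COLUMNS = [
    "sample_id",
    "genotype",
    "timepoint",
    "replicate",
    "weighting",
    "mass_mg",
    "bin_lower_um",
    "bin_upper_um",
    "value",
]


def _frame_for(d: SizeDistribution) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": d.sample_id,
            "genotype": d.genotype,
            "timepoint": d.timepoint,
            "replicate": d.replicate,
            "weighting": d.weighting.value,
            "mass_mg": "" if d.mass_mg is None else repr(float(d.mass_mg)),
            "bin_lower_um": d.grid.edges[:-1],
            "bin_upper_um": d.grid.edges[1:],
            "value": d.values,
        }
    )


def write_sizedist_table(
    dists: Sequence[SizeDistribution], path, sep: str = ","
) -> None:
    """Write distributions in the long CSV/TSV dialect.

    All distributions must share one grid; an empty list is an error rather
    than an empty (unreadable) file.
    """
    dists = list(dists)
    if not dists:
        raise ValueError("refusing to write an empty table: no distributions given")
    ref = dists[0].grid
    for d in dists[1:]:
        if not d.grid.same_edges(ref):
            raise ValueError("all distributions in one file must share a grid")
    for d in dists:
        problems = validate_distribution(d)
        if problems:
            raise ValueError(
                f"invalid distribution {d.sample_id!r}: " + "; ".join(problems)
            )
    frame = pd.concat([_frame_for(d) for d in dists], ignore_index=True)
    # repr() keeps full float precision for a lossless round trip
    frame["bin_lower_um"] = [repr(float(x)) for x in frame["bin_lower_um"]]
    frame["bin_upper_um"] = [repr(float(x)) for x in frame["bin_upper_um"]]
    frame["value"] = [repr(float(x)) for x in frame["value"]]
    frame.to_csv(path, sep=sep, index=False, columns=_COLUMNS)


def _parse_float(raw, row: int, column: str) -> float:
    text = str(raw).strip()
    if "," in text:
        raise FormatError(
            f"row {row}: column {column!r} uses ',' as a decimal separator "
            f"({text!r}); only '.' decimals are accepted"
        )
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"row {row}: cannot parse {column!r} value {text!r}") from exc


def read_sizedist_table(path, sep: str = ",") -> list[SizeDistribution]:
    """Read a long-format table back into one SizeDistribution per sample_id.

    Bins for each sample must be contiguous (each upper edge equals the next
    lower edge) and strictly increasing; violations raise :class:`FormatError`
    naming the offending row.
    """
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise FormatError(f"cannot parse table {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c != "mass_mg" and c not in frame.columns]
    if missing:
        raise FormatError(f"table is missing mandatory columns: {missing}")

    dists: list[SizeDistribution] = []
    for sample_id, rows in frame.groupby("sample_id", sort=False):
        lowers, uppers, values = [], [], []
        for idx, row in rows.iterrows():
            lowers.append(_parse_float(row["bin_lower_um"], idx + 2, "bin_lower_um"))
            uppers.append(_parse_float(row["bin_upper_um"], idx + 2, "bin_upper_um"))
            values.append(_parse_float(row["value"], idx + 2, "value"))
        lowers_a, uppers_a = np.asarray(lowers), np.asarray(uppers)
        for k in range(len(lowers)):
            rownum = int(rows.index[k]) + 2
            if uppers_a[k] <= lowers_a[k]:
                raise FormatError(
                    f"row {rownum}: non-monotonic bin edges for sample "
                    f"{sample_id!r}: upper {uppers_a[k]:g} ≤ lower {lowers_a[k]:g}"
                )
            if k and abs(lowers_a[k] - uppers_a[k - 1]) > 1e-9 * max(1.0, uppers_a[k - 1]):
                raise FormatError(
                    f"row {rownum}: bins for sample {sample_id!r} are not "
                    f"contiguous: lower edge {lowers_a[k]:g} does not match "
                    f"previous upper edge {uppers_a[k - 1]:g}"
                )
        edges = np.append(lowers_a, uppers_a[-1])
        try:
            grid = DiameterGrid(edges)
        except ValueError as exc:
            raise FormatError(f"sample {sample_id!r}: {exc}") from exc

        first = rows.iloc[0]
        try:
            weighting = Weighting(first["weighting"])
        except ValueError as exc:
            raise FormatError(
                f"sample {sample_id!r}: unknown weighting {first['weighting']!r}; "
                f"expected one of {[w.value for w in Weighting]}"
            ) from exc
        mass_raw = str(first.get("mass_mg", "")).strip()
        mass = _parse_float(mass_raw, int(rows.index[0]) + 2, "mass_mg") if mass_raw else None
        values_a = np.asarray(values, dtype=float)
        neg = np.flatnonzero(values_a < 0)
        if neg.size:
            rownum = int(rows.index[neg[0]]) + 2
            raise FormatError(
                f"row {rownum}: negative value {values_a[neg[0]]:g} for sample {sample_id!r}"
            )
        normalized = (
            weighting is Weighting.RELATIVE_VOLUME_PCT
            and abs(float(values_a.sum()) - 100.0) <= _NORM_TOL
        )
        dists.append(
            SizeDistribution(
                grid=grid,
                values=values_a,
                weighting=weighting,
                sample_id=str(sample_id),
                genotype=str(first["genotype"]),
                timepoint=str(first["timepoint"]),
                replicate=int(float(first["replicate"])),
                mass_mg=mass,
                normalized=normalized,
            )
        )
    if not dists:
        raise FormatError("table contains no data rows")
    return dists
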