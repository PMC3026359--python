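"""Deuterium uptake quantification.

Converts isotopic peak clusters into back-exchange-corrected deuteration
percentages.  The central quantity is the intensity-weighted centroid of a
peptide ion's isotopic cluster; uptake is its shift between the nondeuterated
reference (centroid ``c_N``), the partially deuterated measurement (``c_P``)
and a fully deuterated reference (``c_F``):

    raw fraction   r = (c_P - c_N) / (c_F - c_N)
    uptake percent   = 100 * r / (recovery * buffer_d_fraction)

where ``recovery`` undoes back-exchange losses (default 0.70) and
``buffer_d_fraction`` accounts for the labeling buffer containing less than
100% D2O (default 0.80).  ``c_F`` is by default the *theoretical* 100%
exchange reference, ``c_N + n_exch * deuterium_mass_shift / charge``; if a
measured fully-deuterated control is supplied instead, only the
buffer-fraction correction is applied (the control already carries the
back-exchange loss).
"""

from __future__ import annotations

import csv
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from .chem import DEUTERIUM_MASS_SHIFT
from .peptide_map import PeptideRecord, count_exchangeable_amides

__all__ = [
    "IsotopicCluster",
    "CorrectionParams",
    "DeuterationLevel",
    "UptakePoint",
    "UptakeCurve",
    "HdxSummary",
    "centroid",
    "fully_deuterated_centroid",
    "deuteration_level",
    "build_uptake_curves",
    "summarize_hdx",
    "read_peak_csv",
    "write_peak_csv",
    "write_uptake_csv",
]

PEAK_CSV_COLUMNS = [
    "peptide_sequence",
    "charge",
    "condition",
    "time_s",
    "replicate",
    "mz",
    "intensity",
    "sn_ratio",
]

UPTAKE_CSV_COLUMNS = [
    "peptide",
    "start",
    "end",
    "condition",
    "time_s",
    "centroid_mz",
    "uptake_percent",
    "flag",
]

#: corrected values in (100, CLAMP_LIMIT] clamp to 100; above it we refuse.
CLAMP_LIMIT = 105.0


@dataclass(frozen=True)
class IsotopicCluster:
    """One peptide ion's peak list at one timepoint/condition/replicate.

    Peaks are canonicalized on construction: sorted by m/z with duplicate
    m/z rows merged by summing intensity.
    """

    peptide_sequence: str
    charge: int
    condition: str
    time: float
    replicate: int
    peaks: tuple[tuple[float, float], ...]
    sn_ratio: float = float("inf")

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.time < 0:
            raise ValueError("time must be >= 0")
        merged: dict[float, float] = {}
        for mz, intensity in self.peaks:
            if intensity < 0:
                raise ValueError(
                    f"negative intensity {intensity} at m/z {mz} "
                    f"({self.peptide_sequence} {self.condition} t={self.time})"
                )
            merged[mz] = merged.get(mz, 0.0) + intensity
        canonical = tuple(sorted(merged.items()))
        if not any(i > 0 for _, i in canonical):
            raise ValueError(
                f"cluster has no positive-intensity peak "
                f"({self.peptide_sequence} {self.condition} t={self.time})"
            )
        object.__setattr__(self, "peaks", canonical)

    @property
    def key(self) -> tuple[str, int]:
        return (self.peptide_sequence, self.charge)


@dataclass(frozen=True)
class CorrectionParams:
    """Back-exchange and buffer corrections applied to raw uptake."""

    recovery: float = 0.70
    buffer_d_fraction: float = 0.80
    deuterium_mass_shift: float = DEUTERIUM_MASS_SHIFT

    def __post_init__(self) -> None:
        if not (0 < self.recovery <= 1):
            raise ValueError("recovery must be in (0, 1]")
        if not (0 < self.buffer_d_fraction <= 1):
            raise ValueError("buffer_d_fraction must be in (0, 1]")
        if self.deuterium_mass_shift <= 0:
            raise ValueError("deuterium_mass_shift must be > 0")


class DeuterationLevel(NamedTuple):
    percent: float
    flag: str  # "", "clamped_high", or "floored_negative"


def centroid(cluster: IsotopicCluster | Sequence[tuple[float, float]]) -> float:
    """Intensity-weighted mean m/z of a peak list."""
    peaks = cluster.peaks if isinstance(cluster, IsotopicCluster) else list(cluster)
    total = sum(i for _, i in peaks)
    if total <= 0:
        raise ValueError("cannot centroid a cluster with zero total intensity")
    return sum(mz * i for mz, i in peaks) / total


def fully_deuterated_centroid(
    c_n: float, n_exch: int, charge: int, params: CorrectionParams
) -> float:
    """Theoretical centroid at 100% exchange of ``n_exch`` amides."""
    if n_exch < 0:
        raise ValueError("n_exch must be >= 0")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return c_n + n_exch * params.deuterium_mass_shift / charge


def deuteration_level(
    c_p: float,
    c_n: float,
    c_f: float,
    params: CorrectionParams,
    *,
    measured_reference: bool = False,
) -> DeuterationLevel:
    """Corrected deuteration percent from the three centroids.

    With the default computed ``c_F`` the raw fraction is divided by
    ``recovery * buffer_d_fraction``; with ``measured_reference=True`` (a
    measured fully-deuterated control) only ``buffer_d_fraction`` applies.
    Values in (100, 105] clamp to 100 with a flag; larger overshoots indicate
    a broken reference and raise.  Negative values floor at 0 with a flag.
    """
    if c_f <= c_n:
        raise ValueError(
            f"degenerate reference: fully-deuterated centroid {c_f} must exceed "
            f"nondeuterated centroid {c_n}"
        )
    divisor = params.buffer_d_fraction
    if not measured_reference:
        divisor *= params.recovery
    percent = 100.0 * (c_p - c_n) / (c_f - c_n) / divisor
    if percent < 0:
        return DeuterationLevel(0.0, "floored_negative")
    if percent > CLAMP_LIMIT:
        raise ValueError(
            f"corrected deuteration {percent:.1f}% exceeds {CLAMP_LIMIT}%: "
            "reference centroids are inconsistent with the measurement"
        )
    if percent > 100.0 + 1e-9:
        return DeuterationLevel(100.0, "clamped_high")
    return DeuterationLevel(min(percent, 100.0), "")


@dataclass(frozen=True)
class UptakePoint:
    """One nonzero timepoint of an uptake curve (replicates aggregated)."""

    time: float
    centroid: float
    centroid_sd: float
    uptake_percent: float
    flag: str
    replicate_centroids: Mapping[int, float]
    replicate_uptake: Mapping[int, float]  # raw per-replicate, unclamped


@dataclass(frozen=True)
class UptakeCurve:
    """Corrected uptake of one peptide/charge in one condition over time."""

    peptide: PeptideRecord
    condition: str
    reference_centroid: float
    full_centroid: float
    points: tuple[UptakePoint, ...]

    @property
    def key(self) -> tuple[str, int]:
        return self.peptide.key

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(p.time for p in self.points)

    @property
    def uptake(self) -> tuple[float, ...]:
        return tuple(p.uptake_percent for p in self.points)


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def build_uptake_curves(
    clusters: Iterable[IsotopicCluster],
    peptides: Iterable[PeptideRecord],
    params: CorrectionParams = CorrectionParams(),
    sn_threshold: float = 3.0,
    *,
    shared_reference: bool = True,
    exclude_n_terminal: int = 1,
    measured_full: Mapping[tuple[str, int], float] | None = None,
) -> tuple[list[UptakeCurve], list[tuple[tuple[str, int], str]]]:
    """Assemble per-peptide, per-condition uptake curves.

    A time-0 (nondeuterated) cluster must exist for every peptide; by default
    one reference is shared across conditions (time-0 centroids from all
    conditions and replicates are averaged), set ``shared_reference=False``
    for per-condition references.  Peptides with any cluster at or below
    ``sn_threshold`` are dropped entirely and returned in the exclusion list
    as ``(key, reason)`` pairs.  ``measured_full`` optionally maps peptide
    keys to measured fully-deuterated centroids (see ``deuteration_level``).
    """
    peptide_by_key = {p.key: p for p in peptides}
    by_key: dict[tuple[str, int], list[IsotopicCluster]] = defaultdict(list)
    for cluster in clusters:
        by_key[cluster.key].append(cluster)

    exclusions: list[tuple[tuple[str, int], str]] = []
    curves: list[UptakeCurve] = []

    for key in sorted(by_key):
        if key not in peptide_by_key:
            exclusions.append((key, "cluster has no matching peptide record"))
            continue
        peptide = peptide_by_key[key]
        group = by_key[key]

        low = [c for c in group if not (c.sn_ratio > sn_threshold)]
        if low:
            worst = min(c.sn_ratio for c in low)
            exclusions.append((key, f"S/N {worst:g} <= threshold {sn_threshold:g}"))
            continue

        n_exch = count_exchangeable_amides(peptide.sequence, exclude_n_terminal)
        if n_exch == 0:
            exclusions.append((key, "no exchangeable amides"))
            continue

        zero = [c for c in group if c.time == 0]
        nonzero = [c for c in group if c.time > 0]
        conditions = sorted({c.condition for c in nonzero})

        for condition in conditions:
            if shared_reference:
                refs = zero
            else:
                refs = [c for c in zero if c.condition == condition]
            if not refs:
                raise ValueError(
                    f"missing time-0 reference for peptide {key[0]} (z={key[1]})"
                    + ("" if shared_reference else f" in condition {condition!r}")
                )
            c_n = sum(centroid(c) for c in refs) / len(refs)
            measured = measured_full is not None and key in measured_full
            if measured:
                c_f = measured_full[key]
            else:
                c_f = fully_deuterated_centroid(c_n, n_exch, peptide.charge, params)

            points: list[UptakePoint] = []
            cond_clusters = [c for c in nonzero if c.condition == condition]
            for time in sorted({c.time for c in cond_clusters}):
                reps = {
                    c.replicate: centroid(c)
                    for c in cond_clusters
                    if c.time == time
                }
                rep_uptake = {
                    r: 100.0
                    * (c_p - c_n)
                    / (c_f - c_n)
                    / (
                        params.buffer_d_fraction
                        * (1.0 if measured else params.recovery)
                    )
                    for r, c_p in reps.items()
                }
                mean_c, sd_c = _mean_sd(list(reps.values()))
                level = deuteration_level(
                    mean_c, c_n, c_f, params, measured_reference=measured
                )
                points.append(
                    UptakePoint(
                        time=time,
                        centroid=mean_c,
                        centroid_sd=sd_c,
                        uptake_percent=level.percent,
                        flag=level.flag,
                        replicate_centroids=dict(sorted(reps.items())),
                        replicate_uptake=dict(sorted(rep_uptake.items())),
                    )
                )
            curves.append(
                UptakeCurve(
                    peptide=peptide,
                    condition=condition,
                    reference_centroid=c_n,
                    full_centroid=c_f,
                    points=tuple(points),
                )
            )
    return curves, exclusions


@dataclass(frozen=True)
class HdxSummary:
    """Per-peptide mean/max uptake and the grand mean over all points."""

    per_peptide: tuple[tuple[tuple[str, int], float, float], ...]  # key, mean, max
    grand_mean: float


def summarize_hdx(
    curves: Iterable[UptakeCurve], condition: str | None = None
) -> HdxSummary:
    """Summarize uptake curves, optionally restricted to one condition."""
    selected = [
        c for c in curves if condition is None or c.condition == condition
    ]
    if not selected:
        raise ValueError("no curves to summarize")
    rows = []
    all_values: list[float] = []
    for curve in selected:
        values = list(curve.uptake)
        if not values:
            continue
        rows.append((curve.key, sum(values) / len(values), max(values)))
        all_values.extend(values)
    if not all_values:
        raise ValueError("curves contain no uptake points")
    return HdxSummary(
        per_peptide=tuple(rows), grand_mean=sum(all_values) / len(all_values)
    )


# ---------------------------------------------------------------------------
# Peak-list CSV I/O: one row per peak,
# peptide_sequence,charge,condition,time_s,replicate,mz,intensity,sn_ratio
# ---------------------------------------------------------------------------


def read_peak_csv(path: str | Path) -> list[IsotopicCluster]:
    groups: dict[tuple, list[tuple[float, float]]] = defaultdict(list)
    sn: dict[tuple, float] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        missing = set(PEAK_CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(
                f"{path}: peak CSV missing columns: {', '.join(sorted(missing))}"
            )
        for row in reader:
            gkey = (
                row["peptide_sequence"].strip(),
                int(row["charge"]),
                row["condition"].strip(),
                float(row["time_s"]),
                int(row["replicate"]),
            )
            groups[gkey].append((float(row["mz"]), float(row["intensity"])))
            sn[gkey] = float(row["sn_ratio"])
    return [
        IsotopicCluster(
            peptide_sequence=seq,
            charge=charge,
            condition=condition,
            time=time,
            replicate=replicate,
            peaks=tuple(peaks),
            sn_ratio=sn[(seq, charge, condition, time, replicate)],
        )
        for (seq, charge, condition, time, replicate), peaks in sorted(groups.items())
    ]


def write_peak_csv(clusters: Iterable[IsotopicCluster], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(PEAK_CSV_COLUMNS)
        ordered = sorted(
            clusters,
            key=lambda c: (c.peptide_sequence, c.charge, c.condition, c.time, c.replicate),
        )
        for c in ordered:
            for mz, intensity in c.peaks:
                writer.writerow(
                    [
                        c.peptide_sequence,
                        c.charge,
                        c.condition,
                        f"{c.time:g}",
                        c.replicate,
                        f"{mz:.6f}",
                        f"{intensity:.6f}",
                        f"{c.sn_ratio:g}",
                    ]
                )


def write_uptake_csv(curves: Iterable[UptakeCurve], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(UPTAKE_CSV_COLUMNS)
        ordered = sorted(curves, key=lambda c: (c.peptide.start, c.key, c.condition))
        for curve in ordered:
            for point in curve.points:
                writer.writerow(
                    [
                        curve.peptide.sequence,
                        curve.peptide.start,
                        curve.peptide.end,
                        curve.condition,
                        f"{point.time:g}",
                        f"{point.centroid:.6f}",
                        f"{point.uptake_percent:.4f}",
                        point.flag,
                    ]
                )
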