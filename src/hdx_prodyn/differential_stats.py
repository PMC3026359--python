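"""Apo-vs-holo differential analysis.

Per peptide/charge pair: a two-sided paired Student t-test over the last few
(default three) labeling timepoints, with the mean uptake difference
(apo - holo, in percentage points) reported alongside.  Positive differences
mean the holo state exchanged less, i.e. the ligand protected the region.
The test runs on raw cluster centroids by default, matching how such data
are usually compared; because corrected uptake is an affine transform of the
centroid (per peptide/charge, shared reference), both bases give the same t.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .uptake_core import UptakeCurve

__all__ = [
    "PairedTResult",
    "DifferentialResult",
    "paired_t_test",
    "select_last_timepoints",
    "differential_table",
    "benjamini_hochberg",
    "write_differential_csv",
]

DIFF_CSV_COLUMNS = [
    "peptide",
    "start",
    "end",
    "holo_condition",
    "delta_hdx_percent",
    "t",
    "df",
    "p",
    "classification",
]


class PairedTResult(NamedTuple):
    t: float
    p: float
    df: int
    flag: str  # "", "zero_variance", or "untestable"


def paired_t_test(
    apo_values: Sequence[float], holo_values: Sequence[float]
) -> PairedTResult:
    """Two-sided paired Student t-test on series paired by position.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``d = apo - holo`` and the
    sample standard deviation; p comes from the t distribution with ``n - 1``
    degrees of freedom.  Zero-variance differences with nonzero mean give
    ``t = +/-inf, p = 0`` flagged ``zero_variance``; all-zero differences are
    flagged ``untestable``.
    """
    apo = np.asarray(apo_values, dtype=float)
    holo = np.asarray(holo_values, dtype=float)
    if apo.shape != holo.shape or apo.ndim != 1:
        raise ValueError("apo and holo series must be 1-D and the same length")
    n = apo.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = apo - holo
    df = n - 1
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        if mean == 0:
            return PairedTResult(float("nan"), float("nan"), df, "untestable")
        return PairedTResult(math.copysign(float("inf"), mean), 0.0, df, "zero_variance")
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(_scipy_stats.t.sf(abs(t), df))
    return PairedTResult(t, p, df, "")


def select_last_timepoints(
    series: Sequence[tuple[float, float]], k: int = 3
) -> list[tuple[float, float]]:
    """The ``k`` largest-time entries of a (time, value) series, ascending."""
    entries = sorted(series, key=lambda tv: tv[0])
    if len(entries) < k:
        raise ValueError(f"series has {len(entries)} points, need at least {k}")
    return entries[len(entries) - k :]


@dataclass(frozen=True)
class DifferentialResult:
    """One peptide/charge pair's apo-vs-holo comparison."""

    peptide_key: tuple[str, int]
    start: int
    end: int
    apo_condition: str
    holo_condition: str
    delta_hdx_percent: float
    t_statistic: float
    p_value: float
    df: int
    classification: str  # protected | destabilized | not_significant | untestable


def _paired_series(
    apo_curve: UptakeCurve, holo_curve: UptakeCurve, k: int, basis: str
) -> tuple[list[float], list[float]]:
    """Values paired by (timepoint, replicate) over the last-k timepoints."""
    apo_points = {p.time: p for p in apo_curve.points}
    holo_points = {p.time: p for p in holo_curve.points}
    shared = sorted(set(apo_points) & set(holo_points))
    times = [t for t, _ in select_last_timepoints([(t, 0.0) for t in shared], k)]
    apo_series: list[float] = []
    holo_series: list[float] = []
    for time in times:
        a, h = apo_points[time], holo_points[time]
        if basis == "centroid":
            a_reps, h_reps = a.replicate_centroids, h.replicate_centroids
        elif basis == "uptake":
            a_reps, h_reps = a.replicate_uptake, h.replicate_uptake
        else:
            raise ValueError(f"basis must be 'centroid' or 'uptake', got {basis!r}")
        for replicate in sorted(set(a_reps) & set(h_reps)):
            apo_series.append(a_reps[replicate])
            holo_series.append(h_reps[replicate])
    return apo_series, holo_series


def differential_table(
    apo_curves: Iterable[UptakeCurve],
    holo_curves: Iterable[UptakeCurve],
    alpha: float = 0.05,
    last_k: int = 3,
    basis: str = "centroid",
    bh_correction: bool = False,
) -> tuple[list[DifferentialResult], list[tuple[tuple[str, int], str]]]:
    """Compare every peptide/charge present in both condition sets.

    Returns the results plus a list of excluded ``(key, reason)`` pairs for
    peptides present in only one condition.  ``delta_hdx_percent`` is the
    mean over the selected timepoints of (apo uptake - holo uptake), always
    computed from corrected uptake regardless of the test ``basis``.  Apo
    centroids exceed holo centroids under protection, so apo - holo is
    positive for protected peptides on either basis.
    """
    apo_by_key = {c.key: c for c in apo_curves}
    holo_by_key = {c.key: c for c in holo_curves}
    excluded = []
    for key in sorted(set(apo_by_key) - set(holo_by_key)):
        excluded.append((key, f"missing in condition {_label(holo_by_key) or 'holo'}"))
    for key in sorted(set(holo_by_key) - set(apo_by_key)):
        excluded.append((key, f"missing in condition {_label(apo_by_key) or 'apo'}"))

    results: list[DifferentialResult] = []
    for key in sorted(set(apo_by_key) & set(holo_by_key)):
        apo_curve, holo_curve = apo_by_key[key], holo_by_key[key]
        apo_series, holo_series = _paired_series(apo_curve, holo_curve, last_k, basis)
        test = paired_t_test(apo_series, holo_series)

        apo_uptake, holo_uptake = _paired_series(apo_curve, holo_curve, last_k, "uptake")
        deltas = [a - h for a, h in zip(apo_uptake, holo_uptake)]
        delta = sum(deltas) / len(deltas)

        results.append(
            DifferentialResult(
                peptide_key=key,
                start=apo_curve.peptide.start,
                end=apo_curve.peptide.end,
                apo_condition=apo_curve.condition,
                holo_condition=holo_curve.condition,
                delta_hdx_percent=delta,
                t_statistic=test.t,
                p_value=test.p,
                df=test.df,
                classification=_classify(delta, test, alpha),
            )
        )
    if bh_correction:
        results = _apply_bh(results, alpha)
    return results, excluded


def _label(curves_by_key: dict) -> str | None:
    for curve in curves_by_key.values():
        return curve.condition
    return None


def _classify(delta: float, test: PairedTResult, alpha: float) -> str:
    if test.flag == "untestable":
        return "untestable"
    if test.p < alpha:
        return "protected" if delta > 0 else "destabilized"
    return "not_significant"


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH-adjusted p-values (q-values), preserving input order."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running_min = min(running_min, p[idx] * n / rank)
        adjusted[idx] = running_min
    return adjusted.tolist()


def _apply_bh(
    results: list[DifferentialResult], alpha: float
) -> list[DifferentialResult]:
    testable = [r for r in results if r.classification != "untestable"]
    if not testable:
        return results
    q_values = benjamini_hochberg([r.p_value for r in testable])
    q_by_key = {r.peptide_key: q for r, q in zip(testable, q_values)}
    adjusted = []
    for r in results:
        if r.classification == "untestable":
            adjusted.append(r)
            continue
        q = q_by_key[r.peptide_key]
        classification = (
            ("protected" if r.delta_hdx_percent > 0 else "destabilized")
            if q < alpha
            else "not_significant"
        )
        adjusted.append(
            DifferentialResult(
                peptide_key=r.peptide_key,
                start=r.start,
                end=r.end,
                apo_condition=r.apo_condition,
                holo_condition=r.holo_condition,
                delta_hdx_percent=r.delta_hdx_percent,
                t_statistic=r.t_statistic,
                p_value=q,
                df=r.df,
                classification=classification,
            )
        )
    return adjusted


def write_differential_csv(
    results: Iterable[DifferentialResult], path: str | Path
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(DIFF_CSV_COLUMNS)
        for r in sorted(results, key=lambda r: (r.start, r.peptide_key)):
            writer.writerow(
                [
                    r.peptide_key[0],
                    r.start,
                    r.end,
                    r.holo_condition,
                    f"{r.delta_hdx_percent:.4f}",
                    f"{r.t_statistic:.6g}",
                    r.df,
                    f"{r.p_value:.6g}",
                    r.classification,
                ]
            )
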