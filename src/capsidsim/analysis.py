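"""Trajectory analytics: size census time series, pathway statistics,
simulated light scattering and rate-scaling grid scans.

All statistics are computed by replaying an :class:`~capsidsim.engine.EventLog`
against the size census it implies, so they can be recomputed from stored
log files without rerunning the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .corrections import EffectFactors
from .engine import ASSOCIATION, CLOSURE, DISSOCIATION, EventLog, SimConfig, run_ensemble
from .ruleset import RuleSet

__all__ = [
    "MassFractionSeries",
    "TrajectorySummary",
    "mass_fraction_series",
    "frequency_matrix",
    "scattering_curve",
    "scattering_signal",
    "trajectory_summary",
    "grid_scan",
    "PAPER_KON_SCALES",
    "PAPER_KOFF_SCALES",
]

#: The on/off-rate scaling grids of the published 54-point scan.
PAPER_KON_SCALES = (0.1, 0.5, 1.0, 5.0, 10.0, 30.0, 50.0, 100.0, 500.0)
PAPER_KOFF_SCALES = (0.1, 0.25, 0.5, 1.0, 2.0, 5.0)


class LogIntegrityError(ValueError):
    """An event log is inconsistent with the stated subunit count."""


def _census_replay(log: EventLog, n_subunits: int):
    """Yield ``(time, census)`` after every event, starting from all monomers.

    ``census`` maps assembly size -> count.  Raises
    :class:`LogIntegrityError` if an event consumes a species that is not
    present.
    """
    census = {1: n_subunits} if n_subunits else {}
    yield 0.0, dict(census)

    def take(size: int) -> None:
        have = census.get(size, 0)
        if have <= 0:
            raise LogIntegrityError(
                f"event consumes a {size}-mer but none is present"
            )
        if have == 1:
            del census[size]
        else:
            census[size] = have - 1

    def put(size: int) -> None:
        census[size] = census.get(size, 0) + 1

    for rec in log.records:
        if rec.kind == ASSOCIATION:
            take(rec.size_i)
            take(rec.size_j)
            put(rec.product_size)
        elif rec.kind == DISSOCIATION:
            if rec.size_j:  # split into two fragments
                take(rec.product_size)
                put(rec.size_i)
                put(rec.size_j)
            # internal ring-bond break: census unchanged
        elif rec.kind == CLOSURE:
            pass  # intra-fragment bond re-formation: census unchanged
        else:
            raise LogIntegrityError(f"unknown event kind {rec.kind!r}")
        yield rec.time, dict(census)


@dataclass
class MassFractionSeries:
    """Fraction of subunits residing in each assembly size over time.

    ``fractions[t, s-1]`` is ``s * count_s(t) / n_subunits``; each row sums
    to 1.
    """

    times: np.ndarray  # (T,)
    fractions: np.ndarray  # (T, n_subunits)

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.fractions.shape[1] + 1)


def mass_fraction_series(log: EventLog, n_subunits: int | None = None) -> MassFractionSeries:
    """Reconstruct the mass-fraction time series from an event log."""
    if n_subunits is None:
        n_subunits = log.n_subunits
    times, rows = [], []
    for t, census in _census_replay(log, n_subunits):
        row = np.zeros(n_subunits)
        total = 0
        for size, count in census.items():
            row[size - 1] = size * count / n_subunits
            total += size * count
        if total != n_subunits:
            raise LogIntegrityError(
                f"census holds {total} subunits, expected {n_subunits}"
            )
        times.append(t)
        rows.append(row)
    return MassFractionSeries(np.asarray(times), np.vstack(rows))


def frequency_matrix(logs: list[EventLog], capsid_size: int | None = None) -> np.ndarray:
    """Binding-frequency matrix pooled over an ensemble of logs.

    ``matrix[i, j]`` (1-based sizes; row/col 0 unused) is the fraction of
    association events producing an ``i``-mer in which at least one reactant
    was a ``j``-mer.  Each event is counted once per involved reactant size,
    so a row sums to 2 unless equal-size reactants occurred.
    """
    if not logs:
        raise ValueError("at least one log is required")
    if capsid_size is None:
        capsid_size = logs[0].capsid_size
    n = capsid_size
    counts = np.zeros((n + 1, n + 1))
    denom = np.zeros(n + 1)
    for log in logs:
        for rec in log.records:
            if rec.kind != ASSOCIATION:
                continue
            p = rec.product_size
            denom[p] += 1
            counts[p, rec.size_i] += 1
            if rec.size_j != rec.size_i:
                counts[p, rec.size_j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.where(denom[:, None] > 0, counts / denom[:, None], 0.0)
    return matrix


def scattering_signal(census: dict[int, int], n_subunits: int) -> float:
    """Rayleigh-like scattering proxy ``sum_s count_s * s**2 / n**2``.

    Mass-squared weighting makes the signal 1 for a single complete
    ``n``-mer and ``1/n`` for free monomers, mirroring the shape of static
    light-scattering assembly curves.
    """
    return sum(count * size**2 for size, count in census.items()) / n_subunits**2


def scattering_curve(
    logs: list[EventLog],
    n_subunits: int | None = None,
    time_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-averaged scattering proxy on a common time grid.

    Each trajectory's piecewise-constant signal is resampled onto
    ``time_grid`` by last-observation-carried-forward and averaged.  The
    default grid is logarithmic over the protocol window (assembly spans
    orders of magnitude in time).
    """
    if not logs:
        raise ValueError("at least one log is required")
    if n_subunits is None:
        n_subunits = logs[0].n_subunits
    if time_grid is None:
        limit = max(log.time_limit for log in logs)
        time_grid = np.logspace(-4, np.log10(limit), 200)
    time_grid = np.asarray(time_grid, dtype=float)
    acc = np.zeros_like(time_grid)
    for log in logs:
        times, signals = [], []
        for t, census in _census_replay(log, n_subunits):
            times.append(t)
            signals.append(scattering_signal(census, n_subunits))
        idx = np.searchsorted(np.asarray(times), time_grid, side="right") - 1
        acc += np.asarray(signals)[np.clip(idx, 0, None)]
    return time_grid, acc / len(logs)


@dataclass(frozen=True)
class TrajectorySummary:
    """Largest assembly reached, when it was first reached, and completion."""

    max_size: int
    time_to_max: float
    completed: bool


def trajectory_summary(log: EventLog, capsid_size: int | None = None) -> TrajectorySummary:
    """Maximum assembly size and the time of its first attainment."""
    if capsid_size is None:
        capsid_size = log.capsid_size
    best, t_best = 1, 0.0
    for t, census in _census_replay(log, log.n_subunits):
        largest = max(census) if census else 0
        if largest > best:
            best, t_best = largest, t
    return TrajectorySummary(best, t_best, best == capsid_size)


def grid_scan(
    ruleset: RuleSet,
    kon_scales=PAPER_KON_SCALES,
    koff_scales=PAPER_KOFF_SCALES,
    reps: int = 100,
    base_seed: int = 0,
    config: SimConfig | None = None,
    effect_points: dict[str, EffectFactors] | None = None,
) -> pd.DataFrame:
    """Mean max assembly size and time-to-max over a rate-scaling grid.

    Cells are visited row-major (kon outer, koff inner); cell ``k`` uses
    per-rep seeds ``base_seed + k*reps + rep``, so the identity cell
    ``(1, 1)`` with matching seeds reproduces an unscaled ensemble exactly.
    ``effect_points`` optionally appends one row per named
    :class:`EffectFactors` (the 16 RNA-effect combinations) evaluated at
    their (kon_factor, koff_factor) location.
    """
    if not kon_scales or not koff_scales:
        raise ValueError("scaling grids must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    cell = 0
    for kon_s in kon_scales:
        for koff_s in koff_scales:
            logs = run_ensemble(
                ruleset, config=config, reps=reps,
                base_seed=base_seed + cell * reps,
                kon_scale=kon_s, koff_scale=koff_s,
            )
            summaries = [trajectory_summary(log) for log in logs]
            rows.append(
                {
                    "kon_scale": kon_s,
                    "koff_scale": koff_s,
                    "label": "",
                    "mean_max_size": float(np.mean([s.max_size for s in summaries])),
                    "mean_time_to_max": float(np.mean([s.time_to_max for s in summaries])),
                    "completion_fraction": float(
                        np.mean([s.completed for s in summaries])
                    ),
                    "reps": reps,
                }
            )
            cell += 1
    if effect_points:
        for label, factors in effect_points.items():
            logs = run_ensemble(
                ruleset, factors=factors, config=config, reps=reps,
                base_seed=base_seed + cell * reps,
            )
            summaries = [trajectory_summary(log) for log in logs]
            rows.append(
                {
                    "kon_scale": factors.kon_factor,
                    "koff_scale": factors.koff_factor,
                    "label": label,
                    "mean_max_size": float(np.mean([s.max_size for s in summaries])),
                    "mean_time_to_max": float(np.mean([s.time_to_max for s in summaries])),
                    "completion_fraction": float(
                        np.mean([s.completed for s in summaries])
                    ),
                    "reps": reps,
                }
            )
            cell += 1
    return pd.DataFrame(rows)
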