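"""Biomass-specific rate vectors from concentration time series.

A *phenotype* is the vector ``a = (mu, r_2, ..., r_m)'`` of biomass-specific
rates observed at one sampling time of one cultivation: the specific growth
rate mu [1/h] plus, for every non-biomass compound D, the specific
consumption/production rate

    r_D(t) = (1 / c_1(t)) * dc_D/dt        [mmol / g / h]

with c_1 the biomass concentration [g/L].  Consumption is negative.

Between samples each compound's concentration is approximated with the
shape-preserving PCHIP interpolant; the time derivative at a sampling time
t_j is a centered finite difference of the interpolant (default half-step
0.1 h).  mu comes from an ordinary least-squares exponential fit — a line
through ln(biomass) over the window spanning the neighbouring samples.
Rate vectors are anchored at the original interior sampling times (the
centered slope is undefined at the first and last sample).

Because r_D ~ 1/c_1, vectors at very low biomass blow up; percentile
trimming (default 3rd/97th per dimension, pooled over all experiments)
removes them before clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .io import CultivationExperiment
from .registry import CompoundSpec, default_registry

__all__ = [
    "RateVector",
    "interpolate_concentration",
    "specific_rate",
    "growth_rate",
    "compute_rate_vectors",
    "compute_all_rate_vectors",
    "remove_outliers",
    "vectors_to_matrix",
    "vectors_to_frame",
    "frame_to_vectors",
]

logger = logging.getLogger(__name__)


@dataclass
class RateVector:
    """One phenotype observation anchored at time ``time`` of one experiment."""

    experiment_id: str
    time: float  # h
    mu: float  # 1/h
    rates: dict[int, float]  # dimension_index (>= 2) -> mmol/g/h, signed
    concentrations_at_t: dict[int, float]  # dimension_index -> concentration
    tags: dict[str, str] = field(default_factory=dict)
    cumulative_dims: frozenset[int] = frozenset()  # unusable for conc. binning

    def as_array(self, registry: Sequence[CompoundSpec]) -> np.ndarray:
        """Vector in registry dimension order: (mu, r_2, ..., r_m)."""
        out = [self.mu]
        for c in registry:
            if c.role == "biomass":
                continue
            out.append(self.rates.get(c.dimension_index, 0.0))
        return np.asarray(out, dtype=float)


def interpolate_concentration(
    times: Sequence[float], values: Sequence[float], query_times: Sequence[float]
) -> np.ndarray:
    """Shape-preserving (PCHIP) interpolation of one concentration series.

    Requires >= 2 strictly increasing knots; queries must lie inside the
    knot range.  The interpolant passes exactly through the knots and is
    monotone wherever the data are.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    q = np.asarray(query_times, dtype=float)
    if t.size < 2:
        raise ValueError("PCHIP interpolation needs at least 2 knots")
    if not np.all(np.diff(t) > 0):
        raise ValueError("knot times must be strictly increasing")
    if q.size and (q.min() < t[0] or q.max() > t[-1]):
        raise ValueError(
            f"query outside knot range [{t[0]}, {t[-1]}]: [{q.min()}, {q.max()}]"
        )
    return PchipInterpolator(t, v)(q)


def specific_rate(biomass_at_t: float, slope: float) -> float:
    """Biomass-specific rate: concentration slope divided by biomass.

    ``slope`` is in mmol/L/h, biomass in g/L; the result in mmol/g/h keeps
    the slope's sign (consumption negative).  Non-positive biomass leaves
    the rate undefined (the caller drops the vector).
    """
    if biomass_at_t <= 0:
        raise ValueError(f"specific rate undefined for biomass {biomass_at_t} <= 0")
    return slope / biomass_at_t


def growth_rate(
    times: Sequence[float], biomass: Sequence[float], t_query: float, window: float
) -> float:
    """Specific growth rate mu at ``t_query`` from an exponential fit.

    Ordinary least squares of ln(biomass) against time over the window
    ``[t_query - window/2, t_query + window/2]`` (raw sampling points with
    biomass > 0 only); the slope is mu and may be negative.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(biomass, dtype=float)
    half = window / 2.0
    sel = (t >= t_query - half) & (t <= t_query + half) & (x > 0)
    if sel.sum() < 2:
        raise ValueError(
            f"growth rate at t={t_query}: need >= 2 positive biomass points in window"
        )
    tw, lw = t[sel], np.log(x[sel])
    slope, _ = np.polyfit(tw, lw, 1)
    return float(slope)


def compute_rate_vectors(
    exp: CultivationExperiment,
    grid_step: float = 0.1,
    registry: Sequence[CompoundSpec] | None = None,
) -> list[RateVector]:
    """Phenotype vectors at the interior sampling times of one experiment.

    For each compound the slope at t_j is the centered difference
    ``(c(t_j + grid_step) - c(t_j - grid_step)) / (2 grid_step)`` on the
    PCHIP interpolant of that compound's measured points, divided by the
    interpolated biomass.  Cumulative (fed-batch) columns record consumed
    amount, so their slope is negated to the consumption convention and
    their concentration is flagged unusable for concentration binning.
    Experiments with < 3 samples yield an empty list.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    registry = list(registry) if registry is not None else default_registry()
    if exp.n_samples < 3:
        logger.warning("%s: < 3 samples, no rate vectors", exp.experiment_id)
        return []
    bm_t, bm_v = exp.series(1)
    if bm_t.size < 2 or not np.any(bm_v > 0):
        logger.warning("%s: unusable biomass series", exp.experiment_id)
        return []
    bm_interp = PchipInterpolator(bm_t, bm_v)

    interior = [j for j in range(1, exp.n_samples - 1)]
    out: list[RateVector] = []
    non_biomass = [c for c in registry if c.role != "biomass"]

    # per-compound interpolants over that compound's measured points
    interps: dict[int, PchipInterpolator] = {}
    ranges: dict[int, tuple[float, float]] = {}
    for c in non_biomass:
        ct, cv = exp.series(c.dimension_index)
        if ct.size >= 2:
            interps[c.dimension_index] = PchipInterpolator(ct, cv)
            ranges[c.dimension_index] = (float(ct[0]), float(ct[-1]))

    for j in interior:
        tj = exp.times[j]
        if tj < bm_t[0] or tj > bm_t[-1]:
            continue
        biomass_tj = float(bm_interp(tj))
        if biomass_tj <= 0:
            logger.info("%s t=%.3g h: dropped (biomass <= 0)", exp.experiment_id, tj)
            continue
        try:
            window = exp.times[j + 1] - exp.times[j - 1]
            mu = growth_rate(bm_t, bm_v, tj, window)
        except ValueError as err:
            logger.info("%s t=%.3g h: dropped (%s)", exp.experiment_id, tj, err)
            continue
        rates: dict[int, float] = {}
        conc_at_t: dict[int, float] = {1: biomass_tj}
        for c in non_biomass:
            d = c.dimension_index
            if d not in interps:
                rates[d] = 0.0
                continue
            lo, hi = ranges[d]
            if tj < lo or tj > hi:
                rates[d] = 0.0
                continue
            h = min(grid_step, (hi - lo) / 2.0)
            t_lo, t_hi = max(lo, tj - h), min(hi, tj + h)
            f = interps[d]
            slope = (float(f(t_hi)) - float(f(t_lo))) / (t_hi - t_lo)
            if d in exp.fed_batch_cumulative:
                # cumulative consumed amount: slope is a consumption magnitude
                rate = -slope / biomass_tj
            else:
                rate = slope / biomass_tj
            rates[d] = rate
            conc_at_t[d] = max(float(f(tj)), 0.0)
        out.append(
            RateVector(
                experiment_id=exp.experiment_id,
                time=float(tj),
                mu=mu,
                rates=rates,
                concentrations_at_t=conc_at_t,
                tags=dict(exp.tags),
                cumulative_dims=frozenset(exp.fed_batch_cumulative),
            )
        )
    return out


def compute_all_rate_vectors(
    experiments: Sequence[CultivationExperiment],
    grid_step: float = 0.1,
    registry: Sequence[CompoundSpec] | None = None,
) -> list[RateVector]:
    """Concatenate :func:`compute_rate_vectors` over many experiments."""
    vectors: list[RateVector] = []
    for exp in experiments:
        vectors.extend(compute_rate_vectors(exp, grid_step=grid_step, registry=registry))
    return vectors


def vectors_to_matrix(
    vectors: Sequence[RateVector], registry: Sequence[CompoundSpec] | None = None
) -> np.ndarray:
    """Stack rate vectors into an (n, m) matrix in registry dimension order."""
    registry = list(registry) if registry is not None else default_registry()
    return np.vstack([v.as_array(registry) for v in vectors])


def vectors_to_frame(
    vectors: Sequence[RateVector],
    registry: Sequence[CompoundSpec] | None = None,
    kept: Sequence[bool] | None = None,
):
    """Tabulate rate vectors for delimited-text export.

    Columns: experiment_id, time_h, mu, ``r_<abbrev>``, ``c_<abbrev>``
    (interpolated concentration at t; biomass as ``c_BM``), a
    semicolon-joined ``cumulative_dims`` column, and ``kept_flag`` when a
    trim mask is given.
    """
    import pandas as pd

    registry = list(registry) if registry is not None else default_registry()
    non_biomass = [c for c in registry if c.role != "biomass"]
    idx_to_ab = {c.dimension_index: c.abbreviation for c in non_biomass}
    rows = []
    for i, v in enumerate(vectors):
        row: dict[str, object] = {
            "experiment_id": v.experiment_id,
            "time_h": v.time,
            "mu": v.mu,
        }
        for c in non_biomass:
            row[f"r_{c.abbreviation}"] = v.rates.get(c.dimension_index, 0.0)
        if 1 in v.concentrations_at_t:
            row["c_BM"] = v.concentrations_at_t[1]
        for c in non_biomass:
            if c.dimension_index in v.concentrations_at_t:
                row[f"c_{c.abbreviation}"] = v.concentrations_at_t[c.dimension_index]
        row["cumulative_dims"] = ";".join(
            sorted(idx_to_ab[d] for d in v.cumulative_dims if d in idx_to_ab)
        )
        if kept is not None:
            row["kept_flag"] = bool(kept[i])
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_vectors(
    df,
    registry: Sequence[CompoundSpec] | None = None,
    tags: dict[str, dict[str, str]] | None = None,
) -> list[RateVector]:
    """Rebuild rate vectors from a :func:`vectors_to_frame` table."""
    registry = list(registry) if registry is not None else default_registry()
    non_biomass = [c for c in registry if c.role != "biomass"]
    ab_to_idx = {c.abbreviation: c.dimension_index for c in non_biomass}
    out = []
    for _, row in df.iterrows():
        rates = {
            ab_to_idx[c.abbreviation]: float(row[f"r_{c.abbreviation}"])
            for c in non_biomass
            if f"r_{c.abbreviation}" in row and not _isnan(row[f"r_{c.abbreviation}"])
        }
        conc: dict[int, float] = {}
        if "c_BM" in row and not _isnan(row["c_BM"]):
            conc[1] = float(row["c_BM"])
        for c in non_biomass:
            col = f"c_{c.abbreviation}"
            if col in row and not _isnan(row[col]):
                conc[c.dimension_index] = float(row[col])
        cum_raw = row.get("cumulative_dims", "")
        cum = frozenset(
            ab_to_idx[a] for a in str(cum_raw).split(";") if a and a in ab_to_idx
        ) if not _isnan(cum_raw) else frozenset()
        exp_id = str(row["experiment_id"])
        out.append(
            RateVector(
                experiment_id=exp_id,
                time=float(row["time_h"]),
                mu=float(row["mu"]),
                rates=rates,
                concentrations_at_t=conc,
                tags=dict((tags or {}).get(exp_id, {})),
                cumulative_dims=cum,
            )
        )
    return out


def _isnan(x) -> bool:
    try:
        return bool(np.isnan(x))
    except TypeError:
        return False


def remove_outliers(
    vectors: Sequence[RateVector],
    lower_pct: float = 3.0,
    upper_pct: float = 97.0,
    registry: Sequence[CompoundSpec] | None = None,
) -> tuple[list[RateVector], list[RateVector]]:
    """Percentile trimming per dimension, pooled over all experiments.

    For every dimension (mu and each r_D) the empirical ``lower_pct`` and
    ``upper_pct`` percentiles (linear interpolation between order
    statistics) are computed over all vectors; a vector is removed when any
    of its dimensions falls strictly outside its band.  Returns
    ``(kept, removed)``, both in input order.
    """
    if not 0 <= lower_pct < upper_pct <= 100:
        raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
    if len(vectors) == 0:
        raise ValueError("remove_outliers: empty input")
    registry = list(registry) if registry is not None else default_registry()
    X = vectors_to_matrix(vectors, registry)
    lo = np.percentile(X, lower_pct, axis=0)
    hi = np.percentile(X, upper_pct, axis=0)
    outside = (X < lo) | (X > hi)
    kept, removed = [], []
    for v, bad in zip(vectors, outside.any(axis=1)):
        if bad:
            logger.info("%s t=%.3g h: percentile trim", v.experiment_id, v.time)
            removed.append(v)
        else:
            kept.append(v)
    return kept, removed
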