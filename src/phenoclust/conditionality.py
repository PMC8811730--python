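"""Conditionality of cluster prevalence: the log-deviation statistic.

For a cluster CL and a condition ``cond`` (a categorical tag value, or a
concentration range a sample falls in), the statistic

    delta = log10[ (n_CL,cond / n_CL) / (n_cond / n) ]

compares the condition's share inside the cluster with its share in the
whole population.  delta > 0 means the condition is over-represented in the
cluster, delta < 0 under-represented, and it is undefined (reported, never
dropped) whenever any of the four counts is zero.  The statistic is
descriptive: it flags candidate conditionalities, it does not test them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cluster import NOISE, ClusterModel
from .rates import RateVector
from .registry import CompoundSpec, default_registry

__all__ = ["ConditionalityResult", "bin_concentration", "log_deviation"]

#: concentration pooling steps [mmol/L] for substrate/metabolite ranges
ALLOWED_STEPS = (1, 5, 10, 20, 50, 100)

#: default biomass binning step [g/L]
DEFAULT_BIOMASS_STEP = 0.05


@dataclass
class ConditionalityResult:
    cluster: int
    condition: str
    bin_label: str
    n_cluster_cond: int
    n_cluster: int
    n_total_cond: int
    n_total: int
    delta: float | None  # None = undefined (a zero count)


def bin_concentration(
    values: Sequence[float], step: float, enforce_allowed: bool = True
) -> list[str]:
    """Pool concentrations into left-closed half-open ranges ``[a, a+step)``.

    ``a = floor(value / step) * step``.  For substrate/metabolite
    concentrations the step must come from the allowed set
    (1, 5, 10, 20, 50, 100 mmol/L); biomass uses free (g/L) steps via
    ``enforce_allowed=False``.
    """
    if enforce_allowed and step not in ALLOWED_STEPS:
        raise ValueError(f"step {step} not in allowed set {ALLOWED_STEPS}")
    if step <= 0:
        raise ValueError("step must be positive")
    labels = []
    for v in values:
        if v < 0:
            raise ValueError(f"negative concentration {v}")
        a = math.floor(v / step) * step
        a = round(a, 10)
        labels.append(f"[{_fmt(a)}, {_fmt(round(a + step, 10))})")
    return labels


def _fmt(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:g}"


def log_deviation(
    model: ClusterModel,
    vectors: Sequence[RateVector],
    condition: str | tuple[str, float],
    registry: Sequence[CompoundSpec] | None = None,
    biomass_step: float = DEFAULT_BIOMASS_STEP,
) -> list[ConditionalityResult]:
    """Per-(cluster, bin) log10 deviation of condition prevalence.

    ``condition`` is either a tag name (categorical; bins are the tag
    values) or an ``(abbreviation, step)`` pair binning the interpolated
    concentration of that compound at each vector's time point.  Vectors
    whose column for that compound is fed-batch cumulative are excluded
    from numerator *and* denominator (their "concentration" is a consumed
    amount, not a broth concentration), as are DBSCAN noise vectors.
    """
    registry = list(registry) if registry is not None else default_registry()
    assign = model.assignments()
    labels = []
    for v in vectors:
        key = (v.experiment_id, v.time)
        if key not in assign:
            raise ValueError(f"vector {key} not covered by the cluster model")
        labels.append(assign[key])

    if isinstance(condition, tuple):
        abbrev, step = condition
        comp = {c.abbreviation: c for c in registry}.get(abbrev)
        if comp is None:
            raise ValueError(f"unknown compound {abbrev!r}")
        d = comp.dimension_index
        pop, pop_labels = [], []
        for v, lab in zip(vectors, labels):
            if lab == NOISE or d in v.cumulative_dims:
                continue
            if d not in v.concentrations_at_t:
                continue
            pop.append(v.concentrations_at_t[d])
            pop_labels.append(lab)
        enforce = comp.role != "biomass"
        if comp.role == "biomass" and step == DEFAULT_BIOMASS_STEP:
            step = biomass_step
        bins = bin_concentration(pop, step, enforce_allowed=enforce)
        cond_name = f"{abbrev} concentration ({_fmt(step)} steps)"
    else:
        bins, pop_labels = [], []
        for v, lab in zip(vectors, labels):
            if lab == NOISE:
                continue
            if condition not in v.tags:
                raise ValueError(f"unknown condition name {condition!r}")
            bins.append(v.tags[condition])
            pop_labels.append(lab)
        cond_name = condition

    n_total = len(pop_labels)
    clusters = sorted({lab for lab in pop_labels})
    bin_values = sorted(set(bins))
    results: list[ConditionalityResult] = []
    for cl in clusters:
        n_cluster = sum(1 for lab in pop_labels if lab == cl)
        for b in bin_values:
            n_total_cond = sum(1 for x in bins if x == b)
            n_cluster_cond = sum(
                1 for lab, x in zip(pop_labels, bins) if lab == cl and x == b
            )
            if min(n_cluster_cond, n_cluster, n_total_cond, n_total) > 0:
                delta = math.log10(
                    (n_cluster_cond / n_cluster) / (n_total_cond / n_total)
                )
            else:
                delta = None
            results.append(
                ConditionalityResult(
                    cluster=cl,
                    condition=cond_name,
                    bin_label=b,
                    n_cluster_cond=n_cluster_cond,
                    n_cluster=n_cluster,
                    n_total_cond=n_total_cond,
                    n_total=n_total,
                    delta=delta,
                )
            )
    return results


def results_to_frame(results: Sequence[ConditionalityResult]) -> pd.DataFrame:
    """Tabulate conditionality results ('undefined' for zero-count bins)."""
    return pd.DataFrame(
        [
            {
                "cluster": r.cluster,
                "condition": r.condition,
                "bin": r.bin_label,
                "n_cluster_cond": r.n_cluster_cond,
                "n_cluster": r.n_cluster,
                "n_total_cond": r.n_total_cond,
                "n_total": r.n_total,
                "delta": "undefined" if r.delta is None else r.delta,
            }
            for r in results
        ]
    )
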