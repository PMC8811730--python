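"""Carbon and ATP balancing of reference phenotypes.

Each cluster's reference phenotype zeta (raw-space median rate vector) can
be checked against elementary stoichiometry:

*Carbon recovery* — the percentage of consumed substrate carbon accounted
for by biomass, measured products and the theoretical CO2 release of the
pyruvate-decarboxylating product pathways:

    R_C = 100 * [ n_C^BM * zeta_mu * 1000 / M_BM
                  + sum_products n_C^D * zeta_D + r_CO2 ]
              / sum_substrates n_C^D * |zeta_D|

with r_CO2 = zeta_EtOH + zeta_AcAc + 2 zeta_BuOH + b zeta_BuAc - zeta_FoAc
(mmol/g/h).  One mol CO2 is released per pyruvate decarboxylation: one per
ethanol or acetate, two per butanol; formate consumes a would-be CO2.  The
butyrate coefficient b defaults to 2 (butyrate condenses two acetyl-CoA,
i.e. two decarboxylations) but may be set to 1.

*ATP balance* — assuming ATP comes only from substrate-level
phosphorylation, the specific ATP production rate of a cluster is
``q_ATP = sum_D s_ATP/D * zeta_D`` and across clusters should follow

    q_ATP = (1 / Y_BM/ATP) * mu + q_ATP^m

with Y_BM/ATP the ATP-specific biomass yield [g/mol] and q_ATP^m the
growth-independent maintenance demand [mmol/g/h].  Both are estimated by
unweighted ordinary least squares over the clusters whose carbon recovery
is within a threshold (default 19 percentage points) of 100 %; clusters
outside the band, or with no measurable substrate uptake, are excluded and
reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .registry import CompoundSpec, default_registry

__all__ = [
    "co2_rate",
    "carbon_recovery",
    "atp_rate",
    "fit_atp_regression",
    "BalanceResult",
]

logger = logging.getLogger(__name__)

BIOMASS_G_PER_MMOL = 1000.0  # g -> mmol conversion in the biomass carbon term


def _get(centroid: dict[str, float], key: str) -> float:
    return float(centroid.get(key, 0.0))


def co2_rate(centroid: dict[str, float], buac_co2: float = 2.0) -> float:
    """Theoretical specific CO2 production rate of a reference phenotype.

    ``centroid`` maps dimension labels (mu plus compound abbreviations) to
    raw rates [mmol/g/h].  ``buac_co2`` is the CO2 stoichiometry per
    butyrate (2 by default, 1 as the alternative convention).
    """
    return (
        _get(centroid, "EtOH")
        + _get(centroid, "AcAc")
        + 2.0 * _get(centroid, "BuOH")
        + buac_co2 * _get(centroid, "BuAc")
        - _get(centroid, "FoAc")
    )


def carbon_recovery(
    centroid: dict[str, float],
    registry: Sequence[CompoundSpec] | None = None,
    buac_co2: float = 2.0,
) -> float | None:
    """Carbon recovery R_C [%] of a reference phenotype.

    Returns ``None`` when no substrate is consumed (denominator zero): the
    phenotype has an unidentified carbon intake and cannot be balanced.
    Product rates that are negative (net consumption of a "product") are
    kept signed.  A net-*produced* substrate contributes nothing to the
    denominator (warned).
    """
    registry = list(registry) if registry is not None else default_registry()
    biomass = next(c for c in registry if c.role == "biomass")
    mu = _get(centroid, "mu")
    numerator = biomass.n_carbons * mu * BIOMASS_G_PER_MMOL / biomass.molar_mass
    denominator = 0.0
    for c in registry:
        if c.role == "biomass":
            continue
        zeta = _get(centroid, c.abbreviation)
        if c.role == "substrate":
            if zeta > 0:
                logger.warning(
                    "substrate %s has positive (production) rate %.3g; "
                    "excluded from the recovery denominator", c.abbreviation, zeta
                )
            else:
                denominator += c.n_carbons * abs(zeta)
        else:
            numerator += c.n_carbons * zeta
    numerator += co2_rate(centroid, buac_co2=buac_co2)
    if denominator <= 0:
        return None
    return 100.0 * numerator / denominator


def atp_rate(
    centroid: dict[str, float], registry: Sequence[CompoundSpec] | None = None
) -> float:
    """Specific ATP production rate from substrate-level phosphorylation.

    ``sum_D s_ATP/D * zeta_D`` over products with a defined stoichiometry;
    products with undefined stoichiometry contribute zero (logged).
    """
    registry = list(registry) if registry is not None else default_registry()
    total = 0.0
    for c in registry:
        if c.role != "product":
            continue
        zeta = _get(centroid, c.abbreviation)
        if not c.has_atp_stoich:
            if zeta != 0:
                logger.info(
                    "%s has no defined ATP stoichiometry; contributes 0 to q_ATP",
                    c.abbreviation,
                )
            continue
        total += float(c.atp_stoich) * zeta
    return total


@dataclass
class BalanceResult:
    """Per-cluster balances plus the across-cluster ATP regression."""

    clusters: list[int]
    r_co2: dict[int, float]
    carbon_recovery: dict[int, float | None]
    q_atp: dict[int, float]
    included: dict[int, bool]
    slope: float | None = None
    slope_se: float | None = None
    intercept: float | None = None  # q_ATP^m
    intercept_se: float | None = None
    yield_bm_atp: float | None = None  # Y_BM/ATP = 1/slope [g/mol]
    yield_se: float | None = None  # delta-method SE
    slope_ci95: tuple[float, float] | None = None  # t-based OLS slope CI
    yield_ci95: tuple[float, float] | None = None  # bounded Fieller-type CI
    yield_ci_unbounded: bool = False  # slope CI crosses zero: CI is two rays
    residuals: dict[int, float] = field(default_factory=dict)
    confidence_band: pd.DataFrame | None = None  # pointwise 95 % band vs mu
    physical: bool = True
    recovery_threshold: float = 19.0
    buac_co2: float = 2.0

    def yield_ci_contains(self, value: float) -> bool:
        """Whether ``value`` lies in the 95 % confidence set for Y_BM/ATP.

        The set is the inverse image of the t-based slope CI under
        ``Y = 1/slope`` (Fieller-type), so membership is equivalent to
        ``1/value`` lying in the slope CI.  When the slope CI crosses zero
        the set is unbounded (two rays), reflecting that the yield is then
        weakly identified.
        """
        if self.slope_ci95 is None or value == 0:
            return False
        lo, hi = self.slope_ci95
        return lo <= 1.0 / value <= hi

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cl in self.clusters:
            rc = self.carbon_recovery[cl]
            rows.append(
                {
                    "cluster": cl,
                    "r_CO2": self.r_co2[cl],
                    "carbon_recovery_pct": "not computable" if rc is None else rc,
                    "q_ATP": self.q_atp[cl],
                    "included_in_fit": self.included[cl],
                    "residual": self.residuals.get(cl, ""),
                }
            )
        return pd.DataFrame(rows)


def fit_atp_regression(
    centroids: Sequence[dict[str, float]],
    registry: Sequence[CompoundSpec] | None = None,
    recovery_threshold: float = 19.0,
    buac_co2: float = 2.0,
) -> BalanceResult:
    """Estimate Y_BM/ATP and q_ATP^m across reference phenotypes.

    ``centroids`` are the clusters' raw centroid mappings (cluster c is
    ``centroids[c-1]``).  A cluster enters the unweighted OLS fit of
    q_ATP against mu only if its carbon recovery is computable and within
    ``recovery_threshold`` percentage points of 100 %.  The yield is the
    reciprocal slope with a delta-method standard error; its 95 % CI is
    the reciprocal image of the t-based slope CI (exact under monotonicity,
    unbounded when the slope CI crosses zero).  A non-positive slope is
    reported as not physical.
    """
    registry = list(registry) if registry is not None else default_registry()
    clusters = list(range(1, len(centroids) + 1))
    r_co2 = {cl: co2_rate(centroids[cl - 1], buac_co2=buac_co2) for cl in clusters}
    rc = {
        cl: carbon_recovery(centroids[cl - 1], registry, buac_co2=buac_co2)
        for cl in clusters
    }
    q = {cl: atp_rate(centroids[cl - 1], registry) for cl in clusters}
    included = {
        cl: rc[cl] is not None and abs(rc[cl] - 100.0) <= recovery_threshold
        for cl in clusters
    }
    result = BalanceResult(
        clusters=clusters,
        r_co2=r_co2,
        carbon_recovery=rc,
        q_atp=q,
        included=included,
        recovery_threshold=recovery_threshold,
        buac_co2=buac_co2,
    )
    fit_clusters = [cl for cl in clusters if included[cl]]
    if len(fit_clusters) < 3:
        raise ValueError(
            f"ATP regression needs >= 3 clusters within the carbon-recovery "
            f"band; got {len(fit_clusters)}"
        )
    mu = np.array([_get(centroids[cl - 1], "mu") for cl in fit_clusters])
    y = np.array([q[cl] for cl in fit_clusters])
    X = sm.add_constant(mu)
    ols = sm.OLS(y, X).fit()
    intercept, slope = ols.params
    intercept_se, slope_se = ols.bse
    result.slope = float(slope)
    result.slope_se = float(slope_se)
    result.intercept = float(intercept)
    result.intercept_se = float(intercept_se)
    result.residuals = {cl: float(r) for cl, r in zip(fit_clusters, ols.resid)}

    ci_lo, ci_hi = (float(v) for v in np.asarray(ols.conf_int())[1])
    result.slope_ci95 = (ci_lo, ci_hi)
    if slope <= 0:
        result.physical = False
        result.yield_bm_atp = None
        logger.warning(
            "ATP regression slope %.3g <= 0: Y_BM/ATP not physical "
            "(diagnostics: R2=%.3g, n=%d)", slope, ols.rsquared, len(fit_clusters)
        )
    else:
        result.yield_bm_atp = float(1.0 / slope)
        result.yield_se = float(slope_se / slope**2)
    if ci_lo > 0 or ci_hi < 0:
        # slope CI excludes zero: the yield CI is a bounded interval
        result.yield_ci95 = tuple(sorted((1.0 / ci_lo, 1.0 / ci_hi)))
    else:
        result.yield_ci_unbounded = True
        logger.info(
            "slope CI crosses zero: Y_BM/ATP confidence set is unbounded "
            "((-inf, %.3g] union [%.3g, inf))", 1.0 / ci_lo if ci_lo else -math.inf,
            1.0 / ci_hi if ci_hi else math.inf,
        )

    # pointwise 95 % confidence band of the fitted line over the mu range
    grid = np.linspace(float(mu.min()), float(mu.max()), 50)
    pred = ols.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    result.confidence_band = pd.DataFrame(
        {
            "mu": grid,
            "fit": pred["mean"].to_numpy(),
            "ci_lower": pred["mean_ci_lower"].to_numpy(),
            "ci_upper": pred["mean_ci_upper"].to_numpy(),
        }
    )
    return result
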