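"""Synthetic multi-experiment fermentation datasets with planted phenotypes.

The generator inverts the rate definitions: given a planted phenotype
(archetype) with growth rate mu and biomass-specific rates r_D, the broth
obeys

    dc_1/dt = mu * c_1            (biomass, g/L)
    dc_D/dt = r_D * c_1           (compounds, mmol/L)

which is integrated with classical RK4 (step <= 0.01 h) under a schedule of
piecewise-constant (optionally blended) archetypes, sampled at configured
times, and corrupted with multiplicative lognormal measurement noise —
mimicking the scale-proportional error of HPLC/OD measurements while
keeping concentrations non-negative.  If a substrate would be driven below
zero, it is exhausted: all rates switch to zero from that moment (logged).

Planted archetypes are built carbon-closed: the substrate uptake is solved
from the product slate plus the theoretical CO2 release, so the true carbon
recovery is exactly 100 %.  The default library holds five archetypes
spanning the solventogenic/acidogenic spectrum of a glycerol/glucose
clostridial fermentation.  Ground truth (planted mu and rates per sampling
time, plus an archetype label) is emitted alongside for closed-loop
scoring; a sampling point whose centered-difference stencil straddles an
archetype switch is labelled ``mixed`` since no single archetype is true
there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .balancing import co2_rate
from .io import CultivationExperiment
from .registry import CompoundSpec, default_registry

__all__ = [
    "Archetype",
    "SimulationConfig",
    "carbon_closed_archetype",
    "default_archetype_library",
    "simulate_experiment",
    "generate_dataset",
    "truth_labels_for",
    "truth_rate_errors",
]

logger = logging.getLogger(__name__)

RK4_STEP = 0.01  # h


@dataclass(frozen=True)
class Archetype:
    """A planted phenotype: growth rate plus biomass-specific rates."""

    name: str
    mu: float  # 1/h
    rates: Mapping[str, float]  # abbreviation -> mmol/g/h, consumption < 0
    carbon_closed: bool = False

    def as_centroid(self) -> dict[str, float]:
        out = {"mu": self.mu}
        out.update({k: float(v) for k, v in self.rates.items()})
        return out


def carbon_closed_archetype(
    name: str,
    mu: float,
    products: Mapping[str, float],
    substrate: str = "Gly",
    registry: Sequence[CompoundSpec] | None = None,
    buac_co2: float = 2.0,
) -> Archetype:
    """Build an archetype whose substrate uptake closes the carbon balance.

    The consumption rate of ``substrate`` is solved so that biomass carbon
    + product carbon + theoretical CO2 equals substrate carbon exactly
    (true carbon recovery 100 %).
    """
    registry = list(registry) if registry is not None else default_registry()
    by_abbrev = {c.abbreviation: c for c in registry}
    biomass = next(c for c in registry if c.role == "biomass")
    centroid = {"mu": mu, **{k: float(v) for k, v in products.items()}}
    carbon = biomass.n_carbons * mu * 1000.0 / biomass.molar_mass
    for abbrev, rate in products.items():
        carbon += by_abbrev[abbrev].n_carbons * rate
    carbon += co2_rate(centroid, buac_co2=buac_co2)
    sub = by_abbrev[substrate]
    if sub.role != "substrate":
        raise ValueError(f"{substrate} is not a registry substrate")
    uptake = carbon / sub.n_carbons
    rates = dict(products)
    rates[substrate] = -uptake
    return Archetype(name=name, mu=mu, rates=rates, carbon_closed=True)


def default_archetype_library(
    registry: Sequence[CompoundSpec] | None = None,
) -> list[Archetype]:
    """Five carbon-closed archetypes spanning solvento-/acidogenesis."""
    return [
        carbon_closed_archetype(
            "pdo_acetate", 0.10, {"PDO": 6.0, "AcAc": 2.0}, "Gly", registry
        ),
        carbon_closed_archetype(
            "butanol_solvent", 0.17,
            {"BuOH": 5.2, "PDO": 1.0, "AcAc": 0.8, "BuAc": 0.6}, "Gly", registry,
        ),
        carbon_closed_archetype(
            "acidogenic", 0.25,
            {"AcAc": 4.0, "BuAc": 3.0, "FoAc": 1.5, "LaAc": 1.0, "OBuAc": 0.4},
            "Gly", registry,
        ),
        carbon_closed_archetype(
            "glucose_mixed", 0.12,
            {"EtOH": 3.0, "AcAc": 2.5, "LaAc": 2.0, "BuAc": 1.0}, "Glc", registry,
        ),
        carbon_closed_archetype(
            "dormant", 0.01, {"PDO": 0.5, "AcAc": 0.3}, "Gly", registry
        ),
    ]


@dataclass
class SimulationConfig:
    """Everything needed to simulate one cultivation.

    ``schedule`` is a list of contiguous, non-overlapping
    ``(start_h, end_h, {archetype_name: blend_weight})`` segments covering
    the sampling span.  ``noise_sigma`` is the lognormal sigma of the
    multiplicative measurement noise (scalar, or per-abbreviation map with
    'BM' for biomass).
    """

    experiment_id: str
    schedule: list[tuple[float, float, dict[str, float]]]
    initial_concentrations: dict[str, float]  # 'BM' g/L, others mmol/L
    sampling_times: list[float]
    noise_sigma: float | dict[str, float] = 0.0
    seed: int | None = None
    tags: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.initial_concentrations.get("BM", 0.0) <= 0:
            raise ValueError("initial biomass must be positive")
        segs = sorted(self.schedule)
        for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
            if not np.isclose(e1, s2):
                raise ValueError("schedule segments must be contiguous")
        for s, e, _ in segs:
            if e <= s:
                raise ValueError("schedule segment with non-positive length")
        sigmas = (
            self.noise_sigma.values()
            if isinstance(self.noise_sigma, dict)
            else [self.noise_sigma]
        )
        if any(s < 0 for s in sigmas):
            raise ValueError("noise sigma must be >= 0")


def _blend(
    weights: Mapping[str, float], library: Mapping[str, Archetype]
) -> tuple[float, dict[str, float]]:
    total = sum(weights.values())
    mu = 0.0
    rates: dict[str, float] = {}
    for name, w in weights.items():
        arch = library[name]
        mu += w / total * arch.mu
        for k, v in arch.rates.items():
            rates[k] = rates.get(k, 0.0) + w / total * v
    return mu, rates


def simulate_experiment(
    config: SimulationConfig,
    library: Sequence[Archetype] | None = None,
    registry: Sequence[CompoundSpec] | None = None,
) -> tuple[CultivationExperiment, pd.DataFrame]:
    """Integrate the planted dynamics and sample them with noise.

    Returns the noisy :class:`CultivationExperiment` plus a ground-truth
    table with one row per sampling time: planted mu, planted rates
    (``r_<abbrev>``), the archetype ``label`` (``mixed`` when the centered
    stencil spans a switch or an exhaustion event) and ``exhausted``.
    """
    config.validate()
    registry = list(registry) if registry is not None else default_registry()
    lib = {a.name: a for a in (library or default_archetype_library(registry))}
    abbrevs = [c.abbreviation for c in registry if c.role != "biomass"]
    substrates = {c.abbreviation for c in registry if c.role == "substrate"}

    schedule = sorted(config.schedule)
    t_samples = sorted(float(t) for t in config.sampling_times)
    t0, t_end = schedule[0][0], schedule[-1][1]
    if t_samples[0] < t0 or t_samples[-1] > t_end:
        raise ValueError("sampling times outside the scheduled span")

    # integration grid: fine steps hitting every sample and segment boundary
    knots = sorted(
        set(np.round(np.arange(t0, t_end + RK4_STEP / 2, RK4_STEP), 9))
        | set(t_samples)
        | {s for s, _, _ in schedule}
        | {t_end}
    )

    state = {"BM": float(config.initial_concentrations.get("BM", 0.1))}
    for ab in abbrevs:
        state[ab] = float(config.initial_concentrations.get(ab, 0.0))

    def seg_rates(t: float) -> tuple[float, dict[str, float]]:
        for s, e, weights in schedule:
            if s <= t < e or (t == t_end and e == t_end):
                return _blend(weights, lib)
        raise ValueError(f"time {t} not covered by schedule")

    def deriv(c: dict[str, float], mu: float, rates: dict[str, float]):
        d = {"BM": mu * c["BM"]}
        for ab in abbrevs:
            d[ab] = rates.get(ab, 0.0) * c["BM"]
        return d

    exhausted_at: float | None = None
    samples: list[dict[str, float]] = []
    truth_rows: list[dict[str, object]] = []
    sample_iter = iter(t_samples)
    next_sample = next(sample_iter)

    def record(t: float) -> None:
        nonlocal next_sample
        samples.append({"t": t, **{k: max(v, 0.0) for k, v in state.items()}})

    t = knots[0]
    if np.isclose(next_sample, t):
        record(t)
        next_sample = next(sample_iter, None)
    for t_next in knots[1:]:
        h = t_next - t
        if h <= 0:
            continue
        if exhausted_at is None:
            mu, rates = seg_rates(t)
            c = dict(state)
            k1 = deriv(c, mu, rates)
            c2 = {k: c[k] + h / 2 * k1[k] for k in c}
            k2 = deriv(c2, mu, rates)
            c3 = {k: c[k] + h / 2 * k2[k] for k in c}
            k3 = deriv(c3, mu, rates)
            c4 = {k: c[k] + h * k3[k] for k in c}
            k4 = deriv(c4, mu, rates)
            for k in state:
                state[k] = c[k] + h / 6 * (k1[k] + 2 * k2[k] + 2 * k3[k] + k4[k])
            neg = [ab for ab in abbrevs if state[ab] < 0]
            if neg:
                exhausted_at = t_next
                for ab in neg:
                    state[ab] = 0.0
                logger.info(
                    "%s: substrate exhaustion at t=%.3g h (%s); rates set to 0",
                    config.experiment_id, t_next, ",".join(neg),
                )
        t = t_next
        if next_sample is not None and np.isclose(t, next_sample):
            record(t)
            next_sample = next(sample_iter, None)

    # ground truth labels at sampling times
    def segment_of(t_: float) -> tuple[float, float, dict[str, float]]:
        for s, e, w in schedule:
            if s <= t_ < e or (t_ == t_end and e == t_end):
                return s, e, w
        raise ValueError(t_)

    for j, tj in enumerate(t_samples):
        if exhausted_at is not None and tj >= exhausted_at:
            mu_true, rates_true = 0.0, {}
        else:
            mu_true, rates_true = seg_rates(tj)
        s, e, w = segment_of(tj)
        pure = len(w) == 1
        lo = t_samples[j - 1] if j > 0 else tj
        hi = t_samples[j + 1] if j + 1 < len(t_samples) else tj
        stencil_inside = s <= lo and hi <= e
        if exhausted_at is not None and hi >= exhausted_at:
            stencil_inside = False
        label = next(iter(w)) if (pure and stencil_inside) else "mixed"
        if exhausted_at is not None and tj >= exhausted_at:
            label = "mixed"
        row: dict[str, object] = {
            "experiment_id": config.experiment_id,
            "time_h": tj,
            "label": label,
            "mu_true": mu_true,
            "exhausted": exhausted_at is not None and tj >= exhausted_at,
        }
        for ab in abbrevs:
            row[f"r_{ab}"] = rates_true.get(ab, 0.0)
        truth_rows.append(row)

    # sample with multiplicative lognormal noise
    rng = np.random.default_rng(config.seed)
    by_abbrev = {c.abbreviation: c.dimension_index for c in registry}
    by_abbrev["BM"] = 1

    def sigma_of(ab: str) -> float:
        if isinstance(config.noise_sigma, dict):
            return float(config.noise_sigma.get(ab, 0.0))
        return float(config.noise_sigma)

    times, conc_rows = [], []
    for s_row in samples:
        times.append(s_row["t"])
        conc: dict[int, float] = {}
        for ab, d in by_abbrev.items():
            v = s_row[ab]
            sig = sigma_of(ab)
            if sig > 0:
                v = v * float(np.exp(rng.normal(0.0, sig)))
            conc[d] = max(v, 0.0)
        conc_rows.append(conc)

    exp = CultivationExperiment(
        experiment_id=config.experiment_id,
        times=times,
        concentrations=conc_rows,
        tags=dict(config.tags),
    )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["exhausted_at"] = exhausted_at
    return exp, truth


# --------------------------------------------------------------------------
# dataset generation

#: archetype whose presence is tied to the BES tag in the default design
BES_ARCHETYPE = "butanol_solvent"


def generate_dataset(
    n_experiments: int,
    library: Sequence[Archetype] | None = None,
    seed: int = 0,
    noise_sigma: float = 0.02,
    n_samples_range: tuple[int, int] = (4, 15),
    switch_fraction: float = 0.4,
    registry: Sequence[CompoundSpec] | None = None,
) -> tuple[list[CultivationExperiment], pd.DataFrame]:
    """Generate a multi-experiment dataset with planted archetypes.

    Experiments vary in schedule (a ``switch_fraction`` share carries one
    mid-run archetype switch), initial concentrations, sampling density and
    duration; runs are truncated shortly before substrate exhaustion, as a
    real batch campaign ends at depletion.  Condition tags correlate with
    the planted archetypes (the butanol archetype only occurs in BES-tagged
    experiments) so conditionality recovery can be exercised.  Returns the
    experiments plus the pooled ground-truth table.
    """
    registry = list(registry) if registry is not None else default_registry()
    library = list(library) if library is not None else default_archetype_library(registry)
    if len(library) < 2:
        raise ValueError("need at least 2 archetypes")
    rng = np.random.default_rng(seed)
    names = [a.name for a in library]
    experiments: list[CultivationExperiment] = []
    truths: list[pd.DataFrame] = []

    for i in range(n_experiments):
        if rng.uniform() < switch_fraction:
            first, second = rng.choice(len(names), size=2, replace=False)
            picks = [names[first], names[second]]
        else:
            picks = [names[rng.integers(len(names))]]
        n_samples = int(rng.integers(n_samples_range[0], n_samples_range[1] + 1))
        duration = float(rng.uniform(8.0, 16.0))

        init = {"BM": float(rng.uniform(0.05, 0.15))}
        uses = {ab for nm in picks for ab in library[names.index(nm)].rates}
        if "Gly" in uses:
            init["Gly"] = float(rng.uniform(250.0, 600.0))
        if "Glc" in uses:
            init["Glc"] = float(rng.uniform(100.0, 200.0))

        def build(dur: float) -> SimulationConfig:
            base = np.linspace(0.0, dur, n_samples)
            dt = dur / (n_samples - 1)
            jitter = rng.uniform(-0.2, 0.2, size=n_samples) * dt
            jitter[0] = jitter[-1] = 0.0
            t_s = np.round(np.sort(np.clip(base + jitter, 0.0, dur)) / RK4_STEP) * RK4_STEP
            t_s = np.unique(np.round(t_s, 9))
            end = float(t_s[-1])
            if len(picks) == 2:
                t_switch = float(rng.uniform(0.4, 0.6)) * end
                schedule = [
                    (0.0, t_switch, {picks[0]: 1.0}),
                    (t_switch, end, {picks[1]: 1.0}),
                ]
            else:
                schedule = [(0.0, end, {picks[0]: 1.0})]
            return SimulationConfig(
                experiment_id=f"synth_{i + 1:03d}",
                schedule=schedule,
                initial_concentrations=dict(init),
                sampling_times=list(t_s),
                noise_sigma=noise_sigma,
                seed=int(rng.integers(2**31)),
                tags={
                    "vessel": str(rng.choice(["reactor", "bottle"])),
                    "BES": "yes" if BES_ARCHETYPE in picks else "no",
                    "FeSO4_mgL": str(rng.choice(["0", "10", "100"])),
                },
            )

        # dry run without noise to find the exhaustion time, then truncate
        cfg = build(duration)
        probe = SimulationConfig(
            experiment_id=cfg.experiment_id,
            schedule=cfg.schedule,
            initial_concentrations=cfg.initial_concentrations,
            sampling_times=cfg.sampling_times,
            noise_sigma=0.0,
            seed=0,
            tags=cfg.tags,
        )
        _, probe_truth = simulate_experiment(probe, library, registry)
        if probe_truth.attrs.get("exhausted_at") is not None:
            duration = max(0.9 * float(probe_truth.attrs["exhausted_at"]), 2.0)
            cfg = build(duration)

        exp, truth = simulate_experiment(cfg, library, registry)
        experiments.append(exp)
        truths.append(truth)

    truth_df = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(
            columns=["experiment_id", "time_h", "label", "mu_true", "exhausted"]
        )
    )
    return experiments, truth_df


# --------------------------------------------------------------------------
# closed-loop scoring against ground truth

def truth_labels_for(vectors, truth: pd.DataFrame) -> list[str]:
    """Planted archetype label for each rate vector (may be ``mixed``)."""
    tr = truth.set_index(["experiment_id", "time_h"])
    return [str(tr.loc[(v.experiment_id, v.time), "label"]) for v in vectors]


def truth_rate_errors(
    vectors,
    truth: pd.DataFrame,
    registry: Sequence[CompoundSpec] | None = None,
) -> pd.DataFrame:
    """Entrywise relative recovery errors against the planted rates.

    One row per (pure-labelled vector, dimension with nonzero planted
    rate): columns ``archetype``, ``dimension``, ``planted``, ``recovered``,
    ``rel_err``.  Mixed-labelled points (stencil spanning a switch or an
    exhaustion) have no single true phenotype and are skipped.
    """
    registry = list(registry) if registry is not None else default_registry()
    tr = truth.set_index(["experiment_id", "time_h"])
    non_biomass = [c for c in registry if c.role != "biomass"]
    rows = []
    for v in vectors:
        rec = tr.loc[(v.experiment_id, v.time)]
        if rec["label"] == "mixed":
            continue
        planted_mu = float(rec["mu_true"])
        if abs(planted_mu) > 1e-12:
            rows.append(
                {
                    "archetype": rec["label"], "dimension": "mu",
                    "planted": planted_mu, "recovered": v.mu,
                    "rel_err": abs(v.mu - planted_mu) / abs(planted_mu),
                }
            )
        for c in non_biomass:
            col = f"r_{c.abbreviation}"
            planted = float(rec[col]) if col in rec.index else 0.0
            if abs(planted) <= 1e-12:
                continue
            got = v.rates.get(c.dimension_index, 0.0)
            rows.append(
                {
                    "archetype": rec["label"], "dimension": c.abbreviation,
                    "planted": planted, "recovered": got,
                    "rel_err": abs(got - planted) / abs(planted),
                }
            )
    return pd.DataFrame(rows)
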