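"""Reading and writing cultivation-experiment tables.

The samples table is wide delimited text (comma or tab, auto-detected): one
row per sampling point, columns ``experiment_id, time_h, biomass_gL`` and one
``<abbrev>_mM`` column per non-biomass compound of the registry.  A column
``<abbrev>_cumulative`` (boolean, constant within an experiment) marks a
compound whose values are recorded as cumulative consumed amount (fed-batch
book-keeping) rather than instantaneous concentration.  Empty cells mean
"not measured at this sampling point".

Units are fixed: time in h, biomass in g/L, every other compound in mmol/L.

The tags table is long delimited text with header ``experiment_id,key,value``;
tag values are kept as untyped text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .registry import CompoundSpec, default_registry

__all__ = [
    "CultivationExperiment",
    "load_experiments",
    "write_experiments",
    "load_tags",
    "convert_deposit",
]


@dataclass
class CultivationExperiment:
    """One cultivation: sampled concentration series plus condition tags.

    ``samples`` maps dimension_index -> value per row; missing measurements
    are absent from the map.  ``fed_batch_cumulative`` holds the dimension
    indices whose column is a cumulative consumed amount.
    """

    experiment_id: str
    times: list[float]  # h, strictly increasing
    concentrations: list[dict[int, float]]  # one map per sampling time
    tags: dict[str, str] = field(default_factory=dict)
    fed_batch_cumulative: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.concentrations):
            raise ValueError(f"{self.experiment_id}: times/concentrations length mismatch")
        t = np.asarray(self.times, dtype=float)
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError(f"{self.experiment_id}: sampling times must be strictly increasing")
        for j, conc in enumerate(self.concentrations):
            for d, v in conc.items():
                if v < 0:
                    raise ValueError(
                        f"{self.experiment_id}: negative concentration {v} "
                        f"(dimension {d}, t={self.times[j]} h)"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def series(self, dimension_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Measured (time, value) pairs for one dimension, in time order."""
        ts, vs = [], []
        for t, conc in zip(self.times, self.concentrations):
            if dimension_index in conc:
                ts.append(t)
                vs.append(conc[dimension_index])
        return np.asarray(ts, dtype=float), np.asarray(vs, dtype=float)


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


def load_experiments(
    samples_path: str | Path,
    tags_path: str | Path | None = None,
    registry: Sequence[CompoundSpec] | None = None,
) -> list[CultivationExperiment]:
    """Read the wide samples table (and optional tags table).

    Returns one :class:`CultivationExperiment` per distinct experiment_id,
    samples sorted by time.  Unknown ``<abbrev>_mM`` columns raise; unknown
    tag keys are preserved verbatim.
    """
    samples_path = Path(samples_path)
    registry = list(registry) if registry is not None else default_registry()
    by_abbrev = {c.abbreviation: c for c in registry if c.role != "biomass"}

    df = pd.read_csv(samples_path, sep=_detect_delimiter(samples_path))
    for col in ("experiment_id", "time_h", "biomass_gL"):
        if col not in df.columns:
            raise ValueError(f"{samples_path}: missing required column {col!r}")

    conc_cols: dict[str, int] = {"biomass_gL": 1}
    cum_cols: dict[str, int] = {}
    for col in df.columns:
        if col in ("experiment_id", "time_h", "biomass_gL"):
            continue
        if col.endswith("_mM"):
            abbrev = col[:-3]
            if abbrev not in by_abbrev:
                raise ValueError(f"{samples_path}: unknown dimension column {col!r}")
            conc_cols[col] = by_abbrev[abbrev].dimension_index
        elif col.endswith("_cumulative"):
            abbrev = col[: -len("_cumulative")]
            if abbrev not in by_abbrev:
                raise ValueError(f"{samples_path}: unknown cumulative column {col!r}")
            cum_cols[col] = by_abbrev[abbrev].dimension_index
        else:
            raise ValueError(f"{samples_path}: unrecognised column {col!r}")

    tags_by_exp: dict[str, dict[str, str]] = {}
    if tags_path is not None:
        tags_by_exp = load_tags(tags_path)

    experiments: list[CultivationExperiment] = []
    for exp_id, grp in df.groupby("experiment_id", sort=False):
        grp = grp.sort_values("time_h")
        times = grp["time_h"].to_numpy(dtype=float)
        if len(np.unique(times)) != len(times):
            raise ValueError(f"{exp_id}: repeated (experiment_id, time) row")
        cumulative: set[int] = set()
        for col, d in cum_cols.items():
            vals = {str(v).strip().lower() for v in grp[col].fillna("")}
            if not vals <= (_TRUTHY | _FALSY | {"nan"}):
                raise ValueError(f"{exp_id}: non-boolean value in column {col!r}")
            flags = {v in _TRUTHY for v in vals}
            if len(flags) > 1:
                raise ValueError(f"{exp_id}: column {col!r} not constant within experiment")
            if flags == {True}:
                cumulative.add(d)
        conc_rows: list[dict[int, float]] = []
        for _, row in grp.iterrows():
            conc: dict[int, float] = {}
            for col, d in conc_cols.items():
                v = row[col]
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    continue
                conc[d] = float(v)
            conc_rows.append(conc)
        experiments.append(
            CultivationExperiment(
                experiment_id=str(exp_id),
                times=list(times),
                concentrations=conc_rows,
                tags=dict(tags_by_exp.get(str(exp_id), {})),
                fed_batch_cumulative=cumulative,
            )
        )
    return experiments


def load_tags(tags_path: str | Path) -> dict[str, dict[str, str]]:
    """Read the long tags table into {experiment_id: {key: value}}."""
    tags_path = Path(tags_path)
    df = pd.read_csv(tags_path, sep=_detect_delimiter(tags_path), dtype=str)
    for col in ("experiment_id", "key", "value"):
        if col not in df.columns:
            raise ValueError(f"{tags_path}: missing required column {col!r}")
    out: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["experiment_id"]), {})[str(row["key"])] = str(row["value"])
    return out


def write_experiments(
    experiments: Iterable[CultivationExperiment],
    samples_path: str | Path,
    tags_path: str | Path | None = None,
    registry: Sequence[CompoundSpec] | None = None,
) -> None:
    """Write experiments back to the wide samples (and long tags) format."""
    registry = list(registry) if registry is not None else default_registry()
    non_biomass = [c for c in registry if c.role != "biomass"]
    experiments = list(experiments)

    used_dims = set()
    cum_dims = set()
    for exp in experiments:
        for conc in exp.concentrations:
            used_dims |= set(conc)
        cum_dims |= exp.fed_batch_cumulative
    cols = ["experiment_id", "time_h", "biomass_gL"]
    cols += [f"{c.abbreviation}_mM" for c in non_biomass if c.dimension_index in used_dims]
    cols += [f"{c.abbreviation}_cumulative" for c in non_biomass if c.dimension_index in cum_dims]

    rows = []
    for exp in experiments:
        for t, conc in zip(exp.times, exp.concentrations):
            row: dict[str, object] = {"experiment_id": exp.experiment_id, "time_h": t}
            if 1 in conc:
                row["biomass_gL"] = conc[1]
            for c in non_biomass:
                if c.dimension_index in conc:
                    row[f"{c.abbreviation}_mM"] = conc[c.dimension_index]
                if c.dimension_index in cum_dims:
                    row[f"{c.abbreviation}_cumulative"] = (
                        c.dimension_index in exp.fed_batch_cumulative
                    )
            rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(samples_path, index=False)

    if tags_path is not None:
        tag_rows = [
            {"experiment_id": exp.experiment_id, "key": k, "value": v}
            for exp in experiments
            for k, v in exp.tags.items()
        ]
        pd.DataFrame(tag_rows, columns=["experiment_id", "key", "value"]).to_csv(
            tags_path, index=False
        )


def convert_deposit(deposit_dir: str | Path, out_samples: str | Path,
                    out_tags: str | Path) -> None:
    """Converter stub for externally deposited datasets.

    Public fermentation datasets ship in lab-specific layouts; this hook is
    where a site adapts such a layout to the wide samples format above.  The
    stub only raises with instructions, because no deposit layout is bundled.
    """
    raise NotImplementedError(
        "Adapt this converter to the layout of your deposited dataset: produce "
        "a wide samples table (experiment_id, time_h, biomass_gL, <abbrev>_mM...) "
        "and a long tags table (experiment_id, key, value), then load them with "
        "load_experiments()."
    )
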