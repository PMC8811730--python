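"""Compound registry: the chemical dimensions of the phenotype vector.

Each dimension of a phenotype vector corresponds to one compound tracked in
the fermentation broth.  Dimension 1 is always biomass (whose specific rate
is the growth rate mu); the remaining dimensions are substrates and
extracellular products.  The registry stores, per compound, the molar mass,
the carbon count used for carbon balancing, and the stoichiometric ATP yield
of substrate-level phosphorylation used for ATP balancing.

The built-in registry describes the eleven dimensions of a glycerol/glucose
fermentation of *Clostridium pasteurianum* (biomass monomer C4H7O2N plus ten
substrates/metabolites).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CompoundSpec",
    "default_registry",
    "load_compound_registry",
    "write_registry",
    "registry_dimensions",
]

#: sentinel for "no defined ATP stoichiometry" (substrates, and products whose
#: substrate-level phosphorylation yield is not defined)
UNDEFINED = "undefined"


@dataclass(frozen=True)
class CompoundSpec:
    """One chemical dimension of the phenotype vector."""

    dimension_index: int
    name: str
    abbreviation: str
    molar_mass: float  # g/mol
    n_carbons: int
    atp_stoich: float | str  # mol ATP per mol compound, or "undefined"
    role: str  # biomass | substrate | product

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(
                f"{self.abbreviation}: molar mass must be positive, got {self.molar_mass}"
            )
        if self.n_carbons < 0:
            raise ValueError(f"{self.abbreviation}: n_carbons must be >= 0")
        if self.role not in ("biomass", "substrate", "product"):
            raise ValueError(f"{self.abbreviation}: unknown role {self.role!r}")
        if self.atp_stoich == UNDEFINED and self.role == "biomass":
            # biomass carries no product ATP stoichiometry; it enters the ATP
            # balance through the growth term, not through atp_stoich
            pass

    @property
    def has_atp_stoich(self) -> bool:
        return isinstance(self.atp_stoich, (int, float))


# Built-in eleven-dimension registry.  ATP stoichiometries are the
# substrate-level phosphorylation yields per mol of product; "undefined"
# marks substrates and 2-oxobutyric acid, whose yield is not defined.
_DEFAULT_ROWS: tuple[tuple, ...] = (
    (1, "Biomass", "BM", 101.1, 4, UNDEFINED, "biomass"),
    (2, "Glucose", "Glc", 180.2, 6, UNDEFINED, "substrate"),
    (3, "Glycerol", "Gly", 92.09, 3, UNDEFINED, "substrate"),
    (4, "1,3-Propanediol", "PDO", 76.09, 3, 0.0, "product"),
    (5, "Ethanol", "EtOH", 46.07, 2, 1.0, "product"),
    (6, "Butanol", "BuOH", 74.12, 4, 2.0, "product"),
    (7, "Lactic acid", "LaAc", 90.08, 3, 1.0, "product"),
    (8, "Formic acid", "FoAc", 46.03, 1, 0.0, "product"),
    (9, "Acetic acid", "AcAc", 60.05, 2, 2.0, "product"),
    (10, "Butyric acid", "BuAc", 88.11, 4, 3.0, "product"),
    (11, "2-Oxobutyric acid", "OBuAc", 102.1, 4, UNDEFINED, "product"),
)


def default_registry() -> list[CompoundSpec]:
    """Return the built-in eleven-compound registry."""
    return [CompoundSpec(*row) for row in _DEFAULT_ROWS]


def _validate(registry: Sequence[CompoundSpec]) -> list[CompoundSpec]:
    regs = sorted(registry, key=lambda c: c.dimension_index)
    indices = [c.dimension_index for c in regs]
    if len(set(indices)) != len(indices):
        raise ValueError(f"duplicate dimension_index in registry: {indices}")
    biomass = [c for c in regs if c.role == "biomass"]
    if len(biomass) != 1:
        raise ValueError("registry must contain exactly one biomass row")
    if biomass[0].dimension_index != 1:
        raise ValueError("biomass must occupy dimension_index 1")
    abbrevs = [c.abbreviation for c in regs]
    if len(set(abbrevs)) != len(abbrevs):
        raise ValueError("duplicate abbreviation in registry")
    return regs


def load_compound_registry(path: str | Path | None = None) -> list[CompoundSpec]:
    """Load and validate a compound registry.

    With ``path=None`` the built-in eleven-compound registry is returned.
    A registry file is delimited text with header
    ``dimension_index,name,abbreviation,molar_mass,n_carbons,atp_stoich,role``;
    ``atp_stoich`` may be a number or ``undefined``/``-``.
    """
    if path is None:
        return _validate(default_registry())
    path = Path(path)
    rows: list[CompoundSpec] = []
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        required = {
            "dimension_index", "name", "abbreviation",
            "molar_mass", "n_carbons", "atp_stoich", "role",
        }
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise ValueError(f"registry file {path} missing columns: {sorted(missing)}")
        for rec in reader:
            atp_raw = rec["atp_stoich"].strip()
            atp: float | str
            if atp_raw.lower() in ("undefined", "-", "–", ""):
                atp = UNDEFINED
            else:
                atp = float(atp_raw)
            rows.append(
                CompoundSpec(
                    dimension_index=int(rec["dimension_index"]),
                    name=rec["name"].strip(),
                    abbreviation=rec["abbreviation"].strip(),
                    molar_mass=float(rec["molar_mass"]),
                    n_carbons=int(rec["n_carbons"]),
                    atp_stoich=atp,
                    role=rec["role"].strip(),
                )
            )
    return _validate(rows)


def write_registry(registry: Iterable[CompoundSpec], path: str | Path) -> None:
    """Write a registry as delimited text (round-trips with the loader)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["dimension_index", "name", "abbreviation", "molar_mass",
             "n_carbons", "atp_stoich", "role"]
        )
        for c in registry:
            atp = c.atp_stoich if c.has_atp_stoich else UNDEFINED
            writer.writerow(
                [c.dimension_index, c.name, c.abbreviation, c.molar_mass,
                 c.n_carbons, atp, c.role]
            )


def registry_dimensions(registry: Sequence[CompoundSpec]) -> list[str]:
    """Ordered dimension labels: 'mu' for biomass, abbreviation otherwise."""
    regs = _validate(registry)
    return ["mu" if c.role == "biomass" else c.abbreviation for c in regs]


def by_abbreviation(registry: Sequence[CompoundSpec]) -> dict[str, CompoundSpec]:
    return {c.abbreviation: c for c in registry}
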