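"""Bioenergetics of syntrophic and methanogenic catabolism.

Standard and in-situ Gibbs free energies of anaerobic reactions, energy
partitioning along a trophic chain (acetogen -> hydrogenotrophic and
acetoclastic methanogens), thermodynamic threshold concentrations, and
COD-based theoretical methane potential.

Conventions
-----------
* ``dgf0_prime`` values are standard Gibbs free energies of formation at the
  biochemical standard state (pH 7, 298.15 K, 1 M / 1 bar), the Thauer
  convention: the proton carries dGf0' = R*T*ln(1e-7) = -39.95 kJ/mol.
* Aqueous activities are molar concentrations relative to 1 M; gas activities
  are partial pressures relative to 1 bar (1 Pa = 1e-5).
* Liquid water has activity 1 and is excluded from reaction quotients.
* Deviations from pH 7 enter through the quotient as
  ``nu_H+ * R*T*ln(10) * (7 - pH)``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "R_KJ",
    "T_STANDARD",
    "ChemicalSpecies",
    "Reaction",
    "EnvironmentalConditions",
    "TrophicChain",
    "parse_formula",
    "molar_mass_of",
    "default_species_table",
    "load_species_table",
    "balance_check",
    "standard_delta_g",
    "delta_g",
    "threshold_activity",
    "partition_energy",
    "cod_per_gram",
    "methane_yield_mol",
    "theoretical_methane_volume",
]

#: Gas constant, kJ mol^-1 K^-1.
R_KJ = 8.31446e-3

#: Biochemical standard temperature, K.
T_STANDARD = 298.15

#: Molar volume of an ideal gas at 273.15 K and 1 atm, L/mol.
MOLAR_VOLUME_STP = 22.414

#: Grams of O2-equivalent COD per mole of methane (CH4 + 2 O2 -> CO2 + 2 H2O).
COD_PER_MOL_CH4 = 64.0

_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "S": 32.06, "P": 30.974}

_WATER_IDS = frozenset({"H2O", "h2o", "water"})
_PROTON_IDS = frozenset({"H+", "h+", "proton"})

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class SpeciesLookupError(KeyError):
    """A reaction references a species id absent from the species table."""


class ConditionError(ValueError):
    """Environmental conditions lack a required activity."""


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse ``'C4H7O2'`` into ``{'C': 4, 'H': 7, 'O': 2}``."""
    if isinstance(formula, Mapping):
        return {el: int(n) for el, n in formula.items() if int(n) != 0}
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        el, num = match.group(1), match.group(2)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def molar_mass_of(formula: Mapping[str, int]) -> float:
    """Molar mass (g/mol) from elemental composition."""
    try:
        return sum(_ATOMIC_MASS[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"no atomic mass for element {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class ChemicalSpecies:
    """A chemical species with formation energy and phase.

    ``dgf0_prime`` may be ``None`` for species only used in COD arithmetic.
    """

    id: str
    formula: Mapping[str, int]
    charge: int = 0
    dgf0_prime: float | None = None
    phase: str = "aqueous"  # aqueous | gas | liquid-water
    molar_mass: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "formula", parse_formula(self.formula))
        if any(n < 0 for n in self.formula.values()):
            raise ValueError(f"{self.id}: negative element count")
        if self.molar_mass is None:
            object.__setattr__(self, "molar_mass", molar_mass_of(self.formula))
        if self.molar_mass <= 0:
            raise ValueError(f"{self.id}: molar mass must be positive")

    @property
    def is_water(self) -> bool:
        return self.phase == "liquid-water" or self.id in _WATER_IDS

    @property
    def is_proton(self) -> bool:
        return self.id in _PROTON_IDS


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction; negative coefficients are consumed species."""

    id: str
    stoichiometry: Mapping[str, float]
    guild: str | None = None  # acetogen | hydrogenotrophic_methanogen | acetoclastic_methanogen | other

    def reversed(self) -> "Reaction":
        return Reaction(
            id=f"{self.id}_reversed",
            stoichiometry={s: -nu for s, nu in self.stoichiometry.items()},
            guild=self.guild,
        )


@dataclass(frozen=True)
class EnvironmentalConditions:
    """Temperature, pH and activities defining the reaction quotient.

    Aqueous activities are molar concentrations over 1 M; gas activities are
    partial pressures over 1 bar. Water is implicit with activity 1.
    """

    temperature: float = T_STANDARD
    pH: float = 7.0
    activities: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError("pH must be in [0, 14]")
        for sid, a in self.activities.items():
            if a <= 0:
                raise ValueError(f"activity of {sid!r} must be positive")

    def with_activity(self, species_id: str, activity: float) -> "EnvironmentalConditions":
        acts = dict(self.activities)
        acts[species_id] = activity
        return EnvironmentalConditions(self.temperature, self.pH, acts)


@dataclass(frozen=True)
class TrophicChain:
    """An ordered syntrophic chain: reactions with multiplicities per mol substrate."""

    substrate: str
    reactions: Sequence[tuple[Reaction, float]]

    def validate_intermediates(
        self, species_table: Mapping[str, ChemicalSpecies], intermediates: Iterable[str]
    ) -> None:
        """Check that each intermediate produced upstream is consumed downstream."""
        for sid in intermediates:
            total = sum(mult * rxn.stoichiometry.get(sid, 0.0) for rxn, mult in self.reactions)
            if abs(total) > 1e-9:
                raise ValueError(
                    f"intermediate {sid!r} not balanced along chain (net {total:+g})"
                )


# ---------------------------------------------------------------------------
# Species table
# ---------------------------------------------------------------------------

def default_species_table() -> dict[str, ChemicalSpecies]:
    """Built-in thermodynamic table (Thauer-1977-style dGf0' at pH 7, 298.15 K).

    The proton's entry encodes the pH-7 convention:
    dGf0'(H+) = R*T*ln(1e-7) = -39.95 kJ/mol at 298.15 K.
    """
    dgf_h = R_KJ * T_STANDARD * math.log(1e-7)
    species = [
        ChemicalSpecies("butyrate", "C4H7O2", -1, -352.63),
        ChemicalSpecies("butyric_acid", "C4H8O2", 0, None),
        ChemicalSpecies("acetate", "C2H3O2", -1, -369.41),
        ChemicalSpecies("acetic_acid", "C2H4O2", 0, None),
        ChemicalSpecies("oleate", "C18H33O2", -1, None),
        ChemicalSpecies("oleic_acid", "C18H34O2", 0, None),
        ChemicalSpecies("H2O", "H2O", 0, -237.17, phase="liquid-water"),
        ChemicalSpecies("H2", "H2", 0, 0.0, phase="gas"),
        ChemicalSpecies("H+", "H", 1, dgf_h),
        ChemicalSpecies("CH4", "CH4", 0, -50.75, phase="gas"),
        ChemicalSpecies("CO2", "CO2", 0, -394.36, phase="gas"),
        ChemicalSpecies("HCO3-", "CHO3", -1, -586.85),
    ]
    return {sp.id: sp for sp in species}


def load_species_table(path) -> dict[str, ChemicalSpecies]:
    """Load a thermodynamic table from TSV.

    Columns: id, formula, charge, dgf0_prime_kj_mol, phase, molar_mass.
    Empty dgf0_prime_kj_mol / molar_mass cells are allowed.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "formula": str, "phase": str})
    required = {"id", "formula", "charge", "dgf0_prime_kj_mol", "phase", "molar_mass"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"species table missing columns: {sorted(missing)}")
    table: dict[str, ChemicalSpecies] = {}
    for _, row in df.iterrows():
        dgf = row["dgf0_prime_kj_mol"]
        mm = row["molar_mass"]
        table[row["id"]] = ChemicalSpecies(
            id=row["id"],
            formula=row["formula"],
            charge=int(row["charge"]),
            dgf0_prime=None if pd.isna(dgf) else float(dgf),
            phase=row["phase"],
            molar_mass=None if pd.isna(mm) else float(mm),
        )
    return table


def _lookup(species_table: Mapping[str, ChemicalSpecies], sid: str) -> ChemicalSpecies:
    try:
        return species_table[sid]
    except KeyError:
        raise SpeciesLookupError(f"unknown species id {sid!r}") from None


# ---------------------------------------------------------------------------
# Gibbs free energy
# ---------------------------------------------------------------------------

def balance_check(reaction: Reaction, species_table: Mapping[str, ChemicalSpecies]) -> bool:
    """True iff element and charge conservation both hold exactly."""
    elements: dict[str, float] = {}
    charge = 0.0
    for sid, nu in reaction.stoichiometry.items():
        sp = _lookup(species_table, sid)
        for el, n in sp.formula.items():
            elements[el] = elements.get(el, 0.0) + nu * n
        charge += nu * sp.charge
    return all(abs(v) < 1e-9 for v in elements.values()) and abs(charge) < 1e-9


def standard_delta_g(
    reaction: Reaction, species_table: Mapping[str, ChemicalSpecies]
) -> float:
    """Standard Gibbs free energy change dG0' (kJ per mol reaction) at pH 7.

    Sum of nu * dGf0' over the stoichiometry; the proton contributes via its
    pH-7 convention formation energy stored in the table.
    """
    total = 0.0
    for sid, nu in reaction.stoichiometry.items():
        if nu == 0:
            continue
        sp = _lookup(species_table, sid)
        if sp.dgf0_prime is None:
            raise ValueError(f"species {sid!r} has no dgf0_prime; cannot compute dG0'")
        total += nu * sp.dgf0_prime
    return total


def delta_g(
    reaction: Reaction,
    dg0_prime: float,
    conditions: EnvironmentalConditions,
    species_table: Mapping[str, ChemicalSpecies] | None = None,
) -> float:
    """In-situ Gibbs free energy dG = dG0' + R*T*ln(Q), kJ per mol reaction.

    Q runs over all species except water (activity 1); the proton enters as
    the deviation from pH 7. With ``dg0_prime = +53`` for syntrophic butyrate
    oxidation and bioreactor conditions (pH 7, 1 mM butyrate and acetate,
    1 Pa H2, 298.15 K) this yields about -21 kJ/mol.
    """
    table = default_species_table() if species_table is None else species_table
    T = conditions.temperature
    rt = R_KJ * T
    ln_q = 0.0
    for sid, nu in reaction.stoichiometry.items():
        if nu == 0:
            continue
        sp = table.get(sid)
        is_water = sp.is_water if sp is not None else sid in _WATER_IDS
        is_proton = sp.is_proton if sp is not None else sid in _PROTON_IDS
        if is_water:
            continue
        if is_proton:
            # activity relative to the pH-7 standard state: 10**(7 - pH)
            ln_q += nu * math.log(10.0) * (7.0 - conditions.pH)
            continue
        try:
            activity = conditions.activities[sid]
        except KeyError:
            raise ConditionError(f"no activity given for species {sid!r}") from None
        ln_q += nu * math.log(activity)
    return dg0_prime + rt * ln_q


def threshold_activity(
    reaction: Reaction,
    dg0_prime: float,
    conditions: EnvironmentalConditions,
    target_species: str,
    dg_target: float,
    species_table: Mapping[str, ChemicalSpecies] | None = None,
) -> float:
    """Activity of ``target_species`` at which delta_g equals ``dg_target``.

    Closed form: ln a = (dg_target - dg0' - R*T*ln(Q_rest)) / (nu * R*T), where
    Q_rest holds every other activity fixed. Substituting the result back into
    :func:`delta_g` recovers ``dg_target`` to well below 1e-9 kJ/mol.
    """
    nu = reaction.stoichiometry.get(target_species, 0.0)
    if nu == 0:
        raise ValueError(
            f"delta_g does not depend on {target_species!r} (stoichiometric coefficient 0)"
        )
    rt = R_KJ * conditions.temperature
    # delta_g at unit target activity gives dg0' + RT ln Q_rest directly.
    probe = conditions.with_activity(target_species, 1.0)
    dg_rest = delta_g(reaction, dg0_prime, probe, species_table)
    ln_a = (dg_target - dg_rest) / (nu * rt)
    return math.exp(ln_a)


def partition_energy(chain_yields: Sequence[tuple[str, float]]) -> dict[str, float]:
    """Fraction of the overall free-energy yield captured by each guild.

    ``chain_yields`` is a list of (guild, kJ per mol substrate); all yields
    must be exergonic (negative). Fractions sum to 1.
    """
    if not chain_yields:
        raise ValueError("chain_yields must be non-empty")
    for guild, y in chain_yields:
        if y >= 0:
            raise ValueError(
                f"guild {guild!r} has non-exergonic yield {y:+g} kJ; partitioning undefined"
            )
    total = sum(y for _, y in chain_yields)
    return {guild: y / total for guild, y in chain_yields}


# ---------------------------------------------------------------------------
# COD / methane stoichiometry
# ---------------------------------------------------------------------------

def _o2_demand_mol(formula: Mapping[str, int]) -> float:
    """Moles of O2 to fully oxidize one mole (N excreted as ammonia)."""
    supported = {"C", "H", "O", "N"}
    extra = set(formula) - supported
    if extra:
        raise NotImplementedError(f"COD undefined for elements {sorted(extra)}")
    c = formula.get("C", 0)
    h = formula.get("H", 0)
    o = formula.get("O", 0)
    n = formula.get("N", 0)
    return c + (h - 3 * n) / 4.0 - o / 2.0


def cod_per_gram(species: ChemicalSpecies) -> float:
    """Chemical oxygen demand, g O2 per g species.

    Complete oxidation CcHhOo + (c + h/4 - o/2) O2 -> c CO2 + (h/2) H2O;
    nitrogen, if present, leaves as ammonia. Butyric acid gives 1.82 g COD/g.
    """
    o2_mol = _o2_demand_mol(species.formula)
    m_o2 = 2 * _ATOMIC_MASS["O"]
    return max(0.0, o2_mol) * m_o2 / species.molar_mass


def methane_yield_mol(species: ChemicalSpecies) -> float:
    """Moles CH4 per mole of species under complete methanization.

    COD conservation: each mole of CH4 carries 2 mol O2 of COD, so
    mol CH4 = O2 demand / 2 (the Buswell yield for CHON substrates).
    """
    return max(0.0, _o2_demand_mol(species.formula)) / 2.0


def theoretical_methane_volume(
    concentration: float,
    sample_volume: float,
    species: ChemicalSpecies,
    temperature: float = 308.15,
) -> float:
    """Theoretical methane potential, mL CH4 at 1 atm and ``temperature``.

    ``concentration`` in mol/L, ``sample_volume`` in L. 40 mM butyric acid in
    10 mL at 35 C gives 25.3 mL, the full biochemical methane potential of the
    added substrate.
    """
    if concentration < 0 or sample_volume <= 0 or temperature <= 0:
        raise ValueError("concentration must be >= 0; volume and temperature positive")
    grams = concentration * sample_volume * species.molar_mass
    cod_g = grams * cod_per_gram(species)
    mol_ch4 = cod_g / COD_PER_MOL_CH4
    liters = mol_ch4 * MOLAR_VOLUME_STP * (temperature / 273.15)
    return liters * 1e3


# Canonical reaction used throughout: syntrophic butyrate oxidation.
BUTYRATE_OXIDATION = Reaction(
    id="butyrate_oxidation",
    stoichiometry={"butyrate": -1, "H2O": -2, "acetate": 2, "H2": 2, "H+": 1},
    guild="acetogen",
)
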