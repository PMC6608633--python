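"""Unit-cell inventories for dose calculation.

A dose estimate needs to know exactly which atoms sit in the unit cell.  In
macromolecular work the cell is mostly protein plus bulk water, and unoccupied
space is conventionally assumed to be solvent.  Small-molecule cells are
different: the full atomic composition is usually known in advance (from the
CIF, or from the synthesis recipe plus elemental analysis), voids may be
genuinely empty, and nothing should be auto-filled with water.  This module
builds a :class:`CrystalContents` from either source, audits it against the
empirical 18 A^3-per-non-hydrogen-atom packing rule, and derives density and
solvent (hydrate) fractions.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from math import cos, radians, sqrt

import gemmi

__all__ = [
    "CrystalContents",
    "OccupancyReport",
    "CifParseError",
    "parse_cif",
    "parse_cif_file",
    "contents_from_recipe",
    "occupancy_check",
    "fill_voids",
    "mass_fractions",
    "contents_to_cif_text",
    "contents_block",
    "load_reference_crystal",
    "ATOM_VOLUME_RULE_A3",
    "WATER_VOLUME_A3",
]

#: Empirical volume per non-hydrogen atom in a close-packed molecular crystal.
ATOM_VOLUME_RULE_A3 = 18.0

#: Default per-molecule volume convention for water volume fractions
#: (bulk-water density; channel water in hydrates packs tighter, nearer
#: the 18 A^3/non-H-atom rule).
WATER_VOLUME_A3 = 30.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)\s*([0-9]*\.?[0-9]*)")
_MOIETY_GROUP = re.compile(r"^\s*([0-9]*\.?[0-9]*)\s*\((.*)\)\s*$")

WATER_COUNTS = {"H": 2.0, "O": 1.0}
_WATER_MASS = 2 * gemmi.Element("H").weight + gemmi.Element("O").weight


class CifParseError(ValueError):
    """A required CIF item (cell, formula, Z) is missing or malformed."""


def _cell_volume(a, b, c, alpha, beta, gamma) -> float:
    ca, cb, cg = (cos(radians(x)) for x in (alpha, beta, gamma))
    return a * b * c * sqrt(max(1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg, 0.0))


def _parse_formula(text: str) -> dict[str, float]:
    """Parse a CIF sum-formula fragment like ``'C16 H36 N8 Ni O13'``."""
    counts: dict[str, float] = {}
    for sym, num in _FORMULA_TOKEN.findall(text):
        if gemmi.Element(sym).atomic_number == 0:
            raise CifParseError(f"unknown element {sym!r} in formula {text!r}")
        counts[sym] = counts.get(sym, 0.0) + (float(num) if num else 1.0)
    if not counts:
        raise CifParseError(f"could not parse chemical formula {text!r}")
    return counts


def _is_water(counts: dict[str, float]) -> bool:
    keys = {k for k, v in counts.items() if v > 0}
    if keys != {"H", "O"}:
        return False
    return abs(counts["H"] / counts["O"] - 2.0) < 1e-6


def water_from_moiety(moiety: str) -> float:
    """Water molecules per formula unit declared in a moiety formula.

    Hydrates are conventionally written with the lattice water split out,
    e.g. ``'C16 H22 N8 Ni O6, 7(H2 O)'``.
    """
    total = 0.0
    for part in moiety.split(","):
        part = part.strip().strip("'\"")
        if not part:
            continue
        m = _MOIETY_GROUP.match(part)
        if m:
            mult = float(m.group(1)) if m.group(1) else 1.0
            counts = _parse_formula(m.group(2))
        else:
            mult, counts = 1.0, _parse_formula(part)
        if _is_water(counts):
            total += mult * counts["O"]
    return total


@dataclass(frozen=True)
class CrystalContents:
    """Atomic inventory of one unit cell.

    ``element_counts`` are atoms per unit cell (fractional values allowed, for
    partial-occupancy sites).  ``solvent`` holds labelled sub-inventories that
    are *included* in ``element_counts`` -- e.g. ``{"water": 14.0}`` meaning
    14 water molecules per cell -- so that hydrate fractions can be reported.
    """

    cell: tuple[float, float, float, float, float, float]
    volume: float                       # A^3
    z: int
    element_counts: dict[str, float]
    solvent: dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")
        a, b, c, al, be, ga = self.cell
        vcalc = _cell_volume(a, b, c, al, be, ga)
        if abs(vcalc - self.volume) > 1e-3 * self.volume:
            raise ValueError(
                f"volume {self.volume} inconsistent with cell parameters ({vcalc:.2f})"
            )
        if any(v < 0 for v in self.element_counts.values()):
            raise ValueError("negative atom counts")

    @property
    def mass_per_cell_amu(self) -> float:
        return sum(gemmi.Element(s).weight * n for s, n in self.element_counts.items())

    @property
    def density(self) -> float:
        """Crystal density in g/cm^3 (total cell mass / cell volume)."""
        # amu/A^3 -> g/cm^3 : 1/0.602214 (Avogadro x 1e-24)
        return self.mass_per_cell_amu / (0.602214076 * self.volume)

    @property
    def n_non_hydrogen(self) -> float:
        return sum(n for s, n in self.element_counts.items() if s != "H")

    @property
    def water_per_cell(self) -> float:
        return self.solvent.get("water", 0.0)


@dataclass(frozen=True)
class OccupancyReport:
    """Audit of a unit cell against the 18 A^3/non-H-atom packing rule."""

    n_non_hydrogen: float
    occupied_volume: float       # A^3, = 18 * n_nonH
    void_volume: float           # A^3, may be negative (overfull)
    void_fraction: float
    verdict: str                 # "full" | "underfull" | "overfull"
    tolerance: float
    missing_non_h_atoms: int     # estimate, only meaningful when underfull


def parse_cif(cif_text: str, name: str = "") -> CrystalContents:
    """Build unit-cell contents from small-molecule CIF text.

    The primary route uses ``_chemical_formula_sum`` x ``_cell_formula_units_Z``;
    if either is absent the atom-site loop is enumerated instead (occupancy x
    site multiplicity under the declared space group).  Lattice water is
    identified from ``_chemical_formula_moiety`` when present.
    """
    doc = gemmi.cif.read_string(cif_text)
    block = doc.sole_block()

    def num(tag):
        val = block.find_value(tag)
        if val is None:
            return None
        try:
            return float(gemmi.cif.as_number(val))
        except Exception:
            return None

    cell_vals = [num("_cell_length_a"), num("_cell_length_b"), num("_cell_length_c"),
                 num("_cell_angle_alpha"), num("_cell_angle_beta"), num("_cell_angle_gamma")]
    if any(v is None for v in cell_vals):
        raise CifParseError("missing unit-cell parameters (_cell_length_* / _cell_angle_*)")
    cell = tuple(cell_vals)
    volume = num("_cell_volume") or _cell_volume(*cell)

    z_val = num("_cell_formula_units_Z")
    formula = block.find_value("_chemical_formula_sum")

    if formula is not None and z_val is not None:
        z = int(round(z_val))
        per_formula = _parse_formula(gemmi.cif.as_string(formula))
        counts = {s: n * z for s, n in per_formula.items()}
        water_fu = 0.0
        moiety = block.find_value("_chemical_formula_moiety")
        if moiety is not None:
            water_fu = water_from_moiety(gemmi.cif.as_string(moiety))
        solvent = {"water": water_fu * z} if water_fu else {}
        return CrystalContents(cell=cell, volume=volume, z=z, element_counts=counts,
                               solvent=solvent, name=name or block.name)

    # fall back to the atom-site loop
    small = gemmi.make_small_structure_from_block(block)
    sites = small.get_all_unit_cell_sites()
    if not sites:
        raise CifParseError(
            "missing chemical formula (_chemical_formula_sum with "
            "_cell_formula_units_Z) and no atom-site loop to enumerate"
        )
    counts: dict[str, float] = {}
    for site in sites:
        sym = site.element.name
        counts[sym] = counts.get(sym, 0.0) + site.occ
    z = int(round(z_val)) if z_val else 1
    return CrystalContents(cell=cell, volume=volume, z=z, element_counts=counts,
                           name=name or block.name)


def parse_cif_file(path) -> CrystalContents:
    with open(path) as fh:
        return parse_cif(fh.read(), name=str(path))


def contents_from_recipe(formula_units: dict[str, float], z: int,
                         cell: tuple[float, float, float, float, float, float],
                         water_per_formula_unit: float = 0.0,
                         name: str = "") -> CrystalContents:
    """Unit-cell contents from a synthesis recipe: formula-unit counts x Z.

    ``formula_units`` are atom counts for one formula unit *excluding* the
    hydrate water given in ``water_per_formula_unit``.
    """
    if z < 1:
        raise ValueError("Z must be >= 1")
    if any(v < 0 for v in formula_units.values()):
        raise ValueError("negative atom counts in recipe")
    counts = {s: n * z for s, n in formula_units.items() if n > 0}
    n_water = water_per_formula_unit * z
    if n_water:
        for s, per_water in WATER_COUNTS.items():
            counts[s] = counts.get(s, 0.0) + per_water * n_water
    volume = _cell_volume(*cell)
    return CrystalContents(cell=tuple(cell), volume=volume, z=z,
                           element_counts=counts,
                           solvent={"water": n_water} if n_water else {},
                           name=name)


def occupancy_check(contents: CrystalContents, tolerance: float = 0.10) -> OccupancyReport:
    """Judge whether the declared contents account for the cell volume.

    Each non-hydrogen atom is credited 18 A^3; a |void fraction| within
    ``tolerance`` of the cell volume is called "full".  When underfull, the
    void divided by 18 A^3 estimates how many non-H atoms (e.g. of an
    unmodelled solvent) are missing.
    """
    n_nonh = contents.n_non_hydrogen
    occupied = ATOM_VOLUME_RULE_A3 * n_nonh
    void = contents.volume - occupied
    frac = void / contents.volume
    if abs(frac) <= tolerance:
        verdict = "full"
    elif frac > 0:
        verdict = "underfull"
    else:
        verdict = "overfull"
    missing = int(round(void / ATOM_VOLUME_RULE_A3)) if verdict == "underfull" else 0
    return OccupancyReport(n_non_hydrogen=n_nonh, occupied_volume=occupied,
                           void_volume=void, void_fraction=frac, verdict=verdict,
                           tolerance=tolerance, missing_non_h_atoms=missing)


def fill_voids(contents: CrystalContents, solvent="none",
               count_per_cell: float = 0.0, tolerance: float = 0.10) -> CrystalContents:
    """Explicitly add solvent to a unit cell (never automatic).

    ``solvent`` is ``"none"`` (identity), ``"water"``, or a dict of element
    ratios per solvent molecule; ``count_per_cell`` molecules are added.  The
    addition is refused if it would make the cell overfull beyond ``tolerance``
    under the 18 A^3 rule.
    """
    if solvent == "none" or count_per_cell == 0:
        return contents
    ratios = WATER_COUNTS if solvent == "water" else dict(solvent)
    if count_per_cell < 0:
        raise ValueError("solvent count must be non-negative")

    counts = dict(contents.element_counts)
    for s, n in ratios.items():
        counts[s] = counts.get(s, 0.0) + n * count_per_cell
    added_nonh = sum(n for s, n in ratios.items() if s != "H") * count_per_cell
    new_nonh = contents.n_non_hydrogen + added_nonh
    overfill = ATOM_VOLUME_RULE_A3 * new_nonh - contents.volume * (1 + tolerance)
    if overfill > 0:
        raise ValueError(
            f"solvent request overfills the cell by {overfill:.1f} A^3 "
            f"beyond the {tolerance:.0%} tolerance"
        )
    solvent_inv = dict(contents.solvent)
    label = "water" if ratios == WATER_COUNTS else "solvent"
    solvent_inv[label] = solvent_inv.get(label, 0.0) + count_per_cell
    return replace(contents, element_counts=counts, solvent=solvent_inv)


def mass_fractions(contents: CrystalContents,
                   water_volume_a3: float = WATER_VOLUME_A3) -> dict:
    """Per-element mass fractions, hydrate fractions and density.

    The water *mass* fraction follows directly from the labelled solvent
    inventory; the water *volume* fraction depends on a per-molecule volume
    convention (default 30 A^3, bulk-density water; pass 18 A^3 to count
    channel water under the same packing rule as the framework).
    """
    total_mass = contents.mass_per_cell_amu
    if total_mass <= 0:
        raise ValueError("zero cell mass")
    per_element = {s: gemmi.Element(s).weight * n / total_mass
                   for s, n in contents.element_counts.items() if n > 0}
    n_water = contents.water_per_cell
    return {
        "element_mass_fractions": per_element,
        "water_mass_fraction": n_water * _WATER_MASS / total_mass,
        "water_volume_fraction": n_water * water_volume_a3 / contents.volume,
        "water_volume_per_molecule_a3": water_volume_a3,
        "density_g_cm3": contents.density,
    }


def contents_to_cif_text(contents: CrystalContents) -> str:
    """Write contents back as a minimal CIF (round-trips through parse_cif)."""
    a, b, c, al, be, ga = contents.cell
    z = contents.z
    formula = " ".join(
        f"{s}{contents.element_counts[s] / z:g}" for s in sorted(contents.element_counts)
    )
    lines = [
        f"data_{contents.name or 'contents'}",
        f"_chemical_formula_sum '{formula}'",
        f"_cell_length_a {a}",
        f"_cell_length_b {b}",
        f"_cell_length_c {c}",
        f"_cell_angle_alpha {al}",
        f"_cell_angle_beta {be}",
        f"_cell_angle_gamma {ga}",
        f"_cell_volume {contents.volume:.4f}",
        f"_cell_formula_units_Z {z}",
    ]
    n_water_fu = contents.water_per_cell / z
    if n_water_fu:
        main = dict(contents.element_counts)
        main["H"] = main.get("H", 0) - 2 * contents.water_per_cell
        main["O"] = main.get("O", 0) - contents.water_per_cell
        main_formula = " ".join(f"{s}{main[s] / z:g}" for s in sorted(main) if main[s] > 0)
        lines.insert(1, f"_chemical_formula_moiety '{main_formula}, {n_water_fu:g}(H2 O)'")
    return "\n".join(lines) + "\n"


def contents_block(contents: CrystalContents, as_json: bool = False):
    """Composition summary: JSON record or a dose-program-style text block."""
    record = {
        "name": contents.name,
        "cell": list(contents.cell),
        "volume_a3": contents.volume,
        "z": contents.z,
        "element_counts_per_cell": dict(contents.element_counts),
        "solvent_per_cell": dict(contents.solvent),
        "density_g_cm3": contents.density,
    }
    if as_json:
        return json.dumps(record, indent=2)
    a, b, c, al, be, ga = contents.cell
    atoms = " ".join(f"{s} {n:g}" for s, n in sorted(contents.element_counts.items()))
    return (
        "Crystal\n"
        f"UnitCell {a:.4f} {b:.4f} {c:.4f} {al:.2f} {be:.2f} {ga:.2f}\n"
        f"UnitCellContents {atoms}\n"
    )


def load_reference_crystal() -> CrystalContents:
    """The packaged synthetic reference: a nickel dipeptide heptahydrate.

    Reconstructed from published summary characteristics of CSD entry FINWUW
    (formula, Z' = 1, hydrate fractions); see the data file header.  The cell
    edges are synthetic -- only volume, composition and density are meaningful.
    """
    text = resources.files("smxdose.data").joinpath("finwuw_synthetic.cif").read_text()
    return parse_cif(text, name="FINWUW_synthetic")
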