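"""Elemental-composition and monoisotopic-mass arithmetic for modified ribonucleosides.

Everything downstream (fragment neutral masses, negative-ion m/z, isotope
envelopes) derives from the :class:`ElementalComposition` arithmetic and the
modification registry defined here.  Atomic masses are hard-coded from the
NIST/AME monoisotopic tables so that results do not drift with library
versions.

A residue code (``"U"``, ``"cmo5U"``, ``"s4U"`` ...) resolves to a *neutral
nucleoside* composition: the parent nucleoside plus a signed elemental delta.
Isomeric modifications such as pseudouridine carry a ``mass_silent`` flag so
that quantification can warn when two states are indistinguishable by mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

__all__ = [
    "ElementalComposition",
    "ResidueDef",
    "ModRegistry",
    "default_registry",
    "WATER",
    "HPO3",
    "PROTON_MASS",
    "O18_SHIFT",
    "MONOISOTOPIC_MASS",
    "ISOTOPE_ABUNDANCE",
]

# Monoisotopic atomic masses (Da), NIST/AME2020.  Key: (element, isotope mass
# number) with None meaning the most abundant (monoisotopic) isotope.
MONOISOTOPIC_MASS: dict[tuple[str, Optional[int]], float] = {
    ("H", None): 1.00782503207,
    ("H", 1): 1.00782503207,
    ("H", 2): 2.01410177785,
    ("C", None): 12.0,
    ("C", 12): 12.0,
    ("C", 13): 13.00335483507,
    ("N", None): 14.0030740048,
    ("N", 14): 14.0030740048,
    ("N", 15): 15.0001088989,
    ("O", None): 15.9949146196,
    ("O", 16): 15.9949146196,
    ("O", 17): 16.9991317565,
    ("O", 18): 17.9991596129,
    ("P", None): 30.97376163,
    ("P", 31): 30.97376163,
    ("S", None): 31.97207100,
    ("S", 32): 31.97207100,
    ("S", 33): 32.97145876,
    ("S", 34): 33.96786690,
}

# Natural isotopic abundances per element, as (nominal mass shift, fraction),
# used by the isotope-envelope convolution.
ISOTOPE_ABUNDANCE: dict[str, list[tuple[int, float]]] = {
    "H": [(0, 0.999885), (1, 0.000115)],
    "C": [(0, 0.9893), (1, 0.0107)],
    "N": [(0, 0.99636), (1, 0.00364)],
    "O": [(0, 0.99757), (1, 0.00038), (2, 0.00205)],
    "P": [(0, 1.0)],
    "S": [(0, 0.9499), (1, 0.0075), (2, 0.0425)],
}

#: Mass number of the monoisotopic (reference) isotope per element.
LIGHT_ISOTOPE: dict[str, int] = {"H": 1, "C": 12, "N": 14, "O": 16, "P": 31, "S": 32}

PROTON_MASS = 1.00727646677  # H+ (electron mass subtracted)

#: Exact ¹⁸O − ¹⁶O monoisotopic mass difference (Da); nominal "+2 Da" label shift.
O18_SHIFT = MONOISOTOPIC_MASS[("O", 18)] - MONOISOTOPIC_MASS[("O", 16)]


class RegistryError(KeyError):
    """Unknown residue code or invalid registry manipulation."""


class CompositionError(ValueError):
    """Invalid elemental-composition arithmetic (negative counts, unknown atoms)."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_plain_formula(s: str) -> dict[tuple[str, Optional[int]], int]:
    counts: dict[tuple[str, Optional[int]], int] = {}
    pos = 0
    while pos < len(s):
        m = _FORMULA_TOKEN.match(s, pos)
        if not m or m.start() != pos or not m.group(1):
            raise CompositionError(f"cannot parse formula {s!r} at offset {pos}")
        elem, num = m.group(1), m.group(2)
        if (elem, None) not in MONOISOTOPIC_MASS:
            raise CompositionError(f"unknown element {elem!r} in formula {s!r}")
        counts[(elem, None)] = counts.get((elem, None), 0) + (int(num) if num else 1)
        pos = m.end()
    return counts


@dataclass(frozen=True)
class ElementalComposition:
    """Multiset of (element, isotope) atom counts.

    ``isotope=None`` denotes natural (monoisotopic reference) atoms; an explicit
    mass number marks atoms re-assigned by an isotope label.  Supports ``+``
    and ``-`` (element-wise, never negative), scalar ``*``, monoisotopic
    :meth:`mass`, and formula parsing/formatting.
    """

    counts: Mapping[tuple[str, Optional[int]], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for key, n in self.counts.items():
            if n < 0:
                raise CompositionError(f"negative count for {key}: {n}")
            if key not in MONOISOTOPIC_MASS:
                raise CompositionError(f"unknown element/isotope {key}")
            if n > 0:
                clean[key] = int(n)
        object.__setattr__(self, "counts", clean)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a plain formula like ``"C9H12N2O6"`` (natural isotopes only)."""
        return cls(_parse_plain_formula(formula))

    @classmethod
    def from_signed_formula(cls, signed: str) -> "tuple[ElementalComposition, ElementalComposition]":
        """Parse a signed delta like ``"-O+S"`` or ``"+C2H2O3"``.

        Returns (additions, removals) as two compositions; an unsigned leading
        chunk counts as an addition.  The empty string is the zero delta.
        """
        adds: dict[tuple[str, Optional[int]], int] = {}
        subs: dict[tuple[str, Optional[int]], int] = {}
        for sign, chunk in re.findall(r"([+-]?)([A-Za-z0-9]+)", signed):
            target = subs if sign == "-" else adds
            for key, n in _parse_plain_formula(chunk).items():
                target[key] = target.get(key, 0) + n
        return cls(adds), cls(subs)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for key, n in other.counts.items():
            merged[key] = merged.get(key, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for key, n in other.counts.items():
            merged[key] = merged.get(key, 0) - n
            if merged[key] < 0:
                raise CompositionError(
                    f"subtraction yields negative count for {key[0]}"
                )
        return ElementalComposition(merged)

    def __mul__(self, k: int) -> "ElementalComposition":
        if k < 0:
            raise CompositionError("cannot scale a composition by a negative integer")
        return ElementalComposition({key: n * k for key, n in self.counts.items()})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    # -- queries -----------------------------------------------------------
    def mass(self) -> float:
        """Monoisotopic mass in Da (isotope-labelled atoms use their exact mass)."""
        return sum(MONOISOTOPIC_MASS[key] * n for key, n in self.counts.items())

    def count(self, element: str, isotope: Optional[int] = None) -> int:
        return self.counts.get((element, isotope), 0)

    def natural_counts(self) -> dict[str, int]:
        """Per-element counts of natural-abundance atoms only."""
        return {e: n for (e, iso), n in self.counts.items() if iso is None}

    def formula(self) -> str:
        """Hill-ish formula string; labelled atoms rendered as e.g. ``[18O]1``."""
        parts = []
        for (e, iso), n in sorted(self.counts.items(), key=lambda kv: (kv[0][0], kv[0][1] or 0)):
            label = e if iso is None else f"[{iso}{e}]"
            parts.append(f"{label}{n if n != 1 else ''}")
        return "".join(parts)


def mass_of(comp: ElementalComposition) -> float:
    """Monoisotopic mass of a composition in Da (module-level convenience)."""
    return comp.mass()


def apply_isotope_label(
    comp: ElementalComposition, element: str, isotope: int, n: int
) -> ElementalComposition:
    """Re-assign ``n`` natural-abundance atoms of ``element`` to ``isotope``.

    The nominal-mass bookkeeping of metabolic labelling: one ¹⁸O raises the
    monoisotopic mass by :data:`O18_SHIFT` (≈2.0042 Da, the "+2 Da" signature).
    """
    if n < 0:
        raise CompositionError("label count must be non-negative")
    if n == 0:
        return comp
    if (element, isotope) not in MONOISOTOPIC_MASS:
        raise CompositionError(f"unknown isotope {isotope}{element}")
    available = comp.count(element, None)
    if available < n:
        raise CompositionError(
            f"cannot label {n} atoms of {element}: only {available} natural atoms present"
        )
    counts = dict(comp.counts)
    counts[(element, None)] = available - n
    counts[(element, isotope)] = counts.get((element, isotope), 0) + n
    return ElementalComposition(counts)


# --------------------------------------------------------------------------
# Residue registry
# --------------------------------------------------------------------------

#: Neutral parent ribonucleoside compositions.
PARENT_NUCLEOSIDES: dict[str, str] = {
    "A": "C10H13N5O4",
    "C": "C9H13N3O5",
    "G": "C10H13N5O5",
    "U": "C9H12N2O6",
}

WATER = ElementalComposition.from_formula("H2O")
HPO3 = ElementalComposition.from_formula("HPO3")
#: Ribose-minus-water moiety; nucleoside = base(BH) + this.
RIBOSE = ElementalComposition.from_formula("C5H8O4")
CH2 = ElementalComposition.from_formula("CH2")


@dataclass(frozen=True)
class ResidueDef:
    """A registry residue: a parent nucleoside plus a signed elemental delta.

    ``cleavable_override`` forces/blocks RNase T1 cleavage 3' of this residue
    regardless of the parent base.  ``sugar_methyl`` marks 2'-O-methylation
    (the extra CH2 sits on the ribose, which matters for a-B ion base loss and
    blocks T1 cleavage for G residues).
    """

    code: str
    parent: str
    delta: str = ""  # signed formula, e.g. "+O", "-O+S", "+C2H2O3"
    mass_silent: bool = False
    cleavable_override: Optional[bool] = None
    sugar_methyl: bool = False

    def composition(self) -> ElementalComposition:
        base = ElementalComposition.from_formula(PARENT_NUCLEOSIDES[self.parent])
        adds, subs = ElementalComposition.from_signed_formula(self.delta)
        try:
            return base + adds - subs
        except CompositionError as exc:
            raise RegistryError(
                f"delta {self.delta!r} invalid for parent {self.parent}: {exc}"
            ) from exc


class ModRegistry:
    """Residue-code registry with the constants used by mass bookkeeping."""

    water = WATER
    hpo3 = HPO3
    proton = PROTON_MASS

    def __init__(self, residues: Iterable[ResidueDef] = ()) -> None:
        self._residues: dict[str, ResidueDef] = {}
        for r in residues:
            self.register(r)

    def __contains__(self, code: str) -> bool:
        return code in self._residues

    def __iter__(self):
        return iter(self._residues.values())

    def codes(self) -> list[str]:
        return list(self._residues)

    def get(self, code: str) -> ResidueDef:
        try:
            return self._residues[code]
        except KeyError:
            raise RegistryError(f"unknown residue code {code!r}") from None

    def register(self, definition: ResidueDef, overwrite: bool = False) -> None:
        if definition.parent not in PARENT_NUCLEOSIDES:
            raise RegistryError(f"unknown parent base {definition.parent!r}")
        if definition.code in self._residues and not overwrite:
            raise RegistryError(f"residue code {definition.code!r} already registered")
        definition.composition()  # validates the delta eagerly
        self._residues[definition.code] = definition

    def residue_composition(self, code: str) -> ElementalComposition:
        """Neutral nucleoside composition of a registry residue."""
        return self.get(code).composition()

    def residue_mass(self, code: str) -> float:
        return self.residue_composition(code).mass()

    def base_composition(self, code: str) -> ElementalComposition:
        """Neutral nucleobase (BH) composition: nucleoside minus the sugar moiety."""
        comp = self.residue_composition(code) - RIBOSE
        if self.get(code).sugar_methyl:
            comp = comp - CH2
        return comp

    def is_cleavable(self, code: str) -> bool:
        """Whether RNase T1 cuts 3' of this residue (guanosines, unless 2'-O-methylated)."""
        d = self.get(code)
        if d.cleavable_override is not None:
            return d.cleavable_override
        return d.parent == "G" and not d.sugar_methyl

    # -- TSV round trip ----------------------------------------------------
    TSV_HEADER = "code\tparent\tdelta_formula\tmass_silent\tcleavable_override\tsugar_methyl"

    def to_tsv(self, path: Union[str, Path]) -> None:
        lines = [self.TSV_HEADER]
        for d in self._residues.values():
            override = "" if d.cleavable_override is None else str(int(d.cleavable_override))
            lines.append(
                f"{d.code}\t{d.parent}\t{d.delta}\t{int(d.mass_silent)}\t{override}\t{int(d.sugar_methyl)}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "ModRegistry":
        reg = cls()
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0] != cls.TSV_HEADER:
            raise RegistryError(f"unrecognized registry TSV header in {path}")
        for line in lines[1:]:
            if not line.strip():
                continue
            code, parent, delta, silent, override, sugar = line.split("\t")
            reg.register(
                ResidueDef(
                    code=code,
                    parent=parent,
                    delta=delta,
                    mass_silent=bool(int(silent)),
                    cleavable_override=None if override == "" else bool(int(override)),
                    sugar_methyl=bool(int(sugar)),
                )
            )
        return reg


def default_registry() -> ModRegistry:
    """Registry covering the wobble xo⁵U pathway plus common tRNA modifications.

    cmo⁵U is uridine-5-oxyacetic acid (U + C2H2O3 relative to uridine);
    mcmo⁵U its methyl ester; mcmo⁵Um additionally 2'-O-methylated.  s⁴U is an
    O→S substitution and pseudouridine an isomer of U (mass-silent).
    """
    return ModRegistry(
        [
            ResidueDef("A", "A"),
            ResidueDef("C", "C"),
            ResidueDef("G", "G"),
            ResidueDef("U", "U"),
            ResidueDef("ho5U", "U", "+O"),
            ResidueDef("mo5U", "U", "+CH2O"),
            ResidueDef("cmo5U", "U", "+C2H2O3"),
            ResidueDef("mcmo5U", "U", "+C3H4O3"),
            ResidueDef("mcmo5Um", "U", "+C4H6O3", sugar_methyl=True),
            ResidueDef("Um", "U", "+CH2", sugar_methyl=True),
            ResidueDef("Gm", "G", "+CH2", sugar_methyl=True),
            ResidueDef("s4U", "U", "-O+S"),
            ResidueDef("D", "U", "+H2"),
            ResidueDef("m7G", "G", "+CH2"),
            ResidueDef("m5U", "U", "+CH2"),
            ResidueDef("psi", "U", "", mass_silent=True),
        ]
    )
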