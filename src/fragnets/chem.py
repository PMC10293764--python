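"""Elemental mass arithmetic, ion m/z and the chemical-consistency relation.

Formulas are integer vectors over a fixed twelve-dimensional isotope basis:
the most abundant isotope of H, C, N, O, F, Na, P, S, Cl and K, plus the
heavy isotopes 13C and 34S as independent dimensions.  An MS2 fragmentation
event is modelled as a decomposition of one singly charged ion into a
smaller ion and a neutral molecule, so two ion formulas are *chemically
consistent* exactly when one is a proper sub-formula of the other; the
componentwise difference is the neutral loss.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ISOTOPE_LABELS",
    "ISOTOPE_MASSES",
    "ELECTRON_MASS",
    "IsotopeTable",
    "DEFAULT_ISOTOPES",
    "FormulaVector",
    "exact_mass",
    "ion_mz",
    "mass_error_ppm",
    "consistent",
    "neutral_loss",
    "parse_formula",
    "format_formula",
]

#: Canonical dimension order, which is also the display order for formula
#: strings (C, S, O, N, H first, heavy isotopes directly after their light
#: element, remaining elements alphabetically).
ISOTOPE_LABELS: tuple[str, ...] = (
    "C",
    "[13C]",
    "S",
    "[34S]",
    "O",
    "N",
    "H",
    "Cl",
    "F",
    "K",
    "Na",
    "P",
)

# Monoisotopic atomic masses in Da (CODATA / AME values).
ISOTOPE_MASSES: dict[str, float] = {
    "C": 12.0,
    "[13C]": 13.00335484,
    "S": 31.97207117,
    "[34S]": 33.96786701,
    "O": 15.99491462,
    "N": 14.00307401,
    "H": 1.00782503207,
    "Cl": 34.96885268,
    "F": 18.99840316,
    "K": 38.96370649,
    "Na": 22.98976928,
    "P": 30.97376200,
}

ELECTRON_MASS: float = 0.00054857990907  # Da

_INDEX: dict[str, int] = {label: i for i, label in enumerate(ISOTOPE_LABELS)}
_MASS_VECTOR: tuple[float, ...] = tuple(ISOTOPE_MASSES[lab] for lab in ISOTOPE_LABELS)

#: Heavy isotope dimension -> light element dimension it collapses onto.
_HEAVY_TO_LIGHT: dict[str, str] = {"[13C]": "C", "[34S]": "S"}


@dataclass(frozen=True)
class IsotopeTable:
    """The isotope basis: label -> monoisotopic mass, plus the electron mass."""

    entries: Mapping[str, float] = field(default_factory=lambda: dict(ISOTOPE_MASSES))
    electron_mass: float = ELECTRON_MASS

    def __post_init__(self) -> None:
        if set(self.entries) != set(ISOTOPE_LABELS):
            raise ValueError("isotope table must cover exactly the twelve supported dimensions")
        if any(m <= 0 for m in self.entries.values()):
            raise ValueError("isotope masses must be positive")


DEFAULT_ISOTOPES = IsotopeTable()


@dataclass(frozen=True)
class FormulaVector:
    """Integer isotope counts plus a charge (+1, -1 ion or 0 for a neutral loss)."""

    counts: tuple[int, ...]
    charge: int = 0

    def __post_init__(self) -> None:
        if len(self.counts) != len(ISOTOPE_LABELS):
            raise ValueError(f"counts must have {len(ISOTOPE_LABELS)} dimensions")
        if any((not isinstance(c, int)) or c < 0 for c in self.counts):
            raise ValueError("isotope counts must be non-negative integers")
        if self.charge not in (-1, 0, 1):
            raise ValueError("charge must be +1, -1 or 0 (singly charged ions only)")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dict(cls, counts: Mapping[str, int], charge: int = 0) -> "FormulaVector":
        vec = [0] * len(ISOTOPE_LABELS)
        for label, n in counts.items():
            key = _normalize_label(label)
            if key is None:
                raise ValueError(f"unknown element or isotope symbol: {label!r}")
            vec[_INDEX[key]] += int(n)
        return cls(tuple(vec), charge)

    # -- accessors ---------------------------------------------------------
    def __getitem__(self, label: str) -> int:
        key = _normalize_label(label)
        if key is None:
            raise KeyError(label)
        return self.counts[_INDEX[key]]

    def as_dict(self) -> dict[str, int]:
        return {lab: c for lab, c in zip(ISOTOPE_LABELS, self.counts) if c > 0}

    @property
    def atom_count(self) -> int:
        return sum(self.counts)

    def is_empty(self) -> bool:
        return self.atom_count == 0

    def collapsed_counts(self) -> tuple[int, ...]:
        """Element totals with heavy isotopes folded into their light element.

        Used where only elemental composition matters (e.g. deciding whether a
        heavy isotopologue of a fragment could still originate from a given
        precursor composition).
        """
        vec = list(self.counts)
        for heavy, light in _HEAVY_TO_LIGHT.items():
            vec[_INDEX[light]] += vec[_INDEX[heavy]]
            vec[_INDEX[heavy]] = 0
        return tuple(vec)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "FormulaVector") -> "FormulaVector":
        return FormulaVector(
            tuple(a + b for a, b in zip(self.counts, other.counts)), self.charge
        )

    def with_charge(self, charge: int) -> "FormulaVector":
        return FormulaVector(self.counts, charge)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_formula(self)


def _normalize_label(label: str) -> str | None:
    label = label.strip()
    if label in _INDEX:
        return label
    bracketed = f"[{label}]"
    if bracketed in _INDEX:
        return bracketed
    return None


# ---------------------------------------------------------------------------
# mass arithmetic
# ---------------------------------------------------------------------------

def exact_mass(v: FormulaVector) -> float:
    """Sum of monoisotopic atomic masses in Da (no electron correction)."""
    return sum(c * m for c, m in zip(v.counts, _MASS_VECTOR))


def ion_mz(v: FormulaVector) -> float:
    """m/z of a singly charged ion: the atomic-mass sum corrected for the
    electron removed (+1) or gained (-1)."""
    if v.charge == 1:
        return exact_mass(v) - ELECTRON_MASS
    if v.charge == -1:
        return exact_mass(v) + ELECTRON_MASS
    raise ValueError("ion_mz requires a singly charged ion (charge +1 or -1)")


def mass_error_ppm(predicted: float, measured: float) -> float:
    """Magnitude of the relative mass error in parts per million."""
    if predicted <= 0:
        raise ValueError("predicted mass must be positive")
    return abs(predicted - measured) / predicted * 1e6


# ---------------------------------------------------------------------------
# chemical consistency
# ---------------------------------------------------------------------------

def consistent(parent: FormulaVector, child: FormulaVector) -> bool:
    """True iff ``parent`` can decompose into ``child`` plus a non-empty
    neutral molecule: equal charges and a componentwise >= relation with at
    least one strict inequality.  Heavy isotopes are independent dimensions,
    so a 13C-containing fragment cannot arise from an all-12C parent."""
    if parent.charge != child.charge or parent.charge == 0:
        return False
    diff_positive = False
    for p, c in zip(parent.counts, child.counts):
        if p < c:
            return False
        if p > c:
            diff_positive = True
    return diff_positive


def neutral_loss(parent: FormulaVector, child: FormulaVector) -> FormulaVector:
    """The neutral molecule released when ``parent`` fragments to ``child``."""
    if not consistent(parent, child):
        raise ValueError(
            f"{format_formula(parent)} cannot decompose into {format_formula(child)}"
        )
    return FormulaVector(
        tuple(p - c for p, c in zip(parent.counts, child.counts)), charge=0
    )


# ---------------------------------------------------------------------------
# text notation
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"(\[13C\]|\[34S\]|Cl|Na|[CSONHFKP])(\d*)")


def parse_formula(text: str) -> FormulaVector:
    """Parse formula notation like ``"C6NH6+"`` or ``"C14[13C]ON2H13+"``.

    An omitted subscript means one atom; a trailing ``+``/``-`` sets the
    charge; unknown symbols raise ``ValueError`` naming the offender.
    """
    s = text.strip().replace("−", "-")  # unicode minus
    charge = 0
    if s.endswith("+"):
        charge, s = 1, s[:-1]
    elif s.endswith("-"):
        charge, s = -1, s[:-1]
    vec = [0] * len(ISOTOPE_LABELS)
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None:
            bad = re.match(r"\[[^\]]*\]|[A-Za-z][a-z]?|.", s[pos:]).group(0)
            raise ValueError(f"unknown element or isotope symbol: {bad!r}")
        label, digits = m.group(1), m.group(2)
        vec[_INDEX[label]] += int(digits) if digits else 1
        pos = m.end()
    return FormulaVector(tuple(vec), charge)


def format_formula(v: FormulaVector) -> str:
    """Canonical formula string: fixed element order (C, [13C], S, [34S],
    O, N, H, then the rest alphabetically), subscript 1 omitted, trailing
    charge sign for ions."""
    parts = []
    for label, count in zip(ISOTOPE_LABELS, v.counts):
        if count == 0:
            continue
        parts.append(label if count == 1 else f"{label}{count}")
    body = "".join(parts)
    if v.charge == 1:
        return body + "+"
    if v.charge == -1:
        return body + "-"
    return body


def formula(text_or_counts: str | Mapping[str, int] | FormulaVector,
            charge: int | None = None) -> FormulaVector:
    """Convenience coercion used across the package and the CLI."""
    if isinstance(text_or_counts, FormulaVector):
        v = text_or_counts
    elif isinstance(text_or_counts, str):
        v = parse_formula(text_or_counts)
    else:
        v = FormulaVector.from_dict(text_or_counts)
    if charge is not None:
        v = v.with_charge(charge)
    return v
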