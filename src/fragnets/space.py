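"""Candidate molecular-formula enumeration.

For each measured m/z, the chemical space of explanations is every formula
vector within user-supplied maximum atomic subscripts whose ion m/z falls in
the peak's own tolerance window.  The enumeration is an exact bounded
depth-first search over the isotope dimensions (heaviest first) with
mass-interval pruning: no heuristics, and complete within the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .chem import (
    ELECTRON_MASS,
    ISOTOPE_LABELS,
    ISOTOPE_MASSES,
    FormulaVector,
    consistent,
    format_formula,
    ion_mz,
    mass_error_ppm,
)
from .peaks import Peak

__all__ = ["SubscriptBounds", "Candidate", "enumerate_formulas", "fragment_space"]

_INDEX = {label: i for i, label in enumerate(ISOTOPE_LABELS)}
_HEAVY_DEFAULTS = {"[13C]": "C", "[34S]": "S"}


@dataclass(frozen=True)
class SubscriptBounds:
    """Maximum atomic subscript per isotope dimension.

    Heavy isotopes default to at most one atom (a single 13C or 34S
    isotopologue is the realistic annotatable case) whenever the
    corresponding light element is allowed at all; pass explicit values to
    override, including 0 to disable heavy isotopologues.
    """

    max_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.max_counts) != len(ISOTOPE_LABELS):
            raise ValueError(f"bounds must have {len(ISOTOPE_LABELS)} dimensions")
        if any((not isinstance(c, int)) or c < 0 for c in self.max_counts):
            raise ValueError("subscript bounds must be non-negative integers")
        if all(c == 0 for c in self.max_counts):
            raise ValueError("at least one subscript bound must be positive")

    @classmethod
    def from_dict(cls, bounds: Mapping[str, int]) -> "SubscriptBounds":
        vec = [0] * len(ISOTOPE_LABELS)
        seen = set()
        for label, n in bounds.items():
            key = label.strip()
            if key not in _INDEX and f"[{key}]" in _INDEX:
                key = f"[{key}]"
            if key not in _INDEX:
                raise ValueError(f"unknown element or isotope symbol: {label!r}")
            if int(n) < 0:
                raise ValueError(f"negative subscript bound for {label!r}")
            vec[_INDEX[key]] = int(n)
            seen.add(key)
        for heavy, light in _HEAVY_DEFAULTS.items():
            if heavy not in seen and vec[_INDEX[light]] > 0:
                vec[_INDEX[heavy]] = 1
        return cls(tuple(vec))

    def __getitem__(self, label: str) -> int:
        return self.max_counts[_INDEX[label]]


@dataclass(frozen=True)
class Candidate:
    """A formula proposed for a peak, with its predicted ion m/z and the
    ppm deviation from the measured value."""

    formula: FormulaVector
    predicted_mz: float
    error_ppm: float

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{format_formula(self.formula)} ({self.error_ppm:.1f} ppm)"


def enumerate_formulas(
    target_mz: float,
    tol_ppm: float,
    bounds: SubscriptBounds,
    ionization: str = "+",
) -> list[Candidate]:
    """All formulas within ``bounds`` whose ion m/z lies within
    ``target_mz * (1 +/- tol_ppm * 1e-6)``, sorted by ascending |error|.

    The search walks the isotope dimensions in order of decreasing atomic
    mass and prunes any branch whose remaining dimensions cannot bring the
    accumulated mass into the window, which makes it exact and fast even at
    generous bounds.
    """
    if target_mz <= 0:
        raise ValueError("target m/z must be positive")
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if ionization not in ("+", "-"):
        raise ValueError("ionization must be '+' or '-'")
    charge = 1 if ionization == "+" else -1
    # ion m/z window -> neutral atomic-mass-sum window
    shift = ELECTRON_MASS * charge
    lo = target_mz * (1 - tol_ppm * 1e-6) + shift
    hi = target_mz * (1 + tol_ppm * 1e-6) + shift

    dims = [i for i in range(len(ISOTOPE_LABELS)) if bounds.max_counts[i] > 0]
    dims.sort(key=lambda i: -ISOTOPE_MASSES[ISOTOPE_LABELS[i]])
    masses = [ISOTOPE_MASSES[ISOTOPE_LABELS[i]] for i in dims]
    caps = [bounds.max_counts[i] for i in dims]
    # max mass attainable from dimensions k..end
    suffix_max = [0.0] * (len(dims) + 1)
    for k in range(len(dims) - 1, -1, -1):
        suffix_max[k] = suffix_max[k + 1] + caps[k] * masses[k]

    out: list[Candidate] = []
    counts = [0] * len(ISOTOPE_LABELS)

    def descend(k: int, acc: float) -> None:
        if k == len(dims):
            if lo <= acc <= hi and any(counts):
                v = FormulaVector(tuple(counts), charge)
                pred = ion_mz(v)
                out.append(Candidate(v, pred, mass_error_ppm(pred, target_mz)))
            return
        m = masses[k]
        rest = suffix_max[k + 1]
        for c in range(caps[k] + 1):
            mass_here = acc + c * m
            if mass_here > hi:
                break
            if mass_here + rest < lo:
                continue
            counts[dims[k]] = c
            descend(k + 1, mass_here)
        counts[dims[k]] = 0

    descend(0, 0.0)
    out.sort(key=lambda c: (c.error_ppm, format_formula(c.formula)))
    return out


def _fits_collapsed(frag: FormulaVector, precursor: FormulaVector) -> bool:
    """Elemental containment ignoring the heavy/light isotope split.

    A heavy isotopologue of a genuine fragment (e.g. one 13C in place of a
    12C) is a physically possible peak -- the isolation window admits the
    M+1 precursor isotopologue -- so it must stay in the candidate space
    even though it is not a strict sub-formula of the monoisotopic
    precursor formula.
    """
    return all(f <= p for f, p in zip(frag.collapsed_counts(),
                                      precursor.collapsed_counts()))


def fragment_space(
    peaks: Sequence[Peak],
    precursor_candidates: Sequence[Candidate],
    bounds: SubscriptBounds,
    ionization: str = "+",
    default_tol_ppm: float = 10.0,
    tol_floor_ppm: float = 0.5,
    precursor_filter: str = "collapsed",
) -> dict[int, list[Candidate]]:
    """Candidate sets for product-ion peaks, keyed by peak index.

    Each peak is searched within its own confidence interval when one is
    defined (the per-peak-uncertainty idea at the heart of the method), else
    within ``default_tol_ppm``; a configurable floor avoids zero-width
    windows.  Candidates must be compatible with at least one precursor
    candidate: strict sub-formula containment (``precursor_filter='strict'``),
    isotope-collapsed elemental containment (``'collapsed'``, the default,
    which retains heavy-isotopologue explanations), or no filter (``'none'``).
    """
    if not precursor_candidates:
        raise ValueError("no precursor candidates: cannot build a fragment space")
    if precursor_filter not in ("collapsed", "strict", "none"):
        raise ValueError("precursor_filter must be 'collapsed', 'strict' or 'none'")

    spaces: dict[int, list[Candidate]] = {}
    for i, peak in enumerate(peaks):
        tol = peak.ci_ppm if peak.ci_ppm is not None else default_tol_ppm
        tol = max(tol, tol_floor_ppm)
        cands = enumerate_formulas(peak.centroid_mz, tol, bounds, ionization)
        if precursor_filter == "strict":
            cands = [c for c in cands
                     if any(consistent(p.formula, c.formula)
                            for p in precursor_candidates)]
        elif precursor_filter == "collapsed":
            cands = [c for c in cands
                     if any(_fits_collapsed(c.formula, p.formula)
                            for p in precursor_candidates)]
        spaces[i] = cands
    return spaces
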