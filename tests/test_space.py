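"""Candidate-formula enumeration: correctness against a brute-force grid."""

import itertools

import numpy as np
import pytest

from fragnets import (
    Candidate,
    Peak,
    SubscriptBounds,
    enumerate_formulas,
    formula,
    format_formula,
    fragment_space,
    ion_mz,
    mass_error_ppm,
)


def brute_force_grid(target_mz, tol_ppm, bounds, ionization="+"):
    """Independent oracle: full product grid over the subscript ranges,
    filtered by the ion m/z window."""
    charge = 1 if ionization == "+" else -1
    dims = range(len(bounds.max_counts))
    out = set()
    for combo in itertools.product(*(range(bounds.max_counts[d] + 1) for d in dims)):
        if not any(combo):
            continue
        v = formula(dict(zip(
            ("C", "[13C]", "S", "[34S]", "O", "N", "H", "Cl", "F", "K", "Na", "P"),
            combo)), charge=charge)
        if abs(ion_mz(v) - target_mz) / target_mz * 1e6 <= tol_ppm:
            out.add(format_formula(v))
    return out


class TestEnumerateFormulas:
    def test_sulfamethoxazole_precursor_found(self, smx_bounds):
        cands = enumerate_formulas(254.0603, 10.0, smx_bounds)
        assert "C10SO3N3H12+" in {format_formula(c.formula) for c in cands}

    def test_aniline_fragment_found(self, smx_bounds):
        cands = enumerate_formulas(92.0496, 10.0, smx_bounds)
        assert "C6NH6+" in {format_formula(c.formula) for c in cands}

    def test_ultranarrow_window_is_empty(self):
        bounds = SubscriptBounds.from_dict({"C": 3, "H": 8, "O": 2, "N": 2,
                                            "13C": 0})
        cands = enumerate_formulas(100.0000, 0.01, bounds)
        assert cands == []
        assert brute_force_grid(100.0000, 0.01, bounds) == set()

    def test_matches_brute_force_on_seeded_instances(self, chno_bounds):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            target = float(rng.uniform(20, 180))
            tol = float(rng.uniform(1, 2000))
            got = {format_formula(c.formula)
                   for c in enumerate_formulas(target, tol, chno_bounds)}
            assert got == brute_force_grid(target, tol, chno_bounds)

    def test_every_candidate_within_window_and_sorted(self, smx_bounds):
        cands = enumerate_formulas(156.0119, 10.0, smx_bounds)
        errors = []
        for c in cands:
            err = mass_error_ppm(ion_mz(c.formula), 156.0119)
            # independent re-check of the stored error against the window
            assert abs(ion_mz(c.formula) - 156.0119) / 156.0119 * 1e6 <= 10.0
            assert c.error_ppm == pytest.approx(err, rel=1e-9)
            errors.append(c.error_ppm)
        assert errors == sorted(errors)

    def test_monotone_in_tolerance_and_bounds(self, smx_bounds):
        narrow = {format_formula(c.formula)
                  for c in enumerate_formulas(156.0119, 5.0, smx_bounds)}
        wide = {format_formula(c.formula)
                for c in enumerate_formulas(156.0119, 25.0, smx_bounds)}
        assert narrow <= wide
        bigger = SubscriptBounds.from_dict(
            {"C": 12, "S": 2, "O": 4, "N": 4, "H": 14})
        grown = {format_formula(c.formula)
                 for c in enumerate_formulas(156.0119, 5.0, bigger)}
        assert narrow <= grown

    def test_negative_ionization_enumerates_anions(self):
        bounds = SubscriptBounds.from_dict({"C": 6, "N": 1, "H": 6})
        target = ion_mz(formula("C6NH5", charge=-1))
        cands = enumerate_formulas(target, 1.0, bounds, ionization="-")
        assert "C6NH5-" in {format_formula(c.formula) for c in cands}
        assert all(c.formula.charge == -1 for c in cands)

    def test_invalid_inputs(self, smx_bounds):
        with pytest.raises(ValueError):
            enumerate_formulas(-1.0, 10.0, smx_bounds)
        with pytest.raises(ValueError):
            enumerate_formulas(100.0, 0.0, smx_bounds)


def _peak(mz, ci=None):
    return Peak(centroid_mz=mz, ci_ppm=ci, n_points=1, total_intensity=1.0,
                relative_intensity_pct=10.0)


class TestFragmentSpace:
    def test_known_sulfonamide_fragment_present(self, smx_bounds):
        prec = enumerate_formulas(254.0603, 10.0, smx_bounds)
        spaces = fragment_space([_peak(156.0119)], prec, smx_bounds)
        assert "C6SO2NH6+" in {format_formula(c.formula) for c in spaces[0]}

    def test_elemental_budget_of_precursor_enforced(self, smx_bounds):
        # a fragment needing C11 cannot come from a C10 precursor
        big_bounds = SubscriptBounds.from_dict(
            {"C": 11, "S": 1, "O": 3, "N": 3, "H": 14})
        prec = [c for c in enumerate_formulas(254.0603, 10.0, big_bounds)
                if format_formula(c.formula) == "C10SO3N3H12+"]
        target = ion_mz(formula("C11H14", charge=1))
        spaces = fragment_space([_peak(target)], prec, big_bounds)
        assert all(f.formula.collapsed_counts()[0] <= 10 for f in spaces[0])

    def test_isotopologue_survives_collapsed_filter_not_strict(self, smx_bounds):
        prec = enumerate_formulas(254.0603, 10.0, smx_bounds)
        peak = _peak(157.0146)
        relaxed = fragment_space([peak], prec, smx_bounds,
                                 precursor_filter="collapsed")[0]
        strict = fragment_space([peak], prec, smx_bounds,
                                 precursor_filter="strict")[0]
        relaxed_names = {format_formula(c.formula) for c in relaxed}
        strict_names = {format_formula(c.formula) for c in strict}
        assert "C5[13C]SO2NH6+" in relaxed_names
        assert "C5[13C]SO2NH6+" not in strict_names
        assert strict_names <= relaxed_names

    def test_peak_ci_defines_its_window(self, smx_bounds):
        prec = enumerate_formulas(254.0603, 10.0, smx_bounds)
        loose = fragment_space([_peak(157.0146, ci=10.0)], prec, smx_bounds)[0]
        tight = fragment_space([_peak(157.0146, ci=2.0)], prec, smx_bounds)[0]
        assert {format_formula(c.formula) for c in tight} <= \
               {format_formula(c.formula) for c in loose}
        # C9O2NH3+ sits ~7.8 ppm away: inside 10 ppm, outside 2 ppm
        assert "C9O2NH3+" in {format_formula(c.formula) for c in loose}
        assert "C9O2NH3+" not in {format_formula(c.formula) for c in tight}

    def test_no_precursor_candidates_is_an_error(self, smx_bounds):
        with pytest.raises(ValueError):
            fragment_space([_peak(92.0496)], [], smx_bounds)
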