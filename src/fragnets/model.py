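"""Model/Results interface for spectrum annotation.

:class:`SpectrumModel` bundles the data of one DDA MS2 spectrum (profile
points or centroided peaks) with the run parameters and subscript bounds;
``fit()`` runs the full annotation -- precursor formula enumeration,
per-peak candidate spaces, fragments-network selection -- and returns an
:class:`AnnotationResult` carrying the selected network, the per-peak
estimates and uncertainties, and a results table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .chem import FormulaVector, consistent, format_formula
from .networks import (
    FragmentsNetwork,
    NetworkCapExceeded,
    count_networks,
    select_best,
)
from .params import UNANNOTATED, RunParameters
from .peaks import Peak, pick_peaks
from .space import Candidate, SubscriptBounds, enumerate_formulas, fragment_space

__all__ = ["PrecursorNotFound", "ResultRow", "AnnotationResult", "SpectrumModel",
           "annotate_peaks"]


class PrecursorNotFound(ValueError):
    """No precursor peak or no precursor formula candidate within tolerance."""


@dataclass(frozen=True)
class ResultRow:
    """One row of the results table (one reported peak)."""

    measured_mz: float
    molecular_formula: str = UNANNOTATED
    mass_error_ppm: float | None = None
    predicted_mz: float | None = None
    ci_ppm: float | None = None
    relative_intensity_pct: float = 0.0
    n_points: int = 1
    is_precursor: bool = False
    normality_warning: bool = False


#: Results-table column order and headers.
RESULT_COLUMNS = (
    "Molecular formula",
    "Mass error (ppm)",
    "Predicted m/z (Da)",
    "Measured m/z (Da)",
    "Confidence interval (ppm)",
    "Relative intensity (%)",
    "#Data points",
)


@dataclass(frozen=True)
class AnnotationResult:
    """The fitted annotation of one MS2 spectrum."""

    rows: tuple[ResultRow, ...]
    network: FragmentsNetwork
    precursor_formula: FormulaVector
    target_mz: float
    n_networks: int
    selection_mode: str
    params: RunParameters

    @property
    def grade(self) -> int:
        return self.network.grade

    @property
    def annotated_fraction(self) -> float:
        """Share of reported peaks that received a formula."""
        if not self.rows:
            return 0.0
        hits = sum(1 for r in self.rows if r.molecular_formula != UNANNOTATED)
        return hits / len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        """Results as a DataFrame with the canonical columns (unrounded)."""
        data = {
            "Molecular formula": [r.molecular_formula for r in self.rows],
            "Mass error (ppm)": [r.mass_error_ppm for r in self.rows],
            "Predicted m/z (Da)": [r.predicted_mz for r in self.rows],
            "Measured m/z (Da)": [r.measured_mz for r in self.rows],
            "Confidence interval (ppm)": [r.ci_ppm for r in self.rows],
            "Relative intensity (%)": [r.relative_intensity_pct for r in self.rows],
            "#Data points": [r.n_points for r in self.rows],
        }
        return pd.DataFrame(data, columns=list(RESULT_COLUMNS))

    def summary(self) -> str:
        n = self.network.n_nodes
        max_edges = n * (n - 1) // 2
        lines = [
            "Fragments-network annotation",
            "=" * 60,
            f"Target m/z:            {self.target_mz:.4f}",
            f"Precursor formula:     {format_formula(self.precursor_formula)}",
            f"Network nodes:         {n}",
            f"Network grade (edges): {self.network.grade} / {max_edges}",
            f"Assignments examined:  {self.n_networks} ({self.selection_mode} mode)",
            f"Annotated peaks:       "
            f"{sum(1 for r in self.rows if r.molecular_formula != UNANNOTATED)}"
            f" of {len(self.rows)}",
            "",
        ]
        def fmt(spec):
            return lambda x: "" if pd.isna(x) else format(x, spec)

        frame = self.to_frame().copy()
        frame["Mass error (ppm)"] = frame["Mass error (ppm)"].map(fmt(".1f"))
        frame["Predicted m/z (Da)"] = frame["Predicted m/z (Da)"].map(fmt(".7f"))
        frame["Measured m/z (Da)"] = frame["Measured m/z (Da)"].map(fmt(".7f"))
        frame["Confidence interval (ppm)"] = frame[
            "Confidence interval (ppm)"].map(fmt(".1f"))
        frame["Relative intensity (%)"] = frame["Relative intensity (%)"].map(
            fmt(".1f"))
        lines.append(frame.to_string(index=False))
        return "\n".join(lines)


def _find_precursor_peak(peaks: Sequence[Peak], target_mz: float,
                         window_da: float) -> int:
    best, best_d = None, None
    for i, p in enumerate(peaks):
        d = abs(p.centroid_mz - target_mz)
        if d <= window_da and (best_d is None or d < best_d):
            best, best_d = i, d
    if best is None:
        nearest = min(peaks, key=lambda p: abs(p.centroid_mz - target_mz),
                      default=None)
        hint = f"; nearest peak at m/z {nearest.centroid_mz:.4f}" if nearest else ""
        raise PrecursorNotFound(
            f"no peak within {window_da} Da of target m/z {target_mz:.4f}{hint}")
    return best


def annotate_peaks(
    peaks: Sequence[Peak],
    target_mz: float,
    bounds: SubscriptBounds,
    params: RunParameters | None = None,
) -> AnnotationResult:
    """Annotate one MS2 spectrum given its peaks.

    Pipeline: locate the precursor peak near the target m/z; enumerate
    precursor formula candidates within that peak's tolerance; build
    per-fragment candidate spaces (peaks above the precursor window are
    excluded -- product ions are smaller than their precursor); select the
    maximum-grade fragments network; report one row per input peak, with
    the placeholder for candidate-less, above-precursor, or
    precursor-inconsistent peaks.
    """
    params = params or RunParameters()
    if not peaks:
        raise ValueError("no peaks to annotate")

    prec_idx = _find_precursor_peak(peaks, target_mz, params.precursor_match_da)
    prec_peak = peaks[prec_idx]
    prec_tol = prec_peak.ci_ppm if prec_peak.ci_ppm is not None else params.default_tol_ppm
    prec_tol = max(prec_tol, params.tol_floor_ppm)
    prec_cands = enumerate_formulas(prec_peak.centroid_mz, prec_tol, bounds,
                                    params.ionization)
    if not prec_cands and prec_tol < params.default_tol_ppm:
        # The precursor is a mandatory node asserted by the user; when its
        # own interval is so tight that no formula falls inside (expected in
        # ~5% of spectra for a 95% interval), widen once to the default
        # tolerance rather than aborting the whole annotation.
        warnings.warn(
            f"no precursor formula within the peak's own {prec_tol:.2f} ppm "
            f"interval; retrying at the default {params.default_tol_ppm} ppm",
            stacklevel=2)
        prec_tol = params.default_tol_ppm
        prec_cands = enumerate_formulas(prec_peak.centroid_mz, prec_tol,
                                        bounds, params.ionization)
    if not prec_cands:
        raise PrecursorNotFound(
            f"no precursor formula within {prec_tol:.2f} ppm of m/z "
            f"{prec_peak.centroid_mz:.4f} under the given bounds")

    # product ions must be below the precursor window
    upper = prec_peak.centroid_mz * (1 + prec_tol * 1e-6)
    frag_indices = [i for i, p in enumerate(peaks)
                    if i != prec_idx and p.centroid_mz <= upper]
    frag_peaks = [peaks[i] for i in frag_indices]

    spaces = fragment_space(
        frag_peaks, prec_cands, bounds,
        ionization=params.ionization,
        default_tol_ppm=params.default_tol_ppm,
        tol_floor_ppm=params.tol_floor_ppm,
    )
    node_indices = [prec_idx] + [frag_indices[k] for k in sorted(spaces)
                                 if spaces[k]]
    node_cands = [prec_cands] + [spaces[k] for k in sorted(spaces) if spaces[k]]

    n_networks = count_networks([len(c) for c in node_cands])
    mode = params.network_mode
    if mode == "auto":
        mode = "exact" if n_networks <= params.network_cap else "greedy"
    network = select_best(node_cands, mode=mode, cap=params.network_cap)

    prec_formula = network.assignment[0].formula
    assigned: dict[int, Candidate] = {
        peak_i: network.assignment[node_pos]
        for node_pos, peak_i in enumerate(node_indices)
    }

    rows = []
    for i, peak in enumerate(peaks):
        cand = assigned.get(i)
        keep = cand is not None
        if keep and i != prec_idx and params.require_precursor_consistency:
            keep = consistent(prec_formula, cand.formula)
        if keep:
            row = ResultRow(
                measured_mz=peak.centroid_mz,
                molecular_formula=format_formula(cand.formula),
                mass_error_ppm=cand.error_ppm,
                predicted_mz=cand.predicted_mz,
                ci_ppm=peak.ci_ppm,
                relative_intensity_pct=peak.relative_intensity_pct,
                n_points=peak.n_points,
                is_precursor=(i == prec_idx),
                normality_warning=peak.normality_warning,
            )
        else:
            row = ResultRow(
                measured_mz=peak.centroid_mz,
                ci_ppm=peak.ci_ppm,
                relative_intensity_pct=peak.relative_intensity_pct,
                n_points=peak.n_points,
                normality_warning=peak.normality_warning,
            )
        rows.append(row)

    return AnnotationResult(
        rows=tuple(rows),
        network=network,
        precursor_formula=prec_formula,
        target_mz=target_mz,
        n_networks=n_networks,
        selection_mode=mode,
        params=params,
    )


class SpectrumModel:
    """One MS2 spectrum plus annotation settings; ``fit()`` annotates it.

    Construct from raw profile points (:meth:`from_profile`), a centroided
    peak list (:meth:`from_centroided`), or an mzML file
    (:meth:`from_mzml`).
    """

    def __init__(self, peaks: Sequence[Peak], target_mz: float,
                 bounds: SubscriptBounds | Mapping[str, int],
                 params: RunParameters | None = None):
        if not isinstance(bounds, SubscriptBounds):
            bounds = SubscriptBounds.from_dict(bounds)
        self.peaks = list(peaks)
        self.target_mz = float(target_mz)
        self.bounds = bounds
        self.params = params or RunParameters()

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_profile(cls, points, target_mz, bounds,
                     params: RunParameters | None = None) -> "SpectrumModel":
        """From raw profile-mode (m/z, intensity) points."""
        params = params or RunParameters()
        peaks = pick_peaks(
            points,
            noise_threshold=params.noise_threshold,
            gap_ppm=params.gap_ppm,
            confidence_level=params.confidence_level,
            min_cluster_points=params.min_cluster_points,
            intensity_floor_pct=params.intensity_floor_pct,
            weighted=params.weighted_centroid,
        )
        return cls(peaks, target_mz, bounds, params)

    @classmethod
    def from_centroided(cls, peak_list, target_mz, bounds,
                        params: RunParameters | None = None) -> "SpectrumModel":
        """From an already centroided (m/z, intensity) list.

        No per-peak confidence interval exists, so every peak is searched at
        the fixed default tolerance, and peaks below the relative-intensity
        floor are dropped before annotation.
        """
        params = params or RunParameters()
        pairs = [(float(m), float(i)) for m, i in peak_list]
        total = sum(i for _, i in pairs)
        peaks = []
        for m, i in sorted(pairs):
            rel = 100.0 * i / total if total > 0 else 100.0
            if rel < params.intensity_floor_pct:
                continue
            peaks.append(Peak(centroid_mz=m, ci_ppm=None, n_points=1,
                              total_intensity=i, relative_intensity_pct=rel))
        return cls(peaks, target_mz, bounds, params)

    @classmethod
    def from_mzml(cls, path, target_mz, bounds,
                  params: RunParameters | None = None) -> "SpectrumModel":
        """From an mzML file: selects the MS2 scan whose recorded precursor
        is nearest the target, then routes by profile/centroid mode."""
        from .io import read_mzml, select_ms2

        params = params or RunParameters()
        scans = read_mzml(path)
        scan = select_ms2(scans, target_mz, params.precursor_match_da)
        points = list(zip(scan.mz, scan.intensity))
        if scan.is_profile:
            return cls.from_profile(points, target_mz, bounds, params)
        return cls.from_centroided(points, target_mz, bounds, params)

    @classmethod
    def from_simulation(cls, spec, bounds=None,
                        params: RunParameters | None = None) -> "SpectrumModel":
        """From a synthetic-spectrum specification (ground truth discarded;
        use :func:`fragnets.simulate.simulate_spectrum` directly to keep it)."""
        from .simulate import simulate_spectrum

        synth = simulate_spectrum(spec)
        if bounds is None:
            bounds = synth.default_bounds()
        return cls.from_profile(synth.points, synth.precursor_mz, bounds, params)

    # -- fitting -----------------------------------------------------------
    def fit(self) -> AnnotationResult:
        return annotate_peaks(self.peaks, self.target_mz, self.bounds, self.params)
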