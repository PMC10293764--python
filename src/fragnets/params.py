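"""Run parameters shared by the library, the parameter file and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["RunParameters", "UNANNOTATED"]

#: Placeholder written in the results table for peaks without an annotation.
UNANNOTATED = "–"  # en dash


@dataclass(frozen=True)
class RunParameters:
    """Tunable run parameters.

    noise_threshold
        Intensity floor for raw profile points (counts).  The dominant
        runtime knob: everything below it is discarded before clustering.
    ionization
        '+' annotates cations (electron mass subtracted), '-' anions.
    default_tol_ppm
        Mass tolerance used wherever a peak has no confidence interval of
        its own -- in particular for centroided peak lists.
    gap_ppm
        Relative gap between consecutive profile points above which a new
        peak cluster starts.
    confidence_level
        Two-sided level of the per-peak t-interval of the mean m/z.
    intensity_floor_pct
        Peaks contributing less than this percentage of the total spectrum
        intensity are dropped in centroided mode, and undersized clusters
        below it are dropped in profile mode.
    network_mode
        'exact' (optimal, refuses above network_cap), 'greedy'
        (deterministic hill-climb), or 'auto' (exact, falling back to
        greedy above the cap).
    network_cap
        Maximum number of assignments exact enumeration will attempt.
    min_cluster_points
        Smallest cluster reported as a peak unless intensity-dominant.
    tol_floor_ppm
        Lower bound on any per-peak search window, so that an extremely
        tight confidence interval cannot collapse the candidate space.
    precursor_match_da
        Absolute window for locating the precursor peak around the target
        m/z (a typical quadrupole isolation half-width).
    require_precursor_consistency
        Report a fragment annotation only when it is chemically consistent
        with the selected precursor formula (every product ion must arise
        from the precursor); turn off to keep all selected formulas.
    weighted_centroid
        Intensity-weighted centroid (default) versus plain mean.
    """

    noise_threshold: float = 1000.0
    ionization: str = "+"
    default_tol_ppm: float = 10.0
    gap_ppm: float = 10.0
    confidence_level: float = 0.95
    intensity_floor_pct: float = 1.0
    network_mode: str = "auto"
    network_cap: int = 10**6
    min_cluster_points: int = 3
    tol_floor_ppm: float = 0.5
    precursor_match_da: float = 0.5
    require_precursor_consistency: bool = True
    weighted_centroid: bool = True

    def __post_init__(self) -> None:
        if self.ionization not in ("+", "-"):
            raise ValueError("ionization must be '+' or '-'")
        for name in ("noise_threshold", "default_tol_ppm", "gap_ppm",
                     "intensity_floor_pct", "tol_floor_ppm", "precursor_match_da"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must be in (0, 1)")
        if self.network_mode not in ("exact", "greedy", "auto"):
            raise ValueError("network_mode must be 'exact', 'greedy' or 'auto'")
        if self.network_cap < 1 or self.min_cluster_points < 1:
            raise ValueError("network_cap and min_cluster_points must be >= 1")

    def replace(self, **changes) -> "RunParameters":
        return replace(self, **changes)
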