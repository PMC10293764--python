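"""Synthetic profile-mode MS2 spectra with known ground truth.

The generator realises exactly the measurement model the annotation method
assumes: each true fragment ion contributes a cluster of raw points whose
m/z values are normally distributed around the ion's exact m/z (spread and
optional calibration bias in ppm), with a Gaussian-shaped intensity profile
across the cluster as in Orbitrap profile peaks; uniform noise points are
sprinkled over the scan range.  Every point is tagged in the truth map, so
noise filtering, clustering, centroiding, interval coverage and end-to-end
formula recovery are all directly assertable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import FormulaVector, format_formula, ion_mz, parse_formula
from .peaks import ProfilePoint
from .space import SubscriptBounds

__all__ = ["SimulationSpec", "SyntheticSpectrum", "simulate_spectrum",
           "SULFAMETHOXAZOLE_FRAGMENTS"]

#: Known fragment ions of protonated sulfamethoxazole (the worked example
#: used throughout the tests), largest last = precursor.
SULFAMETHOXAZOLE_FRAGMENTS: tuple[str, ...] = (
    "C5H5+",
    "C4NH6+",
    "C6NH6+",
    "C6NH7+",
    "C4ON2H7+",
    "C6ONH6+",
    "C6ONH8+",
    "C8N3H8+",
    "C8N3H9+",
    "C8N3H10+",
    "C6SO2NH6+",
    "C9N3H10+",
    "C10ON3H10+",
    "C10SO3N3H12+",
)


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one synthetic spectrum.

    ``true_fragments`` maps ion formulas (strings or vectors) to relative
    abundances; the heaviest ion is taken as the precursor.  ``sigma_ppm``
    is the m/z spread of the profile points around each true ion m/z,
    ``points_per_peak`` the cluster size, ``calibration_bias_ppm`` a
    systematic shift applied to every true m/z.  Noise points are uniform
    in m/z over the scan range with intensities uniform in
    ``noise_intensity_range``.
    """

    true_fragments: tuple = tuple((f, 1.0) for f in SULFAMETHOXAZOLE_FRAGMENTS)
    sigma_ppm: float = 3.0
    points_per_peak: int = 8
    calibration_bias_ppm: float = 0.0
    noise_points: int = 200
    noise_intensity_range: tuple[float, float] = (10.0, 800.0)
    peak_intensity_scale: float = 1e5
    intensity_profile: str = "gaussian"  # or "flat"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_ppm < 0 or self.points_per_peak < 1:
            raise ValueError("sigma_ppm must be >= 0 and points_per_peak >= 1")
        if self.intensity_profile not in ("gaussian", "flat"):
            raise ValueError("intensity_profile must be 'gaussian' or 'flat'")

    def ions(self) -> list[tuple[FormulaVector, float]]:
        out = []
        for item, abundance in self.true_fragments:
            v = parse_formula(item) if isinstance(item, str) else item
            out.append((v, float(abundance)))
        return out


@dataclass(frozen=True)
class SyntheticSpectrum:
    """Simulated profile points plus the ground truth behind them."""

    points: tuple[ProfilePoint, ...]
    #: (formula, true ion m/z incl. calibration bias) per simulated fragment
    truth: tuple[tuple[FormulaVector, float], ...]
    #: parallel to ``points``: True where the point is noise
    noise_mask: tuple[bool, ...]
    precursor_mz: float
    spec: SimulationSpec

    def true_mz(self, formula: FormulaVector | str) -> float:
        target = formula if isinstance(formula, str) else format_formula(formula)
        for v, mz in self.truth:
            if format_formula(v) == target:
                return mz
        raise KeyError(target)

    def default_bounds(self) -> SubscriptBounds:
        """Elementwise maxima over the true fragments: the bounds a user who
        knows the analyte's composition would write down."""
        maxima = [0] * len(self.truth[0][0].counts)
        for v, _ in self.truth:
            maxima = [max(a, b) for a, b in zip(maxima, v.counts)]
        from .chem import ISOTOPE_LABELS

        return SubscriptBounds.from_dict(
            {lab: m for lab, m in zip(ISOTOPE_LABELS, maxima) if m > 0})


def simulate_spectrum(spec: SimulationSpec) -> SyntheticSpectrum:
    """Draw one synthetic profile-mode spectrum under ``spec``.

    Deterministic for a fixed seed.  Points are returned sorted by m/z,
    with the noise mask permuted accordingly.
    """
    rng = np.random.default_rng(spec.seed)
    ions = spec.ions()
    if not ions:
        raise ValueError("at least one true fragment is required")
    truth = []
    mz_list: list[float] = []
    inten_list: list[float] = []
    noise_flags: list[bool] = []

    for v, abundance in ions:
        mz0 = ion_mz(v) * (1 + spec.calibration_bias_ppm * 1e-6)
        truth.append((v, mz0))
        sigma_da = mz0 * spec.sigma_ppm * 1e-6
        draws = rng.normal(mz0, sigma_da, spec.points_per_peak) if sigma_da > 0 \
            else np.full(spec.points_per_peak, mz0)
        base = abundance * spec.peak_intensity_scale
        if spec.intensity_profile == "gaussian" and sigma_da > 0:
            shape = np.exp(-0.5 * ((draws - mz0) / sigma_da) ** 2)
        else:
            shape = np.ones_like(draws)
        heights = base * shape * rng.uniform(0.8, 1.2, spec.points_per_peak)
        mz_list.extend(draws.tolist())
        inten_list.extend(heights.tolist())
        noise_flags.extend([False] * spec.points_per_peak)

    if spec.noise_points > 0:
        lo = min(mz for _, mz in truth) * 0.5
        hi = max(mz for _, mz in truth) * 1.1
        nmz = rng.uniform(lo, hi, spec.noise_points)
        nint = rng.uniform(*spec.noise_intensity_range, spec.noise_points)
        mz_list.extend(nmz.tolist())
        inten_list.extend(nint.tolist())
        noise_flags.extend([True] * spec.noise_points)

    order = np.argsort(mz_list, kind="stable")
    points = tuple(ProfilePoint(mz_list[i], inten_list[i]) for i in order)
    mask = tuple(noise_flags[i] for i in order)
    precursor_mz = max(mz for _, mz in truth)
    return SyntheticSpectrum(points=points, truth=tuple(truth),
                             noise_mask=mask, precursor_mz=precursor_mz,
                             spec=spec)
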