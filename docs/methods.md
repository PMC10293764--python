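# Methods

## Measurement model and assumptions

The package annotates one data-dependent-acquisition MS2 spectrum at a
time. Its measurement model is:

1. every raw profile signal is one data point;
2. the m/z values of the points of one peak are normally distributed
   around the true ion m/z (verified per peak with a Shapiro–Wilk test;
   a rejection at p < 0.05 sets a warning flag on the peak but does not
   drop it, since the test is a diagnostic, not a gate);
3. fragmentation is decomposition of an ion into a smaller ion plus a
   neutral molecule, so the formulas of a genuine parent/child pair differ
   by a componentwise non-negative, non-empty vector (the neutral loss);
4. each peak corresponds to a unique ion species with a unique annotation;
5. all ions carry a single charge;
6. product ions are smaller than the precursor ion; and
7. the formula alphabet is H, C, N, O, F, Na, P, S, Cl, K plus ¹³C and
   ³⁴S as independent dimensions.

Atomic masses are CODATA/AME monoisotopic values (H 1.00782503207,
C 12 exactly, ¹³C 13.00335484, N 14.00307401, O 15.99491462, F 18.99840316,
Na 22.98976928, P 30.97376200, S 31.97207117, ³⁴S 33.96786701,
Cl 34.96885268, K 38.96370649; electron 5.4857991·10⁻⁴ Da). Ion m/z is the
atomic-mass sum minus (cation) or plus (anion) one electron mass.
Negative-mode annotation differs only in the sign of the charge carrier.

## Peak statistics

Points below the intensity threshold (`noise_threshold`, the dominant
runtime knob) are discarded. Sorted points are clustered greedily: a new
peak starts wherever the gap to the previous point exceeds `gap_ppm`
(default 10 ppm) of the local m/z. A relative rule is used because
Orbitrap peak widths scale with m/z; the value is larger than any plausible
within-peak point spacing at the simulated spreads and far smaller than
isobaric peak separations in the worked examples.

Per cluster the package reports:

- centroid: intensity-weighted mean m/z (a plain mean is available via
  `weighted_centroid=False` for sensitivity checks);
- confidence interval: `t(level, n−1) · s/√n` in ppm of the centroid, with
  `s` the unweighted sample standard deviation and level 0.95 two-sided by
  default (the conventional reading of a "confidence interval"). With a
  Gaussian intensity profile the weighted centroid is strictly more
  precise than the plain mean, so this interval is conservative for the
  default centroid and exact for the unweighted one — the coverage test
  uses the unweighted flag for that reason;
- a single-point cluster has no dispersion estimate: its interval is
  undefined (never zero) and downstream code substitutes the default
  tolerance;
- relative intensity: percent of the total retained spectrum intensity
  (chosen over percent-of-base-peak because the centroided-mode filter is
  phrased as a contribution to total intensity);
- clusters smaller than `min_cluster_points` (default 3, the Shapiro–Wilk
  minimum) are kept only when intensity-dominant (≥ `intensity_floor_pct`
  of total, default 1%).

## Candidate spaces

For each peak the candidate set is every formula within the subscript
bounds whose ion m/z falls inside the peak's own interval (floored at
`tol_floor_ppm`, default 0.5 ppm, so a lucky ultra-tight interval cannot
collapse the space); centroided input has no intervals and uses a fixed
default of 10 ppm. The enumeration is a depth-first search over dimensions
ordered by decreasing atomic mass, pruning when the remaining dimensions
cannot reach the mass window; it is exact (tested against a brute-force
product grid) and fast at realistic bounds. Heavy-isotope subscripts
default to at most 1, and only when the light element is allowed at all.

Fragment candidates must fit the elemental budget of at least one
precursor candidate *after collapsing heavy isotopes onto their light
elements*. The collapsed comparison (rather than strict sub-formula
containment) is deliberate: the isolation window of a DDA experiment
admits the M+1 precursor isotopologue, so peaks such as the ¹³C or ³⁴S
satellites of a fragment are physically real and their isotopologue
formulas must remain available as explanations. Strict containment and no
filter are available through `precursor_filter`.

## Network selection and reporting

An assignment of one candidate per peak defines a network whose edges are
all consistent (proper sub-formula) pairs, in either direction — the
relation is undirected for grading. Selection maximises the grade, then
minimises the summed |error|, then compares formula strings, making the
result deterministic. Exact mode enumerates assignments depth-first with
the upper bound C(n,2) − C(k,2) on edges still obtainable after fixing k
peaks, and refuses instances above `network_cap` (default 10⁶)
assignments; greedy mode seeds every node with its minimum-error candidate,
hill-climbs single-node swaps, and restarts from every single-candidate
perturbation of the optimum. Exact mode is the oracle for greedy mode in
the tests; `auto` (default) uses exact below the cap and greedy above it.

The precursor peak is a mandatory node: networks are compared only among
assignments that give it some formula from its own candidate set, and the
selected precursor formula is reported as the molecular formula of the
target. When the precursor peak's own interval contains no formula at all
(expected in about 5% of spectra, since the interval is a 95% one), the
precursor search widens once to the default tolerance instead of aborting;
fragments get no such fallback, because an empty fragment window is
informative ("this peak is not explainable at its own precision") whereas
an unannotatable precursor would discard the entire spectrum the user
explicitly asked about.

Reported annotations must be consistent with the selected precursor
formula; fragments whose winning candidate is not (typically
heavy-isotopologue formulas, which beat the alternatives on both edges and
mass error) are reported with the "–" placeholder, as are candidate-less
peaks and peaks above the precursor window. This precursor-consistency
gate — rather than a "degree ≥ 1 somewhere in the network" rule — is what
separates isotopologue satellites from genuine fragments in the bundled
reference spectra while keeping single-fragment spectra annotatable; it
can be disabled with `require_precursor_consistency=False`.

One bundled reference cell deserves mention: the sulfamethoxazole list
entry at 108.046 lies 14.9 ppm from its community annotation C₆ONH₆⁺
(predicted 108.0443902; raw-data measurements of the same fragment are
near 108.0444), so no formula exists within 10 ppm and the correct output
for that row is the placeholder. The acceptance test verifies the 14.9 ppm
distance explicitly instead of trusting the bundled metadata.

## Synthetic data

The generator draws, for each true fragment ion, `points_per_peak` m/z
values from Normal(m·(1 + bias·10⁻⁶), (m·σppm·10⁻⁶)²) with
intensity heights shaped as a Gaussian around the centre (Orbitrap profile
peaks are approximately Gaussian; a flat profile is available for
worst-case checks) times a ±20% uniform jitter, plus uniform noise points
tagged in the truth map. Defaults are σ = 3 ppm, 8 points per peak, 200
noise points below the default noise threshold, and the 14-fragment
sulfamethoxazole ion set.

What the simulations do and do not show: they validate the statistical
machinery (noise filtering, clustering, centroid bias, interval coverage,
formula recovery) under the model's own assumptions. They do not emulate
peak-shape asymmetry, coalescence of close isobars, space-charge calibration
drift within a scan, chimeric precursors, or detector saturation, so
passing them says nothing about those failure modes on real data. Problem
sizes used by the test suite and the acceptance script — 20 spectra for
recovery, 200 peaks for coverage — give binomial standard errors of about
1–1.5 percentage points, adequate for the ≥95% and ≈95% claims being
checked.

## Numerical and degenerate-input choices

- Mass window arithmetic is done in neutral-mass space (ion window shifted
  by the electron mass) to keep the enumeration loop branch-free.
- Zero-spread clusters: interval width 0, Shapiro–Wilk undefined.
- Ties everywhere (equal errors, equal grades) break on canonical formula
  strings, so repeated runs are byte-identical.
- Results tables print m/z to 7 decimals and ppm/intensity to 1 decimal;
  rounding is applied at report time only.

## Known limitations

- No valence or ring-double-bond-equivalent filtering: candidate spaces
  can contain chemically exotic formulas; the network grade, not chemistry
  rules, is the only arbiter.
- Singly charged ions and ±H adducts only.
- One MS2 scan at a time; no cross-scan chromatographic integration, no
  MS1 isotope-pattern scoring, no collision-energy ranking.
- Greedy mode is locally optimal only; exact mode is exponential in the
  worst case and capped.
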