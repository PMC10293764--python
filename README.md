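# fragnets

De novo annotation of Orbitrap DDA MS2 spectra through per-peak confidence
intervals and *fragments networks*.

`fragnets` is for mass spectrometrists who want molecular-formula
annotations of product-ion spectra without spectral libraries, databases or
any data beyond the spectrum itself: trace-organic screening, metabolomics
and natural-products work where the analyte may be unknown.

## The method

**Per-peak uncertainty.** In profile mode every spectral peak is a cloud of
raw (m/z, intensity) points tracing the m/z distribution of one ion
species; centroiding collapses it to a single number and discards the
spread. `fragnets` keeps the cloud: after an intensity noise filter, points
are clustered by a relative gap rule (default 10 ppm) and each cluster is
summarised by the intensity-weighted centroid, the classical t-interval of
the mean,

&nbsp;&nbsp;&nbsp;&nbsp;CI = t(α, n−1) · s / √n&nbsp;&nbsp;(expressed in ppm of the centroid),

a Shapiro–Wilk normality check of the m/z values, the point count and the
peak's share of total intensity. Each peak then carries *its own* mass
tolerance instead of one user-imposed number.

**Chemical space.** Candidate formulas are integer vectors over twelve
isotope dimensions (H, C, ¹³C, N, O, F, Na, P, S, ³⁴S, Cl, K) bounded by
user-supplied maximum subscripts. For a peak at m/z *m* with interval *w*
ppm, an exact bounded depth-first search enumerates every singly charged
formula whose ion m/z (atomic-mass sum ∓ the electron mass) lies in
*m*(1 ± *w*·10⁻⁶).

**Chemical consistency.** Fragmentation is modelled as decomposition of an
ion into a smaller ion plus a neutral molecule, e.g.

&nbsp;&nbsp;&nbsp;&nbsp;C_f₀c O_f₀o H_f₀h⁺ → C_f₁c O_f₁o H_f₁h⁺ + C_c O_o H_h,&nbsp;&nbsp;(f₀c, f₀o, f₀h) = (f₁c, f₁o, f₁h) + (c, o, h),

generalised to all twelve dimensions. Two ion formulas are *consistent*
when one is a proper sub-formula of the other; the componentwise
difference is the neutral loss.

**Fragments networks.** An assignment of one candidate per peak is a
network whose nodes are the assigned formulas and whose edges are all
consistent pairs; its *grade* is the edge count (at most n(n−1)/2 for n
nodes). With kᵢ candidates at peak i there are ∏kᵢ networks — five peaks
with five candidates each already span 3125. The annotation of the
spectrum is the maximum-grade network (ties: smallest summed mass error,
then lexicographic), found by exact enumeration with branch-and-bound up
to a configurable cap and by a deterministic greedy hill-climb beyond it.
Fragments whose selected formula is not consistent with the selected
precursor formula are reported unannotated: every genuine product ion must
derive from the precursor, so such peaks (typically heavy-isotopologue
signals) are flagged rather than force-fitted.

## Worked example

Annotate the bundled sulfamethoxazole MS2 peak list (protonated molecule
C₁₀H₁₁N₃O₃S + H⁺, target m/z 254.0603) at a fixed 10 ppm tolerance:

```
fragnets annotate-centroided examples/sulfamethoxazole_peaks.csv 254.0603 \
    --bounds examples/MaxAtomicSubscripts.csv --params examples/ParametersTable.csv
```

```
Fragments-network annotation
============================================================
Target m/z:            254.0603
Precursor formula:     C10SO3N3H12+
Network nodes:         15
Network grade (edges): 62 / 105
Assignments examined:  192 (exact mode)
Annotated peaks:       13 of 16

Molecular formula Mass error (ppm) Predicted m/z (Da) Measured m/z (Da) ...
            C5H5+              5.8         65.0385766        65.0382000
           C4NH6+              7.0         68.0494756        68.0490000
           C6NH6+              1.4         92.0494756        92.0496000
           ...
        C6SO2NH6+              3.4        156.0113760       156.0119000
                –                                           157.0146000
                –                                           158.0078000
         C9N3H10+              2.4        160.0869238       160.0873000
       C10ON3H10+              1.9        188.0818384       188.0822000
     C10SO3N3H12+              3.6        254.0593889       254.0603000
```

The precursor is identified as C₁₀SO₃N₃H₁₂⁺ and 13 of the 16 peaks receive
formulas that form a 62-edge network. The peaks at 157.0146 and 158.0078
stay unannotated ("–"): their best mass matches are the ¹³C and ³⁴S
isotopologues of the 156.0119 fragment, which cannot arise from the
monoisotopic precursor — the network selection recognises them as
inconsistent rather than forcing a poorer formula onto them.

The same model is available programmatically:

```python
from fragnets import SpectrumModel
from fragnets.datasets import load_reference_spectrum

ref = load_reference_spectrum("sulfamethoxazole")
result = SpectrumModel.from_centroided(ref.peaks, ref.target_mz, ref.bounds).fit()
print(result.summary())          # the table above
result.network.to_graph()        # networkx graph with neutral-loss edge labels
```

Profile-mode mzML files go through `SpectrumModel.from_mzml(path, target_mz,
bounds)` or `fragnets annotate run.mzML 254.0603 --bounds ...`, where each
peak is searched within its own confidence interval; `fragnets simulate`
writes a synthetic profile spectrum with a ground-truth sidecar, and
`fragnets exact-mass "C10SO3N3H12+"` prints exact mass (254.0599374 Da) and
ion m/z (254.0593889 Da).

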