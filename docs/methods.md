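# Methods

## Problem and model

Multiple reaction monitoring (MRM) on triple-quadrupole instruments needs,
per analyte, a precursor → product ion pair (transition) and the collision
energy (CE) at which the product is most abundant. `mrmgen` derives these
from MS/MS spectra of the same compound acquired at a small set of discrete
collision energies (the standard grid here is 0, 10, 20 and 40 eV):

1. **Fragment tracking.** Peaks recurring across the per-CE spectra are
   grouped into fragment traces with a ±0.5 Da tolerance. Grouping is
   iterative and greedy: the globally most intense unassigned peak seeds a
   trace, each other CE contributes its nearest unassigned peak within
   tolerance, and the procedure repeats until every peak is assigned. Greedy
   intensity-first seeding makes the assignment deterministic (ties break by
   lower CE, then lower m/z) and anchors each trace on its best-measured
   observation. The trace m/z is the intensity-weighted mean of its members.
2. **Trace QC.** A trace is usable when (a) it is detected at ≥ 3 of the
   measured CEs, (b) its intensity profile is unimodal within a noise
   tolerance and has no internal detected–absent–detected gap, and (c) its
   m/z lies ≥ 2.0 Da below the precursor. The precursor's own surviving
   trace always fails (c) and is reported in the QC output rather than
   silently dropped. These same filters screen out nonspecific in-source
   fragments, which persist without CE-dependent structure.
3. **CE modeling.** Each usable trace's CE–intensity profile is fitted with
   an interpolating univariate spline (`scipy.interpolate.UnivariateSpline`,
   degree 2, smoothing 0 by default, so the curve passes through every
   observation). The optimal CE is the spline maximum, located by dense grid
   search over the measured CE range; predictions below 5 eV or outside the
   range are clamped to 5 eV, the practical floor of QqQ collision cells.
4. **Transition selection.** Fragments are ranked by the spline intensity at
   their own optimal CE (order-equivalent, within a compound, to ranking by
   absolute intensity); ties prefer the fragment farther below the precursor
   and then the smaller m/z. The top fragment is the quantifier; the next
   fragment more than the grouping tolerance away in m/z is the qualifier
   (one by default, configurable). Each transition carries its fragment's
   own integer-rounded CE — quantifier and qualifier routinely peak at
   different energies.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| grouping tolerance | 0.5 | Da | m/z window for tracking a fragment across CEs, and the minimum m/z distance between selected transitions |
| min. CE count | 3 | — | detections required for a usable trace |
| shape noise tolerance | 0.10 | fraction of trace max | allowed non-monotonic wiggle in the unimodality check |
| min. separation | 2.0 | Da | required precursor − product distance |
| spline degree | 2 | — | interpolant degree (3 also interpolates a 4-point profile; 3-point traces always fit at ≤ 2) |
| smoothing | 0 | — | FITPACK `s`; 0 = exact interpolation |
| grid step | 0.1 | eV | argmax search resolution |
| clamp floor | 5 | eV | lowest reportable CE |
| CE range | 0–40 | eV | measured grid span and argmax window |
| ΔCE threshold | 7 | eV | benchmark summary agreement band |

The unimodality check is a brute-force rise-then-fall split test: a profile
passes if some split point exists such that no step before it falls, and no
step after it rises, by more than the tolerance. With ≤ 4 points this exact
test is cheap and has no tuning beyond the tolerance itself. The noise
tolerance (10 % of the trace maximum) is a design choice: small enough to
reject clearly bimodal profiles, large enough to ignore detector-level
ripple on a plateau.

## Numerical choices

- **Argmax by dense grid, not root-finding:** robust for any spline degree,
  trivially auditable against an independent brute-force scan (the test
  suite checks agreement with a 0.01 eV scan on 1000 random traces).
- **Plateau ties** resolve to the smallest CE attaining the maximum
  (gentler fragmentation); a relative tolerance of 1e-9 on the maximum
  absorbs interpolation round-off so exactly flat profiles report the lower
  range end rather than a round-off artifact.
- **Sub-range traces:** the spline is evaluated over the full configured CE
  range even when a trace is detected on a sub-range, so the fit
  extrapolates at the edges; the 5 eV clamp absorbs low-side extrapolation
  artifacts. Boundary maxima (e.g. a profile still rising at 40 eV) are
  reported at the boundary, unclamped.
- **Degenerate inputs:** single-point traces report their one observed CE;
  requested degrees above `n_points − 1` degrade with a logged notice;
  identical-m/z peaks within one scan are merged by summing intensity.

## Benchmarking and refinement

`compare_tables` scores a predicted transition table against a reference
with per-role product-m/z agreement at ±0.5 Da, signed ΔCE
(predicted − reference) for m/z-matched roles, and per-compound overlap (the
fraction of reference products recovered at the tolerance). Compounds whose
quantifier and qualifier are interchanged between the tables are flagged
*flipped*; the summary's quantifier-matched fraction counts a flip as a
mass-level match (the ion was recovered, the role priority differed), while
the per-compound booleans stay strict. ΔCE for flipped compounds is computed
against the swapped partner.

`refine_spline_config` selects among candidate spline settings by K-fold
cross-validation over compounds: per fold, predicted optimal CEs for the
held-out compounds are compared with empirical optima and summarized as
RMSE. The default scorer is the identity mapping (RMSE of predicted vs
empirical directly), which is fully reproducible; any scikit-learn regressor
can be supplied instead to model systematic prediction bias (empirical CE
regressed on predicted CE) before scoring. The candidate with the lowest
mean held-out RMSE wins.

## Synthetic data

The generator emulates per-compound fragment sets whose intensities follow
unimodal CE-dependent breakdown curves:

- fragment curves are Gaussian in CE,
  `amplitude · exp(−(CE − μ)² / 2σ²)`, the simplest unimodal shape
  consistent with observed breakdown behavior (shape functions are
  pluggable);
- the surviving precursor decays exponentially, `amplitude · 2^(−CE/t½)`;
- true peak CEs μ are drawn uniformly on [8, 35] eV and widths σ on
  [16, 22] eV. The widths correspond to FWHM ≈ 38–52 eV: broad curves on
  which a fragment is detectable across at least three of the four measured
  energies — the detection pattern the ≥ 3-CE QC rule presumes. Markedly
  narrower curves would be invisible at all but one grid energy and would
  carry too little information for any four-point fit;
- fragment amplitudes decay geometrically down the intensity ranking (top
  amplitude 10^U(4,5), successive ratios U(1.8, 4)), mimicking the
  dominant-base-peak structure of real MS/MS spectra;
- intensities are perturbed by mean-one lognormal multiplicative noise
  (default CV 10 %, reflecting ion-count heteroscedasticity), observed m/z
  values jitter with sd 0.005 Th, and samples below a detection floor (1 %
  of the compound's strongest signal) are dropped, creating realistic
  missingness;
- degenerate kinds exercise the QC filters: *single_ce* keeps only its
  largest sample, *erratic* permutes its samples across CEs, and
  *precursor_adjacent* sits 0.6–1.9 Da below the precursor. By default 25 %
  of panel compounds receive one extra fragment of each kind.

Panels are written as minimal centroided-MS2 mzML (64-bit little-endian
base64 arrays, uncompressed) plus a manifest and a ground-truth table, so
the exact file formats of a real analysis are exercised end to end.

What the generator does **not** emulate: isotope envelopes, chimeric
spectra, charge states, adducts, matrix effects, retention time, or
physically derived collision-cell energetics. Passing tests on synthetic
panels therefore demonstrate the correctness of tracking, filtering,
fitting and selection logic — not instrument-level accuracy on real
spectra, which depends on how well real breakdown curves match the unimodal
model.

## Problem sizes

The shipped tests and the reproduction script use panels of 6–100 compounds,
500-fragment recovery sweeps and 1000-trace argmax audits; all complete in a
few seconds on one CPU. Larger panels scale linearly in compounds and can be
generated with `mrmgen simulate -n <N>`.

## Known limitations

- A four-point profile constrains any interpolant only loosely between grid
  points; peak-CE recovery is worst for true optima inside the sparse
  20–40 eV interval.
- Quadratic/cubic extrapolation outside a trace's detected CE span is
  unreliable; it is tolerated because the clamp rule catches the low side
  and boundary maxima are reported at the boundary.
- The qualifier is not required to exceed any minimum fraction of the
  quantifier's intensity; very weak qualifiers may be emitted.
- No adduct annotation: transitions are precursor-m/z-centric by design.
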