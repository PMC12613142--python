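# mrmgen

Empirical generation of MRM (multiple reaction monitoring) transitions and
optimized collision energies from multi-collision-energy MS/MS spectra.

Targeted quantitation on triple-quadrupole (QqQ) instruments monitors fixed
precursor → product ion pairs, each at a tuned collision energy (CE).
Developing those transitions normally requires an authentic standard and
repeated instrument optimization per compound. `mrmgen` instead derives them
from MS/MS spectra already acquired at a handful of discrete collision
energies (0, 10, 20, 40 eV by default), for analysts building targeted
assays from spectral libraries or in-house multi-CE acquisitions.

## Method

For each compound, fragment ions are tracked across the per-CE spectra with
a ±0.5 Da tolerance, giving each fragment a breakdown curve — intensity
*I(CE)* sampled at the measured energies. After quality control (detection
at ≥ 3 energies, unimodal profile, product m/z ≥ 2.0 Da below the
precursor), each curve is fitted with an interpolating univariate spline
(degree *k* = 2, smoothing *s* = 0) and the optimal CE is its maximum,

    CE_opt = argmax I_spline(CE),  CE ∈ [0, 40] eV,

located by dense grid search (0.1 eV step) and clamped to 5 eV when the
maximum falls below 5 eV or outside the measured range. Fragments are ranked
by spline intensity at their own CE_opt; the top fragment becomes the
quantifier transition and the next distinct fragment (> 0.5 Da away) the
qualifier, each reported at its own integer-rounded CE. Benchmarking tools
compare predicted tables against reference tables (product m/z agreement at
±0.5 Da, signed ΔCE, transition overlap, flipped-role detection), and a
cross-validated refinement step selects among candidate spline
configurations. A synthetic generator produces multi-CE panels with known
ground truth for validation. See `docs/methods.md` for details.

## Worked example

```sh
mrmgen simulate -n 3 --seed 42 --out-dir demo
mrmgen build --mzml demo/panel.mzML --manifest demo/manifest.csv \
             --out-table demo/transitions.csv --qc-report demo/qc.csv
cat demo/transitions.csv
```

```
compound_id,polarity,precursor_mz,product_mz,ce_eV,role,rank
SYN00000,positive,673.0260,652.9649,24,quantifier,1
SYN00000,positive,673.0260,520.4069,27,qualifier,2
SYN00001,positive,819.8408,198.8664,35,quantifier,1
SYN00001,positive,819.8408,406.9654,19,qualifier,2
SYN00002,positive,155.5217,116.8326,9,quantifier,1
SYN00002,positive,155.5217,120.8882,21,qualifier,2
```

Each row is one transition: the compound's measured precursor m/z, the
selected product ion, the collision energy (eV) at which that ion's fitted
breakdown curve peaks, and its role. The quantifier is the most intense
surviving fragment at its optimum; the qualifier confirms identity and
typically peaks at a different energy. `build` also logs per-stage counts
(spectra loaded, traces rejected by reason, transitions emitted), and
rejected traces land in `demo/qc.csv` with their rejection reason.

Comparing a table against a reference (here, itself):

```sh
mrmgen benchmark demo/transitions.csv demo/transitions.csv
```

```
benchmark summary
  compounds compared:     3 (missing: 0)
  quantifier m/z matched: 1.000
  qualifier m/z matched:  1.000
  |dCE| <= 7 eV:        1.000
  mean |dCE|:             0.00 eV
  mean overlap:           1.000
```

The same functionality is available as a library
(`mrmgen.build_table`, `mrmgen.compare_tables`,
`mrmgen.refine_spline_config`, `mrmgen.simulate_panel`, ...).

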