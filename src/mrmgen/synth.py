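"""Synthetic multi-CE MS/MS data with known ground truth.

Fragment breakdown curves are modeled as Gaussians in collision energy
(intensity = amplitude * exp(-(ce - peak_ce)^2 / 2 width^2)); the surviving
precursor decays exponentially (amplitude * 2^(-ce / halflife)).  Sampling
the curves at the measured CE grid with lognormal multiplicative noise and a
detection floor yields realistic spectra whose true optimal CEs are known,
so every downstream stage can be validated end to end.  Degenerate fragment
kinds (single-CE, erratic, precursor-adjacent) exercise the QC filters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra_io import (
    CompoundSpectrumSet,
    MsmsSpectrum,
    Peak,
    ValidationError,
    write_mzml,
)

DEFAULT_CE_GRID = (0.0, 10.0, 20.0, 40.0)
#: intensities below this fraction of the compound's strongest signal are dropped
DEFAULT_DETECTION_FLOOR_FRAC = 0.01
#: default multiplicative intensity noise (coefficient of variation)
DEFAULT_NOISE_CV = 0.10
#: per-observation m/z jitter (Th, 1 sd) — small against the 0.5 Da tolerance
MZ_JITTER_SD = 0.005

# panel draw ranges (see docs/methods.md for rationale)
PEAK_CE_RANGE = (8.0, 35.0)
WIDTH_RANGE = (16.0, 22.0)
TOP_AMPLITUDE_LOG10_RANGE = (4.0, 5.0)
AMPLITUDE_STEP_RATIO_RANGE = (1.8, 4.0)
PRECURSOR_MZ_RANGE = (150.0, 900.0)
PRECURSOR_HALFLIFE_RANGE = (8.0, 20.0)
N_FRAGMENTS_RANGE = (2, 6)


class FragmentKind(enum.Enum):
    NORMAL = "normal"
    SINGLE_CE = "single_ce"
    ERRATIC = "erratic"
    PRECURSOR_ADJACENT = "precursor_adjacent"


@dataclass(frozen=True)
class FragmentSpec:
    """Ground truth for one synthetic fragment ion."""

    mz: float
    amplitude: float
    peak_ce: float
    width: float
    kind: FragmentKind = FragmentKind.NORMAL

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.width <= 0 or self.peak_ce < 0:
            raise ValidationError("fragment spec needs amplitude > 0, width > 0, peak_ce >= 0")


@dataclass
class CompoundSpec:
    """Ground truth for one synthetic compound."""

    compound_id: str
    polarity: str
    precursor_mz: float
    fragments: list[FragmentSpec]
    precursor_survival_halflife: float = 12.0
    precursor_amplitude: float = 5e4
    noise_cv: float = DEFAULT_NOISE_CV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        for f in self.fragments:
            if f.mz >= self.precursor_mz:
                raise ValidationError("fragment m/z must be below the precursor m/z")


def intensity_curve(frag: FragmentSpec, ce: float) -> float:
    """Noise-free breakdown-curve value for a fragment at one CE."""
    if ce < 0:
        raise ValidationError("ce must be >= 0")
    return frag.amplitude * float(np.exp(-((ce - frag.peak_ce) ** 2) / (2 * frag.width ** 2)))


def precursor_survival(amplitude: float, halflife: float, ce: float) -> float:
    """Exponentially decaying precursor intensity."""
    return amplitude * 2.0 ** (-ce / halflife)


def simulate_compound(spec: CompoundSpec, ce_grid: tuple[float, ...] = DEFAULT_CE_GRID,
                      detection_floor_frac: float = DEFAULT_DETECTION_FLOOR_FRAC,
                      ) -> tuple[CompoundSpectrumSet, pd.DataFrame]:
    """Sample one compound's spectra on the CE grid.

    Per fragment and CE: curve value times lognormal noise (CV = noise_cv,
    mean-one), dropped when below the detection floor (a fraction of the
    compound's largest noise-free signal).  Kind single_ce keeps only its
    largest sample; kind erratic permutes its samples across CEs; the
    precursor itself appears with an exponential survival curve.  Returns the
    spectrum set and a truth table (mz, kind, peak_ce, valid flag).
    """
    rng = np.random.default_rng(spec.seed)
    grid = tuple(sorted(ce_grid))
    # noise-free values, fragments + precursor survival row
    curves: list[tuple[float, np.ndarray, FragmentKind]] = []
    for frag in spec.fragments:
        curves.append((frag.mz, np.array([intensity_curve(frag, ce) for ce in grid]),
                       frag.kind))
    curves.append((spec.precursor_mz,
                   np.array([precursor_survival(spec.precursor_amplitude,
                                                spec.precursor_survival_halflife, ce)
                             for ce in grid]),
                   None))
    floor = detection_floor_frac * max(c[1].max() for c in curves)

    if spec.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(spec.noise_cv ** 2)))
    else:
        sigma = 0.0

    peaks_per_ce: dict[float, list[Peak]] = {ce: [] for ce in grid}
    for mz, clean, kind in curves:
        sampled = clean.copy()
        if sigma > 0:
            sampled = sampled * np.exp(rng.normal(0.0, sigma, len(grid)) - sigma ** 2 / 2)
        if kind is FragmentKind.ERRATIC:
            sampled = rng.permutation(sampled)
        if kind is FragmentKind.SINGLE_CE:
            keep = int(np.argmax(sampled))
            mask = np.zeros(len(grid), dtype=bool)
            mask[keep] = True
        else:
            mask = sampled >= floor
        for i, ce in enumerate(grid):
            if mask[i] and sampled[i] > 0:
                jitter = rng.normal(0.0, MZ_JITTER_SD) if MZ_JITTER_SD > 0 else 0.0
                peaks_per_ce[ce].append(Peak(mz + jitter, float(sampled[i])))

    spectra = {
        ce: MsmsSpectrum(spec.compound_id, spec.polarity, ce, spec.precursor_mz,
                         tuple(peaks))
        for ce, peaks in peaks_per_ce.items() if peaks
    }
    cset = CompoundSpectrumSet(spec.compound_id, spec.polarity, spec.precursor_mz, spectra)

    truth_rows = []
    for frag in spec.fragments:
        valid = (frag.kind is FragmentKind.NORMAL
                 and (spec.precursor_mz - frag.mz) >= 2.0)
        truth_rows.append({
            "compound_id": spec.compound_id, "polarity": cset.polarity,
            "mz": frag.mz, "kind": frag.kind.value, "peak_ce": frag.peak_ce,
            "amplitude": frag.amplitude, "width": frag.width, "valid": valid,
        })
    truth_rows.append({
        "compound_id": spec.compound_id, "polarity": cset.polarity,
        "mz": spec.precursor_mz, "kind": "precursor", "peak_ce": 0.0,
        "amplitude": spec.precursor_amplitude, "width": np.nan, "valid": False,
    })
    return cset, pd.DataFrame(truth_rows)


def random_compound_spec(rng: np.random.Generator, compound_id: str,
                         polarity: str = "positive",
                         extra_kinds: tuple[FragmentKind, ...] = (),
                         noise_cv: float = DEFAULT_NOISE_CV) -> CompoundSpec:
    """Draw one compound: 2-6 normal fragments with rank-ordered amplitudes
    decaying geometrically, plus optional degenerate fragments."""
    precursor = float(rng.uniform(*PRECURSOR_MZ_RANGE))
    n_frag = int(rng.integers(N_FRAGMENTS_RANGE[0], N_FRAGMENTS_RANGE[1] + 1))
    # distinct fragment m/z, all >= 2 Da below the precursor and >= 2 Da apart
    mzs: list[float] = []
    while len(mzs) < n_frag:
        cand = float(rng.uniform(50.0, precursor - 5.0))
        if all(abs(cand - m) > 2.0 for m in mzs):
            mzs.append(cand)
    amp = 10.0 ** rng.uniform(*TOP_AMPLITUDE_LOG10_RANGE)
    fragments = []
    for mz in mzs:
        fragments.append(FragmentSpec(
            mz=mz, amplitude=amp,
            peak_ce=float(rng.uniform(*PEAK_CE_RANGE)),
            width=float(rng.uniform(*WIDTH_RANGE)),
        ))
        amp /= rng.uniform(*AMPLITUDE_STEP_RATIO_RANGE)
    for kind in extra_kinds:
        if kind is FragmentKind.PRECURSOR_ADJACENT:
            mz = precursor - float(rng.uniform(0.6, 1.9))
        else:
            mz = float(rng.uniform(50.0, precursor - 5.0))
            if any(abs(mz - m) <= 2.0 for m in mzs):
                mz = max(50.0, mz - 3.0)
        fragments.append(FragmentSpec(
            mz=mz, amplitude=10.0 ** rng.uniform(*TOP_AMPLITUDE_LOG10_RANGE),
            peak_ce=float(rng.uniform(*PEAK_CE_RANGE)),
            width=float(rng.uniform(*WIDTH_RANGE)), kind=kind))
    return CompoundSpec(
        compound_id=compound_id, polarity=polarity, precursor_mz=precursor,
        fragments=fragments,
        precursor_survival_halflife=float(rng.uniform(*PRECURSOR_HALFLIFE_RANGE)),
        precursor_amplitude=10.0 ** rng.uniform(*TOP_AMPLITUDE_LOG10_RANGE),
        noise_cv=noise_cv,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


DEFAULT_CLASS_MIX = {"single_ce": 0.25, "erratic": 0.25, "precursor_adjacent": 0.25}


@dataclass
class PanelArtifacts:
    """File paths and in-memory products of one simulated panel."""

    specs: list[CompoundSpec]
    sets: list[CompoundSpectrumSet]
    truth: pd.DataFrame
    mzml_path: Path | None = None
    manifest_path: Path | None = None
    truth_path: Path | None = None
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_panel(n_compounds: int, rng_seed: int,
                   class_mix: dict[str, float] | None = None,
                   out_dir: str | Path | None = None,
                   ce_grid: tuple[float, ...] = DEFAULT_CE_GRID,
                   noise_cv: float = DEFAULT_NOISE_CV,
                   polarity: str = "positive") -> PanelArtifacts:
    """Simulate a reproducible multi-compound panel.

    ``class_mix`` maps degenerate kind name -> fraction of compounds that
    receive one extra fragment of that kind (default: 25 % each of single_ce,
    erratic, precursor_adjacent).  When ``out_dir`` is given, writes mzML,
    manifest and truth table consumable by the I/O layer.
    """
    if n_compounds < 1:
        raise ValidationError("n_compounds must be >= 1")
    mix = DEFAULT_CLASS_MIX if class_mix is None else class_mix
    rng = np.random.default_rng(rng_seed)
    specs, sets, truths = [], [], []
    manifest_rows = []
    spectra_for_mzml: list[tuple[str, MsmsSpectrum]] = []
    for i in range(n_compounds):
        extra = tuple(FragmentKind(kind) for kind, frac in sorted(mix.items())
                      if rng.random() < frac)
        spec = random_compound_spec(rng, compound_id=f"SYN{i:05d}", polarity=polarity,
                                    extra_kinds=extra, noise_cv=noise_cv)
        cset, truth = simulate_compound(spec, ce_grid=ce_grid)
        specs.append(spec)
        sets.append(cset)
        truths.append(truth)
        for ce, spectrum in sorted(cset.spectra.items()):
            sid = f"{spec.compound_id}_ce{int(ce)}"
            spectra_for_mzml.append((sid, spectrum))
            manifest_rows.append({
                "spectrum_id": sid, "compound_id": spec.compound_id,
                "polarity": cset.polarity, "collision_energy": ce,
                "precursor_mz": spec.precursor_mz,
            })
    truth = pd.concat(truths, ignore_index=True)
    manifest = pd.DataFrame(manifest_rows)
    art = PanelArtifacts(specs=specs, sets=sets, truth=truth, manifest=manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        art.mzml_path = out / "panel.mzML"
        art.manifest_path = out / "manifest.csv"
        art.truth_path = out / "truth.csv"
        write_mzml(spectra_for_mzml, art.mzml_path, run_id=f"panel_seed{rng_seed}")
        with open(art.manifest_path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# seed={rng_seed} n_compounds={n_compounds}\n")
            manifest.to_csv(fh, index=False,
                            float_format="%.6f")
        truth.to_csv(art.truth_path, index=False, float_format="%.6f")
    return art
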