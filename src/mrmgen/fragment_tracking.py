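"""Tracking fragment ions across collision energies and QC filtering.

Recurring fragment ions are grouped across a compound's spectra with a
±0.5 Da tolerance into :class:`FragmentTrace` objects (one intensity per CE).
Traces are then screened: a usable trace must be detected at >= 3 of the
measured CEs, its CE-intensity profile must be unimodal within a noise
tolerance and free of internal detection gaps, and its m/z must sit at least
2.0 Da below the precursor.  The precursor's own trace (and anything within
the grouping tolerance of it) is tracked but always rejected, which also
screens out nonspecific in-source fragments surviving at every energy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .spectra_io import CompoundSpectrumSet, ValidationError

#: default m/z tolerance for grouping recurring fragments (Th)
DEFAULT_MZ_TOL = 0.5
#: minimum number of CEs a trace must be detected at
DEFAULT_MIN_CE_COUNT = 3
#: minimum precursor-minus-product separation (Th)
DEFAULT_MIN_SEPARATION = 2.0
#: relative noise tolerance for the unimodality check (fraction of trace max)
DEFAULT_SHAPE_NOISE_FRAC = 0.10


class RejectReason(enum.Enum):
    NONE = "none"
    SINGLE_OR_SPARSE_CE = "single_or_sparse_ce"
    ERRATIC_SHAPE = "erratic_shape"
    PRECURSOR_ADJACENT = "precursor_adjacent"


@dataclass
class FragmentTrace:
    """One fragment ion's per-CE intensity profile.

    ``intensities`` maps CE (eV) to absolute intensity; an absent key means
    the ion was not detected at that energy.  ``representative_mz`` is the
    intensity-weighted mean of the member peaks.
    """

    representative_mz: float
    intensities: dict[float, float]
    member_mzs: dict[float, float]

    def __post_init__(self) -> None:
        if set(self.intensities) != set(self.member_mzs):
            raise ValidationError("trace intensities and member_mzs must share CE keys")
        if any(v < 0 for v in self.intensities.values()):
            raise ValidationError("trace intensities must be >= 0")

    @property
    def n_detected(self) -> int:
        return len(self.intensities)

    @property
    def max_intensity(self) -> float:
        return max(self.intensities.values()) if self.intensities else 0.0

    def detected_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(CEs, intensities) sorted ascending by CE, detected points only."""
        ces = np.array(sorted(self.intensities))
        return ces, np.array([self.intensities[c] for c in ces])


@dataclass
class TraceQC:
    """QC verdict for one trace; reject_reason is none iff every check passed."""

    trace: FragmentTrace
    pass_min_ce: bool
    pass_shape: bool
    pass_separation: bool
    reject_reason: RejectReason

    def __post_init__(self) -> None:
        all_pass = self.pass_min_ce and self.pass_shape and self.pass_separation
        if all_pass != (self.reject_reason is RejectReason.NONE):
            raise ValidationError("reject_reason inconsistent with pass flags")


@dataclass
class TraceFilterParams:
    """Thresholds for trace QC, defaulting to the pipeline's standard values."""

    min_ce_count: int = DEFAULT_MIN_CE_COUNT
    min_separation_da: float = DEFAULT_MIN_SEPARATION
    shape_noise_frac: float = DEFAULT_SHAPE_NOISE_FRAC


def group_fragments(cset: CompoundSpectrumSet, tol_da: float = DEFAULT_MZ_TOL
                    ) -> list[FragmentTrace]:
    """Group recurring fragment ions across CEs into traces.

    Iterative matching, seeded greedily: the globally most intense unassigned
    peak starts a trace; every other CE contributes its nearest unassigned
    peak within ``tol_da`` of the seed m/z; repeat until no peaks remain.
    Deterministic (ties broken by lower CE, then lower m/z) and returned
    sorted by descending maximum intensity.
    """
    if tol_da <= 0:
        raise ValidationError(f"tol_da must be > 0, got {tol_da}")
    # pool: (ce, mz, intensity), mutable assignment flags
    pool: list[list] = []
    for ce, spec in sorted(cset.spectra.items()):
        for p in spec.peaks:
            pool.append([ce, p.mz, p.intensity, False])
    traces: list[FragmentTrace] = []
    n_assigned = 0
    while n_assigned < len(pool):
        seed = min((e for e in pool if not e[3]), key=lambda e: (-e[2], e[0], e[1]))
        seed_ce, seed_mz = seed[0], seed[1]
        members: dict[float, list] = {seed_ce: seed}
        for ce in cset.ce_grid:
            if ce == seed_ce:
                continue
            cands = [e for e in pool
                     if not e[3] and e[0] == ce and abs(e[1] - seed_mz) <= tol_da]
            if cands:
                members[ce] = min(cands, key=lambda e: (abs(e[1] - seed_mz), e[1]))
        for e in members.values():
            e[3] = True
            n_assigned += 1
        total = sum(e[2] for e in members.values())
        if total > 0:
            rep = sum(e[1] * e[2] for e in members.values()) / total
        else:  # all-zero intensities: plain mean
            rep = float(np.mean([e[1] for e in members.values()]))
        traces.append(FragmentTrace(
            representative_mz=rep,
            intensities={ce: e[2] for ce, e in members.items()},
            member_mzs={ce: e[1] for ce, e in members.items()},
        ))
    traces.sort(key=lambda t: (-t.max_intensity, t.representative_mz))
    return traces


def is_unimodal(values: np.ndarray, tol: float) -> bool:
    """True iff some rise-then-fall split explains the sequence to within
    ``tol``: values before the split never drop by more than tol from one
    point to the next, values after never rise by more than tol."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n <= 2:
        return True
    for split in range(n):
        rise_ok = all(v[i + 1] >= v[i] - tol for i in range(split))
        fall_ok = all(v[i + 1] <= v[i] + tol for i in range(split, n - 1))
        if rise_ok and fall_ok:
            return True
    return False


def assess_trace(trace: FragmentTrace, ce_grid: list[float], precursor_mz: float,
                 params: TraceFilterParams | None = None) -> TraceQC:
    """Run the three QC checks on one trace.

    Checks, in reject-reason priority order: (1) detection at >=
    ``min_ce_count`` CEs; (2) unimodal profile within the noise tolerance and
    no internal detected-absent-detected gap over ``ce_grid``; (3) m/z at
    least ``min_separation_da`` below the precursor.
    """
    params = params or TraceFilterParams()
    grid = sorted(ce_grid)
    if len(grid) < 3:
        raise ValidationError("ce_grid must have length >= 3")

    pass_min_ce = trace.n_detected >= params.min_ce_count

    detected_idx = [i for i, ce in enumerate(grid) if ce in trace.intensities]
    no_gap = True
    if detected_idx:
        lo, hi = detected_idx[0], detected_idx[-1]
        no_gap = len(detected_idx) == hi - lo + 1
    _, profile = trace.detected_profile()
    tol = params.shape_noise_frac * (profile.max() if len(profile) else 0.0)
    pass_shape = no_gap and is_unimodal(profile, tol)

    pass_separation = (precursor_mz - trace.representative_mz) >= params.min_separation_da

    if not pass_min_ce:
        reason = RejectReason.SINGLE_OR_SPARSE_CE
    elif not pass_shape:
        reason = RejectReason.ERRATIC_SHAPE
    elif not pass_separation:
        reason = RejectReason.PRECURSOR_ADJACENT
    else:
        reason = RejectReason.NONE
    return TraceQC(trace, pass_min_ce, pass_shape, pass_separation, reason)


def filter_traces(traces: list[FragmentTrace], ce_grid: list[float], precursor_mz: float,
                  params: TraceFilterParams | None = None
                  ) -> tuple[list[FragmentTrace], list[TraceQC]]:
    """Partition traces into (kept, rejected-with-verdicts), preserving order."""
    kept: list[FragmentTrace] = []
    rejected: list[TraceQC] = []
    for trace in traces:
        qc = assess_trace(trace, ce_grid, precursor_mz, params)
        if qc.reject_reason is RejectReason.NONE:
            kept.append(trace)
        else:
            rejected.append(qc)
    return kept, rejected
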