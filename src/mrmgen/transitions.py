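"""Quantifier/qualifier transition selection.

Surviving fragments are ranked by the spline intensity at each fragment's
own optimal CE.  The top-ranked fragment becomes the quantifier; the next
fragment whose m/z differs from the quantifier's by more than the grouping
tolerance becomes the qualifier.  Each transition carries the fragment's own
optimal CE (quantifier and qualifier commonly peak at different energies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .ce_model import CEProfileFit, SplineConfig, predict_optimal_ce
from .fragment_tracking import (
    DEFAULT_MZ_TOL,
    TraceFilterParams,
    TraceQC,
    filter_traces,
    group_fragments,
)
from .spectra_io import CompoundSpectrumSet, ValidationError

logger = logging.getLogger("mrmgen")

QUANTIFIER = "quantifier"
QUALIFIER = "qualifier"


@dataclass
class Transition:
    """One precursor -> product pair monitored at an integer CE (eV)."""

    compound_id: str
    polarity: str
    precursor_mz: float
    product_mz: float
    ce_eV: int
    role: str
    rank: int
    intensity_at_optimum: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in (QUANTIFIER, QUALIFIER):
            raise ValidationError(f"unknown transition role {self.role!r}")
        if self.role == QUANTIFIER and self.rank != 1:
            raise ValidationError("quantifier transitions must have rank 1")
        if self.rank < 1:
            raise ValidationError("rank must be >= 1")


@dataclass
class TransitionTable:
    """Rows of transitions; per compound/polarity at most one quantifier and
    the quantifier at least as intense as any qualifier."""

    rows: list[Transition] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str, str], Transition] = {}
        for t in self.rows:
            key = (t.compound_id, t.polarity, t.role)
            if t.role == QUANTIFIER and key in seen:
                raise ValidationError(
                    f"{t.compound_id}/{t.polarity}: more than one quantifier")
            seen.setdefault(key, t)

    def __len__(self) -> int:
        return len(self.rows)

    def by_compound(self) -> dict[tuple[str, str], list[Transition]]:
        out: dict[tuple[str, str], list[Transition]] = {}
        for t in self.rows:
            out.setdefault((t.compound_id, t.polarity), []).append(t)
        return out


def rank_fragments(fits: list[CEProfileFit], precursor_mz: float) -> list[CEProfileFit]:
    """Order fits by descending intensity at their optimal CE.

    Ties favor the fragment farther below the precursor (more selective),
    then the smaller m/z.  All fits must belong to one compound/polarity.
    """
    return sorted(fits, key=lambda f: (
        -f.intensity_at_optimum,
        -(precursor_mz - f.trace.representative_mz),
        f.trace.representative_mz,
    ))


def select_transitions(cset: CompoundSpectrumSet, ranked: list[CEProfileFit],
                       n_qualifiers: int = 1, mz_tol: float = DEFAULT_MZ_TOL
                       ) -> list[Transition]:
    """Assign quantifier and qualifier(s) from an already-ranked fit list.

    The rank-1 fit is the quantifier.  Qualifier candidates are taken in rank
    order, skipping any fragment within ``mz_tol`` of an already-selected
    product m/z (the tolerance defines ion identity, so closer would be the
    same ion twice).  A compound with a single surviving fragment emits only
    a quantifier; with none, nothing.
    """
    if not ranked:
        return []
    out: list[Transition] = []
    chosen_mzs: list[float] = []
    quant = ranked[0]
    out.append(_to_transition(cset, quant, QUANTIFIER, 1))
    chosen_mzs.append(quant.trace.representative_mz)
    rank = 2
    for fit in ranked[1:]:
        if len(out) - 1 >= n_qualifiers:
            break
        mz = fit.trace.representative_mz
        if any(abs(mz - c) <= mz_tol for c in chosen_mzs):
            continue
        out.append(_to_transition(cset, fit, QUALIFIER, rank))
        chosen_mzs.append(mz)
        rank += 1
    return out


def _to_transition(cset: CompoundSpectrumSet, fit: CEProfileFit, role: str,
                   rank: int) -> Transition:
    return Transition(
        compound_id=cset.compound_id,
        polarity=cset.polarity,
        precursor_mz=cset.precursor_mz,
        product_mz=fit.trace.representative_mz,
        ce_eV=int(round(fit.optimal_ce)),
        role=role,
        rank=rank,
        intensity_at_optimum=fit.intensity_at_optimum,
    )


def build_table(sets: list[CompoundSpectrumSet],
                qc_params: TraceFilterParams | None = None,
                spline_config: SplineConfig | None = None,
                mz_tol: float = DEFAULT_MZ_TOL,
                n_qualifiers: int = 1,
                ) -> tuple[TransitionTable, list[tuple[str, str, str]],
                           list[tuple[str, str, TraceQC]]]:
    """Run the full per-compound pipeline: group -> filter -> fit -> select.

    Returns (table, omissions, rejected_qc) where omissions lists
    (compound_id, polarity, reason) for compounds that emitted nothing and
    rejected_qc collects every rejected trace with its compound for the QC
    report.  Per-compound failures are logged and skipped, never fatal.
    """
    qc_params = qc_params or TraceFilterParams()
    spline_config = spline_config or SplineConfig()
    rows: list[Transition] = []
    omissions: list[tuple[str, str, str]] = []
    rejected_all: list[tuple[str, str, TraceQC]] = []
    for cset in sets:
        try:
            traces = group_fragments(cset, tol_da=mz_tol)
            kept, rejected = filter_traces(traces, cset.ce_grid, cset.precursor_mz,
                                           qc_params)
            rejected_all.extend((cset.compound_id, cset.polarity, qc) for qc in rejected)
            fits = [predict_optimal_ce(t, spline_config) for t in kept]
            ranked = rank_fragments(fits, cset.precursor_mz)
            selected = select_transitions(cset, ranked, n_qualifiers=n_qualifiers,
                                          mz_tol=mz_tol)
            if not selected:
                omissions.append((cset.compound_id, cset.polarity,
                                  "no fragment passed QC"))
            rows.extend(selected)
        except Exception:
            logger.exception("compound %s/%s failed; skipped",
                             cset.compound_id, cset.polarity)
            omissions.append((cset.compound_id, cset.polarity, "processing error"))
    return TransitionTable(rows), omissions, rejected_all
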