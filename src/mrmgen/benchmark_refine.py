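"""Benchmarking predicted transitions and spline-configuration refinement.

compare_tables scores a predicted transition table against a reference one
with three metrics: product m/z agreement per role at ±0.5 Da, signed CE
error (ΔCE) for m/z-matched roles, and per-compound transition overlap.
Compounds whose quantifier and qualifier roles are interchanged between the
two tables are flagged "flipped"; a flipped quantifier still counts as a
mass-level match in the summary, since the ion was recovered.

refine_spline_config scores candidate spline settings by cross-validated
CE-prediction error against empirical optima and selects the best, either
with the identity scorer (held-out RMSE of predicted vs empirical CE) or any
scikit-learn regressor supplied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import KFold

from .ce_model import SplineConfig, predict_optimal_ce
from .fragment_tracking import DEFAULT_MZ_TOL, TraceFilterParams, filter_traces, group_fragments
from .spectra_io import CompoundSpectrumSet, ValidationError
from .transitions import QUALIFIER, QUANTIFIER, TransitionTable

#: |ΔCE| threshold for the summary agreement fraction (eV)
DEFAULT_DCE_THRESHOLD = 7.0


@dataclass
class BenchmarkReport:
    """Per-compound benchmark rows plus summary fractions.

    ``per_compound`` columns: compound_id, polarity, quantifier_mz_match,
    qualifier_mz_match, flipped, delta_ce_quant, delta_ce_qual,
    overlap_fraction, missing_in.  ``summary`` keys:
    frac_quantifier_matched, frac_qualifier_matched, frac_dce_within,
    mean_abs_dce, n_compared, n_missing, dce_threshold.
    """

    per_compound: pd.DataFrame
    summary: dict


def _role_map(table: TransitionTable, which: str) -> dict:
    out: dict = {}
    for key, rows in table.by_compound().items():
        roles: dict = {}
        for t in rows:
            if t.role in roles and t.role == QUANTIFIER:
                raise ValidationError(
                    f"{which} table: duplicate {t.role} for {key[0]}/{key[1]}")
            if t.role == QUALIFIER:
                roles.setdefault(QUALIFIER, []).append(t)
            else:
                roles[QUANTIFIER] = t
        out[key] = roles
    return out


def _first_qualifier(roles: dict):
    quals = roles.get(QUALIFIER, [])
    return min(quals, key=lambda t: t.rank) if quals else None


def _mz_match(a, b, tol: float) -> bool:
    return a is not None and b is not None and abs(a.product_mz - b.product_mz) <= tol


def compare_tables(predicted: TransitionTable, reference: TransitionTable,
                   mz_tol: float = DEFAULT_MZ_TOL,
                   dce_threshold: float = DEFAULT_DCE_THRESHOLD) -> BenchmarkReport:
    """Score a predicted table against a reference table.

    Per compound/polarity present in both: per-role product m/z match at
    ``mz_tol``; ΔCE (predicted − reference) for m/z-matched roles (the
    swapped pairing when roles are flipped); overlap_fraction = share of
    reference products recovered by any predicted product.  Compounds present
    on one side only are reported with ``missing_in`` set, not matched.
    """
    pred = _role_map(predicted, "predicted")
    ref = _role_map(reference, "reference")
    rows = []
    for key in sorted(set(pred) | set(ref)):
        base = {"compound_id": key[0], "polarity": key[1],
                "quantifier_mz_match": False, "qualifier_mz_match": False,
                "flipped": False, "delta_ce_quant": np.nan, "delta_ce_qual": np.nan,
                "overlap_fraction": np.nan, "missing_in": ""}
        if key not in pred or key not in ref:
            base["missing_in"] = "predicted" if key not in pred else "reference"
            rows.append(base)
            continue
        p_quant = pred[key].get(QUANTIFIER)
        p_qual = _first_qualifier(pred[key])
        r_quant = ref[key].get(QUANTIFIER)
        r_qual = _first_qualifier(ref[key])

        base["quantifier_mz_match"] = _mz_match(p_quant, r_quant, mz_tol)
        base["qualifier_mz_match"] = _mz_match(p_qual, r_qual, mz_tol)
        base["flipped"] = (not base["quantifier_mz_match"]
                           and _mz_match(p_quant, r_qual, mz_tol)
                           and _mz_match(p_qual, r_quant, mz_tol))
        if base["quantifier_mz_match"]:
            base["delta_ce_quant"] = float(p_quant.ce_eV - r_quant.ce_eV)
        elif base["flipped"]:
            base["delta_ce_quant"] = float(p_quant.ce_eV - r_qual.ce_eV)
        if base["qualifier_mz_match"]:
            base["delta_ce_qual"] = float(p_qual.ce_eV - r_qual.ce_eV)
        elif base["flipped"]:
            base["delta_ce_qual"] = float(p_qual.ce_eV - r_quant.ce_eV)

        ref_products = [t.product_mz for t in reference.by_compound()[key]]
        pred_products = [t.product_mz for t in predicted.by_compound()[key]]
        recovered = sum(any(abs(r - p) <= mz_tol for p in pred_products)
                        for r in ref_products)
        base["overlap_fraction"] = recovered / len(ref_products) if ref_products else np.nan
        rows.append(base)

    df = pd.DataFrame(rows)
    compared = df[df["missing_in"] == ""]
    dces = pd.concat([compared["delta_ce_quant"], compared["delta_ce_qual"]]).dropna()
    n = len(compared)
    summary = {
        "frac_quantifier_matched":
            float((compared["quantifier_mz_match"] | compared["flipped"]).mean()) if n else np.nan,
        "frac_qualifier_matched":
            float((compared["qualifier_mz_match"] | compared["flipped"]).mean()) if n else np.nan,
        "frac_dce_within":
            float((dces.abs() <= dce_threshold).mean()) if len(dces) else np.nan,
        "mean_abs_dce": float(dces.abs().mean()) if len(dces) else np.nan,
        "mean_overlap": float(compared["overlap_fraction"].mean()) if n else np.nan,
        "n_compared": int(n),
        "n_missing": int(len(df) - n),
        "dce_threshold": float(dce_threshold),
    }
    return BenchmarkReport(per_compound=df, summary=summary)


@dataclass
class RefinementResult:
    """Cross-validated scores per candidate config and the selected winner."""

    selected: SplineConfig
    score_table: pd.DataFrame


def _predicted_vs_empirical(cset: CompoundSpectrumSet, empirical: dict,
                            config: SplineConfig, qc_params: TraceFilterParams,
                            mz_tol: float) -> list[tuple[float, float]]:
    """Pair each kept trace's predicted CE with the empirical CE of the
    nearest reference fragment within the grouping tolerance."""
    traces = group_fragments(cset, tol_da=mz_tol)
    kept, _ = filter_traces(traces, cset.ce_grid, cset.precursor_mz, qc_params)
    pairs = []
    for trace in kept:
        matches = [(abs(trace.representative_mz - mz), ce)
                   for mz, ce in empirical.items()
                   if abs(trace.representative_mz - mz) <= mz_tol]
        if not matches:
            continue
        _, emp_ce = min(matches)
        fit = predict_optimal_ce(trace, config)
        pairs.append((fit.optimal_ce, float(emp_ce)))
    return pairs


def refine_spline_config(training: list[tuple[CompoundSpectrumSet, dict]],
                         candidates: list[SplineConfig],
                         folds: int = 3, seed: int = 0,
                         regressor=None,
                         qc_params: TraceFilterParams | None = None,
                         mz_tol: float = DEFAULT_MZ_TOL) -> RefinementResult:
    """Select the spline configuration with the lowest cross-validated
    CE-prediction error.

    ``training`` pairs each compound's spectra with a map of fragment m/z ->
    empirical optimal CE.  Compounds are split into ``folds`` folds (shuffled
    with ``seed``); per fold the held-out root-mean-square CE error is
    computed, by the identity scorer by default or through a fitted
    ``regressor`` (any sklearn regressor; empirical CE regressed on predicted
    CE).  Deterministic for a fixed seed.
    """
    if len(candidates) < 2:
        raise ValidationError("need >= 2 candidate configurations")
    if len(training) < 10:
        raise ValidationError("need >= 10 training compounds")
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    qc_params = qc_params or TraceFilterParams()

    records = []
    for idx, config in enumerate(candidates):
        pairs_per_compound = [
            _predicted_vs_empirical(cset, empirical, config, qc_params, mz_tol)
            for cset, empirical in training
        ]
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        fold_rmses = []
        for train_idx, test_idx in kf.split(pairs_per_compound):
            test_pairs = [p for i in test_idx for p in pairs_per_compound[i]]
            if not test_pairs:
                continue
            pred = np.array([p[0] for p in test_pairs])
            emp = np.array([p[1] for p in test_pairs])
            if regressor is None:
                resid = pred - emp
            else:
                train_pairs = [p for i in train_idx for p in pairs_per_compound[i]]
                model = clone(regressor)
                model.fit(np.array([[p[0]] for p in train_pairs]),
                          np.array([p[1] for p in train_pairs]))
                resid = model.predict(pred.reshape(-1, 1)) - emp
            fold_rmses.append(float(np.sqrt(np.mean(resid ** 2))))
        records.append({
            "candidate": idx,
            "degree": config.degree,
            "smoothing": config.smoothing,
            "mean_cv_rmse": float(np.mean(fold_rmses)) if fold_rmses else np.inf,
            "n_folds": len(fold_rmses),
        })
    score_table = pd.DataFrame(records)
    best = int(score_table["mean_cv_rmse"].idxmin())
    return RefinementResult(selected=candidates[best], score_table=score_table)
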