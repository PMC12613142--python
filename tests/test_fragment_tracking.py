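"""Fragment grouping across CEs and trace QC filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmgen import (
    CompoundSpectrumSet,
    MsmsSpectrum,
    Peak,
    RejectReason,
    TraceFilterParams,
    assess_trace,
    filter_traces,
    group_fragments,
    is_unimodal,
)
from tests.conftest import CE_GRID, make_trace


def build_set(peaks_by_ce: dict[float, list[tuple[float, float]]],
              precursor: float = 300.0) -> CompoundSpectrumSet:
    spectra = {
        ce: MsmsSpectrum("c", "positive", ce, precursor,
                         tuple(Peak(mz, i) for mz, i in peaks))
        for ce, peaks in peaks_by_ce.items() if peaks
    }
    return CompoundSpectrumSet("c", "positive", precursor, spectra)


def oracle_single_linkage_to_seed(peaks, tol):
    """Independent grouping oracle: repeatedly take the most intense
    unassigned peak and exhaustively attach, per CE, the nearest unassigned
    peak within tol of the seed m/z."""
    peaks = [list(p) + [False] for p in peaks]  # [ce, mz, intensity, assigned]
    groups = []
    while any(not p[3] for p in peaks):
        seed = min((p for p in peaks if not p[3]), key=lambda p: (-p[2], p[0], p[1]))
        group = {seed[0]: seed}
        for p in sorted(peaks, key=lambda p: (abs(p[1] - seed[1]), p[1])):
            if p[3] or p[0] in group or abs(p[1] - seed[1]) > tol:
                continue
            group[p[0]] = p
        for p in group.values():
            p[3] = True
        groups.append({ce: (p[1], p[2]) for ce, p in group.items()})
    return groups


class TestGrouping:
    def test_drifting_fragment_forms_one_trace(self):
        """Peaks drifting up to 0.45 Da from the seed still group together."""
        cset = build_set({
            10.0: [(84.00, 9000.0)],
            20.0: [(84.30, 5000.0)],
            40.0: [(84.45, 1000.0)],
        })
        traces = group_fragments(cset, tol_da=0.5)
        assert len(traces) == 1
        assert traces[0].n_detected == 3
        expected = oracle_single_linkage_to_seed(
            [(10.0, 84.00, 9000.0), (20.0, 84.30, 5000.0), (40.0, 84.45, 1000.0)], 0.5)
        assert len(expected) == 1
        assert traces[0].member_mzs == {ce: mz for ce, (mz, _) in expected[0].items()}

    def test_peaks_beyond_tolerance_split(self):
        cset = build_set({10.0: [(84.0, 900.0)], 20.0: [(85.0, 800.0)]})
        traces = group_fragments(cset, tol_da=0.5)
        assert len(traces) == 2

    def test_single_peak_single_trace(self):
        cset = build_set({10.0: [(84.0, 900.0)]})
        traces = group_fragments(cset, tol_da=0.5)
        assert len(traces) == 1
        assert traces[0].n_detected == 1

    def test_matches_oracle_on_random_panels(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            peaks_by_ce = {}
            flat = []
            for ce in CE_GRID:
                n = int(rng.integers(1, 8))
                items = [(float(rng.uniform(50, 290)), float(rng.uniform(1, 1e4)))
                         for _ in range(n)]
                peaks_by_ce[ce] = items
                flat.extend((ce, mz, i) for mz, i in items)
            traces = group_fragments(build_set(peaks_by_ce), tol_da=0.5)
            expected = oracle_single_linkage_to_seed(flat, 0.5)
            got = sorted([t.member_mzs for t in traces], key=lambda d: sorted(d.items()))
            want = sorted([{ce: mz for ce, (mz, _) in g.items()} for g in expected],
                          key=lambda d: sorted(d.items()))
            assert got == want

    def test_every_peak_assigned_exactly_once(self):
        rng = np.random.default_rng(1)
        peaks_by_ce = {ce: [(float(rng.uniform(50, 290)), float(rng.uniform(1, 1e4)))
                            for _ in range(6)] for ce in CE_GRID}
        cset = build_set(peaks_by_ce)
        traces = group_fragments(cset)
        n_members = sum(t.n_detected for t in traces)
        assert n_members == sum(len(v) for v in peaks_by_ce.values())
        for t in traces:
            for ce, mz in t.member_mzs.items():
                assert abs(mz - t.representative_mz) <= 1.0

    def test_traces_sorted_by_descending_max_intensity(self):
        cset = build_set({10.0: [(84.0, 100.0), (120.0, 9000.0), (160.0, 500.0)]})
        traces = group_fragments(cset)
        maxima = [t.max_intensity for t in traces]
        assert maxima == sorted(maxima, reverse=True)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.tuples(st.sampled_from(CE_GRID),
                              st.floats(50, 290),
                              st.floats(1, 1e5)),
                    min_size=1, max_size=25))
    def test_tolerance_monotonicity(self, flat_peaks):
        """Enlarging the grouping tolerance never increases the trace count."""
        peaks_by_ce: dict[float, list] = {}
        for ce, mz, i in flat_peaks:
            peaks_by_ce.setdefault(ce, []).append((mz, i))
        cset = build_set(peaks_by_ce)
        counts = [len(group_fragments(cset, tol_da=tol)) for tol in (0.1, 0.5, 2.0, 10.0)]
        assert counts == sorted(counts, reverse=True)


class TestUnimodality:
    @pytest.mark.parametrize("profile,tol_frac,expected", [
        ((100, 4000, 9000, 2000), 0.10, True),    # single interior maximum
        ((9000, 100, 8000, 200), 0.10, False),    # two maxima beyond tolerance
        ((9000, 4000, 1000, 100), 0.10, True),    # monotone decreasing
        ((100, 1000, 4000, 9000), 0.10, True),    # monotone increasing
        ((5000, 4800, 5100, 400), 0.10, True),    # dip within 10% tolerance
        ((5000, 3000, 5100, 400), 0.10, False),   # dip beyond tolerance
    ])
    def test_brute_force_split_rule(self, profile, tol_frac, expected):
        v = np.array(profile, dtype=float)
        assert is_unimodal(v, tol_frac * v.max()) is expected


class TestAssess:
    def test_sparse_trace_rejected_first(self, ce_grid):
        trace = make_trace(84.0, {10.0: 900.0, 20.0: 800.0})
        qc = assess_trace(trace, ce_grid, precursor_mz=300.0)
        assert not qc.pass_min_ce
        assert qc.reject_reason is RejectReason.SINGLE_OR_SPARSE_CE

    def test_unimodal_trace_passes_shape(self, ce_grid):
        trace = make_trace(84.0, dict(zip(ce_grid, [100.0, 4000.0, 9000.0, 2000.0])))
        qc = assess_trace(trace, ce_grid, precursor_mz=300.0)
        assert qc.pass_shape and qc.reject_reason is RejectReason.NONE

    def test_bimodal_trace_fails_shape(self, ce_grid):
        trace = make_trace(84.0, dict(zip(ce_grid, [9000.0, 100.0, 8000.0, 200.0])))
        qc = assess_trace(trace, ce_grid, precursor_mz=300.0)
        assert not qc.pass_shape
        assert qc.reject_reason is RejectReason.ERRATIC_SHAPE

    def test_internal_detection_gap_fails_shape(self, ce_grid):
        trace = make_trace(84.0, {0.0: 500.0, 10.0: 900.0, 40.0: 700.0})
        qc = assess_trace(trace, ce_grid, precursor_mz=300.0)
        assert not qc.pass_shape

    def test_leading_absence_is_not_a_gap(self, ce_grid):
        trace = make_trace(84.0, {10.0: 500.0, 20.0: 900.0, 40.0: 700.0})
        qc = assess_trace(trace, ce_grid, precursor_mz=300.0)
        assert qc.pass_shape

    def test_precursor_adjacent_rejected(self, ce_grid):
        trace = make_trace(299.0, dict(zip(ce_grid, [1.0, 2.0, 3.0, 2.0])))
        qc = assess_trace(trace, ce_grid, precursor_mz=300.0)
        assert not qc.pass_separation
        assert qc.reject_reason is RejectReason.PRECURSOR_ADJACENT

    def test_separation_boundary_exactly_2da_passes(self, ce_grid):
        trace = make_trace(298.0, dict(zip(ce_grid, [1.0, 2.0, 3.0, 2.0])))
        qc = assess_trace(trace, ce_grid, precursor_mz=300.0)
        assert qc.pass_separation


class TestFilter:
    def test_mixed_panel_partitions_with_distinct_reasons(self, ce_grid):
        traces = [
            make_trace(84.0, dict(zip(ce_grid, [100.0, 4000.0, 9000.0, 2000.0]))),
            make_trace(120.0, {20.0: 5000.0}),
            make_trace(150.0, dict(zip(ce_grid, [9000.0, 100.0, 8000.0, 200.0]))),
            make_trace(299.5, dict(zip(ce_grid, [5000.0, 4000.0, 3000.0, 1000.0]))),
        ]
        kept, rejected = filter_traces(traces, ce_grid, precursor_mz=300.0)
        assert len(kept) == 1 and kept[0].representative_mz == 84.0
        reasons = {qc.reject_reason for qc in rejected}
        assert reasons == {RejectReason.SINGLE_OR_SPARSE_CE,
                           RejectReason.ERRATIC_SHAPE,
                           RejectReason.PRECURSOR_ADJACENT}

    def test_empty_input(self, ce_grid):
        assert filter_traces([], ce_grid, 300.0) == ([], [])

    def test_all_passing_gives_empty_rejects(self, ce_grid):
        traces = [make_trace(84.0 + k, dict(zip(ce_grid, [1.0, 5.0, 9.0, 2.0])))
                  for k in range(3)]
        kept, rejected = filter_traces(traces, ce_grid, 300.0)
        assert len(kept) == 3 and not rejected

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(
        st.floats(50, 299), st.lists(st.floats(0, 1e4), min_size=1, max_size=4)),
        max_size=10))
    def test_partition_and_kept_invariants(self, raw):
        """kept + rejected partition the input; every kept trace satisfies
        the min-CE and separation rules."""
        grid = CE_GRID
        traces = []
        for mz, intens in raw:
            profile = {grid[i]: v for i, v in enumerate(intens)}
            traces.append(make_trace(mz, profile))
        params = TraceFilterParams()
        kept, rejected = filter_traces(traces, grid, 300.0, params)
        assert len(kept) + len(rejected) == len(traces)
        for t in kept:
            assert t.n_detected >= params.min_ce_count
            assert 300.0 - t.representative_mz >= params.min_separation_da
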