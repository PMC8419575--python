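"""Theme-sharing statistics against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whalesong.simulator import SimulationRecord, Topology
from whalesong.summary_stats import (
    DiagnosticStats,
    SongSample,
    SummaryVector,
    classify_revolution,
    diagnostics,
    distance,
    length_stats,
    normalize,
    reference_sds,
    singleton_count,
    summarize,
    theme_sharing,
    transform,
)


def brute_force_sharing(A, B, within):
    """Literal double-loop over singer pairs (the defining formula)."""
    total = 0.0
    for j, tj in enumerate(A):
        inner = 0.0
        count = 0
        for k, tk in enumerate(B):
            if within and j == k:
                continue
            inner += len(set(tj) & set(tk)) / len(tj)
            count += 1
        total += inner / count
    return total / len(A)


theme_sets = st.lists(
    st.integers(min_value=1, max_value=8), min_size=1, max_size=6, unique=True
)


class TestThemeSharing:
    def test_within_two_singer_example(self):
        s = SongSample("X", 1, [(1, 2), (1, 3)])
        assert theme_sharing(s, within=True) == pytest.approx(0.5)

    def test_identical_single_songs_between(self):
        a = SongSample("X", 1, [(1, 2, 3)])
        b = SongSample("Y", 1, [(1, 2, 3)])
        assert theme_sharing(a, b) == pytest.approx(1.0)

    def test_disjoint_sets(self):
        a = SongSample("X", 1, [(1, 2), (3,)])
        b = SongSample("Y", 1, [(4, 5), (6,)])
        assert theme_sharing(a, b) == 0.0

    def test_asymmetric(self):
        a = SongSample("X", 1, [(1,)])
        b = SongSample("Y", 1, [(1, 2, 3, 4)])
        assert theme_sharing(a, b) == pytest.approx(1.0)
        assert theme_sharing(b, a) == pytest.approx(0.25)

    def test_needs_two_singers_within(self):
        with pytest.raises(ValueError):
            theme_sharing(SongSample("X", 1, [(1,)]), within=True)

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(
        A=st.lists(theme_sets, min_size=2, max_size=6),
        B=st.lists(theme_sets, min_size=1, max_size=6),
    )
    def test_brute_force_oracle(self, A, B):
        """Vectorised sharing equals the literal pair-loop exactly."""
        sa = SongSample("A", 1, A)
        sb = SongSample("B", 1, B)
        assert theme_sharing(sa, sb) == pytest.approx(
            brute_force_sharing(A, B, False), abs=1e-12
        )
        got = theme_sharing(sa, within=True)
        assert got == pytest.approx(brute_force_sharing(A, A, True), abs=1e-12)
        assert 0.0 <= got <= 1.0


class TestSimpleStats:
    def test_singletons(self):
        assert singleton_count(SongSample("X", 1, [(1, 2), (1, 3)])) == 2
        assert singleton_count(SongSample("X", 1, [(1, 2), (1, 2)])) == 0
        assert singleton_count(SongSample("X", 1, [(1, 2, 3)])) == 3

    def test_length_stats(self):
        mean, sd = length_stats(SongSample("X", 1, [(1, 2, 3, 4, 5, 6, 7)] * 3))
        assert (mean, sd) == (7.0, 0.0)
        mean, sd = length_stats(
            SongSample("X", 1, [tuple(range(1, 3)), tuple(range(1, 12))])
        )
        assert mean == pytest.approx(6.5)
        assert sd == pytest.approx(6.364, abs=1e-3)  # n-1 denominator


class TestTransforms:
    def test_sqrt_on_selected_stats(self):
        raw = np.array([4.0, 6.0, 9.0, 0.5, 0.25, 0.3, 0.16])
        t = transform(raw)
        assert t == pytest.approx([2.0, 6.0, 3.0, 0.5, 0.5, 0.3, 0.4])

    def test_negative_turnover_clamped(self):
        raw = np.zeros(7)
        raw[4] = -0.2
        assert transform(raw)[4] == 0.0

    def test_normalize(self):
        assert normalize(np.ones(3), np.ones(3)) == pytest.approx([1, 1, 1])
        with pytest.raises(ValueError):
            normalize(np.ones(3), np.array([1.0, 0.0, 1.0]))

    def test_reference_sds_degenerate(self):
        with pytest.raises(ValueError):
            reference_sds(np.ones((10, 7)))


class TestDistance:
    def test_examples(self):
        assert distance([1, 2], [1, 2]) == 0.0
        assert distance([0, 0], [0, 1]) == 1.0
        assert distance([0, 0], [3, 4]) == 5.0
        with pytest.raises(ValueError):
            distance([1], [1, 2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=7, max_size=7),
           st.lists(st.floats(-5, 5), min_size=7, max_size=7),
           st.lists(st.floats(-5, 5), min_size=7, max_size=7))
    def test_metric_properties(self, a, b, c):
        assert distance(a, b) >= 0
        assert distance(a, b) == pytest.approx(distance(b, a))
        assert distance(a, c) <= distance(a, b) + distance(b, c) + 1e-9


def _two_pop_record(samples):
    topo = Topology.ring(("A", "B"))
    return SimulationRecord(
        populations=topo.populations, topology=topo, years=max(y for y, _ in samples),
        samples=dict(samples), seed=0, config_hash="test",
    )


class TestSummarize:
    def test_frozen_record(self):
        """A record where one identical song persists: s4=1, s5=0, s1=0."""
        samples = {
            (y, p): [(1, 2, 3)] * 4 for y in range(0, 13) for p in ("A", "B")
        }
        rec = _two_pop_record(samples)
        v = summarize(rec, last_years=11)
        assert v.raw[0] == 0.0  # no singleton themes
        assert v.raw[3] == 1.0  # TS_FC
        assert v.raw[4] == 0.0  # turnover
        assert v.raw[1] == 3.0

    def test_hand_enumerated_vector(self):
        """Two-population record with 2-singer samples vs hand enumeration."""
        sA1, sA2 = [(1, 2), (1, 3)], [(1, 2), (2, 4)]
        sB1, sB2 = [(5, 6), (5, 7)], [(5, 6), (6, 8)]
        samples = {}
        for y in range(0, 13):
            samples[(y, "A")] = sA1 if y % 2 else sA2
            samples[(y, "B")] = sB1 if y % 2 else sB2
        rec = _two_pop_record(samples)
        v = summarize(rec, last_years=11)
        # every year: 2 singletons in the within-year sense
        assert v.raw[0] == pytest.approx(2.0)
        assert v.raw[1] == pytest.approx(2.0)
        assert v.raw[2] == pytest.approx(0.0)
        fc = brute_force_sharing(sA1, sA1, True)
        assert v.raw[3] == pytest.approx(fc)
        fp = brute_force_sharing(sA1, sA2, False)  # parity alternates
        assert v.raw[4] == pytest.approx(fc - fp)
        # on the 2-ring, A's west and east neighbour are both B: s6 = 0,
        # s7 = sharing with B's previous-year sample (all zero between A and B)
        assert v.raw[5] == pytest.approx(0.0)
        assert v.raw[6] == pytest.approx(0.0)

    def test_singer_order_invariance(self):
        base = [(1, 2), (3, 4), (1, 5)]
        samples_a = {(y, p): base for y in range(13) for p in ("A", "B")}
        samples_b = {(y, p): base[::-1] for y in range(13) for p in ("A", "B")}
        va = summarize(_two_pop_record(samples_a), last_years=11)
        vb = summarize(_two_pop_record(samples_b), last_years=11)
        assert va.raw == pytest.approx(vb.raw)

    def test_short_record_rejected(self):
        samples = {(y, p): [(1,)] for y in range(5) for p in ("A", "B")}
        with pytest.raises(ValueError):
            summarize(_two_pop_record(samples), last_years=11)


class TestDiagnostics:
    def test_classification_thresholds(self):
        assert classify_revolution(0.25) == "eastward"
        assert classify_revolution(-0.25) == "westward"
        assert classify_revolution(0.1) == "none"
        assert classify_revolution(float("nan")) == "none"

    def test_frozen_populations(self):
        samples = {
            (y, p): [(1, 2, 3)] * 3 for y in range(13) for p in ("A", "B")
        }
        d = diagnostics(_two_pop_record(samples), last_years=11)
        assert d.diff == pytest.approx(0.0)
        assert d.label == "none"
        assert d.turnover == pytest.approx(d.ts_fc - d.ts_fp)

    def test_missing_neighbour_reports_nan(self):
        """Clique endpoints have no directional neighbours: Diff unavailable."""
        topo = Topology.cliques([("A", "B")])
        samples = {(y, p): [(1, 2)] * 3 for y in range(13) for p in ("A", "B")}
        rec = SimulationRecord(
            populations=topo.populations, topology=topo, years=12,
            samples=samples, seed=0, config_hash="t",
        )
        d = diagnostics(rec, last_years=11)
        # A has only an eastern neighbour, B only a western one
        assert math.isnan(d.diff)
        assert d.label == "none"

    def test_summary_vector_shape_guard(self):
        with pytest.raises(ValueError):
            SummaryVector.from_raw([1.0, 2.0])

    def test_eastward_wave_train_detected(self):
        """A constructed west-to-east wave train is labelled eastward.

        Pop i sings, in year y, the disjoint lineage (y − i): every
        population adopts its western neighbour's previous-year song
        each year.  The construction is inconsistent at the ring wrap
        (one of five populations), so TS_WP averages 0.8, not 1.
        """
        topo = Topology.ring(tuple("ABCDE"))

        def lineage(k):
            base = 1000 * (k % 20)
            return [tuple(range(base + 1, base + 6))] * 4

        samples = {
            (y, pop): lineage(y - i)
            for y in range(13)
            for i, pop in enumerate(topo.populations)
        }
        rec = SimulationRecord(topo.populations, topo, 12, samples, 0, "t")
        d = diagnostics(rec, last_years=11)
        assert d.label == "eastward"
        assert d.diff == pytest.approx(0.8)
        assert d.ts_fp == 0.0 and d.turnover == pytest.approx(1.0)
        # the mirrored train is labelled westward
        samples_w = {
            (y, pop): lineage(y + i)
            for y in range(13)
            for i, pop in enumerate(topo.populations)
        }
        rec_w = SimulationRecord(topo.populations, topo, 12, samples_w, 0, "t")
        assert diagnostics(rec_w, last_years=11).label == "westward"
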