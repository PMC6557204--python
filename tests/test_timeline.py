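"""Timeline calling, trend detection, series summaries, event ordering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligoclone.samples import PRIMARY, RECURRENT, TUMOR_SAMPLES, XENO1, XENO2
from oligoclone.timeline import (
    RISING,
    STABLE,
    TimelineAssignment,
    TimelineConfig,
    call_timeline,
    detect_increase,
    order_events,
    summarize_series,
)


def hypergeom_tail_p(a, n1, b, n2):
    """Independent one-sided Fisher p by hypergeometric enumeration:
    P(X >= a) for X ~ Hypergeom(N=n1+n2, K=a+b, draws=n1)."""
    N, K = n1 + n2, a + b
    denom = math.comb(N, n1)
    return sum(
        math.comb(K, k) * math.comb(N - K, n1 - k)
        for k in range(a, min(K, n1) + 1)
    ) / denom


class TestDetectIncrease:
    def test_rising_matches_enumerated_exact_p(self):
        call = detect_increase(175, 1000, 800, 1000)
        assert call.trend == RISING
        # oracle on a small table where enumeration is cheap
        small = detect_increase(2, 20, 10, 20)
        assert small.p_rising == pytest.approx(hypergeom_tail_p(10, 20, 2, 20), rel=1e-9)

    def test_equal_fractions_stable(self):
        assert detect_increase(500, 1000, 500, 1000).trend == STABLE

    def test_tiny_difference_stable_at_alpha_005(self):
        call = detect_increase(20, 1000, 21, 1000)
        assert call.trend == STABLE
        assert call.p_rising == pytest.approx(
            hypergeom_tail_p(21, 1000, 20, 1000), rel=1e-9
        )
        assert call.p_rising > 0.05

    def test_falling_detected(self):
        assert detect_increase(400, 1000, 100, 1000).trend == "falling"

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            detect_increase(0, 0, 5, 100)


def _obs(rows):
    return pd.DataFrame(
        rows, columns=["locus", "gene", "sample", "depth", "alt_count"]
    )


class TestCallTimeline:
    def test_clonal_from_primary(self):
        """A variant at 63% in the primary tumor, stable thereafter, is an
        early clonal event."""
        rows = [("v", "PSKH1", s, 1000, 630) for s in TUMOR_SAMPLES]
        [a], never = call_timeline(_obs(rows))
        assert never == []
        assert a.first_sample == PRIMARY
        assert a.category == "primary_clonal"
        assert a.clonality_at_first == "clonal_majority"
        assert a.stable_early

    def test_subclonal_rising_sweep(self):
        """17.5% in primary rising to 80% then 100%: subclonal at first
        appearance, flagged rising."""
        afs = {PRIMARY: 175, RECURRENT: 800, XENO1: 1000, XENO2: 1000}
        rows = [("v", "NDST4", s, 1000, afs[s]) for s in TUMOR_SAMPLES]
        [a], _ = call_timeline(_obs(rows))
        assert a.category == "primary_subclonal"
        assert a.rising and a.trend == RISING
        assert not a.stable_early

    def test_recurrence_only_variant(self):
        afs = {PRIMARY: 0, RECURRENT: 120, XENO1: 0, XENO2: 0}
        rows = [("v", "ARHGAP6", s, 1000, afs[s]) for s in TUMOR_SAMPLES]
        [a], _ = call_timeline(_obs(rows))
        assert a.first_sample == RECURRENT
        assert a.category == "recurrent_only"
        assert not a.rising

    def test_never_present_reported_separately(self):
        rows = [("v", "g", s, 1000, 0) for s in TUMOR_SAMPLES]
        assignments, never = call_timeline(_obs(rows))
        assert assignments == [] and never == ["v"]

    def test_categories_partition_assigned_loci(self, fixture_timeline):
        assignments, _ = fixture_timeline
        assert all(sum(a.category == c for c in (
            "primary_clonal", "primary_subclonal", "recurrent_new_clonal",
            "recurrent_new_subclonal", "recurrent_only", "xeno_new_clonal",
            "xeno_new_subclonal")) == 1 for a in assignments)

    def test_blood_rejected_from_order(self):
        with pytest.raises(ValueError):
            TimelineConfig(sample_order=("blood", "primary"))

    def test_first_sample_recovery_on_simulated_series(self):
        """Over 100 seeded replicates of a 20-variant series at deep depth,
        the sample of first appearance is recovered >= 99% of the time for
        true AF >= 5%."""
        rng = np.random.default_rng(71)
        depth = 1000
        correct = total = 0
        for _ in range(100):
            rows, truth = [], {}
            for v in range(20):
                first_idx = rng.integers(0, 4)
                truth[f"v{v}"] = TUMOR_SAMPLES[first_idx]
                af = rng.uniform(0.05, 0.9)
                for i, s in enumerate(TUMOR_SAMPLES):
                    alt = rng.binomial(depth, af) if i >= first_idx else 0
                    rows.append((f"v{v}", f"v{v}", s, depth, alt))
            assignments, _ = call_timeline(_obs(rows))
            for a in assignments:
                total += 1
                correct += a.first_sample == truth[a.locus]
        assert correct / total >= 0.99

    def test_trend_type_one_error_within_alpha(self):
        """Stable variants (constant true AF) are flagged rising at most at
        the nominal one-sided level."""
        rng = np.random.default_rng(73)
        depth = 1000
        flags = []
        for _ in range(5000):
            af = rng.uniform(0.1, 0.6)
            call = detect_increase(
                int(rng.binomial(depth, af)), depth, int(rng.binomial(depth, af)), depth
            )
            flags.append(call.trend == RISING)
        assert np.mean(flags) <= 0.05


class TestSummarize:
    def test_fixture_bookkeeping(self, fixture_summary):
        s = fixture_summary
        assert s.present_counts == {
            PRIMARY: 11, RECURRENT: 81, XENO1: 86, XENO2: 86,
        }
        assert s.new_counts == {RECURRENT: 70, XENO1: 6, XENO2: 0}
        assert s.lost_counts == {RECURRENT: 0, XENO1: 1, XENO2: 0}

    def test_strict_and_stable_clonal_counts_both_surfaced(self, fixture_summary):
        """Strict >= 50% clonality admits two primary variants; adding the
        stable-AF-series argument admits a third (the IDH1 hotspot at 37%).
        Both readings are reported."""
        assert fixture_summary.clonal_at_first_strict == 2
        assert fixture_summary.clonal_at_first_with_stable == 3

    def test_empty_assignments_all_zero(self):
        s = summarize_series([])
        assert all(v == 0 for v in s.present_counts.values())
        assert s.n_assigned == 0

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_on_random_presence_vectors(self, seed):
        """count(k+1) - count(k) == new - lost at every transition for any
        random presence pattern."""
        rng = np.random.default_rng(seed)
        assignments = []
        for v in range(rng.integers(1, 25)):
            presence = {s: bool(rng.integers(0, 2)) for s in TUMOR_SAMPLES}
            if not any(presence.values()):
                continue
            first = next(s for s in TUMOR_SAMPLES if presence[s])
            assignments.append(
                TimelineAssignment(
                    locus=f"v{v}", gene=f"v{v}", presence=presence,
                    af={s: 0.5 for s in TUMOR_SAMPLES}, first_sample=first,
                    clonality_at_first="clonal_majority", rising=False,
                    rising_p=None, trend=STABLE, category="primary_clonal",
                )
            )
        summary = summarize_series(assignments)  # validates conservation
        for prev, curr in zip(TUMOR_SAMPLES, TUMOR_SAMPLES[1:]):
            delta = summary.present_counts[curr] - summary.present_counts[prev]
            assert delta == summary.new_counts[curr] - summary.lost_counts[curr]


class TestOrderEvents:
    def test_fixture_event_buckets(self, fixture_timeline, paper_fixture):
        """Early bucket: 1p/19q codeletion with the IDH1 hotspot; CIC and
        FUBP1 variants land in the recurrence bucket, after the codeletion."""
        assignments, _ = fixture_timeline
        events = order_events(assignments, paper_fixture.arm_events())
        bucket = {e.label: e.first_sample for e in events}
        assert bucket["1p_loss"] == bucket["19q_loss"] == PRIMARY
        assert bucket["IDH1"] == PRIMARY
        assert bucket["CIC"] == bucket["FUBP1"] == RECURRENT
        assert bucket["4q_cnLOH"] == XENO1
        order = [e.label for e in events]
        assert order.index("1p_loss") < order.index("CIC")

    def test_clonal_before_subclonal_within_bucket(self):
        a = TimelineAssignment("v1", "sub", {PRIMARY: True}, {PRIMARY: 0.2}, PRIMARY,
                               "subclonal", False, None, STABLE, "primary_subclonal")
        b = TimelineAssignment("v2", "clo", {PRIMARY: True}, {PRIMARY: 0.6}, PRIMARY,
                               "clonal_majority", False, None, STABLE, "primary_clonal")
        events = order_events([a, b])
        assert [e.label for e in events] == ["clo", "sub"]

    def test_single_event(self):
        a = TimelineAssignment("v", "g", {PRIMARY: True}, {PRIMARY: 0.6}, PRIMARY,
                               "clonal_majority", False, None, STABLE, "primary_clonal")
        assert len(order_events([a])) == 1

    def test_recovers_simulated_acquisition_order(self):
        """Clonal events simulated from a known clone tree come back in the
        simulated acquisition order."""
        from oligoclone.synthetic import SimulationConfig, demo_model, simulate_clonal_series

        model = demo_model()
        cfg = SimulationConfig(depth_per_sample={s: 5000 for s in model.samples}, seed=79)
        df = simulate_clonal_series(model, cfg).rename(columns={})
        df["alt_count"] = df["alt_count_fwd"] + df["alt_count_rev"]
        assignments, _ = call_timeline(df)
        events = order_events(assignments)
        labels = [e.label for e in events]
        assert labels.index("early_snv") < labels.index("late_snv")
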