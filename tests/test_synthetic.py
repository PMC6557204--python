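"""Expected-AF model and the three simulators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligoclone.allelic_state import SegmentState, classify_segment
from oligoclone.synthetic import (
    ClonalModel,
    Clone,
    OriginMQ,
    SimulationConfig,
    default_mq_params,
    demo_model,
    expected_af,
    simulate_clonal_series,
    simulate_exon_track,
    simulate_xenograft_reads,
)


class TestExpectedAF:
    @pytest.mark.parametrize(
        "m, cn_t, ccf, p, expected",
        [
            (1, 1, 1.0, 1.0, 1.0),    # clonal hemizygous mutant, pure sample
            (0, 2, 1.0, 1.0, 0.0),    # no mutant copies
            (1, 2, 0.5, 0.8, 0.2),    # hand arithmetic: 0.8*0.5*1 / 2
            (1, 2, 1.0, 1.0, 0.5),    # clonal heterozygous diploid
            (2, 2, 1.0, 1.0, 1.0),    # duplicated mutant after cnLOH
        ],
    )
    def test_closed_form(self, m, cn_t, ccf, p, expected):
        assert expected_af(m, cn_t, ccf, p) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(m=2, cn_t=1, ccf=1.0, p=1.0),   # m > cn_t
            dict(m=1, cn_t=2, ccf=1.5, p=1.0),   # ccf out of range
            dict(m=1, cn_t=2, ccf=1.0, p=-0.1),  # purity out of range
            dict(m=-1, cn_t=2, ccf=1.0, p=1.0),  # negative mutant copies
        ],
    )
    def test_domain_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            expected_af(**kwargs)

    @settings(derandomize=True, max_examples=200)
    @given(
        cn_t=st.integers(1, 4),
        m=st.integers(0, 4),
        ccf=st.floats(0, 1),
        p=st.floats(0, 1),
        bump=st.floats(0, 0.5),
    )
    def test_monotone_in_m_ccf_and_purity(self, cn_t, m, ccf, p, bump):
        m = min(m, cn_t)
        base = expected_af(m, cn_t, ccf, p)
        if m + 1 <= cn_t:
            assert expected_af(m + 1, cn_t, ccf, p) >= base
        assert expected_af(m, cn_t, min(ccf + bump, 1.0), p) >= base - 1e-12
        assert expected_af(m, cn_t, ccf, min(p + bump, 1.0)) >= base - 1e-12


class TestClonalSeries:
    def test_empirical_af_converges_to_model(self):
        """At depth 1e5 the simulated alt fraction sits within 0.01 of the
        expected AF for every locus and sample."""
        model = demo_model()
        cfg = SimulationConfig(
            depth_per_sample={s: 100_000 for s in model.samples}, seed=7
        )
        df = simulate_clonal_series(model, cfg)
        assert np.abs(df["af"] - df["true_af"]).max() < 0.01

    def test_seeded_reproducibility(self):
        model = demo_model()
        cfg = SimulationConfig(depth_per_sample={s: 500 for s in model.samples}, seed=11)
        a = simulate_clonal_series(model, cfg)
        b = simulate_clonal_series(model, cfg)
        assert a.equals(b)

    def test_selection_sweep_trajectory_strictly_increases(self):
        """A subclonal variant on a locus reduced to hemizygosity climbs from
        ~0.18 through ~0.8 to 1.0 as its clone sweeps and purity rises."""
        model = demo_model()
        cfg = SimulationConfig(
            depth_per_sample={s: 20_000 for s in model.samples}, seed=3
        )
        df = simulate_clonal_series(model, cfg)
        late = df[df["locus"] == "late_snv"].set_index("sample")["af"]
        assert late["primary"] == pytest.approx(0.18, abs=0.02)
        assert 0.78 <= late["recurrent"] <= 0.9
        assert late["xeno1"] == pytest.approx(1.0, abs=0.01)
        assert late["primary"] < late["recurrent"] < late["xeno1"]

    def test_no_variants_gives_empty_table(self):
        model = ClonalModel(
            clones=[Clone("c0", None, {"primary": 1.0})],
            purity_per_sample={"primary": 1.0},
            samples=("primary",),
        )
        df = simulate_clonal_series(
            model, SimulationConfig(depth_per_sample={"primary": 100})
        )
        assert df.empty

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(depth_per_sample={"primary": 0})
        with pytest.raises(ValueError):
            simulate_clonal_series(
                ClonalModel(clones=[], purity_per_sample={}),
                SimulationConfig(depth_per_sample={"primary": 10}),
            )
        with pytest.raises(ValueError):  # blood must be purity 0
            ClonalModel(
                clones=[Clone("c0", None, {})],
                purity_per_sample={"blood": 0.5},
            )
        with pytest.raises(ValueError):  # clone fractions exceed 1
            ClonalModel(
                clones=[
                    Clone("a", None, {"primary": 0.7}),
                    Clone("b", None, {"primary": 0.6}),
                ],
                purity_per_sample={"primary": 1.0},
            )


class TestXenograftReads:
    def test_empty_mixture(self):
        assert simulate_xenograft_reads(0, 0) == []

    def test_pure_graft_all_labeled_human(self):
        reads = simulate_xenograft_reads(1000, 0, seed=5)
        assert len(reads) == 1000
        assert all(r.true_origin == "human" for r in reads)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError):
            OriginMQ(55, 0.0, 10, 5)
        with pytest.raises(ValueError):
            OriginMQ(80, 5, 10, 5)
        with pytest.raises(ValueError):
            simulate_xenograft_reads(-1, 0)

    def test_mq_values_within_range_and_seeded(self):
        a = simulate_xenograft_reads(200, 200, default_mq_params(35), seed=9)
        b = simulate_xenograft_reads(200, 200, default_mq_params(35), seed=9)
        assert [(r.mq_human, r.mq_mouse) for r in a] == [
            (r.mq_human, r.mq_mouse) for r in b
        ]
        assert all(0 <= r.mq_human <= 60 and 0 <= r.mq_mouse <= 60 for r in a)


class TestExonTrack:
    @staticmethod
    def _track(state, purity=1.0, seed=2, n_exons=40):
        cfg = SimulationConfig(
            depth_per_sample={"tumor": 100, "control": 100}, seed=seed
        )
        return simulate_exon_track([("seg", state)], cfg, purity=purity, n_exons=n_exons)

    def test_conserved_het_balanced_alleles(self):
        df = self._track(SegmentState.CONSERVED_HET)
        ratio = df[["allele1_count", "allele2_count"]].max(axis=1) / (
            df["allele1_count"] + df["allele2_count"]
        )
        assert ratio.mean() == pytest.approx(0.5, abs=0.06)

    def test_copy_loss_halves_coverage(self):
        df = self._track(SegmentState.COPY_LOSS_LOH)
        log2 = np.log2(df["cov_tumor"] / df["cov_control"])
        assert log2.mean() == pytest.approx(-1.0, abs=0.15)

    def test_cnloh_neutral_coverage_skewed_alleles(self):
        df = self._track(SegmentState.COPY_NEUTRAL_LOH)
        log2 = np.log2(df["cov_tumor"] / df["cov_control"])
        assert abs(log2.mean()) < 0.1
        ratio = df[["allele1_count", "allele2_count"]].max(axis=1) / (
            df["allele1_count"] + df["allele2_count"]
        )
        assert ratio.mean() > 0.97

    def test_unknown_state_rejected(self):
        cfg = SimulationConfig(depth_per_sample={}, seed=0)
        with pytest.raises(ValueError):
            simulate_exon_track([("seg", "not_a_state")], cfg)

    def test_round_trips_through_classifier(self):
        df = self._track(SegmentState.COPY_NEUTRAL_LOH)
        call = classify_segment(df.drop(columns=["true_state"]))
        assert call.state is SegmentState.COPY_NEUTRAL_LOH
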