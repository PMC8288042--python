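"""The tau-perturbation measure: exactness, aggregation algebra, signs."""

import numpy as np
import pytest

import apcontrib as ap
from apcontrib.contribution import ContributionResult
from conftest import TOY_OPTS


def _res(gate, D, Dp, delta=0.1, t0=0.0):
    return ContributionResult(
        gate=gate, label="", t_start=t0, t_end=t0 + D,
        duration=D, perturbed=Dp, delta=delta,
    )


class TestPerturbedDuration:
    def test_delta_zero_returns_reference_exactly(self, toy_model, toy_traj, toy_event):
        d = ap.perturbed_duration(toy_model, toy_traj, "x", (0.0, toy_event), 0.0, TOY_OPTS)
        assert d == toy_event

    def test_toy_duration_scales_exactly_with_tau(self, toy_model, toy_traj, toy_event):
        for delta in (0.1, 0.6):
            d = ap.perturbed_duration(
                toy_model, toy_traj, "x", (0.0, toy_event), delta, TOY_OPTS
            )
            assert d == pytest.approx((1.0 + delta) * toy_event, rel=1e-8)

    def test_speeding_up_shortens(self, toy_model, toy_traj, toy_event):
        d = ap.perturbed_duration(
            toy_model, toy_traj, "x", (0.0, toy_event), -0.2, TOY_OPTS
        )
        assert d == pytest.approx(0.8 * toy_event, rel=1e-8)


class TestContributionInterval:
    def test_toy_contribution_is_one_for_any_delta(self, toy_model, toy_traj, toy_event):
        for delta in (0.01, 0.1, 0.6):
            r = ap.contribution_interval(
                toy_model, toy_traj, "x", (0.0, toy_event), delta, TOY_OPTS
            )
            assert abs(r.C - 1.0) < 1e-6

    def test_decoupled_gate_contributes_nothing(self, toy_model, toy_traj, toy_event):
        r = ap.contribution_interval(
            toy_model, toy_traj, "z", (0.0, toy_event), 0.1, TOY_OPTS
        )
        assert abs(r.C) < 1e-9

    def test_rat_slowed_ca_activation_lengthens_repolarization(
        self, rat_model, rat_traj, rat_phases
    ):
        # slowing the L-type activation during the plateau decline delays
        # repolarization (positive duration change)
        a, b = rat_phases.p2, rat_phases.p3
        r = ap.contribution_interval(rat_model, rat_traj, "l", (a, b), 0.6)
        assert r.perturbed > r.duration


class TestAggregation:
    def test_single_interval_identical_modes(self):
        rs = [_res("g", 2.0, 2.2)]
        assert ap.aggregate_summed(rs) == pytest.approx(ap.aggregate_pooled(rs))

    def test_summed_cancellation(self):
        rs = [_res("g", 1.0, 1.03), _res("g", 1.0, 0.97, t0=1.0)]
        assert ap.aggregate_summed(rs) == pytest.approx(0.0, abs=1e-12)

    def test_pooled_equal_durations_is_mean(self):
        rs = [_res("g", 2.0, 2.08), _res("g", 2.0, 2.00, t0=2.0)]
        cs = [r.C for r in rs]
        assert ap.aggregate_pooled(rs) == pytest.approx(np.mean(cs))

    def test_pooled_duration_weighting(self):
        # durations (1, 9), C = (1, 0) -> pooled 0.1
        rs = [_res("g", 1.0, 1.1), _res("g", 9.0, 9.0, t0=1.0)]
        assert ap.aggregate_pooled(rs) == pytest.approx(0.1)

    def test_empty_aggregation_rejected(self):
        with pytest.raises(ValueError):
            ap.aggregate_summed([])
        with pytest.raises(ValueError):
            ap.aggregate_pooled([])

    def test_mixed_gates_rejected(self):
        with pytest.raises(ValueError):
            ap.aggregate_summed([_res("a", 1.0, 1.1), _res("b", 1.0, 1.1)])

    def test_oracle_equivalence_single_epoch_region(self, toy_model, toy_traj, toy_event):
        # a region that is one epoch: summed, pooled and the direct
        # whole-region measurement must coincide
        r = ap.contribution_interval(
            toy_model, toy_traj, "x", (0.0, toy_event), 0.1, TOY_OPTS
        )
        s = ap.aggregate_summed([r])
        p = ap.aggregate_pooled([r])
        direct = r.C
        assert s == pytest.approx(direct, rel=1e-9)
        assert p == pytest.approx(direct, rel=1e-9)


class TestExpectedSign:
    @pytest.mark.parametrize(
        "ion, gdir, vdir, esign, want",
        [
            # positive-reversal channels (Na+, Ca2+)
            ("Na", "rising", "depolarizing", "positive", "+"),
            ("Na", "falling", "depolarizing", "positive", "-"),
            ("Ca", "rising", "repolarizing", "positive", "-"),
            ("Ca", "falling", "repolarizing", "positive", "+"),
            # K+ mirrors every case
            ("K", "rising", "depolarizing", "negative", "-"),
            ("K", "falling", "depolarizing", "negative", "+"),
            ("K", "rising", "repolarizing", "negative", "+"),
            ("K", "falling", "repolarizing", "negative", "-"),
        ],
    )
    def test_rule_table(self, ion, gdir, vdir, esign, want):
        assert ap.expected_sign(ion, gdir, vdir, esign) == want

    def test_invalid_enum_rejected(self):
        with pytest.raises(ValueError):
            ap.expected_sign("Na", "sideways", "depolarizing", "positive")


@pytest.fixture(scope="module")
def squid_table(squid_model):
    proto = ap.StimulusProtocol(amplitude=12.0, onset=2.0, duration=1.0,
                                total_time=40.0, mode="pulse")
    settings = ap.AnalysisSettings(
        delta=0.10, t_end=40.0,
        solver=ap.SolverOptions(rtol=1e-9, atol=1e-11, output_dt=0.005),
        criteria=ap.SegmentationCriteria(plateau_exit_dvdt=-0.05),
    )
    return ap.run_full_analysis(squid_model, proto, settings)


class TestFullAnalysis:
    def test_squid_analysis_completes_for_all_gates(self, squid_table):
        assert list(squid_table.table.index) == ["m", "h", "n"]
        assert squid_table.table[["P0", "P1", "P2", "P3"]].notna().all().all()

    def test_squid_sodium_activation_drives_depolarization(self, squid_table):
        assert squid_table.table.loc["m", "P0"] > 0

    def test_squid_provenance_traceable(self, squid_table):
        # every phase cell must be the sum of its epoch-level results
        for gate in ("m", "h", "n"):
            rs = [
                r for r in squid_table.epoch_results[gate]
                if squid_table.regions.phases.p0 - 1e-9 <= r.t_start
                < squid_table.regions.phases.p1
            ]
            assert squid_table.table.loc[gate, "P0"] == pytest.approx(
                sum(r.C for r in rs)
            )

    def test_table_shape_and_modes(self, squid_table):
        cols = list(squid_table.table.columns)
        assert cols[:4] == ["P0", "P1", "P2", "P3"]
        assert sum(c.count("IoI") for c in cols) == 16
        assert squid_table.modes["P0"] == "summed"
        assert squid_table.modes["P0IoI1"] == "pooled"
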