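"""Interval-rate calculus: rates, yields, gas exchange, carbon balance."""

import math

import pytest

from chemoscale import physiology as phys
from chemoscale.physiology import FeedComposition, OffGasRecord, SampleRecord


def rec(time, dcw, volume=2.0, glucose=0.0, msg=0.0, trehalose=0.0,
        cum_feed=0.0, cum_acid=0.0, cum_bleed=0.0):
    return SampleRecord(time=time, volume=volume, dcw=dcw, glucose=glucose,
                        msg=msg, trehalose=trehalose, cum_feed=cum_feed,
                        cum_acid=cum_acid, cum_bleed=cum_bleed)


class TestElementaryRates:
    def test_dilution_rate(self):
        assert phys.dilution_rate(0.06, 0.0, 2.0) == pytest.approx(0.03)
        assert phys.dilution_rate(0.0, 0.0, 2.0) == 0.0
        assert phys.dilution_rate(5.8, 0.2, 200.0) == pytest.approx(0.03)
        with pytest.raises(ValueError):
            phys.dilution_rate(0.06, 0.0, 0.0)

    def test_growth_rate_steady_state_equals_dilution(self):
        # no net biomass change; 1.44 L bled at 4.16 g/L over 24 h from an
        # 8.32 g standing pool -> mu = 0.03 1/h (= D at steady state)
        a = rec(0.0, 4.16, cum_bleed=0.0)
        b = rec(24.0, 4.16, cum_bleed=1.44)
        assert phys.specific_growth_rate(a, b) == pytest.approx(0.0300, abs=1e-4)

    def test_growth_rate_zero_without_growth_or_bleed(self):
        assert phys.specific_growth_rate(rec(0, 2.0), rec(10, 2.0)) == 0.0

    def test_growth_rate_batch_exponential_oracle(self):
        # exact exponential sampling at mu = 0.05: finite-difference mu
        # within 2% discretisation error for dt <= 2 h
        mu = 0.05
        for dt in (0.5, 1.0, 2.0):
            a = rec(0.0, 1.0)
            b = rec(dt, math.exp(mu * dt))
            est = phys.specific_growth_rate(a, b)
            assert abs(est - mu) / mu <= 0.02

    def test_growth_rate_errors(self):
        with pytest.raises(ValueError):
            phys.specific_growth_rate(rec(10, 1.0), rec(5, 1.0))
        with pytest.raises(ValueError):
            phys.specific_growth_rate(rec(0, 0.0), rec(10, 0.0))

    def test_space_time_yield_table_values(self):
        assert round(phys.space_time_yield(4.16, 0.03), 3) == 0.125
        assert phys.space_time_yield(0.0, 0.03) == 0.0
        assert round(phys.space_time_yield(3.77, 0.03), 3) == 0.113

    def test_batch_space_time_yield(self):
        assert round(phys.batch_space_time_yield(35.0, 310.0), 3) == 0.113
        assert round(phys.batch_space_time_yield(22.6, 170.0), 3) == 0.133
        assert round(phys.batch_space_time_yield(0.65, 90.0), 3) == 0.007
        with pytest.raises(ValueError):
            phys.batch_space_time_yield(1.0, 0.0)


class TestIntervalBalances:
    def test_consumption_no_flows(self):
        # 2.0 g -> 1.0 g broth glucose in 10 h at X_mean = 5 g
        a = rec(0.0, 2.5, volume=2.0, glucose=1.0)
        b = rec(10.0, 2.5, volume=2.0, glucose=0.5)
        q = phys.specific_consumption_rate(a, b, feed_conc=0.0,
                                           broth_attr="glucose")
        assert q == pytest.approx(0.02)

    def test_consumption_steady_through_flow_is_zero(self):
        # S_in = S_out and no inventory change -> q = 0
        a = rec(0.0, 2.5, glucose=1.0, cum_feed=0.0, cum_bleed=0.0)
        b = rec(10.0, 2.5, glucose=1.0, cum_feed=0.5, cum_bleed=0.5)
        q = phys.specific_consumption_rate(a, b, feed_conc=1.0,
                                           broth_attr="glucose")
        assert q == pytest.approx(0.0, abs=1e-15)

    def test_consumption_requires_feed_composition(self):
        a, b = rec(0.0, 2.5, glucose=1.0), rec(10.0, 2.5, glucose=0.5)
        with pytest.raises(ValueError, match="feed"):
            phys.specific_consumption_rate(a, b, feed_conc=None,
                                           broth_attr="glucose")

    def test_production_no_flows(self):
        # trehalose 0 -> 0.25 g/L in 2 L over 10 h at X_mean = 5 g
        a = rec(0.0, 2.5, trehalose=0.0)
        b = rec(10.0, 2.5, trehalose=0.25)
        q = phys.specific_production_rate(a, b)
        assert q == pytest.approx(0.01)
        flat = phys.specific_production_rate(rec(0, 2.5, trehalose=0.1),
                                             rec(10, 2.5, trehalose=0.1))
        assert flat == pytest.approx(0.0, abs=1e-15)


class TestYields:
    def test_biomass_yield(self):
        assert phys.biomass_yield(0.03, 0.1) == pytest.approx(0.3)
        assert phys.biomass_yield(0.0, 0.1) == 0.0
        assert phys.biomass_yield(0.06, 0.2) == pytest.approx(
            phys.biomass_yield(0.03, 0.1))
        with pytest.raises(ValueError):
            phys.biomass_yield(0.03, 0.0)

    def test_trehalose_yield_cmol_arithmetic(self):
        from chemoscale.composition import GLUCOSE, mass_to_cmol
        q_s_cmol = mass_to_cmol(0.1, GLUCOSE)
        assert phys.trehalose_yield(0.01, q_s_cmol) == pytest.approx(
            0.1053, abs=1e-4)
        assert phys.trehalose_yield(0.0, q_s_cmol) == 0.0

    def test_co2_yield_cmol_arithmetic(self):
        from chemoscale.composition import GLUCOSE, mass_to_cmol
        q_s_cmol = mass_to_cmol(0.06, GLUCOSE)
        assert phys.co2_yield(1.0, q_s_cmol) == pytest.approx(0.5005, abs=1e-4)
        assert phys.co2_yield(0.0, q_s_cmol) == 0.0

    def test_c_balance_additivity(self):
        assert phys.c_balance(0.5, 0.45, 0.05) == pytest.approx(1.0)
        assert phys.c_balance(0.0, 0.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            phys.c_balance(-0.1, 0.5, 0.1)


class TestGasRates:
    GAS = OffGasRecord(time=0.0, y_o2_in=0.2095, y_o2_out=0.2045,
                       y_co2_in=0.0004, y_co2_out=0.0054, gas_flow=30.6)

    def test_cer_and_our_hand_values(self):
        assert phys.cer(self.GAS, 2.0) == pytest.approx(3.413, abs=1e-3)
        assert phys.our(self.GAS, 2.0) == pytest.approx(3.413, abs=1e-3)
        assert phys.our(self.GAS, 1.0) == pytest.approx(
            2 * phys.our(self.GAS, 2.0))

    def test_zero_difference_zero_rate(self):
        flat = OffGasRecord(time=0.0, y_o2_in=0.2095, y_o2_out=0.2095,
                            y_co2_in=0.0004, y_co2_out=0.0004, gas_flow=30.6)
        assert phys.cer(flat, 2.0) == 0.0
        assert phys.our(flat, 2.0) == 0.0

    def test_rq(self):
        assert phys.rq(3.413, 3.413) == pytest.approx(1.0)
        assert phys.rq(0.0, 3.413) == 0.0
        assert phys.rq(3.0, 3.3) == pytest.approx(0.909, abs=1e-3)
        with pytest.raises(ValueError):
            phys.rq(1.0, 0.0)

    def test_specific_gas_rates_invert_exactly(self):
        cer_v = phys.cer(self.GAS, 2.0)
        our_v = phys.our(self.GAS, 2.0)
        x = 4.16
        assert phys.q_co2(cer_v, x) * x == cer_v
        assert phys.q_o2(our_v, x) * x == our_v
        assert phys.q_co2(3.4, 4.16) == pytest.approx(0.817, abs=1e-3)


class TestSteadyStateSelection:
    def test_window_cutoff_four_dwell_times(self):
        recs = [rec(t, 4.0) for t in (100.0, 200.0, 233.0, 234.0, 300.0)]
        kept = phys.steady_state_window(recs, chemostat_start=100.0,
                                        dilution=0.03)
        # cutoff at 100 + 4/0.03 = 233.3 h
        assert [r.time for r in kept] == [234.0, 300.0]

    def test_window_keeps_only_late_records(self):
        recs = [rec(3.0, 4.0), rec(5.0, 4.0)]
        kept = phys.steady_state_window(recs, chemostat_start=0.0, dilution=1.0)
        assert [r.time for r in kept] == [5.0]

    def test_window_empty_errors(self):
        with pytest.raises(ValueError, match="cutoff"):
            phys.steady_state_window([rec(10.0, 4.0)], chemostat_start=0.0,
                                     dilution=0.03)

    def test_summary_hand_values(self):
        base = dict(t_mid=0.0, dt=24.0, D=0.03, dx=0.12, q_glc=0.03,
                    q_msg=0.07, q_tre=0.001)
        rates = [phys.IntervalRates(mu=2.0, **base),
                 phys.IntervalRates(mu=4.0, **base)]
        s = phys.summarize_steady_state(rates)
        assert s.mean["mu"] == pytest.approx(3.0)
        assert s.std_percent["mu"] == pytest.approx(47.14, abs=0.01)
        assert s.std_percent["D"] == pytest.approx(0.0)
        assert s.n_samples == 2
        with pytest.raises(ValueError):
            phys.summarize_steady_state(rates[:1])


class TestPipelineOnSimulation:
    def test_steady_state_identities(self, sim2l):
        """Noiseless chemostat: mu = D, interval q_S matches the chemostat
        closed form, gas identities hold exactly."""
        truth = sim2l.truth
        window = phys.steady_state_window(sim2l.samples,
                                          truth["chemostat_start"], truth["D"])
        rates = phys.interval_rates(window, sim2l.offgas,
                                    FeedComposition(msg=9.5, glucose=4.5))
        summary = phys.summarize_steady_state(rates)
        D = truth["D"]
        assert abs(summary.mean["mu"] - D) / D <= 0.01
        # closed form with the substrate-free acid share a of the feed:
        # q_S = D (S_feed/(1+a) - S) / x
        a = sim2l.schedule.acid_fraction
        for key, feed_c, s_res in (("q_glc", 4.5, truth["s_glc_ss"]),
                                   ("q_msg", 9.5, truth["s_msg_ss"])):
            closed = D * (feed_c / (1 + a) - s_res) / truth["x_ss"]
            assert abs(summary.mean[key] - closed) / closed <= 0.01
        for r in rates:
            x_mid = r.cer / r.q_co2
            assert r.q_co2 * x_mid == pytest.approx(r.cer, rel=1e-12)
            assert r.q_o2 * x_mid == pytest.approx(r.our, rel=1e-12)

    def test_literal_closed_form_without_acid(self):
        """With no acid flow the textbook form q_S = D (S_feed - S)/x holds."""
        from chemoscale import ProcessSchedule, simulate_cultivation
        sim = simulate_cultivation(
            schedule=ProcessSchedule(acid_fraction=0.0))
        truth = sim.truth
        window = phys.steady_state_window(sim.samples,
                                          truth["chemostat_start"], truth["D"])
        rates = phys.interval_rates(window, sim.offgas,
                                    FeedComposition(msg=9.5, glucose=4.5))
        summary = phys.summarize_steady_state(rates)
        closed = truth["D"] * (4.5 - truth["s_glc_ss"]) / truth["x_ss"]
        assert abs(summary.mean["q_glc"] - closed) / closed <= 0.01

    def test_rates_invariant_under_intermediate_sample(self, sim2l):
        """Telescoping: dropping every other steady-state sample (doubling
        dt) changes the recovered rates by < 1%."""
        truth = sim2l.truth
        window = phys.steady_state_window(sim2l.samples,
                                          truth["chemostat_start"], truth["D"])
        feed = FeedComposition(msg=9.5, glucose=4.5)
        fine = phys.summarize_steady_state(
            phys.interval_rates(window, sim2l.offgas, feed))
        coarse = phys.summarize_steady_state(
            phys.interval_rates(window[::2], sim2l.offgas, feed))
        for key in ("mu", "q_glc", "q_msg", "q_tre", "D"):
            assert coarse.mean[key] == pytest.approx(fine.mean[key], rel=0.01)

    def test_interval_rates_requires_two_samples(self, sim2l):
        with pytest.raises(ValueError):
            phys.interval_rates(sim2l.samples[:1], None,
                                FeedComposition(msg=9.5, glucose=4.5))
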