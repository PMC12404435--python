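"""Fate classification, encounter histories and the known-fate model."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import hypergeom

import bycatchsurv as b
from bycatchsurv.prs import (
    SCENARIO_TO_FATE, EncounterHistory, fisher_exact_2x2, gelman_rubin,
    histories_from_calls,
)


def _flat_series(days, depth, temp=20.0, step=5):
    n = days * 24 * 60 // step
    return pd.DataFrame({"elapsed_min": np.arange(n) * step,
                         "depth_m": float(depth),
                         "temp_c": float(temp)})


class TestClassifyFate:
    @pytest.mark.parametrize("kind,day", [
        ("survivor", None),
        ("sink_mortality", 10),
        ("seafloor_mortality", 8),
        ("ingestion_mortality", 14),
        ("premature_detachment", 3),
    ])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_recovers_kind_and_day(self, kind, day, seed):
        scen = b.FateScenario(kind=kind, event_day=day)
        call = b.classify_fate(b.generate_tag_series(scen, seed=seed))
        assert call.kind == SCENARIO_TO_FATE[kind]
        assert abs(call.event_day - (day if day else 28)) <= 1

    def test_round_trip_across_many_seeds_and_days(self):
        rng = np.random.default_rng(99)
        for seed in range(40):
            kind = b.simulate.SCENARIO_KINDS[seed % 5]
            if kind == "survivor":
                day = None
            elif kind in ("seafloor_mortality", "premature_detachment"):
                day = int(rng.integers(2, 24))
            else:
                day = int(rng.integers(2, 27))
            scen = b.FateScenario(kind=kind, event_day=day)
            call = b.classify_fate(b.generate_tag_series(scen, seed=seed))
            assert call.kind == SCENARIO_TO_FATE[kind], (kind, seed)
            assert abs(call.event_day - (day if day else 28)) <= 1

    def test_surface_static_from_day_three_is_premature(self):
        # two days of normal diving, then a flat surface record: detachment
        # at day 3
        n_active = 2 * 288
        i = np.arange(n_active)
        active = pd.DataFrame({
            "elapsed_min": i * 5.0,
            "depth_m": 110 + 100 * np.sin(i / 5.0),
            "temp_c": 24.0 - 0.02 * (110 + 100 * np.sin(i / 5.0)),
        })
        flat = _flat_series(4, depth=0.0, temp=24.0)
        flat["elapsed_min"] += n_active * 5
        call = b.classify_fate(pd.concat([active, flat], ignore_index=True))
        assert call.kind == "premature_detachment"
        assert call.event_day == 3

    def test_short_series_unclassifiable(self):
        s = _flat_series(1, depth=50.0).iloc[:100]
        with pytest.raises(ValueError, match="24 h"):
            b.classify_fate(s)

    def test_rule_priority_ingestion_before_sink(self):
        # depth oscillates 0-1900 m while temperature is constant: both the
        # ingestion and sink rules match; ingestion wins by priority
        n = 4 * 288
        depth = 950 + 950 * np.sin(np.arange(n) / 10.0)
        s = pd.DataFrame({"elapsed_min": np.arange(n) * 5.0,
                          "depth_m": depth, "temp_c": 24.0})
        assert b.classify_fate(s).kind == "mortality_ingestion"


class TestEncounterHistories:
    def test_printed_deployment_log_totals(self, table5_histories):
        assert len(table5_histories) == 27
        assert sum(h.days for h in table5_histories) == 638
        assert sum(h.died for h in table5_histories) == 3
        assert sum(h.censored for h in table5_histories) == 5

    def test_mortality_day_one_is_single_failure(self):
        meta = pd.DataFrame({"tag_id": ["t"], "dal": [1], "fate": ["D"]})
        (h,) = b.build_encounter_histories(meta)
        assert h.y == (0,) and h.died and not h.censored

    def test_day28_detachment_indistinguishable_from_survivor(self):
        meta = pd.DataFrame({"tag_id": ["t"], "dal": [28], "fate": ["A"]})
        (h,) = b.build_encounter_histories(meta)
        assert h.y == (1,) * 28 and not h.censored

    def test_invalid_days_at_liberty(self):
        meta = pd.DataFrame({"tag_id": ["t"], "dal": [29], "fate": ["A"]})
        with pytest.raises(ValueError, match="days at liberty"):
            b.build_encounter_histories(meta)

    def test_conservation_from_classifier_calls(self):
        calls = {
            "a": b.prs.FateCall("survived", 28),
            "b": b.prs.FateCall("mortality_sink", 5),
            "c": b.prs.FateCall("premature_detachment", 12),
        }
        hs = histories_from_calls(calls)
        assert sum(h.days for h in hs) == 28 + 5 + 12
        assert sum(h.died for h in hs) == 1

    def test_history_invariants_enforced(self):
        with pytest.raises(ValueError, match="final day"):
            EncounterHistory("x", (1, 0, 1), censored=False)
        with pytest.raises(ValueError, match="censored"):
            EncounterHistory("x", (1, 0), censored=True)


class TestKnownFateLikelihood:
    def test_closed_form_mle_on_printed_data(self, table5_histories):
        m = b.KnownFateModel(table5_histories)
        assert (m.n_survived, m.n_died) == (635, 3)
        assert m.mle() == pytest.approx(635 / 638)
        assert m.mle() ** 28 == pytest.approx(0.8764, abs=5e-5)

    def test_loglik_equals_bernoulli_product(self):
        hs = [EncounterHistory("a", (1, 1, 0), censored=False),
              EncounterHistory("b", (1, 1), censored=True)]
        m = b.KnownFateModel(hs)
        phi = 0.9
        expected = 4 * np.log(phi) + 1 * np.log(1 - phi)
        assert m.loglike(logit(phi)) == pytest.approx(expected)

    def test_boundary_cases(self):
        all_alive = [EncounterHistory("a", (1,) * 10, censored=False)]
        assert b.KnownFateModel(all_alive).mle() == 1.0
        one_death = [EncounterHistory("a", (0,), censored=False)]
        assert b.KnownFateModel(one_death).mle() == 0.0


class TestMCMC:
    def test_posterior_matches_exact_beta_posterior(self, table5_posterior):
        # under the flat prior on the logit, the exact posterior of phi is
        # Beta(S, D); the sampler must agree with its mean and quantiles
        from scipy.stats import beta as beta_dist
        exact = beta_dist(635, 3)
        assert table5_posterior.phi_mean == pytest.approx(exact.mean(),
                                                          abs=0.001)
        lo, hi = table5_posterior.phi_interval()
        assert lo == pytest.approx(exact.ppf(0.025), abs=0.004)
        assert hi == pytest.approx(exact.ppf(0.975), abs=0.002)
        assert table5_posterior.rhat < 1.1
        assert table5_posterior.converged

    def test_sample_count_follows_settings(self, table5_posterior):
        s = table5_posterior.settings
        per_chain = (s["iterations"] - s["burn_in"]) // s["thin"]
        assert table5_posterior.beta0_samples.shape == (s["chains"],
                                                        per_chain)

    def test_large_sample_posterior_concentrates_on_mle(self):
        hs = [EncounterHistory(str(i), (1,), censored=True)
              for i in range(10000)]
        hs += [EncounterHistory(f"d{i}", (0,), censored=False)
               for i in range(50)]
        m = b.KnownFateModel(hs)
        post = m.fit_mcmc(iterations=4000, burn_in=2000, thin=5, seed=7)
        sd = post.phi.std()
        assert abs(post.phi_mean - m.mle()) < 3 * sd

    def test_fixed_seed_reproduces_samples(self, table5_histories):
        m = b.KnownFateModel(table5_histories)
        a = m.fit_mcmc(iterations=2000, burn_in=1000, seed=5)
        c = m.fit_mcmc(iterations=2000, burn_in=1000, seed=5)
        assert np.array_equal(a.beta0_samples, c.beta0_samples)
        d = m.fit_mcmc(iterations=2000, burn_in=1000, seed=6)
        assert not np.array_equal(a.beta0_samples, d.beta0_samples)


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(8)
        chains = rng.normal(0, 1, (3, 200))
        assert gelman_rubin(chains) < 1.05

    def test_separated_chains_diverge(self):
        rng = np.random.default_rng(9)
        chains = rng.normal(0, 1, (2, 100)) + np.array([[0.0], [100.0]])
        assert gelman_rubin(chains) > 10

    def test_constant_chains_report_one(self):
        assert gelman_rubin(np.ones((3, 50))) == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin(np.ones((1, 50)))


class TestHorizonTransform:
    def test_fixed_phi_closed_form(self, table5_histories):
        from conftest import constant_prs_posterior
        post = constant_prs_posterior(0.995 ** 28)
        prs, lo, hi = b.prs_horizon(post)
        assert prs == pytest.approx(0.995 ** 28, abs=1e-9)
        assert lo == pytest.approx(hi)

    def test_zero_horizon_is_one(self, table5_posterior):
        prs, lo, hi = b.prs_horizon(table5_posterior, horizon_days=0)
        assert (prs, lo, hi) == (1.0, 1.0, 1.0)

    def test_monotone_in_horizon(self, table5_posterior):
        points = [b.prs_horizon(table5_posterior, horizon_days=h)[0]
                  for h in (0, 7, 14, 28, 56)]
        assert all(a > c for a, c in zip(points, points[1:]))


class TestConditionTable:
    def test_printed_log_tally(self, table5):
        tab = b.condition_table(table5)
        assert tab.loc["lethargic", "dead"] == 2
        assert tab.loc["lethargic", "alive"] == 4
        assert tab.loc["active", "dead"] == 1
        assert tab.loc["active", "alive"] == 14

    def test_premature_detachments_excluded(self, table5):
        tab = b.condition_table(table5)
        # 21 included (3 dead + 18 full-term with recorded condition),
        # 5 detachments and 1 survivor lacking condition excluded
        assert int(tab.to_numpy().sum()) == 21

    def test_no_deaths_gives_zero_dead_column(self):
        meta = pd.DataFrame({"tag_id": ["a", "b"], "dal": [28, 28],
                             "fate": ["A", "A"],
                             "landing_condition": ["active", "lethargic"]})
        tab = b.condition_table(meta)
        assert (tab["dead"] == 0).all() and tab["alive"].sum() == 2


def _fisher_enumeration(table):
    """Independent oracle: enumerate all tables with the observed margins
    and sum hypergeometric probabilities <= that of the observed table."""
    a, bb = table[0]
    c, d = table[1]
    r1, c1, n = a + bb, a + c, a + bb + c + d
    rv = hypergeom(n, c1, r1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = rv.pmf(k)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestFisherExact:
    def test_printed_condition_table_p_value(self, table5):
        tab = b.condition_table(table5).to_numpy()
        p = fisher_exact_2x2(tab)
        assert p == pytest.approx(_fisher_enumeration(tab), abs=1e-12)
        assert round(p, 2) == 0.18

    def test_diagonal_table(self):
        p = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_independent_table_p_one(self):
        assert fisher_exact_2x2([[2, 2], [2, 2]]) == pytest.approx(1.0)

    def test_empty_margin_convention(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        tab = rng.integers(0, 15, (2, 2))
        if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
            return
        assert fisher_exact_2x2(tab) == pytest.approx(
            _fisher_enumeration(tab.tolist()), abs=1e-10)
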