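"""Birth-death dynamics: rate normalizations, stepping rules, closed-form
count laws, structural invariants over long runs, determinism."""

import numpy as np
import pytest
from dataclasses import replace

import oriturn as ot
from oriturn.evolution import StepSizeError, step
from oriturn.kinetics import GenomeConfiguration


def config_of(length, positions, rates=None, **kw):
    if rates is None:
        rates = np.ones(len(positions))
    return GenomeConfiguration(length, positions, rates, **kw)


@pytest.fixture
def unit_pool():
    return ot.RateDistribution(np.ones(10))


class TestBirthRates:
    def test_unbiased_limit_is_proportional_to_region_length(self):
        cfg = config_of(1_000_000, [0, 100_000, 400_000])
        p = ot.ModelParams(gamma=0.0, length_bp=1_000_000)
        b = ot.birth_rates(cfg, p)
        lengths = cfg.region_lengths()
        assert b == pytest.approx(p.b_bar * lengths / 1e6, rel=1e-12)

    def test_total_birth_rate_is_always_matched(self, small_params):
        rng = np.random.default_rng(0)
        for _ in range(5):
            pos = np.sort(rng.choice(small_params.length_bp, 30, replace=False))
            cfg = config_of(small_params.length_bp, pos, rng.lognormal(size=30))
            b = ot.birth_rates(cfg, small_params)
            total = small_params.b_bar * small_params.length_bp / 1e6
            assert b.sum() == pytest.approx(total, rel=1e-12)
            assert np.all(b >= 0)

    def test_two_region_bias_ratio(self):
        # circle with regions l and 2l at gamma=1: b2/b1 = 2 P(2l)/P(l)
        l = 30_000
        cfg = config_of(3 * l, [0, l])
        p = ot.ModelParams(gamma=1.0, length_bp=3 * l)
        b = ot.birth_rates(cfg, p)
        ratio = (
            2 * ot.double_stall_probability(2 * l, p.kinetic.pi_stall)
            / ot.double_stall_probability(l, p.kinetic.pi_stall)
        )
        assert b[1] / b[0] == pytest.approx(ratio, rel=1e-10)


class TestDeathRates:
    def test_zero_beta_reduces_to_flat_rate(self):
        cfg = config_of(1_000_000, [0, 500_000])
        p = ot.ModelParams(beta=0.0)
        d = ot.death_rates(cfg, np.array([0.2, 0.9]), p)
        assert d == pytest.approx([p.d_bar, p.d_bar])

    def test_unbiased_variant_ignores_efficiency(self):
        cfg = config_of(1_000_000, [0, 500_000])
        p = ot.ModelParams(variant=ot.DOUBLE_STALL_AVERSION, beta=5.0)
        assert p.beta == 0.0  # variant invariant forces beta to zero
        d = ot.death_rates(cfg, np.array([0.1, 0.99]), p)
        assert d == pytest.approx([p.d_bar, p.d_bar])

    def test_mean_death_rate_is_always_matched(self):
        rng = np.random.default_rng(1)
        cfg = config_of(1_000_000, np.sort(rng.choice(1_000_000, 40, replace=False)))
        p = ot.ModelParams(beta=1.9)
        d = ot.death_rates(cfg, rng.random(40), p)
        assert d.mean() == pytest.approx(p.d_bar, rel=1e-12)

    def test_efficiency_contrast_sets_the_ratio(self):
        cfg = config_of(1_000_000, [0, 500_000])
        p = ot.ModelParams(beta=1.9)
        d = ot.death_rates(cfg, np.array([0.0, 1.0]), p)
        assert d[0] / d[1] == pytest.approx(np.exp(1.9), rel=1e-12)

    def test_length_mismatch_rejected(self):
        cfg = config_of(1_000_000, [0, 500_000])
        with pytest.raises(ValueError):
            ot.death_rates(cfg, np.array([0.5]), ot.ModelParams())


class TestStep:
    def test_zero_dt_is_identity(self, unit_pool):
        cfg = config_of(1_000_000, [0, 500_000])
        rng = np.random.default_rng(0)
        new, events = step(cfg, ot.ModelParams(length_bp=1_000_000), unit_pool, 0.0, rng)
        assert events == []
        assert np.array_equal(new.positions, cfg.positions)
        assert np.array_equal(new.ids, cfg.ids)

    def test_oversized_dt_rejected(self, unit_pool):
        cfg = config_of(1_000_000, [0, 500_000])
        rng = np.random.default_rng(0)
        with pytest.raises(StepSizeError):
            step(cfg, ot.ModelParams(length_bp=1_000_000), unit_pool, 1.0, rng)

    def test_newborns_appear_at_region_midpoints(self, unit_pool):
        # high birth rate, no deaths/reshuffles: every birth must land at
        # the floor-midpoint of one of the frozen regions
        cfg = config_of(1_000_000, [100_000, 400_000, 650_000])
        p = ot.ModelParams(
            b_bar=50.0, d_bar=0.0, reshuffle_rate=0.0, gamma=0.0,
            length_bp=1_000_000,
        )
        rng = np.random.default_rng(3)
        expected_midpoints = {
            100_000 + 150_000,          # region 0
            400_000 + 125_000,          # region 1
            (650_000 + 450_000 // 2) % 1_000_000,  # wrap-around region
        }
        births = []
        for _ in range(200):
            new, events = step(cfg, p, unit_pool, 1e-3, rng)
            births.extend(e.position for e in events if e.kind == "birth")
        assert births and set(births) <= expected_midpoints

    def test_midpoint_collision_shifts_by_one(self, unit_pool):
        # a two-origin toy where the midpoint is already occupied
        cfg = config_of(10, [0, 2, 5], rates=[1, 1, 1])
        # region between 0 and 2 has midpoint 1; region between 2 and 5 has
        # midpoint 3; wrap region (5..0) midpoint (5 + 5//2) % 10 = 7
        p = ot.ModelParams(
            b_bar=1e7, d_bar=0.0, reshuffle_rate=0.0, gamma=0.0, length_bp=10
        )
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(300):
            new, events = step(cfg, p, unit_pool, 1e-9, rng)
            seen |= {e.position for e in events if e.kind == "birth"}
        assert seen <= {1, 3, 7}

    def test_extinction_guard_spares_the_last_origin(self, unit_pool, caplog):
        cfg = config_of(1_000_000, [500_000])
        p = ot.ModelParams(
            b_bar=0.0, d_bar=1.0, reshuffle_rate=0.0, length_bp=1_000_000
        )
        rng = np.random.default_rng(0)
        import logging

        with caplog.at_level(logging.WARNING, logger="oriturn.evolution"):
            for _ in range(500):
                cfg, _ev = step(cfg, p, unit_pool, 0.05, rng)
        assert cfg.n == 1
        assert any("spared" in r.message for r in caplog.records)


class TestClosedFormCounts:
    def test_pure_death_decay(self, rate_dist):
        # b=0, R=0: E[n(t)] = n0 exp(-d t)
        p = ot.ModelParams(
            b_bar=0.0, reshuffle_rate=0.0, length_bp=2_000_000
        )
        n0, t = 50, 1.0
        rng = np.random.default_rng(9)
        counts = []
        for child in rng.spawn(200):
            res = ot.simulate_lineage(
                p, rate_dist, t_total=t, burn_in=0.0, snapshot_interval=t,
                n0=n0, rng=child, record_events=False, max_event_prob=0.01,
            )
            counts.append(res.final.n)
        expect = n0 * np.exp(-p.d_bar * t)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expect) < 3 * se + 0.3

    def test_pure_birth_growth(self, rate_dist):
        # d=0: E[n(t)] = n0 + b L t (the bias moves births, not their number)
        p = ot.ModelParams(
            d_bar=0.0, reshuffle_rate=0.0, gamma=0.0, length_bp=2_000_000
        )
        n0, t = 20, 1.0
        rng = np.random.default_rng(10)
        counts = []
        for child in rng.spawn(200):
            res = ot.simulate_lineage(
                p, rate_dist, t_total=t, burn_in=0.0, snapshot_interval=t,
                n0=n0, rng=child, record_events=False,
            )
            counts.append(res.final.n)
        expect = n0 + p.b_bar * p.length_bp / 1e6 * t
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expect) < 3 * se + 0.3


class TestLineage:
    def test_determinism_under_fixed_seed(self, small_params, rate_dist):
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            runs.append(
                ot.simulate_lineage(
                    small_params, rate_dist, t_total=22, burn_in=20, n0=30, rng=rng
                )
            )
        a, b = runs
        assert len(a.snapshots) == len(b.snapshots)
        for sa, sb in zip(a.snapshots, b.snapshots):
            assert sa.time == sb.time
            assert np.array_equal(sa.config.positions, sb.config.positions)
            assert np.array_equal(sa.config.ids, sb.config.ids)
            assert np.array_equal(sa.config.rates, sb.config.rates)
        assert a.events.records == b.events.records

    def test_burn_in_longer_than_total_rejected(self, small_params, rate_dist):
        with pytest.raises(ValueError):
            ot.simulate_lineage(
                small_params, rate_dist, t_total=1.0, burn_in=2.0,
                rng=np.random.default_rng(0),
            )

    def test_structural_invariants_over_a_run(self, small_run):
        # sorted unique positions, unique ids, fresh ids for births,
        # nondecreasing event times
        small_run.events.validate()
        born = small_run.events.ids_of_kind("birth")
        dead = small_run.events.ids_of_kind("death")
        for snap in small_run.snapshots:
            snap.config.validate()
        # an id never re-enters after death
        last_seen_dead = set()
        for rec in small_run.events:
            if rec.kind == "death":
                last_seen_dead.add(rec.origin_id)
            elif rec.kind == "birth":
                assert rec.origin_id not in last_seen_dead
        # bookkeeping closes: ids at the first snapshot, plus births after
        # it, minus deaths after it, give exactly the final id set
        first = small_run.snapshots[0]
        t1 = first.time
        after = small_run.events.slice(t1, np.inf)
        expected_final = (
            set(int(i) for i in first.config.ids)
            | after.ids_of_kind("birth")
        ) - after.ids_of_kind("death")
        assert set(int(i) for i in small_run.final.ids) == expected_final

    def test_stationary_count_matches_balance(self, small_run, small_params):
        mean_n = small_run.counts().mean()
        balance = small_params.expected_stationary_count
        assert 0.9 * balance < mean_n < 1.1 * balance

    def test_joint_spacing_is_narrower_than_exponential(self, small_run):
        # selection against double stalls produces lattice-like spacing
        dists = np.concatenate(
            [ot.interorigin_distances(s.config) for s in small_run.snapshots]
        )
        cv = dists.std() / dists.mean()
        assert cv < 1.0

    def test_bias_narrows_spacing_beyond_midpoint_placement(
        self, rate_dist, small_run
    ):
        # even with the bias off (gamma=0, beta=0) the midpoint placement
        # rule regularizes spacing below the exponential CV of 1; the
        # double-stall bias then narrows it further
        p = ot.ModelParams(gamma=0.0, beta=0.0, length_bp=2_000_000)
        rng = np.random.default_rng(4)
        res = ot.simulate_lineage(
            p, rate_dist, t_total=40, burn_in=20, n0=44, rng=rng,
            record_events=False,
        )
        d0 = np.concatenate(
            [ot.interorigin_distances(s.config) for s in res.snapshots]
        )
        cv0 = d0.std() / d0.mean()
        db = np.concatenate(
            [ot.interorigin_distances(s.config) for s in small_run.snapshots]
        )
        cvb = db.std() / db.mean()
        assert cvb < cv0 < 1.0

    def test_tau_leap_cap_insensitivity(self, small_params, rate_dist):
        # halving the per-event probability cap leaves the stationary mean
        # count within Monte-Carlo noise
        means = []
        for cap in (0.05, 0.025):
            vals = []
            rng = np.random.default_rng(12)
            for child in rng.spawn(4):
                res = ot.simulate_lineage(
                    small_params, rate_dist, t_total=35, burn_in=15, n0=44,
                    rng=child, record_events=False, max_event_prob=cap,
                )
                vals.append(res.counts().mean())
            means.append((np.mean(vals), np.std(vals, ddof=1) / 2))
        (m1, se1), (m2, se2) = means
        assert abs(m1 - m2) < 3 * np.hypot(se1, se2) + 1.0


class TestRateDistribution:
    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            ot.RateDistribution(np.array([]))

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            ot.RateDistribution(np.array([0.5, -0.1]))

    def test_sampling_is_uniform_over_the_pool(self):
        pool = np.array([0.5, 1.0, 1.5])
        rd = ot.RateDistribution(pool)
        rng = np.random.default_rng(0)
        draws = rd.sample(rng, 30_000)
        freqs = [np.mean(draws == v) for v in pool]
        assert freqs == pytest.approx([1 / 3] * 3, abs=0.02)
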