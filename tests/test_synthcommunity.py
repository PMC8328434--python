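"""Simulator physics, determinism, observation model, parameter recovery."""

import numpy as np
import pytest

from chemocomp.popmetrics import net_growth_rate
from chemocomp.synthcommunity import (
    AlgaTraits,
    BacteriaTraits,
    ConsumerTraits,
    SimConfig,
    default_config,
    nitrogen_balance_error,
    observe,
    simulate,
)

CRY = AlgaTraits("Cry", mu_max=0.9, k_n=2.0)


def single_alga_config(**kw):
    defaults = dict(
        algae=(CRY,),
        consumers=(),
        exudation_f=0.0,
        initial_bacteria_carbon=0.0,
        observation_noise_cv=0.0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulatorPhysics:
    def test_grazer_free_steady_state_matches_chemostat_theory(self):
        cfg = single_alga_config(duration=300.0)
        traj = simulate(cfg)
        n_star = cfg.dilution * CRY.k_n / (CRY.mu_max - cfg.dilution)
        a_star = (cfg.n_inflow - n_star) / CRY.n_quota
        assert traj.pools["N"][-1] == pytest.approx(n_star, rel=1e-6)
        assert traj.pools["Cry"][-1] == pytest.approx(a_star, rel=1e-6)

    def test_nitrogen_mass_balance_closes(self):
        traj = simulate(default_config("Col2", seed=3))
        assert nitrogen_balance_error(traj) < 1e-6

    def test_washout_when_growth_below_dilution(self):
        slow = AlgaTraits("Cry", mu_max=0.02, k_n=2.0)
        cfg = single_alga_config(algae=(slow,), duration=33.0)
        traj = simulate(cfg)
        biomass = traj.pools["Cry"]
        assert np.all(np.diff(biomass) < 0)
        # decline at least at delta - mu_max
        assert biomass[-1] <= biomass[0] * np.exp(-(cfg.dilution - slow.mu_max) * 33)
        # extended horizon: below the Cryptomonas detection biomass (10^2.5 pg C/ml)
        long_run = simulate(single_alga_config(algae=(slow,), duration=200.0))
        assert long_run.pools["Cry"][-1] < 10**2.5

    def test_consumer_washout_when_assimilated_intake_below_dilution(self):
        # growth efficiency * I_max < delta at every prey level -> always declines
        weak = ConsumerTraits(
            "Eup", imax_specific={"Cry": 0.2}, half_saturation=1e5,
            growth_efficiency=0.25,
        )
        cfg = single_alga_config(consumers=(weak,), duration=33.0)
        traj = simulate(cfg)
        assert np.all(np.diff(traj.pools["Eup"]) < 0)

    def test_default_treatment_qualitative_pattern(self):
        traj = simulate(default_config("Col2", seed=0))
        cry, nav = traj.pools["Cry"], traj.pools["Nav"]
        assert cry[-1] < 0.01 * cry[0]  # Cryptomonas driven toward detection
        assert nav[-1] > 2 * nav[0]  # Navicula rises...
        late = nav[traj.times > 25]
        assert np.all(np.abs(np.diff(late) / late[:-1]) < 1e-3)  # ...and plateaus

    def test_nonnegative_states(self):
        traj = simulate(default_config("Col1", seed=5))
        for name, arr in traj.pools.items():
            assert np.all(arr >= 0), name


class TestDeterminismAndObservation:
    def test_seed_determinism_byte_identical(self):
        cfg = default_config("Col3", seed=11)
        df1 = observe(simulate(cfg), cfg)
        df2 = observe(simulate(cfg), cfg)
        assert df1.to_csv(index=False) == df2.to_csv(index=False)

    def test_different_seeds_differ(self):
        a = observe(simulate(default_config("Col3", seed=1)))
        b = observe(simulate(default_config("Col3", seed=2)))
        assert not a["abundance_per_ml"].equals(b["abundance_per_ml"])

    def test_zero_noise_observation_matches_latent(self, profiles):
        cfg = default_config("Col2", seed=0, observation_noise_cv=0.0)
        traj = simulate(cfg)
        df = observe(traj, cfg)
        sample = df[(df["taxon"] == "Nav") & (df["replicate"] == "R1")]
        idx = [int(round(t / cfg.dt)) for t in sample["day"]]
        latent = traj.pools["Nav"][idx]
        uncensored = ~sample["censored"].to_numpy()
        assert sample["biomass_pgc_per_ml"].to_numpy()[uncensored] == pytest.approx(
            latent[uncensored], rel=1e-9
        )

    def test_censoring_substitutes_half_detection_limit(self):
        cfg = default_config("Col2", seed=0, observation_noise_cv=0.0)
        df = observe(simulate(cfg), cfg)
        late_cry = df[(df["taxon"] == "Cry") & (df["day"] > 25)]
        assert late_cry["censored"].all()
        assert (late_cry["abundance_per_ml"] == 0.5 * 3.3).all()
        eup = df[df["taxon"] == "Eup"]
        assert set(eup.loc[eup["censored"], "abundance_per_ml"]) <= {0.25}

    def test_noise_cv_reproduced_across_replicates(self):
        cfg_many = default_config("Col2", seed=7, observation_noise_cv=0.10, n_replicates=40)
        df = observe(simulate(cfg_many), cfg_many)
        nav = df[(df["taxon"] == "Nav") & (~df["censored"])]
        by_day = nav.groupby("day")["biomass_pgc_per_ml"]
        cvs = (by_day.std(ddof=1) / by_day.mean()).to_numpy()
        assert np.nanmedian(cvs) == pytest.approx(0.10, abs=0.025)

    def test_sampling_schedule(self):
        cfg = default_config("Col1", seed=0)
        df = observe(simulate(cfg), cfg)
        days = sorted(df["day"].unique())
        assert days == list(np.arange(0.0, 34.0, 2.0))


class TestParameterRecovery:
    def test_net_growth_rate_recovered_noise_free(self):
        # single consumer on one abundant alga: saturated net rate is
        # GE * imax_specific - delta, constant while prey stays saturating
        imax_spec = 1.2
        cons = ConsumerTraits("Eup", imax_specific={"Cry": imax_spec}, half_saturation=1e4)
        cfg = single_alga_config(
            consumers=(cons,),
            initial_algal_biovolume=14.4e9,  # effectively unlimited prey
            duration=6.0,
        )
        traj = simulate(cfg)
        expected = cons.growth_efficiency * imax_spec - cfg.dilution
        i0, i5 = 0, int(round(5.0 / cfg.dt))
        r = net_growth_rate(traj.pools["Eup"][i0], traj.pools["Eup"][i5], 0.0, 5.0)
        assert r == pytest.approx(expected, abs=1e-3)

    def test_replicate_mean_rate_within_two_se_under_noise(self):
        imax_spec = 1.2
        cons = ConsumerTraits("Eup", imax_specific={"Cry": imax_spec}, half_saturation=1e4)
        cfg = single_alga_config(
            consumers=(cons,),
            initial_algal_biovolume=14.4e9,
            duration=6.0,
            observation_noise_cv=0.10,
            n_replicates=4,
            seed=2026,
        )
        traj = simulate(cfg)
        df = observe(traj, cfg)
        expected = cons.growth_efficiency * imax_spec - cfg.dilution
        rates = []
        for _, grp in df[df["taxon"] == "Eup"].groupby("replicate"):
            grp = grp.sort_values("day")
            win = grp[(grp["day"] >= 0) & (grp["day"] <= 4)]
            rates.append(
                net_growth_rate(
                    win["biomass_pgc_per_ml"].iloc[0],
                    win["biomass_pgc_per_ml"].iloc[-1],
                    win["day"].iloc[0],
                    win["day"].iloc[-1],
                )
            )
        rates = np.asarray(rates)
        se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - expected) <= 2 * se


def test_integration_error_reported_with_time():
    bad = BacteriaTraits(uptake_max=1e12, k_doc=1e-12)
    cfg = SimConfig(
        algae=(CRY,),
        consumers=(),
        bacteria=bad,
        exudation_f=0.3,
        initial_doc=1e300,
        observation_noise_cv=0.0,
    )
    with np.errstate(all="ignore"), pytest.raises(FloatingPointError, match="t="):
        simulate(cfg)
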