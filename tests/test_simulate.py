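"""Generator contracts: determinism, configured moments, copula
correlation structure, stay/PCR consistency and CCR linkage."""

import numpy as np
import pandas as pd
import pytest

import paycharge as pc
import paycharge.synth as sim

from _helpers import slim_config


def _small_cfg(seed=7, **kw):
    d = dict(n_states=3, hospitals_per_state=10, seed=seed,
             stay_count_mean={p: 50.0 for p in pc.PAYERS})
    d.update(kw)
    return pc.SimConfig(**d)


class TestStates:
    def test_deterministic(self):
        cfg = _small_cfg(n_states=10)
        a = sim.generate_states(cfg)
        b = sim.generate_states(cfg)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_configured_mean_recovered(self):
        # Medicaid per-capita spending: configured mean 1137, sd 566
        cfg = pc.SimConfig(n_states=200, seed=3)
        states = sim.generate_states(cfg)
        se = 566.0 / np.sqrt(200)
        assert abs(states["medicaid_pc_spend"].mean() - 1137.0) < 3 * se

    def test_single_state(self):
        states = sim.generate_states(_small_cfg(n_states=1))
        assert len(states) == 1
        assert np.isfinite(states.drop(columns="state_id").to_numpy()).all()

    def test_rejects_nonpositive_count(self):
        with pytest.raises(ValueError):
            pc.SimConfig(n_states=0)


class TestHospitals:
    def test_designation_prevalence(self):
        cfg = pc.SimConfig(n_states=10, hospitals_per_state=100, seed=11)
        states = sim.generate_states(cfg)
        hospitals = sim.generate_hospitals(cfg, states)
        share = hospitals["teaching"].mean()
        se = np.sqrt(0.294 * 0.706 / 1000)
        assert abs(share - 0.294) < 3 * se

    def test_zero_prevalence_gives_no_flags(self):
        cfg = _small_cfg()
        cfg.designation_prevalence["teaching"] = 0.0
        hospitals = sim.generate_hospitals(cfg, sim.generate_states(cfg))
        assert hospitals["teaching"].sum() == 0

    def test_counts_balanced_across_states(self):
        cfg = pc.SimConfig(n_states=2, hospitals_per_state=5, seed=1)
        hospitals = sim.generate_hospitals(cfg, sim.generate_states(cfg))
        assert len(hospitals) == 10
        assert hospitals["state_id"].value_counts().tolist() == [5, 5]

    def test_empty_states_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_hospitals(_small_cfg(), pd.DataFrame({"state_id": []}))


class TestTruth:
    def test_degenerate_no_noise_no_slopes(self):
        # huge gamma shape kills the error; zero slopes leave exp(alpha)
        cfg = _small_cfg(gamma_shape=1e8,
                         true_slopes={p: {} for p in pc.PAYERS})
        data = pc.simulate(cfg, with_stays=False)
        for payer, want in cfg.mean_pcr.items():
            got = data.truth.table.loc[data.truth.table["payer"] == payer, "pcr_true"]
            assert np.allclose(got, want, rtol=1e-3)

    def test_identity_copula_uncorrelated(self):
        cfg = slim_config(seed=5, n_states=4, hospitals_per_state=500, R=np.eye(5))
        data = pc.simulate(cfg, with_stays=False)
        z = data.truth.table.pivot(index="hospital_id", columns="payer",
                                   values="latent_z")
        corr = z.corr().to_numpy()
        off = corr[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(len(z)))

    def test_copula_hits_configured_entry(self):
        R = np.eye(5)
        R[0, 1] = R[1, 0] = 0.6  # medicare-medicaid
        cfg = slim_config(seed=5, n_states=4, hospitals_per_state=500, R=R)
        data = pc.simulate(cfg, with_stays=False)
        z = data.truth.table.pivot(index="hospital_id", columns="payer",
                                   values="latent_z")
        r_hat = z[["medicare", "medicaid"]].corr().iloc[0, 1]
        n = len(z)
        assert abs(np.arctanh(r_hat) - np.arctanh(0.6)) < 3 / np.sqrt(n - 3)

    def test_copula_converges_in_frobenius(self):
        dists = {}
        for n_h, seed in ((75, 5), (1500, 5)):
            cfg = slim_config(seed=seed, n_states=4, hospitals_per_state=n_h)
            data = pc.simulate(cfg, with_stays=False)
            z = data.truth.table.pivot(index="hospital_id", columns="payer",
                                       values="latent_z")[list(pc.PAYERS)]
            dists[n_h] = np.linalg.norm(z.corr().to_numpy() - cfg.error_corr)
        assert dists[1500] < dists[75]

    def test_marginal_mean_matches_linear_predictor(self):
        cfg = slim_config(seed=9, n_states=4, hospitals_per_state=500)
        data = pc.simulate(cfg, with_stays=False)
        tab = data.truth.table
        for payer in pc.PAYERS:
            sub = tab[tab["payer"] == payer]
            mu = np.exp(sub["eta"])
            se = sub["pcr_true"].std() / np.sqrt(len(sub))
            assert abs(sub["pcr_true"].mean() - mu.mean()) < 3 * se

    def test_non_psd_R_rejected(self):
        R = np.eye(5)
        R[0, 1] = R[1, 0] = 0.9
        R[0, 2] = R[2, 0] = 0.9
        R[1, 2] = R[2, 1] = -0.9
        with pytest.raises(ValueError):
            pc.SimConfig(error_corr=R)

    def test_nonpositive_shape_rejected(self):
        with pytest.raises(ValueError):
            pc.SimConfig(gamma_shape=0.0)


class TestStays:
    def test_zero_noise_ratio_exact(self):
        cfg = _small_cfg(payment_noise_sd=0.0)
        data = pc.simulate(cfg)
        pcr = pc.compute_pcr(data.stays).merge(
            data.truth.table[["hospital_id", "payer", "pcr_true"]],
            on=["hospital_id", "payer"])
        assert np.allclose(pcr["pcr"], pcr["pcr_true"], rtol=1e-12)

    def test_noisy_ratio_converges_at_two_sizes(self):
        errs = {}
        for n_stays in (200, 10_000):
            cfg = pc.SimConfig(n_states=1, hospitals_per_state=1, seed=13,
                               stay_count_mean={p: float(n_stays) for p in pc.PAYERS},
                               stay_count_cv=0.0, payment_noise_sd=0.2)
            data = pc.simulate(cfg)
            stays = data.stays[data.stays["payer"] == "medicare"]
            truth = data.truth.table.query("payer == 'medicare'")["pcr_true"].iloc[0]
            ratio = stays["payment"].sum() / stays["charge"].sum()
            c = stays["charge"].to_numpy()
            # ratio = pcr * charge-weighted mean of the mean-1 noise
            se = truth * 0.2 * np.sqrt(np.sum(c**2)) / np.sum(c)
            assert abs(ratio - truth) < 3 * se
            errs[n_stays] = abs(ratio - truth)
        assert errs[10_000] < errs[200]

    def test_all_female_configuration(self):
        cfg = _small_cfg(female_mean={p: 1.0 for p in pc.PAYERS})
        data = pc.simulate(cfg)
        assert (data.stays["female"] == 1).all()

    def test_zero_stay_cells_only_when_configured(self):
        cfg = _small_cfg(zero_stay_prob={**{p: 0.0 for p in pc.PAYERS},
                                         "self_pay": 0.5})
        data = pc.simulate(cfg)
        counts = data.hospitals[[f"n_stays_{p}" for p in pc.PAYERS]]
        assert (counts.drop(columns="n_stays_self_pay") > 0).all().all()
        assert (counts["n_stays_self_pay"] == 0).any()
        # those cells produce no stays at all
        present = set(map(tuple, data.stays[["hospital_id", "payer"]]
                          .drop_duplicates().to_numpy()))
        zero_cells = data.hospitals.loc[data.hospitals["n_stays_self_pay"] == 0,
                                        "hospital_id"]
        assert all((h, "self_pay") not in present for h in zero_cells)


class TestCCR:
    def test_pure_medicare_weights(self):
        cfg = _small_cfg(ccr_weights={"medicare": 1.0, "medicaid": 0.0, "private": 0.0},
                         ccr_noise_sd=0.0)
        data = pc.simulate(cfg, with_stays=False)
        mc = data.truth.table.query("payer == 'medicare'")[["hospital_id", "pcr_true"]]
        merged = data.ccrs.merge(mc, on="hospital_id")
        assert np.allclose(merged["ccr"], merged["pcr_true"])

    def test_degenerate_config_rejected(self):
        data = pc.simulate(_small_cfg(), with_stays=False)
        bad = _small_cfg(ccr_weights={"medicare": 0.0, "medicaid": 0.0, "private": 0.0},
                         ccr_noise_sd=0.0)
        with pytest.raises(ValueError):
            sim.generate_ccrs(bad, data.truth)


class TestBundle:
    def test_full_reproducibility(self, tmp_path):
        cfg = _small_cfg(seed=21)
        m1 = pc.simulate(cfg).write(tmp_path / "a")
        m2 = pc.simulate(cfg).write(tmp_path / "b")
        assert m1["files"] == m2["files"]
        assert m1["config_sha256"] == m2["config_sha256"]

    def test_truncation_flags_match_filter(self):
        cfg = _small_cfg(payment_noise_sd=0.0)
        data = pc.simulate(cfg)
        pcr_table = pc.compute_pcr(data.stays)
        _, excluded = pc.filter_pcr_range(pcr_table)
        flagged = data.truth.table.query("flag_above_one == 1 and n_stays > 0")
        assert len(excluded) == len(flagged)
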