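import numpy as np
import pytest

from waveconn import (
    CohortConfig,
    PathModelSpec,
    generate_cohort,
    indirect_effect,
    make_parcel_table,
    simulate_cognition,
    simulate_subject_timeseries,
)

SMALL_NETS = {"DMN": 4, "SN": 3, "FPN": 3}


def small_config(**overrides):
    base = dict(
        n_per_group=(2, 2),
        n_regions=10,
        network_sizes=SMALL_NETS,
        n_timepoints=128,
        seed=0,
    )
    base.update(overrides)
    return CohortConfig(**base)


class TestConfig:
    def test_shared_mediator_coefficient_enforced(self):
        with pytest.raises(ValueError, match="same group->efficiency"):
            small_config(
                path_coeffs={
                    "score_a": {"a": -0.5, "b": 0.4, "c": 0.0},
                    "score_b": {"a": -0.3, "b": 0.4, "c": 0.0},
                }
            )

    def test_too_few_timepoints_for_decomposition(self):
        with pytest.raises(ValueError, match="2\\^6"):
            small_config(n_timepoints=32)


class TestSimulateTimeseries:
    def test_null_correlations_small(self, small_parcels):
        """With nothing planted, mean |r| stays near the 1/sqrt(T) scale."""
        cfg = small_config(
            n_timepoints=500, rho_within={"HC": 0.0, "IC": 0.0}, rho_between=0.0
        )
        ts = simulate_subject_timeseries(cfg, small_parcels, "HC", 1)
        r = np.corrcoef(ts.data, rowvar=False)
        assert np.abs(r[np.triu_indices(10, 1)]).mean() < 0.1

    def test_within_network_correlation_recovery(self, small_parcels):
        """Empirical within-network r approaches the planted target at large T."""
        cfg = small_config(
            n_timepoints=4096, rho_within={"HC": 0.6, "IC": 0.35}, rho_between=0.1
        )
        ts = simulate_subject_timeseries(cfg, small_parcels, "HC", 2)
        r = np.corrcoef(ts.data, rowvar=False)
        dmn = small_parcels.nodes_in("DMN")
        within = r[np.ix_(dmn, dmn)][np.triu_indices(dmn.size, 1)]
        assert within.mean() == pytest.approx(0.6, abs=0.05)

    def test_dominant_power_in_level4_band(self, small_parcels):
        cfg = small_config(n_timepoints=1024)
        ts = simulate_subject_timeseries(cfg, small_parcels, "IC", 3)
        freqs = np.fft.rfftfreq(1024, d=cfg.tr_seconds)
        psd = np.abs(np.fft.rfft(ts.data, axis=0)) ** 2
        peak = freqs[np.argmax(psd.mean(axis=1))]
        band = __import__("waveconn").band_for_level(cfg.tr_seconds, 4)
        assert band.contains(peak)

    def test_same_seed_bit_identical(self, small_parcels):
        cfg = small_config()
        a = simulate_subject_timeseries(cfg, small_parcels, "IC", 42)
        b = simulate_subject_timeseries(cfg, small_parcels, "IC", 42)
        assert np.array_equal(a.data, b.data)

    def test_non_positive_definite_rejected(self, small_parcels):
        cfg = small_config(rho_within={"HC": 0.1, "IC": 0.1}, rho_between=-0.5)
        with pytest.raises(ValueError, match="positive-definite"):
            simulate_subject_timeseries(cfg, small_parcels, "HC", 0)


class TestSimulateCognition:
    def test_noiseless_closed_form(self):
        cfg = small_config(
            noise_sd={"efficiency": 1.0, "score": 0.0},
            path_coeffs={"score_x": {"a": -0.5, "b": 0.0, "c": -0.5}},
        )
        group = np.array([0.0, 1.0, 1.0, 0.0])
        scores = simulate_cognition(cfg, group, np.zeros(4))
        assert np.allclose(scores["score_x"], -0.5 * group)

    def test_planted_indirect_effect_is_product(self):
        cfg = small_config(
            path_coeffs={"score_x": {"a": -0.5, "b": 0.4, "c": 0.0}},
        )
        cohort = generate_cohort(cfg)
        assert cohort.ground_truth.indirect_effect("score_x") == pytest.approx(-0.2)

    def test_deterministic_under_seed(self):
        cfg = small_config()
        a = generate_cohort(cfg).manifest()
        b = generate_cohort(cfg).manifest()
        assert a.equals(b)


class TestGenerateCohort:
    def test_study_template_counts(self):
        cfg = small_config(n_per_group=(30, 27), n_timepoints=64, wavelet_levels=6)
        # keep it cheap: tiny T is enough to count subjects
        cfg = CohortConfig(
            n_per_group=(30, 27), n_regions=10, network_sizes=SMALL_NETS, n_timepoints=64
        )
        cohort = generate_cohort(cfg)
        groups = [s.group for s in cohort.subjects]
        assert len(cohort.subjects) == 57
        assert groups.count("IC") == 30 and groups.count("HC") == 27

    def test_smoke_invariants(self):
        cohort = generate_cohort(small_config(n_timepoints=64))
        assert len(cohort.timeseries) == 4
        for ts in cohort.timeseries.values():
            assert ts.data.shape == (64, 10)
            assert np.all(np.isfinite(ts.data))
        names = {k for s in cohort.subjects for k in s.covariates}
        assert names == {"other_substance_months"}

    def test_seed_changes_scores_not_truth(self):
        a = generate_cohort(small_config(seed=1))
        b = generate_cohort(small_config(seed=2))
        sa = [s.cognitive_scores["score_stroop"] for s in a.subjects]
        sb = [s.cognitive_scores["score_stroop"] for s in b.subjects]
        assert sa != sb
        assert a.ground_truth.path_coeffs == b.ground_truth.path_coeffs

    def test_cohort_written_to_disk(self, tmp_path):
        cohort = generate_cohort(small_config(n_timepoints=64))
        cohort.write(tmp_path / "cohort")
        assert (tmp_path / "cohort" / "manifest.tsv").exists()
        assert (tmp_path / "cohort" / "parcels.tsv").exists()
        assert (tmp_path / "cohort" / "ground_truth.json").exists()
        assert len(list((tmp_path / "cohort" / "timeseries").glob("*.tsv"))) == 4


class TestPlantedMediationRecovery:
    def test_indirect_effect_within_bootstrap_ci(self):
        """The planted a*b falls inside the bootstrap CI in >= 90% of seeded
        replicates at n = 200 per group (mediation on the latent construct)."""
        spec = PathModelSpec(
            ("group", "eff", "score"),
            (("group", "eff"), ("eff", "score"), ("group", "score")),
        )
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            group = np.repeat([0.0, 1.0], 200)
            eff = -0.5 * group + rng.normal(0, 0.97, 400)
            cfg = small_config(
                path_coeffs={"score_x": {"a": -0.5, "b": 0.4, "c": 0.0}},
            )
            scores = simulate_cognition(cfg, group, eff, rng)
            import pandas as pd

            df = pd.DataFrame({"group": group, "eff": eff, "score": scores["score_x"]})
            ie = indirect_effect(spec, df, ("group", "eff", "score"), n_boot=500, seed=seed)
            if ie.ci_low <= -0.2 <= ie.ci_high:
                hits += 1
        assert hits >= int(0.9 * n_rep)
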