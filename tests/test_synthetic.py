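import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from immunopet import (
    OutcomeSpec,
    PhantomSpec,
    gen_expression,
    gen_icb_cohort,
    gen_latent_scores,
    gen_phantom_cohort,
    texture_statistic,
)


class TestPhantoms:
    def test_same_seed_identical_cohort(self):
        spec = PhantomSpec(n_patients=4, rng_seed=11)
        v1, m1, t1 = gen_phantom_cohort(spec)
        v2, m2, t2 = gen_phantom_cohort(spec)
        for a, b in zip(v1, v2):
            np.testing.assert_array_equal(a.data, b.data)
        pd.testing.assert_frame_equal(t1, t2)

    def test_noise_free_lesions_identical_up_to_placement(self):
        spec = PhantomSpec(
            n_patients=4, rng_seed=2, noise_sd=0.0,
            radius_range_mm=(10, 10), aspect_jitter=0.0,
        )
        latent = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(4)],
            "lesion_id": [f"P{i}_L0" for i in range(4)],
            "u": [0.0] * 4,
        })
        vols, masks, table = gen_phantom_cohort(spec, latent=latent)
        crops = []
        for vol, row in zip(vols, table.itertuples(index=False)):
            c = np.array([row.cz, row.cy, row.cx])
            crops.append(vol.data[c[0]-6:c[0]+7, c[1]-6:c[1]+7, c[2]-6:c[2]+7])
        for crop in crops[1:]:
            np.testing.assert_allclose(crop, crops[0], atol=1e-10)

    def test_texture_parameter_strictly_monotone(self):
        spec = PhantomSpec()
        u = np.linspace(-3, 3, 50)
        assert np.all(np.diff(spec.rim_contrast(u)) > 0)
        assert np.all(np.diff(spec.speckle_gain(u)) > 0)

    def test_extreme_latents_have_ordered_texture(self):
        spec = PhantomSpec(n_patients=2, rng_seed=3, radius_range_mm=(10, 10))
        latent = pd.DataFrame(
            {"patient_id": ["A", "B"], "lesion_id": ["A_L0", "B_L0"], "u": [-2.0, 2.0]}
        )
        vols, masks, table = gen_phantom_cohort(spec, latent=latent)
        assert table.loc[1, "texture_stat"] > table.loc[0, "texture_stat"]

    def test_texture_statistic_recovers_latent(self):
        # parameter-level link is exactly monotone; the voxel-measured
        # statistic stays highly rank-correlated under default noise
        spec = PhantomSpec(n_patients=150, rng_seed=1)
        _, _, table = gen_phantom_cohort(spec)
        assert sps.spearmanr(
            spec.rim_contrast(table["u"]), table["u"]
        ).statistic == pytest.approx(1.0)
        assert sps.spearmanr(table["texture_stat"], table["u"]).statistic >= 0.9

    def test_mask_matches_analytic_ellipsoid(self):
        spec = PhantomSpec(n_patients=1, rng_seed=8)
        vols, masks, table = gen_phantom_cohort(spec)
        row = table.iloc[0]
        grids = np.ogrid[0:32, 0:32, 0:32]
        rho = np.sqrt(sum(
            ((g - c) / r) ** 2
            for g, c, r in zip(grids, (row.cz, row.cy, row.cx), (row.rz, row.ry, row.rx))
        ))
        np.testing.assert_array_equal(masks[0].data, rho <= 1.0)

    def test_lesion_too_large_rejected(self):
        spec = PhantomSpec(n_patients=1, volume_shape=(16, 16, 16), radius_range_mm=(14, 14))
        with pytest.raises(ValueError, match="larger than volume"):
            gen_phantom_cohort(spec)


class TestLatentScores:
    def test_single_lesion_default_is_standard_normal(self):
        spec = PhantomSpec(n_patients=4000, rng_seed=0)
        t = gen_latent_scores(spec)
        assert len(t) == 4000
        assert t["u"].mean() == pytest.approx(0.0, abs=0.06)
        assert t["u"].std() == pytest.approx(1.0, abs=0.05)

    def test_multilesion_counts_follow_distribution(self):
        spec = PhantomSpec(
            n_patients=2000, lesions_per_patient_probs=(0.35, 0.3, 0.2, 0.15), rng_seed=1
        )
        counts = gen_latent_scores(spec).groupby("patient_id").size()
        freq = counts.value_counts(normalize=True).sort_index()
        np.testing.assert_allclose(freq.to_numpy(), (0.35, 0.3, 0.2, 0.15), atol=0.04)


class TestICBOutcomes:
    def test_degenerate_slope_response_set_by_intercept(self):
        lat = gen_latent_scores(PhantomSpec(n_patients=10, rng_seed=2))
        spec = OutcomeSpec(size_slope=1e-9, size_noise_sd=0.0, hetero_size_coef=0.0,
                           size_intercept=-50.0, rng_seed=3)
        _, pt = gen_icb_cohort(lat, spec)
        assert pt["responder"].all()
        spec2 = OutcomeSpec(size_slope=1e-9, size_noise_sd=0.0, hetero_size_coef=0.0,
                            size_intercept=-10.0, rng_seed=3)
        _, pt2 = gen_icb_cohort(lat, spec2)
        assert not pt2["responder"].any()

    def test_noise_free_sizechange_perfectly_anticorrelated(self):
        lat = gen_latent_scores(PhantomSpec(n_patients=30, rng_seed=4))
        spec = OutcomeSpec(size_noise_sd=0.0, hetero_size_coef=0.0, rng_seed=5)
        ld, _ = gen_icb_cohort(lat, spec)
        keep = ld["size_change_pct"] > -100  # clipping breaks ties at the floor
        assert sps.spearmanr(ld.loc[keep, "u"], ld.loc[keep, "size_change_pct"]).statistic == pytest.approx(-1.0)

    def test_lesionwise_anticorrelation_at_defaults(self):
        rhos = []
        for s in range(20):
            lat = gen_latent_scores(PhantomSpec(
                n_patients=40, lesions_per_patient_probs=(0.35, 0.3, 0.2, 0.15),
                hetero_traits=True, rng_seed=50 + s,
            ))
            ld, _ = gen_icb_cohort(lat, OutcomeSpec(rng_seed=60 + s))
            rhos.append(sps.spearmanr(ld["u"], ld["size_change_pct"]).statistic)
        assert np.median(rhos) <= -0.5

    def test_schema_and_bounds(self):
        lat = gen_latent_scores(PhantomSpec(
            n_patients=15, lesions_per_patient_probs=(0.25, 0.25, 0.25, 0.25), rng_seed=6
        ))
        ld, pt = gen_icb_cohort(lat, OutcomeSpec(rng_seed=7))
        assert {"patient_id", "lesion_id", "site", "baseline_size_mm",
                "size_change_pct", "predicted_cytact"} <= set(ld.columns)
        assert (ld["size_change_pct"] >= -100).all()
        assert (ld["baseline_size_mm"] > 0).all()
        assert (pt["pfs_months"] > 0).all() and (pt["os_months"] > 0).all()
        assert set(pt["best_response"]) <= {"PR", "SD", "PD"}
        assert (pt["responder"] == (pt["best_response"] == "PR")).all()

    def test_determinism(self):
        lat = gen_latent_scores(PhantomSpec(n_patients=10, rng_seed=8))
        ld1, pt1 = gen_icb_cohort(lat, OutcomeSpec(rng_seed=9))
        ld2, pt2 = gen_icb_cohort(lat, OutcomeSpec(rng_seed=9))
        pd.testing.assert_frame_equal(ld1, ld2)
        pd.testing.assert_frame_equal(pt1, pt2)
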