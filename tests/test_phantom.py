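"""Synthetic sac-phantom generator: determinism, geometry and calibration."""

import dataclasses

import numpy as np
import pytest

from sactex.phantom import CohortParams, PhantomParams, generate_cohort, render_sac_image


def test_noise_free_homogeneous_sac_equals_thrombus_mean():
    p = PhantomParams(thrombus_sd=0.0, n_pockets=0)
    image, mask = render_sac_image(p, expander=False)
    assert (image[mask] == p.thrombus_mean).all()


def test_same_seed_is_bit_identical():
    p = PhantomParams(seed=7)
    a_img, a_mask = render_sac_image(p, expander=True)
    b_img, b_mask = render_sac_image(p, expander=True)
    np.testing.assert_array_equal(a_img, b_img)
    np.testing.assert_array_equal(a_mask, b_mask)


def test_pockets_raise_in_mask_variance():
    strong = PhantomParams(pocket_amplitude=150.0, n_pockets=5, seed=3)
    image_exp, mask = render_sac_image(strong, expander=True)
    image_sta, _ = render_sac_image(strong, expander=False)
    assert image_exp[mask].var() > image_sta[mask].var()


def test_zero_amplitude_makes_groups_exchangeable():
    p = PhantomParams(pocket_amplitude=0.0, seed=5)
    image_exp, _ = render_sac_image(p, expander=True)
    image_sta, _ = render_sac_image(p, expander=False)
    np.testing.assert_array_equal(image_exp, image_sta)


def test_expected_variance_contrast_monotone_in_amplitude():
    gaps = []
    for amp in (0.0, 200.0, 600.0):
        diffs = []
        for seed in range(8):
            p = PhantomParams(pocket_amplitude=amp, seed=seed)
            e, mask = render_sac_image(p, expander=True)
            s, _ = render_sac_image(p, expander=False)
            diffs.append(e[mask].var() - s[mask].var())
        gaps.append(np.mean(diffs))
    assert gaps[0] == 0.0
    assert gaps[0] < gaps[1] < gaps[2]


@pytest.mark.parametrize(
    "kwargs,param",
    [
        ({"sac_radius_px": 60.0}, "sac_radius_px"),  # exceeds image half-size
        ({"lumen_radius_frac": 1.2}, "lumen_radius_frac"),
    ],
)
def test_degenerate_geometry_names_the_parameter(kwargs, param):
    with pytest.raises(ValueError, match=param):
        render_sac_image(PhantomParams(**kwargs), expander=False)


def test_cohort_manifest_counts_and_files(tmp_path):
    cp = CohortParams(n_total=12, n_expanders=5, seed=1)
    pp = PhantomParams(image_size=32, sac_radius_px=12.0)
    manifest = generate_cohort(cp, pp, tmp_path)
    assert len(manifest) == 12
    assert (manifest["group"] == "expander").sum() == 5
    for rec in manifest.itertuples():
        assert (tmp_path / rec.image_path).exists()
        assert (tmp_path / rec.mask_path).exists()
    assert (tmp_path / "manifest.csv").exists()
    assert (tmp_path / "params.json").exists()


def test_default_cohort_reproduces_study_tallies():
    cp = CohortParams()  # 99 patients, 38 expanders, exact endoleak counts
    manifest = generate_cohort(cp, write_images=False)
    counts = manifest.groupby("group")["endoleak"].value_counts()
    assert counts["expander", "type_I"] == 6
    assert counts["expander", "type_II"] == 6
    assert counts["non_expander", "type_I"] == 1
    assert counts["non_expander", "type_II"] == 6
    assert (manifest["endoleak"] == "type_I").sum() + (
        manifest["endoleak"] == "type_II"
    ).sum() == 19


def test_zero_variance_deltas_are_exact():
    cp = CohortParams(n_total=20, n_expanders=8, delta_exp_sd=0.0, seed=2)
    manifest = generate_cohort(cp, write_images=False)
    exp = manifest[manifest["group"] == "expander"]
    rel = (exp["V2"] - exp["V1"]) / exp["V1"]
    np.testing.assert_allclose(rel, 0.098, atol=1e-3)  # manifest rounds to 4 decimals


def test_rule_labels_match_groups_when_deltas_are_deterministic():
    cp = CohortParams(n_total=30, n_expanders=12, delta_exp_sd=0.0,
                      delta_non_sd=0.0, seed=6)
    manifest = generate_cohort(cp, write_images=False)
    from sactex.labeling import apply_reference_standard

    labeled = apply_reference_standard(manifest)
    expected = manifest["group"].map(
        {"expander": "expansion", "non_expander": "non_expansion"}
    )
    assert (labeled["label"] == expected).all()


def test_cohort_generation_deterministic_from_seed():
    cp = CohortParams(n_total=15, n_expanders=6, seed=11)
    a = generate_cohort(cp, write_images=False)
    b = generate_cohort(cp, write_images=False)
    assert a.equals(b)


def test_large_cohort_expander_mean_within_three_se():
    cp = CohortParams(n_total=2000, n_expanders=768, seed=4)
    manifest = generate_cohort(cp, write_images=False)
    exp = manifest[manifest["group"] == "expander"]
    rel = ((exp["V2"] - exp["V1"]) / exp["V1"]).to_numpy()
    se = cp.delta_exp_sd / np.sqrt(len(rel))
    assert abs(rel.mean() - cp.delta_exp_mean) < 3 * se


def test_v1_lognormal_moment_calibration():
    cp = CohortParams(n_total=20000, n_expanders=0, seed=9)
    manifest = generate_cohort(cp, write_images=False)
    v1 = manifest["V1"].to_numpy()
    assert (v1 > 0).all()
    assert v1.mean() == pytest.approx(156.9, rel=0.05)
    assert v1.std() == pytest.approx(133.6, rel=0.08)


def test_impossible_sizes_rejected():
    with pytest.raises(ValueError, match="n_expanders"):
        CohortParams(n_total=10, n_expanders=11)


def test_covariates_independent_of_group_by_construction():
    cp = CohortParams(n_total=3000, n_expanders=1500, seed=12)
    manifest = generate_cohort(cp, write_images=False)
    by_group = manifest.groupby("group")["age_yr"].mean()
    assert abs(by_group.diff().iloc[-1]) < 1.5  # ~3 SE at this n


def test_bernoulli_endoleak_mode_runs():
    cp = CohortParams(n_total=50, n_expanders=20, endoleak_mode="bernoulli", seed=3)
    manifest = generate_cohort(cp, write_images=False)
    assert set(manifest["endoleak"]) <= {"none", "type_I", "type_II"}


def test_per_patient_images_use_distinct_seeds(tmp_path):
    cp = CohortParams(n_total=4, n_expanders=2, seed=0)
    pp = PhantomParams(image_size=32, sac_radius_px=12.0)
    generate_cohort(cp, pp, tmp_path)
    from sactex.io import read_image

    imgs = [read_image(tmp_path / f"images/P{k + 1:04d}.png") for k in range(4)]
    assert not np.array_equal(imgs[2], imgs[3])  # same group, different noise
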