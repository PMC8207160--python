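import numpy as np
import pandas as pd
import pytest

from fluctasym.asymmetry import (
    AnovaResults,
    FluctuatingAsymmetryModel,
    detect_fa,
    mahalanobis_shape_fa,
    procrustes_anova,
    size_anova,
    size_fa_index,
)
from fluctasym.gpa import ProcrustesResult, gpa_align, reflect_side
from fluctasym.simulate import LandmarkModel, gen_landmark_dataset
from fluctasym.tpsio import ReplicateDesign


def brute_force_ss(Y, keys):
    """Balanced-design decomposition from explicit cell/marginal means."""
    df = keys.copy()
    df = df.assign(**{f"y{j}": Y[:, j] for j in range(Y.shape[1])})
    ycols = [c for c in df.columns if c.startswith("y")]
    grand = df[ycols].mean()
    tot = ((df[ycols] - grand) ** 2).sum().sum()

    def between(groupcols):
        means = df.groupby(groupcols, sort=True)[ycols].transform("mean")
        return ((means - grand) ** 2).sum().sum()

    ss_ind = between(["specimen_id"])
    ss_side = between(["side"])
    ss_cells = between(["specimen_id", "side"])
    ss_int = ss_cells - ss_ind - ss_side
    ss_img_tot = between(["specimen_id", "side", "image_rep"])
    ss_img = ss_img_tot - ss_cells
    ss_res = tot - ss_img_tot
    return {
        "individual": ss_ind,
        "side": ss_side,
        "individual_x_side": ss_int,
        "error1": ss_img,
        "residual": ss_res,
        "total": tot,
    }


class TestAnovaAgainstBruteForce:
    def test_shape_ss_match_group_mean_oracle(self, tiny_aligned):
        res = procrustes_anova(tiny_aligned)
        n, k, _ = tiny_aligned.aligned.shape
        Y = tiny_aligned.aligned.reshape(n, 2 * k)
        oracle = brute_force_ss(Y, tiny_aligned.keys)
        for eff in ("individual", "side", "individual_x_side", "error1", "residual"):
            assert res.table.loc[eff, "SS"] == pytest.approx(oracle[eff], abs=1e-9)
        assert res.table["SS"].sum() == pytest.approx(oracle["total"], abs=1e-9)

    def test_size_ss_match_group_mean_oracle(self, tiny_aligned):
        res = size_anova(tiny_aligned)
        Y = tiny_aligned.centroid_sizes.reshape(-1, 1)
        oracle = brute_force_ss(Y, tiny_aligned.keys)
        for eff in ("individual", "side", "individual_x_side", "error1", "residual"):
            assert res.table.loc[eff, "SS"] == pytest.approx(oracle[eff], abs=1e-9)

    def test_balanced_df_pattern_for_the_reference_design(self):
        # 86 individuals, k = 10 landmarks, 2 images x 3 digitizings
        model = LandmarkModel(n_individuals=86, seed=0)
        proc = gpa_align(reflect_side(gen_landmark_dataset(model), "right"))
        shape = procrustes_anova(proc)
        assert shape.table.loc["side", "df"] == 16            # 2k - 4
        assert shape.table.loc["individual", "df"] == 1360    # 85 * 16
        assert shape.table.loc["individual_x_side", "df"] == 1360
        size = size_anova(proc)
        assert size.table.loc["individual", "df"] == 85
        assert size.table.loc["side", "df"] == 1
        assert size.table.loc["individual_x_side", "df"] == 85
        # nested error strata: 86*2*(2-1) image groups, remainder digitizing
        assert size.table.loc["error1", "df"] == 172
        assert size.table.loc["residual", "df"] == 688

    def test_identical_configurations_give_zero_ss(self):
        model = LandmarkModel(
            sigma_ind=0, sigma_fa=0, sigma_image=0, sigma_digit=0,
            rotation_jitter=0, translation_jitter=0,
            n_individuals=3, n_images=2, n_digitizings=2, seed=0,
        )
        proc = gpa_align(reflect_side(gen_landmark_dataset(model), "right"))
        res = size_anova(proc)
        assert res.table["SS"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_single_side_is_an_error(self, tiny_aligned):
        keys = tiny_aligned.keys
        mask = (keys["side"] == "left").to_numpy()
        one_sided = ProcrustesResult(
            aligned=tiny_aligned.aligned[mask],
            consensus=tiny_aligned.consensus,
            centroid_sizes=tiny_aligned.centroid_sizes[mask],
            keys=keys[mask].reset_index(drop=True),
            iterations=1, converged=True, k=tiny_aligned.k,
        )
        with pytest.raises(ValueError, match="side"):
            size_anova(one_sided)


def _anova_from_rows(f_int, p_int, f_err):
    table = pd.DataFrame(
        {
            "SS": [1.0] * 5, "df": [10] * 5, "MS": [1.0] * 5,
            "F": [np.nan, np.nan, f_int, f_err, np.nan],
            "p": [np.nan, np.nan, p_int, 0.5, np.nan],
            "denominator": [""] * 5,
        },
        index=["individual", "side", "individual_x_side", "error1", "residual"],
    )
    return AnovaResults(table, trait="shape", design=ReplicateDesign(2, 3))


class TestDetectionRule:
    def test_reference_table_values_fire_the_rule(self):
        # interaction F 8.89 vs error stratum F 0.63: ratio criterion 8.89 > 6.3
        det = detect_fa(_anova_from_rows(8.89, 1e-5, 0.63))
        assert det.detected and det.p_significant and det.f_ratio_exceeded

    def test_ratio_below_ten_not_detected(self):
        det = detect_fa(_anova_from_rows(5.0, 0.001, 1.0))
        assert not det.detected and det.p_significant and not det.f_ratio_exceeded

    def test_nonsignificant_p_not_detected(self):
        det = detect_fa(_anova_from_rows(100.0, 0.2, 1.0))
        assert not det.detected

    def test_missing_rows_raise(self):
        table = _anova_from_rows(1, 1, 1).table.drop(index="error1")
        with pytest.raises(ValueError, match="error1"):
            detect_fa(AnovaResults(table, "shape", ReplicateDesign(2, 3)))


def _proc_from_asymmetries(asym_vectors, k):
    """One left and one right configuration per specimen whose aligned
    difference equals the requested asymmetry vectors."""
    base = np.linspace(0.0, 1.0, 2 * k).reshape(k, 2)
    rows, keys = [], []
    for i, v in enumerate(asym_vectors):
        v = np.asarray(v, float).reshape(k, 2)
        for side, sgn in (("left", 0.5), ("right", -0.5)):
            rows.append(base + sgn * v)
            keys.append((f"sp{i + 1}", "pop", side, 1, 1))
    keys = pd.DataFrame(
        keys, columns=["specimen_id", "population", "side", "image_rep", "digit_rep"]
    )
    aligned = np.stack(rows)
    return ProcrustesResult(
        aligned=aligned, consensus=base, centroid_sizes=np.ones(len(rows)),
        keys=keys, iterations=1, converged=True, k=k,
    )


class TestMahalanobisScore:
    def test_specimen_at_mean_asymmetry_scores_zero(self):
        # three specimens; the third's asymmetry equals the mean of all three
        vs = [np.full(4, 0.02), np.full(4, -0.02), np.zeros(4)]
        vs = [np.r_[v, np.zeros(0)] for v in vs]
        proc = _proc_from_asymmetries([v.reshape(2, 2) for v in vs], k=2)
        scores = mahalanobis_shape_fa(proc)
        assert scores.set_index("specimen_id").loc["sp3", "shape_fa"] == pytest.approx(0.0, abs=1e-8)

    def test_two_specimens_score_equally(self):
        rng = np.random.default_rng(1)
        proc = _proc_from_asymmetries(rng.normal(0, 0.01, size=(2, 3, 2)), k=3)
        s = mahalanobis_shape_fa(proc)["shape_fa"].to_numpy()
        assert s[0] == pytest.approx(s[1], rel=1e-9)

    def test_diagonal_covariance_matches_hand_formula(self):
        # deviations (+-a, +-b) in two coordinates: S = diag(4a^2/3, 4b^2/3),
        # so every score is sqrt(a^2/(4a^2/3) + b^2/(4b^2/3)) = sqrt(3/2)
        a, b = 0.02, 0.05
        vs = np.zeros((4, 3, 2))
        vs[:, 0, 0] = [a, a, -a, -a]
        vs[:, 0, 1] = [b, -b, b, -b]
        proc = _proc_from_asymmetries(vs, k=3)
        scores = mahalanobis_shape_fa(proc)["shape_fa"].to_numpy()
        np.testing.assert_allclose(scores, np.sqrt(1.5), rtol=1e-9)

    def test_invariant_to_global_rotation_of_aligned_data(self, tiny_aligned):
        s1 = mahalanobis_shape_fa(tiny_aligned)["shape_fa"].to_numpy()
        theta = 0.7
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
        rotated = ProcrustesResult(
            aligned=tiny_aligned.aligned @ R.T,
            consensus=tiny_aligned.consensus @ R.T,
            centroid_sizes=tiny_aligned.centroid_sizes,
            keys=tiny_aligned.keys, iterations=1, converged=True, k=tiny_aligned.k,
        )
        s2 = mahalanobis_shape_fa(rotated)["shape_fa"].to_numpy()
        np.testing.assert_allclose(s1, s2, rtol=1e-6)

    def test_fewer_than_two_specimens_raise(self):
        proc = _proc_from_asymmetries(np.zeros((1, 3, 2)), k=3)
        with pytest.raises(ValueError):
            mahalanobis_shape_fa(proc)


class TestSizeFaIndex:
    def test_signed_and_absolute_arithmetic(self):
        rows, keys = [], []
        for side, reps in (("left", (10.0, 10.2)), ("right", (9.8, 10.0))):
            for j, cs in enumerate(reps, start=1):
                tri = np.array([[0, 0], [1, 0], [0, 1]], float)
                tri *= cs / np.sqrt((
                    (tri - tri.mean(0)) ** 2).sum())
                rows.append(tri - tri.mean(0))
                keys.append(("sp1", "pop", side, j, 1))
        # second specimen: perfectly symmetric
        for side in ("left", "right"):
            for j in (1, 2):
                tri = np.array([[0, 0], [1, 0], [0, 1]], float)
                rows.append(tri - tri.mean(0))
                keys.append(("sp2", "pop", side, j, 1))
        keys = pd.DataFrame(
            keys, columns=["specimen_id", "population", "side", "image_rep", "digit_rep"]
        )
        sizes = np.array([np.sqrt(((r - r.mean(0)) ** 2).sum()) for r in rows])
        proc = ProcrustesResult(
            aligned=np.stack([r / np.sqrt(((r - r.mean(0)) ** 2).sum()) for r in rows]),
            consensus=rows[0], centroid_sizes=sizes, keys=keys,
            iterations=1, converged=True, k=3,
        )
        out = size_fa_index(proc).set_index("specimen_id")
        assert out.loc["sp1", "size_fa_signed"] == pytest.approx(0.2, abs=1e-9)
        assert out.loc["sp1", "size_fa_abs"] == pytest.approx(0.2, abs=1e-9)
        assert out.loc["sp2", "size_fa_signed"] == pytest.approx(0.0, abs=1e-12)

    def test_folded_normal_population_mean(self):
        # only FA noise: signed index ~ N(0, (scale*sigma_fa)^2), so the mean
        # absolute index approaches scale*sigma_fa*sqrt(2/pi)
        sigma_fa, scale = 0.01, 20.0
        model = LandmarkModel(
            sigma_ind=0.0, sigma_fa=sigma_fa, sigma_image=0.0, sigma_digit=0.0,
            rotation_jitter=0.0, translation_jitter=0.0,
            n_individuals=400, n_images=1, n_digitizings=1, scale=scale, seed=11,
        )
        proc = gpa_align(reflect_side(gen_landmark_dataset(model), "right"))
        out = size_fa_index(proc)
        expected = scale * sigma_fa * np.sqrt(2 / np.pi)
        assert out["size_fa_abs"].mean() == pytest.approx(expected, rel=0.12)


def test_variance_components_recover_generating_model(tiny_model):
    model = LandmarkModel(
        sigma_ind=0.02, sigma_fa=0.006, sigma_image=0.001, sigma_digit=0.002,
        n_individuals=200, n_images=2, n_digitizings=3, scale=1.0, seed=4,
    )
    proc = gpa_align(reflect_side(gen_landmark_dataset(model), "right"))
    fit = FluctuatingAsymmetryModel(proc).fit()
    vc = fit.shape_anova.variance_components()
    assert vc["sigma2_fa"] == pytest.approx(model.sigma_fa**2, rel=0.25)
    assert vc["sigma2_image"] == pytest.approx(model.sigma_image**2, rel=0.25)
    assert vc["sigma2_digit"] == pytest.approx(model.sigma_digit**2, rel=0.25)


def test_model_results_summary_mentions_detection(tiny_aligned):
    fit = FluctuatingAsymmetryModel(tiny_aligned).fit()
    text = fit.summary()
    assert "ANOVA for shape" in text and "FA detection" in text
    assert set(fit.scores.columns) >= {
        "specimen_id", "population", "shape_fa", "size_fa_signed", "size_fa_abs"
    }
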