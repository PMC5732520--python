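import numpy as np
import pytest

from femstrength import (
    ForceDisplacementCurve,
    cohort_report,
    fracture_load_fea,
    fracture_load_mechanical,
    linreg,
    mann_whitney_u,
    stiffness_20_80,
)
from femstrength.fracture_metrics import NoFractureError, multiple_regression, students_t
from femstrength.synthetic_specimens import CohortDesign, make_cohort, make_curve


def bilinear_curve(stiffness=1000.0, knee=500.0, post=700.0, increment=0.1, total=1.0):
    d = np.arange(0.0, total + increment / 2, increment)
    d_knee = knee / stiffness
    f = np.where(d <= d_knee, stiffness * d, knee + post * (d - d_knee))
    return ForceDisplacementCurve(d, f)


# ---------------------------------------------------------------------------
# stiffness


def test_stiffness_exact_line():
    c = ForceDisplacementCurve(np.linspace(0, 1, 21), 1000.0 * np.linspace(0, 1, 21))
    assert stiffness_20_80(c, 1000.0) == pytest.approx(1000.0, rel=1e-12)


def test_stiffness_window_avoids_knee():
    c = bilinear_curve(stiffness=1000.0, knee=800.0, post=100.0, increment=0.02, total=1.4)
    # fracture load 800: window [160, 640] is entirely pre-knee
    assert stiffness_20_80(c, 800.0) == pytest.approx(1000.0, rel=1e-9)


def test_stiffness_matches_normal_equations():
    rng = np.random.default_rng(3)
    d = np.sort(rng.uniform(0, 2, 40))
    d += np.arange(40) * 1e-6
    f = 800.0 * d + rng.normal(0, 5, 40)
    c = ForceDisplacementCurve(d, f)
    fl = f.max()
    mask = (f >= 0.2 * fl) & (f <= 0.8 * fl)
    x = np.column_stack([d[mask], np.ones(mask.sum())])
    beta = np.linalg.solve(x.T @ x, x.T @ f[mask])
    assert stiffness_20_80(c, fl) == pytest.approx(beta[0], abs=1e-10 * abs(beta[0]))


def test_stiffness_scale_equivariance():
    c = bilinear_curve(increment=0.02)
    s1 = stiffness_20_80(c, 500.0)
    c2 = ForceDisplacementCurve(c.displacement, 3.7 * c.force)
    assert stiffness_20_80(c2, 3.7 * 500.0) == pytest.approx(3.7 * s1, rel=1e-12)


def test_stiffness_sparse_window_errors():
    c = ForceDisplacementCurve([0.0, 1.0, 2.0], [0.0, 500.0, 1000.0])
    with pytest.raises(ValueError, match="denser"):
        stiffness_20_80(c, 10000.0)


# ---------------------------------------------------------------------------
# fracture detection


def test_fea_detector_constructed_tangent_drop():
    """Tangents 1000 for five 0.1 mm steps then 700 fire at 500 N."""
    d = np.arange(0.0, 1.05, 0.1)
    f = np.where(d <= 0.5, 1000.0 * d, 500.0 + 700.0 * (d - 0.5))
    m = fracture_load_fea(ForceDisplacementCurve(d, f))
    assert m.fracture_load == pytest.approx(500.0)
    assert m.reference_stiffness == pytest.approx(1000.0, rel=1e-9)
    assert m.detection_index == 5
    assert m.method == "fea_20pct"


def test_fea_detector_linear_curve_never_fires():
    c = ForceDisplacementCurve(np.linspace(0, 1, 11), np.linspace(0, 1000, 11))
    with pytest.raises(NoFractureError) as exc:
        fracture_load_fea(c)
    assert exc.value.curve is c


def test_fea_detector_programmed_knee():
    for seed in range(5):
        knee = 800.0 + 100.0 * seed
        c = make_curve(stiffness=1200.0, fracture_load=knee,
                       post_knee_stiffness_fraction=0.3, increment=0.02, seed=seed)
        m = fracture_load_fea(c)
        assert abs(m.fracture_load - knee) <= 1200.0 * 0.02 + 1e-9


def test_mech_detector_noiseless_matches_fea():
    c = bilinear_curve(increment=0.02, total=1.2)
    m_f = fracture_load_fea(c)
    m_m = fracture_load_mechanical(c)
    # smoothing blurs the knee by at most the smoothing window
    assert abs(m_m.fracture_load - m_f.fracture_load) <= 1000.0 * 0.02 * 3
    assert m_m.method == "mech_rapid_drop"


def test_mech_detector_noise_robustness():
    """1% force noise moves the detected load < 3% across 100 replicates."""
    base = make_curve(1000.0, 1000.0, 0.3, increment=0.02, noise_sigma=0.0, seed=0)
    ref = fracture_load_mechanical(base).fracture_load
    devs = []
    for seed in range(100):
        noisy = make_curve(1000.0, 1000.0, 0.3, increment=0.02,
                           noise_sigma=0.01 * 1000.0, seed=seed)
        devs.append(fracture_load_mechanical(noisy).fracture_load)
    devs = np.abs(np.array(devs) - ref) / ref
    assert np.median(devs) < 0.03
    assert np.quantile(devs, 0.9) < 0.06


def test_concave_curve_without_sharp_drop_is_not_fracture():
    d = np.linspace(0.0, 1.0, 30)
    f = 1000.0 * d - 60.0 * d**2  # tangent decays from 1000 to 880 (> 800)
    with pytest.raises(NoFractureError):
        fracture_load_fea(ForceDisplacementCurve(d, f))


def test_detector_resampling_invariance():
    c = make_curve(1000.0, 900.0, 0.25, increment=0.04, seed=0)
    m1 = fracture_load_fea(c)
    d2 = np.linspace(c.displacement[0], c.displacement[-1], 2 * len(c.displacement) - 1)
    f2 = np.interp(d2, c.displacement, c.force)
    m2 = fracture_load_fea(ForceDisplacementCurve(d2, f2))
    assert abs(m2.fracture_load - m1.fracture_load) <= 1000.0 * 0.04 + 1e-9


def test_curve_validation_and_csv(tmp_path):
    with pytest.raises(ValueError, match="strictly increasing"):
        ForceDisplacementCurve([0.0, 0.5, 0.5], [0.0, 1.0, 2.0])
    c = bilinear_curve()
    path = tmp_path / "c.csv"
    c.to_csv(path)
    back = ForceDisplacementCurve.from_csv(path)
    np.testing.assert_allclose(back.force, c.force)


# ---------------------------------------------------------------------------
# statistics


def test_linreg_exact_and_hand_values():
    r = linreg([0, 1, 2, 3], [1, 3, 5, 7])
    assert (r.slope, r.intercept, r.r2) == pytest.approx((2.0, 1.0, 1.0))
    r2 = linreg([0, 1, 2], [0, 1, 4])
    assert r2.slope == pytest.approx(2.0)
    assert r2.intercept == pytest.approx(-1.0 / 3.0)
    assert r2.r2 == pytest.approx(12.0 / 13.0, rel=1e-9)


def test_linreg_matches_normal_equations_on_random_data():
    rng = np.random.default_rng(11)
    for _ in range(50):
        n = rng.integers(3, 30)
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 2 * x
        if np.ptp(x) == 0:
            continue
        r = linreg(x, y)
        xm = np.column_stack([x, np.ones(n)])
        beta = np.linalg.solve(xm.T @ xm, xm.T @ y)
        assert r.slope == pytest.approx(beta[0], rel=1e-10, abs=1e-10)
        assert r.intercept == pytest.approx(beta[1], rel=1e-10, abs=1e-10)


def test_linreg_zero_variance_errors():
    with pytest.raises(ValueError, match="zero variance"):
        linreg([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


def _brute_force_mw(a, b):
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n1 = len(a)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mid = n1 * len(b) / 2
    hits = total = 0
    for combo in combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            hits += 1
    return u_obs, hits / total


def test_mann_whitney_small_examples():
    u, _ = mann_whitney_u([1, 2], [3, 4])
    assert u == 0.0
    _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert p == 1.0
    a, b = [1.0, 5.0, 2.0], [4.0, 0.5, 9.0, 3.0]
    u_ab, _ = mann_whitney_u(a, b)
    u_ba, _ = mann_whitney_u(b, a)
    assert u_ab + u_ba == len(a) * len(b)


def test_mann_whitney_matches_enumeration_oracle():
    rng = np.random.default_rng(5)
    for _ in range(60):
        n1, n2 = rng.integers(2, 7, size=2)
        a = rng.integers(0, 6, size=n1).astype(float)  # ties likely
        b = rng.integers(0, 6, size=n2).astype(float)
        u, p = mann_whitney_u(a, b)
        u_o, p_o = _brute_force_mw(a, b)
        assert u == pytest.approx(u_o)
        assert p == pytest.approx(p_o, abs=1e-12)


def test_mann_whitney_large_uses_normal_approximation():
    rng = np.random.default_rng(9)
    a = rng.normal(0, 1, 30)
    b = rng.normal(1, 1, 30)
    _, p = mann_whitney_u(a, b)
    from scipy.stats import mannwhitneyu

    assert p == pytest.approx(
        mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    )


def test_students_t_and_multiple_regression():
    t, p = students_t([1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0])
    assert p < 0.1
    recs = make_cohort(CohortDesign(n_specimens=40, seed=3))
    coeffs = multiple_regression(recs, "mech_fracture_load", ["age", "sex", "side"])
    assert coeffs["age"]["coef"] < 0  # strength declines with age
    assert set(coeffs) == {"intercept", "age", "sex", "side"}


# ---------------------------------------------------------------------------
# cohort report


def test_cohort_report_identity_cases():
    recs = make_cohort(CohortDesign(n_specimens=12, latent_sd=0, mech_noise_sd=0,
                                    fea_noise_sd=0, stiffness_noise_mech=0,
                                    stiffness_noise_fea=0, seed=2))
    # make left/right identical within each cadaver
    for i in range(0, 12, 2):
        for key in ("mech_fracture_load", "mech_stiffness",
                    "fea_fracture_load", "fea_stiffness"):
            recs[i + 1][key] = recs[i][key]
    rep = cohort_report(recs)
    assert rep.laterality["mech_fracture_load"]["p"] == pytest.approx(1.0)
    # mech and fea are both affine in age -> perfectly correlated
    assert rep.regressions["fracture_load_mech_vs_fea"].r2 == pytest.approx(1.0)
    assert rep.regressions["load_vs_age_mech"].slope == pytest.approx(-142.6, rel=1e-9)


def test_cohort_report_missing_fields_lists_ids():
    recs = make_cohort(CohortDesign(n_specimens=6, seed=4))
    del recs[2]["fea_stiffness"]
    with pytest.raises(ValueError):
        cohort_report(recs)
    recs2 = make_cohort(CohortDesign(n_specimens=6, seed=4))
    recs2[1]["mech_stiffness"] = np.nan
    with pytest.raises(ValueError, match="S001"):
        cohort_report(recs2)


def test_cohort_report_json_and_frame(tmp_path):
    rep = cohort_report(make_cohort(CohortDesign(n_specimens=10, seed=6)))
    rep.to_json(tmp_path / "rep.json")
    import json

    d = json.loads((tmp_path / "rep.json").read_text())
    assert "fracture_load_mech_vs_fea" in d["regressions"]
    assert rep.to_frame().shape[0] == 6
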