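"""Statistics layer: brute-force sums-of-squares oracles and pingouin
cross-checks on toy tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tdcsim import icc_roi_vs_p99, rm_anova, tukey_pairs
from tdcsim.errors import DegenerateDataError, DesignError
from tdcsim.study import gg_epsilon, icc_consistency, ordinal_report


def _long_table(wide: np.ndarray, names=None) -> pd.DataFrame:
    n, k = wide.shape
    names = names or [f"cond{j}" for j in range(k)]
    rows = []
    for i in range(n):
        for j in range(k):
            rows.append({"subject_id": i, "montage_name": names[j],
                         "round_tag": "toy", "roi_mean": wide[i, j],
                         "p99_mean": wide[i, j], "focality_mm3": 1.0,
                         "peak_offset": 0.0})
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_wide(rng):
    base = rng.normal(0.4, 0.1, size=(5, 1))
    effect = np.array([[0.0, 0.05, 0.12]])
    return base + effect + rng.normal(0, 0.02, size=(5, 3))


def _bruteforce_rm_anova(wide):
    """Textbook two-way (subject x condition) decomposition, written
    independently: explicit loops, covariance-matrix epsilon."""
    n, k = wide.shape
    grand = wide.mean()
    ss_cond = 0.0
    for j in range(k):
        ss_cond += n * (wide[:, j].mean() - grand) ** 2
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            pred = wide[i].mean() + wide[:, j].mean() - grand
            ss_err += (wide[i, j] - pred) ** 2
    F = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    S = np.cov(wide.T, ddof=1)
    row = S.mean(axis=1)
    eps = (k * (np.trace(S) / k - S.mean())) ** 2 / (
        (k - 1)
        * (np.sum(S**2) - 2 * k * np.sum(row**2) + k * k * S.mean() ** 2)
    )
    return F, eps, ss_err / ((k - 1) * (n - 1))


def test_rm_anova_matches_bruteforce(toy_wide):
    table = _long_table(toy_wide)
    res = rm_anova(table, "roi_mean")
    F, eps, mse = _bruteforce_rm_anova(toy_wide)
    assert res.F == pytest.approx(F, rel=1e-10)
    assert res.epsilon == pytest.approx(eps, rel=1e-10)
    assert res.ms_error == pytest.approx(mse, rel=1e-10)
    k, n = 3, 5
    assert res.df1 == pytest.approx(eps * (k - 1), rel=1e-10)
    assert res.df2 == pytest.approx(eps * (k - 1) * (n - 1), rel=1e-10)
    assert res.p == pytest.approx(
        stats.f.sf(F, eps * (k - 1), eps * (k - 1) * (n - 1)), rel=1e-10
    )


def test_rm_anova_matches_pingouin(toy_wide):
    pingouin = pytest.importorskip("pingouin")
    table = _long_table(toy_wide)
    res = rm_anova(table, "roi_mean")
    df = table.rename(columns={"subject_id": "subj", "montage_name": "cond"})
    pg = pingouin.rm_anova(
        data=df, dv="roi_mean", within="cond", subject="subj", correction=True
    )
    assert res.F == pytest.approx(float(pg["F"].iloc[0]), rel=1e-8)
    assert res.epsilon == pytest.approx(float(pg["eps"].iloc[0]), rel=1e-6)
    pcol = "p_GG_corr" if "p_GG_corr" in pg.columns else "p-GG-corr"
    assert res.p == pytest.approx(float(pg[pcol].iloc[0]), rel=1e-6)


def test_two_conditions_epsilon_is_one(rng):
    wide = rng.normal(size=(8, 2))
    res = rm_anova(_long_table(wide), "roi_mean")
    assert res.epsilon == pytest.approx(1.0, abs=1e-12)


def test_location_invariance(toy_wide):
    r1 = rm_anova(_long_table(toy_wide), "roi_mean")
    r2 = rm_anova(_long_table(toy_wide + 3.7), "roi_mean")
    assert r1.F == pytest.approx(r2.F, rel=1e-9)
    assert r1.epsilon == pytest.approx(r2.epsilon, rel=1e-9)


def test_design_errors(rng):
    wide = rng.normal(size=(5, 3))
    table = _long_table(wide)
    with pytest.raises(DesignError):
        rm_anova(table.iloc[:-1], "roi_mean")  # broken pairing
    with pytest.raises(DesignError):
        rm_anova(table[table.montage_name == "cond0"], "roi_mean")
    with pytest.raises(DesignError):
        rm_anova(table.iloc[:6], "roi_mean")  # n=2 subjects
    constant = _long_table(np.ones((5, 3)))
    with pytest.raises(DegenerateDataError):
        rm_anova(constant, "roi_mean")


def test_tukey_matches_studentized_range(toy_wide):
    """Adjusted p equals the studentized-range tail evaluated directly."""
    table = _long_table(toy_wide)
    pairs = tukey_pairs(table, "roi_mean")
    n, k = toy_wide.shape
    assert len(pairs) == k * (k - 1) // 2
    _, _, mse = _bruteforce_rm_anova(toy_wide)
    names = [f"cond{j}" for j in range(k)]
    for pr in pairs:
        i, j = names.index(pr.condition_a), names.index(pr.condition_b)
        diff = toy_wide[:, i].mean() - toy_wide[:, j].mean()
        q = abs(diff) / np.sqrt(mse / n)
        p = stats.studentized_range.sf(q, k, (k - 1) * (n - 1))
        assert pr.mean_diff == pytest.approx(diff, rel=1e-10)
        assert pr.p_adj == pytest.approx(p, rel=1e-10)


def test_tukey_identical_conditions(rng):
    wide = rng.normal(size=(6, 3))
    wide[:, 1] = wide[:, 0]  # two identical conditions
    pairs = tukey_pairs(_long_table(wide), "roi_mean")
    first = next(p for p in pairs
                 if {p.condition_a, p.condition_b} == {"cond0", "cond1"})
    assert first.mean_diff == pytest.approx(0.0, abs=1e-15)
    assert first.p_adj == pytest.approx(1.0, abs=1e-12)


def test_icc_perfect_agreement(rng):
    roi = rng.uniform(0.2, 0.6, 30)
    table = pd.DataFrame({
        "subject_id": np.arange(30), "montage_name": "APPS",
        "round_tag": "round1", "roi_mean": roi, "p99_mean": roi,
        "focality_mm3": 1.0, "peak_offset": 0.0,
    })
    assert icc_roi_vs_p99(table, "APPS").icc == pytest.approx(1.0, abs=1e-12)
    # consistency form ignores a fixed offset
    table["p99_mean"] = roi + 0.2
    assert icc_roi_vs_p99(table, "APPS").icc == pytest.approx(1.0, abs=1e-12)


def test_icc_independence_near_zero():
    rng = np.random.default_rng(99)
    roi = rng.normal(0.4, 0.08, 200)
    p99 = rng.normal(0.4, 0.08, 200)
    table = pd.DataFrame({
        "subject_id": np.arange(200), "montage_name": "APPS",
        "round_tag": "round1", "roi_mean": roi, "p99_mean": p99,
        "focality_mm3": 1.0, "peak_offset": 0.0,
    })
    assert abs(icc_roi_vs_p99(table, "APPS").icc) < 0.2


def test_icc_matches_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    data = rng.normal(0.4, 0.1, size=(12, 2)) + rng.normal(0, 0.03, size=(12, 1))
    ours = icc_consistency(data)
    long = pd.DataFrame({
        "targets": np.repeat(np.arange(12), 2),
        "raters": np.tile(["a", "b"], 12),
        "scores": data.ravel(),
    })
    pg = pingouin.intraclass_corr(
        data=long, targets="targets", raters="raters", ratings="scores"
    )
    sel = pg["Type"].isin(["ICC3", "ICC(C,1)"])
    icc3 = float(pg.loc[sel, "ICC"].iloc[0])
    assert ours == pytest.approx(icc3, rel=1e-8)


def test_icc_agreement_form(rng):
    pingouin = pytest.importorskip("pingouin")
    roi = rng.uniform(0.2, 0.6, 15)
    p99 = roi + 0.2 + rng.normal(0, 0.02, 15)
    table = pd.DataFrame({
        "subject_id": np.arange(15), "montage_name": "APPS",
        "round_tag": "round1", "roi_mean": roi, "p99_mean": p99,
        "focality_mm3": 1.0, "peak_offset": 0.0,
    })
    cons = icc_roi_vs_p99(table, "APPS", form="consistency").icc
    agree = icc_roi_vs_p99(table, "APPS", form="agreement").icc
    # a fixed 0.2 offset: consistency stays high, agreement is punished
    assert cons > 0.9 > agree
    long = pd.DataFrame({
        "targets": np.repeat(np.arange(15), 2),
        "raters": np.tile(["roi", "p99"], 15),
        "scores": np.column_stack([roi, p99]).ravel(),
    })
    pg = pingouin.intraclass_corr(
        data=long, targets="targets", raters="raters", ratings="scores"
    )
    ref = float(pg.loc[pg["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0])
    assert agree == pytest.approx(ref, rel=1e-8)
    with pytest.raises(DesignError):
        icc_roi_vs_p99(table, "APPS", form="median")


def test_icc_degenerate(rng):
    table = pd.DataFrame({
        "subject_id": np.arange(10), "montage_name": "APPS",
        "round_tag": "round1", "roi_mean": np.ones(10),
        "p99_mean": rng.normal(size=10), "focality_mm3": 1.0, "peak_offset": 0.0,
    })
    with pytest.raises(DegenerateDataError):
        icc_roi_vs_p99(table, "APPS")


def test_gg_epsilon_bounds(rng):
    for _ in range(5):
        wide = rng.normal(size=(8, 4))
        eps = gg_epsilon(wide)
        assert 1.0 / 3.0 - 1e-9 <= eps <= 1.0 + 1e-9


def test_ordinal_report_dominant_montage():
    """A montage dominating every subject ranks first with full sign
    consistency; the report is a pure function of the table."""
    rng = np.random.default_rng(5)
    n = 10
    rows = []
    for i in range(n):
        base = rng.uniform(0.2, 0.4)
        for name, bump, tag in (("APPS", 0.2, "round1"), ("M1_SO", 0.0, "round1"),
                                ("BILAT_M1", 0.02, "round1")):
            rows.append({"subject_id": i, "montage_name": name, "round_tag": tag,
                         "roi_mean": base + bump, "p99_mean": base,
                         "focality_mm3": 1e4 * (1 + bump), "peak_offset": 1.0})
    table = pd.DataFrame(rows)
    rep = ordinal_report(table)
    assert rep["round1"]["roi_mean"]["ranking"][0] == "APPS"
    c = rep["contrasts"]["roi_mean"][0]
    assert c["pair"] == ("APPS", "M1_SO")
    assert c["sign_consistency"] == 1.0
    assert rep == ordinal_report(table.copy())
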