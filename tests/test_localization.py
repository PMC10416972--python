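import numpy as np
import pandas as pd
import pytest
from scipy.special import betainc

from nucyto.io_formats import ExpressionMatrix
from nucyto.localization import (
    CLASS_CYTOPLASMIC,
    CLASS_FILTERED,
    CLASS_NUCLEAR,
    CLASS_UNCHANGED,
    LocalizationConfig,
    classify,
    cn_ratios,
    filter_expressed,
    heatmap_zscore,
    localization_test,
    localize,
    volcano_table,
)

from conftest import make_matrix, make_sheet


def oracle_student_t(x, y):
    """Independent textbook pooled-variance t with exact beta-function CDF."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, p


# -------------------------------------------------------------------- filter


def test_filter_retains_above_threshold(sheet3):
    m = make_matrix({"g": [1.0] * 12}, sheet3)
    assert filter_expressed(m, sheet3) == ["g"]


def test_filter_coordinate_rule_one_low_sample(sheet3):
    values = [1.0] * 12
    values[7] = 0.4  # log2(0.4) ~ -1.32
    m = make_matrix({"g": values}, sheet3)
    assert filter_expressed(m, sheet3) == []


def test_filter_strict_at_boundary(sheet3):
    m = make_matrix({"g": [0.5] * 12}, sheet3)  # log2 = -1.0 exactly
    assert filter_expressed(m, sheet3) == []
    cfg = LocalizationConfig(expression_log2_threshold=-1.0000001)
    assert filter_expressed(m, sheet3, cfg) == ["g"]


def test_filter_monotone_in_threshold(rng, sheet3):
    values = {f"g{i}": rng.lognormal(mean=-1, sigma=2, size=12).tolist() for i in range(50)}
    m = make_matrix(values, sheet3)
    previous = None
    for threshold in (1.0, 0.0, -1.0, -2.0, -5.0):
        kept = set(filter_expressed(m, sheet3, LocalizationConfig(expression_log2_threshold=threshold)))
        if previous is not None:
            assert previous <= kept
        previous = kept


def test_filter_either_fraction_scope(sheet3):
    # above threshold in every cytoplasmic sample, below in one nuclear sample
    values = {"g": [1.0] * 12}
    m = make_matrix(values, sheet3)
    low = m.data.copy()
    nuclear_cols = [s for s in sheet3.sample_ids if "nuclear" in s]
    low.loc["g", nuclear_cols[0]] = 0.1
    m = ExpressionMatrix(low)
    assert filter_expressed(m, sheet3) == []
    cfg = LocalizationConfig(filter_scope="either_fraction")
    assert filter_expressed(m, sheet3, cfg) == ["g"]


# ------------------------------------------------------------------ cn_ratios


def test_cn_ratio_basic(sheet3):
    values = {
        "g": [
            2.0 if "nuclear" in s else 4.0  # nuclear 2, cytoplasmic 4
            for s in sheet3.sample_ids
        ]
    }
    m = make_matrix(values, sheet3)
    ratios = cn_ratios(m, sheet3, "g")
    np.testing.assert_allclose(ratios["control"], [2.0, 2.0, 2.0])
    np.testing.assert_allclose(ratios["repeat"], [2.0, 2.0, 2.0])


def test_cn_ratio_symmetry(sheet3):
    m = make_matrix({"g": [3.0] * 12}, sheet3)
    ratios = cn_ratios(m, sheet3, "g")
    assert (ratios["control"] == 1.0).all() and (ratios["repeat"] == 1.0).all()


def test_cn_ratio_unknown_gene(sheet3):
    m = make_matrix({"g": [1.0] * 12}, sheet3)
    with pytest.raises(KeyError):
        cn_ratios(m, sheet3, "nope")


# ----------------------------------------------------------------- the test


def test_identical_groups_fc1_p1():
    ratios = np.array([1.0, 2.0, 4.0])
    fc, log2fc, p = localization_test(ratios, ratios)
    assert fc == 1.0 and log2fc == 0.0 and p == 1.0


def test_derived_textbook_example():
    # control log2 ratios (0, .1, -.1); repeat (-1, -.9, -1.1)
    rc = 2.0 ** np.array([0.0, 0.1, -0.1])
    rr = 2.0 ** np.array([-1.0, -0.9, -1.1])
    fc, log2fc, p = localization_test(rc, rr)
    # frozen from the independent formula: t = 1/(0.1*sqrt(2/3)) = sqrt(150)
    assert abs(p - 0.00025521674944192703) < 1e-10
    assert abs(fc - 0.5) < 1e-12
    t, p_oracle = oracle_student_t(np.log2(rc), np.log2(rr))
    assert abs(t - 12.247448713915887) < 1e-10
    assert abs(p - p_oracle) < 1e-10


def test_scale_invariance_under_log2():
    rng = np.random.default_rng(3)
    rc, rr = rng.lognormal(size=3), rng.lognormal(size=3)
    base = localization_test(rc, rr)
    doubled = localization_test(2 * rc, 2 * rr)
    assert abs(base[0] - doubled[0]) < 1e-12
    assert abs(base[2] - doubled[2]) < 1e-12


def test_oracle_equivalence_random_genes(rng):
    cfg = LocalizationConfig()
    for _ in range(50):
        rc = rng.lognormal(sigma=0.5, size=3)
        rr = rng.lognormal(sigma=0.5, size=3)
        fc, _, p = localization_test(rc, rr, cfg)
        _, p_oracle = oracle_student_t(np.log2(rr), np.log2(rc))
        assert abs(p - p_oracle) < 1e-10
        assert abs(fc - rr.mean() / rc.mean()) < 1e-12


def test_zero_variance_unequal_means_is_floored():
    fc, _, p = localization_test(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
    assert 0 < p < 1e-300
    assert fc == 2.0


def test_too_few_replicates():
    with pytest.raises(ValueError, match="at least 2"):
        localization_test(np.array([1.0]), np.array([1.0, 2.0]))


def test_geometric_mean_aggregation():
    cfg = LocalizationConfig(fc_aggregation="geometric_mean")
    rc = np.array([1.0, 4.0])  # geometric mean 2
    rr = np.array([2.0, 8.0])  # geometric mean 4
    fc, _, _ = localization_test(rc, rr, cfg)
    assert abs(fc - 2.0) < 1e-12


def test_welch_differs_with_unequal_variance(rng):
    rc = rng.lognormal(sigma=0.1, size=3)
    rr = rng.lognormal(sigma=2.0, size=3) * 3
    p_student = localization_test(rc, rr)[2]
    p_welch = localization_test(rc, rr, LocalizationConfig(welch=True))[2]
    assert p_student != p_welch


# ------------------------------------------------------------------ classify


@pytest.mark.parametrize(
    "fc,p,expected",
    [
        (0.5, 0.01, CLASS_NUCLEAR),
        (2.0, 0.30, CLASS_UNCHANGED),
        (1.0, 0.001, CLASS_UNCHANGED),
        (2.0, 0.01, CLASS_CYTOPLASMIC),
        (0.5, 0.05, CLASS_UNCHANGED),  # p == alpha not significant
    ],
)
def test_classify(fc, p, expected):
    assert classify(fc, p) == expected


# ----------------------------------------------------------- localize (bulk)


def _random_dataset(rng, n_genes=40, sheet=None):
    sheet = sheet or make_sheet(3)
    values = {
        f"g{i}": rng.lognormal(mean=1.0, sigma=0.5, size=12).tolist()
        for i in range(n_genes)
    }
    return make_matrix(values, sheet), sheet


def test_localize_matches_scalar_path(rng):
    matrix, sheet = _random_dataset(rng)
    cfg = LocalizationConfig()
    table = localize(matrix, sheet, cfg).set_index("gene")
    for gene in filter_expressed(matrix, sheet, cfg):
        ratios = cn_ratios(matrix, sheet, gene)
        fc, log2fc, p = localization_test(ratios["control"], ratios["repeat"], cfg)
        row = table.loc[gene]
        assert abs(row["fc"] - fc) < 1e-12
        assert abs(row["p_value"] - p) < 1e-12
        assert row["class"] == classify(fc, p, cfg)


def test_localize_filtered_rows_are_nan(sheet3):
    m = make_matrix({"lo": [0.1] * 12, "hi": [2.0] * 12}, sheet3)
    table = localize(m, sheet3).set_index("gene")
    assert table.loc["lo", "class"] == CLASS_FILTERED
    assert np.isnan(table.loc["lo", ["fc", "p_value", "log2fc"]].to_numpy().astype(float)).all()
    assert table.loc["hi", "class"] == CLASS_UNCHANGED


def test_localize_fc_log2fc_consistency(rng):
    matrix, sheet = _random_dataset(rng)
    table = localize(matrix, sheet)
    tested = table.dropna(subset=["fc"])
    np.testing.assert_allclose(tested["log2fc"], np.log2(tested["fc"]), atol=1e-12)
    np.testing.assert_allclose(
        tested["fc"], tested["cn_mean_repeat"] / tested["cn_mean_control"], atol=0
    )


# ------------------------------------------------------------------- exports


def test_volcano_table_values_and_order(rng):
    matrix, sheet = _random_dataset(rng)
    table = localize(matrix, sheet)
    volcano = volcano_table(table.sample(frac=1.0, random_state=1))
    assert (volcano["log2fc"].diff().dropna() >= 0).all()
    merged = volcano.merge(table, on="gene")
    np.testing.assert_allclose(
        merged["neg_log10_p"], -np.log10(merged["p_value"]), atol=1e-12
    )
    assert CLASS_FILTERED not in set(volcano["class"])


def test_volcano_closed_forms(sheet3):
    table = pd.DataFrame(
        {"gene": ["a", "b"], "log2fc": [0.0, 1.0], "p_value": [0.05, 1.0],
         "class": [CLASS_UNCHANGED, CLASS_UNCHANGED]}
    )
    volcano = volcano_table(table)
    assert abs(volcano.loc[volcano["gene"] == "a", "neg_log10_p"].iloc[0] - 1.3010299956639813) < 1e-12
    assert volcano.loc[volcano["gene"] == "b", "neg_log10_p"].iloc[0] == 0.0


def test_heatmap_zscore_hand_case(sheet3):
    # C/N per (condition, replicate) = (1, 2, 3, 1, 2, 3): z from row stats
    values = {}
    cn = {"1": 1.0, "2": 2.0, "3": 3.0}
    row = []
    for s in sheet3.sample_ids:
        r = s.split("_")[-1]
        row.append(2.0 * cn[r] if "cytoplasmic" in s else 2.0)
    m = make_matrix({"g": row}, sheet3)
    z = heatmap_zscore(m, sheet3, ["g"])
    expected_sd = np.std([1, 2, 3, 1, 2, 3], ddof=1)
    np.testing.assert_allclose(
        z.loc["g"].to_numpy(),
        (np.array([1, 2, 3, 1, 2, 3]) - 2.0) / expected_sd,
        atol=1e-12,
    )


def test_heatmap_zscore_row_stats(rng):
    matrix, sheet = _random_dataset(rng, n_genes=10)
    z = heatmap_zscore(matrix, sheet, matrix.row_ids)
    np.testing.assert_allclose(z.to_numpy().mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.to_numpy().std(axis=1, ddof=1), 1.0, atol=1e-12)


def test_heatmap_zscore_constant_row(sheet3):
    m = make_matrix({"g": [5.0] * 12}, sheet3)
    z = heatmap_zscore(m, sheet3, ["g"])
    assert (z.loc["g"] == 0.0).all()


# --------------------------------------------------------------------- config


def test_config_validation():
    with pytest.raises(ValueError):
        LocalizationConfig(alpha=0.0)
    with pytest.raises(ValueError):
        LocalizationConfig(ratio_scale="log10")
    with pytest.raises(ValueError):
        LocalizationConfig(fc_aggregation="median")
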