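"""Cytosol/nucleus localization statistic.

Given a gene-level FPKM matrix over a complete two-condition, two-fraction
design, this module filters expressed genes, forms per-replicate
cytoplasmic/nuclear (C/N) ratios, tests the condition effect with a
two-sample Student t-test, and classifies each gene as nuclear- or
cytoplasmic-accumulated.  Volcano and row-z-score heatmap tables are derived
from the same records.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CONDITIONS, ExpressionMatrix, FRACTIONS, SampleSheet

#: Smallest reportable p-value, used when the pooled variance is exactly zero
#: but the group means differ (the test statistic is formally infinite).
P_FLOOR = np.nextafter(0.0, 1.0)

CLASS_NUCLEAR = "nuclear_accumulated"
CLASS_CYTOPLASMIC = "cytoplasmic_accumulated"
CLASS_UNCHANGED = "unchanged"
CLASS_FILTERED = "filtered"


@dataclasses.dataclass(frozen=True)
class LocalizationConfig:
    """Tuning knobs for the localization analysis.

    expression_log2_threshold
        A gene is retained only if log2(FPKM) strictly exceeds this value in
        every sample (both fractions, both conditions, all replicates).
    alpha
        Significance level; p exactly equal to alpha is NOT significant.
    ratio_scale
        Scale on which the t-test sees the per-replicate ratios: ``"log2"``
        (default; ratios are multiplicative) or ``"linear"``.
    fc_aggregation
        How per-replicate ratios are collapsed into a per-condition mean:
        ``"mean_of_ratios"`` (arithmetic, default) or ``"geometric_mean"``.
    apply_bh
        If true, classification uses Benjamini-Hochberg adjusted p-values.
    welch
        If true, use the unequal-variance (Welch) t-test instead of the
        pooled-variance Student test.
    filter_scope
        ``"all_samples"`` (default): the expression filter must hold in every
        sample.  ``"either_fraction"``: it must hold in all samples of at
        least one fraction (looser reading; ratios may then involve
        sub-threshold denominators).
    """

    expression_log2_threshold: float = -1.0
    alpha: float = 0.05
    ratio_scale: str = "log2"
    fc_aggregation: str = "mean_of_ratios"
    apply_bh: bool = False
    welch: bool = False
    filter_scope: str = "all_samples"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.ratio_scale not in ("log2", "linear"):
            raise ValueError(f"ratio_scale must be 'log2' or 'linear', got {self.ratio_scale!r}")
        if self.fc_aggregation not in ("mean_of_ratios", "geometric_mean"):
            raise ValueError(f"unknown fc_aggregation {self.fc_aggregation!r}")
        if self.filter_scope not in ("all_samples", "either_fraction"):
            raise ValueError(f"unknown filter_scope {self.filter_scope!r}")


def filter_expressed(
    matrix: ExpressionMatrix, sheet: SampleSheet, cfg: LocalizationConfig | None = None
) -> list[str]:
    """Genes with log2(FPKM) strictly above the threshold in every sample.

    Returns retained gene ids in matrix row order.  Samples are taken from
    the sheet, so extra matrix columns are ignored.
    """
    cfg = cfg or LocalizationConfig()
    threshold_fpkm = 2.0 ** cfg.expression_log2_threshold
    data = matrix.data[sheet.sample_ids]
    if cfg.filter_scope == "all_samples":
        keep = (data.to_numpy() > threshold_fpkm).all(axis=1)
    else:
        keep = np.zeros(len(data), dtype=bool)
        for fraction in FRACTIONS:
            cols = [
                s
                for condition in CONDITIONS
                for s in sheet.samples(condition, fraction).values()
            ]
            keep |= (data[cols].to_numpy() > threshold_fpkm).all(axis=1)
    return list(data.index[keep])


def cn_ratios(
    matrix: ExpressionMatrix, sheet: SampleSheet, gene: str
) -> dict[str, np.ndarray]:
    """Per-condition arrays of per-replicate cytoplasmic/nuclear ratios.

    Fractions are paired by replicate index within each condition; a
    replicate missing its fraction partner is a hard error.
    """
    if gene not in matrix.data.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    row = matrix.data.loc[gene]
    out: dict[str, np.ndarray] = {}
    for condition in CONDITIONS:
        nuclear = sheet.samples(condition, "nuclear")
        cytoplasmic = sheet.samples(condition, "cytoplasmic")
        replicates = sorted(nuclear)
        if sorted(cytoplasmic) != replicates:
            missing = set(nuclear) ^ set(cytoplasmic)
            raise ValueError(
                f"condition {condition!r}: replicate(s) {sorted(missing)} lack a "
                "fraction partner"
            )
        out[condition] = np.array(
            [row[cytoplasmic[r]] / row[nuclear[r]] for r in replicates], dtype=float
        )
    return out


def _student_t(x: np.ndarray, y: np.ndarray, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test; returns (t, p).

    Zero-variance degenerate cases: equal means -> p = 1; unequal means ->
    p = P_FLOOR with an infinite-signed statistic.
    """
    n1, n2 = len(x), len(y)
    m1, m2 = x.mean(), y.mean()
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0.0:
            return (0.0, 1.0) if m1 == m2 else (math.inf * np.sign(m1 - m2), P_FLOOR)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        t = (m1 - m2) / math.sqrt(se2)
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if sp2 == 0.0:
            return (0.0, 1.0) if m1 == m2 else (math.inf * np.sign(m1 - m2), P_FLOOR)
        t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(max(p, P_FLOOR), 1.0))


def localization_test(
    ratios_control: np.ndarray,
    ratios_repeat: np.ndarray,
    cfg: LocalizationConfig | None = None,
) -> tuple[float, float, float]:
    """Fold change and significance of the repeat-vs-control C/N shift.

    Returns ``(fc, log2fc, p_value)`` where ``fc`` is the ratio of the
    per-condition aggregated C/N ratios (repeat over control) and the p-value
    comes from a two-sided two-sample t-test on the ratios transformed per
    ``cfg.ratio_scale``.
    """
    cfg = cfg or LocalizationConfig()
    rc = np.asarray(ratios_control, dtype=float)
    rr = np.asarray(ratios_repeat, dtype=float)
    if rc.size < 2 or rr.size < 2:
        raise ValueError("localization_test needs at least 2 ratios per group")
    if (rc <= 0).any() or (rr <= 0).any():
        raise ValueError("C/N ratios must be positive")
    if cfg.fc_aggregation == "mean_of_ratios":
        mean_control, mean_repeat = rc.mean(), rr.mean()
    else:
        mean_control = float(np.exp(np.log(rc).mean()))
        mean_repeat = float(np.exp(np.log(rr).mean()))
    fc = mean_repeat / mean_control
    if cfg.ratio_scale == "log2":
        x, y = np.log2(rc), np.log2(rr)
    else:
        x, y = rc, rr
    _, p = _student_t(y, x, welch=cfg.welch)
    return float(fc), float(np.log2(fc)), p


def classify(fc: float, p_value: float, cfg: LocalizationConfig | None = None) -> str:
    """Direction call: significant fc < 1 is nuclear, fc > 1 cytoplasmic.

    fc exactly 1 is never significant-directional; p equal to alpha is not
    significant (strict ``<``).
    """
    cfg = cfg or LocalizationConfig()
    if p_value < cfg.alpha:
        if fc < 1.0:
            return CLASS_NUCLEAR
        if fc > 1.0:
            return CLASS_CYTOPLASMIC
    return CLASS_UNCHANGED


def localize(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    cfg: LocalizationConfig | None = None,
) -> pd.DataFrame:
    """Full per-gene localization table (vectorized over genes).

    One row per matrix gene, with columns ``gene, cn_mean_control,
    cn_mean_repeat, fc, log2fc, p_value, p_effective, class``.  Genes failing
    the expression filter get class ``filtered`` and NaN statistics.
    ``p_effective`` equals ``p_value`` unless ``cfg.apply_bh`` is set, in
    which case it holds the BH-adjusted p used for classification.
    """
    cfg = cfg or LocalizationConfig()
    retained = filter_expressed(matrix, sheet, cfg)
    genes = matrix.row_ids

    ratios: dict[str, np.ndarray] = {}
    if retained:
        sub = matrix.data.loc[retained]
        for condition in CONDITIONS:
            nuclear = sheet.samples(condition, "nuclear")
            cytoplasmic = sheet.samples(condition, "cytoplasmic")
            replicates = sorted(nuclear)
            if sorted(cytoplasmic) != replicates:
                missing = set(nuclear) ^ set(cytoplasmic)
                raise ValueError(
                    f"condition {condition!r}: replicate(s) {sorted(missing)} lack a "
                    "fraction partner"
                )
            num = sub[[cytoplasmic[r] for r in replicates]].to_numpy()
            den = sub[[nuclear[r] for r in replicates]].to_numpy()
            ratios[condition] = num / den

    table = pd.DataFrame(
        {
            "gene": genes,
            "cn_mean_control": np.nan,
            "cn_mean_repeat": np.nan,
            "fc": np.nan,
            "log2fc": np.nan,
            "p_value": np.nan,
            "p_effective": np.nan,
            "class": CLASS_FILTERED,
        }
    ).set_index("gene")

    if retained:
        rc, rr = ratios["control"], ratios["repeat"]
        if cfg.fc_aggregation == "mean_of_ratios":
            mean_control, mean_repeat = rc.mean(axis=1), rr.mean(axis=1)
        else:
            mean_control = np.exp(np.log(rc).mean(axis=1))
            mean_repeat = np.exp(np.log(rr).mean(axis=1))
        fc = mean_repeat / mean_control

        x = np.log2(rc) if cfg.ratio_scale == "log2" else rc
        y = np.log2(rr) if cfg.ratio_scale == "log2" else rr
        n1, n2 = x.shape[1], y.shape[1]
        m1, m2 = x.mean(axis=1), y.mean(axis=1)
        v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            if cfg.welch:
                se2 = v1 / n1 + v2 / n2
                df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
                t = (m2 - m1) / np.sqrt(se2)
            else:
                df = np.full(len(m1), n1 + n2 - 2, dtype=float)
                sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
                t = (m2 - m1) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            p = 2.0 * stats.t.sf(np.abs(t), df)
        # zero pooled variance: t is nan (equal means) or +/-inf (unequal)
        p = np.where(np.isnan(t), np.where(m1 == m2, 1.0, P_FLOOR), p)
        p = np.clip(p, P_FLOOR, 1.0)

        p_eff = bh_adjust_inline(p) if cfg.apply_bh else p
        significant = p_eff < cfg.alpha
        cls = np.where(
            significant & (fc < 1.0),
            CLASS_NUCLEAR,
            np.where(significant & (fc > 1.0), CLASS_CYTOPLASMIC, CLASS_UNCHANGED),
        )

        table.loc[retained, "cn_mean_control"] = mean_control
        table.loc[retained, "cn_mean_repeat"] = mean_repeat
        table.loc[retained, "fc"] = fc
        table.loc[retained, "log2fc"] = np.log2(fc)
        table.loc[retained, "p_value"] = p
        table.loc[retained, "p_effective"] = p_eff
        table.loc[retained, "class"] = cls

    return table.reset_index()


def bh_adjust_inline(p: np.ndarray) -> np.ndarray:
    # thin indirection so localization does not import enrichment at top level
    from .enrichment import bh_adjust

    return bh_adjust(p)


def volcano_table(records: pd.DataFrame) -> pd.DataFrame:
    """(gene, log2fc, -log10 p, class) for tested genes, sorted by log2fc."""
    tested = records[records["class"] != CLASS_FILTERED].copy()
    tested["neg_log10_p"] = -np.log10(tested["p_value"])
    out = tested[["gene", "log2fc", "neg_log10_p", "class"]]
    return out.sort_values("log2fc", kind="mergesort", ignore_index=True)


def heatmap_zscore(
    matrix: ExpressionMatrix, sheet: SampleSheet, genes: list[str]
) -> pd.DataFrame:
    """Row z-scores of per-sample C/N ratios for the given genes.

    Columns are ``{condition}_{replicate}``; z uses the sample standard
    deviation (ddof=1); constant rows map to all-zero rows.
    """
    columns: list[str] = []
    ratio_cols: list[np.ndarray] = []
    sub = matrix.data.loc[genes]
    for condition in CONDITIONS:
        nuclear = sheet.samples(condition, "nuclear")
        cytoplasmic = sheet.samples(condition, "cytoplasmic")
        for r in sorted(nuclear):
            columns.append(f"{condition}_{r}")
            ratio_cols.append(
                sub[cytoplasmic[r]].to_numpy() / sub[nuclear[r]].to_numpy()
            )
    values = np.column_stack(ratio_cols) if ratio_cols else np.empty((len(genes), 0))
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0.0, z.shape)] = 0.0
    return pd.DataFrame(z, index=pd.Index(genes, name="gene"), columns=columns)
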