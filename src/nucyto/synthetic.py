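"""Seeded generators for fractionation expression data with known truth.

The generative model: per gene g an abundance A_g ~ 2^Normal(mu, sd) and a
baseline localization L_g ~ Normal(mu_L, sd_L) on the log2 C/N scale.  For
condition c and replicate r,

    nuclear FPKM      = A_g * 2^(-L_gc / 2) * eps
    cytoplasmic FPKM  = A_g * 2^(+L_gc / 2) * eps'

with eps, eps' independent multiplicative 2^Normal(0, noise_log2_sd) noise
and L_g,repeat = L_g + shift for planted genes.  The half-and-half split
keeps nuclear x cytoplasmic abundance independent of L_g (relocalization,
not degradation).  A minority of genes is split into 2-3 loci whose
per-sample mean equals the gene value, and a configurable fraction is scaled
below the expression filter.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_formats import (
    CONDITIONS,
    ExpressionMatrix,
    FRACTIONS,
    GeneSetCollection,
    SampleSheet,
)
from .qpcr import DEFAULT_HOUSEKEEPING, QpcrTable

TRUE_NUCLEAR = "nuclear_shifted"
TRUE_CYTOPLASMIC = "cytoplasmic_shifted"
TRUE_NULL = "null"
TRUE_SUBTHRESHOLD = "subthreshold"


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic fractionation experiment (all seeded)."""

    n_genes: int
    replicates: int = 3
    abundance_log2_mean: float = 3.0
    abundance_log2_sd: float = 2.0
    baseline_cn_log2_mean: float = 0.0
    baseline_cn_log2_sd: float = 1.0
    noise_log2_sd: float = 0.2
    frac_nuclear_shifted: float = 0.05
    frac_cytoplasmic_shifted: float = 0.002
    shift_log2: float = -1.5
    frac_multilocus: float = 0.02
    frac_subthreshold: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        for name in ("frac_nuclear_shifted", "frac_cytoplasmic_shifted",
                     "frac_multilocus", "frac_subthreshold"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.frac_nuclear_shifted + self.frac_cytoplasmic_shifted >= 1.0:
            raise ValueError("shifted fractions must sum to < 1")
        if self.noise_log2_sd < 0:
            raise ValueError("noise_log2_sd must be >= 0")
        if self.shift_log2 > 0:
            raise ValueError(
                "shift_log2 is the nuclear-shift and must be <= 0; the "
                "cytoplasmic counterpart uses its negation"
            )


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleSheet, dict[str, str], pd.DataFrame]:
    """Generate (matrix, sample sheet, locus map, truth table).

    The truth table has columns ``gene, true_class, true_shift_log2`` with
    classes partitioning the gene list.  Subthreshold genes are rescaled so
    at least one sample falls at FPKM <= 0.5; multi-locus genes are split
    into 2-3 loci whose per-sample arithmetic mean equals the gene value.
    """
    rng = np.random.default_rng(cfg.seed)
    n, reps = cfg.n_genes, cfg.replicates
    genes = np.array([f"gene{i + 1:05d}" for i in range(n)])

    n_nuclear = int(round(cfg.frac_nuclear_shifted * n))
    n_cytoplasmic = int(round(cfg.frac_cytoplasmic_shifted * n))
    if cfg.shift_log2 == 0.0:
        n_nuclear = n_cytoplasmic = 0
    n_sub = int(round(cfg.frac_subthreshold * n))
    n_multi = int(round(cfg.frac_multilocus * n))
    if n_nuclear + n_cytoplasmic + n_sub + n_multi > n:
        raise ValueError("class fractions exceed the gene count")

    perm = rng.permutation(n)
    idx_nuclear = np.sort(perm[:n_nuclear])
    idx_cytoplasmic = np.sort(perm[n_nuclear:n_nuclear + n_cytoplasmic])
    idx_sub = np.sort(perm[n_nuclear + n_cytoplasmic:n_nuclear + n_cytoplasmic + n_sub])
    start = n_nuclear + n_cytoplasmic + n_sub
    idx_multi = np.sort(perm[start:start + n_multi])

    abundance = 2.0 ** rng.normal(cfg.abundance_log2_mean, cfg.abundance_log2_sd, n)
    baseline = rng.normal(cfg.baseline_cn_log2_mean, cfg.baseline_cn_log2_sd, n)
    shift = np.zeros(n)
    shift[idx_nuclear] = cfg.shift_log2
    shift[idx_cytoplasmic] = -cfg.shift_log2

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for condition in CONDITIONS:
        loc = baseline + (shift if condition == "repeat" else 0.0)
        for r in range(1, reps + 1):
            eps = {
                fraction: 2.0 ** rng.normal(0.0, cfg.noise_log2_sd, n)
                for fraction in FRACTIONS
            }
            for fraction, sign in (("nuclear", -1.0), ("cytoplasmic", +1.0)):
                sample = f"{condition}_{fraction}_{r}"
                columns[sample] = abundance * 2.0 ** (sign * loc / 2.0) * eps[fraction]
                sheet_rows.append(
                    {"sample_id": sample, "condition": condition,
                     "fraction": fraction, "replicate": r}
                )

    values = pd.DataFrame(columns, index=genes)

    if n_sub:
        block = values.iloc[idx_sub]
        row_min = block.to_numpy().min(axis=1)
        target_min = rng.uniform(0.05, 0.45, n_sub)
        values.iloc[idx_sub] = block.to_numpy() * (target_min / row_min)[:, None]

    truth = pd.DataFrame({"gene": genes, "true_class": TRUE_NULL,
                          "true_shift_log2": 0.0})
    truth.loc[idx_nuclear, "true_class"] = TRUE_NUCLEAR
    truth.loc[idx_nuclear, "true_shift_log2"] = cfg.shift_log2
    truth.loc[idx_cytoplasmic, "true_class"] = TRUE_CYTOPLASMIC
    truth.loc[idx_cytoplasmic, "true_shift_log2"] = -cfg.shift_log2
    truth.loc[idx_sub, "true_class"] = TRUE_SUBTHRESHOLD

    # explode selected genes into loci with per-sample mean preserved
    multi_set = set(idx_multi.tolist())
    locus_ids: list[str] = []
    locus_rows: list[np.ndarray] = []
    locus_map: dict[str, str] = {}
    matrix_values = values.to_numpy()
    for i, gene in enumerate(genes):
        if i in multi_set:
            k = int(rng.integers(2, 4))
            weights = rng.uniform(0.25, 1.75, k)
            weights *= k / weights.sum()  # mean exactly 1 up to fp rounding
            for j in range(k):
                locus = f"{gene}.L{j + 1}"
                locus_ids.append(locus)
                locus_rows.append(matrix_values[i] * weights[j])
                locus_map[locus] = gene
        else:
            locus_ids.append(gene)
            locus_rows.append(matrix_values[i])
            locus_map[gene] = gene

    matrix = ExpressionMatrix(
        pd.DataFrame(np.vstack(locus_rows), index=locus_ids, columns=values.columns)
    )
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    return matrix, sheet, locus_map, truth


def simulate_genesets(
    truth: pd.DataFrame,
    n_sets: int = 20,
    enriched_set_fraction: float = 0.6,
    seed: int = 0,
    set_size: int = 50,
    enriched_name: str = "membrane_trafficking",
) -> GeneSetCollection:
    """Decoy sets plus one set overrepresenting nuclear-shifted genes.

    The universe is every non-subthreshold gene in the truth table.  With
    ``enriched_set_fraction == 0`` all ``n_sets`` sets are uniform decoys;
    otherwise the last set draws that fraction of its members from the
    nuclear-shifted genes.
    """
    if not 0.0 <= enriched_set_fraction <= 1.0:
        raise ValueError("enriched_set_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = truth.loc[truth["true_class"] != TRUE_SUBTHRESHOLD, "gene"].to_numpy()
    shifted = truth.loc[truth["true_class"] == TRUE_NUCLEAR, "gene"].to_numpy()
    size = min(set_size, len(universe))
    sets: dict[str, frozenset[str]] = {}
    n_decoys = n_sets if enriched_set_fraction == 0.0 else n_sets - 1
    for i in range(n_decoys):
        members = rng.choice(universe, size=size, replace=False)
        sets[f"decoy_{i + 1:02d}"] = frozenset(members.tolist())
    if enriched_set_fraction > 0.0:
        n_shifted = min(int(round(enriched_set_fraction * size)), len(shifted))
        members = set(rng.choice(shifted, size=n_shifted, replace=False).tolist())
        background = np.array([g for g in universe if g not in members])
        fill = rng.choice(background, size=size - len(members), replace=False)
        members.update(fill.tolist())
        sets[enriched_name] = frozenset(members)
    return GeneSetCollection(sets=sets, universe=frozenset(universe.tolist()))


def simulate_qpcr(
    truth: pd.DataFrame,
    targets: list[str],
    cfg: SimulationConfig,
    base_cq: tuple[float, float] = (20.0, 18.0),
) -> QpcrTable:
    """Cq table whose planted shifts reproduce the truth fold changes.

    Target Cq per fraction is the housekeeping base Cq offset by the log2
    relative abundance implied by the condition's localization (control
    baseline 0, repeat the planted shift), plus Normal(0, noise_log2_sd)
    cycle noise on target wells.  With zero noise,
    ``cn_fold_change`` recovers fc = 2^true_shift exactly.
    """
    known = set(truth["gene"])
    for target in targets:
        if target not in known:
            raise ValueError(f"qPCR target {target!r} absent from the truth table")
    shifts = dict(zip(truth["gene"], truth["true_shift_log2"]))
    rng = np.random.default_rng([cfg.seed, 104729])  # independent stream
    nuclear_base, cytoplasmic_base = base_cq
    rows = []
    for condition in CONDITIONS:
        for r in range(1, cfg.replicates + 1):
            rows.append({"target": DEFAULT_HOUSEKEEPING["nuclear"],
                         "fraction": "nuclear", "condition": condition,
                         "replicate": r, "cq": nuclear_base})
            rows.append({"target": DEFAULT_HOUSEKEEPING["cytoplasmic"],
                         "fraction": "cytoplasmic", "condition": condition,
                         "replicate": r, "cq": cytoplasmic_base})
            for target in targets:
                loc = shifts[target] if condition == "repeat" else 0.0
                noise_n = rng.normal(0.0, cfg.noise_log2_sd)
                noise_c = rng.normal(0.0, cfg.noise_log2_sd)
                rows.append({"target": target, "fraction": "nuclear",
                             "condition": condition, "replicate": r,
                             "cq": nuclear_base + loc / 2.0 + noise_n})
                rows.append({"target": target, "fraction": "cytoplasmic",
                             "condition": condition, "replicate": r,
                             "cq": cytoplasmic_base - loc / 2.0 + noise_c})
    return QpcrTable(pd.DataFrame(rows), dict(DEFAULT_HOUSEKEEPING))


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str})
    df["true_shift_log2"] = df["true_shift_log2"].astype(float)
    return df
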