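"""qPCR relative-localization fold change (2^-dCt against housekeeping).

Each fraction is normalized to its own housekeeping reference (nuclear:
Malat1, cytoplasmic: GAPDH by default).  Per replicate, the C/N ratio is the
cytoplasmic relative expression over the nuclear one; per condition the
replicate ratios are averaged, and the repeat-condition ratio is reported
relative to control (control == 1 by construction).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import CONDITIONS, FormatError
from .localization import _student_t

DEFAULT_HOUSEKEEPING: dict[str, str] = {"nuclear": "Malat1", "cytoplasmic": "GAPDH"}

_QPCR_COLUMNS = ("target", "fraction", "condition", "replicate", "cq")


@dataclasses.dataclass(frozen=True)
class QpcrTable:
    """Long-format Cq table plus the fraction -> housekeeping-gene mapping.

    ``data`` columns: target, fraction, condition, replicate, cq.  The
    housekeeping genes appear as ordinary target rows; every measured
    (target, fraction, condition, replicate) cell must have a matching
    housekeeping Cq in the same cell.
    """

    data: pd.DataFrame
    housekeeping: Mapping[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_HOUSEKEEPING)
    )

    def __post_init__(self) -> None:
        missing = set(_QPCR_COLUMNS) - set(self.data.columns)
        if missing:
            raise FormatError(f"qPCR table missing columns: {sorted(missing)}")
        cq = self.data["cq"].to_numpy(dtype=float)
        if not np.isfinite(cq).all():
            raise FormatError("qPCR table contains non-finite Cq values")
        key = self.data[["target", "fraction", "condition", "replicate"]]
        if key.duplicated().any():
            row = key.loc[key.duplicated()].iloc[0]
            raise FormatError(
                "duplicate qPCR measurement for "
                f"({row['target']}, {row['fraction']}, {row['condition']}, {row['replicate']})"
            )

    def cq(self, target: str, fraction: str, condition: str, replicate: int) -> float:
        sel = self.data[
            (self.data["target"] == target)
            & (self.data["fraction"] == fraction)
            & (self.data["condition"] == condition)
            & (self.data["replicate"] == replicate)
        ]
        if sel.empty:
            raise FormatError(
                f"missing Cq for ({target}, {fraction}, {condition}, replicate {replicate})"
            )
        return float(sel["cq"].iloc[0])


def read_qpcr(
    path: str | Path, housekeeping: Mapping[str, str] | None = None
) -> QpcrTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"target": str})
    df["replicate"] = df["replicate"].astype(int)
    return QpcrTable(df, dict(housekeeping or DEFAULT_HOUSEKEEPING))


def write_qpcr(table: QpcrTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def relative_expression(cq_target: float, cq_reference: float) -> float:
    """2^-(Cq_target - Cq_reference)."""
    return 2.0 ** -(cq_target - cq_reference)


@dataclasses.dataclass(frozen=True)
class QpcrResult:
    """C/N fold change of one target relative to control."""

    target: str
    fc_vs_control: float
    cn_control: np.ndarray  # raw per-replicate C/N, control
    cn_repeat: np.ndarray  # raw per-replicate C/N, repeat
    normalized_control: np.ndarray  # per-replicate, control mean scaled to 1
    normalized_repeat: np.ndarray
    p_value: float


def cn_fold_change(table: QpcrTable, target: str) -> QpcrResult:
    """C/N ratio of ``target`` in repeat cells relative to control cells.

    Per condition and replicate: relative expression in each fraction against
    that fraction's housekeeping gene, then cytoplasmic/nuclear.  Replicate
    ratios are averaged arithmetically per condition; the fold change is the
    repeat mean over the control mean (so the control bar is exactly 1).  The
    p-value is a two-sided Student t-test on per-replicate log2 C/N values.
    """
    ratios: dict[str, np.ndarray] = {}
    for condition in CONDITIONS:
        replicates = sorted(
            set(
                table.data.loc[
                    (table.data["target"] == target)
                    & (table.data["condition"] == condition),
                    "replicate",
                ]
            )
        )
        if not replicates:
            raise FormatError(f"target {target!r} has no measurements in {condition!r}")
        values = []
        for r in replicates:
            rel = {}
            for fraction, reference in table.housekeeping.items():
                cq_t = table.cq(target, fraction, condition, r)
                cq_ref = table.cq(reference, fraction, condition, r)
                rel[fraction] = relative_expression(cq_t, cq_ref)
            values.append(rel["cytoplasmic"] / rel["nuclear"])
        ratios[condition] = np.array(values, dtype=float)
    mean_control = ratios["control"].mean()
    mean_repeat = ratios["repeat"].mean()
    fc = mean_repeat / mean_control
    if len(ratios["control"]) >= 2 and len(ratios["repeat"]) >= 2:
        _, p = _student_t(np.log2(ratios["repeat"]), np.log2(ratios["control"]))
    else:
        p = float("nan")
    return QpcrResult(
        target=target,
        fc_vs_control=float(fc),
        cn_control=ratios["control"],
        cn_repeat=ratios["repeat"],
        normalized_control=ratios["control"] / mean_control,
        normalized_repeat=ratios["repeat"] / mean_control,
        p_value=p,
    )


def fold_change_table(table: QpcrTable, targets: list[str] | None = None) -> pd.DataFrame:
    """Fold-change summary rows for all (or the given) non-housekeeping targets."""
    if targets is None:
        housekeeping = set(table.housekeeping.values())
        targets = [t for t in dict.fromkeys(table.data["target"]) if t not in housekeeping]
    rows = []
    for target in targets:
        res = cn_fold_change(table, target)
        rows.append(
            {
                "target": target,
                "fc_vs_control": res.fc_vs_control,
                "control_normalized": 1.0,
                "p_value": res.p_value,
                "n_control": len(res.cn_control),
                "n_repeat": len(res.cn_repeat),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "target",
            "fc_vs_control",
            "control_normalized",
            "p_value",
            "n_control",
            "n_repeat",
        ],
    )
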