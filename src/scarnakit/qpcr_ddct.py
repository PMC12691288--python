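"""Relative expression by the ddCt method with a nested replicate test.

Ct values are normalized per biological replicate to a reference amplicon
(dCt = mean technical-replicate Ct of the target minus that of the
normalizer), then calibrated against a control group
(ddCt = mean dCt(test) - mean dCt(calibrator)).  Relative expression is
E^-ddCt with amplification efficiency E fixed at 2 (perfect doubling)
unless overridden.  Fold change uses the signed convention: ratio r >= 1
is reported as +r, r < 1 as -1/r, so a 40% reduction prints as -1.67.

The "nested" group test averages technical replicates within biological
replicate and applies a two-sided Welch t test to the biological-replicate
dCt means — the summary-statistic equivalent of a two-level nested model,
approximating the commercial implementation it emulates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample", "group", "target", "bio_rep", "tech_rep", "ct"]


def validate_ct_table(table: pd.DataFrame, require: tuple[str, ...] = ()) -> pd.DataFrame:
    """Check the long-format Ct table schema and ranges; returns the table."""
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns {missing}")
    ct = table["ct"].astype(float)
    if not ((ct > 0) & (ct < 45)).all():
        raise ValueError("Ct values must lie in (0, 45)")
    for target in require:
        if target not in set(table["target"]):
            raise ValueError(f"required target {target!r} absent from Ct table")
    return table


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    return validate_ct_table(pd.read_csv(path, sep="\t", comment="#"))


def write_ct_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DdctResult:
    target: str
    ratio: float
    fold_change: float
    ddct: float
    p_value: float
    n_bio: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "ratio": self.ratio,
            "fold_change": self.fold_change,
            "ddct": self.ddct,
            "p_value": self.p_value,
            "n_bio": dict(self.n_bio),
        }


def signed_fold_change(ratio: float) -> float:
    """Map an expression ratio to the signed fold-change convention (|fc| >= 1)."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return ratio if ratio >= 1 else -1.0 / ratio


def delta_ct(table: pd.DataFrame, target: str, normalizer: str) -> pd.DataFrame:
    """Per-(sample, bio_rep) dCt: mean tech-rep Ct(target) - mean tech-rep Ct(normalizer)."""
    validate_ct_table(table, require=(target, normalizer))
    keys = ["sample", "group", "bio_rep"]
    t = table[table["target"] == target].groupby(keys, as_index=False)["ct"].mean()
    n = table[table["target"] == normalizer].groupby(keys, as_index=False)["ct"].mean()
    merged = t.merge(n, on=keys, how="left", suffixes=("_target", "_norm"))
    if merged["ct_norm"].isna().any():
        bad = merged.loc[merged["ct_norm"].isna(), "sample"].unique().tolist()
        raise ValueError(f"normalizer {normalizer!r} missing for samples {bad}")
    merged["delta_ct"] = merged["ct_target"] - merged["ct_norm"]
    return merged[keys + ["delta_ct"]]


def relative_expression(
    deltas: pd.DataFrame,
    calibrator_group: str,
    test_group: str,
    target: str = "",
    efficiency: float = 2.0,
    p_value: float = math.nan,
) -> DdctResult:
    """ddCt of ``test_group`` against ``calibrator_group`` with signed fold change."""
    groups = set(deltas["group"])
    if calibrator_group not in groups or test_group not in groups:
        raise ValueError(f"need both groups {calibrator_group!r} and {test_group!r} in the dCt table")
    cal = deltas.loc[deltas["group"] == calibrator_group, "delta_ct"]
    test = deltas.loc[deltas["group"] == test_group, "delta_ct"]
    ddct = float(test.mean() - cal.mean())
    ratio = float(efficiency ** (-ddct))
    return DdctResult(
        target=target,
        ratio=ratio,
        fold_change=signed_fold_change(ratio),
        ddct=ddct,
        p_value=p_value,
        n_bio={calibrator_group: int(cal.size), test_group: int(test.size)},
    )


def nested_test(table: pd.DataFrame, target: str, normalizer: str, groups: tuple[str, str]) -> float:
    """Two-sided Welch t test on biological-replicate dCt means between two groups."""
    deltas = delta_ct(table, target, normalizer)
    a = deltas.loc[deltas["group"] == groups[0], "delta_ct"].to_numpy()
    b = deltas.loc[deltas["group"] == groups[1], "delta_ct"].to_numpy()
    if len(a) < 1 or len(b) < 1 or (len(a) < 2 and len(b) < 2):
        raise ValueError("need at least two biological replicates in one group and one in the other")
    if min(len(a), len(b)) < 3:
        warnings.warn(
            f"group with fewer than 3 biological replicates (n = {min(len(a), len(b))}); "
            "the nested test is underpowered",
            stacklevel=2,
        )
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


def ddct_analysis(
    table: pd.DataFrame,
    target: str,
    normalizer: str,
    calibrator_group: str,
    efficiency: float = 2.0,
) -> list[DdctResult]:
    """Full ddCt workflow: one result per non-calibrator group, with nested-test p."""
    deltas = delta_ct(table, target, normalizer)
    out = []
    for grp in sorted(set(deltas["group"]) - {calibrator_group}):
        try:
            p = nested_test(table, target, normalizer, (calibrator_group, grp))
        except ValueError:
            p = math.nan
        res = relative_expression(deltas, calibrator_group, grp, target=target,
                                  efficiency=efficiency, p_value=p)
        out.append(res)
    if not out:
        raise ValueError("Ct table contains only the calibrator group")
    return out
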