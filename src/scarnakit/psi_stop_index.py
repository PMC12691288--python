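"""Site-specific pseudouridylation from a CMC reverse-transcription-stop qPCR design.

CMC adducts at a pseudouridine block reverse transcription, so a qPCR
amplicon spanning the site (the "long" fragment) loses template in
CMC-treated RNA in proportion to the modified fraction, while a "short"
amplicon entirely downstream of the site serves as internal control.  The
RT-stop index is

    R = 2^(Ct_untreated,long - Ct_CMC,long) / 2^(Ct_untreated,short - Ct_CMC,short)

with each Ct a replicate mean, and percent pseudouridylation is
100 x (1 - R).  Higher R means less pseudouridylation; R > 1 yields a
negative percentage, which is reported with a warning flag rather than
clamped (clamping would bias group comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qpcr_ddct import validate_ct_table

CONDITIONS = ("untreated", "CMC")


@dataclass(frozen=True)
class PsiDesign:
    """Amplicon ids of the site-spanning (long) and downstream control (short) fragments."""

    long_amplicon: str = "U2_long"
    short_amplicon: str = "U2_short"


@dataclass(frozen=True)
class PsiResult:
    sample: str
    group: str
    r_index: float
    percent_psi: float
    negative_flag: bool

    def to_dict(self) -> dict:
        return {
            "sample": self.sample,
            "group": self.group,
            "r_index": self.r_index,
            "percent_psi": self.percent_psi,
            "negative_flag": self.negative_flag,
        }


def _cell_mean(table: pd.DataFrame, condition: str, target: str) -> float:
    sub = table[(table["condition"] == condition) & (table["target"] == target)]
    if sub.empty:
        raise ValueError(f"no Ct observations for cell (condition={condition!r}, target={target!r})")
    return float(sub["ct"].mean())


def rt_stop_ratio(table: pd.DataFrame, design: PsiDesign, sample: str | None = None) -> float:
    """RT-stop index R for one sample's Ct observations.

    ``table`` must carry a ``condition`` column in {untreated, CMC}; means
    are taken over all replicates in each (condition, amplicon) cell.
    """
    validate_ct_table(table)
    if "condition" not in table.columns:
        raise ValueError("Ct table needs a 'condition' column (untreated/CMC)")
    if sample is not None:
        table = table[table["sample"] == sample]
        if table.empty:
            raise ValueError(f"sample {sample!r} absent from Ct table")
    ul = _cell_mean(table, "untreated", design.long_amplicon)
    cl = _cell_mean(table, "CMC", design.long_amplicon)
    us = _cell_mean(table, "untreated", design.short_amplicon)
    cs = _cell_mean(table, "CMC", design.short_amplicon)
    return float(2.0 ** (ul - cl) / 2.0 ** (us - cs))


def percent_pseudouridylation(r_index: float) -> float:
    """Convert the RT-stop index to percent pseudouridylation, 100 x (1 - R)."""
    if r_index <= 0:
        raise ValueError("r_index must be positive")
    return 100.0 * (1.0 - r_index)


def psi_per_replicate(table: pd.DataFrame, design: PsiDesign) -> pd.DataFrame:
    """One percent-psi value per (sample, bio_rep): technical replicates averaged first."""
    validate_ct_table(table)
    rows = []
    for (sample, group, bio), sub in table.groupby(["sample", "group", "bio_rep"]):
        r = rt_stop_ratio(sub, design)
        rows.append({"sample": sample, "group": group, "bio_rep": bio,
                     "r_index": r, "percent_psi": percent_pseudouridylation(r),
                     "negative_flag": r > 1})
    return pd.DataFrame(rows)


def compare_psi(per_replicate: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Welch t test of each group's per-replicate percent psi against the control group."""
    groups = per_replicate.groupby("group")["percent_psi"]
    if control_group not in groups.groups:
        raise ValueError(f"control group {control_group!r} absent")
    ctrl = groups.get_group(control_group).to_numpy()
    if ctrl.size < 2:
        raise ValueError("control group needs at least 2 replicates")
    rows = []
    for grp, vals in groups:
        if grp == control_group:
            continue
        v = vals.to_numpy()
        if v.size < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 replicates")
        p = float(stats.ttest_ind(v, ctrl, equal_var=False).pvalue)
        rows.append({"group": grp, "n": int(v.size), "mean_percent_psi": float(np.mean(v)),
                     "control_mean": float(np.mean(ctrl)), "p_value": p})
    return pd.DataFrame(rows)
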