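"""Transcript-level differential expression and isoform-switch calling.

From a transcript x sample count matrix: trimmed-mean-of-M-values (TMM)
normalization factors; per-transcript Poisson regression (log link,
library-size x factor offset, two-group indicator) with a likelihood-ratio
test; Benjamini-Hochberg step-up FDR; a +/-1.5 signed fold-change split of
the significant transcripts; and the isoform-switch rule — a gene is called
iff it carries at least one significantly up- and one significantly
down-regulated transcript.

The Poisson model matches the upstream platform's stated procedure.  With
one sample per group it remains defined but its p-values reflect counting
noise only; a prominent warning is emitted in that case.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qpcr_ddct import signed_fold_change

log = logging.getLogger("scarnakit")


@dataclass
class CountMatrix:
    """Non-negative integer transcript x sample counts with a transcript->gene map."""

    counts: pd.DataFrame  # index: transcript_id; columns: samples
    gene_of: pd.Series  # index: transcript_id -> gene id
    sample_groups: dict[str, str]  # sample -> group label
    biotype: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.index) - set(self.gene_of.index)
        if missing:
            raise ValueError(f"{len(missing)} transcripts lack a gene mapping")
        ungrouped = set(self.counts.columns) - set(self.sample_groups)
        if ungrouped:
            raise ValueError(f"samples without a group: {sorted(ungrouped)}")
        if len(set(self.sample_groups.values())) < 1:
            raise ValueError("need at least one sample group")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def protein_coding(self) -> "CountMatrix":
        """Restrict to protein-coding transcripts when a biotype column is present."""
        if self.biotype is None:
            return self
        keep = self.biotype[self.biotype == "protein_coding"].index
        return CountMatrix(
            counts=self.counts.loc[self.counts.index.intersection(keep)],
            gene_of=self.gene_of,
            sample_groups=self.sample_groups,
            biotype=self.biotype,
        )


def read_counts_tsv(counts_path: str | Path, groups_path: str | Path) -> CountMatrix:
    """Counts TSV (transcript_id, gene_id[, biotype], sample columns) + groups TSV (sample, group)."""
    df = pd.read_csv(counts_path, sep="\t", comment="#")
    meta_cols = [c for c in ("transcript_id", "gene_id", "biotype") if c in df.columns]
    df = df.set_index("transcript_id")
    samples = [c for c in df.columns if c not in meta_cols]
    groups = pd.read_csv(groups_path, sep="\t", comment="#")
    return CountMatrix(
        counts=df[samples].astype(int),
        gene_of=df["gene_id"],
        sample_groups=dict(zip(groups["sample"], groups["group"])),
        biotype=df["biotype"] if "biotype" in df.columns else None,
    )


def write_counts_tsv(cm: CountMatrix, counts_path: str | Path, groups_path: str | Path) -> None:
    out = cm.counts.copy()
    out.insert(0, "gene_id", cm.gene_of.reindex(out.index))
    if cm.biotype is not None:
        out.insert(1, "biotype", cm.biotype.reindex(out.index))
    out.index.name = "transcript_id"
    out.to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"sample": list(cm.sample_groups), "group": list(cm.sample_groups.values())}
    ).to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TMM normalization

def _quantile_fraction(counts: pd.DataFrame, p: float = 0.75) -> np.ndarray:
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    q = np.array([np.quantile(counts.iloc[:, j].to_numpy(dtype=float), p) for j in range(counts.shape[1])])
    return q / lib


def tmm_factors(
    cm: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean rescaled to 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean of those fractions.  M (log ratio) and A (average
    log abundance) statistics use transcripts expressed in both members of
    the pair; the extremes of M and A are trimmed symmetrically and the
    factor is two to the precision-weighted mean of the retained M values.
    """
    counts = cm.counts
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    if ref_sample is None:
        f75 = _quantile_fraction(counts)
        ref_sample = counts.columns[int(np.argmin(np.abs(f75 - f75.mean())))]
    ref = counts[ref_sample].to_numpy(dtype=float)
    n_ref = float(lib[ref_sample])
    factors = {}
    for s in counts.columns:
        if s == ref_sample:
            factors[s] = 1.0
            continue
        obs = counts[s].to_numpy(dtype=float)
        n_obs = float(lib[s])
        both = (obs > 0) & (ref > 0)
        if not both.any():
            raise ValueError(f"sample {s!r} shares no expressed transcripts with the reference")
        o, r = obs[both], ref[both]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
        n = m.size
        lo_m = int(np.floor(n * trim_m)) + 1
        hi_m = n + 1 - lo_m
        lo_a = int(np.floor(n * trim_a)) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        factors[s] = float(2.0 ** (np.sum(m[keep] * w[keep]) / np.sum(w[keep])))
    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())


# ---------------------------------------------------------------------------
# Poisson differential transcript expression

def _group_vectors(cm: CountMatrix) -> tuple[np.ndarray, list[str]]:
    groups = sorted(set(cm.sample_groups.values()))
    if len(groups) != 2:
        raise ValueError(f"exactly two sample groups required, found {groups}")
    # a group named like the control condition is the baseline; else alphabetical
    for baseline_name in ("control", "WT", "wild-type", "wildtype"):
        if baseline_name in groups:
            groups = [baseline_name] + [g for g in groups if g != baseline_name]
            break
    x = np.array([1.0 if cm.sample_groups[s] == groups[1] else 0.0 for s in cm.counts.columns])
    return x, groups


def transcript_de(cm: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Per-transcript Poisson GLM with offset log(library size x TMM factor).

    The group effect is tested with a 1-df likelihood-ratio test against
    the intercept-only model; the rate ratio (second group over first,
    alphabetically) is reported in the signed fold-change convention.
    Transcripts with zero counts everywhere are excluded and logged.
    Columns: transcript_id, gene_id, rate_ratio, fold_change, lrt, p_value.
    """
    if factors is None:
        factors = tmm_factors(cm)
    x, groups = _group_vectors(cm)
    n_per_group = [int((x == 0).sum()), int((x == 1).sum())]
    if min(n_per_group) == 1:
        warnings.warn(
            "a group has a single sample: Poisson p-values reflect counting noise only, "
            "not biological replication",
            stacklevel=2,
        )
    offset = np.log(cm.library_sizes.to_numpy(dtype=float) * factors.reindex(cm.counts.columns).to_numpy())
    X_full = sm.add_constant(x)
    X_null = np.ones((x.size, 1))
    rows = []
    dropped = 0
    mat = cm.counts.to_numpy(dtype=float)
    for i, tid in enumerate(cm.counts.index):
        y = mat[i]
        if y.sum() == 0:
            dropped += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.GLM(y, X_full, family=sm.families.Poisson(), offset=offset).fit()
            null = sm.GLM(y, X_null, family=sm.families.Poisson(), offset=offset).fit()
        lrt = max(0.0, 2.0 * (full.llf - null.llf))
        p = float(stats.chi2.sf(lrt, df=1))
        ratio = float(np.exp(full.params[1]))
        fc = signed_fold_change(ratio) if ratio > 0 else -np.inf
        rows.append({"transcript_id": tid, "gene_id": cm.gene_of[tid], "rate_ratio": ratio,
                     "fold_change": fc, "lrt": lrt, "p_value": p})
    if dropped:
        log.info("transcript_de: excluded %d all-zero transcripts", dropped)
    if not rows:
        raise ValueError("no transcript with nonzero counts")
    df = pd.DataFrame(rows)
    df.attrs["groups"] = groups
    return df


def fdr_step_up(p_values: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class SwitchCall:
    gene: str
    up_transcripts: tuple[str, ...]
    down_transcripts: tuple[str, ...]


def classify_directions(de: pd.DataFrame, alpha: float = 0.05, fc_threshold: float = 1.5) -> pd.DataFrame:
    """Append q-values and up/down/ns direction labels to a transcript_de table."""
    de = de.copy()
    de["q_value"] = fdr_step_up(de["p_value"].to_numpy())
    sig = de["q_value"] < alpha
    de["direction"] = "ns"
    de.loc[sig & (de["fold_change"] > fc_threshold), "direction"] = "up"
    de.loc[sig & (de["fold_change"] < -fc_threshold), "direction"] = "down"
    return de


def call_switches(de: pd.DataFrame, alpha: float = 0.05, fc_threshold: float = 1.5) -> list[SwitchCall]:
    """Genes with at least one up- and one down-regulated transcript, sorted by gene id."""
    if "q_value" not in de.columns or "direction" not in de.columns:
        de = classify_directions(de, alpha=alpha, fc_threshold=fc_threshold)
    calls = []
    for gene, sub in de.groupby("gene_id"):
        up = tuple(sorted(sub.loc[sub["direction"] == "up", "transcript_id"]))
        down = tuple(sorted(sub.loc[sub["direction"] == "down", "transcript_id"]))
        if up and down:
            calls.append(SwitchCall(gene=str(gene), up_transcripts=up, down_transcripts=down))
    return sorted(calls, key=lambda c: c.gene)


def switch_table(calls: list[SwitchCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "up_transcripts": [",".join(c.up_transcripts) for c in calls],
            "down_transcripts": [",".join(c.down_transcripts) for c in calls],
        }
    )
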