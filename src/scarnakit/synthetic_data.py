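"""Synthetic inputs with planted ground truth for every pipeline stage.

The study whose analysis chain this package implements deposited no raw
data, so each stage is exercised on simulated inputs that carry the
statistical structure the corresponding estimator assumes:

* mixed-allele Sanger traces — Gaussian peak rendering of a random
  reference sequence plus indel alleles applied at the cut site, mixed at
  planted fractions with additive channel noise;
* qPCR Ct tables — Ct = baseline - log2(relative template) + N(0, sigma)
  per technical replicate, with planted expression ratios, and for the
  CMC design a (1 - psi) template loss on the CMC-treated long amplicon;
* transcript count matrices — log-normal baseline means, Poisson counts,
  reciprocal fold swaps planted in switch genes;
* annotation maps — random categories with one planted enriched category
  from which the query is drawn at elevated odds.

Every generator takes a :class:`SimConfig`, derives an independent
substream from the single seed, and returns a truth record echoing the
planted parameters; round-trip tests read truth only from that record.
Synthetic reference sequences reproducing the published guide and primer
coordinates are also built here (the real accessions are not deposited).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import AnnotationMap
from .guide_geometry import ReferenceSeq, revcomp
from .isoform_switch import CountMatrix
from .trace_decomposition import TraceSet

# ---------------------------------------------------------------------------
# published guide / primer sequences (inputs printed in the study's tables)

GRNA1 = "AGTGTATCTTTACACACTGGGCT"  # antisense, PAM TGG, cut 115
GRNA2 = "CACTCTGAGTTATAACTCAG"  # sense, PAM AGG, cut 162
LOCUS_FWD = "GACAGGGTTGCCTAGTCTTAAT"  # 990 bp genotyping amplicon
LOCUS_REV = "CATACTAGAGATTTAGGGATTTCTTTGAGAGG"
U2_UP_FWD = "CTGATACGTCCTCTATCCGA"  # long (108 bp) fragment, spans psi89
U2_DOWN_FWD = "TGGAGCAGGGAGATGGAATAGG"  # short (65 bp) internal control
U2_SHARED_REV = "TACTGCAATACCAGGTCGATGCGT"

_BASES = np.array(list("ACGT"))
_STREAMS = {"traces": 1, "qpcr": 2, "psi": 3, "counts": 4, "annotation": 5, "refs": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class TraceSim:
    """Chromatogram simulation: a clone-like deletion spectrum by default."""

    seq_length: int = 620
    # the decomposition window conventionally starts just downstream of the
    # break, so the default cut sits 4 bases upstream of window start 115:
    # the junction, where peak bleed mixes shifted and unshifted contexts,
    # then lies outside the fitted window
    cut_site: int = 111
    peak_width: float = 0.35
    amplitude: float = 1000.0
    noise_sigma: float = 0.02  # fraction of peak amplitude
    # deletion profile mirroring an edited clone: unedited fraction 0.34
    allele_spectrum: dict[int, float] = field(
        default_factory=lambda: {0: 0.34, -20: 0.18, -15: 0.17, -10: 0.16, -5: 0.15}
    )

    def __post_init__(self) -> None:
        total = sum(self.allele_spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele spectrum sums to {total}, not 1")
        if any(f < 0 for f in self.allele_spectrum.values()):
            raise ValueError("allele fractions must be non-negative")


@dataclass(frozen=True)
class QpcrSim:
    """Expression qPCR: planted ratios match the study's reported reductions."""

    target: str = "scaRNA1"
    normalizer: str = "RN7SL"
    baseline_ct: dict[str, float] = field(default_factory=lambda: {"scaRNA1": 26.0, "RN7SL": 19.0})
    bio_reps: int = 3
    tech_reps: int = 3
    sigma: float = 0.15  # cycle noise per technical replicate
    expression_ratios: dict[str, float] = field(default_factory=lambda: {"6A1": 0.60, "3B2": 0.53})
    control_group: str = "WT"


@dataclass(frozen=True)
class PsiSim:
    """CMC RT-stop qPCR: stop fractions and replicate counts from the study design."""

    long_amplicon: str = "U2_long"
    short_amplicon: str = "U2_short"
    baseline_long: float = 23.0
    baseline_short: float = 22.0
    tech_reps: int = 3
    sigma: float = 0.15
    psi_fractions: dict[str, float] = field(default_factory=lambda: {"WT": 0.93, "6A1": 0.70, "3B2": 0.88})
    bio_reps: dict[str, int] = field(default_factory=lambda: {"WT": 9, "6A1": 5, "3B2": 6})
    control_group: str = "WT"


@dataclass(frozen=True)
class CountsSim:
    """Count-matrix simulation with reciprocal isoform swaps in switch genes."""

    n_genes: int = 1000
    transcripts_per_gene: int = 2
    samples_per_group: int = 3
    baseline_log_mean: float = 3.5  # natural-log mean of per-transcript rates
    baseline_log_sd: float = 1.0
    n_switch: int = 40
    switch_fold: float = 3.0
    lib_size_factors: tuple[float, ...] | None = None
    overdispersion: float = 0.0  # gamma mixing CV^2; 0 = pure Poisson


@dataclass(frozen=True)
class AnnotationSim:
    n_genes: int = 1000
    n_categories: int = 50
    category_size_range: tuple[int, int] = (20, 100)
    planted_category_size: int = 100
    query_size: int = 150
    odds: float = 10.0


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    trace: TraceSim = field(default_factory=TraceSim)
    qpcr: QpcrSim = field(default_factory=QpcrSim)
    psi: PsiSim = field(default_factory=PsiSim)
    counts: CountsSim = field(default_factory=CountsSim)
    annotation: AnnotationSim = field(default_factory=AnnotationSim)


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain (YAML-loaded) mapping."""
    def sub(cls, key):
        block = dict(d.get(key, {}))
        if cls is TraceSim and "allele_spectrum" in block:
            block["allele_spectrum"] = {int(k): float(v) for k, v in block["allele_spectrum"].items()}
        if cls is CountsSim and block.get("lib_size_factors") is not None:
            block["lib_size_factors"] = tuple(block["lib_size_factors"])
        return cls(**block)

    return SimConfig(
        seed=int(d.get("seed", 0)),
        trace=sub(TraceSim, "trace"),
        qpcr=sub(QpcrSim, "qpcr"),
        psi=sub(PsiSim, "psi"),
        counts=sub(CountsSim, "counts"),
        annotation=sub(AnnotationSim, "annotation"),
    )


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# trace generation

def render_trace(sequence: str, peak_width: float = 0.5, amplitude: float = 1000.0) -> np.ndarray:
    """Gaussian-peak rendering: one peak per base on its channel, small bleed to neighbours."""
    n = len(sequence)
    sig = np.zeros((n, 4))
    chan = np.array(["ACGT".index(b) for b in sequence])
    pos = np.arange(n)
    for off in range(-3, 4):
        src = pos + off
        ok = (src >= 0) & (src < n)
        weight = amplitude * np.exp(-(off ** 2) / (2.0 * peak_width ** 2))
        np.add.at(sig, (pos[ok], chan[src[ok]]), weight)
    return sig


def _apply_indel(seq: str, cut_site: int, d: int) -> str:
    """Apply a net indel of size d immediately after 1-based position cut_site.

    Insertions duplicate the d bases immediately upstream of the cut, the
    dominant templated-repair signature at Cas9 blunt cuts; deletions
    remove the d bases immediately downstream.
    """
    c = cut_site
    if d < 0:
        k = -d
        if c + k > len(seq):
            raise ValueError(f"deletion of {k} exceeds the downstream sequence")
        return seq[:c] + seq[c + k:]
    if d > 0:
        if d > c:
            raise ValueError(f"insertion of {d} exceeds the upstream sequence")
        return seq[:c] + seq[c - d : c] + seq[c:]
    return seq


def gen_traces(config: SimConfig) -> tuple[TraceSet, TraceSet, dict]:
    """Control and mixed-allele edited traces with the planted spectrum as truth."""
    t = config.trace
    rng = _rng(config.seed, "traces")
    seq = "".join(rng.choice(_BASES, size=t.seq_length))
    control_sig = render_trace(seq, t.peak_width, t.amplitude)
    n = t.seq_length
    edited_sig = np.zeros_like(control_sig)
    for d, frac in sorted(t.allele_spectrum.items()):
        allele = _apply_indel(seq, t.cut_site, d)
        sig = render_trace(allele, t.peak_width, t.amplitude)
        if sig.shape[0] >= n:
            edited_sig += frac * sig[:n]
        else:
            pad = np.zeros((n, 4))
            pad[: sig.shape[0]] = sig
            edited_sig += frac * pad
    if t.noise_sigma > 0:
        # noise enters the edited (mixture) trace; the control is the clean peak sum
        edited_sig = np.clip(edited_sig + rng.normal(0.0, t.noise_sigma * t.amplitude, size=(n, 4)), 0.0, None)
    control = TraceSet(signal=control_sig, base_calls=seq)
    edited = TraceSet(signal=edited_sig, base_calls="".join("ACGT"[i] for i in edited_sig.argmax(axis=1)))
    truth = {
        "spectrum": {str(d): f for d, f in t.allele_spectrum.items()},
        "cut_site": t.cut_site,
        "editing_efficiency_pct": 100.0 * (1.0 - t.allele_spectrum.get(0, 0.0)),
        "seed": config.seed,
    }
    return control, edited, truth


# ---------------------------------------------------------------------------
# qPCR tables

def gen_ct_table(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Expression Ct table: Ct = baseline - log2(relative template) + noise."""
    q = config.qpcr
    rng = _rng(config.seed, "qpcr")
    groups = {q.control_group: 1.0, **q.expression_ratios}
    rows = []
    for grp, ratio in groups.items():
        for b in range(1, q.bio_reps + 1):
            for target, base in q.baseline_ct.items():
                template = ratio if target == q.target else 1.0
                for tr in range(1, q.tech_reps + 1):
                    ct = base - np.log2(template) + rng.normal(0.0, q.sigma)
                    rows.append({"sample": f"{grp}_b{b}", "group": grp, "target": target,
                                 "bio_rep": b, "tech_rep": tr, "ct": float(ct)})
    truth = {"expression_ratios": dict(q.expression_ratios), "control_group": q.control_group,
             "sigma": q.sigma, "seed": config.seed}
    return pd.DataFrame(rows), truth


def gen_psi_ct_table(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """CMC RT-stop Ct table: the CMC-treated long amplicon loses a (1 - psi) template share."""
    p = config.psi
    rng = _rng(config.seed, "psi")
    rows = []
    for grp, psi in p.psi_fractions.items():
        if not 0 <= psi < 1:
            raise ValueError(f"psi fraction for {grp!r} must lie in [0, 1)")
        for b in range(1, p.bio_reps[grp] + 1):
            cells = {
                ("untreated", p.long_amplicon): p.baseline_long,
                ("CMC", p.long_amplicon): p.baseline_long - np.log2(1.0 - psi),
                ("untreated", p.short_amplicon): p.baseline_short,
                ("CMC", p.short_amplicon): p.baseline_short,
            }
            for (cond, target), base in cells.items():
                for tr in range(1, p.tech_reps + 1):
                    rows.append({"sample": f"{grp}_b{b}", "group": grp, "condition": cond,
                                 "target": target, "bio_rep": b, "tech_rep": tr,
                                 "ct": float(base + rng.normal(0.0, p.sigma))})
    truth = {"psi_fractions": dict(p.psi_fractions), "bio_reps": dict(p.bio_reps),
             "sigma": p.sigma, "control_group": p.control_group, "seed": config.seed}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# count matrices

def gen_counts(config: SimConfig) -> tuple[CountMatrix, dict]:
    """Poisson counts with log-normal baselines and reciprocal switch-gene swaps."""
    c = config.counts
    if c.transcripts_per_gene < 2 and c.n_switch > 0:
        raise ValueError("switch genes need at least 2 transcripts per gene")
    rng = _rng(config.seed, "counts")
    genes = [f"G{i:05d}" for i in range(1, c.n_genes + 1)]
    tids, gene_of = [], {}
    for g in genes:
        for j in range(1, c.transcripts_per_gene + 1):
            tid = f"{g}.t{j}"
            tids.append(tid)
            gene_of[tid] = g
    base = rng.lognormal(c.baseline_log_mean, c.baseline_log_sd, size=len(tids))
    switch_genes = sorted(rng.choice(genes, size=c.n_switch, replace=False)) if c.n_switch else []
    switch_set = set(switch_genes)

    n = c.samples_per_group
    samples = [f"ctrl_{i + 1}" for i in range(n)] + [f"clone_{i + 1}" for i in range(n)]
    groups = {s: ("control" if s.startswith("ctrl") else "clone") for s in samples}
    lib = c.lib_size_factors or tuple(1.0 for _ in samples)
    if len(lib) != len(samples):
        raise ValueError("lib_size_factors must have one entry per sample")

    means = np.tile(base[:, None], (1, len(samples)))
    for gi, g in enumerate(genes):
        if g not in switch_set:
            continue
        row0 = gi * c.transcripts_per_gene
        for si, s in enumerate(samples):
            if groups[s] == "clone":
                means[row0, si] *= c.switch_fold
                means[row0 + 1, si] /= c.switch_fold
    means = means * np.asarray(lib)[None, :]
    if c.overdispersion > 0:
        shape = 1.0 / c.overdispersion
        means = means * rng.gamma(shape, 1.0 / shape, size=means.shape)
    counts = rng.poisson(means)
    index = pd.Index(tids, name="transcript_id")
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=index, columns=samples),
        gene_of=pd.Series(gene_of),
        sample_groups=groups,
        biotype=pd.Series("protein_coding", index=tids),
    )
    truth = {"switch_genes": list(switch_genes), "switch_fold": c.switch_fold,
             "n_genes": c.n_genes, "seed": config.seed}
    return cm, truth


# ---------------------------------------------------------------------------
# annotation maps

def gen_annotation(config: SimConfig) -> tuple[AnnotationMap, set[str], dict]:
    """Random categories, one planted enriched category, and a biased query."""
    a = config.annotation
    rng = _rng(config.seed, "annotation")
    if a.planted_category_size >= a.n_genes:
        raise ValueError("planted category must be smaller than the universe")
    # same gene namespace as gen_counts so switch calls feed enrichment directly
    universe = [f"G{i:05d}" for i in range(1, a.n_genes + 1)]
    cats: dict[str, frozenset[str]] = {}
    planted = "CAT_planted"
    cats[planted] = frozenset(rng.choice(universe, size=a.planted_category_size, replace=False))
    lo, hi = a.category_size_range
    for i in range(1, a.n_categories):
        size = int(rng.integers(lo, hi + 1))
        cats[f"CAT{i:03d}"] = frozenset(rng.choice(universe, size=size, replace=False))
    weights = np.array([a.odds if g in cats[planted] else 1.0 for g in universe])
    weights = weights / weights.sum()
    query = set(rng.choice(universe, size=a.query_size, replace=False, p=weights))
    truth = {"planted_category": planted, "odds": a.odds,
             "planted_size": a.planted_category_size, "seed": config.seed}
    return AnnotationMap(categories=cats, universe=frozenset(universe)), query, truth


# ---------------------------------------------------------------------------
# synthetic reference sequences reproducing the published coordinates

def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_BASES, size=n))


def _plant(seq: list[str], start_1based: int, insert: str) -> None:
    seq[start_1based - 1 : start_1based - 1 + len(insert)] = list(insert)


def scarna1_reference(seed: int = 0) -> ReferenceSeq:
    """Synthetic scaRNA1-transcript-like reference (620 bp).

    The real accession sequence is not deposited; this stand-in plants the
    two published guide sites so that the predicted cut coordinates land at
    115 (antisense guide, TGG PAM) and 162 (sense guide, AGG PAM).
    """
    rng = _rng(seed, "refs")
    seq = _random_seq(rng, 620)
    _plant(seq, 110, revcomp("TGG"))  # PAM on the antisense strand
    _plant(seq, 113, revcomp(GRNA1))  # protospacer span 113-135 -> cut 115
    _plant(seq, 145, GRNA2 + "AGG")  # protospacer span 145-164 -> cut 162
    return ReferenceSeq(id="scaRNA1_synthetic", sequence="".join(seq))


def scarna1_locus_reference(seed: int = 0) -> ReferenceSeq:
    """Synthetic genotyping-locus reference (1000 bp) sized for the 990 bp amplicon."""
    rng = _rng(seed, "refs")
    _random_seq(rng, 620)  # keep the substream aligned with scarna1_reference
    seq = _random_seq(rng, 1000)
    _plant(seq, 6, LOCUS_FWD)
    _plant(seq, 995 - len(LOCUS_REV) + 1, revcomp(LOCUS_REV))  # downstream edge at 995
    return ReferenceSeq(id="scaRNA1_locus_synthetic", sequence="".join(seq))


def u2_reference(seed: int = 0) -> ReferenceSeq:
    """Synthetic U2-snRNA-cDNA-like reference (150 bp) for the 108/65 bp RT-stop design."""
    rng = _rng(seed, "refs")
    _random_seq(rng, 620)
    _random_seq(rng, 1000)
    seq = _random_seq(rng, 150)
    end = 140  # downstream edge of the shared-reverse binding site
    _plant(seq, end - len(U2_SHARED_REV) + 1, revcomp(U2_SHARED_REV))
    _plant(seq, end - 108 + 1, U2_UP_FWD)  # long fragment: 108 bp
    _plant(seq, end - 65 + 1, U2_DOWN_FWD)  # short fragment: 65 bp
    return ReferenceSeq(id="U2_snRNA_synthetic", sequence="".join(seq))


def config_to_dict(config: SimConfig) -> dict:
    return dataclasses.asdict(config)
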