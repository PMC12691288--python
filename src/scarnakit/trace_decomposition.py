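"""Indel-spectrum estimation from Sanger traces by shifted-template decomposition.

An edited cell population yields a chromatogram that is, downstream of the
Cas9 cut, a mixture of the wild-type trace and copies of it shifted by each
allele's net indel size (a deletion of k bases shifts the downstream signal
k positions to the left).  Decomposing the edited four-channel signal over a
bank of shifted control templates with a non-negativity-constrained
least-squares fit recovers the allele fractions; the zero-shift coefficient
estimates the unedited fraction, so aggregate editing efficiency is
100 x (1 - c0).

Quality gates follow common practice for this assay: coefficients are tested
against residual noise with a two-sided t test on an ordinary-least-squares
refit restricted to the active set (an approximation, since the reference
web tool does not publish its exact test), and fits are flagged
uninterpretable below an R^2 floor (default 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

CHANNELS = ("A", "C", "G", "T")


@dataclass(frozen=True)
class TraceSet:
    """Aligned four-channel chromatogram intensities with base calls.

    ``signal`` is positions x 4 (A, C, G, T order), finite and >= 0;
    ``base_calls`` has one character per position.
    """

    signal: np.ndarray
    base_calls: str

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2 or sig.shape[1] != 4:
            raise ValueError("signal must be positions x 4 channels")
        if not np.all(np.isfinite(sig)) or np.any(sig < 0):
            raise ValueError("signal must be finite and non-negative")
        if len(self.base_calls) != sig.shape[0]:
            raise ValueError("base_calls length must equal signal length")
        object.__setattr__(self, "signal", sig)

    def __len__(self) -> int:
        return self.signal.shape[0]


@dataclass(frozen=True)
class DecompParams:
    """Decomposition settings.

    Positions are 1-based trace coordinates.  ``window`` is the closed
    interval actually decomposed and should sit downstream of the cut;
    ``left_boundary`` bounds the upstream region used for trace alignment.
    The fit covers all shifts in [-max_indel, +max_indel]; reporting of
    significant indels is restricted to |d| >= min_indel_reported.
    """

    left_boundary: int = 100
    window: tuple[int, int] = (115, 560)
    max_indel: int = 27
    min_indel_reported: int = 2
    p_threshold: float = 0.001
    r2_gate: float = 0.90

    def __post_init__(self) -> None:
        if self.window[0] <= self.left_boundary:
            raise ValueError("window start must exceed left_boundary")
        if self.window[1] < self.window[0]:
            raise ValueError("empty decomposition window")
        if not (self.max_indel >= self.min_indel_reported >= 0):
            raise ValueError("require max_indel >= min_indel_reported >= 0")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if not 0 < self.r2_gate <= 1:
            raise ValueError("r2_gate must lie in (0, 1]")


@dataclass(frozen=True)
class DecompositionResult:
    coefficients: dict[int, float]
    pvalues: dict[int, float]
    r2: float
    efficiency_pct: float
    efficiency_significant_pct: float
    interpretable: bool
    params: DecompParams = field(repr=False, default=DecompParams())

    def to_dict(self) -> dict:
        return {
            "coefficients": {str(k): v for k, v in sorted(self.coefficients.items())},
            "pvalues": {str(k): v for k, v in sorted(self.pvalues.items())},
            "r2": self.r2,
            "efficiency_pct": self.efficiency_pct,
            "efficiency_significant_pct": self.efficiency_significant_pct,
            "interpretable": self.interpretable,
            "params": {
                "left_boundary": self.params.left_boundary,
                "window": list(self.params.window),
                "max_indel": self.params.max_indel,
                "min_indel_reported": self.params.min_indel_reported,
                "p_threshold": self.params.p_threshold,
                "r2_gate": self.params.r2_gate,
            },
        }


def build_templates(control: TraceSet, params: DecompParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shifted-copy template bank over the decomposition window.

    Returns ``(indel_sizes, positions, bank)`` where ``bank`` has shape
    (kept positions * 4, n indel sizes) and the template for shift d at
    window position p is the control signal at p - d.  Window positions
    whose shifted source would fall outside the trace for any d are
    dropped from the fit.
    """
    lo, hi = params.window
    if hi > len(control):
        raise ValueError(f"window end {hi} exceeds trace length {len(control)}")
    sizes = np.arange(-params.max_indel, params.max_indel + 1)
    positions = np.arange(lo, hi + 1)
    keep = (positions - sizes.max() >= 1) & (positions - sizes.min() <= len(control))
    positions = positions[keep]
    if positions.size == 0:
        raise ValueError("no window positions with valid shifted sources for all indel sizes")
    cols = []
    for d in sizes:
        src = positions - d - 1  # 0-based source rows
        cols.append(control.signal[src, :].ravel())
    bank = np.column_stack(cols)
    return sizes, positions, bank


def align_traces(control: TraceSet, edited: TraceSet, params: DecompParams,
                 max_lag: int | None = None, min_corr: float = 0.9) -> int:
    """Best integer lag aligning the pre-cut region of ``edited`` to ``control``.

    Cross-correlates the flattened four-channel signal over [1, left_boundary];
    raises if even the best lag correlates below ``min_corr``.
    """
    if max_lag is None:
        max_lag = params.max_indel
    lb = params.left_boundary
    best_lag, best_r = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        lo = max(0, lag)
        hi = min(lb, len(edited) + lag)
        if hi - lo < 10:
            continue
        e = edited.signal[lo - lag : hi - lag].ravel()
        cc = control.signal[lo:hi].ravel()
        if np.std(e) == 0 or np.std(cc) == 0:
            continue
        r = float(np.corrcoef(cc, e)[0, 1])
        if r > best_r:
            best_r, best_lag = r, lag
    if best_r < min_corr:
        raise ValueError(
            f"traces do not align upstream of the cut (best correlation {best_r:.3f} < {min_corr})"
        )
    return best_lag


def _apply_lag(trace: TraceSet, lag: int) -> TraceSet:
    if lag == 0:
        return trace
    sig = np.zeros_like(trace.signal)
    n = len(trace)
    if lag > 0:
        sig[lag:] = trace.signal[: n - lag]
    else:
        sig[: n + lag] = trace.signal[-lag:]
    calls = list("N" * n)
    for i in range(n):
        j = i - lag
        if 0 <= j < n:
            calls[i] = trace.base_calls[j]
    return TraceSet(signal=sig, base_calls="".join(calls))


def decompose(control: TraceSet, edited: TraceSet, params: DecompParams | None = None,
              prune_fraction: float = 0.005) -> DecompositionResult:
    """Fit the edited trace as a non-negative mixture of shifted control templates.

    Coefficients are normalized to sum to one; R^2 is the fraction of
    window variance explained; per-coefficient p-values come from a
    two-sided t test on an OLS refit over the NNLS active set.

    Under channel noise a plain NNLS fit scatters small positive mass over
    many templates, inflating the apparent edited fraction; components
    below ``prune_fraction`` of the total are therefore dropped and the
    fit repeated until the active set is stable (the zero-shift template
    is never pruned).
    """
    params = params or DecompParams()
    lag = align_traces(control, edited, params)
    edited = _apply_lag(edited, lag)
    sizes, positions, bank = build_templates(control, params)
    y = edited.signal[positions - 1, :].ravel()
    if not np.any(y) or not np.any(bank):
        raise ValueError("decomposition window is all zero")
    active = np.ones(sizes.size, dtype=bool)
    for _ in range(4):
        coef = np.zeros(sizes.size)
        coef[active], rnorm = optimize.nnls(bank[:, active], y)
        total = coef.sum()
        if total <= 0:
            raise ValueError(f"solver returned an all-zero fit (residual norm {rnorm:.3g})")
        keep = (coef / total >= prune_fraction) | (sizes == 0)
        if keep.sum() == active.sum():
            break
        active = keep
    frac = coef / total
    resid = y - bank @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)

    pvals = _active_set_pvalues(bank, y, coef)
    c0 = float(frac[sizes == 0][0])
    sig_mask = np.array(
        [pvals[i] < params.p_threshold and abs(int(d)) >= params.min_indel_reported
         for i, d in enumerate(sizes)]
    )
    eff_sig = 100.0 * float(frac[sig_mask].sum())
    return DecompositionResult(
        coefficients={int(d): float(f) for d, f in zip(sizes, frac)},
        pvalues={int(d): float(p) for d, p in zip(sizes, pvals)},
        r2=r2,
        efficiency_pct=100.0 * (1.0 - c0),
        efficiency_significant_pct=eff_sig,
        interpretable=r2 >= params.r2_gate,
        params=params,
    )


def _active_set_pvalues(bank: np.ndarray, y: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """Two-sided t p-values from an OLS refit restricted to the nonzero coefficients."""
    pvals = np.ones(bank.shape[1])
    active = np.flatnonzero(coef > 1e-12)
    if active.size == 0:
        return pvals
    X = bank[:, active]
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    dof = y.size - rank
    if dof <= 0:
        return pvals
    resid = y - X @ beta
    s2 = float(resid @ resid) / dof
    if s2 == 0:
        pvals[active] = 0.0
        return pvals
    cov = s2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf)
    pvals[active] = 2.0 * stats.t.sf(np.abs(t), dof)
    return pvals


def significant_spectrum(result: DecompositionResult, params: DecompParams | None = None) -> dict[int, float]:
    """Coefficients passing the significance and minimum-size filters; d = 0 always kept.

    Fractions are reported as fitted, without renormalization.
    """
    params = params or result.params
    out = {0: result.coefficients.get(0, 0.0)}
    for d, frac in result.coefficients.items():
        if d != 0 and abs(d) >= params.min_indel_reported and result.pvalues.get(d, 1.0) < params.p_threshold:
            out[d] = frac
    return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# TraceSet I/O: TSV of per-position channel intensities (pos, A, C, G, T, base)

def read_trace_tsv(path: str | Path) -> TraceSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.sort_values("pos")
    sig = df[list(CHANNELS)].to_numpy(dtype=float)
    return TraceSet(signal=sig, base_calls="".join(df["base"].astype(str)))


def write_trace_tsv(trace: TraceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# chromatogram peak intensities; pos is 1-based\n")
        fh.write("pos\tA\tC\tG\tT\tbase\n")
        for i in range(len(trace)):
            vals = "\t".join(f"{v:.4f}" for v in trace.signal[i])
            fh.write(f"{i + 1}\t{vals}\t{trace.base_calls[i]}\n")
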