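"""Splicing quantification from dual-fluorescence flow-cytometry events.

In the dual-fluorescence reporter, tdTomato tracks the monitored splice
isoform while eGFP is constitutive, so on the log2 scale the per-event
ratio M = log2(tdTomato) - log2(eGFP) is an exon-inclusion proxy up to
an unidentifiable constant: log2(PSI) = M + c.  Absolute PSI is never
reported from fluorescence; only differences of median M between a
sample and a non-targeting control, where c cancels, are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_COLUMNS = ("eGFP", "tdTomato", "BFP", "viable")

#: Minimum gated events for a trustworthy summary.
DEFAULT_MIN_EVENTS = 2400


@dataclass
class PsiSummary:
    """Median-based summary of the per-event log-ratio M."""

    median_m: float
    mad_m: float
    n: int
    n_dropped_nonpositive: int = 0


def read_events(path: str | Path) -> pd.DataFrame:
    """Event table CSV with columns eGFP, tdTomato, BFP, viable."""
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    df["viable"] = df["viable"].astype(bool)
    return df


def gate_events(
    events: pd.DataFrame, bfp_threshold: float = 0.0, require_viable: bool = True
) -> pd.DataFrame:
    """Keep viable, BFP-high events (BFP marks dCas13d expression).

    The returned frame records retained/total in ``attrs``.
    """
    mask = events["BFP"] >= bfp_threshold
    if require_viable:
        mask &= events["viable"].astype(bool)
    gated = events.loc[mask].copy()
    if len(gated) == 0:
        raise ValueError("gating retained zero events")
    gated.attrs["n_total"] = int(len(events))
    gated.attrs["n_retained"] = int(len(gated))
    return gated


def psi_log_ratio(events: pd.DataFrame) -> tuple[pd.DataFrame, PsiSummary]:
    """Per-event M and A values plus a median/MAD summary of M.

    Events with a non-positive intensity in either channel are dropped
    and counted, not silently ignored.
    """
    ok = (events["eGFP"] > 0) & (events["tdTomato"] > 0)
    dropped = int((~ok).sum())
    kept = events.loc[ok].copy()
    if len(kept) == 0:
        raise ValueError("no events with positive intensities in both channels")
    log_td = np.log2(kept["tdTomato"].to_numpy(dtype=float))
    log_gfp = np.log2(kept["eGFP"].to_numpy(dtype=float))
    kept["M"] = log_td - log_gfp
    kept["A"] = (log_td + log_gfp) / 2.0
    m = kept["M"].to_numpy()
    med = float(np.median(m))
    summary = PsiSummary(
        median_m=med,
        mad_m=float(np.median(np.abs(m - med))),
        n=int(len(kept)),
        n_dropped_nonpositive=dropped,
    )
    return kept, summary


def delta_psi_vs_control(
    sample: PsiSummary, control: PsiSummary, min_events: int = DEFAULT_MIN_EVENTS
) -> float:
    """log2 fold change of the PSI proxy vs the non-targeting control.

    delta = median M(sample) - median M(control); the reporter constant
    c cancels, so this is directly comparable to orthogonal (RT-PCR)
    fold-change estimates.  Summaries built from fewer than
    ``min_events`` events trigger a warning but the value is returned.
    """
    if sample.n < min_events or control.n < min_events:
        warnings.warn(
            f"summary below the recommended minimum of {min_events} events "
            f"(sample n={sample.n}, control n={control.n})",
            stacklevel=2,
        )
    return sample.median_m - control.median_m


def summarize_events_csv(path: str | Path, bfp_threshold: float = 0.0) -> PsiSummary:
    events = read_events(path)
    gated = gate_events(events, bfp_threshold=bfp_threshold)
    _, summary = psi_log_ratio(gated)
    return summary


def ma_plot(events_with_ma: pd.DataFrame, out_path: str | Path) -> None:
    """Contour-style MA plot of gated events (optional matplotlib output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.hexbin(events_with_ma["A"], events_with_ma["M"], gridsize=60, mincnt=1, cmap="viridis")
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("A = (log2 tdTomato + log2 eGFP)/2")
    ax.set_ylabel("M = log2 tdTomato - log2 eGFP")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
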