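"""Enrichment statistics for sorted-bin tiling screens.

For each guide g and each sorted bin (top, bottom) compared against the
unsorted bin, an enrichment score ``e`` is computed from a binomial
model of read allocation, normalized to a robust Z-score using the
median and scaled MAD across the whole library, gated by a
quantifiability filter (read count >= 5 in both compared conditions and
RPM >= 20 in at least one), combined across the two sorted bins of a
replicate by Stouffer's method, and finally combined across replicates
with reporter-dependent signs so that a positive combined Z always
means splicing activation (more inclusion of the monitored exon).
Combined scores supported by at least four quantifiable bins are
converted to two-sided normal p-values and Benjamini-Hochberg FDR.

Two readings of the enrichment score are provided:

``per_guide`` (default)
    Two-sample binomial comparison of the guide's reads between the two
    bins: r = n_bin/(n_bin + n_ref) against r0 = N_bin/(N_bin + N_ref),
    with s = sqrt(r(1-r)/(n_bin + n_ref)).
``as_printed``
    r = n_bin/(N_bin + N_ref) against the same r0, with
    s = sqrt(r(1-r)/(N_bin + N_ref)).  This reading carries a large
    guide-independent offset that the median-centering of the Z step
    removes.

Missing values are explicit NaN sentinels propagated alongside 0/1
quantifiability flags; a NaN is never compared, only gated by its flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .counting import BinCountTable, rpm_normalize

MAD_SCALE = 0.6745  # MAD-to-sigma consistency constant for a normal distribution

MIN_READS = 5
MIN_RPM = 20.0
MIN_QUANTIFIABLE_BINS = 4

#: Sign of each (bin, reporter) term in the cross-replicate combination.
#: Enrichment in the top bin of an inclusion reporter (DUAL_IN) and in the
#: bottom bin of an exclusion reporter (DUAL_EX) both indicate activation.
COMBINE_SIGN = {
    ("top", "DUAL_IN"): +1.0,
    ("bottom", "DUAL_IN"): -1.0,
    ("top", "DUAL_EX"): -1.0,
    ("bottom", "DUAL_EX"): +1.0,
}


@dataclass
class ZNormStats:
    """Location/scale used for robust Z-normalization of one comparison."""

    m: float
    sigma: float
    n_used: int


# ---------------------------------------------------------------------------
# elementary operations


def quantifiable(n_bin: int, n_ref: int, rpm_bin: float, rpm_ref: float) -> bool:
    """Read-coverage gate: count >= 5 in both conditions, RPM >= 20 in at least one."""
    return n_bin >= MIN_READS and n_ref >= MIN_READS and (rpm_bin >= MIN_RPM or rpm_ref >= MIN_RPM)


def enrichment_score(
    n_g_bin: int, n_g_ref: int, N_bin: int, N_ref: int, mode: str = "per_guide"
) -> float:
    """Binomial enrichment score of one guide in bin vs reference.

    Returns NaN when the score is undefined (degenerate proportion with
    zero standard error).
    """
    if mode == "per_guide":
        n = n_g_bin + n_g_ref
        if n == 0:
            return math.nan
        r = n_g_bin / n
        r0 = N_bin / (N_bin + N_ref)
        s = math.sqrt(r * (1.0 - r) / n)
    elif mode == "as_printed":
        N = N_bin + N_ref
        r = n_g_bin / N
        r0 = N_bin / N
        s = math.sqrt(r * (1.0 - r) / N)
    else:
        raise ValueError(f"unknown enrichment mode {mode!r}")
    if s == 0.0:
        return math.nan
    return (r - r0) / s


def _enrichment_vec(n_bin, n_ref, N_bin, N_ref, mode):
    n_bin = np.asarray(n_bin, dtype=float)
    n_ref = np.asarray(n_ref, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "per_guide":
            n = n_bin + n_ref
            r = np.where(n > 0, n_bin / np.where(n > 0, n, 1), np.nan)
            r0 = N_bin / (N_bin + N_ref)
            s = np.sqrt(r * (1.0 - r) / np.where(n > 0, n, 1))
        elif mode == "as_printed":
            N = N_bin + N_ref
            r = n_bin / N
            r0 = N_bin / N
            s = np.sqrt(r * (1.0 - r) / N)
        else:
            raise ValueError(f"unknown enrichment mode {mode!r}")
        e = (r - r0) / s
    e[~np.isfinite(e)] = np.nan
    return e


def robust_z(e: np.ndarray | Sequence[float]) -> tuple[np.ndarray, ZNormStats]:
    """Z-normalize enrichment scores by median and scaled MAD.

    The location m and scale sigma = MAD/0.6745 are computed across all
    entries with a defined score (controls included); NaN entries stay
    NaN in the output.
    """
    e = np.asarray(e, dtype=float)
    ok = np.isfinite(e)
    if ok.sum() < 2:
        raise ValueError("robust_z needs at least 2 defined enrichment scores")
    m = float(np.median(e[ok]))
    mad = float(np.median(np.abs(e[ok] - m)))
    if mad == 0.0:
        raise ValueError(
            "MAD of enrichment scores is zero (degenerate input); "
            "use a larger library or switch enrichment mode"
        )
    sigma = mad / MAD_SCALE
    z = np.full_like(e, np.nan)
    z[ok] = (e[ok] - m) / sigma
    return z, ZNormStats(m=m, sigma=sigma, n_used=int(ok.sum()))


def replicate_z(z_top: float, z_bottom: float, w_top: int, w_bottom: int) -> float:
    """Stouffer combination of the two sorted bins within one replicate.

    Top enrichment counts positively, bottom negatively; unquantifiable
    bins are dropped through their 0 weights.  Missing (NaN) when
    neither bin is quantifiable.
    """
    w = w_top + w_bottom
    if w == 0:
        return math.nan
    zt = z_top if w_top else 0.0
    zb = z_bottom if w_bottom else 0.0
    return (zt * w_top - zb * w_bottom) / math.sqrt(w)


# ---------------------------------------------------------------------------
# per-replicate table


def replicate_stats(table: BinCountTable, mode: str = "per_guide") -> pd.DataFrame:
    """Per-guide e, z, w for top and bottom vs unsorted, plus the replicate z.

    Returns a DataFrame indexed by guide id with columns
    ``e_top, z_top, w_top, e_bottom, z_bottom, w_bottom, z_rep`` and
    attrs recording the normalization stats and replicate metadata.
    """
    rpm = rpm_normalize(table).rpm
    out = pd.DataFrame(index=table.counts.index)
    norm_stats = {}
    for bin_name, s in (("top", "t"), ("bottom", "b")):
        n_bin = table.counts[f"n_{s}"].to_numpy()
        n_ref = table.counts["n_u"].to_numpy()
        e = _enrichment_vec(n_bin, n_ref, table.totals[bin_name], table.totals["unsorted"], mode)
        z, zstats = robust_z(e)
        w = (
            (n_bin >= MIN_READS)
            & (n_ref >= MIN_READS)
            & (
                (rpm[f"rpm_{s}"].to_numpy() >= MIN_RPM)
                | (rpm["rpm_u"].to_numpy() >= MIN_RPM)
            )
            & np.isfinite(z)
        ).astype(int)
        out[f"e_{bin_name}"] = e
        out[f"z_{bin_name}"] = z
        out[f"w_{bin_name}"] = w
        norm_stats[bin_name] = zstats
    zt = np.where(out["w_top"] == 1, out["z_top"], 0.0)
    zb = np.where(out["w_bottom"] == 1, out["z_bottom"], 0.0)
    w_sum = (out["w_top"] + out["w_bottom"]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        z_rep = np.where(w_sum > 0, (zt - zb) / np.sqrt(w_sum), np.nan)
    out["z_rep"] = z_rep
    out.attrs["replicate_id"] = table.replicate_id
    out.attrs["reporter"] = table.reporter
    out.attrs["mode"] = mode
    out.attrs["znorm"] = norm_stats
    return out


# ---------------------------------------------------------------------------
# cross-replicate combination


def combine_replicates(per_replicate: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-replicate Z-scores into a final activation Z per guide.

    Each entry of ``per_replicate`` is a :func:`replicate_stats` frame
    (its attrs carry the reporter orientation).  The canonical design is
    four replicates, two per reporter, giving up to eight quantifiable
    bins; any number of replicates is accepted.  Positive Z = splicing
    activation.
    """
    if not per_replicate:
        raise ValueError("no replicate tables given")
    index = per_replicate[0].index
    for df in per_replicate[1:]:
        if not df.index.equals(index):
            raise ValueError("replicate tables must share the same guide index")
    num = np.zeros(len(index))
    W = np.zeros(len(index), dtype=int)
    for df in per_replicate:
        reporter = df.attrs.get("reporter")
        if reporter not in ("DUAL_IN", "DUAL_EX"):
            raise ValueError(f"replicate table lacks a valid reporter tag: {reporter!r}")
        w_t = df["w_top"].to_numpy()
        w_b = df["w_bottom"].to_numpy()
        z_t = np.where(w_t == 1, df["z_top"].to_numpy(), 0.0)
        z_b = np.where(w_b == 1, df["z_bottom"].to_numpy(), 0.0)
        # one fused contribution per replicate keeps bin-swap antisymmetry
        # exact in floating point (negation commutes with the accumulation)
        num += (
            COMBINE_SIGN[("top", reporter)] * z_t * w_t
            + COMBINE_SIGN[("bottom", reporter)] * z_b * w_b
        )
        W += w_t + w_b
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(W > 0, num / np.sqrt(np.where(W > 0, W, 1)), np.nan)
    return pd.DataFrame({"Z": Z, "W": W}, index=index)


def call_hits(combined: pd.DataFrame, fdr_threshold: float = 0.01) -> pd.DataFrame:
    """p-values, BH FDR and hit classes for guides with enough quantifiable bins.

    Only guides with ``W >= 4`` enter the p-value/FDR computation; the
    BH correction runs over exactly that filtered set.  A guide passes
    as ``activator`` (Z > 0) or ``inhibitor`` (Z < 0) at
    ``fdr <= fdr_threshold``.
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must be in (0, 1)")
    out = combined.copy()
    out["p"] = np.nan
    out["fdr"] = np.nan
    out["hit_class"] = "none"
    mask = (out["W"] >= MIN_QUANTIFIABLE_BINS) & np.isfinite(out["Z"])
    if not mask.any():
        import warnings

        warnings.warn("no guides pass the W >= 4 filter; no hits callable", stacklevel=2)
        return out
    z = out.loc[mask, "Z"].to_numpy()
    p = 2.0 * sps.norm.sf(np.abs(z))
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    out.loc[mask, "p"] = p
    out.loc[mask, "fdr"] = fdr
    sig = mask.copy()
    sig.loc[mask] = fdr <= fdr_threshold
    out.loc[sig & (out["Z"] > 0), "hit_class"] = "activator"
    out.loc[sig & (out["Z"] < 0), "hit_class"] = "inhibitor"
    return out


def analyze_screen(
    tables: Sequence[BinCountTable],
    mode: str = "per_guide",
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Counts-to-hits convenience wrapper over the full statistics chain.

    Returns the combined table (Z, W, p, fdr, hit_class) with each
    replicate's z_rep joined as ``z_rep_<replicate_id>``.
    """
    per_rep = [replicate_stats(t, mode=mode) for t in tables]
    combined = call_hits(combine_replicates(per_rep), fdr_threshold)
    for df in per_rep:
        combined[f"z_rep_{df.attrs['replicate_id']}"] = df["z_rep"]
    combined.attrs["mode"] = mode
    combined.attrs["fdr_threshold"] = fdr_threshold
    combined.attrs["replicates"] = [
        {"replicate_id": df.attrs["replicate_id"], "reporter": df.attrs["reporter"]}
        for df in per_rep
    ]
    return combined
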