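"""Spacer-length shift analysis: 25-nt vs nested 22-nt guide concordance.

Every 25-nt guide tiled at a 1-nt step is fully covered by four 22-nt
guides.  Shift 0 pairs the 22-mer sharing the gRNA 5' end (the spacer
5' end pairs the 3'-most target base, so the two footprints share their
target 3' end); shift 3 pairs the 22-mer sharing the gRNA 3' end (same
target start).  In target coordinates a 25-mer footprint [s, s+25)
pairs at shift k with the 22-mer footprint [s+3-k, s+25-k).

Per shift, concordance is the squared Pearson correlation of the final
combined Z-scores over pairs where both are defined.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .library import GuideLibrary

logger = logging.getLogger(__name__)

SHIFTS = (0, 1, 2, 3)
LONG_LEN = 25
SHORT_LEN = 22


def partner_interval(start25: int, shift: int) -> tuple[int, int]:
    """22-mer footprint paired with the 25-mer footprint [start25, start25+25)."""
    if shift not in SHIFTS:
        raise ValueError("shift must be 0..3")
    lo = start25 + (LONG_LEN - SHORT_LEN) - shift
    return lo, lo + SHORT_LEN


def long_interval_from_partner(start22: int, shift: int) -> tuple[int, int]:
    """Invert :func:`partner_interval`: recover the 25-mer footprint."""
    s = start22 - (LONG_LEN - SHORT_LEN) + shift
    return s, s + LONG_LEN


def pair_by_shift(library: GuideLibrary) -> pd.DataFrame:
    """Pair table (guide25_id, guide22_id, shift) for a 1-nt-step library.

    25-mers whose shift-k partner falls off the tiled region are
    omitted for that shift (logged).
    """
    by_start = {
        (g.length, g.target_start): g.id for g in library.on_target() if g.target_start is not None
    }
    rows = []
    n_missing = 0
    for g in library.on_target():
        if g.length != LONG_LEN:
            continue
        for shift in SHIFTS:
            lo, _hi = partner_interval(g.target_start, shift)
            partner = by_start.get((SHORT_LEN, lo))
            if partner is None:
                n_missing += 1
                continue
            rows.append({"guide25_id": g.id, "guide22_id": partner, "shift": shift})
    if n_missing:
        logger.info("omitted %d shift pairs missing a 22-nt partner at region edges", n_missing)
    return pd.DataFrame(rows, columns=["guide25_id", "guide22_id", "shift"])


def attach_z(pairs: pd.DataFrame, combined: pd.DataFrame, z_col: str = "Z") -> pd.DataFrame:
    """Join combined Z-scores onto the pair table as Z25/Z22."""
    out = pairs.copy()
    out["Z25"] = combined[z_col].reindex(out["guide25_id"]).to_numpy()
    out["Z22"] = combined[z_col].reindex(out["guide22_id"]).to_numpy()
    return out


def shift_correlation(pair_table: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Per-shift n and squared Pearson correlation of (Z25, Z22).

    Pairs with either Z missing are dropped per shift; shifts with
    fewer than ``min_pairs`` complete pairs get a missing R2.
    """
    rows = []
    for shift in SHIFTS:
        sub = pair_table.loc[pair_table["shift"] == shift, ["Z25", "Z22"]].dropna()
        n = len(sub)
        if n < min_pairs:
            r2 = np.nan
        else:
            r = np.corrcoef(sub["Z25"], sub["Z22"])[0, 1]
            r2 = float(r * r)
        rows.append({"shift": shift, "n": n, "R2": r2})
    return pd.DataFrame(rows)


def analyze_shifts(library: GuideLibrary, combined: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full shift analysis: pair table with Z values and per-shift summary."""
    pairs = attach_z(pair_by_shift(library), combined)
    return pairs, shift_correlation(pairs)
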