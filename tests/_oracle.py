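"""Independent straight-line re-implementation of the screen statistics.

Deliberately written with plain Python floats, explicit loops and the
statistics module — no numpy, no shared code with the package — so it
can serve as an oracle for the vectorized implementation.
"""

from __future__ import annotations

import math
from statistics import NormalDist, median

SIGN = {
    ("top", "DUAL_IN"): 1.0,
    ("bottom", "DUAL_IN"): -1.0,
    ("top", "DUAL_EX"): -1.0,
    ("bottom", "DUAL_EX"): 1.0,
}


def oracle_enrichment(n_bin, n_ref, N_bin, N_ref, mode="per_guide"):
    if mode == "per_guide":
        n = n_bin + n_ref
        if n == 0:
            return None
        r = n_bin / n
        r0 = N_bin / (N_bin + N_ref)
        s = math.sqrt(r * (1 - r) / n)
    else:
        N = N_bin + N_ref
        r = n_bin / N
        r0 = N_bin / N
        s = math.sqrt(r * (1 - r) / N)
    if s == 0:
        return None
    return (r - r0) / s


def oracle_robust_z(values):
    """values: list of float-or-None; returns (z list, m, sigma)."""
    ok = [v for v in values if v is not None]
    m = median(ok)
    mad = median([abs(v - m) for v in ok])
    sigma = mad / 0.6745
    return [None if v is None else (v - m) / sigma for v in values], m, sigma


def oracle_replicate(counts, totals, mode="per_guide"):
    """counts: {gid: (n_u, n_t, n_b)}; totals: (N_u, N_t, N_b).

    Returns {gid: {"e_top", "z_top", "w_top", ..., "z_rep"}}.
    """
    gids = list(counts)
    N_u, N_t, N_b = totals
    out = {g: {} for g in gids}
    for bin_name, bin_i, N_bin in (("top", 1, N_t), ("bottom", 2, N_b)):
        es = [oracle_enrichment(counts[g][bin_i], counts[g][0], N_bin, N_u, mode) for g in gids]
        zs, _, _ = oracle_robust_z(es)
        for g, e, z in zip(gids, es, zs):
            n_bin, n_ref = counts[g][bin_i], counts[g][0]
            rpm_bin = n_bin / N_bin * 1e6
            rpm_ref = n_ref / N_u * 1e6
            w = int(
                n_bin >= 5 and n_ref >= 5 and (rpm_bin >= 20 or rpm_ref >= 20) and z is not None
            )
            out[g][f"e_{bin_name}"] = e
            out[g][f"z_{bin_name}"] = z
            out[g][f"w_{bin_name}"] = w
    for g in gids:
        wt, wb = out[g]["w_top"], out[g]["w_bottom"]
        if wt + wb == 0:
            out[g]["z_rep"] = None
        else:
            zt = out[g]["z_top"] if wt else 0.0
            zb = out[g]["z_bottom"] if wb else 0.0
            out[g]["z_rep"] = (zt * wt - zb * wb) / math.sqrt(wt + wb)
    return out


def oracle_combine(replicates):
    """replicates: list of (per_guide dict from oracle_replicate, reporter)."""
    gids = list(replicates[0][0])
    out = {}
    for g in gids:
        num, W = 0.0, 0
        for rep, reporter in replicates:
            for bin_name in ("top", "bottom"):
                w = rep[g][f"w_{bin_name}"]
                if w:
                    num += SIGN[(bin_name, reporter)] * rep[g][f"z_{bin_name}"]
                    W += 1
        out[g] = {"Z": num / math.sqrt(W) if W else None, "W": W}
    return out


def oracle_bh(pvalues):
    """Benjamini-Hochberg step-up adjusted values (brute force)."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adj = [0.0] * n
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = n - rank_from_end
        running = min(running, pvalues[i] * n / rank)
        adj[i] = running
    return adj


def oracle_hits(combined, fdr_threshold=0.01):
    nd = NormalDist()
    gids = [g for g in combined if combined[g]["W"] >= 4 and combined[g]["Z"] is not None]
    ps = [2.0 * (1.0 - nd.cdf(abs(combined[g]["Z"]))) for g in gids]
    fdrs = oracle_bh(ps)
    out = {}
    for g, p, q in zip(gids, ps, fdrs):
        Z = combined[g]["Z"]
        cls = "none"
        if q <= fdr_threshold and Z > 0:
            cls = "activator"
        elif q <= fdr_threshold and Z < 0:
            cls = "inhibitor"
        out[g] = {"p": p, "fdr": q, "hit_class": cls}
    return out
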