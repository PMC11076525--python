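"""Synthetic tiling-screen generator with known ground truth.

Emulates the full experimental chain of a pooled dCas13d splicing
screen so every analysis stage can be exercised without sequencing
data: ground-truth splicing-regulatory elements (SREs) on a reporter
region, per-guide PSI effects from footprint/SRE overlap on the logit
scale, single-integration cells with lognormal fluorescence, top/bottom
quantile sorting of the BFP-positive subpopulation, and multinomial
read sampling per bin (optionally emitted as FASTQ).

The generative model (documented in docs/methods.md):

- logit(psi_g) = logit(baseline) - sum_sre effect * overlap_frac * potency(length),
  overlap_frac = |footprint ∩ sre| / |sre|.  A silencer carries a
  negative effect, so a guide masking it raises inclusion.
- the effective footprint is anchored at the spacer 5' end (the
  3'-most target bases), reflecting that the 5' end of the spacer plus
  the upstream scaffold positions the ribonucleoprotein on the target.
- DUAL_IN: tdTomato tracks psi; DUAL_EX: tracks 1 - psi; eGFP is
  constitutive; all intensities lognormal with log2-scale Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counting import BinCountTable, BinCounts
from .library import GuideLibrary, GuideRNA, ReporterAnnotation, design_library

# Fluorescence model constants (log2 arbitrary units).
GFP_LOG2_MEAN = 13.0
GFP_LOG2_SD = 0.5
REPORTER_CONST_LOG2 = 2.0  # the unidentifiable offset c of the PSI proxy
BFP_POS_LOG2_MEAN = 12.0
BFP_NEG_LOG2_MEAN = 5.0
BFP_LOG2_SD = 0.7
BFP_GATE = 2.0**8.5
VIABLE_FRAC = 0.95


@dataclass(frozen=True)
class SRE:
    """Ground-truth splicing-regulatory element.

    ``effect`` acts on logit-PSI per unit overlap: negative for a
    silencer (masking it activates inclusion), positive for an enhancer.
    """

    start: int
    end: int
    effect: float
    kind: str  # {"enhancer", "silencer"}

    def __post_init__(self):
        if self.kind not in ("enhancer", "silencer"):
            raise ValueError("SRE kind must be 'enhancer' or 'silencer'")
        if self.end <= self.start:
            raise ValueError("SRE interval must be non-empty")


@dataclass
class SimTruth:
    region_length: int = 835
    sres: tuple[SRE, ...] = ()
    baseline_psi: float = 0.4
    potency: dict[int, float] = field(default_factory=lambda: {22: 0.7, 25: 1.0})
    #: Effective footprint length, anchored at the spacer 5' end (the
    #: target 3' end of the protospacer); None = the full target interval.
    footprint_extent: int | None = 22

    def __post_init__(self):
        if not 0.0 < self.baseline_psi < 1.0:
            raise ValueError("baseline_psi must be in (0, 1)")
        for sre in self.sres:
            if not (0 <= sre.start < sre.end <= self.region_length):
                raise ValueError(f"SRE [{sre.start},{sre.end}) outside region")
        if any(v <= 0 for v in self.potency.values()):
            raise ValueError("potency multipliers must be positive")


@dataclass
class SimConfig:
    cells_per_guide: int = 1000
    moi_model: str = "single_integration"
    bfp_positive_frac: float = 0.4
    fluor_noise_sd: float = 0.5
    sort_fraction: float = 0.05
    reads_per_bin: int = 1_000_000
    nt_guides: int = 312
    seed: int = 0

    def __post_init__(self):
        if self.moi_model != "single_integration":
            raise ValueError("only the single_integration MOI model is supported")
        if not 0.0 < self.sort_fraction < 0.5:
            raise ValueError("sort_fraction must be in (0, 0.5)")
        if min(self.cells_per_guide, self.reads_per_bin) <= 0:
            raise ValueError("cells_per_guide and reads_per_bin must be positive")
        if not 0.0 < self.bfp_positive_frac <= 1.0:
            raise ValueError("bfp_positive_frac must be in (0, 1]")


# ---------------------------------------------------------------------------
# demo region: cassette exon 7 context mirrored qualitatively


def default_annotation(seed: int = 0, region_length: int = 835) -> ReporterAnnotation:
    """Random-sequence reporter with the canonical exon/intron layout.

    Feature sizes follow a cassette-exon minigene: short flanking exons,
    a 54-nt cassette exon, and a long downstream intron hosting both the
    proximal silencer and the distal enhancer of the demo truth.
    """
    if region_length != 835:
        raise ValueError("the default layout is defined for an 835-nt region")
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=region_length)])
    features = (
        ("exon6", 0, 60),
        ("intron6", 60, 260),
        ("exon7", 260, 314),
        ("intron7", 314, 775),
        ("exon8", 775, 835),
    )
    return ReporterAnnotation(sequence=seq, features=features)


def default_demo_truth(annotation: ReporterAnnotation | None = None) -> SimTruth:
    """One proximal intronic silencer and one distal intronic enhancer.

    The silencer occupies downstream-intron positions 10-34 (the
    ISS-N1-like element) and the enhancer positions 333-357 (the
    ISE-D1-like element), both 25 nt.
    """
    if annotation is None:
        i7s = 314
    else:
        i7s, _ = annotation.feature_interval("intron7")
    return SimTruth(
        sres=(
            SRE(start=i7s + 9, end=i7s + 34, effect=-3.0, kind="silencer"),
            SRE(start=i7s + 332, end=i7s + 357, effect=+3.0, kind="enhancer"),
        )
    )


def null_truth() -> SimTruth:
    return SimTruth(sres=())


def demo_library(seed: int = 0, n_controls: int = 312) -> GuideLibrary:
    return design_library(default_annotation(seed), lengths=(22, 25), step=1,
                          n_controls=n_controls, seed=seed)


# ---------------------------------------------------------------------------
# guide effects


def _effective_footprint(guide: GuideRNA, extent: int | None) -> tuple[int, int]:
    s, e = guide.target_start, guide.target_end
    if extent is None or extent >= e - s:
        return s, e
    return e - extent, e  # anchored at the spacer-5'-end-pairing target bases


def _overlap_frac(footprint: tuple[int, int], sre: SRE) -> float:
    lo = max(footprint[0], sre.start)
    hi = min(footprint[1], sre.end)
    return max(0, hi - lo) / (sre.end - sre.start)


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def guide_logit_shift(guide: GuideRNA, truth: SimTruth) -> float:
    """Shift applied to logit(baseline PSI) when this guide is expressed."""
    if guide.is_control:
        return 0.0
    fp = _effective_footprint(guide, truth.footprint_extent)
    pot = truth.potency.get(guide.length, 1.0)
    return -sum(sre.effect * _overlap_frac(fp, sre) * pot for sre in truth.sres)


def guide_effects(library: GuideLibrary, truth: SimTruth) -> pd.Series:
    """True PSI per guide; controls sit at the baseline."""
    base = logit(truth.baseline_psi)
    psi = {g.id: expit(base + guide_logit_shift(g, truth)) for g in library.guides}
    return pd.Series(psi, name="psi")


def guide_truth_table(library: GuideLibrary, truth: SimTruth) -> pd.DataFrame:
    """Per-guide ground truth: max SRE overlap, logit shift, true PSI."""
    base = logit(truth.baseline_psi)
    rows = []
    for g in library.guides:
        if g.is_control:
            rows.append({"guide_id": g.id, "overlap_frac": 0.0, "logit_shift": 0.0,
                         "psi": truth.baseline_psi, "is_control": True})
            continue
        fp = _effective_footprint(g, truth.footprint_extent)
        ovl = max((_overlap_frac(fp, sre) for sre in truth.sres), default=0.0)
        shift = guide_logit_shift(g, truth)
        rows.append({"guide_id": g.id, "overlap_frac": ovl, "logit_shift": shift,
                     "psi": expit(base + shift), "is_control": False})
    return pd.DataFrame(rows).set_index("guide_id")


# ---------------------------------------------------------------------------
# cells


def simulate_cells(
    psis: pd.Series,
    config: SimConfig,
    reporter: str,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Single-integration cell population with lognormal fluorescence.

    Returns an event table (one row per cell) with columns ``guide_id``,
    ``eGFP``, ``tdTomato``, ``BFP``, ``viable``.  tdTomato tracks psi
    (DUAL_IN) or 1 - psi (DUAL_EX) on top of the constitutive eGFP, with
    log2-scale Gaussian noise of sd ``fluor_noise_sd``.
    """
    if reporter not in ("DUAL_IN", "DUAL_EX"):
        raise ValueError("reporter must be DUAL_IN or DUAL_EX")
    p = psis.to_numpy(dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("all psi values must lie strictly in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_guides = len(psis)
    n_cells = n_guides * config.cells_per_guide
    guide_idx = np.repeat(np.arange(n_guides), config.cells_per_guide)

    tracked = p if reporter == "DUAL_IN" else 1.0 - p
    log2_gfp = rng.normal(GFP_LOG2_MEAN, GFP_LOG2_SD, size=n_cells)
    noise = (
        rng.normal(0.0, config.fluor_noise_sd, size=n_cells)
        if config.fluor_noise_sd > 0
        else np.zeros(n_cells)
    )
    m_true = REPORTER_CONST_LOG2 + np.log2(tracked)[guide_idx] + noise
    bfp_pos = rng.random(n_cells) < config.bfp_positive_frac
    log2_bfp = np.where(
        bfp_pos,
        rng.normal(BFP_POS_LOG2_MEAN, BFP_LOG2_SD, size=n_cells),
        rng.normal(BFP_NEG_LOG2_MEAN, BFP_LOG2_SD, size=n_cells),
    )
    viable = rng.random(n_cells) < VIABLE_FRAC

    cells = pd.DataFrame(
        {
            "guide_id": pd.Categorical.from_codes(guide_idx, categories=psis.index),
            "eGFP": np.exp2(log2_gfp),
            "tdTomato": np.exp2(log2_gfp + m_true),
            "BFP": np.exp2(log2_bfp),
            "viable": viable,
        }
    )
    cells.attrs["reporter"] = reporter
    return cells


# ---------------------------------------------------------------------------
# sorting + sequencing


def sort_and_sequence(
    cells: pd.DataFrame,
    config: SimConfig,
    replicate_id: str,
    reporter: str,
    rng: np.random.Generator | None = None,
    guide_ids: pd.Index | None = None,
) -> BinCountTable:
    """Top/bottom quantile sort of BFP-positive cells + multinomial reads.

    Bins are the strict upper/lower ``sort_fraction`` quantiles of
    M = log2(tdTomato/eGFP) among gated (viable, BFP-positive) cells,
    ties broken deterministically by event index; the unsorted sample is
    the whole gated population.  Reads per bin are multinomial over the
    bin's guide composition with ``reads_per_bin`` trials.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gated = cells.loc[cells["viable"] & (cells["BFP"] >= BFP_GATE)]
    if len(gated) == 0:
        raise ValueError("no gated (viable, BFP-positive) cells to sort")
    if guide_ids is None:
        guide_ids = cells["guide_id"].cat.categories
    n_guides = len(guide_ids)

    m = np.log2(gated["tdTomato"].to_numpy()) - np.log2(gated["eGFP"].to_numpy())
    k = int(math.floor(len(gated) * config.sort_fraction))
    if k < 1:
        raise ValueError("sort fraction yields an empty bin")
    order = np.argsort(m, kind="stable")  # stable: ties keep event order
    codes = gated["guide_id"].cat.codes.to_numpy()
    comp = {
        "unsorted": np.bincount(codes, minlength=n_guides),
        "top": np.bincount(codes[order[-k:]], minlength=n_guides),
        "bottom": np.bincount(codes[order[:k]], minlength=n_guides),
    }
    columns = {}
    for bin_name in ("unsorted", "top", "bottom"):
        c = comp[bin_name]
        reads = rng.multinomial(config.reads_per_bin, c / c.sum())
        columns[bin_name] = BinCounts(
            counts=dict(zip(guide_ids, (int(x) for x in reads))),
            total=config.reads_per_bin,
            unassigned=0,
        )
    return BinCountTable.from_columns(replicate_id, reporter, columns, guide_ids)


def write_bin_fastq(counts: dict[str, int], library: GuideLibrary, path) -> None:
    """FASTQ whose reads embed each guide's cassette exactly ``counts`` times."""
    five, three = library.adapters
    spacer = {g.id: g.spacer_seq for g in library.guides}
    i = 0
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for gid, n in counts.items():
            cassette = five + library.dr_seq + spacer[gid] + three
            qual = "I" * len(cassette)
            for _ in range(n):
                fh.write(f"@sim_{i} {gid}\n{cassette}\n+\n{qual}\n")
                i += 1


# ---------------------------------------------------------------------------
# whole screens


DEFAULT_REPLICATES = (("IN1", "DUAL_IN"), ("IN2", "DUAL_IN"), ("EX1", "DUAL_EX"), ("EX2", "DUAL_EX"))


def simulate_screen(
    library: GuideLibrary,
    truth: SimTruth,
    config: SimConfig,
    replicates: tuple[tuple[str, str], ...] = DEFAULT_REPLICATES,
) -> list[BinCountTable]:
    """Simulate count tables for a multi-replicate screen (default 2 IN + 2 EX)."""
    psis = guide_effects(library, truth)
    seeds = np.random.SeedSequence(config.seed).spawn(len(replicates))
    tables = []
    for (rep_id, reporter), ss in zip(replicates, seeds):
        rng = np.random.default_rng(ss)
        cells = simulate_cells(psis, config, reporter, rng=rng)
        tables.append(sort_and_sequence(cells, config, rep_id, reporter, rng=rng))
    return tables


# ---------------------------------------------------------------------------
# recovery evaluation


def evaluate_recovery(
    results: pd.DataFrame,
    library: GuideLibrary,
    truth: SimTruth,
    overlap_min: float = 0.8,
    fdr: float = 0.01,
) -> dict:
    """Hit-recovery metrics of an analyzed screen against its ground truth.

    - sensitivity: fraction of on-target guides with SRE overlap >=
      ``overlap_min`` called at ``fdr`` (NaN if no such guide);
    - false_positive_rate_controls: called fraction among controls;
    - sign_accuracy: among called true-positive guides, fraction whose Z
      sign matches the expected direction (silencer-blocking positive,
      enhancer-blocking negative).
    """
    tt = guide_truth_table(library, truth).loc[results.index]
    return evaluate_recovery_from_table(results, tt, overlap_min=overlap_min, fdr=fdr)


def evaluate_recovery_from_table(
    results: pd.DataFrame,
    truth_table: pd.DataFrame,
    overlap_min: float = 0.8,
    fdr: float = 0.01,
) -> dict:
    """Like :func:`evaluate_recovery` but from a saved per-guide truth table."""
    tt = truth_table.loc[results.index]
    called = (results["fdr"] <= fdr).fillna(False).to_numpy()
    z = results["Z"].to_numpy()

    tp_mask = (~tt["is_control"]) & (tt["overlap_frac"] >= overlap_min) & (tt["logit_shift"] != 0)
    tp_mask = tp_mask.to_numpy()
    ctrl_mask = tt["is_control"].to_numpy()

    out: dict = {
        "n_true": int(tp_mask.sum()),
        "n_controls": int(ctrl_mask.sum()),
        "false_positive_rate_controls": float(called[ctrl_mask].mean()) if ctrl_mask.any() else math.nan,
    }
    if not tp_mask.any():
        out["sensitivity"] = math.nan
        out["sign_accuracy"] = math.nan
        out["sensitivity_defined"] = False
        return out
    out["sensitivity_defined"] = True
    out["sensitivity"] = float(called[tp_mask].mean())
    called_tp = tp_mask & called
    if called_tp.any():
        expected = np.sign(tt["logit_shift"].to_numpy()[called_tp])
        out["sign_accuracy"] = float((np.sign(z[called_tp]) == expected).mean())
    else:
        out["sign_accuracy"] = math.nan
    return out
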