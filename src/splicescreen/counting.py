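"""Per-bin spacer counting and RPM normalization.

Reads from each FACS bin (unsorted / top / bottom) are assigned to
library guides by exact spacer match, then scaled to reads per million
(RPM).  Two matching modes are provided:

``anchored`` (default)
    The spacer is extracted between the 3' end of the direct repeat (DR)
    and the 3' backbone anchor, so the read must carry the expression
    cassette.  Tolerates untrimmed reads: the DR is located anywhere in
    the read.
``substring``
    Exact substring occurrence anywhere in the (pre-trimmed) read, with
    longest-match tie-breaking so a read carrying a 25-nt spacer is
    never credited to a nested 22-nt spacer.

Matching is exact (no mismatches) and on the sequenced strand only;
amplicon orientation is fixed by the PCR primers.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import GuideLibrary

BINS = ("unsorted", "top", "bottom")
BIN_SUFFIX = {"unsorted": "u", "top": "t", "bottom": "b"}

REPORTERS = ("DUAL_IN", "DUAL_EX")


@dataclass
class BinCountTable:
    """Per-guide read counts for the three bins of one screen replicate.

    ``counts`` is indexed by guide id with integer columns ``n_u``,
    ``n_t``, ``n_b``; ``totals``/``unassigned`` hold per-bin totals so
    that total = assigned + unassigned for each bin.
    """

    replicate_id: str
    reporter: str
    counts: pd.DataFrame
    totals: dict[str, int]
    unassigned: dict[str, int]

    def __post_init__(self):
        if self.reporter not in REPORTERS:
            raise ValueError(f"reporter must be one of {REPORTERS}")
        missing = {f"n_{s}" for s in BIN_SUFFIX.values()} - set(self.counts.columns)
        if missing:
            raise ValueError(f"counts table missing columns: {sorted(missing)}")
        if (self.counts[["n_u", "n_t", "n_b"]] < 0).any().any():
            raise ValueError("negative counts")
        for b in BINS:
            s = BIN_SUFFIX[b]
            assigned = int(self.counts[f"n_{s}"].sum())
            if self.totals[b] != assigned + self.unassigned[b]:
                raise ValueError(
                    f"bin {b}: total {self.totals[b]} != assigned {assigned} "
                    f"+ unassigned {self.unassigned[b]}"
                )

    @classmethod
    def from_columns(
        cls,
        replicate_id: str,
        reporter: str,
        columns: dict[str, "BinCounts"],
        guide_ids: Iterable[str],
    ) -> "BinCountTable":
        ids = list(guide_ids)
        data = {}
        totals, unassigned = {}, {}
        for b in BINS:
            col = columns[b]
            data[f"n_{BIN_SUFFIX[b]}"] = [col.counts.get(g, 0) for g in ids]
            totals[b] = col.total
            unassigned[b] = col.unassigned
        df = pd.DataFrame(data, index=pd.Index(ids, name="guide_id"), dtype=np.int64)
        return cls(replicate_id, reporter, df, totals, unassigned)


@dataclass
class BinCounts:
    """Counting result for a single bin (one FASTQ)."""

    counts: dict[str, int]
    total: int
    unassigned: int


@dataclass
class RPMTable:
    """Reads-per-million per guide and bin; sums to 1e6 × assigned fraction."""

    rpm: pd.DataFrame  # columns rpm_u, rpm_t, rpm_b


def _open_maybe_gzip(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(handle) -> Iterator[tuple[str, str]]:
    """Yield (title, sequence), reporting the record index on parse failure."""
    it = FastqGeneralIterator(handle)
    idx = 0
    while True:
        try:
            title, seq, _qual = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {idx}: {exc}") from exc
        yield title, seq.upper()
        idx += 1


def count_spacers(
    reads: str | Path | Iterable[str],
    library: GuideLibrary,
    mode: str = "anchored",
) -> BinCounts:
    """Count reads perfectly matching each library spacer.

    ``reads`` may be a FASTQ path (gzip-transparent) or an iterable of
    read sequences.  Each read is assigned to at most one guide;
    unmatched reads are tallied as unassigned.
    """
    if len(library) == 0:
        raise ValueError("empty guide library")
    if mode not in ("anchored", "substring"):
        raise ValueError(f"unknown mode {mode!r}")

    spacer_to_id: dict[str, str] = {}
    for g in library.guides:
        if g.spacer_seq in spacer_to_id:
            raise ValueError(f"duplicate spacer in library: {g.spacer_seq}")
        spacer_to_id[g.spacer_seq] = g.id
    lengths = sorted({g.length for g in library.guides}, reverse=True)
    dr = library.dr_seq
    anchor = library.adapters[1]

    counts = {g.id: 0 for g in library.guides}
    total = 0
    unassigned = 0

    if isinstance(reads, (str, Path)):
        with _open_maybe_gzip(reads) as fh:
            seqs = [s for _, s in _iter_fastq(fh)]
    else:
        seqs = [s.upper() for s in reads]

    for seq in seqs:
        total += 1
        gid = (
            _match_anchored(seq, spacer_to_id, lengths, dr, anchor)
            if mode == "anchored"
            else _match_substring(seq, spacer_to_id, lengths)
        )
        if gid is None:
            unassigned += 1
        else:
            counts[gid] += 1
    return BinCounts(counts=counts, total=total, unassigned=unassigned)


def _match_anchored(seq, spacer_to_id, lengths, dr, anchor):
    i = seq.find(dr)
    if i < 0:
        return None
    start = i + len(dr)
    rest = seq[start:]
    for L in lengths:  # longest first: a 25-nt cassette never credits a nested 22-mer
        cand = rest[:L]
        if len(cand) < L or cand not in spacer_to_id:
            continue
        tail = rest[L:]
        k = min(len(tail), len(anchor))
        if k == 0 or tail[:k] == anchor[:k]:
            return spacer_to_id[cand]
    return None


def _match_substring(seq, spacer_to_id, lengths):
    for L in lengths:
        hits = set()
        for i in range(len(seq) - L + 1):
            gid = spacer_to_id.get(seq[i : i + L])
            if gid is not None:
                hits.add(gid)
                if len(hits) > 1:
                    return None  # ambiguous among equal-length spacers
        if hits:
            return hits.pop()
    return None


def count_replicate(
    fastq_unsorted: str | Path,
    fastq_top: str | Path,
    fastq_bottom: str | Path,
    library: GuideLibrary,
    replicate_id: str,
    reporter: str,
    mode: str = "anchored",
) -> BinCountTable:
    cols = {
        "unsorted": count_spacers(fastq_unsorted, library, mode),
        "top": count_spacers(fastq_top, library, mode),
        "bottom": count_spacers(fastq_bottom, library, mode),
    }
    return BinCountTable.from_columns(replicate_id, reporter, cols, (g.id for g in library.guides))


# ---------------------------------------------------------------------------
# RPM and mini-library enrichment


def rpm_normalize(table: BinCountTable) -> RPMTable:
    """RPM per guide and bin: n / N × 1e6 over the bin's total reads."""
    data = {}
    for b in BINS:
        s = BIN_SUFFIX[b]
        N = table.totals[b]
        if N == 0:
            raise ValueError(f"bin {b!r} has zero total reads; cannot normalize")
        data[f"rpm_{s}"] = table.counts[f"n_{s}"] / N * 1e6
    return RPMTable(rpm=pd.DataFrame(data, index=table.counts.index))


def mini_library_enrichment(rpm: RPMTable, pseudo: float = 0.0) -> pd.DataFrame:
    """Small-pool enrichment ratios: bin RPM over unsorted RPM, log2 scale.

    Returns columns ``log2_top``, ``log2_bottom`` and their difference
    ``top_vs_bottom``.  With ``pseudo == 0`` a zero RPM yields an
    undefined (NaN) value, flagged in the ``undefined`` column rather
    than dropped.
    """
    if pseudo < 0:
        raise ValueError("pseudo must be >= 0")
    df = rpm.rpm
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_top = np.log2((df["rpm_t"] + pseudo) / (df["rpm_u"] + pseudo))
        log2_bottom = np.log2((df["rpm_b"] + pseudo) / (df["rpm_u"] + pseudo))
    out = pd.DataFrame(
        {
            "log2_top": log2_top,
            "log2_bottom": log2_bottom,
            "top_vs_bottom": log2_top - log2_bottom,
        },
        index=df.index,
    )
    out["undefined"] = ~np.isfinite(out[["log2_top", "log2_bottom"]]).all(axis=1)
    return out


# ---------------------------------------------------------------------------
# I/O


def write_counts(table: BinCountTable, tsv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    long = (
        table.counts.rename(columns={f"n_{BIN_SUFFIX[b]}": b for b in BINS})
        .reset_index()
        .melt(id_vars="guide_id", var_name="bin", value_name="count")
        .sort_values(["bin", "guide_id"], kind="stable")
    )
    long.to_csv(tsv_path, sep="\t", index=False)
    if sidecar_path is None:
        sidecar_path = str(tsv_path) + ".json"
    meta = {
        "replicate_id": table.replicate_id,
        "reporter": table.reporter,
        "totals": table.totals,
        "unassigned": table.unassigned,
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_counts(tsv_path: str | Path, sidecar_path: str | Path | None = None) -> BinCountTable:
    if sidecar_path is None:
        sidecar_path = str(tsv_path) + ".json"
    meta = json.loads(Path(sidecar_path).read_text())
    long = pd.read_csv(tsv_path, sep="\t")
    wide = long.pivot(index="guide_id", columns="bin", values="count")
    df = pd.DataFrame(
        {f"n_{BIN_SUFFIX[b]}": wide[b].astype(np.int64) for b in BINS},
        index=wide.index,
    )
    return BinCountTable(
        replicate_id=meta["replicate_id"],
        reporter=meta["reporter"],
        counts=df,
        totals={b: int(v) for b, v in meta["totals"].items()},
        unassigned={b: int(v) for b, v in meta["unassigned"].items()},
    )
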