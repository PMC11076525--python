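"""Screen manifest validation and the end-to-end pipeline driver.

A manifest (YAML or dict) names the guide library and, per replicate,
either a pre-computed counts table or the three bin FASTQs, plus
analysis options.  ``run_pipeline`` executes counting (where needed),
per-replicate statistics, cross-replicate combination, hit calling and
shift analysis, writing all tables plus a run-metadata JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import counting, shifts, stats
from .counting import BinCountTable, read_counts, count_replicate
from .library import GuideLibrary, read_library_tsv

logger = logging.getLogger(__name__)

MISSING = "."
FLOAT_FMT = "%.6g"


class ManifestError(ValueError):
    """Schema violation in a screen manifest; message carries the field path."""


@dataclass
class ReplicateSpec:
    replicate_id: str
    reporter: str
    counts: str | None = None
    fastq: dict[str, str] | None = None


@dataclass
class ScreenManifest:
    library: str
    replicates: list[ReplicateSpec]
    mode: str = "per_guide"
    fdr: float = 0.01
    count_mode: str = "anchored"

    @classmethod
    def from_dict(cls, d: dict, base: Path | None = None) -> "ScreenManifest":
        def fail(path, msg):
            raise ManifestError(f"{path}: {msg}")

        if not isinstance(d, dict):
            fail("$", "manifest must be a mapping")
        if "library" not in d:
            fail("$.library", "required")
        reps_raw = d.get("replicates")
        if not isinstance(reps_raw, list) or not reps_raw:
            fail("$.replicates", "at least one replicate required")
        reps = []
        for i, r in enumerate(reps_raw):
            where = f"$.replicates[{i}]"
            if not isinstance(r, dict):
                fail(where, "must be a mapping")
            for key in ("replicate_id", "reporter"):
                if key not in r:
                    fail(f"{where}.{key}", "required")
            if r["reporter"] not in counting.REPORTERS:
                fail(f"{where}.reporter", f"must be one of {counting.REPORTERS}")
            has_counts = "counts" in r
            has_fastq = "fastq" in r
            if has_counts == has_fastq:
                fail(where, "exactly one of 'counts' or 'fastq' required")
            if has_fastq:
                fq = r["fastq"]
                if not isinstance(fq, dict) or set(fq) != {"unsorted", "top", "bottom"}:
                    fail(f"{where}.fastq", "needs keys unsorted/top/bottom")
            reps.append(
                ReplicateSpec(
                    replicate_id=str(r["replicate_id"]),
                    reporter=r["reporter"],
                    counts=_resolve(r.get("counts"), base),
                    fastq={k: _resolve(v, base) for k, v in r["fastq"].items()} if has_fastq else None,
                )
            )
        ids = [r.replicate_id for r in reps]
        if len(ids) != len(set(ids)):
            fail("$.replicates", "replicate_id values must be unique")
        fdr = float(d.get("fdr", 0.01))
        if not 0 < fdr < 1:
            fail("$.fdr", "must be in (0, 1)")
        mode = d.get("mode", "per_guide")
        if mode not in ("per_guide", "as_printed"):
            fail("$.mode", "must be per_guide or as_printed")
        return cls(
            library=_resolve(d["library"], base),
            replicates=reps,
            mode=mode,
            fdr=fdr,
            count_mode=d.get("count_mode", "anchored"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenManifest":
        path = Path(path)
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), base=path.parent)


def _resolve(p, base: Path | None):
    if p is None:
        return None
    p = Path(p)
    if base is not None and not p.is_absolute():
        p = base / p
    return str(p)


# ---------------------------------------------------------------------------
# TSV conventions: '.' for missing, 6 significant digits on disk


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=MISSING, float_format=FLOAT_FMT)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="guide_id", na_values=[MISSING])


# ---------------------------------------------------------------------------


def _package_version() -> str:
    try:
        return version("splicescreen")
    except PackageNotFoundError:
        return "unknown"


def load_replicate_counts(spec: ReplicateSpec, library: GuideLibrary, count_mode: str) -> BinCountTable:
    if spec.counts is not None:
        table = read_counts(spec.counts)
        return BinCountTable(
            replicate_id=spec.replicate_id,
            reporter=spec.reporter,
            counts=table.counts,
            totals=table.totals,
            unassigned=table.unassigned,
        )
    return count_replicate(
        spec.fastq["unsorted"], spec.fastq["top"], spec.fastq["bottom"],
        library, spec.replicate_id, spec.reporter, mode=count_mode,
    )


def run_pipeline(manifest: ScreenManifest, out_dir: str | Path) -> pd.DataFrame:
    """Counts -> per-replicate stats -> combined hits -> shift analysis.

    Writes ``replicate_<id>.stats.tsv``, ``results.tsv``,
    ``shift_pairs.tsv``, ``shift_summary.tsv`` and ``run_metadata.json``
    under ``out_dir``; partial outputs are removed on failure.  Returns
    the combined results table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        library = read_library_tsv(manifest.library)
        tables = [
            load_replicate_counts(spec, library, manifest.count_mode)
            for spec in manifest.replicates
        ]
        per_rep = [stats.replicate_stats(t, mode=manifest.mode) for t in tables]
        for df in per_rep:
            p = out_dir / f"replicate_{df.attrs['replicate_id']}.stats.tsv"
            write_tsv(df, p)
            written.append(p)
        combined = stats.call_hits(stats.combine_replicates(per_rep), manifest.fdr)
        for df in per_rep:
            combined[f"z_rep_{df.attrs['replicate_id']}"] = df["z_rep"]

        meta_cols = _guide_columns(library).reindex(combined.index)
        results = pd.concat([meta_cols, combined], axis=1)
        results.index.name = "guide_id"
        p = out_dir / "results.tsv"
        write_tsv(results, p)
        written.append(p)

        if {22, 25} <= set(library.spacer_lengths()):
            pairs, summary = shifts.analyze_shifts(library, combined)
            p1, p2 = out_dir / "shift_pairs.tsv", out_dir / "shift_summary.tsv"
            write_tsv(pairs, p1, index=False)
            write_tsv(summary, p2, index=False)
            written += [p1, p2]

        meta = {
            "package_version": _package_version(),
            "mode": manifest.mode,
            "fdr_threshold": manifest.fdr,
            "count_mode": manifest.count_mode,
            "quantifiability": {"min_reads": stats.MIN_READS, "min_rpm": stats.MIN_RPM,
                                "min_bins": stats.MIN_QUANTIFIABLE_BINS},
            "znorm": {
                df.attrs["replicate_id"]: {
                    b: {"m": s.m, "sigma": s.sigma, "n_used": s.n_used}
                    for b, s in df.attrs["znorm"].items()
                }
                for df in per_rep
            },
            "replicates": [
                {"replicate_id": s.replicate_id, "reporter": s.reporter}
                for s in manifest.replicates
            ],
            "median_mad_pool": "all guides with defined enrichment scores, controls included",
        }
        p = out_dir / "run_metadata.json"
        p.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
        written.append(p)
        return results
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _guide_columns(library: GuideLibrary) -> pd.DataFrame:
    rows = {
        g.id: {
            "name": g.name,
            "length": g.length,
            "position": np.nan if g.target_start is None else g.target_start,
            "control_kind": g.control_kind,
        }
        for g in library.guides
    }
    return pd.DataFrame.from_dict(rows, orient="index")
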