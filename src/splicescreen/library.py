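"""Tiling gRNA library design for dCas13d splicing screens.

A library tiles every position of a splicing-reporter pre-mRNA region
(upstream exon through downstream exon) with spacers of one or more
lengths at a fixed step, plus non-targeting (NT) controls.  Spacers are
antisense to the target RNA: the spacer is the reverse complement of the
target window on the sense strand.

Coordinates are 0-based half-open internally; display names follow the
splice-site convention used in the field (1-based, no position zero,
negative positions counting back across a splice junction).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_ALPHABET = set("ACGTN")

#: RfxCas13d direct repeat placed 5' of the spacer in the expression cassette.
DEFAULT_DR = "AACCCCTACCAACTGGTCGGGGTTTGAAAC"
#: Flanking cassette sequence used for oligo assembly and read anchoring.
DEFAULT_ADAPTERS = ("GGAAAGGACGAAACACCG", "TTTTTTAAGCTTGGCGTAACTAGATCT")

CONTROL_KINDS = ("none", "non_targeting", "sense")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class ReporterAnnotation:
    """Reporter sequence plus an ordered exon/intron feature table.

    ``features`` is a list of ``(label, start, end)`` with 0-based
    half-open coordinates that tile the sequence without gaps or
    overlaps.  The canonical labels for a cassette-exon reporter are
    ``exon6, intron6, exon7, intron7, exon8`` but free-form labels are
    accepted.
    """

    sequence: str
    features: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "features", tuple((l, int(s), int(e)) for l, s, e in self.features))
        bad = set(seq) - _VALID_ALPHABET
        if bad:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
        pos = 0
        for label, start, end in self.features:
            if start != pos or end <= start:
                raise ValueError(
                    f"features must tile the sequence without gaps/overlaps; "
                    f"feature {label!r} spans [{start},{end}) but expected start {pos}"
                )
            pos = end
        if self.features and pos != len(seq):
            raise ValueError(f"features end at {pos} but sequence has length {len(seq)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_interval(self, label: str) -> tuple[int, int]:
        for l, s, e in self.features:
            if l == label:
                return s, e
        raise KeyError(f"no feature labelled {label!r}")

    def has_feature(self, label: str) -> bool:
        return any(l == label for l, _, _ in self.features)


@dataclass(frozen=True)
class GuideRNA:
    """One spacer: either on-target (with a footprint on the reporter) or a control."""

    id: str
    spacer_seq: str
    length: int
    target_start: int | None = None
    target_end: int | None = None
    name: str = ""
    is_control: bool = False
    control_kind: str = "none"
    has_ambiguous_base: bool = False

    def __post_init__(self):
        if self.control_kind not in CONTROL_KINDS:
            raise ValueError(f"control_kind must be one of {CONTROL_KINDS}")
        if self.is_control:
            if self.target_start is not None or self.target_end is not None:
                raise ValueError("control guides carry no target interval")
        else:
            if self.target_start is None or self.target_end is None:
                raise ValueError("on-target guides need a target interval")
            if self.target_end - self.target_start != self.length:
                raise ValueError("target interval width must equal spacer length")

    @property
    def anchor_position(self) -> int | None:
        """5'-most target coordinate (pairs the spacer's 3' end); plotting anchor."""
        return self.target_start


@dataclass
class GuideLibrary:
    guides: list[GuideRNA]
    annotation: ReporterAnnotation
    dr_seq: str = DEFAULT_DR
    adapters: tuple[str, str] = DEFAULT_ADAPTERS

    def __post_init__(self):
        ids = [g.id for g in self.guides]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"guide ids must be unique; duplicated: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.guides)

    def on_target(self) -> list[GuideRNA]:
        return [g for g in self.guides if not g.is_control]

    def controls(self) -> list[GuideRNA]:
        return [g for g in self.guides if g.is_control]

    def by_id(self) -> dict[str, GuideRNA]:
        return {g.id: g for g in self.guides}

    def spacer_lengths(self) -> list[int]:
        return sorted({g.length for g in self.guides})


# ---------------------------------------------------------------------------
# tiling


def tile_guides(
    annotation: ReporterAnnotation,
    lengths: Sequence[int] = (22, 25),
    step: int = 1,
) -> list[GuideRNA]:
    """Tile the reporter with spacers of each requested length.

    For a region of length ``n`` and spacer length ``L`` this emits
    ``floor((n - L)/step) + 1`` guides, one per window, ordered by
    (length, target_start).  Each spacer is the reverse complement of
    its target window.  Windows containing N are emitted but flagged.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    seq = annotation.sequence
    guides: list[GuideRNA] = []
    for length in sorted(lengths):
        if length < 1:
            raise ValueError("spacer length must be positive")
        if length > len(seq):
            logger.warning("spacer length %d exceeds region length %d; skipping", length, len(seq))
            continue
        for start in range(0, len(seq) - length + 1, step):
            end = start + length
            window = seq[start:end]
            name = name_interval(start, end, annotation)
            guides.append(
                GuideRNA(
                    id=f"{name}_{length}",
                    spacer_seq=reverse_complement(window),
                    length=length,
                    target_start=start,
                    target_end=end,
                    name=name,
                    has_ambiguous_base="N" in window,
                )
            )
    return _dedupe_ids(guides)


def _dedupe_ids(guides: list[GuideRNA]) -> list[GuideRNA]:
    seen: dict[str, int] = {}
    out = []
    for g in guides:
        if g.id in seen:
            seen[g.id] += 1
            out.append(replace(g, id=f"{g.id}.{seen[g.id]}"))
        else:
            seen[g.id] = 0
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# naming


def name_interval(start: int, end: int, annotation: ReporterAnnotation) -> str:
    """Name a target interval by the splice-junction convention.

    - fully inside the cassette exon (exon7): ``E[a,b]``, 1-based from the
      exon start;
    - inside the downstream intron (intron7) or spanning the 5' splice
      site: ``D[a,b]`` with intron position 1 = first intronic base and
      exonic positions negative, counted back from the exon's last base
      (no zero);
    - inside the upstream intron (intron6) or spanning the 3' splice
      site: ``A[a,b]`` with exon position 1 = first exonic base and
      intronic positions negative, counted back from the intron's last
      base (no zero);
    - anything else: ``abs[a,b]``, 1-based inclusive on the reporter.
    """
    need = ("intron6", "exon7", "intron7")
    if all(annotation.has_feature(f) for f in need):
        e7s, e7e = annotation.feature_interval("exon7")
        i6s, _ = annotation.feature_interval("intron6")
        _, i7e = annotation.feature_interval("intron7")
        lo, hi = start, end - 1  # inclusive coords of the footprint
        if e7s <= lo and hi < e7e:
            return f"E[{lo - e7s + 1},{hi - e7s + 1}]"
        # D: within intron7, or spanning the exon7/intron7 junction
        if lo >= e7s and hi < i7e and hi >= e7e:
            a = _donor_pos(lo, e7e)
            b = _donor_pos(hi, e7e)
            return f"D[{a},{b}]"
        # A: within intron6, or spanning the intron6/exon7 junction
        if lo >= i6s and hi < e7e and lo < e7s:
            a = _acceptor_pos(lo, e7s)
            b = _acceptor_pos(hi, e7s)
            return f"A[{a},{b}]"
    return f"abs[{start + 1},{end}]"


def _donor_pos(p: int, intron_start: int) -> int:
    """Position relative to the 5' splice site: intron base 1, exon base -1."""
    return p - intron_start + 1 if p >= intron_start else p - intron_start


def _acceptor_pos(p: int, exon_start: int) -> int:
    """Position relative to the 3' splice site: exon base 1, intron base -1."""
    return p - exon_start + 1 if p >= exon_start else p - exon_start


def name_guide(guide: GuideRNA, annotation: ReporterAnnotation) -> str:
    if guide.is_control:
        raise ValueError("control guides have no coordinates to name")
    return name_interval(guide.target_start, guide.target_end, annotation)


_NAME_RE = re.compile(r"^(E|D|A|abs)\[(-?\d+),(-?\d+)\]$")


def parse_guide_name(name: str, annotation: ReporterAnnotation) -> tuple[int, int]:
    """Invert :func:`name_interval`: recover the 0-based half-open interval."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"unparseable guide name: {name!r}")
    kind, a, b = m.group(1), int(m.group(2)), int(m.group(3))
    if kind == "abs":
        return a - 1, b
    e7s, e7e = annotation.feature_interval("exon7")
    if kind == "E":
        return e7s + a - 1, e7s + b
    if kind == "D":
        lo = e7e + a - 1 if a > 0 else e7e + a
        hi = e7e + b - 1 if b > 0 else e7e + b
        return lo, hi + 1
    lo = e7s + a - 1 if a > 0 else e7s + a
    hi = e7s + b - 1 if b > 0 else e7s + b
    return lo, hi + 1


# ---------------------------------------------------------------------------
# controls


def generate_controls(
    n: int,
    length: int,
    forbidden: Sequence[str],
    seed: int,
    kind: str = "non_targeting",
    max_retries: int = 10_000,
) -> list[GuideRNA]:
    """Draw ``n`` random spacers absent (fwd and revcomp) from every forbidden sequence.

    Uniform ACGT rejection sampling; reproducible under ``seed``.  An
    external screen (e.g. a genome-wide alignment check) can be folded in
    by passing extra sequences in ``forbidden``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    if not forbidden:
        raise ValueError("forbidden sequences required when generating controls")
    haystacks = [s.upper() for s in forbidden]
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out: list[GuideRNA] = []
    spacers: set[str] = set()
    for i in range(n):
        for attempt in range(max_retries):
            spacer = "".join(bases[rng.integers(0, 4, size=length)])
            rc = reverse_complement(spacer)
            if spacer in spacers:
                continue
            if any(spacer in h or rc in h for h in haystacks):
                continue
            break
        else:
            raise RuntimeError(
                f"control generation exceeded {max_retries} retries for control {i}"
            )
        spacers.add(spacer)
        label = "NT" if kind == "non_targeting" else "SC"
        out.append(
            GuideRNA(
                id=f"{label}{i + 1:03d}_{length}",
                spacer_seq=spacer,
                length=length,
                name=f"{label}{i + 1:03d}",
                is_control=True,
                control_kind=kind,
            )
        )
    return out


def design_library(
    annotation: ReporterAnnotation,
    lengths: Sequence[int] = (22, 25),
    step: int = 1,
    n_controls: int = 312,
    control_length: int = 25,
    seed: int = 0,
    dr_seq: str = DEFAULT_DR,
    adapters: tuple[str, str] = DEFAULT_ADAPTERS,
) -> GuideLibrary:
    """Full library: tiled on-target guides plus NT controls."""
    guides = tile_guides(annotation, lengths, step)
    forbidden = [annotation.sequence] if annotation.sequence else []
    guides += generate_controls(n_controls, control_length, forbidden, seed)
    return GuideLibrary(guides=guides, annotation=annotation, dr_seq=dr_seq, adapters=adapters)


# ---------------------------------------------------------------------------
# oligo assembly


def assemble_oligos(library: GuideLibrary) -> list[tuple[str, str]]:
    """Cassette oligo per guide: 5' adapter + DR + spacer + 3' adapter."""
    if not library.dr_seq:
        raise ValueError("dr_seq must be set to assemble oligos")
    five, three = library.adapters
    return [(g.id, five + library.dr_seq + g.spacer_seq + three) for g in library.guides]


def extract_spacer(oligo: str, dr_seq: str, three_prime: str) -> str:
    """Recover the spacer between the DR and the 3' adapter (assembly round-trip)."""
    i = oligo.index(dr_seq) + len(dr_seq)
    j = oligo.rindex(three_prime)
    return oligo[i:j]


# ---------------------------------------------------------------------------
# I/O

LIBRARY_COLUMNS = ["id", "name", "length", "target_start", "target_end", "spacer", "control_kind"]


def read_annotation(fasta_path: str | Path, features_path: str | Path) -> ReporterAnnotation:
    """Reporter FASTA (first record) + BED-like feature table (label, start, end)."""
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    feats = []
    with open(features_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, start, end = line.split("\t")[:3]
            feats.append((label, int(start), int(end)))
    return ReporterAnnotation(sequence=str(record.seq), features=tuple(feats))


def write_library_tsv(library: GuideLibrary, path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "id": g.id,
            "name": g.name,
            "length": g.length,
            "target_start": "." if g.target_start is None else g.target_start,
            "target_end": "." if g.target_end is None else g.target_end,
            "spacer": g.spacer_seq,
            "control_kind": g.control_kind,
        }
        for g in library.guides
    ]
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_library_tsv(
    path: str | Path,
    annotation: ReporterAnnotation | None = None,
    dr_seq: str = DEFAULT_DR,
    adapters: tuple[str, str] = DEFAULT_ADAPTERS,
) -> GuideLibrary:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    guides = []
    for row in df.itertuples(index=False):
        is_control = row.control_kind != "none"
        guides.append(
            GuideRNA(
                id=row.id,
                spacer_seq=row.spacer,
                length=int(row.length),
                target_start=None if row.target_start == "." else int(row.target_start),
                target_end=None if row.target_end == "." else int(row.target_end),
                name=row.name,
                is_control=is_control,
                control_kind=row.control_kind,
            )
        )
    if annotation is None:
        annotation = ReporterAnnotation(sequence="", features=())
    return GuideLibrary(guides=guides, annotation=annotation, dr_seq=dr_seq, adapters=adapters)


def write_oligos_fasta(library: GuideLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, oligo in assemble_oligos(library):
            fh.write(f">{gid}\n{oligo}\n")
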