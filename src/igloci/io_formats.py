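"""Reading/writing the formats the pipeline touches, plus run configuration.

Coordinate conventions are enforced here and only here: everything serialized
as GFF3 is 1-based inclusive, everything serialized as BED is 0-based
half-open.  Internal pipeline arithmetic is 0-based half-open; ``Feature``
stores GFF3-style coordinates and exposes ``start0``/``end0`` views.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import quote, unquote

import yaml

from ._seq import AA_ALPHABET, DNA_ALPHABET


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass
class SequenceRecord:
    id: str
    seq: str
    alphabet: str = "dna"  # "dna" | "aa"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty sequence id")
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        self.seq = self.seq.upper()
        allowed = DNA_ALPHABET if self.alphabet == "dna" else AA_ALPHABET
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(
                f"{self.id}: illegal {self.alphabet} character(s) {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Feature:
    """A located annotation; ``start``/``end`` are 1-based inclusive (GFF3)."""

    seq_id: str
    start: int
    end: int
    strand: str
    type: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.start}..{self.end} on {self.seq_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @classmethod
    def from_zero_based(cls, seq_id: str, start0: int, end0: int, strand: str,
                        type: str, attributes: dict[str, str] | None = None
                        ) -> "Feature":
        return cls(seq_id, start0 + 1, end0, strand, type,
                   dict(attributes or {}))

    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:
        return self.end

    def __len__(self) -> int:
        return self.end0 - self.start0

    def shifted(self, offset0: int) -> "Feature":
        return Feature(self.seq_id, self.start + offset0, self.end + offset0,
                       self.strand, self.type, dict(self.attributes))


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Parse FASTA; case-normalized to upper; order preserved.

    Raises :class:`ParseError` naming the line for malformed headers or
    characters outside the declared IUPAC alphabet.
    """
    allowed = DNA_ALPHABET if alphabet == "dna" else AA_ALPHABET
    records: list[SequenceRecord] = []
    current_id: str | None = None
    chunks: list[str] = []

    def flush(lineno: int) -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"line {lineno}: record {current_id!r} has no sequence")
        records.append(SequenceRecord(current_id, seq, alphabet))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                current_id = line[1:].split()[0] if line[1:].strip() else ""
                if not current_id:
                    raise ParseError(f"line {lineno}: empty FASTA header")
                chunks = []
            else:
                if current_id is None:
                    raise ParseError(
                        f"line {lineno}: sequence data before any '>' header")
                up = line.upper()
                bad = set(up) - allowed
                if bad:
                    raise ParseError(
                        f"line {lineno}: illegal {alphabet} character(s) "
                        f"{sorted(bad)}")
                chunks.append(up)
        flush(lineno + 1 if records or current_id else 0)
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


_GFF_SAFE = " :^*$@!+_|,.-"  # characters left unescaped in attribute values


def write_gff3(features: list[Feature], path: str | Path,
               source: str = "igloci") -> None:
    """Serialize features as GFF3 (1-based inclusive, attributes URL-escaped)."""
    lines = ["##gff-version 3"]
    for f in features:
        if not isinstance(f, Feature):
            raise TypeError("write_gff3 expects Feature objects")
        attrs = ";".join(f"{quote(str(k), safe='')}={quote(str(v), safe=_GFF_SAFE)}"
                         for k, v in f.attributes.items()) or "."
        lines.append("\t".join([f.seq_id, source, f.type, str(f.start),
                                str(f.end), ".", f.strand, ".", attrs]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[Feature]:
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"line {lineno}: expected 9 GFF3 columns, "
                                 f"got {len(cols)}")
            seq_id, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            attributes: dict[str, str] = {}
            if attrs != ".":
                for pair in attrs.split(";"):
                    if not pair:
                        continue
                    if "=" not in pair:
                        raise ParseError(f"line {lineno}: malformed attribute "
                                         f"{pair!r}")
                    k, v = pair.split("=", 1)
                    attributes[unquote(k)] = unquote(v)
            try:
                features.append(Feature(seq_id, start_i, end_i, strand, ftype,
                                        attributes))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return features


def read_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED-style 0-based half-open intervals (first three columns)."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"line {lineno}: expected >=3 BED columns")
            try:
                start0, end0 = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            if not 0 <= start0 < end0:
                raise ParseError(f"line {lineno}: degenerate interval "
                                 f"{start0}..{end0}")
            out.append((cols[0], start0, end0))
    return out


def write_intervals(intervals: list[tuple[str, int, int]],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, s0, e0 in intervals:
            if not 0 <= s0 < e0:
                raise ValueError(f"degenerate interval {s0}..{e0}")
            fh.write(f"{seq_id}\t{s0}\t{e0}\n")


@dataclass
class RunConfig:
    """All tunable thresholds of a pipeline run.

    Score units follow the mapper's scheme (match +2, mismatch -3, gap
    open -5, gap extend -2 per base).  A perfect 50-bp alignment scores 100,
    the default significance threshold for V and C segments; J and D segments
    are shorter than 50 bp and use their own thresholds.
    """

    score_threshold: int = 100
    j_score_threshold: int = 50
    d_score_threshold: int = 26
    seed_k: int = 11
    band: int = 32
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_intron: int = 30
    max_intron: int = 10000
    max_query_gap: int = 5
    long_intron: int = 150
    heptamer_max_mm: int = 2
    nonamer_max_mm: int = 3
    spacer_tolerance: int = 1
    rss_window: int = 42
    window_size: int = 2500
    ac_identity_threshold: float = 0.95
    expression_read_threshold: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("score_threshold", "j_score_threshold", "d_score_threshold",
                     "heptamer_max_mm", "nonamer_max_mm", "spacer_tolerance",
                     "expression_read_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.seed_k < 1 or self.band < 1 or self.rss_window < 1:
            raise ValueError("seed_k, band and rss_window must be >= 1")
        if not 0.0 <= self.ac_identity_threshold <= 1.0:
            raise ValueError("ac_identity_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))
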