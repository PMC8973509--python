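"""Readers and writers for the genomic text formats the tool touches, plus the
session ledger and per-session logging.

All coordinates inside the package are 0-based half-open (BED-native). WIG is
1-based on disk, so the reader converts on entry and the writer converts on
exit; bedGraph is already 0-based half-open.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .config import RunConfig, load_run_config, save_run_config  # noqa: F401 (re-export)

VALID_BASES = set("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

logger = logging.getLogger("branchnet")


@dataclass
class GenomicInterval:
    """A strand-aware genomic locus with a class label (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "+"
    label: str = ""

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval coordinates {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceGenome:
    """Uppercase chromosome sequences over {A,C,G,T,N}."""

    sequences: dict[str, str]

    def __post_init__(self):
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name}")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


@dataclass
class ConservationTrack:
    """Sparse per-base conservation scores; uncovered positions score 0.0."""

    values: dict[str, dict[int, float]] = field(default_factory=dict)

    def get(self, chrom: str, pos: int) -> float:
        return self.values.get(chrom, {}).get(pos, 0.0)

    def set(self, chrom: str, pos: int, score: float) -> None:
        if pos < 0:
            raise ValueError(f"negative position {pos}")
        self.values.setdefault(chrom, {})[pos] = score

    def get_range(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores for [start, end) as a float vector; absent bases are 0."""
        chrom_vals = self.values.get(chrom, {})
        return np.array([chrom_vals.get(p, 0.0) for p in range(start, end)])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> ReferenceGenome:
    """Read a (multi-record) FASTA into a :class:`ReferenceGenome`.

    Lowercase (soft-masked) bases are uppercased; the record id is the first
    whitespace-delimited header token. Duplicate ids and characters outside
    {A,C,G,T,N} are errors.
    """
    sequences: dict[str, str] = {}
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    for rec in records:
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA record id '{rec.id}' in {path}")
        seq = str(rec.seq).upper()
        illegal = set(seq) - VALID_BASES
        if illegal:
            raise ValueError(
                f"illegal characters {sorted(illegal)} in FASTA record '{rec.id}'"
            )
        sequences[rec.id] = seq
    return ReferenceGenome(sequences)


def write_fasta(genome: ReferenceGenome, path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path, label: str = "") -> list[GenomicInterval]:
    """Read BED3/BED6 intervals, attaching ``label`` as the class name.

    Column 4 provides the interval name when present (default
    ``"chrom:start-end"``), column 6 the strand (default '+'); the score
    column is ignored — class identity comes from which file an interval
    was read from.
    """
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from None
            chrom = cols[0]
            name = cols[3] if len(cols) > 3 and cols[3] else f"{chrom}:{start}-{end}"
            strand = cols[5] if len(cols) > 5 else "+"
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{ln}: unknown strand symbol {strand!r}")
            if start >= end:
                raise ValueError(f"{path}:{ln}: start ({start}) must be < end ({end})")
            intervals.append(GenomicInterval(chrom, start, end, name, strand, label))
    return intervals


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# WIG / bedGraph


def read_wig(path) -> ConservationTrack:
    """Read fixedStep / variableStep WIG or 4-column bedGraph.

    WIG positions are 1-based on disk and stored 0-based; bedGraph intervals
    are expanded per base. Later declarations overwrite earlier ones at the
    same base.
    """
    track = ConservationTrack()
    mode = None  # ("fixed", chrom, next_pos0, step, span) | ("variable", chrom, span)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                params = _wig_params(line, ln, path)
                start = int(params.get("start", 0))
                step = int(params.get("step", 1))
                span = int(params.get("span", 1))
                if start < 1 or step < 1 or span < 1:
                    raise ValueError(f"{path}:{ln}: start/step/span must be >= 1")
                mode = ["fixed", params["chrom"], start - 1, step, span]
                continue
            if line.startswith("variableStep"):
                params = _wig_params(line, ln, path)
                span = int(params.get("span", 1))
                if span < 1:
                    raise ValueError(f"{path}:{ln}: span must be >= 1")
                mode = ["variable", params["chrom"], span]
                continue
            fields_ = line.split()
            if len(fields_) == 4:  # bedGraph data line
                chrom, start, end, score = fields_[0], int(fields_[1]), int(fields_[2]), float(fields_[3])
                for p in range(start, end):
                    track.set(chrom, p, score)
                mode = None
                continue
            if mode is None:
                raise ValueError(f"{path}:{ln}: data line outside any WIG declaration")
            if mode[0] == "fixed":
                _, chrom, pos, step, span = mode
                score = float(fields_[0])
                for p in range(pos, pos + span):
                    track.set(chrom, p, score)
                mode[2] = pos + step
            else:
                _, chrom, span = mode
                pos1, score = int(fields_[0]), float(fields_[1])
                if pos1 < 1:
                    raise ValueError(f"{path}:{ln}: variableStep positions are 1-based")
                for p in range(pos1 - 1, pos1 - 1 + span):
                    track.set(chrom, p, score)
    return track


def _wig_params(line: str, ln: int, path) -> dict[str, str]:
    params = dict(tok.split("=", 1) for tok in line.split()[1:] if "=" in tok)
    if "chrom" not in params:
        raise ValueError(f"{path}:{ln}: malformed WIG declaration (missing chrom)")
    return params


def write_wig(track: ConservationTrack, path) -> None:
    """Write as fixedStep step=1 WIG, one block per run of consecutive bases."""
    with open(path, "w") as fh:
        for chrom in track.values:
            positions = sorted(track.values[chrom])
            prev = None
            for pos in positions:
                if prev is None or pos != prev + 1:
                    fh.write(f"fixedStep chrom={chrom} start={pos + 1} step=1\n")
                fh.write(f"{track.values[chrom][pos]:g}\n")
                prev = pos


def read_conservation(path) -> ConservationTrack:
    """Dispatch on extension: text WIG/bedGraph always; bigWig when pyBigWig
    is importable."""
    path = Path(path)
    if path.suffix.lower() in (".bw", ".bigwig"):
        return _read_bigwig(path)
    return read_wig(path)


def _read_bigwig(path) -> ConservationTrack:  # pragma: no cover - optional format
    try:
        import pyBigWig
    except ImportError as exc:
        raise RuntimeError("bigWig input requires the optional pyBigWig package") from exc
    track = ConservationTrack()
    with pyBigWig.open(str(path)) as bw:
        for chrom, length in bw.chroms().items():
            vals = bw.values(chrom, 0, length, numpy=True)
            for pos in np.flatnonzero(~np.isnan(vals)):
                track.set(chrom, int(pos), float(vals[pos]))
    return track


# ---------------------------------------------------------------------------
# Session ledger and logging


def append_session_ledger(ledger_path, config: RunConfig, metrics: dict | None = None,
                          session_id: str = "", timestamp: str | None = None) -> None:
    """Append one row (flattened config columns + headline metrics) to the TSV
    ledger shared by all sessions in an output folder.

    The header is written once; when a newer session introduces columns an
    older ledger lacks, the old rows are padded with empty cells. A lock file
    guards against concurrent appends — a second concurrent writer gets an
    error rather than a silently merged ledger.
    """
    ledger_path = Path(ledger_path)
    if timestamp is None:
        timestamp = pd.Timestamp.now().isoformat(timespec="seconds")
    row: dict[str, object] = {"timestamp": timestamp, "session_id": session_id}
    row.update(_flatten("", config.model_dump(mode="json")))
    for k, v in (metrics or {}).items():
        row[f"metric.{k}"] = v

    lock = ledger_path.with_suffix(ledger_path.suffix + ".lock")
    try:
        fd = os.open(lock, os.O_CREAT | os.O_EXCL | os.O_WRONLY)
    except FileExistsError:
        raise RuntimeError(
            f"ledger {ledger_path} is locked by a concurrent session ({lock} exists)"
        ) from None
    try:
        new = pd.DataFrame([row])
        if ledger_path.exists():
            old = pd.read_csv(ledger_path, sep="\t", dtype=str)
            merged = pd.concat([old, new.astype(str)], ignore_index=True)
        else:
            merged = new
        merged.to_csv(ledger_path, sep="\t", index=False, na_rep="")
    finally:
        os.close(fd)
        lock.unlink(missing_ok=True)


def _flatten(prefix: str, obj: dict) -> dict[str, object]:
    out: dict[str, object] = {}
    for k, v in obj.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(key + ".", v))
        else:
            out[key] = _scalar(v)
    return out


def _scalar(v):
    if isinstance(v, (list, tuple)):
        return ",".join(str(x) for x in v)
    return v


def setup_session_logging(output_dir, session_id: str) -> logging.Logger:
    """Route all package log records (user input, warnings, errors) to a
    per-session log file inside the output folder."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(output_dir / f"{session_id}.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return logger
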