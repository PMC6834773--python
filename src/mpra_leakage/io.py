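"""Readers and writers for the plain-text formats the pipeline touches.

Formats: FASTA for reporter sequences, a tab-separated effect table
(columns ``reporter_id position ref alt confidence direction``), 4-column
bedGraph for signal tracks, and HOCOMOCO-style plain-text count matrices for
motifs.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    DNA_ALPHABET,
    PWM,
    PWMOrder,
    SignalTrack,
    SNVRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

SNV_TABLE_COLUMNS = ["reporter_id", "position", "ref", "alt", "confidence", "direction"]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# effect tables


def read_snv_table(path: str | Path) -> dict[str, list[SNVRecord]]:
    """Read a per-SNV effect table, grouped by reporter, row order preserved.

    Raises :class:`ParseError` for malformed rows and
    :class:`~mpra_leakage.core.ValidationError` when a record violates the
    confidence/direction coupling.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in SNV_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")

    grouped: dict[str, list[SNVRecord]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = SNVRecord(
                reporter_id=str(row.reporter_id),
                position=int(row.position),
                ref_allele=str(row.ref),
                alt_allele=str(row.alt),
                confidence=float(row.confidence),
                direction=int(row.direction),
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(f"{path}: line {i}: {exc}") from exc
        grouped.setdefault(rec.reporter_id, []).append(rec)
    return grouped


def write_snv_table(snvs: Iterable[SNVRecord], path: str | Path) -> None:
    rows = [
        (s.reporter_id, s.position, s.ref_allele, s.alt_allele,
         repr(float(s.confidence)), s.direction)
        for s in snvs
    ]
    df = pd.DataFrame(rows, columns=SNV_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Map record id (header up to first whitespace) to uppercase sequence."""
    result: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in result:
            raise ParseError(f"{path}: duplicate record id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - set(DNA_ALPHABET)
        if bad:
            raise ParseError(
                f"{path}: record {record.id!r} has non-ACGT characters {sorted(bad)}"
            )
        result[record.id] = seq
    return result


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path, track_id: str | None = None) -> list[SignalTrack]:
    """Expand a 4-column bedGraph into per-base :class:`SignalTrack` segments.

    Adjacent intervals are merged into one segment; uncovered bases are simply
    absent (a new segment starts after every gap).  Overlapping intervals are
    an error.
    """
    path = Path(path)
    if track_id is None:
        track_id = path.stem
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            chrom, start_s, end_s, value_s = parts
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if end <= start:
                raise ParseError(f"{path}: line {lineno}: empty/negative interval")
            intervals.setdefault(chrom, []).append((start, end, value))

    tracks: list[SignalTrack] = []
    for chrom in sorted(intervals):
        ivs = sorted(intervals[chrom])
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ParseError(
                    f"{path}: overlapping intervals [{s1},{e1}) and starting at "
                    f"{s2} on {chrom}"
                )
        seg_start: int | None = None
        seg_values: list[float] = []
        prev_end: int | None = None
        for start, end, value in ivs:
            if seg_start is None:
                seg_start, prev_end = start, start
            if start != prev_end:  # gap: flush current segment
                tracks.append(SignalTrack(track_id, chrom, seg_start, np.array(seg_values)))
                seg_start, seg_values = start, []
            seg_values.extend([value] * (end - start))
            prev_end = end
        if seg_start is not None and seg_values:
            tracks.append(SignalTrack(track_id, chrom, seg_start, np.array(seg_values)))
    return tracks


def write_bedgraph(tracks: Sequence[SignalTrack], path: str | Path) -> None:
    """Write segments as run-length-compressed bedGraph lines."""
    with open(path, "w") as fh:
        for track in tracks:
            vals = track.values
            pos = 0
            while pos < len(vals):
                run_end = pos + 1
                while run_end < len(vals) and vals[run_end] == vals[pos]:
                    run_end += 1
                fh.write(
                    f"{track.chrom}\t{track.start + pos}\t{track.start + run_end}\t"
                    f"{repr(float(vals[pos]))}\n"
                )
                pos = run_end


# ---------------------------------------------------------------------------
# PWMs

MONO_PSEUDOCOUNT = 0.25
DI_PSEUDOCOUNT = 0.0625


def _counts_to_logodds(counts: np.ndarray, background: np.ndarray,
                       pseudocount: float) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True) + counts.shape[1] * pseudocount
    freqs = (counts + pseudocount) / totals
    return np.log(freqs / background[None, :])


def read_pwm(path: str | Path) -> PWM:
    """Read one HOCOMOCO-style matrix: a ``>motif_id`` header then one row of
    4 (mono) or 16 (di) numbers per scored step.

    Non-negative matrices are treated as counts and converted to log-odds
    against a uniform background with a pseudocount (0.25 per cell for mono,
    0.0625 for di); matrices containing negative entries are taken to be
    precomputed weights and used as-is.
    """
    pwms = read_pwm_collection(path)
    if len(pwms) != 1:
        raise ParseError(f"{path}: expected exactly one motif, found {len(pwms)}")
    return pwms[0]


def read_pwm_collection(path: str | Path) -> list[PWM]:
    path = Path(path)
    pwms: list[PWM] = []
    motif_id: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows, motif_id
        if motif_id is None:
            return
        if not rows:
            raise ParseError(f"{path}: motif {motif_id!r} has no matrix rows")
        widths = {len(r) for r in rows}
        if widths not in ({4}, {16}):
            raise ParseError(
                f"{path}: motif {motif_id!r}: rows must have 4 or 16 numbers, "
                f"got lengths {sorted(widths)}"
            )
        counts = np.array(rows, dtype=float)
        order = PWMOrder.MONO if widths == {4} else PWMOrder.DI
        if np.all(counts >= 0):
            pc = MONO_PSEUDOCOUNT if order == PWMOrder.MONO else DI_PSEUDOCOUNT
            bg = np.full(counts.shape[1], 1.0 / counts.shape[1])
            weights = _counts_to_logodds(counts, bg, pc)
        else:
            weights = counts
        pwms.append(PWM(motif_id=motif_id, order=order, weights=weights))
        rows = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
            else:
                if motif_id is None:
                    raise ParseError(f"{path}: line {lineno}: matrix row before header")
                try:
                    rows.append([float(x) for x in line.split()])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    flush()
    if not pwms:
        raise ParseError(f"{path}: no motifs found")
    return pwms


def write_pwm_collection(pwms: Sequence[PWM], path: str | Path) -> None:
    """Write log-odds weights (readable back as precomputed weights)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for row in pwm.weights:
                fh.write("\t".join(repr(float(x)) for x in row) + "\n")
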