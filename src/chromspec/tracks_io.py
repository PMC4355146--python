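"""Binarized chromatin-mark tracks, observation encoding and genomic intervals.

The on-disk dialect is the ChromHMM binarized-track text format: two header
lines (cell type + chromosome, then tab-separated mark names) followed by one
tab-separated row of 0/1 values per fixed-width genomic segment.  Each row is
encoded into a single integer observation code over the combination alphabet
of size ``N = 2**M`` (mark column ``m`` contributes bit ``m``, LSB first, so
the all-absent combination is code 0).
"""

from __future__ import annotations

import gzip
import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Largest number of marks for which the dense 2**M alphabet is enumerated.
MAX_DENSE_MARKS = 24


class TrackFormatError(ValueError):
    """Malformed binarized-track or interval input."""


class AlignmentError(ValueError):
    """Inputs that must cover the same segments do not."""


@dataclass
class MarkMatrix:
    """Binary presence/absence calls for M marks over T fixed-width segments.

    Segment ``i`` covers bases ``[i*segment_width, (i+1)*segment_width)`` in
    0-based half-open coordinates on ``chromosome``.
    """

    cell_type: str
    chromosome: str
    marks: list[str]
    values: np.ndarray  # (T, M) uint8 in {0, 1}
    segment_width: int = 200

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise TrackFormatError("values must be a 2-D (segments x marks) array")
        if not self.marks:
            raise TrackFormatError("mark list is empty")
        if len(set(self.marks)) != len(self.marks):
            raise TrackFormatError(f"duplicate mark names: {self.marks}")
        if self.values.shape[1] != len(self.marks):
            raise TrackFormatError(
                f"{self.values.shape[1]} value columns for {len(self.marks)} marks"
            )
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise TrackFormatError("values must be 0 or 1")
        if self.segment_width <= 0:
            raise TrackFormatError("segment_width must be positive")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def n_marks(self) -> int:
        return len(self.marks)


@dataclass
class ObservationSequence:
    """Integer observation codes for one chromosome over alphabet [0, N)."""

    chromosome: str
    codes: np.ndarray  # (T,) int64
    alphabet_size: int

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.size and (
            self.codes.min() < 0 or self.codes.max() >= self.alphabet_size
        ):
            raise ValueError("observation code outside [0, alphabet_size)")

    def __len__(self) -> int:
        return self.codes.size


@dataclass
class FeatureIntervals:
    """Named set of genomic intervals in 0-based half-open coordinates."""

    name: str
    intervals: list[tuple[str, int, int]]
    strands: list[str] | None = None

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise TrackFormatError(
                    f"{self.name}: interval {chrom}:{start}-{end} has start >= end"
                )

    def by_chromosome(self) -> dict[str, np.ndarray]:
        """Intervals grouped per chromosome as (n, 2) start/end arrays."""
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            out.setdefault(chrom, []).append((start, end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def merged(self) -> "FeatureIntervals":
        """Sorted, overlap-merged copy (explicit step; reading keeps records)."""
        merged: list[tuple[str, int, int]] = []
        for chrom, arr in sorted(self.by_chromosome().items()):
            arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
            cur_s, cur_e = int(arr[0, 0]), int(arr[0, 1])
            for s, e in arr[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, int(e))
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = int(s), int(e)
            merged.append((chrom, cur_s, cur_e))
        return FeatureIntervals(self.name, merged)


def _open_text(path_or_stream, mode: str = "rt"):
    if hasattr(path_or_stream, "read") or hasattr(path_or_stream, "write"):
        return path_or_stream, False
    path = Path(path_or_stream)
    if path.suffix == ".gz":
        return gzip.open(path, mode), True
    return open(path, mode), True


def read_binarized(path_or_stream, segment_width: int = 200) -> MarkMatrix:
    """Read one ChromHMM-format binarized track file.

    Raises :class:`TrackFormatError` naming the offending line for ragged
    rows, non-binary tokens or an empty mark list.
    """
    handle, close = _open_text(path_or_stream)
    try:
        header = handle.readline().rstrip("\n")
        if not header:
            raise TrackFormatError("line 1: missing cell-type/chromosome header")
        fields = header.split("\t")
        if len(fields) < 2:
            fields = header.split()
        if len(fields) < 2:
            raise TrackFormatError("line 1: expected '<cell type>\\t<chromosome>'")
        cell_type, chromosome = fields[0], fields[1]

        marks_line = handle.readline().rstrip("\n")
        marks = [m for m in marks_line.split("\t") if m] or marks_line.split()
        if not marks:
            raise TrackFormatError("line 2: empty mark list")

        rows: list[list[int]] = []
        for lineno, line in enumerate(handle, start=3):
            line = line.strip()
            if not line:
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if len(tokens) != len(marks):
                raise TrackFormatError(
                    f"line {lineno}: {len(tokens)} fields, expected {len(marks)}"
                )
            row = []
            for tok in tokens:
                if tok == "0":
                    row.append(0)
                elif tok == "1":
                    row.append(1)
                else:
                    raise TrackFormatError(f"line {lineno}: non-binary token {tok!r}")
            rows.append(row)
    finally:
        if close:
            handle.close()

    values = (
        np.asarray(rows, dtype=np.uint8)
        if rows
        else np.zeros((0, len(marks)), dtype=np.uint8)
    )
    if not rows:
        logger.warning("%s/%s: binarized file has no data rows", cell_type, chromosome)
    return MarkMatrix(cell_type, chromosome, marks, values, segment_width)


def write_binarized(m: MarkMatrix, path_or_stream) -> None:
    """Write a :class:`MarkMatrix` in the ChromHMM binarized dialect."""
    handle, close = _open_text(path_or_stream, "wt")
    try:
        handle.write(f"{m.cell_type}\t{m.chromosome}\n")
        handle.write("\t".join(m.marks) + "\n")
        for row in m.values:
            handle.write("\t".join("1" if v else "0" for v in row) + "\n")
    finally:
        if close:
            handle.close()


def encode_observations(m: MarkMatrix, max_marks: int = MAX_DENSE_MARKS) -> ObservationSequence:
    """Collapse each segment's mark vector into one integer code.

    ``code = sum_m values[t, m] * 2**m`` (mark 0 is the least-significant bit).
    """
    if m.n_marks > max_marks:
        raise ValueError(
            f"{m.n_marks} marks exceeds the dense-alphabet cap of {max_marks}"
        )
    weights = (1 << np.arange(m.n_marks, dtype=np.int64))
    codes = m.values.astype(np.int64) @ weights
    return ObservationSequence(m.chromosome, codes, 1 << m.n_marks)


def decode_observations(
    seq: ObservationSequence,
    marks: Sequence[str],
    cell_type: str = "decoded",
    segment_width: int = 200,
) -> MarkMatrix:
    """Inverse of :func:`encode_observations` for a known mark list."""
    n_marks = len(marks)
    if seq.alphabet_size != (1 << n_marks):
        raise ValueError("alphabet size does not match 2**len(marks)")
    bits = (seq.codes[:, None] >> np.arange(n_marks)) & 1
    return MarkMatrix(cell_type, seq.chromosome, list(marks), bits.astype(np.uint8), segment_width)


def stack_cell_types(matrices: Sequence[MarkMatrix]) -> MarkMatrix:
    """Concatenate the mark columns of several cell types on one chromosome.

    Mark names become ``<cellType>.<markName>``; column order follows input
    order, so the stacked observation code is the bit-concatenation of the
    per-cell codes (first input in the low bits).
    """
    if not matrices:
        raise ValueError("no matrices to stack")
    first = matrices[0]
    for m in matrices[1:]:
        if m.chromosome != first.chromosome:
            raise AlignmentError(
                f"chromosome mismatch: {m.chromosome} vs {first.chromosome}"
            )
        if m.segment_width != first.segment_width:
            raise AlignmentError("segment_width mismatch")
        if m.n_segments != first.n_segments:
            raise AlignmentError(
                f"segment count mismatch: {m.n_segments} vs {first.n_segments}"
            )
    marks = [f"{m.cell_type}.{name}" for m in matrices for name in m.marks]
    values = np.hstack([m.values for m in matrices])
    cell_type = "+".join(m.cell_type for m in matrices)
    return MarkMatrix(cell_type, first.chromosome, marks, values, first.segment_width)


def observed_alphabet(
    seqs: Iterable[ObservationSequence], min_count: int = 1
) -> pd.DataFrame:
    """Codes occurring at least ``min_count`` times, sorted by descending count.

    Supports the sparsity report (only a small fraction of the 2**M
    combinations ever occurs in real genomes) and sparse moment indexing.
    Setting ``min_count=2`` drops singleton combinations that are likely noise.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: Counter[int] = Counter()
    for seq in seqs:
        codes, c = np.unique(seq.codes, return_counts=True)
        for code, k in zip(codes, c):
            counts[int(code)] += int(k)
    items = [(code, k) for code, k in counts.items() if k >= min_count]
    items.sort(key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(items, columns=["code", "count"]).astype(np.int64)


def read_intervals(
    path_or_stream,
    name: str | None = None,
    chrom_map: dict[str, str] | None = None,
) -> FeatureIntervals:
    """Read a BED3+ file (0-based half-open) into :class:`FeatureIntervals`.

    Overlapping records are retained unmerged; call ``.merged()`` explicitly.
    """
    handle, close = _open_text(path_or_stream)
    try:
        intervals: list[tuple[str, int, int]] = []
        strands: list[str] = []
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise TrackFormatError(f"line {lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            if chrom_map:
                chrom = chrom_map.get(chrom, chrom)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise TrackFormatError(f"line {lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise TrackFormatError(
                    f"line {lineno}: invalid interval {chrom}:{start}-{end}"
                )
            intervals.append((chrom, start, end))
            strands.append(fields[5] if len(fields) >= 6 else ".")
    finally:
        if close:
            handle.close()
    if name is None:
        name = Path(getattr(path_or_stream, "name", str(path_or_stream))).stem
    return FeatureIntervals(name, intervals, strands)


def mask_segments(
    seq: ObservationSequence,
    mask: FeatureIntervals | None,
    segment_width: int = 200,
) -> list[ObservationSequence]:
    """Drop segments overlapping ``mask`` and splice at each gap.

    Splicing creates sequence breaks so that no pair or triple moment ever
    spans a masked region (masking must not fabricate false transitions).
    Returns the list of unmasked runs, in genomic order; with no mask the
    input is returned as a single run.
    """
    if mask is None:
        return [seq]
    drop = np.zeros(len(seq), dtype=bool)
    for chrom, arr in mask.by_chromosome().items():
        if chrom != seq.chromosome:
            continue
        for start, end in arr:
            lo = int(start) // segment_width
            hi = -(-int(end) // segment_width)  # ceil
            drop[max(lo, 0): min(hi, len(seq))] = True
    if not drop.any():
        return [seq]
    keep = ~drop
    runs: list[ObservationSequence] = []
    boundaries = np.flatnonzero(np.diff(keep.astype(np.int8)) != 0) + 1
    for lo, hi in zip(
        np.r_[0, boundaries], np.r_[boundaries, len(seq)]
    ):
        if keep[lo] and hi > lo:
            runs.append(
                ObservationSequence(seq.chromosome, seq.codes[lo:hi], seq.alphabet_size)
            )
    return runs
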