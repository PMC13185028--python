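"""sgRNA quantification from FASTQ reads by exact spacer matching.

Each read is scanned over a configurable window of start offsets; the length-L
substring at each offset is looked up in the library's exact-match spacer
index. This reproduces the counting role of standard screen quantifiers with a
fully specified, deterministic tie-break: the first matching offset wins, and
the forward orientation is scanned completely before the reverse complement.
No mismatch tolerance, adapter trimming, or quality filtering is applied.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass

import numpy as np

from .library import CountMatrix, GuideLibrary, SampleInfo

UNMAPPED = "UNMAPPED"
AMBIGUOUS = "AMBIGUOUS"

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class FastqError(ValueError):
    """Raised on a malformed FASTQ record; message carries the line number."""


@dataclass(frozen=True)
class QuantConfig:
    """Scanning parameters for exact spacer matching.

    scan_offsets: inclusive 0-based [o_min, o_max] range of read positions where
        the spacer may start. The default 0..30 covers typical vector-derived
        constant offsets in amplicon designs.
    try_reverse_complement: scan the reverse complement after an unproductive
        forward scan (a read hitting distinct guides in the two orientations is
        AMBIGUOUS).
    min_read_length: reads shorter than this are UNMAPPED without scanning;
        defaults to o_min + spacer length at match time when left as None.
    """

    scan_offsets: tuple[int, int] = (0, 30)
    try_reverse_complement: bool = False
    min_read_length: int | None = None

    def __post_init__(self) -> None:
        o_min, o_max = self.scan_offsets
        if not (0 <= o_min <= o_max):
            raise ValueError(f"invalid scan_offsets {self.scan_offsets}")


def match_read(read_sequence: str, library: GuideLibrary, config: QuantConfig) -> str:
    """Match one read to a guide_id, or UNMAPPED / AMBIGUOUS.

    Offsets are scanned in increasing order; the substring [o, o+L) is looked
    up exactly. The first hit wins within an orientation; forward is tried
    fully before reverse complement.
    """
    seq = read_sequence.upper()
    L = library.spacer_length
    o_min, o_max = config.scan_offsets
    min_len = config.min_read_length if config.min_read_length is not None else o_min + L
    if len(seq) < min_len:
        return UNMAPPED

    index = library.spacer_index

    def scan(s: str) -> str | None:
        hi = min(o_max, len(s) - L)
        for o in range(o_min, hi + 1):
            hit = index.get(s[o : o + L])
            if hit is not None:
                return hit
        return None

    fwd = scan(seq)
    if not config.try_reverse_complement:
        return fwd if fwd is not None else UNMAPPED
    rev = scan(reverse_complement(seq))
    if fwd is not None and rev is not None and fwd != rev:
        return AMBIGUOUS
    if fwd is not None:
        return fwd
    return rev if rev is not None else UNMAPPED


def _open_text(path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def _iter_fastq(path):
    """Yield (sequence, first_line_number) for each 4-line FASTQ record."""
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FastqError(
                    f"{path}: line {lineno}: record header must start with '@', "
                    f"got {header.rstrip()[:30]!r}"
                )
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqError(f"{path}: line {lineno}: truncated FASTQ record")
            seq = seq.rstrip("\n")
            qual = qual.rstrip("\n")
            if not plus.startswith("+"):
                raise FastqError(
                    f"{path}: line {lineno + 2}: separator line must start with '+'"
                )
            if len(seq) != len(qual):
                raise FastqError(
                    f"{path}: line {lineno + 3}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            yield seq, lineno
            lineno += 3


def count_fastq(
    sample: SampleInfo, library: GuideLibrary, config: QuantConfig | None = None
) -> tuple[np.ndarray, int, int, int]:
    """Count one sample's FASTQ file(s) into a library-ordered count column.

    Returns (counts, mapped, unmapped, ambiguous). Every read contributes to
    exactly one bucket, so mapped + unmapped + ambiguous equals the number of
    reads processed and the column sum equals mapped.
    """
    config = config or QuantConfig()
    if not sample.fastq_paths:
        raise ValueError(f"sample {sample.sample_id!r} has no fastq paths")
    order = {gid: i for i, gid in enumerate(library.guide_ids)}
    counts = np.zeros(len(order), dtype=np.int64)
    unmapped = ambiguous = total = 0
    for path in sample.fastq_paths:
        n_before = total
        for seq, _ in _iter_fastq(path):
            total += 1
            hit = match_read(seq, library, config)
            if hit == UNMAPPED:
                unmapped += 1
            elif hit == AMBIGUOUS:
                ambiguous += 1
            else:
                counts[order[hit]] += 1
        if total == n_before:
            warnings.warn(f"FASTQ file {path} contains no reads", stacklevel=2)
    mapped = total - unmapped - ambiguous
    return counts, mapped, unmapped, ambiguous


def count_samples(
    samples: list[SampleInfo], library: GuideLibrary, config: QuantConfig | None = None
) -> CountMatrix:
    """Quantify every sample in a sheet into a CountMatrix."""
    cols, unm, amb = [], [], []
    for s in samples:
        c, _, u, a = count_fastq(s, library, config)
        cols.append(c)
        unm.append(u)
        amb.append(a)
    return CountMatrix(
        guide_ids=library.guide_ids,
        samples=list(samples),
        counts=np.column_stack(cols) if cols else np.zeros((len(library.records), 0), dtype=np.int64),
        unmapped=np.array(unm, dtype=np.int64),
        ambiguous=np.array(amb, dtype=np.int64),
    )


def mapping_rate(mapped: int, unmapped: int, ambiguous: int) -> float:
    """Fraction of reads assigned to a guide; 0.0 when no reads were seen."""
    total = mapped + unmapped + ambiguous
    if total == 0:
        return 0.0
    return mapped / total


__all__ = [
    "UNMAPPED",
    "AMBIGUOUS",
    "FastqError",
    "QuantConfig",
    "match_read",
    "count_fastq",
    "count_samples",
    "mapping_rate",
    "reverse_complement",
]
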