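"""Data model and I/O for sgRNA libraries, sample sheets, and count matrices.

The screen design modeled here is a two-set, one-guide-per-gene-per-set pooled
CRISPR knockout library (so each gene is covered by at most two guides), plus a
set of safe-harbor control guides that target phenotypically neutral loci. Safe
harbors are carried as a CONTROL set under the pseudo-gene ``SAFE_HARBOR``;
they anchor normalization and the empirical null but are never eligible for
gene-level calling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAFE_HARBOR_GENE = "SAFE_HARBOR"
SET_LABELS = ("SET1", "SET2", "CONTROL")

#: Minimum number of safe-harbor guides required before the empirical null
#: (2.5%/97.5% quantiles of control log2FC) is considered meaningful.
N_CTRL_MIN = 20

_DNA = frozenset("ACGT")


class ValidationError(ValueError):
    """Raised when a library, sample sheet, or count matrix violates an invariant."""


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: a spacer sequence assigned to a gene within a library set."""

    guide_id: str
    gene: str
    spacer: str
    set_label: str
    is_safe_harbor: bool

    def __post_init__(self) -> None:
        if self.set_label not in SET_LABELS:
            raise ValidationError(
                f"guide {self.guide_id!r}: set_label {self.set_label!r} "
                f"not one of {SET_LABELS}"
            )
        if not set(self.spacer) <= _DNA:
            bad = sorted(set(self.spacer) - _DNA)
            raise ValidationError(
                f"guide {self.guide_id!r}: non-ACGT character(s) {bad} in spacer"
            )
        if self.is_safe_harbor != (self.set_label == "CONTROL"):
            raise ValidationError(
                f"guide {self.guide_id!r}: is_safe_harbor={self.is_safe_harbor} "
                f"inconsistent with set_label={self.set_label!r} "
                "(safe harbors are exactly the CONTROL set)"
            )
        if self.is_safe_harbor and self.gene != SAFE_HARBOR_GENE:
            raise ValidationError(
                f"guide {self.guide_id!r}: safe-harbor guides must use the "
                f"pseudo-gene {SAFE_HARBOR_GENE!r}, got {self.gene!r}"
            )


@dataclass
class GuideLibrary:
    """An ordered sgRNA catalog with an exact-match spacer index.

    Invariants enforced at construction: unique guide ids and spacers, a single
    spacer length L, and at most one guide per (gene, set) for non-control genes.
    """

    records: list[GuideRecord]
    spacer_index: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("library is empty")
        seen_ids: dict[str, str] = {}
        seen_spacers: dict[str, str] = {}
        seen_gene_set: dict[tuple[str, str], str] = {}
        lengths = {len(r.spacer) for r in self.records}
        if len(lengths) > 1:
            raise ValidationError(
                f"mixed spacer lengths {sorted(lengths)}; all spacers must share one length"
            )
        for r in self.records:
            if r.guide_id in seen_ids:
                raise ValidationError(f"duplicate guide_id {r.guide_id!r}")
            seen_ids[r.guide_id] = r.guide_id
            if r.spacer in seen_spacers:
                raise ValidationError(
                    f"duplicate spacer shared by guides "
                    f"{seen_spacers[r.spacer]!r} and {r.guide_id!r}"
                )
            seen_spacers[r.spacer] = r.guide_id
            if not r.is_safe_harbor:
                key = (r.gene, r.set_label)
                if key in seen_gene_set:
                    raise ValidationError(
                        f"gene {r.gene!r} has two guides in {r.set_label}: "
                        f"{seen_gene_set[key]!r} and {r.guide_id!r}"
                    )
                seen_gene_set[key] = r.guide_id
        self.spacer_index = {r.spacer: r.guide_id for r in self.records}

    @property
    def spacer_length(self) -> int:
        return len(self.records[0].spacer)

    @property
    def guide_ids(self) -> list[str]:
        return [r.guide_id for r in self.records]

    @property
    def n_safe_harbors(self) -> int:
        return sum(r.is_safe_harbor for r in self.records)

    @property
    def safe_harbor_ids(self) -> list[str]:
        return [r.guide_id for r in self.records if r.is_safe_harbor]

    @property
    def genes(self) -> list[str]:
        """Non-control gene symbols, in first-appearance order."""
        out: list[str] = []
        seen = set()
        for r in self.records:
            if not r.is_safe_harbor and r.gene not in seen:
                seen.add(r.gene)
                out.append(r.gene)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [r.guide_id for r in self.records],
                "gene": [r.gene for r in self.records],
                "spacer": [r.spacer for r in self.records],
                "set_label": [r.set_label for r in self.records],
                "is_safe_harbor": [r.is_safe_harbor for r in self.records],
            }
        )


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced sample: condition, optional timepoint, replicate index."""

    sample_id: str
    condition: str
    timepoint: str | None = None
    replicate: int = 1
    fastq_paths: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )

    @property
    def group(self) -> str:
        """Group label used in contrasts: the timepoint when present, else condition."""
        return self.timepoint if self.timepoint else self.condition


@dataclass
class CountMatrix:
    """Integer guide x sample read counts plus per-sample mapping totals."""

    guide_ids: list[str]
    samples: list[SampleInfo]
    counts: np.ndarray
    unmapped: np.ndarray | None = None
    ambiguous: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.guide_ids), len(self.samples)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.guide_ids)} guides x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.unmapped is None:
            self.unmapped = np.zeros(len(self.samples), dtype=np.int64)
        if self.ambiguous is None:
            self.ambiguous = np.zeros(len(self.samples), dtype=np.int64)
        self.unmapped = np.asarray(self.unmapped, dtype=np.int64)
        self.ambiguous = np.asarray(self.ambiguous, dtype=np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def mapped(self) -> np.ndarray:
        """Per-sample mapped totals; by invariant, the column sums."""
        return self.counts.sum(axis=0)

    def group_labels(self) -> list[str]:
        return [s.group for s in self.samples]

    def sample_indices(self, group: str) -> list[int]:
        idx = [j for j, s in enumerate(self.samples) if s.group == group]
        if not idx:
            known = sorted({s.group for s in self.samples})
            raise ValidationError(f"unknown group {group!r}; known groups: {known}")
        return idx

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.guide_ids == other.guide_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.unmapped, other.unmapped)
            and np.array_equal(self.ambiguous, other.ambiguous)
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_LIBRARY_COLUMNS = ["guide_id", "gene", "spacer", "set_label", "is_safe_harbor"]
_SHEET_COLUMNS = ["sample_id", "condition", "timepoint", "replicate", "fastq"]

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f", ""}


def _parse_bool(value: str, context: str) -> bool:
    v = value.strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise ValidationError(f"{context}: cannot interpret {value!r} as a boolean")


def read_library(path) -> GuideLibrary:
    """Read a guide-library CSV (guide_id, gene, spacer, set_label, is_safe_harbor).

    Spacers are case-normalized to uppercase. All library invariants (unique
    ids/spacers, single spacer length, one guide per gene per set, safe-harbor
    consistency) are enforced; violations raise :class:`ValidationError`.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _LIBRARY_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValidationError(f"library file {path}: missing column(s) {missing}")
        records = []
        for row in reader:
            records.append(
                GuideRecord(
                    guide_id=row["guide_id"].strip(),
                    gene=row["gene"].strip(),
                    spacer=row["spacer"].strip().upper(),
                    set_label=row["set_label"].strip().upper(),
                    is_safe_harbor=_parse_bool(
                        row["is_safe_harbor"], f"guide {row['guide_id']!r}"
                    ),
                )
            )
    return GuideLibrary(records)


def write_library(library: GuideLibrary, path) -> None:
    library.to_frame().to_csv(path, index=False)


def read_sample_sheet(path) -> list[SampleInfo]:
    """Read a sample sheet CSV (sample_id, condition, timepoint, replicate, fastq)."""
    samples: list[SampleInfo] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _SHEET_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValidationError(f"sample sheet {path}: missing column(s) {missing}")
        for row in reader:
            sid = row["sample_id"].strip()
            if sid in seen:
                raise ValidationError(f"duplicate sample_id {sid!r}")
            seen.add(sid)
            tp = row["timepoint"].strip() or None
            fq = tuple(p for p in row["fastq"].strip().split(";") if p) or None
            try:
                rep = int(row["replicate"])
            except ValueError as exc:
                raise ValidationError(
                    f"sample {sid!r}: replicate {row['replicate']!r} is not an integer"
                ) from exc
            samples.append(
                SampleInfo(
                    sample_id=sid,
                    condition=row["condition"].strip(),
                    timepoint=tp,
                    replicate=rep,
                    fastq_paths=fq,
                )
            )
    if not samples:
        raise ValidationError(f"sample sheet {path} contains no samples")
    return samples


def write_sample_sheet(samples: list[SampleInfo], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SHEET_COLUMNS)
        for s in samples:
            writer.writerow(
                [
                    s.sample_id,
                    s.condition,
                    s.timepoint or "",
                    s.replicate,
                    ";".join(s.fastq_paths) if s.fastq_paths else "",
                ]
            )


def write_counts(matrix: CountMatrix, path) -> None:
    """Write a count matrix as TSV: guide_id column then one column per sample.

    Unmapped/ambiguous per-sample totals are preserved in ``#`` comment lines so
    the round trip is lossless.
    """
    with open(path, "w") as fh:
        fh.write("#unmapped\t" + "\t".join(str(int(v)) for v in matrix.unmapped) + "\n")
        fh.write(
            "#ambiguous\t" + "\t".join(str(int(v)) for v in matrix.ambiguous) + "\n"
        )
        fh.write("guide_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, gid in enumerate(matrix.guide_ids):
            fh.write(gid + "\t" + "\t".join(str(int(v)) for v in matrix.counts[i]) + "\n")


def read_counts(path, library: GuideLibrary, samples: list[SampleInfo] | None = None) -> CountMatrix:
    """Read a count TSV back into a :class:`CountMatrix` aligned to ``library``.

    The file must cover exactly the library's guides (any order); missing or
    extra guide ids raise :class:`ValidationError` naming them. When ``samples``
    is None, placeholder :class:`SampleInfo` rows are synthesized from the
    header (condition ``"unspecified"``).
    """
    meta: dict[str, list[int]] = {}
    with open(path) as fh:
        line = fh.readline()
        while line.startswith("#"):
            tag, *vals = line.rstrip("\n").split("\t")
            meta[tag.lstrip("#")] = [int(v) for v in vals]
            line = fh.readline()
        header = line.rstrip("\n").split("\t")
        if not header or header[0] != "guide_id":
            raise ValidationError(f"count file {path}: first column must be guide_id")
        sample_ids = header[1:]
        rows: dict[str, list[int]] = {}
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValidationError(
                    f"count file {path}: row {parts[0]!r} has {len(parts) - 1} "
                    f"values, expected {len(sample_ids)}"
                )
            try:
                vals = [int(v) for v in parts[1:]]
            except ValueError as exc:
                raise ValidationError(
                    f"count file {path}: non-integer count in row {parts[0]!r}"
                ) from exc
            if any(v < 0 for v in vals):
                raise ValidationError(
                    f"count file {path}: negative count in row {parts[0]!r}"
                )
            if parts[0] in rows:
                raise ValidationError(f"count file {path}: duplicate guide {parts[0]!r}")
            rows[parts[0]] = vals

    lib_ids = library.guide_ids
    missing = [g for g in lib_ids if g not in rows]
    extra = [g for g in rows if g not in set(lib_ids)]
    if missing or extra:
        raise ValidationError(
            f"count file {path} does not match library: "
            f"missing guides {missing[:10]}{'...' if len(missing) > 10 else ''}, "
            f"unknown guides {extra[:10]}{'...' if len(extra) > 10 else ''}"
        )
    counts = np.array([rows[g] for g in lib_ids], dtype=np.int64)

    if samples is None:
        samples = [
            SampleInfo(sample_id=sid, condition="unspecified", replicate=j + 1)
            for j, sid in enumerate(sample_ids)
        ]
    else:
        by_id = {s.sample_id: s for s in samples}
        missing_s = [sid for sid in sample_ids if sid not in by_id]
        if missing_s:
            raise ValidationError(
                f"count file {path}: samples {missing_s} absent from sample sheet"
            )
        samples = [by_id[sid] for sid in sample_ids]

    return CountMatrix(
        guide_ids=list(lib_ids),
        samples=samples,
        counts=counts,
        unmapped=np.array(meta.get("unmapped", [0] * len(sample_ids)), dtype=np.int64),
        ambiguous=np.array(meta.get("ambiguous", [0] * len(sample_ids)), dtype=np.int64),
    )


def check_groups_for_comparison(samples: list[SampleInfo], group_a: str, group_b: str) -> None:
    """Require >=2 replicates in each side of a differential comparison."""
    for g in (group_a, group_b):
        n = sum(1 for s in samples if s.group == g)
        if n == 0:
            known = sorted({s.group for s in samples})
            raise ValidationError(f"unknown group {g!r}; known groups: {known}")
        if n < 2:
            raise ValidationError(
                f"group {g!r} has only {n} sample; >=2 replicates are required "
                "for a differential comparison"
            )


__all__ = [
    "SAFE_HARBOR_GENE",
    "N_CTRL_MIN",
    "ValidationError",
    "GuideRecord",
    "GuideLibrary",
    "SampleInfo",
    "CountMatrix",
    "read_library",
    "write_library",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_counts",
    "write_counts",
    "check_groups_for_comparison",
]
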