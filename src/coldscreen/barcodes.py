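"""Barcode extraction from barcode-PCR reads and the count matrix.

Each mutant carries a cassette with a unique internal barcode flanked by
fixed cassette sequence.  A barcode-PCR read therefore looks like

    <upstream anchor> <barcode> <downstream anchor> <backbone filler...>

Extraction locates the upstream anchor (tolerating a configurable number
of substitutions), takes the following ``barcode_len`` bases as the
barcode, and — when the read is long enough — confirms the downstream
anchor.  Counting one FASTQ per sample yields the barcode × sample count
matrix on which all screen statistics operate.  Quality scores are not
used: the fixed anchors and barcode length already constrain calls.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

# Cassette anchor defaults shared with the simulator.  These are package
# defaults for synthetic data, not the (unpublished) cassette internals of
# any particular vector; real runs must configure the true anchors.
DEFAULT_UPSTREAM_ANCHOR = "GCTACTTGTCGACGGAGC"
DEFAULT_DOWNSTREAM_ANCHOR = "AGATCGGAAGAGCGTCG"

_VALID_BASES = frozenset("ACGT")

#: no-call reason codes
NOCALL_ANCHOR_MISSING = "anchor-missing"
NOCALL_AMBIGUOUS_BASE = "ambiguous-base"
NOCALL_TRUNCATED = "truncated"


@dataclass(frozen=True)
class CassetteSpec:
    """Fixed cassette geometry used to pull barcodes out of reads."""

    upstream_anchor: str = DEFAULT_UPSTREAM_ANCHOR
    downstream_anchor: str = DEFAULT_DOWNSTREAM_ANCHOR
    barcode_len: int = 22
    max_anchor_mismatches: int = 1

    def __post_init__(self) -> None:
        for name in ("upstream_anchor", "downstream_anchor"):
            anchor = getattr(self, name)
            if not anchor or len(anchor) < 8:
                raise ValueError(f"{name} must be at least 8 bases, got {anchor!r}")
        if self.barcode_len < 8:
            raise ValueError(f"barcode_len must be >= 8, got {self.barcode_len}")
        if self.max_anchor_mismatches < 0:
            raise ValueError("max_anchor_mismatches must be >= 0")


def _best_anchor_offset(read: str, anchor: str, max_mm: int) -> int | None:
    """Leftmost best-scoring occurrence of ``anchor`` in ``read``.

    Returns the 0-based offset of the occurrence with the fewest
    mismatches (<= ``max_mm``); ties broken by the smaller offset.
    Exact matches are resolved with ``str.find`` first for speed.
    """
    exact = read.find(anchor)
    if exact != -1:
        return exact
    if max_mm == 0:
        return None
    best_off, best_mm = None, max_mm + 1
    la = len(anchor)
    for off in range(len(read) - la + 1):
        mm = 0
        window = read[off : off + la]
        for a, b in zip(window, anchor):
            if a != b:
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best_off, best_mm = off, mm
            if mm == 0:
                break
    return best_off


def extract_barcode(read_sequence: str, spec: CassetteSpec) -> tuple[str | None, str | None]:
    """Extract the cassette barcode from one read.

    Returns ``(barcode, None)`` on success or ``(None, reason)`` with one
    of the reason codes ``anchor-missing``, ``ambiguous-base`` or
    ``truncated``.  Never raises on a well-formed read.
    """
    read = read_sequence.upper()
    min_len = len(spec.upstream_anchor) + spec.barcode_len
    if len(read) < min_len:
        return None, NOCALL_TRUNCATED
    off = _best_anchor_offset(read, spec.upstream_anchor, spec.max_anchor_mismatches)
    if off is None:
        return None, NOCALL_ANCHOR_MISSING
    start = off + len(spec.upstream_anchor)
    barcode = read[start : start + spec.barcode_len]
    if len(barcode) < spec.barcode_len:
        return None, NOCALL_TRUNCATED
    if not set(barcode) <= _VALID_BASES:
        return None, NOCALL_AMBIGUOUS_BASE
    # Confirm the downstream anchor when the read reaches that far.
    down = spec.downstream_anchor
    dstart = start + spec.barcode_len
    if len(read) >= dstart + len(down):
        window = read[dstart : dstart + len(down)]
        mm = sum(a != b for a, b in zip(window, down))
        if mm > spec.max_anchor_mismatches:
            return None, NOCALL_ANCHOR_MISSING
    return barcode, None


@dataclass
class ExtractionReport:
    """Per-sample tally of reads seen, recognized, and no-calls by reason."""

    sample: str
    total: int = 0
    recognized: int = 0
    no_call: Counter = field(default_factory=Counter)

    @property
    def no_call_total(self) -> int:
        return sum(self.no_call.values())

    def as_dict(self) -> dict:
        d = {"sample": self.sample, "total": self.total, "recognized": self.recognized}
        for reason in (NOCALL_ANCHOR_MISSING, NOCALL_AMBIGUOUS_BASE, NOCALL_TRUNCATED):
            d[reason] = self.no_call.get(reason, 0)
        return d


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_fastq(path: str | Path) -> Iterable[tuple[str, str, str]]:
    """Yield ``(title, sequence, quality)`` tuples from a (possibly
    gzipped) FASTQ file, raising with the failing record index on a
    malformed record."""
    n = 0
    with _open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {n} in {path}: {exc}") from exc
            n += 1
            yield rec


def count_sample(
    fastq_path: str | Path, spec: CassetteSpec, sample_label: str
) -> tuple[Counter, ExtractionReport]:
    """Count barcodes in one per-sample FASTQ.

    Returns ``(counts, report)`` where ``report.recognized +
    report.no_call_total == report.total``.
    """
    counts: Counter = Counter()
    report = ExtractionReport(sample=sample_label)
    for _title, seq, _qual in iter_fastq(fastq_path):
        report.total += 1
        barcode, reason = extract_barcode(seq, spec)
        if barcode is None:
            report.no_call[reason] += 1
        else:
            counts[barcode] += 1
            report.recognized += 1
    return counts, report


class CountMatrix:
    """Integer barcode × sample read-count table.

    Thin wrapper over a :class:`pandas.DataFrame` (rows: barcodes in
    lexicographic order; columns: sample labels) plus the per-sample
    recognized-read totals, which by construction equal the column sums.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            raise ValueError("duplicate barcode rows")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample labels")
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.df = counts.sort_index().astype(int)
        self.df.index.name = "barcode"

    @property
    def barcodes(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    @property
    def totals(self) -> pd.Series:
        """Recognized reads per sample (column sums)."""
        return self.df.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.df.equals(other.df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="barcode", dtype={"barcode": str})
        return cls(df)


def build_count_matrix(
    sample_counts: Mapping[str, Mapping[str, int]] | Sequence[tuple[str, Mapping[str, int]]],
) -> CountMatrix:
    """Assemble per-sample barcode counts into one matrix.

    ``sample_counts`` maps sample label → {barcode: count} (a sequence of
    pairs is accepted too, and duplicate labels are rejected).  The row
    set is the union of barcodes; missing cells are zero; rows are sorted
    lexicographically.
    """
    pairs = list(sample_counts.items()) if isinstance(sample_counts, Mapping) else list(sample_counts)
    labels = [label for label, _ in pairs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate sample labels in {labels}")
    if not pairs:
        raise ValueError("at least one sample is required")
    df = pd.DataFrame(
        {label: pd.Series(dict(counts), dtype="int64") for label, counts in pairs}
    ).fillna(0)
    df.index = df.index.astype(str)
    return CountMatrix(df[labels])


def write_reports(reports: Sequence[ExtractionReport], path: str | Path) -> None:
    pd.DataFrame([r.as_dict() for r in reports]).to_csv(path, sep="\t", index=False)


def collapse_barcodes(counts: Mapping[str, int], min_ratio: int = 10) -> Counter:
    """Optional directional error-collapse of barcode counts.

    A barcode is absorbed into a Hamming-distance-1 neighbour whose count
    is at least ``min_ratio`` times its own (the dominant neighbour wins).
    Off by default in the pipeline: the screen protocol describes no
    barcode error correction, and the anchored fixed-length extraction
    already rejects most artefacts.
    """
    merged = Counter(dict(counts))
    for bc in sorted(merged, key=lambda b: (merged[b], b)):
        best = None
        for i, base in enumerate(bc):
            for alt in "ACGT":
                if alt == base:
                    continue
                nb = bc[:i] + alt + bc[i + 1 :]
                c = merged.get(nb, 0)
                if c >= min_ratio * merged[bc] and (best is None or c > merged[best]):
                    best = nb
        if best is not None:
            merged[best] += merged[bc]
            del merged[bc]
    return merged
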