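"""Demultiplexing, quality filtering and tag extraction from multiplexed FASTQ.

Pipeline per read: quality filter -> barcode demultiplex -> tag
extraction (skip barcode, digitally remove the degenerate bases, require
an exact anchor match, emit the following tag_len bases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .layout import LibraryLayout
from .synthetic_data import SampleSheet

UNASSIGNED = "unassigned"


@dataclass
class ReadRecord:
    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class ExtractionStats:
    """Per-run accounting; reads_total reconciles exactly with the outcomes."""

    reads_total: int = 0
    reads_failed_quality: int = 0
    reads_no_barcode: int = 0
    reads_no_anchor: int = 0
    tags_emitted: int = 0
    per_sample: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        assert self.reads_total == (
            self.reads_failed_quality + self.reads_no_barcode + self.reads_no_anchor + self.tags_emitted
        ), "extraction accounting does not reconcile"
        assert self.tags_emitted == sum(self.per_sample.values())

    def as_dict(self) -> dict:
        return {
            "reads_total": self.reads_total,
            "reads_failed_quality": self.reads_failed_quality,
            "reads_no_barcode": self.reads_no_barcode,
            "reads_no_anchor": self.reads_no_anchor,
            "tags_emitted": self.tags_emitted,
            "per_sample": dict(self.per_sample),
        }


def quality_filter(
    read: ReadRecord,
    poor_accuracy_threshold: float = 0.5,
    max_poor_fraction: float = 0.20,
) -> tuple[bool, str]:
    """Pass/fail by the fraction of low-accuracy base calls.

    A base is poor when its Phred-implied accuracy ``1 - 10**(-Q/10)``
    falls below ``poor_accuracy_threshold``; the read fails iff the poor
    fraction strictly exceeds ``max_poor_fraction``. Returns
    ``(passed, reason)``.
    """
    if not read.qualities:
        return False, "empty_read"
    n_poor = sum(1 for q in read.qualities if 1.0 - 10.0 ** (-q / 10.0) < poor_accuracy_threshold)
    if n_poor / len(read.qualities) > max_poor_fraction:
        return False, "poor_quality"
    return True, "ok"


def demultiplex(read: ReadRecord, sample_sheet: SampleSheet, max_mismatch: int = 0) -> str:
    """Assign a read to the sample whose barcode uniquely best-matches its prefix.

    Ties and matches beyond ``max_mismatch`` yield the sentinel
    ``"unassigned"`` (a value, not an error).
    """
    best_sample, best_dist, tied = UNASSIGNED, max_mismatch + 1, False
    for sample_id, barcode in sample_sheet.barcode_of.items():
        prefix = read.sequence[: len(barcode)]
        if len(prefix) < len(barcode):
            continue
        dist = sum(a != b for a, b in zip(prefix, barcode))
        if dist < best_dist:
            best_sample, best_dist, tied = sample_id, dist, False
        elif dist == best_dist:
            tied = True
    if tied or best_dist > max_mismatch:
        return UNASSIGNED
    return best_sample


def extract_tag(read: ReadRecord, layout: LibraryLayout) -> tuple[str | None, str]:
    """Extract the tag from a demultiplexed read.

    Skips the barcode, discards the degenerate bases (the digital
    removal), requires an exact anchor, and returns the next ``tag_len``
    bases uppercased. Returns ``(tag, "ok")`` or ``(None, reason)`` with
    reason ``"truncated"`` or ``"no_anchor"``.
    """
    seq = read.sequence.upper()
    if len(seq) < layout.min_read_len:
        return None, "truncated"
    start = layout.barcode_len + layout.degenerate_len
    if seq[start : start + layout.anchor_len] != layout.anchor:
        return None, "no_anchor"
    tag = seq[layout.tag_start : layout.tag_start + layout.tag_len]
    return tag, "ok"


def iter_fastq(path: str | Path) -> Iterator[ReadRecord]:
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield ReadRecord(title.split()[0], seq, [ord(c) - 33 for c in qual])


def process_reads(
    reads: Iterable[ReadRecord],
    sample_sheet: SampleSheet,
    layout: LibraryLayout | None = None,
    *,
    max_mismatch: int = 0,
    poor_accuracy_threshold: float = 0.5,
    max_poor_fraction: float = 0.20,
) -> tuple[dict[str, list[str]], ExtractionStats]:
    """Run the full per-read pipeline; returns per-sample tag lists and stats."""
    layout = layout or LibraryLayout()
    tags: dict[str, list[str]] = {s: [] for s in sample_sheet.sample_ids}
    stats = ExtractionStats(per_sample={s: 0 for s in sample_sheet.sample_ids})
    for read in reads:
        stats.reads_total += 1
        ok, _ = quality_filter(read, poor_accuracy_threshold, max_poor_fraction)
        if not ok:
            stats.reads_failed_quality += 1
            continue
        sample = demultiplex(read, sample_sheet, max_mismatch)
        if sample == UNASSIGNED:
            stats.reads_no_barcode += 1
            continue
        tag, _ = extract_tag(read, layout)
        if tag is None:
            stats.reads_no_anchor += 1
            continue
        tags[sample].append(tag)
        stats.tags_emitted += 1
        stats.per_sample[sample] += 1
    stats.check()
    return tags, stats


def process_fastq(path: str | Path, sample_sheet: SampleSheet, layout: LibraryLayout | None = None, **kw):
    """Convenience wrapper: :func:`process_reads` over a FASTQ file."""
    return process_reads(iter_fastq(path), sample_sheet, layout, **kw)
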