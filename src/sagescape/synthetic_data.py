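"""Synthetic inputs for the tag-profiling pipeline.

Generates every artifact the downstream stages consume — a transcriptome
FASTA, a sample sheet, a block-structured expression matrix with
tissue-specific clusters, multiplexed FASTQ reads following a
:class:`~sagescape.layout.LibraryLayout`, and promoter sets with planted
PWM sites — together with the ground truth needed to score recovery.

All generators are deterministic for a fixed seed and configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .layout import LayoutError, LibraryLayout

UNTAGGABLE = "untaggable"

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# arbitrary fixed filler appended 3' of the tag so reads reach read_len;
# stands in for the real 3' linker sequence, which is not modelled
_LINKER_FILL = "TCGTATGCCGTCTTCTGCTTGAAAAAAAAAAAAAAAAAAAAAAAAAAA"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


@dataclass
class SampleSheet:
    """Rows of (sample_id, tissue, barcode); barcodes unique per run."""

    frame: pd.DataFrame  # columns: sample_id, tissue, barcode

    def __post_init__(self) -> None:
        required = {"sample_id", "tissue", "barcode"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        barcodes = self.frame["barcode"]
        if barcodes.duplicated().any():
            dup = sorted(barcodes[barcodes.duplicated()].unique())
            raise ValueError(f"barcode collision in sample sheet: {dup}")
        if len(set(barcodes.str.len())) > 1:
            raise ValueError("barcodes must all have the same length")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def barcode_of(self) -> dict[str, str]:
        return dict(zip(self.frame["sample_id"], self.frame["barcode"]))

    def tissue_of(self) -> dict[str, str]:
        return dict(zip(self.frame["sample_id"], self.frame["tissue"]))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    expression: pd.DataFrame | None = None  # transcripts x samples
    cluster_of: dict[str, int] = field(default_factory=dict)
    tissue_of: dict[str, str] = field(default_factory=dict)
    tag_of: dict[str, str] = field(default_factory=dict)
    planted_motif_positions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)


def _strip_anchor(seq: list[str], anchor: str, rng: np.random.Generator, start: int = 0) -> None:
    """Mutate `seq` in place until it contains no anchor at offset >= start."""
    text = "".join(seq)
    pos = text.find(anchor, start)
    while pos != -1:
        old = seq[pos + 1]
        seq[pos + 1] = str(rng.choice([b for b in "ACGT" if b != old]))
        text = "".join(seq)
        pos = text.find(anchor, start)


def simulate_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int] = (200, 600),
    gc: float = 0.45,
    seed: int = 0,
    *,
    layout: LibraryLayout | None = None,
    untaggable_fraction: float = 0.02,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Generate sense-strand transcript sequences plus their expected tags.

    Every taggable transcript is guaranteed to carry at least one anchor
    with >= tag_len bases 3' of it; a configurable fraction are generated
    anchor-free as untaggable controls. Returns ``(records, tag_of)`` where
    records are ``(id, sequence)`` pairs and ``tag_of`` maps transcript id
    to its tag (the tag_len bases 3' of the 3'-most anchor) or
    ``"untaggable"``.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    layout = layout or LibraryLayout()
    lo, hi = length_range
    if lo > hi or lo < layout.anchor_len + layout.tag_len:
        raise LayoutError(
            f"length_range {length_range} cannot host anchor+tag "
            f"({layout.anchor_len + layout.tag_len} nt)"
        )
    rng = np.random.default_rng(seed)
    n_untag = int(round(untaggable_fraction * n_transcripts))
    untag_idx = set(rng.choice(n_transcripts, size=n_untag, replace=False)) if n_untag else set()

    records: list[tuple[str, str]] = []
    tag_of: dict[str, str] = {}
    for i in range(n_transcripts):
        tid = f"T{i:05d}"
        length = int(rng.integers(lo, hi + 1))
        seq = list(_random_seq(rng, length, gc))
        if i in untag_idx:
            _strip_anchor(seq, layout.anchor, rng)
            tag_of[tid] = UNTAGGABLE
        else:
            margin = int(rng.integers(0, 3))
            pos = length - layout.anchor_len - layout.tag_len - margin
            pos = max(pos, 0)
            seq[pos : pos + layout.anchor_len] = list(layout.anchor)
            # the planted anchor must stay 3'-most
            _strip_anchor(seq, layout.anchor, rng, start=pos + 1)
            tag_of[tid] = "".join(seq[pos + layout.anchor_len : pos + layout.anchor_len + layout.tag_len])
        records.append((tid, "".join(seq)))
    return records, tag_of


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def make_sample_sheet(
    tissues: Sequence[str],
    reps_per_tissue: int,
    *,
    barcode_len: int = 6,
    seed: int = 0,
) -> SampleSheet:
    """Build a sample sheet with one unique random barcode per sample."""
    rng = np.random.default_rng(seed)
    n = len(tissues) * reps_per_tissue
    barcodes: set[str] = set()
    while len(barcodes) < n:
        barcodes.add("".join(_BASES[rng.integers(0, 4, size=barcode_len)]))
    ordered = sorted(barcodes)
    rng.shuffle(ordered)
    rows = []
    k = 0
    for tissue in tissues:
        for rep in range(1, reps_per_tissue + 1):
            rows.append({"sample_id": f"{tissue}_{rep}", "tissue": tissue, "barcode": ordered[k]})
            k += 1
    return SampleSheet(pd.DataFrame(rows))


def block_design(n_clusters: int, tissues: Sequence[str], tissues_per_cluster: int = 1) -> dict[int, list[str]]:
    """Assign each cluster a block of tissues where it is highly expressed."""
    design = {}
    for c in range(1, n_clusters + 1):
        start = ((c - 1) * tissues_per_cluster) % len(tissues)
        design[c] = [tissues[(start + j) % len(tissues)] for j in range(tissues_per_cluster)]
    return design


def simulate_expression(
    transcript_ids: Sequence[str],
    design: Mapping[int, Sequence[str]],
    tissues: Sequence[str],
    reps_per_tissue: int,
    *,
    basal: float = 10.0,
    fold: float = 8.0,
    sigma: float = 0.3,
    basal_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int], dict[str, str]]:
    """Block-structured tissue expression with lognormal replicate noise.

    Transcripts are assigned round-robin to the clusters of ``design``;
    a transcript is expressed at ``basal * fold`` in its cluster's high
    tissues and at ``basal`` elsewhere, with multiplicative lognormal
    noise of scale ``sigma`` per replicate. Returns the abundance matrix
    (transcripts x samples) plus cluster and tissue ground truth.
    """
    if reps_per_tissue < 2:
        warnings.warn("reps_per_tissue < 2: differential-expression stage needs replication")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    rng = np.random.default_rng(seed)
    labels = sorted(design)
    cluster_of = {tid: labels[i % len(labels)] for i, tid in enumerate(transcript_ids)}
    samples = [f"{t}_{r}" for t in tissues for r in range(1, reps_per_tissue + 1)]
    tissue_of = {s: s.rsplit("_", 1)[0] for s in samples}

    base = np.full((len(transcript_ids), len(samples)), basal)
    if basal_sigma > 0:  # per-transcript dynamic range, shared across samples
        base = base * rng.lognormal(0.0, basal_sigma, size=len(transcript_ids))[:, None]
    for i, tid in enumerate(transcript_ids):
        high = set(design[cluster_of[tid]])
        for j, s in enumerate(samples):
            if tissue_of[s] in high:
                base[i, j] *= fold
    if sigma > 0:
        base = base * rng.lognormal(mean=0.0, sigma=sigma, size=base.shape)
    expr = pd.DataFrame(base, index=list(transcript_ids), columns=samples)
    return expr, cluster_of, tissue_of


def simulate_reads(
    expression: pd.DataFrame,
    tag_of: Mapping[str, str],
    sample_sheet: SampleSheet,
    layout: LibraryLayout,
    depth: int,
    error_rate: float = 0.0,
    seed: int = 0,
    *,
    base_quality: int = 35,
    low_quality_fraction: float = 0.0,
    low_quality_q: int = 2,
    path: str | Path | None = None,
    shuffle: bool = True,
) -> list[tuple[str, str, str]]:
    """Emit multiplexed single-end reads as (id, sequence, quality) tuples.

    Each read is ``barcode + degenerate bases + anchor + tag + linker
    fill`` trimmed to ``read_len``; per-sample tags are drawn multinomially
    in proportion to the expression of taggable transcripts, the tag is
    mutated at ``error_rate`` per base, and Phred+33 qualities are
    attached (uniform ``base_quality``, with ``low_quality_fraction`` of
    reads degraded to ``low_quality_q`` for filter testing). If ``path``
    is given the reads are also written as FASTQ.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    barcode_of = sample_sheet.barcode_of
    taggable = [t for t in expression.index if tag_of.get(t, UNTAGGABLE) != UNTAGGABLE]
    reads: list[tuple[str, str, str]] = []
    if not taggable:
        warnings.warn("no taggable transcripts expressed; zero reads emitted")
    else:
        fill = (_LINKER_FILL * 4)[: layout.read_len]  # ample fixed filler
        hi_q = chr(base_quality + 33)
        lo_q = chr(low_quality_q + 33)
        n = 0
        for sample_id in sample_sheet.sample_ids:
            barcode = barcode_of[sample_id]
            w = expression.loc[taggable, sample_id].to_numpy(dtype=float)
            if w.sum() <= 0:
                warnings.warn(f"sample {sample_id} has zero taggable expression; skipped")
                continue
            counts = rng.multinomial(depth, w / w.sum())
            for tid, c in zip(taggable, counts):
                tag = tag_of[tid]
                for _ in range(c):
                    t = tag
                    if error_rate > 0:
                        t = _mutate(t, error_rate, rng)
                    degen = "".join(_BASES[rng.integers(0, 4, size=layout.degenerate_len)])
                    seq = (barcode + degen + layout.anchor + t + fill)[: layout.read_len]
                    if low_quality_fraction > 0 and rng.random() < low_quality_fraction:
                        qual = lo_q * len(seq)
                    else:
                        qual = hi_q * len(seq)
                    reads.append((f"read{n:08d}_{sample_id}_{tid}", seq, qual))
                    n += 1
        if shuffle:
            order = rng.permutation(len(reads))
            reads = [reads[i] for i in order]
    if path is not None:
        write_fastq(reads, path)
    return reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def simulate_promoters(
    n_fore: int,
    n_back: int,
    pwm,
    plant_rate: float,
    *,
    length: int = 1000,
    gc: float = 0.45,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], dict[str, list[tuple[int, str]]]]:
    """Foreground promoters with PWM-sampled planted sites plus GC-matched background.

    Each foreground sequence independently receives one sampled site with
    probability ``plant_rate`` at a uniform offset on a random strand.
    Returns (foreground records, background records, planted positions).
    """
    if not 0 <= plant_rate <= 1:
        raise ValueError("plant_rate must lie in [0, 1]")
    if pwm.width >= length:
        raise ValueError("PWM wider than promoter length")
    rng = np.random.default_rng(seed)
    planted: dict[str, list[tuple[int, str]]] = {}
    fore = []
    for i in range(n_fore):
        pid = f"P{i:04d}"
        seq = list(_random_seq(rng, length, gc))
        planted[pid] = []
        if rng.random() < plant_rate:
            site = pwm.sample_site(rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                site = reverse_complement(site)
            off = int(rng.integers(0, length - pwm.width + 1))
            seq[off : off + pwm.width] = list(site)
            planted[pid].append((off, strand))
        fore.append((pid, "".join(seq)))
    back = [(f"B{i:04d}", _random_seq(rng, length, gc)) for i in range(n_back)]
    return fore, back, planted
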