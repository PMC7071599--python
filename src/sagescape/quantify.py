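"""Tag counting, transcript assignment with multi-map averaging, normalization.

A tag mapping to *k* transcripts contributes ``count / k`` to each, so the
total assigned mass plus the unmatched-tag mass equals the counted mass
exactly. Quantile normalization forces every sample onto the mean sorted
distribution, resolving within-column ties to the mean of the reference
values they span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tagref import TagReference

SCALES = ("raw", "quantile_normalized", "log2")


@dataclass
class ExpressionMatrix:
    """Transcripts x samples values with an explicit scale flag."""

    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}")
        if self.scale != "log2" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative entries in a non-log expression matrix")

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str = "raw") -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0), scale)


def count_tags(
    tags_by_sample: Mapping[str, Sequence[str]],
    sample_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Exact multiset counts of tags per sample (tags x samples, int)."""
    samples = list(sample_order) if sample_order is not None else list(tags_by_sample)
    cols = {}
    for s in samples:
        tags = tags_by_sample.get(s, [])
        if len(tags) == 0:
            warnings.warn(f"sample {s} emitted no tags; all-zero column")
        cols[s] = pd.Series(tags, dtype="object").value_counts()
    mat = pd.DataFrame(cols).fillna(0).astype(np.int64)
    return mat.reindex(columns=samples, fill_value=0).sort_index()


def assign_to_transcripts(
    counts: pd.DataFrame, ref: TagReference
) -> tuple[ExpressionMatrix, dict]:
    """Distribute tag counts over transcripts through the reference.

    A tag mapped to k transcripts is split evenly (count/k each); tags
    absent from the reference are tallied as unmatched mass, never
    assigned. Returns the raw expression matrix and a conservation report.
    """
    bad = [t for t in counts.index if len(t) != ref.tag_len]
    if bad:
        raise ValueError(f"tag length mismatch vs reference tag_len={ref.tag_len}: {bad[:3]}")
    transcripts = sorted({tid for ids in ref.tag_index.values() for tid in ids} | set(ref.untaggable))
    row_of = {tid: i for i, tid in enumerate(transcripts)}
    acc = np.zeros((len(transcripts), counts.shape[1]))
    unmatched = np.zeros(counts.shape[1])
    for tag, row in zip(counts.index, counts.to_numpy(dtype=float)):
        ids = ref.tag_index.get(tag)
        if not ids:
            unmatched += row
            continue
        share = row / len(ids)
        for tid in ids:
            acc[row_of[tid]] += share
    expr = pd.DataFrame(acc, index=transcripts, columns=counts.columns)
    report = {
        "total_mass": float(counts.to_numpy().sum()),
        "assigned_mass": float(acc.sum()),
        "unmatched_mass": float(unmatched.sum()),
        "unmatched_per_sample": dict(zip(counts.columns, unmatched.tolist())),
    }
    return ExpressionMatrix(expr, "raw"), report


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the across-sample mean sorted distribution."""
    if m.values.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = m.values.to_numpy(dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(ref)
        mapped[order] = ref
        # ties take the mean of the reference values they span
        s = pd.Series(mapped).groupby(col, sort=False).transform("mean")
        out[:, j] = s.to_numpy()
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        "quantile_normalized",
    )


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise ``log2(x + pseudocount)``."""
    if m.scale == "log2":
        raise ValueError("matrix already log2-scaled")
    x = m.values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative entries; cannot log-transform")
    out = np.log2(x + pseudocount)
    return ExpressionMatrix(pd.DataFrame(out, index=m.values.index, columns=m.values.columns), "log2")
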