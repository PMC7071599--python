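"""PWM over-representation in promoter sets versus a matched background.

A motif's likelihood ratio at a site is the product over positions of
``pwm[j, base] / background[base]``; a sequence's score is the arithmetic
mean of the site ratios over both strands, and a set's raw score is the
sum of ``ln(avg_lr)`` over its sequences (negative when the motif is
depleted). Significance comes from randomization: either drawing
size-matched sets from a background pool or shuffling bases within each
foreground sequence, with the add-one rule so p never reaches 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGT"
DEFAULT_PSEUDOCOUNT = 0.375
DEFAULT_LR_THRESHOLD = 2.0 ** 6


@dataclass
class MotifPWM:
    """Position probability matrix in A, C, G, T column order."""

    id: str
    name: str
    probs: np.ndarray  # width x 4, rows sum to 1
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"motif {self.id}: probs must be width x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.id}: probability rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, id: str, name: str, counts: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> "MotifPWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(id, name, counts / counts.sum(axis=1, keepdims=True), pseudocount)

    def information_content(self, background: np.ndarray | None = None) -> float:
        """Total information in bits relative to the background."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        p = np.clip(self.probs, 1e-12, None)
        return float((p * np.log2(p / bg)).sum())

    def sample_site(self, rng: np.random.Generator) -> str:
        return "".join(_BASES[rng.choice(4, p=row / row.sum())] for row in self.probs)


def read_jaspar(path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[MotifPWM]:
    """Parse JASPAR flat-format PWMs (">ID NAME" then four base count rows).

    Counts (or probabilities) get ``pseudocount`` added per cell before
    row-wise normalization. Ragged matrices raise, naming the motif.
    """
    motifs: list[MotifPWM] = []
    header: tuple[str, str] | None = None
    rows: dict[str, list[float]] = {}

    def _flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        mid, name = header
        missing = [b for b in _BASES if b not in rows]
        if missing:
            raise ValueError(f"motif {mid}: missing base row(s) {missing}")
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise ValueError(f"motif {mid}: ragged count rows (widths {sorted(widths)})")
        counts = np.column_stack([rows[b] for b in _BASES])
        motifs.append(MotifPWM.from_counts(mid, name, counts, pseudocount))
        header, rows = None, {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                parts = line[1:].split(None, 1)
                header = (parts[0], parts[1] if len(parts) > 1 else parts[0])
            else:
                if header is None:
                    raise ValueError("count row before any motif header")
                base = line[0].upper()
                body = line[1:].replace("[", " ").replace("]", " ")
                rows[base] = [float(v) for v in body.split()]
    _flush()
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs


def write_jaspar(motifs: Sequence[MotifPWM], path: str | Path) -> None:
    """Write PWMs in JASPAR flat format (probability rows, full precision)."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.id} {m.name}\n")
            for b in _BASES:
                vals = " ".join(f"{v:.12g}" for v in m.probs[:, _BASE_INDEX[b]])
                fh.write(f"{b} [ {vals} ]\n")


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(c, 4) for c in seq.upper()], dtype=np.int64)


def _site_lrs_one_strand(codes: np.ndarray, log_ratio: np.ndarray) -> np.ndarray:
    w = log_ratio.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return np.exp(log_ratio[np.arange(w), windows].sum(axis=1))


def sequence_score(
    seq: str, pwm: MotifPWM, background: np.ndarray | Sequence[float] | None = None
) -> tuple[float, np.ndarray]:
    """Average likelihood ratio of a sequence under a PWM, both strands.

    Positions containing N contribute a neutral factor of 1. Returns
    ``(avg_lr, site_lrs)`` where site_lrs concatenates forward then
    reverse-strand site ratios.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if (bg <= 0).any():
        raise ValueError("background frequencies must be strictly positive")
    if len(seq) < pwm.width:
        raise ValueError(f"sequence shorter than motif width {pwm.width}")
    p = np.clip(pwm.probs, 1e-300, None)
    # column 4 = N: neutral log-ratio 0
    lr_fwd = np.zeros((pwm.width, 5))
    lr_fwd[:, :4] = np.log(p / bg)
    # reverse strand: scanning forward with the reverse-complemented matrix
    lr_rev = np.zeros((pwm.width, 5))
    lr_rev[:, :4] = np.log(p[::-1, ::-1] / bg[::-1])
    codes = _encode(seq)
    site_lrs = np.concatenate(
        [_site_lrs_one_strand(codes, lr_fwd), _site_lrs_one_strand(codes, lr_rev)]
    )
    return float(site_lrs.mean()), site_lrs


def set_raw_score(
    sequences: Sequence[str], pwm: MotifPWM, background=None
) -> float:
    """Sum over sequences of ln(average likelihood ratio)."""
    if not sequences:
        raise ValueError("empty sequence set")
    total = 0.0
    for s in sequences:
        avg, _ = sequence_score(s, pwm, background)
        if avg <= 0:
            raise ValueError("non-positive average likelihood ratio")
        total += float(np.log(avg))
    return total


def background_frequencies(sequences: Sequence[str]) -> np.ndarray:
    """Mononucleotide frequencies over a sequence pool (N excluded)."""
    counts = np.zeros(4)
    for s in sequences:
        codes = _encode(s)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no unambiguous bases in pool")
    return counts / counts.sum()


def randomization_p(
    foreground: Sequence[str],
    pwm: MotifPWM,
    background_pool: Sequence[str],
    n_rand: int = 1000,
    strategy: str = "draw_matched_background",
    seed: int = 0,
    background=None,
) -> tuple[float, float]:
    """Add-one randomization p-value for a foreground set's raw score.

    ``draw_matched_background`` scores size-matched draws (without
    replacement) from the pool; ``shuffle_mononucleotide`` permutes bases
    within each foreground sequence. Returns (p, observed raw score).
    """
    if n_rand < 19:
        raise ValueError("n_rand < 19 cannot resolve p <= 0.05")
    if strategy not in ("draw_matched_background", "shuffle_mononucleotide"):
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    if background is None:
        background = background_frequencies(background_pool)
    observed = set_raw_score(foreground, pwm, background)
    pool = list(background_pool)
    n_ge = 0
    if strategy == "draw_matched_background":
        if len(pool) < len(foreground):
            raise ValueError("background pool smaller than foreground set")
        # a drawn set's raw score is a sum of per-sequence terms: score the
        # pool once and resample sums instead of rescanning every replicate
        pool_scores = np.array(
            [np.log(sequence_score(s, pwm, background)[0]) for s in pool]
        )
        for _ in range(n_rand):
            idx = rng.choice(len(pool), size=len(foreground), replace=False)
            if pool_scores[idx].sum() >= observed:
                n_ge += 1
    else:
        for _ in range(n_rand):
            rand_set = ["".join(rng.permutation(list(s))) for s in foreground]
            if set_raw_score(rand_set, pwm, background) >= observed:
                n_ge += 1
    return (1 + n_ge) / (1 + n_rand), observed


def site_calls(
    sequences: Sequence[str],
    pwm: MotifPWM,
    background=None,
    lr_threshold: float = DEFAULT_LR_THRESHOLD,
) -> tuple[int, int]:
    """(occurrence, gene_count) of above-threshold sites across a set.

    Occurrence counts every site (both strands, overlaps independent);
    gene count is the number of sequences with at least one site.
    """
    if lr_threshold <= 0:
        raise ValueError("lr_threshold must be positive")
    occurrence = gene_count = 0
    for s in sequences:
        _, lrs = sequence_score(s, pwm, background)
        hits = int((lrs > lr_threshold).sum())
        occurrence += hits
        gene_count += hits > 0
    return occurrence, gene_count


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def enrichment_report(
    clusters: Mapping[object, Sequence[str]],
    motifs: Sequence[MotifPWM],
    background_pool: Sequence[str],
    alpha: float = 0.05,
    n_rand: int = 1000,
    strategy: str = "draw_matched_background",
    lr_threshold: float = DEFAULT_LR_THRESHOLD,
    seed: int = 0,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Per-cluster motif over-representation table.

    Columns: cluster, jaspar_id, tf_name, occurrence, gene_count,
    raw_score, p, fdr (BH across motifs within the cluster), significant.
    Rows are sorted by raw score within each cluster; ``top_n`` truncates
    each cluster's block.
    """
    background = background_frequencies(background_pool)
    frames = []
    for ci, (cluster, seqs) in enumerate(clusters.items()):
        seqs = list(seqs)
        if not seqs:
            warnings.warn(f"cluster {cluster!r}: empty promoter set, skipped")
            continue
        rows = []
        for mi, m in enumerate(motifs):
            p, raw = randomization_p(
                seqs, m, background_pool, n_rand=n_rand, strategy=strategy,
                seed=hash((seed, ci, mi)) % (2**32), background=background,
            )
            occ, genes = site_calls(seqs, m, background, lr_threshold)
            rows.append(
                {"cluster": cluster, "jaspar_id": m.id, "tf_name": m.name,
                 "occurrence": occ, "gene_count": genes, "raw_score": raw, "p": p}
            )
        block = pd.DataFrame(rows)
        block["fdr"] = _bh_adjust(block["p"].to_numpy())
        block["significant"] = block["fdr"] <= alpha
        block = block.sort_values("raw_score", ascending=False)
        if top_n is not None:
            block = block.head(top_n)
        frames.append(block)
    if not frames:
        raise ValueError("no non-empty clusters")
    return pd.concat(frames, ignore_index=True)
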