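"""Rarefaction / saturation analysis of per-sample tag libraries.

Classical subsampling without replacement: at each depth, reads are drawn
from the sample's read multiset and the number of distinct transcripts
discovered is averaged over replicates. The closed-form expectation
``E[discovered at d] = sum_t [1 - C(N - n_t, d) / C(N, d)]`` is exposed
for verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln


@dataclass
class RarefactionCurve:
    sample_id: str
    depths: np.ndarray
    discovered: np.ndarray  # mean distinct transcripts per depth
    sd: np.ndarray
    n_reps: int

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.discovered) >= -1e-9), "discovery must be non-decreasing"


def default_depth_grid(total: int, n_points: int = 20) -> np.ndarray:
    """Log-spaced depths from 1 to the library total."""
    grid = np.unique(np.round(np.logspace(0, np.log10(total), n_points)).astype(int))
    return grid[grid <= total]


def rarefy(
    counts,
    depth_grid=None,
    n_reps: int = 10,
    seed: int = 0,
    sample_id: str = "sample",
) -> RarefactionCurve:
    """Mean distinct-transcript discovery over subsampled depths.

    ``counts`` is the per-transcript read-count vector of one sample.
    Draws are without replacement (multivariate hypergeometric).
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if total == 0:
        raise ValueError("empty library")
    if depth_grid is None:
        depth_grid = default_depth_grid(total)
    depth_grid = np.asarray(sorted(depth_grid), dtype=np.int64)
    if depth_grid.size and depth_grid[-1] > total:
        raise ValueError(f"depth {depth_grid[-1]} exceeds library total {total}")
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for d in depth_grid:
        if d == 0:
            means.append(0.0)
            sds.append(0.0)
            continue
        if d == total:
            means.append(float(np.count_nonzero(counts)))
            sds.append(0.0)
            continue
        vals = [
            np.count_nonzero(rng.multivariate_hypergeometric(counts, int(d)))
            for _ in range(n_reps)
        ]
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals, ddof=1)) if n_reps > 1 else 0.0)
    return RarefactionCurve(sample_id, depth_grid, np.array(means), np.array(sds), n_reps)


def expected_discovered(counts, depth: int) -> float:
    """Closed-form hypergeometric expectation of distinct transcripts at a depth."""
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    n = int(counts.sum())
    if depth > n:
        raise ValueError("depth exceeds library total")
    # P(transcript unseen) = C(N - n_t, d) / C(N, d), via log-gammas
    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    p_unseen = np.where(
        n - counts >= depth,
        np.exp(logc(n - counts, depth) - logc(n, depth)),
        0.0,
    )
    return float(np.sum(1.0 - p_unseen))


def saturation_index(curve: RarefactionCurve) -> float:
    """Discovery at half depth over discovery at full depth (1 = saturated)."""
    if len(curve.depths) < 2:
        raise ValueError("curve needs >= 2 depths")
    full = curve.discovered[-1]
    if full <= 0:
        raise ValueError("degenerate curve: nothing discovered at full depth")
    half = float(np.interp(curve.depths[-1] / 2.0, curve.depths, curve.discovered))
    return half / float(full)


def curve_table(curves) -> "pd.DataFrame":  # noqa: F821 - optional import
    import pandas as pd

    rows = []
    for c in curves:
        for d, m, s in zip(c.depths, c.discovered, c.sd):
            rows.append({"sample": c.sample_id, "depth": int(d), "mean_discovered": m, "sd": s})
    return pd.DataFrame(rows)
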