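"""Alpha diversity: bias-corrected Chao1, Shannon entropy (natural log) and
rarefaction averaging by multivariate-hypergeometric subsampling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountTable

DEFAULT_DEPTH = 10_000
DEFAULT_REPS = 1000


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1)).

    F1/F2 are the singleton/doubleton counts; the +1 in the denominator keeps
    the estimator defined when no doubletons are observed."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    present = counts[counts > 0]
    if present.size == 0:
        return 0.0
    s_obs = present.size
    f1 = int((present == 1).sum())
    f2 = int((present == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy -sum p ln p over non-zero proportions."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count must be > 0")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


@dataclass
class DiversityEstimate:
    sample_id: str
    chao1: float
    shannon: float
    depth: int
    reps: int


def rarefied_alpha(
    counts: np.ndarray,
    depth: int = DEFAULT_DEPTH,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    sample_id: str = "",
) -> DiversityEstimate:
    """Mean Chao1 and Shannon over repeated subsamples without replacement."""
    counts = np.asarray(counts).astype(np.int64)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds sample depth {total}")
    rng = np.random.default_rng(seed)
    if depth == total:
        return DiversityEstimate(sample_id, chao1(counts), shannon(counts), depth, reps)
    c_sum = 0.0
    s_sum = 0.0
    for _ in range(reps):
        sub = rng.multivariate_hypergeometric(counts, depth)
        c_sum += chao1(sub)
        s_sum += shannon(sub)
    return DiversityEstimate(sample_id, c_sum / reps, s_sum / reps, depth, reps)


def diversity_table(
    t: CountTable,
    depth: int = DEFAULT_DEPTH,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> pd.DataFrame:
    """Rarefied alpha diversity for every sample of a count table."""
    rows = []
    for i, sid in enumerate(t.sample_ids):
        est = rarefied_alpha(t.counts[:, i], depth=depth, reps=reps,
                             seed=seed + i, sample_id=sid)
        rows.append({"sample_id": sid, "chao1": est.chao1, "shannon": est.shannon,
                     "depth": depth, "reps": reps})
    return pd.DataFrame(rows)
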