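"""Features tracking progression paths: Spearman statistics with a
permutation false-discovery-rate control and abundance/effect-size filters.

For every feature the statistic is |Spearman rho| between its abundance and
the pseudo-time order of a path. The null distribution is built by permuting
the sample order jointly for all features (preserving the between-feature
correlation structure); the estimated FDR at threshold t is the mean null
exceedance count over the observed exceedance count, and the largest
rejection set with estimated FDR below target is reported. Discoveries are
further filtered by mean relative abundance and a minimum |rho|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable
from .progression import Path

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.01
DEFAULT_MIN_ABUND = 1e-3
DEFAULT_MIN_ABS_RHO = 0.3
DEFAULT_N_PERM = 1000


def spearman_rho(values: np.ndarray, order: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties.

    A constant input has no defined rank correlation; 0 is returned."""
    values = np.asarray(values, dtype=float)
    order = np.asarray(order, dtype=float)
    if values.size != order.size or values.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(values) == 0 or np.ptp(order) == 0:
        return 0.0
    rho = stats.spearmanr(values, order).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def _rho_matrix(X: np.ndarray, order: np.ndarray) -> np.ndarray:
    """|rho|-free Spearman rho of every row of X against ``order`` (vectorised)."""
    ranks_x = stats.rankdata(X, axis=1)
    ranks_o = stats.rankdata(order)
    rx = ranks_x - ranks_x.mean(axis=1, keepdims=True)
    ro = ranks_o - ranks_o.mean()
    denom = np.sqrt((rx**2).sum(axis=1) * (ro**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ro) / denom
    return np.where(np.isfinite(rho), rho, 0.0)


def permutation_fdr(
    X: np.ndarray,
    target_fdr: float = DEFAULT_FDR,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Permutation FDR on |Spearman rho| along the sample order of ``X``.

    ``X`` is features x ordered samples. Returns (threshold, selected feature
    indices, observed rho). The sample order is permuted jointly for all
    features; the threshold is the smallest observed |rho| whose estimated
    FDR is still below target (largest admissible rejection set)."""
    X = np.asarray(X, dtype=float)
    n_feat, n_samp = X.shape
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    order = np.arange(n_samp, dtype=float)
    # rank the data once; permutations only reshuffle the order ranks
    ranks_x = stats.rankdata(X, axis=1)
    rx = ranks_x - ranks_x.mean(axis=1, keepdims=True)
    ro = stats.rankdata(order) - (n_samp + 1) / 2.0
    denom = np.sqrt((rx**2).sum(axis=1) * (ro**2).sum())
    safe = denom > 0

    def rho_for(o_centered: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (rx @ o_centered) / denom
        return np.where(safe, rho, 0.0)

    obs_rho = rho_for(ro)
    obs_abs = np.abs(obs_rho)

    rng = np.random.default_rng(seed)
    null_abs = np.empty((n_perm, n_feat))
    for p in range(n_perm):
        null_abs[p] = np.abs(rho_for(rng.permutation(ro)))

    thresholds = np.unique(obs_abs)[::-1]  # descending candidate thresholds
    null_sorted = np.sort(null_abs.ravel())
    best_t = np.inf
    for t in thresholds:
        if t <= 0:
            break
        n_obs = int((obs_abs >= t).sum())
        mean_null = (null_sorted.size - np.searchsorted(null_sorted, t)) / n_perm
        if mean_null / n_obs <= target_fdr:
            best_t = float(t)  # keep growing the rejection set
        else:
            break
    if not np.isfinite(best_t):
        return np.inf, np.array([], dtype=int), obs_rho
    return best_t, np.flatnonzero(obs_abs >= best_t), obs_rho


@dataclass
class AssociationResult:
    table: pd.DataFrame      # otu_id, path_id, rho, mean_abund, fdr_pass, selected
    fdr_thresholds: dict[int, float]
    n_permutations: int


def select_associated(
    abund: AbundanceTable,
    paths: list[Path],
    orders: dict[int, list[str]],
    fdr: float = DEFAULT_FDR,
    min_abund: float = DEFAULT_MIN_ABUND,
    min_abs_rho: float = DEFAULT_MIN_ABS_RHO,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> AssociationResult:
    """Features changing along at least one progression path.

    ``orders`` maps path_id to the pseudo-time-ordered sample ids of that
    path. A feature is selected if on some path it passes the permutation FDR
    AND has mean relative abundance >= min_abund AND |rho| >= min_abs_rho;
    per-path rho is retained for every feature. Filters are applied after the
    FDR step (conservative for the FDR denominator)."""
    sample_pos = {s: i for i, s in enumerate(abund.sample_ids)}
    rows = []
    thresholds: dict[int, float] = {}
    for path in paths:
        ordered = orders.get(path.path_id)
        if ordered is None or len(ordered) < 3:
            logger.warning("path %s has < 3 ordered samples; skipped", path.path_id)
            continue
        cols = [sample_pos[s] for s in ordered]
        rel = abund.rel[:, cols]
        t, fdr_idx, rho = permutation_fdr(rel, target_fdr=fdr, n_perm=n_perm,
                                          seed=seed + path.path_id)
        thresholds[path.path_id] = t
        fdr_pass = np.zeros(rel.shape[0], dtype=bool)
        fdr_pass[fdr_idx] = True
        mean_rel = rel.mean(axis=1)
        selected = fdr_pass & (mean_rel >= min_abund) & (np.abs(rho) >= min_abs_rho)
        rows.append(pd.DataFrame({
            "otu_id": abund.otu_ids,
            "path_id": path.path_id,
            "rho": rho,
            "mean_abund": mean_rel,
            "fdr_pass": fdr_pass,
            "selected": selected,
        }))
    table = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["otu_id", "path_id", "rho",
                                        "mean_abund", "fdr_pass", "selected"]))
    return AssociationResult(table=table, fdr_thresholds=thresholds, n_permutations=n_perm)
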