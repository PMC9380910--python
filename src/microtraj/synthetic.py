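"""Seeded synthetic datasets with the statistical structure the pipeline
stages assume: compositional count tables sampled along a double-bifurcating
latent trajectory, mean-shifted labelled datasets for feature selection, and
numerically integrated Lotka-Volterra pseudo-series.

The trajectory generator emulates a chronic-disease cohort: subjects carry
short runs of serial samples, healthy controls split into two community
types (the two disease origins), informative taxa follow logistic-shaped
monotone trends in latent time (branch-specific before the merge and after
the split), all other taxa are i.i.d. log-scale noise, and compositions are
closed to integer counts by multinomial draws at a fixed sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .glv import PseudoSeries
from .io import CountTable, SampleMetadata

# stage boundaries of the latent time axis
ORIGIN_END = 0.25    # before: two separate healthy origins
FADE_END = 0.32      # origin identity has fully merged into the trunk
SPLIT_START = 0.6    # after: two separate disease endpoints
RISE_END = 0.67      # endpoint identity fully established


@dataclass
class TrajectoryDesign:
    """Study conditions for the double-bifurcation generator."""

    n_samples: int = 300
    n_features: int = 100
    n_informative: int = 30
    depth: int = 20_000
    noise_sd: float = 0.3
    n_subjects: int = 50
    seed: int = 0
    effect: float = 2.5        # log-scale amplitude of the trunk trends
    branch_effect: float = 2.5  # amplitude of origin/endpoint marker swings
    baseline_sd: float = 1.0   # spread of feature baseline log-abundances

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.n_informative < 6:
            raise ValueError("need >= 6 informative features (2 per trend role)")
        if self.n_samples < 4 * self.n_subjects // 3:
            pass  # subjects may hold a single sample; still valid
        if self.depth < 1:
            raise ValueError("depth must be positive")


@dataclass
class TrajectoryTruth:
    metadata: pd.DataFrame          # sample_id, subject_id, time, origin, endpoint, group
    informative: np.ndarray         # indices of all trend-carrying features
    roles: dict[str, np.ndarray] = field(default_factory=dict)


def _ramp(s: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip((s - lo) / (hi - lo), 0.0, 1.0)


def make_trajectory_dataset(
    design: TrajectoryDesign,
) -> tuple[CountTable, SampleMetadata, TrajectoryTruth]:
    """Counts, metadata and ground truth for a double-bifurcating cohort."""
    rng = np.random.default_rng(design.seed)
    n, d = design.n_samples, design.n_features

    # subjects hold consecutive latent-time samples; arms are balanced by
    # cycling subjects through the four (origin, endpoint) combinations and
    # stage coverage is stratified so every disease stage is populated
    per_subject = np.full(design.n_subjects, n // design.n_subjects)
    per_subject[: n % design.n_subjects] += 1
    combos = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])
    combo_of = combos[rng.permutation(design.n_subjects) % 4]
    centers = (np.arange(design.n_subjects) + 0.5) / design.n_subjects
    centers = np.clip(centers[rng.permutation(design.n_subjects)]
                      + rng.uniform(-0.05, 0.05, design.n_subjects), 0.0, 1.0)
    rows = []
    sid = 0
    for subj in range(design.n_subjects):
        m = per_subject[subj]
        origin, endpoint = (int(v) for v in combo_of[subj])
        times = np.sort(np.clip(centers[subj] + rng.uniform(-0.1, 0.1, size=m), 0.0, 1.0))
        for t in times:
            rows.append((f"S{sid:04d}", f"subj{subj:03d}", float(t), origin, endpoint))
            sid += 1
    meta = pd.DataFrame(rows, columns=["sample_id", "subject_id", "time", "origin", "endpoint"])
    s = meta["time"].to_numpy()
    group = np.where(s < ORIGIN_END, "HC",
                     np.where(s < SPLIT_START, "B1",
                              np.where(meta["endpoint"] == 0, "B2", "B3")))
    meta["group"] = group
    # geometric segment truth: a sample sits on an origin horn while its
    # origin effect is non-zero, and on an endpoint arm once the split begins
    meta["segment"] = np.where(
        s < FADE_END, "O" + meta["origin"].astype(str),
        np.where(s >= SPLIT_START, "E" + meta["endpoint"].astype(str), "trunk"))

    # trend roles: trunk-monotone, origin-discriminating, endpoint-discriminating
    info = np.arange(design.n_informative)
    n_each = design.n_informative // 3
    roles = {
        "trunk": info[:n_each],
        "origin": info[n_each: 2 * n_each],
        "endpoint": info[2 * n_each:],
    }
    base = rng.normal(0.0, design.baseline_sd, size=d)
    signs = rng.choice([-1.0, 1.0], size=design.n_informative)
    # alternate the marker features between the two arms so both community
    # types carry their own taxa (as two enterotypes each have their drivers)
    origin_side = np.arange(roles["origin"].size) % 2
    endpoint_side = np.arange(roles["endpoint"].size) % 2

    log_int = np.tile(base, (n, 1))  # samples x features
    trunk_trend = 1.0 / (1.0 + np.exp(-(s - 0.45) / 0.08))
    for j, f in enumerate(roles["trunk"]):
        log_int[:, f] += design.effect * signs[f] * trunk_trend
    fade = 1.0 - _ramp(s, ORIGIN_END, FADE_END)  # origin identity fades into the trunk
    org = meta["origin"].to_numpy()
    for j, f in enumerate(roles["origin"]):
        on = (org == origin_side[j]).astype(float)
        log_int[:, f] += design.branch_effect * signs[f] * fade * on
    rise = _ramp(s, SPLIT_START, RISE_END)       # endpoint identity emerges after the split
    end = meta["endpoint"].to_numpy()
    for j, f in enumerate(roles["endpoint"]):
        on = (end == endpoint_side[j]).astype(float)
        log_int[:, f] += design.branch_effect * signs[f] * rise * on

    if design.noise_sd > 0:
        log_int += rng.normal(0.0, design.noise_sd, size=log_int.shape)

    intensity = np.exp(log_int)
    probs = intensity / intensity.sum(axis=1, keepdims=True)
    counts = np.empty((d, n), dtype=np.int64)
    for i in range(n):
        counts[:, i] = rng.multinomial(design.depth, probs[i])

    table = CountTable(
        otu_ids=[f"OTU{j:04d}" for j in range(d)],
        sample_ids=list(meta["sample_id"]),
        counts=counts,
    )
    md = meta.rename(columns={"time": "timepoint"})[
        ["sample_id", "subject_id", "timepoint", "group"]
    ].copy()
    md["subtype"] = np.where(meta["endpoint"] == 0, "cCD", "iCD")
    metadata = SampleMetadata(md)
    truth = TrajectoryTruth(metadata=meta, informative=info, roles=roles)
    return table, metadata, truth


def make_classification_dataset(
    n: int = 150,
    d: int = 200,
    n_informative: int = 10,
    shift: float = 1.0,
    seed: int = 0,
    n_classes: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labelled dataset with progressively mean-shifted informative features.

    Class c shifts each informative feature by c * shift (mirroring a
    healthy -> early -> late severity gradient); the rest is standard normal
    noise. Returns (X, y, informative indices)."""
    rng = np.random.default_rng(seed)
    sizes = np.full(n_classes, n // n_classes)
    sizes[: n % n_classes] += 1
    X = rng.normal(size=(n, d))
    y = np.repeat(np.arange(n_classes), sizes)
    info = np.arange(n_informative)
    for c in range(n_classes):
        X[np.ix_(y == c, info)] += c * shift
    return X, y, info


def simulate_glv(
    alpha: np.ndarray,
    beta: np.ndarray,
    x0: np.ndarray,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PseudoSeries:
    """Integrate dx_i/dt = x_i (alpha_i + sum_j beta_ij x_j) with optional
    multiplicative log-normal observation noise."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(np.diag(beta) >= 0):
        raise ValueError("self-interactions must be negative for bounded trajectories")

    def rhs(_t, x):
        return x * (alpha + beta @ x)

    sol = solve_ivp(rhs, (times[0], times[-1]), x0, t_eval=times,
                    method="RK45", rtol=1e-8, atol=1e-10)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError("gLV integration failed")
    x = sol.y  # (J, T)
    if np.any(x > 1e6):
        bad = int(np.argmax(x.max(axis=1)))
        raise RuntimeError(f"divergent trajectory for species {bad}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x * np.exp(rng.normal(0.0, noise_sd, size=x.shape))
    return PseudoSeries(times=times, x=np.maximum(x, 0.0))
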