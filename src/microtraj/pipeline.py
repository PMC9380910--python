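"""End-to-end orchestration: preprocess -> select -> cluster -> tree ->
progression -> association (+ optional diversity, network), with a resolved
parameter manifest written next to every run and per-stage seeds derived
stably from one global seed."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path as FilePath

import numpy as np
import pandas as pd

from . import association, diversity as diversity_mod, io, progression
from .cluster import ConsensusKMeans
from .glv import GlvModel, PseudoSeries, fit_glv, build_network
from .logo import LogoSelector
from .tree import (DDRTree, DEFAULT_LAMBDA_GRID, DEFAULT_SIGMA_GRID,
                   tune_elbow)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters; defaults reproduce the reference configuration."""

    counts: str = ""
    metadata: str = ""
    orientation: str = "features_rows"
    out_dir: str = "results"
    seed: int = 0
    # preprocess
    min_reads: int = 10_000
    pseudo: float = 1e-6
    transform: str = "log10"          # log10 | clr
    # feature selection
    l1_penalty: str = "auto"
    k: int = 10
    cutoff: float = 0.001
    merge_classes: str = "B2,B3=B2B3"  # caller-level class merging, "" to disable
    # clustering
    n_clusters: str = "gap"
    consensus_runs: int = 1000
    consensus_frac: float = 0.8
    k_max: int = 8
    # principal tree
    dim: int = 3
    gamma: float = 2.0
    sigma: str = "auto"          # "auto" = elbow-tuned, or a float
    lambda_tree: str = "auto"
    # progression
    root: str = "auto"
    equalize_origins: bool = True
    healthy_label: str = "HC"
    # association
    fdr: float = 0.01
    min_abund: float = 0.001
    min_abs_rho: float = 0.3
    n_perm: int = 1000
    # optional stages
    run_diversity: bool = False
    rarefaction_depth: int = 10_000
    rarefaction_reps: int = 1000
    run_network: bool = False
    network_top_features: int = 30
    glv_penalty: str = "auto"

    @classmethod
    def from_file(cls, path: str | FilePath) -> "RunConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(FilePath(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _coerce(value, known[key].type)
        return cls(**kwargs)


def _coerce(value: str, typ) -> object:
    t = str(typ)
    if "bool" in t:
        return value.lower() in ("1", "true", "yes", "on")
    if "int" in t:
        return int(value)
    if "float" in t:
        try:
            return float(value)
        except ValueError:
            return value  # "auto"-style strings on float-ish fields
    return value


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31 - 1)


def _merged_groups(groups: pd.Series, rule: str) -> np.ndarray:
    y = groups.to_numpy().astype(object).copy()
    if rule:
        src, dst = rule.split("=")
        for lab in src.split(","):
            y[y == lab.strip()] = dst.strip()
    return y.astype(str)


def run_all(config: RunConfig, counts: io.CountTable | None = None,
            metadata: io.SampleMetadata | None = None) -> dict:
    """Execute the full pipeline; returns the in-memory results bundle and
    writes TSV/JSON artifacts plus a parameter manifest under ``out_dir``."""
    out = FilePath(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.txt").write_text(
        "".join(f"{k} = {v}\n" for k, v in asdict(config).items())
    )

    # ---- preprocess -------------------------------------------------------
    if counts is None:
        counts = io.read_count_table(config.counts, orientation=config.orientation)
    if metadata is None:
        metadata = io.read_metadata(config.metadata)
    metadata.check_covers(counts)
    counts = io.filter_low_depth(counts, config.min_reads)
    abund = io.to_relative(counts)
    if config.transform == "clr":
        abund = io.clr_transform(abund, config.pseudo)
    else:
        abund = io.log10_pseudo_transform(abund, config.pseudo)
    io.write_abundance_table(abund, out / "transformed.tsv")
    groups = metadata.groups(abund.sample_ids)

    # ---- feature selection ------------------------------------------------
    X = abund.transformed.T  # samples x features
    y = _merged_groups(groups, config.merge_classes)
    selector = LogoSelector(
        l1_penalty=(config.l1_penalty if config.l1_penalty == "auto"
                    else float(config.l1_penalty)),
        k=config.k, cutoff=config.cutoff, random_state=stage_seed(config.seed, "select"),
    ).fit(X, y)
    weights = pd.DataFrame({
        "otu_id": abund.otu_ids,
        "weight": selector.weights_,
        "selected": selector.get_support(),
    })
    weights.to_csv(out / "weights.tsv", sep="\t", index=False, float_format="%.10g")
    sel_idx = np.flatnonzero(selector.get_support())
    if sel_idx.size == 0:
        raise RuntimeError("feature selection retained no features; lower the penalty")
    X_sel = X[:, sel_idx]
    logger.info("selected %d features above the %.3g cutoff", sel_idx.size, config.cutoff)

    # ---- clustering --------------------------------------------------------
    clus = ConsensusKMeans(
        n_clusters=(config.n_clusters if config.n_clusters == "gap"
                    else int(config.n_clusters)),
        k_max=config.k_max, runs=config.consensus_runs, frac=config.consensus_frac,
        random_state=stage_seed(config.seed, "cluster"),
    ).fit(X_sel)
    pd.DataFrame({"sample_id": abund.sample_ids, "cluster": clus.labels_,
                  "silhouette": clus.silhouette_}).to_csv(
        out / "clusters.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(clus.consensus_, index=abund.sample_ids, columns=abund.sample_ids
                 ).to_csv(out / "consensus.tsv", sep="\t", float_format="%.6g")
    if clus.gap_curve_ is not None:
        clus.gap_curve_.to_csv(out / "gap_curve.tsv", sep="\t", index=False,
                               float_format="%.10g")

    # ---- principal tree ----------------------------------------------------
    sigma, lam = config.sigma, config.lambda_tree
    if sigma == "auto" or lam == "auto":
        sigma_t, lam_t = tune_elbow(
            X_sel,
            sigma_grid=DEFAULT_SIGMA_GRID if sigma == "auto" else None,
            lambda_grid=DEFAULT_LAMBDA_GRID if lam == "auto" else None,
            d=config.dim, gamma=config.gamma,
        )
        sigma = sigma_t if sigma == "auto" else float(sigma)
        lam = lam_t if lam == "auto" else float(lam)
        logger.info("elbow-tuned sigma=%g lambda=%g", sigma, lam)
    ddr = DDRTree(dim=config.dim, gamma=config.gamma, sigma=float(sigma),
                  lambda_tree=float(lam)).fit(X_sel)
    emb = pd.DataFrame(ddr.embedding_, index=abund.sample_ids,
                       columns=[f"dim{i+1}" for i in range(ddr.embedding_.shape[1])])
    emb.to_csv(out / "latent.tsv", sep="\t", index_label="sample_id",
               float_format="%.10g")
    tree = ddr.tree_
    pd.DataFrame(
        [(i, j, float(((tree.Z[:, i] - tree.Z[:, j]) ** 2).sum()))
         for i, j in tree.edges],
        columns=["node_i", "node_j", "cost"],
    ).to_csv(out / "tree_edges.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(tree.Z.T, index=abund.sample_ids,
                 columns=[f"dim{i+1}" for i in range(tree.Z.shape[0])]).to_csv(
        out / "tree_nodes.tsv", sep="\t", index_label="node", float_format="%.10g")

    # ---- progression model -------------------------------------------------
    model = progression.build_progression_graph(
        tree, clus.labels_, groups=groups, healthy_label=config.healthy_label)
    if config.root != "auto":
        paths = progression.extract_paths(model, root=int(config.root))
    else:
        paths = progression.extract_paths(model)
    if config.equalize_origins and len(model.origins) == 2:
        model.branch_scale.update(progression.equalize_origin_scale(model))

    sample_ids = np.asarray(abund.sample_ids)
    per_sample_rows = []
    orders: dict[int, list[str]] = {}
    for path in paths:
        on_path = np.isin(clus.labels_, path.clusters)
        ids = list(sample_ids[on_path])
        arc, _ = progression.project_to_path(ddr.embedding_[on_path], path)
        dist = progression.progression_distance(arc, path, model)
        orders[path.path_id] = progression.order_pseudotime(ids, dist)
        for s, a, dd in zip(ids, arc, dist):
            per_sample_rows.append((s, path.path_id, float(a), float(dd)))
    per_sample = pd.DataFrame(
        per_sample_rows, columns=["sample_id", "path_id", "arc_position",
                                  "progression_distance"])
    per_sample.to_csv(out / "progression.tsv", sep="\t", index=False,
                      float_format="%.10g")
    model_json = {
        "clusters": [int(c) for c in model.graph.nodes],
        "edges": [[int(a), int(b),
                   float(model.graph.edges[a, b]["raw_length"]),
                   model.edge_scale(a, b)]
                  for a, b in sorted(model.graph.edges)],
        "origins": [int(o) for o in model.origins],
        "paths": {int(p.path_id): [int(c) for c in p.clusters] for p in paths},
    }
    (out / "model.json").write_text(json.dumps(model_json, indent=2, sort_keys=True))

    # ---- association -------------------------------------------------------
    assoc = association.select_associated(
        abund, paths, orders, fdr=config.fdr, min_abund=config.min_abund,
        min_abs_rho=config.min_abs_rho, n_perm=config.n_perm,
        seed=stage_seed(config.seed, "associate"),
    )
    assoc.table.to_csv(out / "association.tsv", sep="\t", index=False,
                       float_format="%.10g")

    results = {
        "counts": counts, "abund": abund, "metadata": metadata,
        "selector": selector, "clustering": clus, "ddrtree": ddr,
        "model": model, "paths": paths, "orders": orders,
        "per_sample": per_sample, "association": assoc,
    }

    # ---- optional stages ---------------------------------------------------
    if config.run_diversity:
        div = diversity_mod.diversity_table(
            counts, depth=config.rarefaction_depth, reps=config.rarefaction_reps,
            seed=stage_seed(config.seed, "diversity"))
        div.to_csv(out / "diversity.tsv", sep="\t", index=False, float_format="%.10g")
        results["diversity"] = div
    if config.run_network:
        results["networks"] = _network_stage(config, abund, assoc, orders, out)
    return results


def _network_stage(config, abund, assoc, orders, out: FilePath) -> dict:
    nets = {}
    pos = {s: i for i, s in enumerate(abund.sample_ids)}
    for pid, ordered in orders.items():
        if len(ordered) < 10:
            continue
        sub = assoc.table[assoc.table.path_id == pid]
        ranked = sub.reindex(sub.rho.abs().sort_values(ascending=False).index)
        feats = ranked[ranked.mean_abund >= config.min_abund].otu_id.head(
            config.network_top_features)
        fidx = [abund.otu_ids.index(f) for f in feats]
        if len(fidx) < 2:
            continue
        cols = [pos[s] for s in ordered]
        series = PseudoSeries(times=np.arange(len(cols), dtype=float),
                              x=abund.rel[np.ix_(fidx, cols)], path_id=pid,
                              feature_ids=list(feats))
        fit = fit_glv(series, penalty=config.glv_penalty,
                      seed=stage_seed(config.seed, f"network{pid}"))
        rho_signs = np.sign(ranked.set_index("otu_id").rho.loc[feats].to_numpy())
        net = build_network(fit, rho_signs=rho_signs)
        pd.DataFrame(
            [(feats.iloc[j], feats.iloc[i], b) for j, i, b in net.edges],
            columns=["source", "target", "beta"],
        ).to_csv(out / f"network_path{pid}_edges.tsv", sep="\t", index=False,
                 float_format="%.10g")
        pd.DataFrame({"otu_id": list(feats), "out_degree": net.out_degree,
                      "rho_sign": rho_signs}).to_csv(
            out / f"network_path{pid}_nodes.tsv", sep="\t", index=False)
        nets[pid] = net
    return nets
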