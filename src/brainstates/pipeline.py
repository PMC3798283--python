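"""End-to-end orchestration: simulate/load -> connectivity -> graphs ->
metrics -> null normalization -> classification -> repeated-measures stats.

A single structured config drives every stage; every paper-unspecified
default is materialized into the resolved-config dump so a run is fully
described by its ``run_manifest.json``. Re-running with the same config
and master seed is byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .atlas import (
    CONDITIONS,
    ConnectivityMatrix,
    ROIAtlas,
    StudyDataset,
    ValidationError,
    euclidean_distances,
    load_atlas,
    load_study,
    write_matrix,
)
from .classify import (
    classify_edge_kinds,
    compare_edge_distributions,
    importance_maps,
    loocv_classify,
    permutation_test,
    top_edges,
)
from .connectivity import bin_by_distance, clean_timeseries, correlation_matrix, \
    correlation_summary, ks_compare
from .metrics import compute_metrics
from .nulls import normalize_metrics
from .stats import nodewise_fdr, per_threshold_anovas, rm_anova, rm_ancova_distance
from .synthetic import make_atlas, make_ground_truth, simulate_study
from .thresholding import proportional_threshold

DEFAULT_CONFIG = {
    "seed": None,  # required
    "simulation": {
        "n_roi": 194,
        "n_subjects": 12,
        "n_timepoints": 196,
        "tr": 2.46,
        "n_modules": 6,
        "lambda_mm": 60.0,
    },
    "study": None,  # {"atlas": path, "manifest": path} overrides simulation
    "connectivity": {
        "clean": False,  # synthetic series are generated clean
        "band_hz": [0.01, 0.1],
        "trim": 4,
        "distance_bin_mm": 9.0,
        "n_distance_bins": 15,
    },
    "thresholds": {"grid": [0.11, 0.16, 0.21, 0.26, 0.31]},
    "metrics": {"n_restarts": 50, "include_local": True, "include_modularity": True},
    "nulls": {"n_null": 100, "swaps_per_edge": 10, "null_restarts": 10},
    "classification": {
        "comparisons": [["S", "W"], ["LOC", "S"], ["R", "LOC"]],
        "svm_cost": 1.0,
        "n_perm": 1000,
        "top_fraction": 0.01,
    },
    "stats": {"fdr_q": 0.05},
    "motion_limit_mm": 3.0,
}


def resolve_config(config: dict) -> dict:
    """Merge a user config over the defaults; the master seed is mandatory."""
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in config.items():
        if key not in out:
            raise ValidationError(f"unknown config key: {key!r}")
        if isinstance(val, dict) and isinstance(out[key], dict):
            unknown = set(val) - set(out[key])
            if unknown:
                raise ValidationError(f"unknown config keys in {key!r}: {sorted(unknown)}")
            out[key].update(val)
        else:
            out[key] = val
    if out["seed"] is None:
        raise ValidationError("config must name a master seed (key: seed)")
    return out


def exclude_subjects_by_motion(
    dataset: StudyDataset,
    motion: dict[tuple[str, str], np.ndarray] | None,
    limit_mm: float = 3.0,
) -> tuple[StudyDataset, list[dict]]:
    """Drop subjects whose displacement exceeds ``limit_mm`` in any scan.

    A subject exceeding the limit in any one condition is removed from all
    four conditions (balanced design preserved). Returns the filtered
    dataset and an exclusion log. With no motion traces the stage is a
    no-op (logged).
    """
    if not motion:
        return dataset, [{"event": "motion traces missing; exclusion skipped"}]
    log: list[dict] = []
    bad: set[str] = set()
    for subject in dataset.subjects:
        for cond in CONDITIONS:
            trace = motion.get((subject, cond))
            if trace is None:
                continue
            peak = float(np.max(np.abs(trace)))
            if peak > limit_mm:
                bad.add(subject)
                log.append({"event": "excluded", "subject": subject,
                            "condition": cond, "peak_mm": peak})
    return dataset.drop_subjects(bad), log


def _spawn_seeds(master: int, n: int, tag: int) -> list[int]:
    ss = np.random.SeedSequence([int(master), tag])
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_pipeline(config: dict, outdir: str | os.PathLike) -> dict:
    """Run every stage and write the report bundle to ``outdir``."""
    cfg = resolve_config(config)
    seed = int(cfg["seed"])
    os.makedirs(outdir, exist_ok=True)
    outdir = os.fspath(outdir)
    report: dict = {"config": cfg, "version": __version__}

    # --- stage 1: data ----------------------------------------------------
    truth = None
    if cfg["study"]:
        atlas = load_atlas(cfg["study"]["atlas"])
        dataset = load_study(cfg["study"]["manifest"], atlas,
                             tr=cfg["simulation"]["tr"])
    else:
        sim = cfg["simulation"]
        atlas = make_atlas(sim["n_roi"], seed=seed)
        truth = make_ground_truth(atlas, n_modules=sim["n_modules"],
                                  lambda_mm=sim["lambda_mm"], seed=seed)
        dataset, truth = simulate_study(atlas, truth, sim["n_subjects"],
                                        sim["n_timepoints"], seed=seed,
                                        tr=sim["tr"])
        with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
    atlas.to_tsv(os.path.join(outdir, "atlas.tsv"))
    dist = euclidean_distances(atlas)

    # --- stage 2: connectivity -------------------------------------------
    conn_cfg = cfg["connectivity"]
    matrices: dict[tuple[str, str], ConnectivityMatrix] = {}
    for key, panel in sorted(dataset.panels.items()):
        if conn_cfg["clean"]:
            panel = clean_timeseries(panel, band=tuple(conn_cfg["band_hz"]),
                                     trim=conn_cfg["trim"])
        matrices[key] = correlation_matrix(panel)

    cond_mean = {c: np.mean([m.values for (s, cc), m in matrices.items() if cc == c],
                            axis=0) for c in CONDITIONS}
    for c in CONDITIONS:
        write_matrix(cond_mean[c], atlas.names,
                     os.path.join(outdir, f"mean_connectivity_{c}.tsv"))
    summaries = {c: correlation_summary(
        [m for (s, cc), m in matrices.items() if cc == c]).to_dict()
        for c in CONDITIONS}
    iu = np.triu_indices(atlas.n, k=1)
    ks = {}
    for i, a in enumerate(CONDITIONS):
        for b in CONDITIONS[i + 1:]:
            d_stat, p = ks_compare(cond_mean[a][iu], cond_mean[b][iu])
            ks[f"{a} vs {b}"] = {"D": d_stat, "p": p}
    report["correlation_summaries"] = summaries
    report["ks_tests"] = ks

    binned_rows = []
    for (s, c), m in sorted(matrices.items()):
        bins = bin_by_distance(m, dist, conn_cfg["distance_bin_mm"],
                               conn_cfg["n_distance_bins"])
        bins.insert(0, "condition", c)
        bins.insert(0, "subject", s)
        binned_rows.append(bins)
    binned = pd.concat(binned_rows, ignore_index=True)
    binned.to_csv(os.path.join(outdir, "binned_correlations.tsv"),
                  sep="\t", index=False, float_format="%.10g")

    # --- stage 3-5: graphs, metrics, normalization ------------------------
    grid = list(cfg["thresholds"]["grid"])
    met_cfg, null_cfg = cfg["metrics"], cfg["nulls"]
    keys = sorted(matrices)
    seeds = _spawn_seeds(seed, len(keys) * len(grid), tag=0x9E7)
    norm_rows, local_records = [], []
    si = 0
    for key in keys:
        for dens in grid:
            graph = proportional_threshold(matrices[key], dens)
            raw = compute_metrics(graph, n_restarts=met_cfg["n_restarts"],
                                  seed=seeds[si],
                                  include_local=met_cfg["include_local"],
                                  include_modularity=met_cfg["include_modularity"])
            norm = normalize_metrics(
                graph, n_null=null_cfg["n_null"], seed=seeds[si],
                swaps_per_edge=null_cfg["swaps_per_edge"],
                null_restarts=null_cfg["null_restarts"],
                include_modularity=met_cfg["include_modularity"], raw=raw)
            norm_rows.append({
                "subject": key[0], "condition": key[1], "density": dens,
                "L": raw.L, "E": raw.E, "C": raw.C, "Q": raw.Q,
                "n_modules": raw.n_modules,
                "nC": norm.nC, "nL": norm.nL, "nE": norm.nE, "nQ": norm.nQ,
                "sigma": norm.sigma, "mean_degree": float(graph.degrees().mean()),
            })
            if met_cfg["include_local"]:
                local_records.append((key[0], key[1], dens, raw.strength,
                                      raw.local_eff))
            si += 1
    norm_table = pd.DataFrame(norm_rows)
    norm_table.to_csv(os.path.join(outdir, "metrics.tsv"), sep="\t",
                      index=False, float_format="%.10g")

    # --- stage 6: repeated-measures statistics ----------------------------
    stats_out: dict = {}
    metric_cols = ["nC", "nL", "nE", "sigma"] + \
        (["nQ", "n_modules"] if met_cfg["include_modularity"] else [])
    for col in metric_cols:
        tab = norm_table.rename(columns={col: "value", "density": "threshold"})
        tab = tab[["subject", "condition", "threshold", "value"]].copy()
        tab["condition"] = pd.Categorical(tab["condition"], categories=CONDITIONS,
                                          ordered=True)
        res = rm_anova(tab)
        follow = per_threshold_anovas(tab)
        stats_out[col] = {
            "effects": {k: asdict(v) for k, v in res.effects.items()},
            "pairwise": res.pairwise.to_dict(orient="records"),
            "per_threshold": [
                {"label": r.label,
                 "effects": {k: asdict(v) for k, v in r.effects.items()},
                 "pairwise": r.pairwise.to_dict(orient="records")}
                for r in follow],
        }

    if met_cfg["include_local"] and local_records:
        stats_out["local"] = _nodewise_stats(local_records, atlas,
                                             cfg["stats"]["fdr_q"])

    anc = rm_ancova_distance(binned)
    stats_out["distance_ancova"] = {
        "condition": asdict(anc.condition),
        "distance": asdict(anc.distance),
        "interaction": asdict(anc.interaction),
        "per_bin": [{"label": r.label,
                     "effects": {k: asdict(v) for k, v in r.effects.items()},
                     "pairwise": r.pairwise.to_dict(orient="records")}
                    for r in anc.per_bin],
    }
    report["stats"] = stats_out

    # --- stage 7: classification ------------------------------------------
    cls_cfg = cfg["classification"]
    cls_out: dict = {}
    kinds_by_comparison = {}
    comp_seeds = _spawn_seeds(seed, len(cls_cfg["comparisons"]), tag=0xC1A)
    family = len(cls_cfg["comparisons"])
    for ci, (cond_a, cond_b) in enumerate(cls_cfg["comparisons"]):
        group_a = [matrices[(s, cond_a)] for s in dataset.subjects]
        group_b = [matrices[(s, cond_b)] for s in dataset.subjects]
        res = loocv_classify(group_a, group_b, svm_cost=cls_cfg["svm_cost"],
                             comparison=f"{cond_a} vs {cond_b}")
        p, p_bonf = permutation_test(group_a, group_b, res.accuracy,
                                     n_perm=cls_cfg["n_perm"],
                                     seed=comp_seeds[ci],
                                     svm_cost=cls_cfg["svm_cost"],
                                     family_size=family)
        res.p_perm, res.p_perm_bonferroni, res.n_perm = p, p_bonf, cls_cfg["n_perm"]
        maps = importance_maps(res, group_a, group_b)
        edges_a = top_edges(maps.map_a, cls_cfg["top_fraction"])
        kinds_a = classify_edge_kinds(edges_a, atlas, maps.map_a)
        kinds_by_comparison[f"{cond_a} vs {cond_b}"] = kinds_a
        cls_out[f"{cond_a} vs {cond_b}"] = {
            "accuracy": res.accuracy, "sensitivity": res.sensitivity,
            "specificity": res.specificity, "p_perm": p,
            "p_perm_bonferroni": p_bonf, "n_perm": res.n_perm,
            "top_edge_kinds": kinds_a.counts,
            "top_edge_kind_percent": kinds_a.percentages(),
        }
        write_matrix(maps.map_a, atlas.names,
                     os.path.join(outdir, f"importance_{cond_a}_vs_{cond_b}.tsv"))
    if "S vs W" in kinds_by_comparison and "LOC vs S" in kinds_by_comparison:
        chi2, df, p = compare_edge_distributions(
            kinds_by_comparison["S vs W"], kinds_by_comparison["LOC vs S"])
        cls_out["edge_kind_chi2"] = {"chi2": chi2, "df": df, "p": p}
    report["classification"] = cls_out

    with open(os.path.join(outdir, "run_manifest.json"), "w") as fh:
        json.dump({"config": cfg, "version": __version__,
                   "stage_seeds": {"graphs": seeds, "classification": comp_seeds}},
                  fh, indent=1, sort_keys=True)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    return report


def _nodewise_stats(local_records, atlas: ROIAtlas, q: float) -> dict:
    """Per-node 2-way RM-ANOVAs on strength and local efficiency, BY-FDR."""
    out = {}
    for mi, name in ((3, "strength"), (4, "local_efficiency")):
        rows = []
        for rec in local_records:
            for node in range(atlas.n):
                rows.append((rec[0], rec[1], rec[2], node, rec[mi][node]))
        tab = pd.DataFrame(rows, columns=["subject", "condition", "threshold",
                                          "node", "value"])
        pvals = np.empty(atlas.n)
        for node in range(atlas.n):
            res = rm_anova(tab[tab["node"] == node])
            pvals[node] = res.effects["condition"].p
        reject, p_adj = nodewise_fdr(pvals, q=q)
        out[name] = {"n_significant": int(reject.sum()),
                     "p_adjusted": p_adj.tolist(),
                     "significant_nodes": np.flatnonzero(reject).tolist()}
    return out
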