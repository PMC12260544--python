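"""Stage orchestration: simulate -> detect -> match -> mana -> profile -> lag -> report.

Each stage reads its inputs from a shared work directory, writes its outputs
into a stage subdirectory, and drops a ``manifest.json`` recording the
command, resolved configuration, input digests, seed, tool version, and
timestamp. Reruns with identical manifests reproduce identical outputs for
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from subnets import __version__, io
from subnets.config import AnalysisConfig
from subnets.communities import (
    detect_communities,
    extract_parent_subnetworks,
    identify_parent_network,
)
from subnets.lags import group_ordering, seed_lag_map
from subnets.mana import annotate_terms, extract_regions, match_studies, peak_density_map
from subnets.matching import (
    MatchedCluster,
    OverlapMatrix,
    SubnetworkInstance,
    cluster_overlap_matrix,
    density_map,
    instances_from_subnetworks,
    threshold_density,
    winner_take_all,
)
from subnets.profiling import (
    GraphCluster,
    export_graph,
    post_hoc_paired,
    rm_anova,
    spring_graph_export,
    subnetwork_network_fc,
    task_condition_means,
)
from subnets.spaces import LabelMap, compute_connectivity, density_threshold_rowcol
from subnets.synthetic import (
    PlantedDesign,
    grid_nodespace,
    simulate_meta_database,
    simulate_task_maps,
    simulate_timeseries,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "detect", "match", "mana", "profile", "lag", "report")


class MissingStageError(RuntimeError):
    """An upstream stage's outputs are absent."""


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def write_manifest(
    stage_dir: Path, command: str, config: AnalysisConfig, inputs: list[Path],
    seed: int, extra: dict | None = None,
) -> None:
    manifest = {
        "command": command,
        "config": config.to_dict(),
        "inputs": {str(p): _digest(p) for p in sorted(inputs) if p.is_file()},
        "rng_seed": seed,
        "tool_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingStageError(
            f"missing {path}; run the `{stage}` stage first"
        )
    return path


def _stage_dir(workdir: Path, stage: str) -> Path:
    d = Path(workdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


# ---------------------------------------------------------------------------
# simulate


def run_simulate(
    workdir: str | Path,
    config: AnalysisConfig,
    design: PlantedDesign | None = None,
    n_frames: int = 800,
    tr: float = 1.0,
) -> Path:
    """Emit a complete on-disk fixture set with ground truth.

    Writes: node space, ground-truth network/subnetwork label maps,
    per-subject timeseries, a meta-analytic database with planted term
    associations, task z-maps with planted effects, and a ground-truth JSON.
    """
    workdir = Path(workdir)
    out = _stage_dir(workdir, "simulate")
    if design is None:
        truth_tmp = PlantedDesign(rng_seed=config.rng_seed)
        design = PlantedDesign(
            rng_seed=config.rng_seed,
            planted_lags={"sub11": -1.0, "sub12": 0.0, "sub13": 1.0},
            planted_terms={
                f"planted_term_{l}": (int(l), 0.2)
                for l in sorted(set(truth_tmp.subnetwork_labels_flat().tolist()))[:3]
            },
        )
    space = grid_nodespace(design.n_nodes)
    io.write_nodespace_tsv(space, out / "space.tsv")
    net_truth, sub_truth = design.truth_maps()
    io.write_labelmap_tsv(net_truth, out / "truth_networks.tsv")
    io.write_labelmap_tsv(sub_truth, out / "truth_subnetworks.tsv")
    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for s in range(design.n_subjects):
        ts = simulate_timeseries(design, s, n_frames=n_frames, tr=tr)
        io.write_timeseries_tsv(ts, ts_dir / f"{ts.subject_id}.tsv")
    # meta-analytic database planted on the truth subnetworks of network 1
    target_net = 1
    target_subs = [l for l in sub_truth.present_labels() if l // 10 == target_net]
    regions_by_sub = {}
    for lab in target_subs:
        regs = extract_regions(
            sub_truth.node_set(lab), space, min_area_mm2=config.min_cluster_area_mm2
        )
        regions_by_sub[lab] = [r.representative for r in regs]
    activations, features = simulate_meta_database(
        design, regions_by_sub, exclusion_coords=space.coords
    )
    io.write_meta_tables(activations, features, out / "meta")
    # task maps: planted effect 1.0 on the first target subnetwork
    effects = {
        "condition_A": {target_subs[0]: 1.0},
        "condition_B": {lab: 0.0 for lab in target_subs},
    }
    task = simulate_task_maps(design, sub_truth, effects)
    task_dir = out / "task"
    task_dir.mkdir(exist_ok=True)
    for cond, per_subj in task.items():
        for subj, zmap in per_subj.items():
            np.savetxt(task_dir / f"{cond}_{subj}.tsv", zmap, delimiter="\t")
    truth_json = {
        "design": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(design).items()
        },
        "target_network": target_net,
        "target_subnetworks": target_subs,
        "task_effects": {c: {str(k): v for k, v in e.items()} for c, e in effects.items()},
        "n_frames": n_frames,
        "tr": tr,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_json, indent=2) + "\n")
    write_manifest(out, "simulate", config, [], config.rng_seed)
    return out


def _load_simulation(workdir: Path):
    sim = _require(Path(workdir) / "simulate", "simulate")
    space = io.read_nodespace_tsv(sim / "space.tsv")
    truth = json.loads((sim / "ground_truth.json").read_text())
    return sim, space, truth


def _load_timeseries(sim: Path, space):
    ts_dir = _require(sim / "timeseries", "simulate")
    return [
        io.read_timeseries_tsv(p, space)
        for p in sorted(ts_dir.glob("sub-*.tsv"))
    ]


# ---------------------------------------------------------------------------
# detect


def scale_aware_density(requested: float, n_nodes: int, min_neighbors: int = 8) -> float:
    """Raise a density so each row keeps at least ``min_neighbors`` entries.

    The sparse-tier fraction meaningful on a ~60k-node cortical matrix
    retains less than one entry per row on a few-hundred-node synthetic
    matrix; the working density is floored so the graph stays connected
    enough for community detection.
    """
    floor = min(1.0, min_neighbors / max(n_nodes - 1, 1))
    if requested < floor:
        logger.info(
            "density %.4g retains <%d neighbors at N=%d; using %.4g",
            requested, min_neighbors, n_nodes, floor,
        )
        return floor
    return requested


def run_detect(
    workdir: str | Path, config: AnalysisConfig, method: str = "map_equation"
) -> Path:
    """Per-subject community detection at network and subnetwork tiers.

    The network-tier solution is matched to the ground-truth template to
    locate the target network; subnetwork-tier communities represented
    within it become that subject's subnetworks.
    """
    workdir = Path(workdir)
    sim, space, truth = _load_simulation(workdir)
    out = _stage_dir(workdir, "detect")
    net_template = io.read_labelmap_tsv(sim / "truth_networks.tsv", space)
    target_net = truth["target_network"]
    all_ts = _load_timeseries(sim, space)
    net_density = config.network_density
    sub_density = scale_aware_density(config.subnetwork_density, space.n_nodes, 8)
    provenance = {}
    for ts in all_ts:
        cm = compute_connectivity(ts, r_max=config.r_max)
        net_mask = density_threshold_rowcol(cm, net_density)
        net_sol = detect_communities(
            cm, net_mask, method=method, seed=config.rng_seed,
            min_community_size=config.min_community_size,
        )
        parent = identify_parent_network(net_sol, net_template, target_net)
        sub_mask = density_threshold_rowcol(cm, sub_density)
        sub_sol = detect_communities(
            cm, sub_mask, method=method, seed=config.rng_seed,
            min_community_size=config.min_community_size,
        )
        subnets = extract_parent_subnetworks(
            sub_sol, parent, overlap_fraction=config.parent_overlap_fraction
        )
        labels = np.zeros(space.n_nodes, dtype=int)
        for lab, nodes in subnets.items():
            labels[sorted(nodes)] = lab
        io.write_labelmap_tsv(
            LabelMap(labels=labels), out / f"{ts.subject_id}_subnetworks.tsv"
        )
        provenance[ts.subject_id] = {
            "network_density": net_density,
            "subnetwork_density": sub_density,
            "method": method,
            "network_quality": net_sol.quality,
            "subnetwork_quality": sub_sol.quality,
            "n_subnetworks": len(subnets),
        }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    write_manifest(
        out, "detect", config,
        sorted((sim / "timeseries").glob("sub-*.tsv")), config.rng_seed,
    )
    return out


# ---------------------------------------------------------------------------
# match


def load_subject_subnetworks(detect_dir: Path, space) -> dict[str, dict[int, frozenset[int]]]:
    per_subject = {}
    for p in sorted(detect_dir.glob("sub-*_subnetworks.tsv")):
        subj = p.name.replace("_subnetworks.tsv", "")
        lm = io.read_labelmap_tsv(p, space)
        per_subject[subj] = {lab: lm.node_set(lab) for lab in lm.present_labels()}
    if not per_subject:
        raise MissingStageError(f"no per-subject subnetworks in {detect_dir}; run `detect`")
    return per_subject


def run_match(workdir: str | Path, config: AnalysisConfig) -> Path:
    """Jaccard-match subnetworks across subjects; density + winner-take-all maps."""
    workdir = Path(workdir)
    sim, space, truth = _load_simulation(workdir)
    detect_dir = _require(workdir / "detect", "detect")
    out = _stage_dir(workdir, "match")
    per_subject = load_subject_subnetworks(detect_dir, space)
    n_subjects = len(per_subject)
    instances = instances_from_subnetworks(per_subject)
    om = OverlapMatrix.from_instances(instances)
    clusters = cluster_overlap_matrix(
        om, n_subjects,
        min_subject_fraction=config.min_subject_fraction,
        seed=config.rng_seed,
    )
    membership = {
        f"cluster_{c.cluster_id}": [
            {"subject": m.subject_id, "subnetwork": m.subnetwork_id}
            for m in c.members
        ]
        for c in clusters
    }
    (out / "clusters.json").write_text(json.dumps(membership, indent=2) + "\n")
    dms = {}
    for c in clusters:
        dm = density_map(c, space.n_nodes)
        dms[c.cluster_id] = dm
        io.write_density_map_tsv(dm, out / f"cluster_{c.cluster_id}_density.tsv")
    if dms:
        wta, ties = winner_take_all(dms)
        io.write_labelmap_tsv(wta, out / "winner_take_all.tsv")
        np.savetxt(out / "wta_ties.tsv", ties.astype(int), fmt="%d", delimiter="\t")
    write_manifest(
        out, "match", config,
        sorted(detect_dir.glob("sub-*_subnetworks.tsv")), config.rng_seed,
        extra={"n_clusters": len(clusters), "n_subjects": n_subjects},
    )
    return out


def load_clusters(workdir: Path) -> dict[int, np.ndarray]:
    match_dir = _require(Path(workdir) / "match", "match")
    dms = {}
    for p in sorted(match_dir.glob("cluster_*_density.tsv")):
        cid = int(p.name.split("_")[1])
        dms[cid] = io.read_density_map_tsv(p)
    if not dms:
        raise MissingStageError(f"no cluster density maps in {match_dir}; run `match`")
    return dms


# ---------------------------------------------------------------------------
# mana


def run_mana(workdir: str | Path, config: AnalysisConfig) -> Path:
    """Annotate matched subnetworks with meta-analytic terms."""
    workdir = Path(workdir)
    sim, space, truth = _load_simulation(workdir)
    out = _stage_dir(workdir, "mana")
    activations, features = io.read_meta_tables(
        sim / "meta_activations.tsv", sim / "meta_features.tsv"
    )
    match_manifest = json.loads(
        _require(workdir / "match" / "manifest.json", "match").read_text()
    )
    n_subjects = match_manifest["n_subjects"]
    dms = load_clusters(workdir)
    matches: dict[int, list[int]] = {}
    region_counts = {}
    for cid, dm in dms.items():
        nodes = threshold_density(
            dm, mode="fraction",
            fraction=config.region_fraction_threshold, n_subjects=n_subjects,
        )
        if not nodes:
            logger.warning("cluster %d empty after density threshold", cid)
            continue
        regions = extract_regions(nodes, space, config.min_cluster_area_mm2)
        if not regions:
            continue
        region_counts[cid] = len(regions)
        matches[cid] = match_studies(
            activations, regions, space,
            radius_mm=config.peak_match_radius_mm,
            fraction=config.region_match_fraction,
        )
    results = annotate_terms(features, matches, alpha=config.fdr_alpha)
    rows = [
        {
            "term": r.term,
            "F": r.f_stat,
            "df1": r.df[0],
            "df2": r.df[1],
            "p": r.p,
            "q": r.q,
            "significant": r.significant,
            "assigned_subnetwork": r.assigned_subnetwork,
            "magnitude": r.magnitude,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(out / "term_table.tsv", sep="\t", index=False)
    cloud = [
        {
            "term": r.term,
            "subnetwork": int(r.assigned_subnetwork),
            "magnitude": r.magnitude,
            "tier": "fdr" if r.significant else ("uncorrected" if r.p < 0.05 else "ns"),
        }
        for r in results
        if r.p < 0.05
    ]
    (out / "wordcloud.json").write_text(json.dumps(cloud, indent=2) + "\n")
    peak_density = peak_density_map(activations, space, config.peak_density_radius_mm)
    io.write_density_map_tsv(peak_density, out / "peak_density.tsv")
    write_manifest(
        out, "mana", config,
        [sim / "meta_activations.tsv", sim / "meta_features.tsv"],
        config.rng_seed,
        extra={
            "n_matched_studies": {str(k): len(v) for k, v in matches.items()},
            "n_regions": {str(k): v for k, v in region_counts.items()},
            "n_significant_terms": int(sum(r.significant for r in results)),
        },
    )
    return out


# ---------------------------------------------------------------------------
# profile


def run_profile(workdir: str | Path, config: AnalysisConfig) -> Path:
    """Subnetwork-network FC profiles, task means, ANOVAs, spring-graph export."""
    workdir = Path(workdir)
    sim, space, truth = _load_simulation(workdir)
    detect_dir = _require(workdir / "detect", "detect")
    out = _stage_dir(workdir, "profile")
    net_truth = io.read_labelmap_tsv(sim / "truth_networks.tsv", space)
    per_subject = load_subject_subnetworks(detect_dir, space)
    all_ts = {ts.subject_id: ts for ts in _load_timeseries(sim, space)}
    target_net = truth["target_network"]
    other_nets = [l for l in net_truth.present_labels() if l != target_net]

    rows = []
    for subj, subnets in per_subject.items():
        ts = all_ts[subj]
        for lab, nodes in subnets.items():
            for net in other_nets:
                z = subnetwork_network_fc(
                    ts, nodes, net_truth.node_set(net), space=space
                )
                rows.append(
                    {"subject": subj, "subnetwork": lab, "network": net, "z": z}
                )
    profiles = pd.DataFrame(rows)
    profiles.to_csv(out / "profiles.tsv", sep="\t", index=False)

    stats_out = {}
    for net in other_nets:
        sub = profiles[profiles.network == net]
        table = {
            subj: {
                str(l): g["z"].mean()
                for l, g in grp.groupby("subnetwork")
            }
            for subj, grp in sub.groupby("subject")
        }
        try:
            res = rm_anova(table, effect=f"network_{net}", n_tests=len(other_nets))
        except ValueError as exc:
            logger.warning("network %s ANOVA skipped: %s", net, exc)
            continue
        entry = {
            "F": res.f_stat, "df": list(res.df), "p": res.p,
            "p_bonferroni": res.p_bonferroni, "flags": res.flags,
        }
        if res.p_bonferroni < 0.05:
            per_level = {}
            for (subj, lev), g in sub.groupby(["subject", "subnetwork"]):
                per_level.setdefault(str(lev), {})[subj] = float(g["z"].mean())
            entry["post_hoc"] = [
                {"pair": list(pair), "t": t, "df": df, "p": p}
                for pair, t, df, p in post_hoc_paired(per_level)
            ]
        stats_out[f"network_{net}"] = entry

    # task analysis
    task_dir = sim / "task"
    task_stats = {}
    if task_dir.exists():
        conditions = sorted({p.name.rsplit("_", 1)[0] for p in task_dir.glob("*.tsv")})
        for cond in conditions:
            table = {}
            for p in sorted(task_dir.glob(f"{cond}_sub-*.tsv")):
                subj = p.stem.rsplit("_", 1)[1]
                if subj not in per_subject:
                    continue
                zmap = np.loadtxt(p, delimiter="\t")
                means = task_condition_means(zmap, per_subject[subj])
                table[subj] = {str(l): m for l, m in means.items()}
            try:
                res = rm_anova(table, effect=cond, n_tests=len(conditions))
                task_stats[cond] = {
                    "F": res.f_stat, "df": list(res.df), "p": res.p,
                    "p_bonferroni": res.p_bonferroni, "flags": res.flags,
                }
            except ValueError as exc:
                logger.warning("condition %s ANOVA skipped: %s", cond, exc)
    (out / "stats.json").write_text(
        json.dumps({"connectivity": stats_out, "task": task_stats}, indent=2) + "\n"
    )

    # spring graph for the first subject
    subj = sorted(per_subject)[0]
    clusters = []
    for lab, nodes in per_subject[subj].items():
        for i, reg in enumerate(
            extract_regions(nodes, space, config.min_cluster_area_mm2)
        ):
            clusters.append(
                GraphCluster(f"sub{lab}_r{i}", f"subnetwork_{lab}", reg.nodes)
            )
    for net in other_nets:
        for i, reg in enumerate(
            extract_regions(net_truth.node_set(net), space, config.min_cluster_area_mm2)
        ):
            clusters.append(
                GraphCluster(f"net{net}_r{i}", f"network_{net}", reg.nodes, is_network=True)
            )
    declared = [f"network_{net}" for net in other_nets]
    g, final_density, warn = spring_graph_export(
        all_ts[subj], clusters, declared,
        density=config.graph_density, step=config.graph_density_step,
        r_max=config.r_max,
    )
    export_graph(g, out / f"{subj}_graph")
    (out / "graph_info.json").write_text(
        json.dumps({"subject": subj, "final_density": final_density,
                    "warnings": warn}) + "\n"
    )
    write_manifest(out, "profile", config, [sim / "truth_networks.tsv"], config.rng_seed)
    return out


# ---------------------------------------------------------------------------
# lag


def run_lag(workdir: str | Path, config: AnalysisConfig) -> Path:
    """Seeded lag maps per subject and the group-level temporal ordering."""
    workdir = Path(workdir)
    sim, space, truth = _load_simulation(workdir)
    detect_dir = _require(workdir / "detect", "detect")
    out = _stage_dir(workdir, "lag")
    per_subject = load_subject_subnetworks(detect_dir, space)
    all_ts = {ts.subject_id: ts for ts in _load_timeseries(sim, space)}
    sub_truth = io.read_labelmap_tsv(sim / "truth_subnetworks.tsv", space)
    structures = {
        f"sub{l}": sub_truth.node_set(l) for l in truth["target_subnetworks"]
    }
    per_subject_maps = {}
    for subj, subnets in per_subject.items():
        maps = []
        for lab, nodes in sorted(subnets.items()):
            lm = seed_lag_map(all_ts[subj], nodes, config)
            maps.append(lm)
            df = pd.DataFrame(
                {
                    "node_id": np.arange(space.n_nodes),
                    "delay_s": lm.delay_s,
                    "valid": lm.valid.astype(int),
                    "peak_r": lm.peak_r,
                }
            )
            df.to_csv(out / f"{subj}_seed{lab}_lagmap.tsv", sep="\t", index=False)
        if maps:
            per_subject_maps[subj] = maps
    ordering = group_ordering(per_subject_maps, structures)
    (out / "ordering.json").write_text(
        json.dumps(
            {
                "mean_delay_s": ordering.mean_delay_s,
                "F": ordering.f_stat,
                "df": list(ordering.df),
                "p": ordering.p,
                "post_hoc": [
                    {"pair": list(pair), "t": t, "df": df, "p": p}
                    for pair, t, df, p in ordering.post_hoc
                ],
            },
            indent=2,
        )
        + "\n"
    )
    write_manifest(out, "lag", config, [sim / "truth_subnetworks.tsv"], config.rng_seed)
    return out


# ---------------------------------------------------------------------------
# report


def run_report(workdir: str | Path, config: AnalysisConfig) -> Path:
    """Collate cluster maps, term table, profiles, and ordering into a summary."""
    workdir = Path(workdir)
    out = _stage_dir(workdir, "report")
    summary: dict = {}
    lines = ["# Subnetwork pipeline summary", ""]
    match_manifest = workdir / "match" / "manifest.json"
    if match_manifest.exists():
        m = json.loads(match_manifest.read_text())
        summary["n_clusters"] = m.get("n_clusters")
        summary["n_subjects"] = m.get("n_subjects")
        lines.append(
            f"- Matched clusters: {m.get('n_clusters')} across {m.get('n_subjects')} subjects"
        )
    term_table = workdir / "mana" / "term_table.tsv"
    if term_table.exists():
        df = pd.read_csv(term_table, sep="\t")
        n_sig = int(df["significant"].sum()) if len(df) else 0
        summary["n_significant_terms"] = n_sig
        if n_sig:
            top = df[df.significant].nlargest(min(5, n_sig), "magnitude")
            lines.append(f"- Significant meta-analytic terms (FDR): {n_sig}")
            for _, r in top.iterrows():
                lines.append(
                    f"    - {r['term']} -> subnetwork {int(r['assigned_subnetwork'])} "
                    f"(q={r['q']:.3g})"
                )
        else:
            lines.append("- Meta-analytic annotation: no significant terms")
    stats_json = workdir / "profile" / "stats.json"
    if stats_json.exists():
        stats = json.loads(stats_json.read_text())
        sig = [k for k, v in stats.get("connectivity", {}).items()
               if v.get("p_bonferroni", 1) < 0.05]
        summary["significant_connectivity_effects"] = sig
        lines.append(f"- Networks with significant subnetwork FC differences: {len(sig)}")
    ordering_json = workdir / "lag" / "ordering.json"
    if ordering_json.exists():
        o = json.loads(ordering_json.read_text())
        summary["lag_ordering"] = o["mean_delay_s"]
        summary["lag_anova_p"] = o["p"]
        order = sorted(o["mean_delay_s"], key=o["mean_delay_s"].get)
        lines.append(
            f"- Temporal ordering (earliest first): {' < '.join(order)} "
            f"(ANOVA p={o['p']:.3g})"
        )
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    (out / "summary.md").write_text("\n".join(lines) + "\n")
    write_manifest(out, "report", config, [], config.rng_seed)
    return out


RUNNERS = {
    "simulate": run_simulate,
    "detect": run_detect,
    "match": run_match,
    "mana": run_mana,
    "profile": run_profile,
    "lag": run_lag,
    "report": run_report,
}


def run_pipeline(
    workdir: str | Path, config: AnalysisConfig, stages: list[str] | None = None
) -> None:
    """Run the requested stages (default: all) in canonical order."""
    stages = list(STAGES) if stages is None else stages
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in STAGES:
        if stage in stages:
            logger.info("running stage %s", stage)
            RUNNERS[stage](workdir, config)
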