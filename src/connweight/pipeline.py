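"""Pipeline driver: runs the analysis stages end to end from a config file.

Stages (in order): simulate, build, normalize, metrics, communities,
smallworld, predict, ablate.  Later stages consume the artifacts of earlier
ones; disabling a prerequisite makes dependents fail with a dependency
error.  A run manifest records the config snapshot, seeds, package version,
per-stage output hashes, and the design-decision flags in effect.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import community as community_mod
from . import connectome as conn_mod
from . import io as io_mod
from . import metrics as metrics_mod
from . import prediction as pred_mod
from . import smallworld as sw_mod
from .synthetic import CohortConfig, PlantedEffect, ScalarParams, generate_cohort, generate_scores

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "build",
    "normalize",
    "metrics",
    "communities",
    "smallworld",
    "predict",
    "ablate",
)

#: stage -> stages it requires
DEPENDENCIES = {
    "build": ("simulate",),
    "normalize": ("build",),
    "metrics": ("normalize",),
    "communities": ("normalize",),
    "smallworld": ("build",),
    "predict": ("build",),
    "ablate": ("predict",),
}

WEIGHT_KINDS = ("NOS", "FA", "ADD")


class ConfigurationError(ValueError):
    pass


class StageDependencyError(RuntimeError):
    pass


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    stages: list = field(default_factory=list)
    output_hashes: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _cohort_config(cfg: dict) -> CohortConfig:
    c = dict(cfg.get("cohort", {}))
    for key in ("fa_params", "add_params"):
        if key in c:
            c[key] = ScalarParams(**c[key])
    if "network_labels" in c:
        c["network_labels"] = tuple(c["network_labels"])
    try:
        return CohortConfig(**c)
    except TypeError as exc:
        raise ConfigurationError(f"bad cohort config: {exc}") from exc


def run_pipeline(
    config: dict | str | Path,
    outdir: str | Path,
    stages: tuple = STAGES,
    seed: int | None = None,
) -> RunManifest:
    """Execute the enabled stages in order and write a run manifest.

    ``config`` is a dict or a path to a YAML/JSON file.  ``seed`` overrides
    the config's cohort seed.  Deterministic given (config, seed).
    """
    if not isinstance(config, dict):
        config = io_mod.load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in stages:
        if s not in STAGES:
            raise ConfigurationError(f"unknown stage {s!r}")
    stages = tuple(s for s in STAGES if s in stages)

    cohort_cfg = _cohort_config(config)
    if seed is not None:
        cohort_cfg = cohort_cfg.with_seed(seed)
    manifest = RunManifest(config=config, seed=cohort_cfg.seed)
    manifest.flags = {
        "histogram_match_exclusion": "post-matching, values < 1 dropped",
        "efficiency_lengths": "1/w",
        "pca_fit": "full cohort before splitting",
        "mad_z_threshold": config.get("mad_z_threshold", 3.5),
    }
    art: dict = {}

    def require(stage: str) -> None:
        for dep in DEPENDENCIES.get(stage, ()):
            if dep not in manifest.stages:
                raise StageDependencyError(
                    f"stage {stage!r} requires {dep!r}, which did not run"
                )

    def record(stage: str, files: list[Path]) -> None:
        manifest.stages.append(stage)
        for f in files:
            manifest.output_hashes[str(f.relative_to(outdir))] = _sha256(f)

    for stage in stages:
        t0 = time.time()
        require(stage)
        files = _run_stage(stage, config, cohort_cfg, art, outdir)
        record(stage, files)
        logger.info("stage %s done in %.1f s", stage, time.time() - t0)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    return manifest


def _run_stage(stage, config, cohort_cfg, art, outdir) -> list:
    if stage == "simulate":
        atlas, tables = generate_cohort(cohort_cfg)
        art["atlas"], art["tables"] = atlas, tables
        p = outdir / "atlas.tsv"
        io_mod.write_atlas(p, atlas)
        return [p]

    if stage == "build":
        atlas, tables = art["atlas"], art["tables"]
        n = atlas.n_nodes
        art["matrices"] = {
            "NOS": [conn_mod.build_nos(t, n) for t in tables],
            "FA": [conn_mod.build_mean_scalar(t, "fa", n) for t in tables],
            "ADD": [conn_mod.build_mean_scalar(t, "add", n) for t in tables],
        }
        art["dist"] = conn_mod.build_distance(atlas)
        return []

    if stage == "normalize":
        mats = art["matrices"]
        thr = config.get("mad_z_threshold", 3.5)
        art["matched"] = {
            kind: [
                conn_mod.histogram_match(m, ref)
                for m, ref in zip(mats[kind], mats["NOS"])
            ]
            for kind in ("FA", "ADD")
        }
        art["matched"]["NOS"] = [
            conn_mod.histogram_match(m, m) for m in mats["NOS"]
        ]
        art["group_matched"] = {
            kind: conn_mod.group_average(ms, thr)
            for kind, ms in art["matched"].items()
        }
        files = []
        for kind, gm in art["group_matched"].items():
            p = outdir / f"group_{kind.lower()}_matched.npz"
            io_mod.write_matrix(p, gm)
            files.append(p)
        return files

    if stage == "metrics":
        files = []
        art["metrics"] = {}
        for kind, gm in art["group_matched"].items():
            strength = metrics_mod.node_strength(gm)
            eff = metrics_mod.nodal_efficiency(gm)
            r, p_val, n_edges = metrics_mod.edge_distance_correlation(gm, art["dist"])
            art["metrics"][kind] = {
                "strength": strength, "efficiency": eff,
                "edge_distance": {"r": r, "p": p_val, "n_edges": n_edges},
            }
            for vec in (strength, eff):
                p = outdir / f"{vec.metric}_{kind.lower()}.tsv"
                io_mod.write_node_metric(
                    p, vec.values,
                    {"metric": vec.metric, "kind": kind, "provenance": vec.provenance},
                )
                files.append(p)
        p = outdir / "edge_distance_correlations.json"
        p.write_text(json.dumps(
            {k: v["edge_distance"] for k, v in art["metrics"].items()}, indent=2
        ))
        files.append(p)
        return files

    if stage == "communities":
        ccfg = community_mod.ConsensusConfig(
            **config.get("consensus", {"n_samples": 100, "n_restarts": 20})
        )
        files = []
        art["communities"] = {}
        for kind, gm in art["group_matched"].items():
            gmin, gmax = community_mod.find_gamma_range(gm, ccfg)
            parts = community_mod.sample_partitions(gm, gmin, gmax, ccfg)
            cons = community_mod.consensus_partition(parts, ccfg)
            art["communities"][kind] = cons
            p = outdir / f"communities_{kind.lower()}.tsv"
            io_mod.write_partition(
                p, cons,
                {"gamma_range": [gmin, gmax], "n_samples": ccfg.n_samples,
                 "tau": ccfg.tau, "seed": ccfg.seed},
            )
            files.extend([p, p.with_suffix(p.suffix + ".json")])
        return files

    if stage == "smallworld":
        n_nulls = config.get("swp_n_nulls", 10)
        rows = []
        phi = {}
        for kind in WEIGHT_KINDS:
            phi[kind] = []
            for s, m in enumerate(art["matrices"][kind]):
                res = sw_mod.swp(m, n_nulls=n_nulls, seed=cohort_cfg.seed + s)
                phi[kind].append(res)
                rows.append((m.provenance, kind, res.phi, res.delta_c, res.delta_l))
        p = outdir / "swp.tsv"
        with open(p, "w") as fh:
            fh.write("subject\tweight_kind\tphi\tdelta_c\tdelta_l\n")
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        files = [p]
        if len(art["matrices"]["NOS"]) >= 3:
            mat = np.array(
                [[phi[k][s].phi for k in WEIGHT_KINDS]
                 for s in range(len(phi["NOS"]))]
            )
            stats = sw_mod.swp_group_stats(mat, kinds=WEIGHT_KINDS)
            ps = outdir / "swp_stats.json"
            ps.write_text(json.dumps({
                "f_statistic": stats.f_statistic,
                "f_p_value": stats.f_p_value,
                "pairwise_t": {f"{a}-{b}": t for (a, b), t in stats.pairwise_t.items()},
                "p_corrected": {f"{a}-{b}": v for (a, b), v in stats.p_values.items()},
            }, indent=2))
            files.append(ps)
        art["swp"] = phi
        return files

    if stage == "predict":
        pcfg = config.get("predict", {})
        kind = pcfg.get("weight_kind", "FA")
        atlas = art["atlas"]
        partition = pred_mod.partition_subnetworks(atlas)
        mats = art["matrices"][kind]
        block_means = pred_mod.block_mean_table(mats, partition)
        effect_cfg = pcfg.get("planted_effect")
        if effect_cfg is None:
            effect = pred_mod.default_planted_effect(partition)
        else:
            label_to_id = {b.label: b.block_id for b in partition.blocks}
            coeffs = {
                label_to_id[lab]: v
                for lab, v in effect_cfg.get("coefficients", {}).items()
            }
            effect = PlantedEffect(
                block_coefficients=coeffs,
                noise_sd=effect_cfg.get("noise_sd", 0.0),
            )
        scores = generate_scores(block_means, effect, seed=cohort_cfg.seed + 7777)
        spec = pred_mod.ModelSpec(**pcfg.get("model", {}))
        n_iter = pcfg.get("n_iter", 100)
        feats_sub = pred_mod.assemble_features(
            mats, partition, "subnetworks", pcfg.get("subnetwork_threshold", 0.2)
        )
        feats_wb = pred_mod.assemble_features(
            mats, partition, "whole_brain", pcfg.get("whole_brain_threshold", 0.3)
        )
        res_sub = pred_mod.fit_and_evaluate(
            feats_sub, scores, spec, n_iter, cohort_cfg.seed, label=f"{kind}_subnetworks"
        )
        res_wb = pred_mod.fit_and_evaluate(
            feats_wb, scores, spec, n_iter, cohort_cfg.seed, label=f"{kind}_whole_brain"
        )
        table = pred_mod.compare_models([res_sub, res_wb])
        art["prediction"] = {
            "partition": partition, "scores": scores, "spec": spec,
            "features_sub": feats_sub, "result_sub": res_sub,
            "result_wb": res_wb, "n_iter": n_iter,
        }
        p = outdir / "prediction_comparison.tsv"
        table.to_csv(p, sep="\t", index=False)
        return [p]

    if stage == "ablate":
        pr = art["prediction"]
        full, results = pred_mod.ablation_importance(
            pr["features_sub"], pr["partition"], pr["scores"], pr["spec"],
            n_iter=pr["n_iter"], seed=cohort_cfg.seed,
            full_result=pr["result_sub"],
        )
        p = outdir / "ablation.tsv"
        with open(p, "w") as fh:
            fh.write("group\tmedian_r\tdelta_median_r\twilcoxon_statistic\tp_corrected\n")
            for res in results:
                fh.write(
                    f"{res.group}\t{np.nanmedian(res.r):.6g}\t{res.delta_median_r:.6g}"
                    f"\t{res.wilcoxon_statistic:.6g}\t{res.p_corrected:.6g}\n"
                )
        return [p]

    raise ConfigurationError(f"unknown stage {stage!r}")
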