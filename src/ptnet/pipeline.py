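"""End-to-end orchestration: data -> networks -> metrics -> regressions.

``run_pipeline`` executes the whole analysis for either a pair of input
CSVs (trait matrix + environmental table) or a synthetic configuration,
and writes every artefact — per-group edge lists, GraphML, adjacency
matrices, node and topology metric tables, CV tables, screening and
regression reports — plus a JSON manifest recording the configuration,
input checksums, package versions, and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigurationError, InsufficientDataError, JoinError, PTNError
from .graph_metrics import (
    identify_hubs,
    node_metrics,
    node_metrics_frame,
    topology_metrics,
)
from .network import networks_per_group, pearson_with_pvalues, write_network
from .regression import (
    cv_vs_node_metrics,
    regression_report,
    screen_and_regress,
    topology_vs_group_cv,
)
from .synthetic import SyntheticConfig, generate, write_dataset
from .trait_data import (
    EnvTable,
    cv_table,
    read_env_table,
    read_trait_matrix,
    write_cv_tables,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one data source must be set."""

    trait_path: str | None = None
    env_path: str | None = None
    group_column: str = "group"
    synthetic: SyntheticConfig | None = None
    alpha: float = 0.05
    community_method: str = "greedy"
    p_remove: float = 0.10
    out_dir: str = "ptnet_out"
    seed: int = 0
    top_n: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha must be in (0,1), got {self.alpha}")
        has_files = self.trait_path is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ConfigurationError(
                "exactly one of (trait/env input paths, synthetic config) "
                "must be provided"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", None)
        if synth is not None:
            env_model = synth.pop("env_model", None)
            if env_model is not None:
                from .synthetic import EnvModel

                synth["env_model"] = EnvModel(
                    **{k: tuple(v) if isinstance(v, list) else v
                       for k, v in env_model.items()}
                )
            synth = SyntheticConfig(**synth)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(synthetic=synth, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "community_method": config.community_method,
        "p_remove": config.p_remove,
        "inputs": {},
        "stages": [],
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        if config.synthetic is not None:
            # the pipeline seed is the single source of randomness
            sc = SyntheticConfig(**{**config.synthetic.__dict__,
                                    "seed": config.seed})
            ds = generate(sc)
            paths = write_dataset(ds, out / "synthetic")
            manifest["inputs"] = {
                k: {"path": str(p), "sha256": _sha256(p)} for k, p in paths.items()
            }
            tm, env = ds.trait_matrix, ds.env_table
        else:
            tm = read_trait_matrix(config.trait_path, config.group_column)
            env = (
                read_env_table(config.env_path, config.group_column)
                if config.env_path
                else None
            )
            manifest["inputs"]["traits"] = {
                "path": config.trait_path,
                "sha256": _sha256(Path(config.trait_path)),
            }
            if config.env_path:
                manifest["inputs"]["env"] = {
                    "path": config.env_path,
                    "sha256": _sha256(Path(config.env_path)),
                }
        if env is not None:
            unknown = [g for g in tm.groups if g not in env.groups]
            if unknown:
                raise JoinError(
                    f"trait groups missing from environmental table: {unknown}",
                    unmatched=unknown,
                )

        stage("cv")
        cvt = cv_table(tm)
        write_cv_tables(cvt, out)

        stage("networks")
        nets = networks_per_group(tm, alpha=config.alpha)
        corr = {g: pearson_with_pvalues(tm, g) for g in tm.groups}
        for g, net in nets.items():
            write_network(net, out / "networks", f"network_{g}", corr[g])

        stage("metrics")
        node_frames = {}
        topo_rows = []
        hub_rows = []
        for g, net in nets.items():
            topo = topology_metrics(net, method=config.community_method,
                                    seed=config.seed)
            nm = node_metrics(net)
            for x in nm:
                x.module = topo.module_assignment[x.trait_name]
            frame = node_metrics_frame(nm)
            frame.insert(0, "group", g)
            node_frames[g] = frame
            topo_rows.append(
                {
                    "group": g,
                    "ED": topo.edge_density,
                    "AL": topo.average_path_length,
                    "AC": topo.average_clustering,
                    "Q": topo.modularity,
                    "n_modules": topo.n_modules,
                    "n_edges": topo.n_edges,
                }
            )
            hubs = identify_hubs(nm, top_n=min(config.top_n, len(nm)))
            for kind, table in (("hub", hubs.hubs), ("mediator", hubs.mediators)):
                for _, row in table.iterrows():
                    hub_rows.append({"group": g, "role": kind, **row.to_dict()})
        pd.concat(node_frames.values(), ignore_index=True).to_csv(
            out / "node_metrics.csv", index=False
        )
        topo_df = pd.DataFrame(topo_rows).set_index("group")
        topo_df.to_csv(out / "topology_metrics.csv")
        pd.DataFrame(hub_rows).to_csv(out / "hub_traits.csv", index=False)
        manifest["n_networks"] = len(nets)
        manifest["topology_rows"] = len(topo_rows)

        stage("regressions")
        metrics_only = topo_df[["ED", "AL", "AC", "Q"]]
        reports = {}
        try:
            node_models = cv_vs_node_metrics(cvt, node_frames)
            reports.update({f"{k}_on_cv": v for k, v in node_models.items()})
        except (InsufficientDataError, JoinError) as exc:
            logger.warning("cv-vs-node regression skipped: %s", exc)
        try:
            topo_models = topology_vs_group_cv(cvt, metrics_only)
            reports.update({f"{k}_on_mean_cv": v for k, v in topo_models.items()})
        except InsufficientDataError as exc:
            logger.warning("topology-vs-CV regression skipped: %s", exc)
        if env is not None:
            try:
                screens, env_models = screen_and_regress(
                    metrics_only, env, alpha=config.alpha, p_remove=config.p_remove
                )
                pd.DataFrame(
                    [s.__dict__ for s in screens]
                ).to_csv(out / "environment_screen.csv", index=False)
                reports.update({f"{k}_on_env": v for k, v in env_models.items()})
            except InsufficientDataError as exc:
                logger.warning("environment screening skipped: %s", exc)
        if reports:
            rep = regression_report(reports)
            rep.to_csv(out / "regressions.csv", index=False)
            (out / "regressions.txt").write_text(
                "\n".join(
                    f"{r.equation()}  (R2={r.r_squared:.2f}; F={r.f_statistic:.3f}; "
                    f"P={r.p_value:.4f}; n={r.n_obs})"
                    for r in reports.values()
                )
                + "\n"
            )
        manifest["n_regressions"] = len(reports)
    except PTNError:
        manifest["status"] = "failed"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    manifest["status"] = "ok"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
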