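"""Config-driven orchestration of the full analysis pipeline.

One :class:`RunConfig` drives simulate (or load) -> filter -> diversity ->
beta statistics -> per-stratum networks -> stability -> comparison report.
Every stochastic stage receives a seed derived deterministically from the
global seed plus the stage name (and stratum label), so adding a stratum
never perturbs another stratum's results, and rerunning a config reproduces
every artifact checksum exactly.
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
import pandas as pd
import yaml

from . import beta, datagen, network, profiles, stability
from ._util import derive_seed

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serialisable to/from YAML or JSON."""

    seed: int = 0
    outdir: str = "streamnet_out"
    # either file inputs ...
    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    # ... or a simulation block
    simulate: bool = True
    design: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    persistent_loss: bool = False
    # filters
    filter_singletons: bool = True
    prevalence_min: float = 0.3
    abundance_threshold: float | None = None
    # beta statistics
    anosim_groups: list = field(default_factory=lambda: ["hydrology", "habitat"])
    n_permutations: int = 999
    anosim_alpha: float = 0.05
    nmds_dimensions: int = 2
    nmds_starts: int = 20
    # network
    rho_min: float = 0.7
    alpha: float = 0.001
    p_method: str = "t_approx"
    strata: list = field(default_factory=lambda: ["hydrology", "day"])
    # stability
    removal_fraction: float = 0.5
    n_reps: int = 100

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            doc = (
                json.load(fh)
                if path.suffix == ".json"
                else yaml.safe_load(fh)
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Decorator-ish context: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            log.info("stage %-12s done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def _stratum_label(cols: list, key) -> str:
    vals = key if isinstance(key, tuple) else (key,)
    return "_".join(f"{c}-{v}" for c, v in zip(cols, vals))


def run_pipeline(config: RunConfig) -> Path:
    """Run the full pipeline; returns the output directory.

    Artifacts: counts/design/truth (if simulated), diversity tables, ANOSIM
    JSON, NMDS coordinates, per-stratum GraphML + edge lists + role tables +
    stability reports, a cross-network comparison table, and a manifest with
    a sha256 checksum for every file.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, **kw) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=False, **kw)
        artifacts.append(p)

    def save_json(doc: dict, name: str) -> None:
        p = out / name
        with open(p, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True, default=float)
        artifacts.append(p)

    # -- config is serialised verbatim into the run directory
    save_json(config.to_dict(), "config.json")

    taxonomy = None
    with _stage("input"):
        if config.simulate:
            design = datagen.generate_design(**config.design)
            truth = datagen.make_truth(
                seed=derive_seed(config.seed, "truth"), **config.truth
            )
            table = datagen.generate_counts(
                truth,
                design,
                seed=derive_seed(config.seed, "counts"),
                persistent_loss=config.persistent_loss,
            )
            truth.to_json(out / "truth.json")
            artifacts.append(out / "truth.json")
        else:
            if not config.counts_path or not config.metadata_path:
                raise ValueError(
                    "counts_path and metadata_path are required when "
                    "simulate is false"
                )
            table = profiles.read_count_table(config.counts_path)
            design = pd.read_csv(config.metadata_path, sep="\t")
        if config.taxonomy_path:
            taxonomy = profiles.read_annotation_map(config.taxonomy_path)
        profiles.write_count_table(table, out / "counts.tsv")
        artifacts.append(out / "counts.tsv")
        design.to_csv(out / "design.tsv", sep="\t", index=False)
        artifacts.append(out / "design.tsv")

    with _stage("filter"):
        n0 = table.shape[1]
        if config.filter_singletons:
            table = profiles.filter_singletons(table)
        if config.abundance_threshold is not None:
            table = profiles.filter_abundant(table, config.abundance_threshold)
        log.info("filters kept %d of %d taxa", table.shape[1], n0)

    with _stage("diversity"):
        summary = profiles.diversity_summary(table, design)
        save_df(summary, "diversity.tsv")
        by = [c for c in ("hydrology", "habitat", "day") if c in summary.columns]
        if by:
            save_df(profiles.group_diversity_stats(summary, by),
                    "diversity_groups.tsv")

    with _stage("beta"):
        dm_bray = beta.distance_matrix(table, "bray_curtis")
        frame = dm_bray.to_frame()
        frame.index.name = "sample_id"
        frame.to_csv(out / "distance_bray.tsv", sep="\t")
        artifacts.append(out / "distance_bray.tsv")
        anosim_out = {}
        pvals, names = [], []
        for col in config.anosim_groups:
            if col not in design.columns:
                continue
            labels = (
                design.set_index("sample_id")
                .loc[dm_bray.sample_ids, col]
                .tolist()
            )
            res = beta.anosim(
                dm_bray,
                labels,
                n_permutations=config.n_permutations,
                seed=derive_seed(config.seed, "anosim", col),
            )
            anosim_out[col] = res.to_dict()
            pvals.append(res.p)
            names.append(col)
        if pvals:
            adj, rej = beta.bonferroni(pvals, alpha=config.anosim_alpha)
            for name, a, r in zip(names, adj, rej):
                anosim_out[name]["p_bonferroni"] = float(a)
                anosim_out[name]["reject"] = bool(r)
        save_json(anosim_out, "anosim.json")

        dm_eucl = beta.distance_matrix(table, "euclidean")
        nm = beta.nmds(
            dm_eucl,
            k=config.nmds_dimensions,
            n_starts=config.nmds_starts,
            seed=derive_seed(config.seed, "nmds"),
        )
        coords = pd.DataFrame(
            nm.configuration,
            columns=[f"NMDS{i + 1}" for i in range(config.nmds_dimensions)],
        )
        coords.insert(0, "sample_id", dm_eucl.sample_ids)
        save_df(coords, "nmds_coords.tsv")
        save_json(
            {"stress": nm.stress, "converged": nm.converged,
             "n_starts": nm.n_starts, "metric": "euclidean"},
            "nmds.json",
        )

    reports = []
    with _stage("networks"):
        strata_cols = [c for c in config.strata if c in design.columns]
        groups = (
            design.groupby(strata_cols, observed=True).groups.items()
            if strata_cols
            else [("all", design.index)]
        )
        for key, idx in groups:
            label = (
                _stratum_label(strata_cols, key) if strata_cols else "all"
            )
            sample_ids = design.loc[idx, "sample_id"].tolist()
            core = network.select_core_taxa(
                table, config.prevalence_min, sample_ids
            )
            if core.shape[0] < 5 or core.shape[1] < 2:
                log.warning("stratum %s too small for a network; skipped", label)
                continue
            candidates = network.spearman_screen(
                core,
                rho_min=config.rho_min,
                alpha=config.alpha,
                p_method=config.p_method,
                seed=derive_seed(config.seed, "screen", label),
            )
            net = network.build_network(candidates, name=label)
            partition = network.detect_modules(
                net, seed=derive_seed(config.seed, "modules", label)
            )
            roles = (
                network.node_roles(net, partition)
                if net.number_of_nodes()
                else pd.DataFrame(
                    columns=["node", "module", "zi", "pi", "degree", "role"]
                )
            )
            network.write_graphml(net, out / f"network_{label}.graphml",
                                  roles if len(roles) else None, taxonomy)
            artifacts.append(out / f"network_{label}.graphml")
            network.write_edge_list(net, out / f"edges_{label}.csv")
            artifacts.append(out / f"edges_{label}.csv")
            save_df(roles, f"roles_{label}.tsv")
            save_df(network.keystone_summary(roles, taxonomy)
                    if len(roles)
                    else pd.DataFrame(columns=["label", "role", "count"]),
                    f"keystones_{label}.tsv")
            rep = stability.stability_report(
                net,
                partition,
                removal_fraction=config.removal_fraction,
                n_reps=config.n_reps,
                seed=derive_seed(config.seed, "robustness", label),
            )
            save_json(rep.to_dict(), f"stability_{label}.json")
            reports.append(rep)

    with _stage("compare"):
        if len(reports) >= 2:
            long, deltas = stability.compare_networks(reports)
            save_df(long, "comparison.tsv")
            save_df(deltas, "comparison_deltas.tsv")

    with _stage("manifest"):
        manifest = {
            "files": {p.name: _sha256(p) for p in sorted(set(artifacts))},
            "seed": config.seed,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    return out
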