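"""End-to-end study analogue: diversity → PERMANOVA → networks → cohesion.

``run_all`` drives every stage from one :class:`RunConfig` (YAML-loadable) and
writes a result bundle of plain-text artifacts per group:

* per-sample Shannon alpha diversity and bacteria-vs-phage Mann–Whitney tests;
* Bray–Curtis distance matrices, NMDS coordinates, UPGMA dendrograms (Newick);
* a PERMANOVA table (one row per factor per domain, Df/F/R2/p);
* Sørensen composition-coupling regressions (all samples and per group);
* co-occurrence networks in bacteria / phage / interdomain modes with
  topology, keystone and module tables, GraphML and edge-list exports;
* a network summary table (nodes, edges, signed-edge rates, 2E/N, modularity);
* cohesion tables with between-group comparisons;
* a JSON manifest recording versions, seeds and thresholds.

One master seed is configured; each stage derives its own seed from a stable
hash of (master seed, stage name) so stages can be rerun independently and a
rerun of the whole bundle is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
import platform
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .tables import (
    AbundanceTable,
    read_tables,
    relative_abundance,
    to_presence_absence,
    top_k_by_abundance,
    write_tables,
)
from .synth import BlockSpec, HubSpec, SynthConfig, generate_community
from . import diversity as dv
from . import network as nw
from . import cohesion as ch

NETWORK_MODES = ("bacteria", "phage", "interdomain")

TABLE2_COLUMNS = [
    "Network",
    "Group",
    "Node",
    "Edge",
    "Positive Correlation",
    "Negative Correlation",
    "Positive Correlation Rate",
    "Negative Correlation Rate",
    "Average Degree",
    "Modularity Value",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    abundance_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    synth: SynthConfig | None = None
    groups: list[str] | None = None
    rho_min: float = 0.6
    q_max: float = 0.01
    top_k_bacteria: int = 1000
    permutations: int = 999
    pa_threshold: float = 0.0
    nmds_restarts: int = 20
    cohesion_iterations: int = 200
    cohesion_min_prevalence: float = 0.1
    cohesion_kind: str = "pearson"
    factors: tuple[str, ...] = ("diet", "host_order", "host_family")

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.rho_min <= 1:
            raise ValueError(f"rho_min {self.rho_min} outside (0, 1]")
        if not 0 < self.q_max <= 1:
            raise ValueError(f"q_max {self.q_max} outside (0, 1]")
        if self.top_k_bacteria < 1:
            raise ValueError("top_k_bacteria must be >= 1")
        if self.permutations < 99:
            raise ValueError("permutations must be >= 99")
        if self.pa_threshold < 0:
            raise ValueError("pa_threshold must be >= 0")
        has_paths = all(
            p is not None
            for p in (self.abundance_path, self.taxonomy_path, self.metadata_path)
        )
        if has_paths == (self.synth is not None):
            raise ValueError("configure either the three input paths or a synth block")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        synth = raw.pop("synth", None)
        if synth is not None:
            synth = synth_config_from_dict(synth)
        factors = tuple(raw.pop("factors", ("diet", "host_order", "host_family")))
        return cls(synth=synth, factors=factors, **raw)


def synth_config_from_dict(raw: dict[str, Any]) -> SynthConfig:
    raw = dict(raw)
    blocks = tuple(
        BlockSpec(tuple(b["members"]), float(b["rho"])) for b in raw.pop("block_specs", [])
    )
    hubs = tuple(
        HubSpec(h["hub"], tuple(h["satellites"]), int(h.get("sign", 1)))
        for h in raw.pop("hub_specs", [])
    )
    return SynthConfig(block_specs=blocks, hub_specs=hubs, **raw)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from the master seed."""
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _tsv(frame: pd.DataFrame, path, **kwargs) -> None:
    frame.to_csv(path, sep="\t", **kwargs)


def make_table2(summaries: dict[tuple[str, str], nw.NetworkSummary]) -> pd.DataFrame:
    """Network summary rows ordered (mode, group), columns matching the field's
    conventional topology-table layout."""
    if not summaries:
        raise ValueError("need at least one summary")
    label = {"bacteria": "Bacteria", "phage": "Phages", "interdomain": "Bacteria–Phages"}
    order = {m: i for i, m in enumerate(NETWORK_MODES)}
    rows = []
    for (mode, group), s in sorted(
        summaries.items(), key=lambda kv: (order.get(kv[0][0], 99), kv[0][1])
    ):
        rows.append(
            {
                "Network": label.get(mode, mode),
                "Group": group,
                "Node": s.node_count,
                "Edge": s.edge_count,
                "Positive Correlation": s.positive_edges,
                "Negative Correlation": s.negative_edges,
                "Positive Correlation Rate": _pct(s.positive_rate),
                "Negative Correlation Rate": _pct(s.negative_rate),
                "Average Degree": s.average_degree,
                "Modularity Value": s.modularity_Q,
            }
        )
    return pd.DataFrame(rows, columns=TABLE2_COLUMNS)


def _pct(rate: float | None) -> str:
    return "" if rate is None else f"{rate:.2f}%"


def _load_table(config: RunConfig):
    if config.synth is not None:
        table, truth = generate_community(config.synth)
        return table, truth
    table = read_tables(config.abundance_path, config.taxonomy_path, config.metadata_path)
    return table, None


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run every stage; returns a manifest dict (also written to disk)."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict[str, Any] = {
        "phagenet_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "rho_min": config.rho_min,
        "q_max": config.q_max,
        "top_k_bacteria": config.top_k_bacteria,
        "permutations": config.permutations,
        "cohesion": {
            "n_iter": config.cohesion_iterations,
            "kind": config.cohesion_kind,
            "min_prevalence": config.cohesion_min_prevalence,
        },
        "stages": {},
        "notes": [],
    }

    def _stage(name):
        seed = stage_seed(config.seed, name)
        manifest["stages"][name] = {"seed": seed}
        return seed

    try:
        table, truth = _load_table(config)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'load': {exc}") from exc
    if truth is not None:
        write_tables(table, config.out_dir, prefix="synthetic")
        truth.to_json(os.path.join(config.out_dir, "synthetic_ground_truth.json"))

    groups = config.groups or table.groups()
    table = table.subset_samples(
        table.metadata.index[table.metadata["group"].isin(groups)]
    )
    # each domain is analyzed as its own composition (re-closed to sum 1):
    # whole-table closure would otherwise leak variation between domains
    by_domain = {
        d: relative_abundance(table.subset_domain(d)) for d in ("bacteria", "phage")
    }

    # ---- alpha diversity + bacteria-vs-phage comparison per group --------
    try:
        _stage("alpha")
        alpha = pd.DataFrame(
            {
                "bacteria": dv.alpha_diversity(by_domain["bacteria"]),
                "phage": dv.alpha_diversity(by_domain["phage"]),
            }
        )
        alpha["group"] = table.metadata["group"]
        _tsv(alpha, os.path.join(config.out_dir, "alpha_diversity.tsv"),
             index_label="sample_id")
        tests = []
        for g in groups:
            sub = alpha[alpha["group"] == g]
            U, p = dv.mann_whitney(sub["bacteria"], sub["phage"])
            tests.append({"group": g, "U": U, "p": p})
        _tsv(pd.DataFrame(tests), os.path.join(config.out_dir, "alpha_tests.tsv"),
             index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'alpha': {exc}") from exc

    # ---- beta diversity, ordination, clustering, PERMANOVA ---------------
    dist: dict[str, dv.DistanceMatrix] = {}
    try:
        nmds_seed = _stage("beta")
        permanova_seed = stage_seed(config.seed, "permanova")
        manifest["stages"]["permanova"] = {"seed": permanova_seed}
        permanova_rows = []
        for domain, sub in by_domain.items():
            D = dv.bray_curtis(sub)
            dist[domain] = D
            _tsv(D.to_frame(), os.path.join(config.out_dir, f"braycurtis_{domain}.tsv"))
            ord_res = dv.nmds(D, n_restarts=config.nmds_restarts, seed=nmds_seed)
            _tsv(
                ord_res.coordinates.assign(stress=ord_res.stress),
                os.path.join(config.out_dir, f"nmds_{domain}.tsv"),
                index_label="sample_id",
            )
            newick = dv.hclust_average(D).to_newick()
            with open(os.path.join(config.out_dir, f"upgma_{domain}.nwk"), "w") as fh:
                fh.write(newick + "\n")
            for factor in config.factors:
                if table.metadata[factor].nunique() < 2:
                    manifest["notes"].append(
                        f"factor {factor!r} has a single level; PERMANOVA skipped"
                    )
                    continue
                res = dv.permanova(
                    D,
                    table.metadata[factor],
                    n_permutations=config.permutations,
                    seed=permanova_seed,
                    factor_name=factor,
                )
                permanova_rows.append(
                    {
                        "Group": "Bacteria" if domain == "bacteria" else "Phages",
                        "Type": factor,
                        "Df": res.df,
                        "F": res.pseudo_F,
                        "R2": res.R2,
                        "p": res.p_value,
                    }
                )
        _tsv(pd.DataFrame(permanova_rows),
             os.path.join(config.out_dir, "permanova.tsv"), index=False)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'beta': {exc}") from exc

    # ---- composition coupling (Sørensen) ---------------------------------
    try:
        _stage("coupling")
        rows = []
        scopes = [("all", table)] + [(g, table.subset_group(g)) for g in groups]
        for scope, sub in scopes:
            if sub.n_samples < 3:
                manifest["notes"].append(f"coupling scope {scope!r} has < 3 samples; skipped")
                continue
            Db = dv.sorensen(to_presence_absence(sub.subset_domain("bacteria"),
                                                 config.pa_threshold))
            Dp = dv.sorensen(to_presence_absence(sub.subset_domain("phage"),
                                                 config.pa_threshold))
            try:
                fit = dv.coupling_regression(Db, Dp)
            except ValueError as exc:
                manifest["notes"].append(f"coupling scope {scope!r}: {exc}")
                continue
            rows.append(
                {
                    "scope": scope,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "p": fit.p_value,
                    "r_squared": fit.r_squared,
                    "n_pairs": fit.n_pairs,
                }
            )
        _tsv(pd.DataFrame(rows), os.path.join(config.out_dir, "coupling.tsv"), index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'coupling': {exc}") from exc

    # ---- networks ---------------------------------------------------------
    summaries: dict[tuple[str, str], nw.NetworkSummary] = {}
    try:
        _stage("network")
        net_dir = os.path.join(config.out_dir, "networks")
        os.makedirs(net_dir, exist_ok=True)
        for g in groups:
            sub = table.subset_group(g)
            sub = top_k_by_abundance(sub, "bacteria", config.top_k_bacteria)
            for mode in NETWORK_MODES:
                screen = nw.spearman_screen(sub, mode=mode, group=g)
                net = nw.build_network(screen, config.rho_min, config.q_max)
                tag = f"{g}_{mode}"
                net.to_graphml(os.path.join(net_dir, f"{tag}.graphml"))
                _tsv(net.edge_list(), os.path.join(net_dir, f"{tag}_edges.tsv"),
                     index=False)
                if net.n_edges == 0:
                    summaries[(mode, g)] = nw.network_summary(net)
                    continue
                topo = nw.topology(net)
                partition = nw.modularity_partition(net)
                topo["module"] = pd.Series(partition.assignment)
                _tsv(topo, os.path.join(net_dir, f"{tag}_topology.tsv"))
                _tsv(nw.keystone_zscore(topo), os.path.join(net_dir, f"{tag}_keystones.tsv"))
                summaries[(mode, g)] = nw.network_summary(net, partition)
        _tsv(make_table2(summaries),
             os.path.join(config.out_dir, "network_summary.tsv"), index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'network': {exc}") from exc

    # ---- cohesion ----------------------------------------------------------
    try:
        coh_seed = _stage("cohesion")
        per_group = {g: table.subset_group(g) for g in groups}
        usable = {g: t for g, t in per_group.items() if t.n_samples >= 5}
        for g in set(per_group) - set(usable):
            manifest["notes"].append(f"group {g!r} has < 5 samples; cohesion skipped")
        if usable:
            _, long, comps = ch.cohesion_by_group(
                usable,
                n_iter=config.cohesion_iterations,
                seed=coh_seed,
                kind=config.cohesion_kind,
                min_prevalence=config.cohesion_min_prevalence,
            )
            _tsv(long, os.path.join(config.out_dir, "cohesion.tsv"), index=False)
            _tsv(comps, os.path.join(config.out_dir, "cohesion_tests.tsv"), index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'cohesion': {exc}") from exc

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
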