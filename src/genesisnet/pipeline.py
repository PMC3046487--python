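"""End-to-end orchestration: inputs -> classify -> network -> statistics.

A single YAML-style config drives one reproducible run.  Exactly one of
``inputs`` (paths to the five tables) or ``simulate`` (synthetic-generator
parameters) must be present.  All randomness flows from one root seed
through named per-stage substreams, so toggling one stage never perturbs
another stage's draws.

Artifacts written to the output directory:

* ``classification.tsv`` — per-gene age/origin labels and rule fired
* ``centrality.tsv``     — per-protein degree/betweenness (+ per-aa)
* ``group_summary.tsv``  — per-group mean/SE of each centrality statistic
* ``assort.tsv``         — group-pair interaction counts vs the null
* ``table1.tsv``         — per-group functional attribute summaries
* ``young_novel_subnet.tsv`` — ego subnetwork edge list of young novel
  proteins, plus ``young_novel_components.tsv`` with the component report
* ``run_log.json``       — config echo, seeds, versions, filter decisions
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import genesisnet
from genesisnet import assortativity, attributes, classification, dataio, network
from genesisnet import synthetic_data

logger = logging.getLogger(__name__)

#: fixed substream index per stage (stable across config changes)
_STAGE_STREAMS = {"simulate": 0, "classify": 1, "null_ensemble": 2}

_FLOAT_FORMAT = "%.10g"


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed for one pipeline run."""

    outdir: str = "genesisnet_out"
    inputs: dict | None = None  # catalog/edges/families/reconstruction/orthologs paths
    simulate: dict | None = None  # kwargs for synthetic_data.SyntheticConfig
    sticky_threshold: int = 50
    n_random: int = 1000
    alpha: float = 0.05
    seed: int = 0
    exclude_essential: bool = False
    exclude_subtelomeric: bool = False
    source_filter: str | None = None
    progenitor_variant: bool = False
    species_ranks: dict = field(
        default_factory=lambda: dict(synthetic_data.DEFAULT_SPECIES_RANKS)
    )

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigError("exactly one of 'inputs' and 'simulate' must be given")
        if self.inputs is not None:
            required = ("catalog", "edges", "families", "reconstruction", "orthologs")
            missing = [k for k in required if k not in self.inputs]
            if missing:
                raise ConfigError(f"inputs missing paths for {missing}")
            for key in required:
                if not Path(self.inputs[key]).exists():
                    raise ConfigError(f"input file not found: {self.inputs[key]}")
        if self.n_random < 1:
            raise ConfigError("n_random must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.sticky_threshold < 1:
            raise ConfigError("sticky_threshold must be >= 1")
        if self.source_filter is not None and self.source_filter not in dataio.EDGE_SOURCES:
            raise ConfigError(f"unknown source_filter {self.source_filter!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _stage_seed(config: RunConfig, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([config.seed, _STAGE_STREAMS[stage]])


def _build_simulate_config(config: RunConfig) -> synthetic_data.SyntheticConfig:
    params = dict(config.simulate or {})
    params.pop("seed", None)  # the run seed governs; avoid two seed knobs
    if "group_sizes" in params:
        params["group_sizes"] = {
            tuple(k.split("/")) if isinstance(k, str) else tuple(k): v
            for k, v in params["group_sizes"].items()
        }
    if "mixing" in params and isinstance(params["mixing"], dict):
        mix = params["mixing"]
        if set(mix) == {"within", "between"}:
            params["mixing"] = synthetic_data.assortative_mixing(
                mix["within"], mix["between"]
            )
        else:
            params["mixing"] = {
                tuple(sorted(k.split("="))): v for k, v in mix.items()
            }
    scale = params.pop("scale", None)
    sim = synthetic_data.SyntheticConfig(**params)
    if scale is not None:
        sim = sim.scaled(scale)
    return sim


def _write_frame(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns a summary dict (also saved as run_log.json)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "package_version": genesisnet.__version__,
        "seed": config.seed,
        "stages": {},
    }

    # ---- stage: obtain inputs -------------------------------------------
    try:
        if config.simulate is not None:
            sim_config = _build_simulate_config(config)
            sim_config.seed = config.seed  # recorded; substream actually used
            dataset = synthetic_data.generate_dataset(
                sim_config, seed=_stage_seed(config, "simulate")
            )
            inputs_dir = outdir / "inputs"
            dataset.write(inputs_dir)
            paths = {
                "catalog": inputs_dir / "catalog.tsv",
                "edges": inputs_dir / "edges.tsv",
                "families": inputs_dir / "families.tsv",
                "reconstruction": inputs_dir / "reconstruction.tsv",
                "orthologs": inputs_dir / "orthologs.tsv",
            }
        else:
            paths = {k: Path(v) for k, v in config.inputs.items()}
        catalog = dataio.parse_gene_catalog(paths["catalog"])
        edges = dataio.parse_edge_list(paths["edges"], catalog=catalog)
        evidence = dataio.parse_evolution_inputs(
            paths["families"], paths["reconstruction"], paths["orthologs"]
        )
        log["stages"]["inputs"] = {
            "n_genes": len(catalog),
            "n_dubious": catalog.n_dubious,
            "n_edges": len(edges),
            "edge_log": {
                "self_dropped": edges.n_self_dropped,
                "duplicates_collapsed": edges.n_duplicates_collapsed,
                "unknown_dropped": edges.n_unknown_dropped,
            },
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("inputs", exc) from exc

    # ---- stage: classification ------------------------------------------
    try:
        labels = classification.classify(catalog, evidence)
        if config.progenitor_variant:
            labels = classification.apply_progenitor_variant(
                labels,
                evidence,
                config.species_ranks,
                seed=_stage_seed(config, "classify"),
            )
        dataio.write_classification(labels.rows(), outdir / "classification.tsv")
        log["stages"]["classification"] = {
            "group_counts": labels.group_counts(),
            "progenitor_variant": config.progenitor_variant,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("classification", exc) from exc

    # ---- stage: network --------------------------------------------------
    try:
        keep = {
            rec.gene_id
            for rec in catalog.non_dubious()
            if not (config.exclude_essential and rec.essential)
            and not (config.exclude_subtelomeric and rec.subtelomeric)
        }
        net = network.build_network(edges, restrict_to=keep, source_filter=config.source_filter)
        net, sticky_log = network.filter_sticky(net, threshold=config.sticky_threshold)
        cent = network.centrality_table(net, catalog)
        _write_frame(cent, outdir / "centrality.tsv")

        gene_groups = labels.labels()
        summaries = []
        for column in ("degree", "betweenness", "degree_per_aa", "betweenness_per_aa"):
            values = dict(zip(cent["gene_id"], cent[column]))
            frame = network.group_summary(values, gene_groups)
            frame.insert(0, "statistic", column)
            summaries.append(frame)
        _write_frame(pd.concat(summaries, ignore_index=True), outdir / "group_summary.tsv")
        log["stages"]["network"] = {
            "n_vertices": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "sticky_removed": sorted(sticky_log.removed),
            "sticky_rounds": sticky_log.n_rounds,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("network", exc) from exc

    # ---- stage: assortativity -------------------------------------------
    try:
        analyzed = net.subgraph(
            [v for v in net.nodes() if v in gene_groups and net.degree(v) > 0]
        ).copy()
        results = assortativity.group_interaction_test(
            analyzed,
            {v: gene_groups[v] for v in analyzed.nodes()},
            n_random=config.n_random,
            seed=_stage_seed(config, "null_ensemble"),
            alpha=config.alpha,
        )
        frame = pd.DataFrame(
            [
                {
                    "group_a": r.group_a,
                    "group_b": r.group_b,
                    "observed": r.observed,
                    "null_mean": r.null_mean,
                    "null_sd": r.null_sd,
                    "glass_delta": r.delta,
                    "p_enrich": r.p_enrich,
                    "p_deplete": r.p_deplete,
                    "call": r.call,
                }
                for r in results
            ]
        )
        _write_frame(frame, outdir / "assort.tsv")
        log["stages"]["assortativity"] = {
            "n_random": config.n_random,
            "alpha": config.alpha,
            "calls": {f"{r.group_a}={r.group_b}": r.call for r in results},
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("assortativity", exc) from exc

    # ---- stage: attributes ----------------------------------------------
    try:
        table1 = attributes.attribute_table(catalog, labels, net=net)
        _write_frame(table1, outdir / "table1.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("attributes", exc) from exc

    # ---- stage: young-novel ego subnetwork ------------------------------
    try:
        seeds = {
            rec.gene_id
            for rec in labels
            if rec.age == "post_wgd" and rec.origin == "novel"
        }
        sub, components = network.ego_subnetwork(net, seeds, radius=1, labels=gene_groups)
        with open(outdir / "young_novel_subnet.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\n")
            for u, v in sorted(tuple(sorted(e)) for e in sub.edges()):
                fh.write(f"{u}\t{v}\n")
        comp_frame = pd.DataFrame(
            [
                {
                    "component": i + 1,
                    "size": c.size,
                    "n_seed_genes": c.n_seeds,
                    "group_counts": ";".join(
                        f"{g}:{n}" for g, n in sorted(c.group_counts.items())
                    ),
                    "members": "|".join(c.members),
                }
                for i, c in enumerate(components)
            ]
        )
        _write_frame(comp_frame, outdir / "young_novel_components.tsv")
        log["stages"]["young_novel_subnet"] = {
            "n_seeds_total": len(seeds),
            "n_seeds_with_interactions": sum(c.n_seeds for c in components),
            "n_components": len(components),
            "largest_component": components[0].size if components else 0,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("young_novel_subnet", exc) from exc

    log["config"] = {
        k: v for k, v in asdict(config).items() if k not in ("species_ranks",)
    }
    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return log
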