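"""End-to-end run: (simulate or load) -> correlations -> density stats ->
graphs -> communities -> node metrics -> hub tables -> behavior indexes,
with a provenance record and a log.

Every output TSV starts with a comment line naming the config hash that
produced it, so any file can be traced back to its exact run; the full
config, seed and package version live in provenance.yaml. A failed stage
aborts the run, names the stage and cause, and leaves partial outputs
behind next to a FAILED marker file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .behavior import score_trials
from .connectivity import DensityComparison, compare_density, correlation_matrix
from .data import GroupDesign, RegionActivityTable, ValidationError
from .io import (
    FLOAT_FMT,
    read_activity_table,
    read_behavior_table,
    write_activity_table,
    write_graph,
)
from .network import build_graph, detect_communities, hub_table, node_metrics
from .synth import SyntheticNetworkSpec, generate_activity

logger = logging.getLogger("fosnet")

#: groups entering the density comparison by default: the four exposure
#: groups (home-cage controls excluded, as in the group x genotype design)
DEFAULT_DENSITY_GROUPS = [
    ("WT", "object"),
    ("WT", "conspecific"),
    ("KO", "object"),
    ("KO", "conspecific"),
]


@dataclass
class RunConfig:
    """Single source of parameters for a pipeline run."""

    out_dir: str = "fosnet_out"
    counts_path: str | None = None
    design_path: str | None = None
    trials_path: str | None = None
    synthetic: SyntheticNetworkSpec | None = None
    threshold_r: float = 0.60
    alpha: float = 0.05
    seed: int = 0
    weighted_communities: bool = True
    resolution: float = 1.0
    sided: str = "two-sided"
    bh_correction: bool = False
    density_groups: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_DENSITY_GROUPS)
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # analysis parameters only: where outputs land
        # must not change what they contain
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
            d["synthetic"]["groups"] = [list(g) for g in self.synthetic.groups]
            if self.synthetic.group_effects:
                d["synthetic"]["group_effects"] = {
                    "/".join(k): v for k, v in self.synthetic.group_effects.items()
                }
        d["density_groups"] = [list(g) for g in self.density_groups]
        return d

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    out_dir: Path
    table: RegionActivityTable
    design: GroupDesign
    correlations: dict
    density: DensityComparison | None
    graphs: dict
    partitions: dict
    metrics: dict


def _write_tsv(frame, path: Path, config_hash: str, extra_header: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        if extra_header:
            fh.write(f"# {extra_header}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig) -> RunResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    stage = "setup"
    try:
        with open(out / "provenance.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "config": config.to_dict(),
                    "config_hash": chash,
                    "seed": config.seed,
                    "version": __version__,
                    "caveat": (
                        "density ANOVA treats each region-pair Z as one "
                        "observation; pairs within a matrix share subjects, "
                        "so observations are not independent"
                    ),
                },
                fh,
                sort_keys=True,
            )

        stage = "inputs"
        if config.synthetic is not None:
            spec = dataclasses.replace(config.synthetic, seed=config.seed)
            table, design, truth = generate_activity(spec)
            write_activity_table(
                table, design, out / "counts.tsv", out / "design.tsv"
            )
            with open(out / "truth.yaml", "w", encoding="utf-8") as fh:
                yaml.safe_dump(
                    {
                        "community_map": truth["community_map"],
                        "hubs": list(truth["hubs"]),
                        "seed": truth["seed"],
                    },
                    fh,
                    sort_keys=True,
                )
            logger.info("simulated counts: %d regions, %d subjects",
                        table.n_regions, table.n_subjects)
        else:
            if not config.counts_path or not config.design_path:
                raise ValidationError(
                    "config needs counts_path and design_path, or a synthetic spec"
                )
            table, design, warnings = read_activity_table(
                config.counts_path, config.design_path
            )
            for w in warnings:
                logger.warning(w)

        stage = "correlations"
        correlations = {}
        for genotype, condition in design.groups():
            n = len(design.subjects_in(genotype, condition))
            if n < 4:
                logger.warning(
                    "skipping group (%s, %s): only %d subjects", genotype,
                    condition, n,
                )
                continue
            corr = correlation_matrix(
                table, design, genotype, condition, sided=config.sided
            )
            for w in corr.warnings:
                logger.warning(w)
            correlations[(genotype, condition)] = corr
            tag = f"{genotype}_{condition}"
            _write_tsv(corr.upper_triangle(), out / f"correlations_{tag}.tsv", chash)
            matrix = pd.DataFrame(corr.r, index=corr.regions, columns=corr.regions)
            with open(out / f"matrix_{tag}.tsv", "w", encoding="utf-8") as fh:
                fh.write(f"# config_hash={chash}\n")
                matrix.index.name = "region"
                matrix.to_csv(fh, sep="\t", float_format=FLOAT_FMT)
            logger.info("group (%s, %s): n=%d", genotype, condition, corr.n)

        stage = "density"
        density = None
        wanted = [g for g in config.density_groups if g in correlations]
        if len(wanted) >= 2:
            density = compare_density([correlations[g] for g in wanted])
            _write_tsv(density.anova, out / "density_anova.tsv", chash)
            _write_tsv(density.contrasts, out / "density_contrasts.tsv", chash)
            means = pd.DataFrame(
                [
                    {
                        "genotype": g[0],
                        "condition": g[1],
                        "mean_r": density.group_mean_r[g],
                        "mean_z": density.group_mean_z[g],
                    }
                    for g in wanted
                ]
            )
            _write_tsv(means, out / "density_means.tsv", chash)
        else:
            logger.warning(
                "density comparison skipped: fewer than 2 of the configured "
                "groups are available"
            )

        stage = "network"
        graphs, partitions, metrics = {}, {}, {}
        for group, corr in correlations.items():
            tag = "_".join(group)
            graph = build_graph(
                corr, config.threshold_r, config.alpha,
                bh_correction=config.bh_correction,
            )
            partition = detect_communities(
                graph,
                seed=config.seed,
                weighted=config.weighted_communities,
                resolution=config.resolution,
            )
            table_m = node_metrics(graph, partition)
            for _, row in table_m.iterrows():
                graph.nodes[row["region"]]["z"] = row["z"]
                graph.nodes[row["region"]]["P"] = row["P"]
            graphs[group], partitions[group], metrics[group] = (
                graph, partition, table_m,
            )
            logger.info(
                "group (%s, %s): %d edges, %d communities, Q=%.4f",
                group[0], group[1], graph.number_of_edges(),
                len(set(partition.assignment.values())), partition.Q,
            )

            write_graph(graph, partition.assignment, out / f"graph_{tag}.graphml")
            write_graph(graph, partition.assignment, out / f"edges_{tag}.tsv",
                        format="edgelist")
            comm = pd.DataFrame(
                [
                    {"region": v, "community": c}
                    for v, c in partition.assignment.items()
                ]
            )
            _write_tsv(comm, out / f"communities_{tag}.tsv", chash,
                       extra_header=f"Q={partition.Q:.6f} seed={partition.seed}")
            _write_tsv(table_m, out / f"node_metrics_{tag}.tsv", chash)
            _write_tsv(hub_table(table_m), out / f"hubs_{tag}.tsv", chash)

        stage = "behavior"
        if config.trials_path:
            trials = read_behavior_table(config.trials_path)
            result = score_trials(trials)
            _write_tsv(result.table, out / "behavior_indexes.tsv", chash)
            logger.info(
                "behavior: n=%d, chamber index mean %.2f", result.n,
                result.chamber_mean,
            )

        return RunResult(
            out_dir=out,
            table=table,
            design=design,
            correlations=correlations,
            density=density,
            graphs=graphs,
            partitions=partitions,
            metrics=metrics,
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n", encoding="utf-8")
        logger.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
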