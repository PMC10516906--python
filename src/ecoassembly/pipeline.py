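"""End-to-end orchestration: simulate/load → rarefy → ordinate → assembly →
network → feature screen, with one config object, derived per-stage seeds and
a checksummed manifest so identical configs reproduce identical outputs."""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import diversity, io, network, stats, synth
from .assembly import assembly_distance_matrix, beta_nti
from .containers import CountTable, FormatError, validate_metadata

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a reproducible, stage-isolated seed from one global seed."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; validated before any stage executes.

    Either ``scenario`` (a synthetic world) or ``table_path`` (+
    ``tree_path`` / ``metadata_path``) must be supplied. Stage toggles
    default to the full analysis graph.
    """

    out_dir: str | Path = "pipeline_out"
    seed: int = 0
    scenario: synth.AssemblyScenario | None = None
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    feature_table_path: str | None = None
    rarefy_depth: int | None = None
    run_ordination: bool = True
    run_assembly: bool = True
    run_network: bool = True
    run_screen: bool = False
    n_rand: int = 1000
    n_perm: int = 999
    weighted: bool = True
    prevalence: float = 0.5
    network_threshold: float | None = None  # overrides the RMT scan
    positive_only: bool = True
    screen_reference: str | None = None
    alpha: float = 0.05

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".toml", ".tml"):
            import tomllib

            raw = tomllib.loads(path.read_text())
        elif path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(path.read_text())
        else:
            raise ValueError(f"config must be TOML or YAML, got {path.suffix!r}")
        scenario = raw.pop("scenario", None)
        config = cls(**raw)
        if scenario is not None:
            config.scenario = synth.AssemblyScenario(**scenario)
        return config

    def validate(self) -> None:
        if self.scenario is None and self.table_path is None:
            raise FormatError("config needs either a scenario or a table_path")
        if self.scenario is None:
            if not Path(self.table_path).exists():
                raise FormatError(f"count table not found: {self.table_path}")
            if self.run_assembly and (
                self.tree_path is None or not Path(self.tree_path).exists()
            ):
                raise FormatError("assembly stage enabled but no tree available")
            if self.run_ordination and self.metadata_path is not None and not Path(
                self.metadata_path
            ).exists():
                raise FormatError(f"metadata not found: {self.metadata_path}")
        if self.run_screen and self.scenario is None and (
            self.feature_table_path is None
            or not Path(self.feature_table_path).exists()
        ):
            raise FormatError("screen stage enabled but no feature table available")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the enabled stages in dependency order.

    Writes per-stage TSV/GraphML outputs under ``config.out_dir`` plus a
    ``manifest.json`` recording parameters, derived seeds and the sha256 of
    every written file. Identical config + seed reproduce byte-identical
    outputs for all deterministic stages.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": {},
        "parameters": {
            "n_rand": config.n_rand, "n_perm": config.n_perm,
            "weighted": config.weighted, "prevalence": config.prevalence,
            "alpha": config.alpha, "rarefy_depth": config.rarefy_depth,
        },
        "outputs": {},
    }
    results: dict[str, Any] = {}

    # --- inputs -----------------------------------------------------------
    if config.scenario is not None:
        scenario = config.scenario
        tree = synth.simulate_tree(scenario.n_taxa,
                                   stage_seed(config.seed, "tree"))
        scenario = synth.AssemblyScenario(**{
            **scenario.__dict__, "seed": stage_seed(config.seed, "communities"),
        })
        table = synth.simulate_communities(tree, scenario)
        groups = synth.sample_blocks(scenario)
        io.write_tree(tree, out / "tree.nwk")
        io.write_count_table(table, out / "counts.tsv")
        groups.to_frame().rename_axis("sample_id").to_csv(
            out / "metadata.tsv", sep="\t"
        )
        manifest["stages"]["simulate"] = {"regime": scenario.regime,
                                          "n_taxa": scenario.n_taxa,
                                          "n_samples": scenario.n_samples}
    else:
        table = io.read_count_table(config.table_path)
        tree = io.read_tree(config.tree_path) if config.tree_path else None
        groups = None
        if config.metadata_path:
            meta = io.read_metadata(config.metadata_path)
            groups = validate_metadata(meta, table.sample_ids)
    results["table"], results["tree"], results["groups"] = table, tree, groups

    # --- rarefaction ------------------------------------------------------
    if config.rarefy_depth is not None:
        table = diversity.rarefy(table, config.rarefy_depth,
                                 stage_seed(config.seed, "rarefy"))
        io.write_count_table(table, out / "counts_rarefied.tsv")
        manifest["stages"]["rarefy"] = {"depth": config.rarefy_depth,
                                        "n_samples_kept": table.n_samples}
        results["table"] = table

    # --- ordination + PERMANOVA ------------------------------------------
    bray = None
    if config.run_ordination:
        bray = diversity.bray_curtis(table)
        io.write_distance_matrix(bray, out / "bray_curtis.tsv")
        ordination = diversity.nmds(bray, seed=stage_seed(config.seed, "nmds"))
        ordination.coordinates.rename_axis("sample_id").to_csv(
            out / "nmds_coordinates.tsv", sep="\t"
        )
        manifest["stages"]["ordination"] = {"stress": ordination.stress}
        results["ordination"] = ordination
        if groups is not None and groups.nunique() >= 2:
            perma = diversity.permanova(bray, groups, n_perm=config.n_perm,
                                        seed=stage_seed(config.seed, "permanova"))
            manifest["stages"]["permanova"] = {
                "pseudo_f": perma.pseudo_f, "r_squared": perma.r_squared,
                "p_value": perma.p_value,
            }
            results["permanova"] = perma
        results["bray_curtis"] = bray

    # --- assembly null model ---------------------------------------------
    if config.run_assembly and tree is not None:
        assembly = beta_nti(table, tree, n_rand=config.n_rand,
                            weighted=config.weighted,
                            seed=stage_seed(config.seed, "assembly"))
        assembly.to_frame().to_csv(out / "assembly_pairs.tsv", sep="\t",
                                   index=False)
        manifest["stages"]["assembly"] = {
            "n_randomizations": config.n_rand,
            "class_fractions": assembly.class_fractions().to_dict(),
        }
        results["assembly"] = assembly
        try:
            nti_matrix = assembly_distance_matrix(assembly)
        except FormatError as exc:
            # undefined pairs: a real outcome (zero null spread), recorded
            # rather than aborting the run; downstream Mantel is skipped
            logger.warning("beta-NTI matrix not exported: %s", exc)
            manifest["stages"]["assembly"]["matrix_skipped"] = str(exc)
            nti_matrix = None
        if nti_matrix is not None:
            io.write_distance_matrix(nti_matrix, out / "beta_nti_matrix.tsv")
            results["beta_nti_matrix"] = nti_matrix
            if bray is not None:
                mantel_res = stats.mantel(bray, nti_matrix, n_perm=config.n_perm,
                                          seed=stage_seed(config.seed, "mantel"))
                manifest["stages"]["mantel"] = {"r": mantel_res.r,
                                                "p_value": mantel_res.p_value}
                results["mantel"] = mantel_res

    # --- co-occurrence network -------------------------------------------
    if config.run_network:
        if table.n_samples >= 10:
            corr = network.correlation_matrix(table, prevalence=config.prevalence)
            if config.network_threshold is not None:
                s_star, scan = float(config.network_threshold), None
            else:
                try:
                    s_star, scan = network.rmt_threshold(corr)
                except FormatError:
                    # no sustained Poisson-like regime: a legitimate
                    # no-structure outcome, not a pipeline failure
                    logger.warning("RMT scan found no structure; "
                                   "network stage skipped")
                    manifest["stages"]["network"] = {"skipped": "no structure"}
                    s_star = None
            if s_star is None:
                model = None
            else:
                if scan is not None:
                    scan.to_csv(out / "threshold_scan.tsv", sep="\t",
                                index=False)
                model = network.build_network(corr, s_star,
                                              positive_only=config.positive_only)
            if model is not None:
                io.write_graphml(model, out / "network.graphml")
                pd.DataFrame(model.edges,
                             columns=["taxon_a", "taxon_b", "r"]).to_csv(
                    out / "edges.tsv", sep="\t", index=False
                )
                pd.Series(model.degrees,
                          name="degree").rename_axis("taxon").to_csv(
                    out / "degrees.tsv", sep="\t"
                )
                manifest["stages"]["network"] = {"threshold": s_star,
                                                 "n_edges": model.n_edges,
                                                 "n_nodes": len(model.nodes)}
                results["network"] = model
        else:
            manifest["stages"]["network"] = {"skipped": "fewer than 10 samples"}

    # --- feature screen ---------------------------------------------------
    if config.run_screen:
        if config.feature_table_path is not None:
            feats = pd.read_csv(config.feature_table_path, sep="\t", index_col=0)
            fgroups = groups
        else:
            feats, fgroups, truth = synth.simulate_feature_table(
                n_features=100,
                group_sizes={"white": 10, "green": 10},
                effect_size=2.0,
                seed=stage_seed(config.seed, "features"),
            )
            manifest["stages"]["screen_truth"] = {"n_true": len(truth)}
        reference = config.screen_reference or fgroups.unique()[0]
        treatment = [g for g in fgroups.unique() if g != reference][0]
        screen = stats.wilcoxon_screen(feats, fgroups, treatment, reference,
                                       alpha=config.alpha)
        screen.to_csv(out / "screen.tsv", sep="\t")
        manifest["stages"]["screen"] = {
            "reference": reference, "treatment": treatment,
            "n_significant": int(screen["significant"].sum()),
        }
        results["screen"] = screen

    for path in sorted(out.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _checksum(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True, default=float))
    results["manifest"] = manifest
    return results
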