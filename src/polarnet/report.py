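"""End-to-end pipeline orchestration with provenance.

``run_pipeline`` composes the stages — simulate (optional) -> relative
quantification -> trait statistics -> per-genotype PCA -> differential
network — from a single config, failing fast with stage-labelled errors.
``write_report`` serializes every table with a config-hash header line and
a checksummed manifest, so a bundle can be reproduced byte-identically
from the same inputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffnet, multivariate, qpcr, synthdata, traits as traits_mod
from .design import PCA_DEFAULT_TRAITS, StudyDesign, build_design

__all__ = ["PipelineConfig", "ReportBundle", "PipelineError", "run_pipeline", "write_report"]

logger = logging.getLogger("polarnet")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Everything needed to run (and re-run) the pipeline.

    Either ``simulate=True`` (tables are generated from the default design
    and ground truth at ``seed``) or ``ct_path``/``trait_path`` point to
    long-format CSV tables.
    """

    simulate: bool = True
    seed: int = 0
    ct_path: str | None = None
    trait_path: str | None = None
    reference_gene: str = "Actin-7"
    calibrator_treatment: str = "control"
    stress_treatment: str = "stress"
    genotype_tolerant: str = "Misr2"
    genotype_susceptible: str = "Line4"
    tier_low: float = 0.25
    tier_high: float = 0.75
    theta_rev: int = 3
    theta_conn: float | str = "median"
    theta_switch: float = 1.0
    basis: str = "replicates"
    scale: str = "fold"
    alpha: float = 0.05
    pca_traits: tuple[str, ...] = PCA_DEFAULT_TRAITS
    yield_trait: str = "grain_yield"

    def __post_init__(self) -> None:
        if not 0 < self.tier_low < self.tier_high <= 1:
            raise ValueError("tier thresholds must satisfy 0 < low < high <= 1")
        self.pca_traits = tuple(self.pca_traits)
        if not self.simulate:
            for p, name in ((self.ct_path, "ct_path"), (self.trait_path, "trait_path")):
                if p is None:
                    raise ValueError(f"{name} is required when simulate=False")
                if not Path(p).exists():
                    raise PipelineError("input", f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["pca_traits"] = list(self.pca_traits)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def config_hash(self) -> str:
        data = asdict(self)
        data["pca_traits"] = list(self.pca_traits)
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ReportBundle:
    """Machine-readable results of one pipeline run."""

    config: PipelineConfig
    expression: pd.DataFrame
    expression_summary: pd.DataFrame
    trait_summary: pd.DataFrame
    anova: dict[str, pd.DataFrame]
    tukey: dict[str, pd.DataFrame]
    percent_change: pd.DataFrame
    pca: dict[str, multivariate.PCAResult]
    network: diffnet.DifferentialNetwork
    truth: synthdata.TruthRecord | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        """All flat tables keyed by artifact name."""
        out = {
            "expression": self.expression,
            "expression_summary": self.expression_summary,
            "trait_summary": self.trait_summary,
            "percent_change": self.percent_change,
            "edges_compared": self.network.edge_table(),
            "node_profiles": self.network.node_table(),
        }
        for trait, table in self.anova.items():
            out[f"anova_{trait}"] = table.reset_index(names="effect")
        for trait, table in self.tukey.items():
            out[f"tukey_{trait}"] = table
        for g, res in self.pca.items():
            out[f"pca_{g}_loadings"] = res.loadings.reset_index(names="variable")
            out[f"pca_{g}_scores"] = res.scores.reset_index()
            out[f"pca_{g}_variance"] = pd.DataFrame(
                {
                    "component": [f"PC{i+1}" for i in range(len(res.variance_percent))],
                    "variance_percent": res.variance_percent,
                }
            )
        for g, corr in self.network.correlations_.items():
            out[f"corr_{g}"] = corr.to_frame().reset_index(names="gene")
        return out


def _stage(stage: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001 - re-labelled with stage context
            raise PipelineError(stage, str(e)) from e

    return wrap


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute simulate? -> qpcr -> traits -> pca -> network -> bundle."""
    logger.info("pipeline start (config hash %s)", config.config_hash())
    for key, value in sorted(asdict(config).items()):
        logger.info("config: %s = %r", key, value)

    truth_record = None
    if config.simulate:
        def simulate():
            design = StudyDesign()
            truth = synthdata.paper_like_truth(design)
            return synthdata.generate_study(design, truth, config.seed)

        ct_table, trait_table, truth_record = _stage("simulate")(simulate)
    else:
        ct_table = _stage("input")(synthdata.read_ct_table, config.ct_path)
        trait_table = _stage("input")(synthdata.read_trait_table, config.trait_path)

    expression = _stage("qpcr")(
        qpcr.quantify,
        ct_table,
        reference_gene=config.reference_gene,
        calibrator_treatment=config.calibrator_treatment,
    )
    expression_summary = _stage("qpcr")(qpcr.summarize_expression, expression)

    trait_summary = _stage("traits")(traits_mod.summarize_traits, trait_table)
    anova, tukey = {}, {}
    for trait in trait_table["trait"].unique():
        anova[trait] = _stage("traits")(traits_mod.two_way_anova, trait_table, trait)
        tukey[trait] = _stage("traits")(
            traits_mod.tukey_cld, trait_table, trait, alpha=config.alpha
        )

    def yield_changes():
        rows = []
        for genotype, grp in trait_summary[trait_summary["trait"] == config.yield_trait].groupby(
            "genotype"
        ):
            ctrl = grp[grp["treatment"] == config.calibrator_treatment]["mean"].iloc[0]
            stress = grp[grp["treatment"] == config.stress_treatment]["mean"].iloc[0]
            pct, rounded = traits_mod.percent_change(ctrl, stress)
            rows.append(
                {
                    "genotype": genotype,
                    "trait": config.yield_trait,
                    "control_mean": ctrl,
                    "stress_mean": stress,
                    "percent_reduction": pct,
                    "percent_reduction_rounded": rounded,
                }
            )
        return pd.DataFrame(rows)

    percent_change = _stage("traits")(yield_changes)

    def run_pca():
        out = {}
        for g in (config.genotype_tolerant, config.genotype_susceptible):
            X = multivariate.assemble_matrix(
                trait_table, expression, g, trait_list=config.pca_traits
            )
            out[g] = multivariate.pca(X)
        return out

    pca_results = _stage("pca")(run_pca)

    def run_network():
        model = diffnet.DifferentialNetwork(
            genotype_tolerant=config.genotype_tolerant,
            genotype_susceptible=config.genotype_susceptible,
            thresholds=(config.tier_low, config.tier_high),
            theta_rev=config.theta_rev,
            theta_conn=config.theta_conn,
            theta_switch=config.theta_switch,
            basis=config.basis,
            scale=config.scale,
            alpha_up=config.alpha,
            stress_treatment=config.stress_treatment,
        )
        return model.fit(expression, trait_table)

    network = _stage("network")(run_network)
    logger.info("pipeline done: roles %s", network.roles_)

    return ReportBundle(
        config=config,
        expression=expression,
        expression_summary=expression_summary,
        trait_summary=trait_summary,
        anova=anova,
        tukey=tukey,
        percent_change=percent_change,
        pca=pca_results,
        network=network,
        truth=truth_record,
    )


def write_report(
    bundle: ReportBundle, directory: str | Path, force: bool = False
) -> dict:
    """Write every bundle table plus GraphML/DOT and ``manifest.json``.

    Each CSV starts with a comment line recording the config hash. Existing
    artifact files raise unless ``force=True``. Returns the manifest
    (artifact name -> path, sha256).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = f"# polarnet config_hash={bundle.config.config_hash()}\n"
    manifest: dict = {"config_hash": bundle.config.config_hash(), "artifacts": {}}

    def register(name: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["artifacts"][name] = {"path": path.name, "sha256": digest}

    for name, table in bundle.tables().items():
        path = directory / f"{name}.csv"
        if path.exists() and not force:
            raise PipelineError("report", f"{path} exists (use force=True to overwrite)")
        path.write_text(header + table.to_csv(index=False, float_format="%.10g"))
        register(name, path)

    for path in diffnet.export_network(bundle.network, directory):
        register(path.stem + path.suffix.replace(".", "_"), path)

    if bundle.truth is not None:
        path = directory / "truth.json"
        path.write_text(json.dumps(bundle.truth.to_jsonable(), indent=1))
        register("truth", path)

    config_path = directory / "config.yaml"
    bundle.config.to_yaml(config_path)
    register("config", config_path)

    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
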