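"""End-to-end orchestration: filter -> missing-data handling -> stationarity
report -> lagged design -> node-wise fits -> networks -> centralities."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from esmnet import centrality as centrality_mod
from esmnet import networks as networks_mod
from esmnet.dataset import EsmDataset, missingness_summary
from esmnet.mlvar import FitConfig, fit_all_nodes, fit_contemporaneous, random_effects_sd_network
from esmnet.preprocess import (
    DEFAULT_IMPUTE_WINDOW,
    build_lagged_rows,
    cronbach_alpha_daily,
    filter_attention_checks,
    impute_dataset,
    kpss_report,
    within_person_center,
)

logger = logging.getLogger("esmnet")

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Run-level settings; serializable to/from YAML (versioned schema)."""

    input_path: str
    output_dir: str
    variable_names: list[str] | None = None
    missing_mode: str = "listwise"  # or "impute"
    impute_window: int = DEFAULT_IMPUTE_WINDOW
    alpha: float = 0.05
    kpss_level: float = 0.05
    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.missing_mode not in ("listwise", "impute"):
            raise ValueError("missing_mode must be 'listwise' or 'impute'")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload.pop("schema_version", None)
        return cls(**payload)


@dataclass
class ResultBundle:
    """In-memory products of one pipeline run."""

    config: PipelineConfig
    dataset: EsmDataset
    design: object
    fits: list
    temporal: networks_mod.TemporalNetwork
    contemporaneous: networks_mod.ContemporaneousNetwork
    centrality: centrality_mod.CentralityTable
    re_sd_network: np.ndarray
    kpss: pd.DataFrame
    reliability: pd.Series
    missingness: dict
    output_files: dict = field(default_factory=dict)


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def analyze_dataset(
    dataset: EsmDataset,
    missing_mode: str = "listwise",
    impute_window: int = DEFAULT_IMPUTE_WINDOW,
    fit_config: FitConfig | None = None,
    kpss_level: float = 0.05,
    with_reports: bool = True,
):
    """Core analysis on an in-memory dataset; returns the pieces of a bundle.

    Shared by :func:`run_pipeline` and programmatic callers that do not need
    file output.
    """
    fit_config = fit_config or FitConfig()
    filtered = filter_attention_checks(dataset)
    missingness = missingness_summary(filtered)
    logger.info(
        "missingness: %s of %s cells (%.2f%%)",
        missingness["missing_cells"],
        missingness["scheduled_cells"],
        missingness["missing_percent"],
    )
    if missing_mode == "impute":
        analyzed = impute_dataset(filtered, impute_window)
        design_mode = "imputed"
    else:
        analyzed = filtered
        design_mode = "listwise"
    kpss = kpss_report(analyzed, level=kpss_level) if with_reports else pd.DataFrame()
    reliability = cronbach_alpha_daily(filtered) if with_reports else pd.Series(dtype=float)
    design = within_person_center(build_lagged_rows(analyzed, design_mode))
    logger.info("lagged design: %d rows, %d persons", design.n_rows, design.n_persons)
    fits = fit_all_nodes(design, fit_config)
    temporal = networks_mod.build_temporal_network(fits, fit_config.alpha)
    contemporaneous = fit_contemporaneous(fits, fit_config)
    table = centrality_mod.centrality_table(temporal, contemporaneous)
    re_sd = random_effects_sd_network(fits)
    return analyzed, design, fits, temporal, contemporaneous, table, re_sd, kpss, reliability, missingness


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute the full pipeline and write every report under ``output_dir``.

    The run manifest lists the configuration hash, seeds, package version and
    a checksum for every output file.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = EsmDataset.from_csv(config.input_path, config.variable_names, likert_bounds=None)
    fit_config = FitConfig(alpha=config.alpha)
    (
        analyzed,
        design,
        fits,
        temporal,
        contemporaneous,
        table,
        re_sd,
        kpss,
        reliability,
        missingness,
    ) = analyze_dataset(
        dataset,
        missing_mode=config.missing_mode,
        impute_window=config.impute_window,
        fit_config=fit_config,
        kpss_level=config.kpss_level,
    )

    files: dict[str, Path] = {}

    def _write(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        files[name] = path

    _write("design.csv", lambda p: design.frame.to_csv(p, index=False))
    _write("kpss.tsv", lambda p: kpss.to_csv(p, sep="\t", index=False))
    _write("reliability.tsv", lambda p: reliability.to_csv(p, sep="\t"))
    _write(
        "fit.json",
        lambda p: p.write_text(json.dumps([f.to_dict() for f in fits], indent=2)),
    )
    _write("temporal_edges.tsv", lambda p: temporal.edge_list().to_csv(p, sep="\t", index=False))
    _write(
        "contemporaneous_edges.tsv",
        lambda p: contemporaneous.edge_list().to_csv(p, sep="\t", index=False),
    )
    _write("temporal.graphml", lambda p: networks_mod.export_graphml(temporal.to_graph(), p))
    _write(
        "contemporaneous.graphml",
        lambda p: networks_mod.export_graphml(contemporaneous.to_graph(), p),
    )
    _write(
        "temporal.json", lambda p: networks_mod.export_node_link_json(temporal.to_graph(), p)
    )
    loops = networks_mod.find_feedback_loops(temporal, max_length=3)
    _write(
        "loops.tsv",
        lambda p: pd.DataFrame(
            [
                {"nodes": " -> ".join(l["nodes"]), "weights": ",".join(f"{w:.4f}" for w in l["weights"])}
                for l in loops
            ]
        ).to_csv(p, sep="\t", index=False),
    )
    _write("centrality.tsv", lambda p: table.to_frame().to_csv(p, sep="\t", index=False))
    _write(
        "random_effect_sd.tsv",
        lambda p: pd.DataFrame(
            re_sd, index=temporal.variable_names, columns=temporal.variable_names
        ).to_csv(p, sep="\t"),
    )

    manifest = {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "package": "esmnet",
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "missingness": missingness,
        "n_design_rows": design.n_rows,
        "n_persons": design.n_persons,
        "outputs": {name: _sha256(path) for name, path in files.items()},
    }
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    files["manifest.yaml"] = manifest_path

    return ResultBundle(
        config=config,
        dataset=analyzed,
        design=design,
        fits=fits,
        temporal=temporal,
        contemporaneous=contemporaneous,
        centrality=table,
        re_sd_network=re_sd,
        kpss=kpss,
        reliability=reliability,
        missingness=missingness,
        output_files={k: str(v) for k, v in files.items()},
    )


def compare_strategies(bundle_listwise: ResultBundle, bundle_imputed: ResultBundle) -> dict:
    """Similarity of the two missing-data strategies' temporal results.

    Reports the Pearson correlation of the masked temporal weight matrices,
    the Jaccard overlap of the significant edge sets, and the Spearman rank
    correlation of Out-strengths.
    """
    t1, t2 = bundle_listwise.temporal, bundle_imputed.temporal
    if t1.variable_names != t2.variable_names:
        raise ValueError("bundles cover different variables")
    w1, w2 = t1.masked_weights.ravel(), t2.masked_weights.ravel()
    if np.std(w1) == 0 or np.std(w2) == 0:
        weight_corr = 1.0 if np.allclose(w1, w2) else 0.0
    else:
        weight_corr = float(np.corrcoef(w1, w2)[0, 1])
    m1, m2 = t1.significant.ravel(), t2.significant.ravel()
    union = int((m1 | m2).sum())
    jaccard = float((m1 & m2).sum() / union) if union else 1.0
    s1 = centrality_mod.out_strength(t1)
    s2 = centrality_mod.out_strength(t2)
    if np.std(s1) == 0 or np.std(s2) == 0:
        rank_corr = 1.0 if np.allclose(s1, s2) else 0.0
    else:
        rank_corr = float(stats.spearmanr(s1, s2).statistic)
    return {
        "edge_weight_correlation": weight_corr,
        "significant_edge_jaccard": jaccard,
        "out_strength_rank_correlation": rank_corr,
    }
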