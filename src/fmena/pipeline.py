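"""End-to-end orchestration of the analysis stages.

``run_pipeline`` drives preprocess -> group statistics -> dissimilarity
tests -> per-group RMT network inference -> topology + null models ->
node roles + module-environment correlations, and returns a
JSON-serializable run report holding every parameter, the seed, and all
summary tables, so a run is reproducible from its report alone.
"""

from __future__ import annotations

import traceback
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dissimilarity import contrast_table
from .group_stats import overlap, results_table, richness, category_ttest
from .preprocess import group_difference, run_preprocessing
from .rmt import (
    NETWORK_CATEGORIES,
    ThresholdScanError,
    build_network,
    pearson_matrix,
    select_common_genes,
    select_threshold,
)
from .roles import (
    env_correlation,
    env_correlation_table,
    module_eigengene,
    node_roles,
    roles_table,
    top_connectivity_genes,
)
from .synthetic import SynthConfig, generate_dataset
from .topology import fast_greedy_modules, random_ensemble, summary_table, topology_summary


@dataclass
class RunConfig:
    """Everything needed to re-execute a run bit-identically."""

    # input: either a synthetic config or paths to the three input tables
    synthetic: SynthConfig | None = None
    signal_table: str | None = None
    design_table: str | None = None
    env_table: str | None = None
    # preprocessing
    snr_min: float = 2.0
    min_detected_per_lake: int | None = 2
    divide_before_log: bool = False
    # dissimilarity tests
    metrics: tuple[str, ...] = ("euclidean", "horn", "bray")
    n_perm: int = 999
    # network inference
    network_categories: tuple[str, ...] = NETWORK_CATEGORIES
    min_prevalence_fraction: float = 0.5
    st_grid_start: float = 0.30
    st_grid_stop: float = 0.99
    st_grid_step: float = 0.01
    gof: str = "ks"
    #: fixed similarity threshold used when the spacing scan cannot
    #: stabilize (small-sample spectra); None disables the fallback
    fallback_st: float | None = 0.8
    null_method: str = "degree_preserving"
    n_random: int = 100
    top_k_modules: int = 5
    # stages
    run_network: bool = True
    seed: int = 0

    def st_grid(self) -> np.ndarray:
        grid = np.round(
            np.arange(self.st_grid_start, self.st_grid_stop + 1e-9, self.st_grid_step),
            6,
        )
        return grid[grid < 1.0]

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if synth is not None:
            cfg.synthetic = SynthConfig(**synth)
        return cfg


def _df_record(df: pd.DataFrame) -> list[dict]:
    return df.replace({np.nan: None}).to_dict(orient="records")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; on a stage error the report records
    the failing stage and keeps the partial outputs."""
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": [],
        "failed_stage": None,
    }
    stage = "input"
    try:
        if config.synthetic is not None:
            dataset = generate_dataset(config.synthetic)
            raw, annotation, design, env = (
                dataset.raw,
                dataset.annotation,
                dataset.design,
                dataset.env,
            )
        else:
            from . import io as fio

            raw, annotation = fio.read_signal_table(config.signal_table)
            design = fio.read_design(config.design_table)
            env = fio.read_env(config.env_table) if config.env_table else None
        report["stages"].append(stage)

        stage = "preprocess"
        pre = run_preprocessing(
            raw,
            design,
            snr_min=config.snr_min,
            min_detected_per_lake=config.min_detected_per_lake,
            divide_before_log=config.divide_before_log,
        )
        report["preprocess"] = pre.report

        stage = "group_stats"
        rich = richness(pre.matrix, design, annotation)
        ov = overlap(pre.matrix, design)
        tests = category_ttest(pre.matrix, design, annotation, level="category")
        deltas = group_difference(pre.matrix, design, annotation, level="category")
        report["group_stats"] = {
            "richness_total": rich.total,
            "richness_per_group": rich.per_group.to_dict(),
            "overlap": {
                "n_shared": ov.n_shared,
                "n_unique_low": ov.n_unique_low,
                "n_unique_high": ov.n_unique_high,
                "pct_shared": ov.pct_shared,
            },
            "category_tests": _df_record(results_table(tests)),
            "category_deltas": [
                {"unit": d.unit, "s_high": d.s_high, "s_low": d.s_low, "delta": d.delta}
                for d in deltas
            ],
        }
        enriched = [
            t.unit
            for t in tests
            if t.p is not None and t.p < 0.05 and t.mean_high > t.mean_low
        ]
        report["group_stats"]["enriched_in_high"] = enriched

        stage = "dissimilarity_tests"
        profiles = pre.relative.values.T  # samples x probes
        labels = design.group_labels(list(profiles.index)).to_numpy()
        table = contrast_table(
            profiles, labels, metrics=config.metrics, n_perm=config.n_perm, seed=config.seed
        )
        report["dissimilarity_tests"] = _df_record(table)

        if config.run_network:
            stage = "network"
            report["networks"] = {}
            for group in design.groups:
                report["networks"][group] = _network_stage(config, pre, design, annotation, env, group)
        return report
    except Exception as exc:  # keep partial outputs, record the failure
        report["failed_stage"] = stage
        report["error"] = f"{type(exc).__name__}: {exc}"
        report["traceback"] = traceback.format_exc()
        return report


def _network_stage(config, pre, design, annotation, env, group: str) -> dict:
    genes = select_common_genes(
        pre.matrix,
        design,
        annotation,
        group,
        min_prevalence_fraction=config.min_prevalence_fraction,
        categories=tuple(config.network_categories),
    )
    samples = [s for s in pre.matrix.samples if design.group_of_sample(s) == group]
    corr = pearson_matrix(pre.matrix.values.loc[genes, samples])
    out: dict = {"n_original_genes": len(genes)}
    try:
        scan = select_threshold(corr, grid=config.st_grid(), gof=config.gof)
        st = scan.selected_st
    except ThresholdScanError as exc:
        out["threshold_scan_error"] = str(exc)
        if config.fallback_st is None:
            return out
        st = config.fallback_st
        out["fallback_st_used"] = st
    out["selected_st"] = st
    network = build_network(corr, st, annotation)
    if network.L == 0:
        out["empty_network"] = True
        return out
    partition = fast_greedy_modules(network)
    summary = topology_summary(network, partition)
    ensemble = random_ensemble(
        network, n_networks=config.n_random, method=config.null_method, seed=config.seed
    )
    out["topology"] = _df_record(
        summary_table(group, len(genes), network, summary, ensemble)
    )[0]
    roles = node_roles(network, partition)
    out["role_counts"] = roles_table(roles)["role"].value_counts().to_dict()
    out["top_genes"] = top_connectivity_genes(network, k=5)
    from .datatypes import SignalMatrix

    group_matrix = SignalMatrix(
        pre.matrix.values[samples], transformed=True, normalized=True
    )
    eigengenes = module_eigengene(group_matrix, partition, top_k_modules=config.top_k_modules)
    out["eigengene_variance_explained"] = {
        eg.module: eg.variance_explained for eg in eigengenes
    }
    if env is not None:
        env_sub = env.loc[samples]
        corrs = env_correlation(eigengenes, env_sub)
        out["module_env_correlations"] = _df_record(env_correlation_table(corrs))
    return out
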