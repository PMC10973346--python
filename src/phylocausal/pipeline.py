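"""Full-study orchestration: signal -> path analysis -> GLMM robustness.

:func:`run_full_pipeline` executes the complete workflow from one
:class:`AnalysisConfig`: derive/align the sample, cross-tabulate case
against each word-order trait, estimate D per trait, rank the causal model
set and average the top models, and (optionally) run the Bayesian
mixed-model robustness stages. Every output is written with a manifest of
seeds, versions, and content checksums so reruns are verifiable. Pointing
the config at the archived study inputs (tree, Grambank long table,
coordinates) reproduces the published analysis; the flagged ``replication``
switch enables the full-sample GLMM refits.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dags import equivalence_classes, null_model, paper_model_set, load_model_file
from .glmm import kfold_compare, refit_path_models, spatial_correlation
from .pathanalysis import run_path_analysis
from .signal import d_statistic
from .treedata import (
    ANALYSIS_TRAITS,
    Phylogeny,
    align_tree_and_traits,
    derive_features,
    read_coordinates,
    read_trait_matrix,
    read_trait_table,
)

logger = logging.getLogger("phylocausal")


@dataclass
class AnalysisConfig:
    """Inputs, engine choices, and seeds for one pipeline run."""

    tree: str
    traits: str
    output_dir: str
    coordinates: str | None = None
    traits_format: str = "long"        # "long" (Grambank-style) | "matrix"
    models: str = "builtin:paper12"
    engine: str = "logistic"
    n_perm: int = 1000
    n_sim: int = 1000
    seed: int = 1
    run_glmm: bool = False             # flagged robustness / replication stages
    kfold: int = 10
    chains: int = 2
    warmup: int = 500
    draws: int = 500
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8-sig") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for label, path in (("tree", self.tree), ("traits", self.traits),
                            ("coordinates", self.coordinates)):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label} file not found: {path}")
        if self.traits_format not in ("long", "matrix"):
            raise ValueError("traits_format must be 'long' or 'matrix'")
        if self.engine not in ("logistic", "gls"):
            raise ValueError("engine must be 'logistic' or 'gls'")


def cross_tab(traits: pd.DataFrame, wo_trait: str) -> pd.DataFrame:
    """2x2 counts and integer percentages of case against a word-order trait."""
    if wo_trait not in traits.columns:
        raise KeyError(f"unknown trait {wo_trait!r}")
    if "case" not in traits.columns:
        raise KeyError("trait matrix has no 'case' column")
    sub = traits[["case", wo_trait]].dropna()
    n = len(sub)
    if n == 0:
        raise ValueError("no complete rows to tabulate")
    cells = []
    for case_val, wo_val, label in (
        (1, 1, f"case & {wo_trait}"),
        (1, 0, f"case & not {wo_trait}"),
        (0, 1, f"no case & {wo_trait}"),
        (0, 0, f"no case & not {wo_trait}"),
    ):
        count = int(((sub["case"] == case_val) & (sub[wo_trait] == wo_val)).sum())
        cells.append({
            "cell": label, "case": case_val, wo_trait: wo_val,
            "count": count, "percent": int(round(100.0 * count / n)),
        })
    return pd.DataFrame(cells)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_inputs(config: AnalysisConfig):
    """Read and align the tree, traits, and optional coordinates."""
    tree = Phylogeny.from_file(config.tree)
    if config.traits_format == "long":
        table = read_trait_table(config.traits)
        traits = derive_features(table)
    else:
        traits = read_trait_matrix(config.traits)
    locations = read_coordinates(config.coordinates) if config.coordinates else None
    return align_tree_and_traits(tree, traits, locations)


def _resolve_models(spec: str) -> dict:
    if spec == "builtin:paper12":
        models = paper_model_set()
        models["null"] = null_model()
        return models
    return load_model_file(spec)


def run_full_pipeline(config: AnalysisConfig) -> dict:
    """Execute every stage and write the report bundle to the output directory.

    Returns a dict of in-memory results (cross-tabs, D results, comparison
    table, averaged model, optional GLMM tables) alongside the files.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "phylocausal",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
        "outputs": {},
    }
    results: dict = {}
    t0 = time.time()

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {"started": time.time() - t0}
        return time.time()

    def done(name, start):
        manifest["stages"][name]["seconds"] = round(time.time() - start, 3)

    def emit(name: str, path: Path):
        manifest["outputs"][name] = {"path": path.name, "sha256": _sha256(path)}

    try:
        s = stage("align")
        tree, traits, locations = load_inputs(config)
        scaled = tree.scaled_to_unit_height()
        corr = scaled.correlation_matrix()
        n = len(traits)
        manifest["n_taxa"] = n
        traits_path = out / "aligned_traits.csv"
        traits.to_csv(traits_path)
        emit("aligned_traits", traits_path)
        done("align", s)

        s = stage("cross_tabs")
        tabs = {wo: cross_tab(traits, wo) for wo in ("verb_final", "flexible")}
        tab_frames = []
        for wo, tab in tabs.items():
            t = tab[["cell", "count", "percent"]].copy()
            t.insert(0, "word_order_trait", wo)
            tab_frames.append(t)
        tab_path = out / "cross_tabs.csv"
        pd.concat(tab_frames).to_csv(tab_path, index=False)
        emit("cross_tabs", tab_path)
        results["cross_tabs"] = tabs
        done("cross_tabs", s)

        s = stage("signal")
        d_rows = []
        for i, trait in enumerate(ANALYSIS_TRAITS):
            res = d_statistic(
                scaled, traits[trait].to_numpy(),
                n_perm=config.n_perm, n_sim=config.n_sim,
                seed=config.seed + i, trait_name=trait,
            )
            d_rows.append(res.as_dict())
        d_table = pd.DataFrame(d_rows)
        d_path = out / "phylogenetic_signal.csv"
        d_table.round(6).to_csv(d_path, index=False)
        emit("phylogenetic_signal", d_path)
        results["signal"] = d_table
        done("signal", s)

        s = stage("path_analysis")
        models = _resolve_models(config.models)
        table, averaged, _ = run_path_analysis(
            traits, corr, models, engine=config.engine,
        )
        eq = equivalence_classes(models)
        table = table.copy()
        table["equiv_class"] = table["model"].map(eq)
        table_out = table.copy()
        for col in ("CICc", "delta_CICc", "rel_likelihood", "weight", "C", "p"):
            table_out[col] = table_out[col].round(2)
        cmp_path = out / "model_comparison.csv"
        table_out.to_csv(cmp_path, index=False)
        emit("model_comparison", cmp_path)
        results["comparison"] = table
        results["averaged"] = averaged
        avg_path = out / "averaged_model.json"
        with open(avg_path, "w") as fh:
            json.dump(averaged.as_dict() if averaged else None, fh, indent=2)
        emit("averaged_model", avg_path)
        done("path_analysis", s)

        if config.run_glmm:
            s = stage("glmm_kfold")
            y_specs = {"phylo": ("phylo",)}
            corr_spatial = None
            if locations is not None:
                corr_spatial = spatial_correlation(locations)
                y_specs["spatial"] = ("spatial",)
                y_specs["both"] = ("phylo", "spatial")
            kf_rows = []
            X = pd.DataFrame({"intercept": np.ones(n)}, index=traits.index)
            for i, trait in enumerate(ANALYSIS_TRAITS):
                kt = kfold_compare(
                    traits[trait].to_numpy(), X, y_specs,
                    corr_phylo=corr, corr_spatial=corr_spatial,
                    K=config.kfold, seed=config.seed + 100 + i,
                    chains=config.chains, warmup=config.warmup,
                    draws=config.draws,
                )
                for m in kt.elpd:
                    kf_rows.append({
                        "response": trait, "model": m,
                        "elpd": kt.elpd[m], "se": kt.se[m],
                    })
            kf_path = out / "kfold_comparison.csv"
            pd.DataFrame(kf_rows).to_csv(kf_path, index=False)
            emit("kfold_comparison", kf_path)
            results["kfold"] = kf_rows
            done("glmm_kfold", s)

            s = stage("glmm_refits")
            bcd = {m: d for m, d in paper_model_set().items() if m in ("b", "c", "d")}
            refits = refit_path_models(
                traits, corr, bcd, chains=config.chains,
                warmup=config.warmup, draws=config.draws,
                seed=config.seed + 500, check_convergence=False,
            )
            refit_path = out / "glmm_path_refits.csv"
            refits.round(4).to_csv(refit_path, index=False)
            emit("glmm_path_refits", refit_path)
            results["refits"] = refits
            done("glmm_refits", s)

        manifest["elapsed_seconds"] = round(time.time() - t0, 3)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        results["manifest"] = manifest
        return results
    except Exception:
        manifest["elapsed_seconds"] = round(time.time() - t0, 3)
        manifest["failed"] = True
        try:
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
        except OSError:
            pass
        raise
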