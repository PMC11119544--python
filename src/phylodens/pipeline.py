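"""Config-driven orchestration of the full analysis.

Stages mirror the analysis workflow: ``simulate`` (synthetic data),
``classify`` (biome / climate-zone annotation and group comparison),
``signal`` (per-group Pagel's lambda report), and ``partition``
(subset selection, PMM variance partition, environment-only regression,
permutation importance).  Every output carries a provenance block
(package version, seed, config hash) and reruns with an identical config
are byte-identical for the deterministic (ML) backend.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, dataset, phylo_signal, pmm, synthetic
from .treekit import read_newick_file

logger = logging.getLogger("phylodens")

__all__ = ["RunConfig", "run_simulate", "run_classify", "run_signal",
           "run_partition", "run_report"]

_DEFAULTS = {
    "seed": 0,
    "output_dir": "phylodens_out",
    "tree": None,
    "table": None,
    "biome_config": None,
    "grouping": ["climate_zone"],
    "min_group_size": 3,
    "n_perm": 1000,
    "backend": "ml",
    "reml": False,
    "candidates": ["mat", "map", "clay", "soc", "ndvi", "slope", "aspect"],
    "selection_criterion": "aic",
    "importance_repeats": 20,
    "mcmc": {"n_iter": 6000, "burnin": 1000, "thin": 5},
    "simulate": {},
}


@dataclass
class RunConfig:
    """Validated run configuration (YAML-backed)."""

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = dict(_DEFAULTS)
        merged.update(self.values or {})
        unknown = set(merged) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if merged["backend"] not in ("ml", "mcmc"):
            raise ValueError("backend must be 'ml' or 'mcmc'")
        for key in ("tree", "table", "biome_config"):
            path = merged[key]
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{key} file not found: {path}")
        self.values = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.values[key]

    @property
    def out_dir(self) -> Path:
        p = Path(self.values["output_dir"])
        p.mkdir(parents=True, exist_ok=True)
        return p

    def provenance(self) -> dict:
        # hash the analysis settings, not the output destination
        hashed = {k: v for k, v in self.values.items() if k != "output_dir"}
        blob = json.dumps(hashed, sort_keys=True, default=str)
        return {
            "package": f"phylodens {__version__}",
            "seed": self.values["seed"],
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        }


def _write_csv(df: pd.DataFrame, path: Path, provenance: dict) -> None:
    with open(path, "w") as fh:
        for key, value in provenance.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def _write_json(obj: dict, path: Path, provenance: dict) -> None:
    with open(path, "w") as fh:
        json.dump({"provenance": provenance, **obj}, fh, indent=1,
                  sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    return str(x)


def _load_inputs(config: RunConfig):
    if config["tree"] is None or config["table"] is None:
        raise ValueError("config must provide 'tree' and 'table' paths")
    tree = read_newick_file(config["tree"])
    table = dataset.load_table(config["table"])
    return tree, table


def run_simulate(config: RunConfig) -> dict:
    """Generate a synthetic tree + table + truth record into output_dir."""
    sim_kwargs = dict(config["simulate"])
    clades = sim_kwargs.pop("clades", None)
    if clades:
        sim_kwargs["clades"] = [synthetic.CladeSpec(**c) for c in clades]
    sim_kwargs.setdefault("seed", config["seed"])
    sim = synthetic.simulate_table(synthetic.SimConfig(**sim_kwargs))
    out = config.out_dir
    paths = {
        "tree": out / "simulated_tree.nwk",
        "table": out / "simulated_table.csv",
        "truth": out / "simulated_truth.json",
    }
    sim.write(paths["tree"], paths["table"], paths["truth"])
    logger.info("simulated %d species, %d rows", sim.tree.n_tips,
                len(sim.table))
    return {str(k): str(v) for k, v in paths.items()}


def _annotated_species_table(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate to site-species rows and attach climate_zone per species."""
    kept, _ = dataset.filter_records(table)
    agg = dataset.aggregate_site_species(kept)
    zones = dataset.classify_climate_zones(agg)
    agg["climate_zone"] = agg["species"].map(zones)
    return agg


def run_classify(config: RunConfig) -> dict:
    """Annotate biomes and climate zones; summarize density by biome."""
    _, table = _load_inputs(config) if config["tree"] else (None, dataset.load_table(config["table"]))
    prov = config.provenance()
    biome_cfg = (dataset.BiomeConfig.from_yaml(config["biome_config"])
                 if config["biome_config"] else dataset.BiomeConfig.default())

    kept, rejections = dataset.filter_records(table)
    agg = dataset.aggregate_site_species(kept)
    zones = dataset.classify_climate_zones(agg)
    agg["climate_zone"] = agg["species"].map(zones)
    annotated = dataset.classify_biomes(agg, biome_cfg)
    _write_json({"n_input": len(table), "n_kept": len(kept),
                 "rejections": rejections},
                config.out_dir / "rejection_log.json", prov)

    groups = {name: sub["wood_density"].to_numpy()
              for name, sub in annotated.groupby("biome") if len(sub) >= 2}
    summary_rows = []
    comparison = dataset.compare_groups(groups) if len(groups) >= 2 else None
    for name, sub in annotated.groupby("biome"):
        dens = sub["wood_density"]
        summary_rows.append({
            "biome": name, "n": len(sub), "mean": dens.mean(),
            "median": dens.median(), "q25": dens.quantile(0.25),
            "q75": dens.quantile(0.75),
            "letters": comparison.letters.get(name, "") if comparison else "",
        })
    summary = pd.DataFrame(summary_rows)

    out = config.out_dir
    _write_csv(annotated, out / "classified_table.csv", prov)
    _write_csv(summary, out / "biome_summary.csv", prov)
    result = {"summary": summary}
    if comparison is not None:
        result["anova"] = {"F": comparison.f_stat, "p": comparison.p_value,
                           "df_between": comparison.df_between,
                           "df_within": comparison.df_within}
        _write_json(result["anova"] | {"letters": comparison.letters},
                    out / "biome_anova.json", prov)
    return result


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def run_signal(config: RunConfig) -> pd.DataFrame:
    """Per-group Pagel's lambda report (lambda, LRT p, permutation p)."""
    tree, table = _load_inputs(config)
    prov = config.provenance()
    agg = _annotated_species_table(table)
    trait = dataset.species_mean(agg)
    trait = trait[trait.index.isin(set(tree.tip_labels))]

    rows = []
    seed = int(config["seed"])
    fit = phylo_signal.fit_lambda(trait, tree)
    perm = phylo_signal.permutation_test(trait, tree, n_perm=config["n_perm"],
                                         seed=seed)
    rows.append({"group": "Total", "n_species": fit.n_tips,
                 "lambda": fit.lambda_hat, "lrt_p": fit.lrt_p,
                 "perm_p": perm.perm_p, "status": "ok"})

    species_info = agg.drop_duplicates("species").set_index("species")
    for gi, gcol in enumerate(config["grouping"]):
        if gcol not in species_info.columns:
            logger.warning("grouping column %r not present; skipped", gcol)
            continue
        groups = species_info.loc[trait.index, gcol]
        res = phylo_signal.signal_by_group(
            trait, groups, tree, n_perm=config["n_perm"],
            seed=seed + 1000 * (gi + 1), min_species=config["min_group_size"])
        rows.extend(res.to_dict(orient="records"))
    report = pd.DataFrame(rows)
    report["significance"] = [_stars(p) for p in report["perm_p"]]
    _write_csv(report, config.out_dir / "signal_report.csv", prov)
    return report


class _LinearPredictor:
    """OLS fit/predict wrapper used as the default importance regressor."""

    def __init__(self, table: pd.DataFrame, variables,
                 response: str = "wood_density"):
        import statsmodels.api as sm

        self.variables = list(variables)
        X = sm.add_constant(table[self.variables].to_numpy(dtype=float),
                            has_constant="add")
        self._res = sm.OLS(table[response].to_numpy(dtype=float), X).fit()

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        import statsmodels.api as sm

        X = sm.add_constant(table[self.variables].to_numpy(dtype=float),
                            has_constant="add")
        return self._res.predict(X)


def run_partition(config: RunConfig) -> dict:
    """Model selection, PMM fit, environment-only R2, importance ranking."""
    tree, table = _load_inputs(config)
    prov = config.provenance()
    agg = _annotated_species_table(table)

    candidates = [c for c in config["candidates"] if c in agg.columns]
    if candidates:
        selection = pmm.select_fixed_effects(
            agg, candidates, criterion=config["selection_criterion"])
        fixed = list(selection.best)
    else:
        selection = None
        fixed = []
    logger.info("selected fixed effects: %s", fixed)

    design = pmm.build_design(agg, tree, fixed)
    if config["backend"] == "mcmc":
        m = config["mcmc"]
        fit = pmm.fit_pmm_mcmc(design, n_iter=m["n_iter"], burnin=m["burnin"],
                               thin=m["thin"], seed=config["seed"])
    else:
        fit = pmm.fit_pmm_ml(design, reml=config["reml"])

    env = pmm.env_only_r2(agg, fixed) if fixed else None
    importance = None
    if fixed:
        predictor = _LinearPredictor(agg, fixed)
        importance = pmm.permutation_importance(
            predictor, agg, fixed, n_repeats=config["importance_repeats"],
            seed=config["seed"])

    out = config.out_dir
    beta = fit.beta.reset_index(names="term")
    stats_row = {"sigma2_p": fit.sigma2_p, "sigma2_s": fit.sigma2_s,
                 "sigma2_e": fit.sigma2_e, "sigma2_f": fit.sigma2_f,
                 **fit.partition,
                 "env_r2": env.r2 if env else 0.0,
                 "backend": fit.method}
    _write_csv(beta, out / "partition_fixed_effects.csv", prov)
    _write_csv(pd.DataFrame([stats_row]), out / "partition_stats.csv", prov)
    payload = {
        "selected_fixed_effects": fixed,
        "fixed_effects": beta,
        "model_statistics": {k: v for k, v in stats_row.items()
                             if k != "backend"},
        "backend": fit.method,
        "warnings": fit.warnings,
    }
    if selection is not None:
        payload["selection_table"] = selection.table.assign(
            subset=selection.table["subset"].map(lambda s: "+".join(s)))
    if importance is not None:
        payload["importance"] = importance.scores
        _write_csv(importance.scores, out / "importance.csv", prov)
    if fit.chain is not None:
        _write_csv(fit.chain, out / "mcmc_chain.csv", prov)
    _write_json(payload, out / "partition_report.json", prov)
    return payload


def run_report(config: RunConfig) -> dict:
    """Run classify, signal, and partition in sequence."""
    out = {}
    out["classify"] = run_classify(config)
    out["signal"] = run_signal(config)
    out["partition"] = run_partition(config)
    return out
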