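"""Reproducible experiment orchestration and the ``flornet`` CLI.

Chains the pipeline stages (generate -> fit -> simulate -> compare ->
nn-train -> knockout) from a YAML/JSON config, records every seed in a
run manifest, and renders the model-comparison table with the
conventional significance bands: one-sided
rank-sum p-values labeled ns (p > 0.05), * (0.01 < p <= 0.05),
** (0.001 < p <= 0.01), *** (1e-4 < p <= 0.001) and **** (p <= 1e-4).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import click
import numpy as np
import pandas as pd
import yaml

from . import data_model, fitting, knockout as ko, nn_models, ode_models, synthetic_data

log = logging.getLogger("flornet")

_BANDS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def significance_band(p: float) -> str:
    """Label a p-value with the figure-style significance band."""
    if not (0.0 < p <= 1.0):
        raise ValueError("p-value must lie in (0, 1]")
    for cut, label in _BANDS:
        if p <= cut:
            return label
    return "ns"


def parse_scope(scope: Sequence[str]) -> list[data_model.ConditionKey]:
    """Parse condition strings like 'WT-LD' or 'gigas-2-LD'."""
    out = []
    for s in scope:
        genotype, _, photoperiod = s.rpartition("-")
        out.append(data_model.ConditionKey(genotype, photoperiod))
    return out


def compare_report(ensembles: Mapping[str, fitting.EnsembleResult],
                   pairs: Sequence[tuple], alternative: str = "less") -> pd.DataFrame:
    """Pairwise rank-sum comparison table of ensemble NRMSE distributions."""
    rows = []
    for a, b in pairs:
        if a not in ensembles or b not in ensembles:
            raise KeyError(f"comparison pair ({a}, {b}) references a missing ensemble")
        p = fitting.compare_models(ensembles[a].nrmse_values(),
                                   ensembles[b].nrmse_values(),
                                   alternative=alternative)
        rows.append({"model_a": a, "model_b": b, "alternative": alternative,
                     "p_value": p, "band": significance_band(p)})
    return pd.DataFrame(rows)


def _solutions_to_dataset(solutions: Mapping) -> pd.DataFrame:
    rows = []
    for (gene, condition), tr in solutions.items():
        data_gene, tissue = ode_models.MODELED_TO_DATA[gene]
        for t, v in zip(tr.times, tr.values):
            rows.append({"gene": data_gene, "tissue": tissue,
                         "genotype": condition.genotype,
                         "photoperiod": condition.photoperiod,
                         "time": t, "mean": v, "sd": 0.0})
    return pd.DataFrame(rows, columns=data_model.COLUMNS)


def _fit_to_dict(fit: fitting.FitResult) -> dict:
    return {
        "params": dataclasses.asdict(fit.params),
        "wrss": fit.wrss,
        "nrmse_by_scope": {str(k): v for k, v in fit.nrmse_by_scope.items()},
        "seed": fit.seed,
        "n_cost_evals": fit.n_cost_evals,
        "converged": fit.converged,
    }


def run_experiment(config: Mapping | str | Path, out_dir=None) -> dict:
    """Execute the stages requested in a run config; return the manifest.

    Config keys: ``out`` (directory), ``seed``, and a ``stages`` list of
    stage dicts; each stage has a ``stage`` name plus its own options.
    Deterministic outputs are reproduced bit-identically on re-run.
    """
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir or config.get("out", "run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = {"seed": seed, "stages": [], "status": "complete"}
    state: dict = {"ensembles": {}, "nn": None, "expanded": None}

    for stage_cfg in config.get("stages", []):
        stage = stage_cfg["stage"]
        try:
            record = _run_stage(stage, stage_cfg, state, out, seed)
        except Exception as exc:  # record partial completion
            manifest["stages"].append({"stage": stage, "status": "failed",
                                       "error": str(exc)})
            manifest["status"] = "partial"
            log.exception("stage %s failed", stage)
            break
        record["status"] = "ok"
        manifest["stages"].append(record)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_stage(stage, cfg, state, out, seed):
    record = {"stage": stage, "options": {k: v for k, v in cfg.items() if k != "stage"}}

    if stage == "generate":
        kind = cfg.get("kind", "phenomenological")
        gc = synthetic_data.GeneratorConfig(noise_cv=cfg.get("noise_cv", 0.1),
                                            seed=seed)
        if kind == "phenomenological":
            ds = synthetic_data.generate_phenomenological(gc)
            truth = None
        elif kind == "mechanistic":
            spec = ode_models.model_spec(cfg.get("variant", "MC"))
            conditions = parse_scope(cfg.get("scope", ["WT-LD", "WT-SD"]))
            ds = synthetic_data.generate_mechanistic(
                spec, config=gc, conditions=conditions,
                jitter=cfg.get("jitter", False))
            truth = dataclasses.asdict(synthetic_data.TRUE_PARAMS_MC)
        elif kind == "benchmark":
            expanded, signs = synthetic_data.generate_network_benchmark(seed=seed)
            state["expanded"] = expanded
            truth = {"signed_adjacency": signs.tolist(),
                     "regulators": list(nn_models.INPUT_GENES),
                     "targets": list(nn_models.OUTPUT_GENES)}
            ds = None
        else:
            raise ValueError(f"unknown generation kind {kind!r}")
        if ds is not None:
            data_model.write_expression_table(ds, out / "dataset.csv")
            state["dataset"] = ds
            record["dataset"] = "dataset.csv"
        if truth is not None:
            with open(out / "truth.json", "w") as fh:
                json.dump(truth, fh, indent=2)
            record["truth"] = "truth.json"
        return record

    if stage == "fit":
        ds = _require_dataset(state, cfg)
        spec = ode_models.model_spec(cfg.get("variant", "MC"))
        scope = parse_scope(cfg.get("scope", ["WT-LD", "WT-SD"]))
        settings = fitting.DESettings(**cfg.get("de_settings", {}))
        ens = fitting.run_ensemble(spec, ds, scope,
                                   n_runs=cfg.get("n_runs", 20),
                                   base_seed=cfg.get("base_seed", seed),
                                   de_settings=settings)
        name = cfg.get("name", spec.variant)
        state["ensembles"][name] = ens
        with open(out / f"fit_{name}.json", "w") as fh:
            json.dump({"fits": [_fit_to_dict(f) for f in ens.fits],
                       "best": ens.best}, fh, indent=2)
        ctx = fitting.CostContext(spec, ds, scope, fast_step=settings.fast_step)
        sols = ctx.solutions(ens.best_fit.params)
        _solutions_to_dataset(sols).to_csv(out / f"solutions_{name}.csv", index=False)
        record.update({"name": name, "best_wrss": float(ens.best_fit.wrss)})
        return record

    if stage == "simulate":
        ds = _require_dataset(state, cfg)
        spec = ode_models.model_spec(cfg.get("variant", "MC"))
        scope = parse_scope(cfg.get("scope", ["WT-LD", "WT-SD"]))
        if "params" in cfg and isinstance(cfg["params"], str):
            with open(cfg["params"]) as fh:
                payload = json.load(fh)
            best = payload["fits"][payload["best"]]["params"]
            params = ode_models.ParameterSet(**best)
        elif "params" in cfg:
            params = ode_models.ParameterSet(**cfg["params"])
        else:
            from .synthetic_data import TRUE_PARAMS_MC
            params = TRUE_PARAMS_MC
        ctx = fitting.CostContext(spec, ds, scope)
        sols = ctx.solutions(params)
        name = cfg.get("name", spec.variant)
        _solutions_to_dataset(sols).to_csv(out / f"solutions_{name}.csv", index=False)
        record.update({"name": name,
                       "nrmse": fitting.nrmse(sols, ds, scope)})
        return record

    if stage == "compare":
        pairs = [tuple(p) for p in cfg["pairs"]]
        table = compare_report(state["ensembles"], pairs,
                               alternative=cfg.get("alternative", "less"))
        table.to_csv(out / "comparison.csv", index=False)
        record["table"] = "comparison.csv"
        return record

    if stage == "nn-train":
        ds = _require_dataset(state, cfg)
        protocol = cfg.get("protocol", "NN")
        expanded = nn_models.expand_dataset(ds, n_samples=cfg.get("samples", 1000),
                                            seed=seed)
        train, _test = nn_models.split_train_test(expanded, protocol)
        pairs = nn_models.build_training_pairs(train)
        ens = nn_models.train_regressor(pairs,
                                        topology=tuple(cfg.get("topology", (16,))),
                                        n_members=cfg.get("members", 20),
                                        seed=seed,
                                        max_iter=cfg.get("max_iter", 500))
        state["nn"] = ens
        state["expanded"] = expanded
        nn_models.save_ensemble(ens, out / f"nn_{protocol}.json")
        record.update({"protocol": protocol, "model": f"nn_{protocol}.json",
                       "mean_cv_score": float(np.mean(ens.cv_scores))})
        return record

    if stage == "knockout":
        if state.get("nn") is None and "model" in cfg:
            state["nn"] = nn_models.load_ensemble(cfg["model"])
        if state.get("nn") is None:
            raise ValueError("knockout stage requires a trained model")
        condition = parse_scope([cfg.get("condition", "WT-LD")])[0]
        expanded = state.get("expanded")
        if expanded is None:
            ds = _require_dataset(state, cfg)
            expanded = nn_models.expand_dataset(ds, n_samples=cfg.get("samples", 1000),
                                                seed=seed)
        matrix = ko.knockout_ratio_matrix(state["nn"], expanded, condition)
        pd.DataFrame(matrix.ratios, index=list(matrix.regulators),
                     columns=list(matrix.targets)).to_csv(out / "knockout_ratios.csv")
        calls = ko.classify_interactions(matrix, tolerance=cfg.get("tolerance", 0.05))
        pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
            out / "knockout_calls.csv", index=False)
        record["ratios"] = "knockout_ratios.csv"
        return record

    raise ValueError(f"unknown stage {stage!r}")


def _require_dataset(state, cfg):
    if "data" in cfg:
        ds = data_model.load_expression_table(cfg["data"])
        state["dataset"] = ds
        return ds
    if state.get("dataset") is None:
        raise ValueError("stage needs a dataset: give 'data' or run generate first")
    return state["dataset"]


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
def main():
    """Pea floral-transition gene network modeling pipeline."""
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


def _single_stage(stage: str, seed: int, out: str, **options):
    cfg = {"seed": seed, "out": out,
           "stages": [{"stage": stage, **options}]}
    return run_experiment(cfg)


@main.command()
@click.option("--kind", default="phenomenological",
              type=click.Choice(["phenomenological", "mechanistic", "benchmark"]))
@click.option("--variant", default="MC")
@click.option("--seed", default=0, type=int)
@click.option("--out", default="run")
def generate(kind, variant, seed, out):
    """Generate a synthetic dataset and its ground truth."""
    _single_stage("generate", seed, out, kind=kind, variant=variant)


@main.command()
@click.option("--config", "config_path", default=None, type=click.Path(exists=True))
@click.option("--data", default=None, type=click.Path(exists=True))
@click.option("--variant", default="MC")
@click.option("--scope", default="WT-LD,WT-SD")
@click.option("--n-runs", default=20, type=int)
@click.option("--seed", default=0, type=int)
@click.option("--out", default="run")
def fit(config_path, data, variant, scope, n_runs, seed, out):
    """Fit an ODE model variant by a differential-evolution ensemble."""
    if config_path:
        run_experiment(config_path, out_dir=out)
        return
    opts = {"variant": variant, "scope": scope.split(","), "n_runs": n_runs}
    if data:
        opts["data"] = data
    _single_stage("fit", seed, out, **opts)


@main.command()
@click.option("--data", required=True, type=click.Path(exists=True))
@click.option("--variant", default="MC")
@click.option("--params", "params_path", default=None, type=click.Path(exists=True),
              help="fit_*.json whose best member supplies the parameters")
@click.option("--scope", default="WT-LD,WT-SD")
@click.option("--seed", default=0, type=int)
@click.option("--out", default="run")
def simulate(data, variant, params_path, scope, seed, out):
    """Simulate a model variant with data-driven regulators."""
    opts = {"data": data, "variant": variant, "scope": scope.split(",")}
    if params_path:
        opts["params"] = params_path
    _single_stage("simulate", seed, out, **opts)


@main.command()
@click.option("--fits", "fit_paths", required=True, multiple=True,
              type=click.Path(exists=True),
              help="two or more fit_*.json files; compared pairwise in order")
@click.option("--alternative", default="less", type=click.Choice(["less", "two-sided", "greater"]))
@click.option("--out", default="run")
def compare(fit_paths, alternative, out):
    """Rank-sum comparison of saved fit ensembles' NRMSE distributions."""
    import pandas as pd

    from pathlib import Path as _P
    named = {}
    for p in fit_paths:
        with open(p) as fh:
            payload = json.load(fh)
        nrmses = [f["nrmse_by_scope"]["full"] for f in payload["fits"]]
        named[_P(p).stem.removeprefix("fit_")] = nrmses
    names = list(named)
    rows = []
    for a, b in zip(names, names[1:]):
        p_val = fitting.compare_models(named[a], named[b], alternative=alternative)
        rows.append({"model_a": a, "model_b": b, "alternative": alternative,
                     "p_value": p_val, "band": significance_band(p_val)})
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out_dir / "comparison.csv", index=False)
    click.echo((out_dir / "comparison.csv").read_text())


@main.command("nn-train")
@click.option("--protocol", default="NN",
              type=click.Choice(["NN", "NN_SDdata", "NN_LDdata"]))
@click.option("--data", required=True, type=click.Path(exists=True))
@click.option("--samples", default=1000, type=int)
@click.option("--members", default=20, type=int)
@click.option("--seed", default=0, type=int)
@click.option("--out", default="run")
def nn_train(protocol, data, samples, members, seed, out):
    """Train the one-step neural regression ensemble."""
    _single_stage("nn-train", seed, out, protocol=protocol, data=data,
                  samples=samples, members=members)


@main.command("knockout")
@click.option("--model", required=True, type=click.Path(exists=True))
@click.option("--data", required=True, type=click.Path(exists=True))
@click.option("--condition", default="WT-LD")
@click.option("--seed", default=0, type=int)
@click.option("--out", default="run")
def knockout_cmd(model, data, condition, seed, out):
    """Run the in-silico knockout screen on a trained model."""
    _single_stage("knockout", seed, out, model=model, data=data,
                  condition=condition)


@main.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--out", default=None)
def report(config_path, out):
    """Run a full multi-stage experiment from a YAML config."""
    run_experiment(config_path, out_dir=out)


if __name__ == "__main__":
    main()
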