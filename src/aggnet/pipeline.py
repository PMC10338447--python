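"""End-to-end orchestration of the analysis pipeline.

Stages, in order: cohort generation (or ingest) -> item and participant
filtering -> outcome construction (first-PC general psychopathology fitted on
discovery rows only, BPAQ sums) -> discovery/holdout and repeated inner
splits -> per-outcome LASSO ensembles with holdout validation -> overlap
extraction, restricted-model and cross-outcome predictions -> factor
reduction of the overlap features on complete cases -> automatic
normalization of factor scores and outcomes -> unregularized GGM -> edge
bootstrap and case-drop stability. Every stage seed derives deterministically
from the master seed, so a run is reproducible end to end, and no fitted
statistic ever sees holdout rows before the final prediction step.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import stage_seed
from . import ensemble as ens
from . import factors as fac
from . import ggm
from . import normalize as nrm
from . import outcomes as out
from . import preprocess as pre
from . import stability as stab
from . import synthetic as syn


@dataclass
class StabilitySettings:
    n_boot_edges: int = 200
    n_boot_per_level: int = 20
    drop_grid: tuple[float, ...] = stab.DEFAULT_DROP_GRID


@dataclass
class RunConfig:
    synthetic: syn.SyntheticConfig | None = None
    cohort_csv: str | None = None
    dictionary_yaml: str | None = None
    plan: pre.PreprocessPlan = field(default_factory=pre.PreprocessPlan)
    ensemble: ens.EnsembleConfig = field(default_factory=ens.EnsembleConfig)
    ggm: ggm.GgmConfig = field(default_factory=ggm.GgmConfig)
    stability: StabilitySettings = field(default_factory=StabilitySettings)
    target_r: float | None = None  # calibrate the generator before running
    master_seed: int = 0
    output_dir: str | None = None
    run_stability: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "synthetic" in raw:
            kwargs["synthetic"] = syn.SyntheticConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["synthetic"].items()
            })
        if "plan" in raw:
            kwargs["plan"] = pre.PreprocessPlan(**raw["plan"])
        if "ensemble" in raw:
            e = dict(raw["ensemble"])
            if "alpha_grid" in e:
                e["alpha_grid"] = tuple(e["alpha_grid"])
            kwargs["ensemble"] = ens.EnsembleConfig(**e)
        if "ggm" in raw:
            kwargs["ggm"] = ggm.GgmConfig(**raw["ggm"])
        if "stability" in raw:
            s = dict(raw["stability"])
            if "drop_grid" in s:
                s["drop_grid"] = tuple(s["drop_grid"])
            kwargs["stability"] = StabilitySettings(**s)
        for key in ("cohort_csv", "dictionary_yaml", "target_r", "master_seed", "output_dir", "run_stability"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class RunReport:
    """Aggregated quantities from one full pipeline run."""

    n_included: int
    n_discovery: int
    n_holdout: int
    n_features_kept: int
    pc1_variance_explained: float
    outcome_r_discovery: float
    outcome_r_holdout: float
    subfactor_significant_cells: int
    holdout_metrics: dict
    restricted_metrics: dict
    cross_prediction_metrics: dict
    n_significant: dict
    n_overlap: int
    n_complete_cases: int
    n_factors: int
    network_nodes: list[str]
    network_edges: list[dict]
    expected_influence: dict
    stable_outcome_edges: list[dict] | None = None
    cs_coefficient: float | None = None
    transform_choices: dict | None = None
    timings: dict = field(default_factory=dict)

    def to_json(self, path=None, include_timings: bool = False) -> str:
        """Serialize the report; deterministic given the master seed.

        Wall-clock timings are excluded by default so two runs with the same
        seed produce byte-identical output.
        """
        payload = asdict(self)
        if not include_timings:
            payload.pop("timings", None)
        text = json.dumps(payload, indent=2, sort_keys=True, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_pipeline(config: RunConfig) -> RunReport:
    timings: dict[str, float] = {}

    def tic(stage):
        timings[stage] = time.perf_counter()

    def toc(stage):
        timings[stage] = round(time.perf_counter() - timings[stage], 3)

    # --- stage: cohort ----------------------------------------------------
    tic("cohort")
    if config.synthetic is not None:
        scfg = config.synthetic.replace(seed=stage_seed(config.master_seed, "synthetic"))
        if config.target_r is not None:
            scfg = syn.tune_overlap_for_target_r(scfg, config.target_r)
        table, outcome_items, truth = syn.generate_cohort(scfg)
    elif config.cohort_csv and config.dictionary_yaml:
        table = pre.FeatureTable.from_csv(config.cohort_csv, config.dictionary_yaml)
        outcome_cols = [c for c, m in table.dictionary.items() if m.role == "outcome"]
        outcome_items = table.values[outcome_cols].astype(float)
        table = table.subset_items([c for c in table.items if c not in outcome_cols])
        truth = None
    else:
        raise ValueError("provide either a synthetic config or cohort paths")
    toc("cohort")

    # --- stage: preprocessing filters ------------------------------------
    tic("filters")
    table, item_log = pre.filter_items(table, config.plan)
    table, outcome_items, part_log = pre.filter_participants(
        table, outcome_items, config.plan
    )
    table.values.reset_index(drop=True, inplace=True)
    outcome_items = outcome_items.reset_index(drop=True)
    n = len(table.values)
    toc("filters")

    # --- stage: splits ----------------------------------------------------
    splits = pre.make_splits(
        n,
        n_repeats=config.ensemble.n_repeats,
        seed=stage_seed(config.master_seed, "splits"),
    )
    disc, hold = splits.discovery_idx, splits.holdout_idx

    # --- stage: outcomes --------------------------------------------------
    tic("outcomes")
    scale_cols = [c for c in syn.SYMPTOM_SCALES if c in outcome_items.columns]
    bpaq_cols = [c for c in outcome_items.columns if c.startswith("bpaq_")]
    gp = out.compute_general_psychopathology(outcome_items.iloc[disc][scale_cols])
    gpsy = pd.Series(index=outcome_items.index, dtype=float)
    gpsy.iloc[disc] = gp.score.to_numpy()
    gpsy.iloc[hold] = gp.project(outcome_items.iloc[hold][scale_cols]).to_numpy()
    aggr = out.compute_bpaq(outcome_items[bpaq_cols]).total
    sub = out.compute_bpaq(outcome_items[bpaq_cols])
    r_disc, _ = out.pearson_with_p(gpsy.iloc[disc], aggr.iloc[disc])
    r_hold, _ = out.pearson_with_p(gpsy.iloc[hold], aggr.iloc[hold])
    corr_report = out.correlate_with_fdr(
        sub.as_frame().iloc[disc], outcome_items.iloc[disc][scale_cols]
    )
    toc("outcomes")

    # --- stage: ensembles -------------------------------------------------
    tic("ensembles")
    disc_table = table.subset_rows(table.values.index[disc])
    hold_table = table.subset_rows(table.values.index[hold])
    ref_ft, X_disc = pre.fit_transform(disc_table, config.plan)
    X_hold = pre.apply_transform(ref_ft, hold_table)
    y_scalers = {
        "gpsy": pre.OutcomeScaler.fit(gpsy.iloc[disc].to_numpy()),
        "aggr": pre.OutcomeScaler.fit(aggr.iloc[disc].to_numpy()),
    }
    y_disc = {
        "gpsy": gpsy.iloc[disc].to_numpy(),
        "aggr": aggr.iloc[disc].to_numpy(),
    }
    y_hold_std = {
        k: y_scalers[k].transform(v.iloc[hold].to_numpy())
        for k, v in (("gpsy", gpsy), ("aggr", aggr))
    }
    models: dict[str, ens.EnsembleModel] = {}
    for name in ("gpsy", "aggr"):
        cfg_r = ens.EnsembleConfig(
            **{
                **asdict(config.ensemble),
                "seed": stage_seed(config.master_seed, f"ensemble-{name}"),
                "alpha_grid": config.ensemble.alpha_grid,
            }
        )
        models[name] = ens.run_ensemble(X_disc, y_disc[name], splits, cfg_r, config.plan)
    holdout_metrics = {
        name: ens.predict_with_mean_betas(models[name], X_hold, y_hold_std[name]).to_dict()
        for name in models
    }
    overlap, r_gpsy, r_aggr = ens.overlap_and_restrict(models["gpsy"], models["aggr"])
    restricted = {"gpsy": r_gpsy, "aggr": r_aggr}
    restricted_metrics = {
        name: ens.predict_with_mean_betas(restricted[name], X_hold, y_hold_std[name]).to_dict()
        for name in restricted
    }
    cross_metrics = {
        "aggr_model_predicts_gpsy": ens.cross_predict(
            restricted["aggr"], X_hold, y_hold_std["gpsy"]
        ).to_dict(),
        "gpsy_model_predicts_aggr": ens.cross_predict(
            restricted["gpsy"], X_hold, y_hold_std["aggr"]
        ).to_dict(),
    }
    toc("ensembles")

    # --- stage: factors on complete cases ---------------------------------
    tic("factors")
    complete = (~table.missing_mask.any(axis=1)).to_numpy()
    complete &= ~outcome_items.isna().any(axis=1).to_numpy()
    comp_idx = np.flatnonzero(complete)
    comp_table = table.subset_rows(table.values.index[comp_idx])
    X_comp = pre.apply_transform(ref_ft, comp_table)
    n_factors = 0
    net = None
    report_stab = None
    cs = None
    transform_audit = None
    ei_dict: dict[str, float] = {}
    edges: list[dict] = []
    node_names: list[str] = []
    stable_edges = None
    if overlap:
        X_overlap = X_comp[overlap]
        pa_seed = stage_seed(config.master_seed, "parallel-analysis")
        n_factors = fac.parallel_analysis(X_overlap.to_numpy(), seed=pa_seed)
        n_factors = max(1, min(n_factors, max(1, len(overlap) - 1)))
        fm = fac.fit_minres_oblimin(X_overlap, n_factors)
        scores = fac.factor_scores(fm, X_overlap)
        toc("factors")

        # --- stage: normalization + network -------------------------------
        tic("network")
        net_input = scores.copy()
        net_input["GPsy"] = gpsy.iloc[comp_idx].to_numpy()
        net_input["Aggr"] = aggr.iloc[comp_idx].to_numpy()
        transform_audit = {}
        for col in net_input.columns:
            choice = nrm.fit_best_transform(net_input[col].to_numpy())
            net_input[col] = choice.apply(net_input[col].to_numpy())
            transform_audit[col] = {
                "method": choice.method,
                "normality_stat": choice.normality_stat,
            }
        net = ggm.ggm_mod_select(net_input, config.ggm)
        node_names = net.nodes
        edges = net.edge_list().to_dict("records")
        ei_dict = stab.expected_influence(net).expected_influence.to_dict()
        toc("network")

        # --- stage: stability ---------------------------------------------
        if config.run_stability:
            tic("stability")
            boot = stab.bootstrap_edges(
                net_input,
                config.ggm,
                n_boot=config.stability.n_boot_edges,
                seed=stage_seed(config.master_seed, "boot-edges"),
                sample_network=net,
            )
            stable_edges = boot.outcome_edges(["GPsy", "Aggr"]).to_dict("records")
            cs_report = stab.casedrop_cs(
                net_input,
                config.ggm,
                drop_grid=config.stability.drop_grid,
                n_boot_per_level=config.stability.n_boot_per_level,
                seed=stage_seed(config.master_seed, "casedrop"),
            )
            cs = cs_report.cs_coefficient
            toc("stability")
    else:
        toc("factors")
        warnings.warn("empty overlap; network stages skipped")

    report = RunReport(
        n_included=n,
        n_discovery=len(disc),
        n_holdout=len(hold),
        n_features_kept=len(table.items),
        pc1_variance_explained=gp.variance_explained,
        outcome_r_discovery=r_disc,
        outcome_r_holdout=r_hold,
        subfactor_significant_cells=int(corr_report.significant.to_numpy().sum()),
        holdout_metrics=holdout_metrics,
        restricted_metrics=restricted_metrics,
        cross_prediction_metrics=cross_metrics,
        n_significant={k: m.n_significant for k, m in models.items()},
        n_overlap=len(overlap),
        n_complete_cases=int(complete.sum()),
        n_factors=n_factors,
        network_nodes=node_names,
        network_edges=edges,
        expected_influence=ei_dict,
        stable_outcome_edges=stable_edges,
        cs_coefficient=cs,
        transform_choices=transform_audit,
        timings=timings,
    )

    if config.output_dir:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_json(out_dir / "report.json")
        corr_report.to_csv(str(out_dir / "subfactor_correlations"))
        splits.to_json(out_dir / "splits.json")
        for name, m in models.items():
            m.to_json(out_dir / f"ensemble_{name}.json")
        if net is not None:
            net.edge_list().to_csv(out_dir / "network_edges.csv", index=False)
            net.to_json(out_dir / "network.json")
    return report
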