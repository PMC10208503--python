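"""End-to-end analysis: scores -> plausibility -> adjustment -> BART -> ALE.

Given a cohort table (and optionally item-level exams) plus a causal DAG,
the pipeline

1. computes or accepts the polychoric-PCA summary scores,
2. tests the DAG's implied conditional independencies against the data,
3. derives minimal backdoor adjustment sets for each exposure,
4. fits one sum-of-trees model per distinct predictor set — with the study
   DAG that is two models: one for GDI (predictors: GDI plus its adjustment
   set, which includes walking speed) and one shared by the four
   impairments,
5. computes an accumulated-local-effects curve with posterior bands and an
   effect size (curve range over the factor's middle-95% window) per factor,
6. ranks the factors by effect size.

Walking speed's curve can be requested too; it comes from the GDI model and
is labeled a direct effect (nothing downstream of speed except GDI and
power is in the graph), and it never enters the five-factor ranking.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import __version__
from .ale import ALECurve, EffectSize, ale_uncertainty, effect_size
from .bart import BARTConfig, FitMetrics, SumOfTreesPosterior, cv_select, default_cv_grid, fit, fit_metrics
from .causal_graph import CausalDAG, minimal_adjustment_sets, study_dag
from .cohort_scores import summary_score, zscore_factors
from .model_validation import PlausibilityReport, ValidationConfig, test_model_plausibility

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisReport", "run_analysis"]

EXPOSURES = ("GDI", "DMC", "SMC", "Spasticity", "Strength")
OUTCOME = "MetPower"


@dataclass
class PipelineConfig:
    """Settings for one analysis run."""

    seed: int = 42
    bart: BARTConfig = field(default_factory=BARTConfig)
    bins: int = 40
    cutoff: float = 0.3
    zscore: bool = True
    include_speed: bool = True
    cv: bool = False
    cv_folds: int = 5
    hard_fail_plausibility: bool = False
    ale_max_draws: int = 200


@dataclass
class AnalysisReport:
    plausibility: PlausibilityReport
    adjustment_sets: dict[str, list[str]]
    model_predictors: dict[str, list[str]]
    metrics: dict[str, FitMetrics]
    factor_model: dict[str, str]
    curves: dict[str, ALECurve]
    effects: dict[str, EffectSize]
    ranking: list[tuple[str, float]]
    scaling: dict[str, dict[str, float]]
    metadata: dict

    def to_json(self) -> str:
        payload = {
            "metadata": self.metadata,
            "plausibility": json.loads(self.plausibility.to_json()),
            "adjustment_sets": self.adjustment_sets,
            "model_predictors": self.model_predictors,
            "factor_model": self.factor_model,
            "metrics": {k: asdict(v) for k, v in self.metrics.items()},
            "effects": {
                k: {
                    "window": list(v.window),
                    "effect_range_w": v.effect_range,
                    "lo": v.lo,
                    "hi": v.hi,
                }
                for k, v in self.effects.items()
            },
            "ranking": self.ranking,
            "scaling": self.scaling,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def to_markdown(self) -> str:
        lines = ["# Causal effect analysis of net metabolic power", ""]
        md = self.metadata
        lines.append(
            f"Run: seed {md['seed']}, n = {md['n']}, software {md['version']}."
        )
        lines.append("")
        lines.append("## Model plausibility")
        lines.append(
            f"max |partial r| = {self.plausibility.max_abs_r:.3f} "
            f"(cutoff {self.plausibility.cutoff}) — "
            + ("plausible" if self.plausibility.plausible else "NOT plausible")
        )
        lines.append("")
        lines.append("## Fit metrics")
        for name, m in self.metrics.items():
            lines.append(f"- model {name}: pseudo-R² = {m.r_squared:.2f}, RMSE = {m.rmse:.2f} W")
        lines.append("")
        lines.append("## Effect sizes (range of the ALE curve over the middle 95%)")
        lines.append("")
        lines.append("| rank | factor | effect (W) | 95% interval |")
        lines.append("|---|---|---|---|")
        for i, (factor, eff) in enumerate(self.ranking, start=1):
            e = self.effects[factor]
            ci = f"[{e.lo:.1f}, {e.hi:.1f}]" if e.lo is not None else "--"
            lines.append(f"| {i} | {factor} | {eff:.1f} | {ci} |")
        if "Speed" in self.effects:
            e = self.effects["Speed"]
            lines.append("")
            lines.append(
                f"Walking speed (direct effect, excluded from ranking): "
                f"{e.effect_range:.1f} W"
            )
        return "\n".join(lines)


def _ensure_scores(cohort: pd.DataFrame, exams: pd.DataFrame | None) -> pd.DataFrame:
    """Fill absent summary-score columns from item-level exams if possible."""
    out = cohort.copy()
    mapping = {"spasticity": "Spasticity", "strength": "Strength", "smc": "SMC"}
    for domain, col in mapping.items():
        if col in out.columns:
            continue
        if exams is None:
            raise KeyError(
                f"cohort lacks column {col!r} and no exam table was given"
            )
        scores, _ = summary_score(exams, domain)
        out = out.merge(
            scores.rename(col).rename_axis("child").reset_index(), on="child", how="left"
        )
    return out


def run_analysis(
    cohort: pd.DataFrame,
    dag: CausalDAG | None = None,
    exams: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> AnalysisReport:
    """Run the full analysis and return a structured report.

    ``cohort`` needs one row per child with the DAG's observed variables as
    columns (missing values allowed everywhere except the outcome).  Every
    reported effect size comes from a model whose predictors are exactly the
    exposure plus its minimal adjustment set.
    """
    cfg = config or PipelineConfig()
    dag = dag or study_dag()

    cohort = _ensure_scores(cohort, exams)
    required = sorted((dag.observed | {OUTCOME}) - set(cohort.columns))
    if required:
        raise KeyError(f"cohort lacks required column(s): {required}")

    # 1-2. plausibility of the causal model against the data
    plaus = test_model_plausibility(dag, cohort, ValidationConfig(cutoff=cfg.cutoff))
    if not plaus.plausible:
        msg = (
            f"model implausible: max |partial r| = {plaus.max_abs_r:.3f} "
            f">= cutoff {plaus.cutoff}"
        )
        if cfg.hard_fail_plausibility:
            raise RuntimeError(msg)
        logger.warning("%s; proceeding", msg)

    # 3. adjustment sets
    adj: dict[str, list[str]] = {}
    skipped: list[str] = []
    for exposure in EXPOSURES:
        sets = minimal_adjustment_sets(dag, exposure, OUTCOME)
        if not sets:
            logger.warning("%s: not identifiable by covariate adjustment; skipped", exposure)
            skipped.append(exposure)
            continue
        adj[exposure] = sorted(sets[0])

    # 4. factor normalization and model fitting
    analysis = cohort[cohort[OUTCOME].notna()].reset_index(drop=True)
    scaling: dict[str, dict[str, float]] = {}
    if cfg.zscore:
        analysis, scaling = zscore_factors(analysis)

    predictor_sets: dict[str, tuple[str, ...]] = {}
    factor_model: dict[str, str] = {}
    for exposure in adj:
        preds = tuple(sorted({exposure, *adj[exposure]}))
        name = next((k for k, v in predictor_sets.items() if v == preds), None)
        if name is None:
            name = chr(ord("A") + len(predictor_sets))
            predictor_sets[name] = preds
        factor_model[exposure] = name

    models: dict[str, SumOfTreesPosterior] = {}
    metrics: dict[str, FitMetrics] = {}
    bart_cfg = BARTConfig(**{**asdict(cfg.bart), "seed": cfg.seed})
    y = analysis[OUTCOME].to_numpy(dtype=float)
    for name, preds in predictor_sets.items():
        X = analysis[list(preds)]
        model_cfg = bart_cfg
        if cfg.cv:
            model_cfg, cv_table = cv_select(
                X, y, default_cv_grid(bart_cfg), folds=cfg.cv_folds, seed=cfg.seed
            )
            logger.info("model %s: CV selected %s", name, model_cfg)
        models[name] = fit(X, y, model_cfg)
        metrics[name] = fit_metrics(models[name], X, y, max_draws=cfg.ale_max_draws)
        logger.info(
            "model %s (p=%d): R²=%.3f RMSE=%.1f W",
            name, len(preds), metrics[name].r_squared, metrics[name].rmse,
        )

    # 5. ALE curves and effect sizes
    curves: dict[str, ALECurve] = {}
    effects: dict[str, EffectSize] = {}
    targets = list(adj)
    if cfg.include_speed and "Speed" in analysis.columns and "GDI" in factor_model:
        targets.append("Speed")
    for factor in targets:
        model_name = factor_model.get(factor, factor_model.get("GDI"))
        model = models[model_name]
        data = analysis[list(predictor_sets[model_name])]
        curve = ale_uncertainty(
            model, data, factor, bins=cfg.bins, max_draws=cfg.ale_max_draws
        )
        es = effect_size(curve, analysis[factor])
        curves[factor] = curve
        effects[factor] = es

    ranking = sorted(
        ((f, effects[f].effect_range) for f in adj if f in effects),
        key=lambda t: -t[1],
    )

    metadata = {
        "seed": cfg.seed,
        "n": int(len(analysis)),
        "version": __version__,
        "bins": cfg.bins,
        "bart": asdict(bart_cfg),
        "zscore": cfg.zscore,
        "not_identifiable": skipped,
        "models": {name: list(preds) for name, preds in predictor_sets.items()},
    }
    return AnalysisReport(
        plausibility=plaus,
        adjustment_sets=adj,
        model_predictors={n: list(p) for n, p in predictor_sets.items()},
        metrics=metrics,
        factor_model={f: factor_model.get(f, factor_model.get("GDI")) for f in targets},
        curves=curves,
        effects=effects,
        ranking=ranking,
        scaling=scaling,
        metadata=metadata,
    )
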