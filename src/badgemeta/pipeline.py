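"""End-to-end re-analysis pipeline: convert, audit, fit, summarize.

Stages: read the extraction table and the Newick tree; convert every reported
statistic to a signed correlation with sampling variance; audit the
per-origin sign distribution; build the within-study sampling VCV and the
phylogenetic correlation matrix; fit the intercept-only phylogenetic
multilevel model; decompose heterogeneity (Q, sigma^2, multilevel I^2,
prediction interval); run the small-study-effects meta-regression; and
optionally fit a uni-moderator meta-regression (e.g. effect-size origin).
Every excluded or flagged effect is listed with its reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import effect_sizes as es
from . import heterogeneity_bias as hb
from . import meta_engine as me
from . import phylo as ph


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    data_path: str
    tree_path: str
    rho: float = 0.5
    scale: str = "raw_r"
    moderator: str | None = None
    small_study_kind: str = "inv_sqrt_n_eff"
    inference: str = "z"
    seed: int = 1
    output_dir: str | None = None
    keep_unsigned: bool = False
    variant: str = "fixed"

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        es.ScaleTag(self.scale)
        if self.inference not in ("z", "t"):
            raise ValueError("inference must be 'z' or 't'")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PipelineStageError(RuntimeError):
    """Error in a named pipeline stage, with row/species context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


def _stage(stage: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(stage, str(exc)) from exc
        return wrapped
    return deco


@_stage("read")
def load_inputs(cfg: RunConfig) -> tuple[pd.DataFrame, ph.Phylogeny]:
    table = pd.read_csv(cfg.data_path)
    missing = [c for c in es.INPUT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"input table is missing columns: {missing}")
    tree = ph.parse_newick(Path(cfg.tree_path).read_text())
    return table, tree


@_stage("convert")
def convert_effects(table: pd.DataFrame, cfg: RunConfig
                    ) -> tuple[list[es.EffectSizeRecord], list[dict]]:
    records = [es.convert_row(row, variant=cfg.variant) for _, row in table.iterrows()]
    log: list[dict] = []
    kept = []
    for rec in records:
        if rec.sign_source is es.SignSource.FLAGGED_UNKNOWN and not cfg.keep_unsigned:
            log.append({"effect_id": rec.effect_id,
                        "reason": "unknown sign: direction not reported"})
        else:
            kept.append(rec)
    return kept, log


@_stage("audit")
def audit_effects(records: list[es.EffectSizeRecord], cfg: RunConfig
                  ) -> tuple[list[es.EffectSizeRecord], pd.DataFrame]:
    records = es.fisher_z_guard(records, cfg.scale)
    audit = es.sign_distribution_audit(records)
    return records, audit


@_stage("tree")
def build_phylo_correlation(tree: ph.Phylogeny, records) -> ph.PhyloCorrelation:
    needs_lengths = any(
        e.length is None for e in tree.tree.preorder_edge_iter()
        if e.head_node.parent_node is not None
    )
    if needs_lengths:
        tree = ph.grafen_lengths(tree)
    corr = ph.correlation_matrix(tree)
    ph.check_species_coverage([r.species for r in records], corr)
    return corr


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full re-analysis; returns (and optionally writes) a report."""
    table, tree = load_inputs(cfg)
    records, exclusion_log = convert_effects(table, cfg)
    records, audit = audit_effects(records, cfg)
    corr = build_phylo_correlation(tree, records)
    dataset = me.MetaDataset.from_records(records, phylo_corr=corr, rho=cfg.rho)

    report = analyze_dataset(dataset, cfg)
    report["audit"] = audit.to_dict(orient="records")
    report["excluded_effects"] = exclusion_log
    report["meta"] = {
        "package_version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        coefs = pd.DataFrame(report["overall"]["coefficients"])
        coefs.to_csv(out / "coefficients.csv", index=False)
        es.convert_table(table, variant=cfg.variant).to_csv(
            out / "effects_converted.csv", index=False)
    return report


@_stage("fit")
def analyze_dataset(dataset: me.MetaDataset, cfg: RunConfig) -> dict:
    """Intercept-only fit, heterogeneity block, small-study test, moderator fit."""
    fit = me.fit_intercept_model(dataset, seed=cfg.seed, inference=cfg.inference)
    wald = me.wald_inference(fit)
    q, q_df, q_p = me.cochran_q(dataset.y, dataset.v)
    v_bar = hb.typical_sampling_variance(dataset.v)
    i2_level, i2_total = hb.i2_multilevel(fit, v_bar)
    pi = hb.prediction_interval(fit)

    report: dict = {
        "k": dataset.k,
        "n_studies": dataset.n_studies,
        "n_species": dataset.n_species,
        "overall": {
            "estimate": float(fit.beta[0]),
            "se": float(fit.se[0]),
            "ci": [float(wald["ci_lower"][0]), float(wald["ci_upper"][0])],
            "p": float(wald["p"][0]),
            "pi": list(pi),
            "sigma2": fit.sigma2,
            "sigma2_total": fit.sigma2_total,
            "i2_total": i2_total,
            "i2_by_level": i2_level,
            "typical_v": v_bar,
            "Q": q, "Q_df": q_df, "Q_p": q_p,
            "converged": fit.converged,
            "loglik_reml": fit.loglik_reml,
            "coefficients": me.wald_inference(fit).to_dict(orient="records"),
        },
    }

    ss = hb.small_study_test(dataset, cfg.small_study_kind, seed=cfg.seed,
                             inference=cfg.inference)
    report["small_study"] = ss.to_dict()

    if cfg.moderator:
        mod_fit = me.meta_regression(dataset, cfg.moderator, seed=cfg.seed,
                                     inference=cfg.inference)
        report["moderator"] = {
            "name": cfg.moderator,
            "r2_marginal": hb.r2_marginal(mod_fit),
            "coefficients": me.wald_inference(mod_fit).to_dict(orient="records"),
            "sigma2": mod_fit.sigma2,
        }
    return report


def effect_size_origin_report(dataset: me.MetaDataset, cfg: RunConfig | None = None
                              ) -> dict:
    """Per-origin pooled estimates from the origin meta-regression.

    Fits the phylogenetic multilevel model with effect-size origin as a
    categorical moderator (no intercept, so coefficients are per-origin
    means) and tabulates per-origin k, number of studies, percent positive,
    estimate and CI, plus the moderator's marginal R^2.
    """
    cfg = cfg or RunConfig(data_path="", tree_path="")
    origins = dataset.moderators["origin"]
    if origins.nunique() < 2:
        raise PipelineStageError(
            "origin-report", f"single effect-size origin {origins.unique().tolist()}")
    fit = me.meta_regression(dataset, "origin", seed=cfg.seed, inference=cfg.inference)
    wald = me.wald_inference(fit)
    rows = []
    for _, coef in wald.iterrows():
        mask = (origins == coef["coef"]).to_numpy()
        rows.append({
            "origin": coef["coef"],
            "k": int(mask.sum()),
            "n_studies": int(len(set(dataset.study_ids[mask].tolist()))),
            "percent_positive": round(100.0 * float(np.mean(dataset.y[mask] > 0)), 1),
            "estimate": float(coef["estimate"]),
            "ci_lower": float(coef["ci_lower"]),
            "ci_upper": float(coef["ci_upper"]),
            "p": float(coef["p"]),
        })
    return {
        "table": rows,
        "r2_marginal": hb.r2_marginal(fit),
        "sigma2": fit.sigma2,
    }
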