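"""End-to-end orchestration: simulate/ingest -> harmonize -> similarity ->
brain age -> expression association, from a single YAML-able config.

Every stage persists its outputs before the next starts, so a failed run
leaves completed stages on disk; ``run_pipeline`` skips stages whose outputs
already exist when ``resume=True``. All randomness derives from the single
config seed through documented per-stage offsets.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .brainage import (
    BrainAgeConfig,
    compare_ded_prd_cognition,
    compare_models_mae,
    cross_validated_brainage,
    split_ded_prd,
)
from .harmonize import BatchDesign, combat, covbat
from .io import (
    read_expression,
    read_phenotypes,
    read_profiles,
    write_expression,
    write_phenotypes,
    write_profiles,
    write_table,
)
from .pbsi import (
    correlate_with_covariates,
    compare_groups,
    delta_contribution_map,
    group_contributions,
    group_pbsi,
    regionwise_group_difference,
)
from .synthetic import CohortSpec, ExpressionSpec, generate_cohort, generate_expression
from .transcriptomics import associate_delta_expression

logger = logging.getLogger("pbsikit")

__all__ = ["RunConfig", "run_pipeline"]

# fixed offsets so stage seeds are reproducible and independent
_STAGE_SEED_OFFSET = {"cohort": 1, "expression": 2, "brainage": 3}


@dataclass
class RunConfig:
    """Pipeline configuration; build from a YAML mapping via ``from_dict``."""

    out_dir: str
    seed: int = 0
    profiles_path: str | None = None
    phenotypes_path: str | None = None
    expression_path: str | None = None
    cohort: CohortSpec | None = None
    expression_spec: ExpressionSpec | None = None
    harmonization_method: str = "combat"
    covariate_columns: tuple[str, ...] = ("age", "sex", "tiv")
    covbat_var_explained: float = 0.95
    group_col: str = "dx"
    brainage: BrainAgeConfig = field(default_factory=BrainAgeConfig)
    fdr: float = 0.05
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        cfg = dict(cfg)
        seed = int(cfg.get("seed", 0))
        synth = cfg.get("synthetic", {}) or {}
        cohort = None
        if "cohort" in synth:
            cohort = CohortSpec(**{**synth["cohort"],
                                   "seed": synth["cohort"].get(
                                       "seed", seed + _STAGE_SEED_OFFSET["cohort"])})
        expr_spec = None
        if "expression" in synth:
            expr_spec = ExpressionSpec(**{**synth["expression"],
                                          "seed": synth["expression"].get(
                                              "seed", seed + _STAGE_SEED_OFFSET["expression"])})
        inputs = cfg.get("inputs", {}) or {}
        harm = cfg.get("harmonization", {}) or {}
        ba_cfg = cfg.get("brainage", {}) or {}
        ba = BrainAgeConfig(**{**ba_cfg, "seed": ba_cfg.get(
            "seed", seed + _STAGE_SEED_OFFSET["brainage"])})
        return cls(
            out_dir=cfg["out_dir"],
            seed=seed,
            profiles_path=inputs.get("profiles"),
            phenotypes_path=inputs.get("phenotypes"),
            expression_path=inputs.get("expression"),
            cohort=cohort,
            expression_spec=expr_spec,
            harmonization_method=harm.get("method", "combat"),
            covariate_columns=tuple(harm.get("covariates", ("age", "sex", "tiv"))),
            covbat_var_explained=float(harm.get("var_explained", 0.95)),
            group_col=cfg.get("pbsi", {}).get("group_col", "dx"),
            brainage=ba,
            fdr=float(cfg.get("fdr", 0.05)),
            alpha=float(cfg.get("alpha", 0.05)),
        )

    def validate(self) -> None:
        if self.cohort is None:
            for name in ("profiles_path", "phenotypes_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"either a synthetic cohort spec or {name} is required")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")
        if self.expression_spec is None and self.expression_path is not None:
            if not Path(self.expression_path).exists():
                raise FileNotFoundError(f"expression_path: {self.expression_path}")
        if self.harmonization_method not in ("combat", "covbat", "none"):
            raise ValueError(f"unknown harmonization method {self.harmonization_method!r}")
        self.brainage.validate()


def _log_stage(name: str, t0: float, **shapes) -> None:
    desc = " ".join(f"{k}={v}" for k, v in shapes.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0, desc)


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Run every stage; returns the report dict (also written to report.json)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # -- stage 1: inputs -----------------------------------------------------
    t0 = time.time()
    profiles_csv = out / "profiles.csv"
    phenotypes_csv = out / "phenotypes.csv"
    if config.cohort is not None and not (resume and profiles_csv.exists()):
        cohort = generate_cohort(config.cohort)
        write_profiles(cohort.profiles, profiles_csv)
        write_phenotypes(cohort.phenotypes, phenotypes_csv)
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in cohort.truth.items()}
        (out / "truth.json").write_text(json.dumps(truth))
    elif config.cohort is None:
        profiles_csv = Path(config.profiles_path)
        phenotypes_csv = Path(config.phenotypes_path)
    profiles = read_profiles(profiles_csv)
    phenotypes = read_phenotypes(phenotypes_csv)
    if profiles.subject_ids != phenotypes["subject_id"].astype(str).tolist():
        raise ValueError("profiles and phenotypes subject ids do not match")
    report["stages"]["inputs"] = {
        "n_subjects": profiles.n_subjects, "n_regions": profiles.n_regions,
    }
    _log_stage("inputs", t0, subjects=profiles.n_subjects, regions=profiles.n_regions)

    # -- stage 2: harmonization ---------------------------------------------
    t0 = time.time()
    harmonized_csv = out / "harmonized.csv"
    if config.harmonization_method == "none":
        harmonized = profiles
    else:
        cov = phenotypes[list(config.covariate_columns)].to_numpy(dtype=float)
        design = BatchDesign(batch_labels=phenotypes["site"].to_numpy(), covariates=cov)
        if config.harmonization_method == "combat":
            harmonized = combat(profiles, design).adjusted
        else:
            harmonized = covbat(profiles, design, config.covbat_var_explained).adjusted
    write_profiles(harmonized, harmonized_csv)
    report["stages"]["harmonization"] = {"method": config.harmonization_method}
    _log_stage("harmonization", t0, method=config.harmonization_method)

    # -- stage 3: similarity scores and contributions ------------------------
    t0 = time.time()
    groups = phenotypes[config.group_col].to_numpy()
    scores = group_pbsi(harmonized, groups)
    contrib = group_contributions(harmonized, groups)
    delta = delta_contribution_map(contrib, groups)

    scores_df = pd.DataFrame({"subject_id": harmonized.subject_ids,
                              "dx": groups, "pbsi": scores})
    write_table(scores_df, out / "pbsi_scores.csv")
    contrib_df = pd.DataFrame(contrib, columns=harmonized.region_labels)
    contrib_df.insert(0, "subject_id", harmonized.subject_ids)
    write_table(contrib_df, out / "contributions.csv")
    delta_df = pd.DataFrame({
        "region": harmonized.region_labels,
        "mean_asd": contrib[groups == "ASD"].mean(axis=0),
        "mean_nc": contrib[groups == "NC"].mean(axis=0),
        "delta": delta,
    })
    write_table(delta_df, out / "delta_contributions.csv")

    cov_age_sex = phenotypes[["age", "sex"]].to_numpy(dtype=float)
    group_test = compare_groups(scores, groups, cov_age_sex)
    rho_age, p_age = correlate_with_covariates(
        scores, phenotypes["age"].to_numpy(dtype=float))
    region_stats = regionwise_group_difference(
        contrib, groups, cov_age_sex, alpha=config.alpha,
        region_labels=harmonized.region_labels)
    write_table(region_stats, out / "regional_stats.csv")

    med = {g: float(np.median(scores[groups == g])) for g in ("ASD", "NC")}
    iqr = {g: float(np.subtract(*np.percentile(scores[groups == g], [75, 25])))
           for g in ("ASD", "NC")}
    report["stages"]["pbsi"] = {
        "median": med, "iqr": iqr,
        "group_test": {"test": group_test.test_name, "p": group_test.p_value},
        "age_correlation": {"rho": rho_age, "p": p_age},
        "n_significant_regions": int(region_stats["significant"].sum()),
    }
    _log_stage("pbsi", t0, n_significant=int(region_stats["significant"].sum()))

    # -- stage 4: brain age ---------------------------------------------------
    t0 = time.time()
    nc_mask = groups == "NC"
    asd_mask = groups == "ASD"
    ages = phenotypes["age"].to_numpy(dtype=float)
    perf, nc_res, asd_res = cross_validated_brainage(
        contrib[nc_mask], ages[nc_mask], config.brainage,
        asd_X=contrib[asd_mask], asd_age=ages[asd_mask])
    split = split_ded_prd(asd_res, config.brainage.split_sd_factor)
    ba_df = pd.DataFrame({
        "subject_id": np.asarray(harmonized.subject_ids)[asd_mask],
        "brain_age": split.brain_age,
        "age": split.age,
        "gap": split.gap,
        "dev_label": split.dev_label,
    })
    write_table(ba_df, out / "brainage.csv")
    cognition = {}
    if np.sum(split.dev_label == "DED") >= 3 and np.sum(split.dev_label == "PRD") >= 3:
        cog = compare_ded_prd_cognition(split, phenotypes.loc[asd_mask].reset_index(drop=True))
        cognition = {k: {"test": v.test_name, "p": v.p_value} for k, v in cog.items()}
    report["stages"]["brainage"] = {
        "model": config.brainage.model,
        "performance": perf.summary(),
        "n_ded": int(np.sum(split.dev_label == "DED")),
        "n_prd": int(np.sum(split.dev_label == "PRD")),
        "cognition": cognition,
    }
    _log_stage("brainage", t0, model=config.brainage.model)

    # -- stage 5: expression association --------------------------------------
    if config.expression_spec is not None or config.expression_path is not None:
        t0 = time.time()
        delta_series = pd.Series(delta, index=harmonized.region_labels)
        if config.expression_spec is not None:
            expr, planted = generate_expression(config.expression_spec, delta_series)
            write_expression(expr, out / "expression.csv")
            (out / "planted_genes.json").write_text(json.dumps(planted))
        else:
            expr = read_expression(config.expression_path)
        assoc = associate_delta_expression(delta_series, expr, fdr=config.fdr)
        write_table(assoc.table, out / "genes.csv")
        report["stages"]["association"] = {
            "n_genes": int(len(assoc.table)),
            "n_significant": int(assoc.table["significant"].sum()),
            "fdr": config.fdr,
        }
        _log_stage("association", t0,
                   n_significant=int(assoc.table["significant"].sum()))

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
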