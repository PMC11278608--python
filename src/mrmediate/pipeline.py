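"""Two-stage orchestration: univariable/bidirectional MR + MVMR (stage 1)
and two-step mediator screening (stage 2), driven by a YAML run config."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import estimators, mediation, mvmr, sensitivity, summary_data
from .estimators import MREstimate
from .exceptions import ConfigurationError, MRMediateError
from .summary_data import SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class TraitSource:
    path: str
    name: str
    trait_type: str = "continuous"
    dialect: dict = field(default_factory=dict)
    category: str = ""

    def load(self) -> SummaryStats:
        return summary_data.read_summary_stats(
            self.path, trait_name=self.name, trait_type=self.trait_type, dialect=self.dialect
        )


@dataclass
class RunConfig:
    """Validated run configuration for both pipeline stages."""

    exposure: TraitSource
    outcome: TraitSource
    mediators: list[TraitSource] = field(default_factory=list)
    covariates: list[TraitSource] = field(default_factory=list)
    ld_path: Optional[str] = None
    instrument_p: float = summary_data.GENOME_WIDE_P
    clump_r2: float = summary_data.DEFAULT_CLUMP_R2
    clump_window_kb: float = summary_data.DEFAULT_CLUMP_WINDOW_KB
    outcome_p_exclude: float = summary_data.GENOME_WIDE_P
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int = 0
    out_dir: str = "mr_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        def source(d: dict) -> TraitSource:
            d = dict(d)
            d["path"] = str((base / d["path"]).resolve()) if not Path(d["path"]).is_absolute() else d["path"]
            return TraitSource(**d)

        try:
            thresholds = raw.get("thresholds", {})
            options = raw.get("options", {})
            ld = raw.get("ld")
            cfg = cls(
                exposure=source(raw["exposure"]),
                outcome=source(raw["outcome"]),
                mediators=[source(m) for m in raw.get("mediators", [])],
                covariates=[source(c) for c in raw.get("covariates", [])],
                ld_path=str((base / ld).resolve()) if ld and not Path(ld).is_absolute() else ld,
                instrument_p=float(thresholds.get("instrument_p", summary_data.GENOME_WIDE_P)),
                clump_r2=float(thresholds.get("clump_r2", summary_data.DEFAULT_CLUMP_R2)),
                clump_window_kb=float(
                    thresholds.get("clump_window_kb", summary_data.DEFAULT_CLUMP_WINDOW_KB)
                ),
                outcome_p_exclude=float(
                    thresholds.get("outcome_p_exclude", summary_data.GENOME_WIDE_P)
                ),
                n_boot=int(options.get("n_boot", 1000)),
                presso_n_sim=int(options.get("presso_n_sim", 1000)),
                seed=int(options["seed"]) if "seed" in options else 0,
                out_dir=str(raw.get("out_dir", "mr_out")),
            )
        except KeyError as exc:
            raise ConfigurationError(f"missing config key: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for src in [self.exposure, self.outcome, *self.mediators, *self.covariates]:
            if not Path(src.path).exists():
                raise ConfigurationError(f"input path does not exist: {src.path}")
        if self.ld_path and not Path(self.ld_path).exists():
            raise ConfigurationError(f"LD matrix path does not exist: {self.ld_path}")

    def load_ld(self) -> Optional[pd.DataFrame]:
        return summary_data.read_ld_matrix(self.ld_path) if self.ld_path else None

    def screen_config(self, ld=None) -> mediation.ScreenConfig:
        return mediation.ScreenConfig(
            p_threshold=self.instrument_p,
            outcome_p_exclude=self.outcome_p_exclude,
            ld=ld,
            clump_r2=self.clump_r2,
            clump_window_kb=self.clump_window_kb,
        )


@dataclass
class ReportBundle:
    """All tables produced by one stage, plus per-analysis error strings."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    audit: dict[str, dict] = field(default_factory=dict)
    total_effect: Optional[MREstimate] = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in sorted(self.tables.items()):
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
        if self.errors or self.audit:
            meta = {"errors": self.errors, "audit": self.audit}
            (out / "run_log.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def _univariable(
    exposure: SummaryStats, outcome: SummaryStats, cfg: RunConfig, ld, seed: int
):
    """select -> clump -> harmonize -> five estimators; returns (harmonized, estimates)."""
    inst = summary_data.select_instruments(exposure, cfg.instrument_p)
    if ld is not None:
        inst = summary_data.clump(inst, ld, cfg.clump_r2, cfg.clump_window_kb)
    h = summary_data.harmonize(inst, outcome, cfg.outcome_p_exclude)
    ests = estimators.all_estimators(h, n_boot=cfg.n_boot, seed=seed)
    return h, ests


def run_stage1(cfg: RunConfig) -> ReportBundle:
    """Forward and reverse univariable MR, sensitivity battery, optional MVMR.

    Each sub-analysis failure is recorded in ``bundle.errors`` without
    aborting the rest of the bundle.
    """
    bundle = ReportBundle()
    exposure = cfg.exposure.load()
    outcome = cfg.outcome.load()
    ld = cfg.load_ld()

    try:
        h_fwd, ests = _univariable(exposure, outcome, cfg, ld, cfg.seed)
        bundle.tables["forward_estimates"] = estimators.estimates_to_frame(ests)
        bundle.audit["forward_harmonization"] = dict(h_fwd.audit)
        bundle.total_effect = next(e for e in ests if e.method == "ivw")
        rep = sensitivity.run_sensitivity(h_fwd, n_sim=cfg.presso_n_sim, seed=cfg.seed)
        for name, df in rep.to_blocks().items():
            bundle.tables[f"forward_{name}"] = df
    except MRMediateError as exc:
        bundle.errors["forward"] = str(exc)
        logger.error("forward MR failed: %s", exc)

    try:
        h_rev, ests_rev = _univariable(outcome, exposure, cfg, ld, cfg.seed + 1)
        bundle.tables["reverse_estimates"] = estimators.estimates_to_frame(ests_rev)
        bundle.audit["reverse_harmonization"] = dict(h_rev.audit)
    except MRMediateError as exc:
        bundle.errors["reverse"] = str(exc)
        logger.error("reverse MR failed: %s", exc)

    if cfg.covariates:
        try:
            covs = [c.load() for c in cfg.covariates]
            mset = mvmr.build_mvmr_set(
                [exposure, *covs],
                outcome,
                ld=ld,
                p_threshold=cfg.instrument_p,
                r2_threshold=cfg.clump_r2,
                window_kb=cfg.clump_window_kb,
                outcome_p_exclude=cfg.outcome_p_exclude,
            )
            bundle.tables["mvmr_estimates"] = mvmr.mvmr_to_frame(mset, mvmr.mvmr_ivw(mset))
            bundle.audit["mvmr_harmonization"] = dict(mset.audit)
        except MRMediateError as exc:
            bundle.errors["mvmr"] = str(exc)
            logger.error("MVMR failed: %s", exc)
    return bundle


def run_stage2(cfg: RunConfig, total: Optional[MREstimate] = None) -> ReportBundle:
    """Two-step mediator screen plus the joined mediation table.

    ``total`` is the stage-1 forward IVW estimate; when omitted it is
    recomputed here from the configured exposure and outcome.
    """
    bundle = ReportBundle()
    exposure = cfg.exposure.load()
    outcome = cfg.outcome.load()
    ld = cfg.load_ld()
    panel = [m.load() for m in cfg.mediators]
    categories = {m.name: m.category for m in cfg.mediators}

    if total is None:
        h_fwd, _ = _univariable(exposure, outcome, cfg, ld, cfg.seed)
        total = estimators.ivw(h_fwd)
    bundle.total_effect = total

    if not panel:
        logger.warning("empty mediator panel; emitting empty tables")
        bundle.tables["mediation_headline"] = mediation.mediation_to_frame([], True)
        bundle.tables["mediation_full"] = mediation.mediation_to_frame([])
        return bundle

    scfg = cfg.screen_config(ld)
    step1 = mediation.screen_step1(exposure, panel, scfg)
    step2 = mediation.screen_step2(panel, outcome, scfg)
    results = mediation.run_mediation(total, step1, step2)
    bundle.tables["mediation_full"] = mediation.mediation_to_frame(results, categories=categories)
    bundle.tables["mediation_headline"] = mediation.mediation_to_frame(
        results, headline_only=True, categories=categories
    )
    bundle.audit["step_failures"] = {
        r.mediator_name: r.error for r in [*step1, *step2] if r.error
    }
    return bundle
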