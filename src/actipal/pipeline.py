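"""End-to-end pipeline: simulate -> wear filter -> energy/PAL -> validation.

``run_pipeline`` composes the stages over a synthetic cohort: minute
streams are imputed and wear-filtered, the energy stack is predicted per
participant, the chosen PAL correction is applied, and the validation
report (prediction errors, correlations, fitted correction equations,
paired t tests) is produced per sex. Every exclusion is logged with the
rule that triggered it, and all randomness flows from the single
configured seed.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .energy import participant_energy
from .exceptions import InputError, ParseError
from .params import (
    EnergyParams,
    IntensityCutoffs,
    MEN_CORRECTION,
    NagayoshiModel,
    WOMEN_CORRECTION,
    WearRules,
)
from .synthetic import CohortSpec, SyntheticParticipant, gen_cohort
from .validation import validation_report
from .wear import day_summaries, impute_nonwear, select_valid

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "predict_cohort"]

logger = logging.getLogger("actipal")

CORRECTION_MODES = ("none", "nagayoshi", "regression")


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level configuration of the end-to-end run."""

    seed: int = 0
    correction: str = "regression"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    wear_rules: WearRules = field(default_factory=WearRules)
    energy: EnergyParams = field(default_factory=EnergyParams)
    nagayoshi: NagayoshiModel = field(default_factory=NagayoshiModel)
    intensity: IntensityCutoffs = field(default_factory=IntensityCutoffs)

    def __post_init__(self):
        if self.correction not in CORRECTION_MODES:
            raise InputError(f"correction must be one of {CORRECTION_MODES}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(raw)
        for name, sub in [
            ("cohort", CohortSpec),
            ("wear_rules", WearRules),
            ("energy", EnergyParams),
            ("nagayoshi", NagayoshiModel),
            ("intensity", IntensityCutoffs),
        ]:
            if name in kwargs and isinstance(kwargs[name], dict):
                sub_kwargs = dict(kwargs[name])
                sub_known = {f.name for f in dataclasses.fields(sub)}
                sub_unknown = set(sub_kwargs) - sub_known
                if sub_unknown:
                    raise ParseError(
                        f"unknown key(s) in {name}: {sorted(sub_unknown)}"
                    )
                if sub is CohortSpec:
                    from .synthetic import AnthroDistribution

                    for grp in ("women", "men"):
                        if isinstance(sub_kwargs.get(grp), dict):
                            sub_kwargs[grp] = AnthroDistribution(**sub_kwargs[grp])
                kwargs[name] = sub(**sub_kwargs)
        cfg = cls(**kwargs)
        # the top-level seed drives the cohort generator
        object.__setattr__(cfg, "cohort", dataclasses.replace(cfg.cohort, seed=cfg.seed))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ParseError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(raw)


@dataclass
class PipelineResult:
    """Participant-level predictions, the validation report, and exclusions."""

    results: pd.DataFrame
    report: dict
    exclusions: list[dict]
    day_tables: dict[str, pd.DataFrame]


def predict_cohort(
    participants: list[SyntheticParticipant], config: PipelineConfig
) -> PipelineResult:
    """Wear-filter and energy-predict every participant; validate per sex."""
    fixtures = {"F": WOMEN_CORRECTION, "M": MEN_CORRECTION}
    rows, exclusions, day_tables = [], [], {}
    for p in participants:
        minutes = impute_nonwear(p.minutes, config.wear_rules)
        days = day_summaries(minutes, config.wear_rules, config.intensity)
        valid_days, retained = select_valid(days, config.wear_rules)
        day_tables[p.pid] = days
        if not retained:
            exclusions.append(
                {
                    "id": p.pid,
                    "rule": f"<{config.wear_rules.min_valid_days} valid days "
                    f"(wear >= {config.wear_rules.valid_day_min} min)",
                    "valid_days": int(len(valid_days)),
                }
            )
            logger.info("excluded %s: %d valid days", p.pid, len(valid_days))
            continue
        correction = (
            fixtures[p.anthropometry.sex] if config.correction == "regression" else None
        )
        pred = participant_energy(
            minutes,
            p.anthropometry,
            rules=config.wear_rules,
            energy_params=config.energy,
            nagayoshi=config.nagayoshi,
            correction=correction,
        )
        rows.append(
            {
                "id": p.pid,
                "sex": p.anthropometry.sex,
                "age_y": p.anthropometry.age_y,
                "stature_cm": p.anthropometry.stature_cm,
                "weight_kg": p.anthropometry.weight_kg,
                "bmr_pred": pred.bmr_pred,
                "bmr_meas": p.measured.bmr_kcal_d,
                "aee_pred": pred.aee_pred,
                "tee_pred": pred.tee_pred,
                "tee_meas": p.measured.tee_kcal_d,
                "pal_pred": pred.pal_pred,
                "pal_meas": p.measured.pal,
                "pal_nagayoshi": pred.pal_nagayoshi,
                "tee_nagayoshi": pred.tee_nagayoshi,
                "pal_corrected_fixture": pred.pal_corrected,
                "tee_corrected_fixture": pred.tee_corrected,
            }
        )
    results = pd.DataFrame(rows)
    if len(results) == 0:
        report = {"n_total": 0, "per_sex": {}, "note": "all participants excluded"}
    else:
        report = validation_report(results)
    report["exclusions"] = exclusions
    logger.info(
        "pipeline: %d participants retained, %d excluded",
        len(results),
        len(exclusions),
    )
    return PipelineResult(results=results, report=report, exclusions=exclusions, day_tables=day_tables)


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Simulate a cohort under ``config`` and run the full prediction/validation."""
    config = config or PipelineConfig()
    spec = dataclasses.replace(config.cohort, seed=config.seed)
    participants = gen_cohort(spec)
    logger.info("simulated cohort of %d participants (seed %d)", len(participants), config.seed)
    return predict_cohort(participants, config)
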