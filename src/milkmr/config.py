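"""YAML configuration for the pipeline: cohort, instrument, scan and MR blocks."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .exceptions import ValidationError
from .instrument import InstrumentWeight
from .phewas_scan import DEFAULT_COVARIATES, ScanConfig
from .synthetic_biobank import CohortConfig, OutcomeSpec


@dataclass(frozen=True)
class MrConfig:
    unit_g: float = 50.0
    method: str = "first_order"

    def __post_init__(self) -> None:
        if self.unit_g <= 0:
            raise ValidationError(f"MR unit must be positive, got {self.unit_g}")
        if self.method not in ("first_order", "second_order"):
            raise ValidationError(f"unknown delta-method order {self.method!r}")


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig
    instrument: InstrumentWeight
    scan: ScanConfig
    mr: MrConfig
    raw: dict

    def with_overrides(
        self,
        seed: Optional[int] = None,
        min_cases: Optional[int] = None,
        include_bmi: Optional[bool] = None,
        fdr_level: Optional[float] = None,
    ) -> "PipelineConfig":
        from dataclasses import replace

        cohort = self.cohort if seed is None else replace(self.cohort, seed=int(seed))
        scan = self.scan
        if min_cases is not None:
            scan = replace(scan, min_cases=int(min_cases))
        if include_bmi is not None:
            scan = replace(scan, include_bmi=bool(include_bmi))
        if fdr_level is not None:
            scan = replace(scan, fdr_level=float(fdr_level))
        return PipelineConfig(cohort=cohort, instrument=self.instrument, scan=scan, mr=self.mr, raw=self.raw)


def _outcome_from_dict(d: dict) -> OutcomeSpec:
    try:
        return OutcomeSpec(
            phecode=str(d["phecode"]),
            baseline_prevalence=float(d["baseline_prevalence"]),
            log_or_per_50g=float(d.get("log_or_per_50g", 0.0)),
            covariate_log_ors={str(k): float(v) for k, v in (d.get("covariate_log_ors") or {}).items()},
            icd_codes=tuple((str(c), str(v)) for c, v in d.get("icd_codes", ())),
        )
    except KeyError as exc:
        raise ValidationError(f"outcome block is missing field {exc}") from exc


def load_config(path) -> PipelineConfig:
    """Parse a pipeline YAML file into validated configuration objects."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} is not a YAML mapping")

    c = dict(raw.get("cohort") or {})
    outcomes = tuple(_outcome_from_dict(o) for o in c.pop("outcomes", []))
    try:
        cohort = CohortConfig(outcome_specs=outcomes, **c)
    except TypeError as exc:
        raise ValidationError(f"bad cohort block: {exc}") from exc

    i = dict(raw.get("instrument") or {})
    instrument = InstrumentWeight(
        snp_id=str(i.get("snp", "rs4988235")),
        effect_allele=str(i.get("effect_allele", "T")),
        other_allele=str(i.get("other_allele", "C")),
        per_allele_effect=float(i.get("per_allele_effect_g", 17.1)),
        ci_low=float(i.get("ci_low", 10.6)),
        ci_high=float(i.get("ci_high", 23.6)),
    )

    s = dict(raw.get("scan") or {})
    scan = ScanConfig(
        covariates=tuple(s.get("covariates", DEFAULT_COVARIATES)),
        include_bmi=bool(s.get("include_bmi", True)),
        min_cases=int(s.get("min_cases", 200)),
        fdr_level=float(s.get("fdr_level", 0.05)),
        bmi_cut=float(s.get("bmi_cut", 25.0)),
    )

    m = dict(raw.get("mr") or {})
    mr = MrConfig(unit_g=float(m.get("unit_g", 50.0)), method=str(m.get("method", "first_order")))
    return PipelineConfig(cohort=cohort, instrument=instrument, scan=scan, mr=mr, raw=raw)
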