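"""Map ICD-9/ICD-10 diagnosis records to phecode case/control phenotypes.

Phecodes group raw ICD diagnosis codes into clinically meaningful
phenotypes.  A person is a case for a phecode if at least one of their
diagnosis records maps to it.  A phecode may carry an exclusion range: a
non-case who is a case of another phecode inside that range is removed
from the control pool (status "excluded") rather than counted as a
control, which keeps controls free of closely related disease.  Scans are
restricted to phenotypes with a minimum number of cases (200 by default).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "CASE",
    "CONTROL",
    "EXCLUDED",
    "VOCABULARIES",
    "normalize_icd",
    "PhecodeMap",
    "load_phecode_map",
    "map_records",
    "PhenotypeMatrix",
    "build_phenotype_matrix",
    "filter_min_cases",
]

logger = logging.getLogger(__name__)

CASE: int = 1
CONTROL: int = 0
EXCLUDED: int = -1

VOCABULARIES = frozenset({"ICD9", "ICD10"})

_PHECODE_RE = re.compile(r"^\d{1,4}(\.\d{1,2})?$")

_MAP_COLUMNS = ["icd_code", "vocabulary", "phecode", "label", "category"]
_OPTIONAL_COLUMNS = ["exclude_low", "exclude_high", "sex"]


def normalize_icd(code: str, vocabulary: str) -> str:
    """Canonical ICD code: uppercase, dot removed, whitespace stripped."""
    if vocabulary not in VOCABULARIES:
        raise ValidationError(f"unknown vocabulary {vocabulary!r}; expected one of {sorted(VOCABULARIES)}")
    if code is None:
        raise ValidationError("ICD code is missing")
    canon = str(code).strip().upper().replace(".", "")
    if not canon:
        raise ValidationError("ICD code is empty or whitespace-only")
    return canon


def parse_phecode(phecode: str) -> float:
    """Numeric value of a dotted-decimal phecode string, for interval order only.

    Phecode identity is always compared on the string form; the parsed
    value is used solely to decide membership in exclusion ranges.
    """
    s = str(phecode).strip()
    if not _PHECODE_RE.match(s):
        raise ValidationError(f"malformed phecode {phecode!r}; expected dotted decimal like '250.2'")
    return float(s)


@dataclass(frozen=True)
class PhecodeMap:
    """Validated table linking (icd_code, vocabulary) pairs to phecodes.

    ``table`` has normalized ``icd_code``, ``vocabulary`` in {ICD9, ICD10},
    string ``phecode``, ``label``, ``category``, optional float
    ``exclude_low``/``exclude_high`` (a phecode interval whose cases are
    dropped from this phecode's controls) and optional ``sex``
    restriction ('F'/'M', empty = both).
    """

    table: pd.DataFrame

    @property
    def phecodes(self) -> list[str]:
        return sorted(self.table["phecode"].unique())

    def codes_for(self, phecode: str) -> pd.DataFrame:
        """Rows (icd_code, vocabulary) mapped to ``phecode``."""
        return self.table.loc[self.table["phecode"] == phecode, ["icd_code", "vocabulary"]]

    def phecode_info(self) -> pd.DataFrame:
        """One row per phecode: label, category, exclusion bounds, sex."""
        first = self.table.groupby("phecode", sort=True).first()
        return first[["label", "category", "exclude_low", "exclude_high", "sex"]]

    def __len__(self) -> int:
        return len(self.table)


def _validate_map_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phecode map is missing required columns: {missing}")
    if len(df) == 0:
        raise ValidationError("empty map: no data rows")
    df = df.copy()
    for col in _OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    bad_vocab = sorted(set(df["vocabulary"]) - VOCABULARIES)
    if bad_vocab:
        raise ValidationError(f"unknown vocabulary labels in map: {bad_vocab}")
    df["icd_code"] = [normalize_icd(c, v) for c, v in zip(df["icd_code"], df["vocabulary"])]
    df["phecode"] = df["phecode"].astype(str).str.strip()
    for ph in df["phecode"]:
        parse_phecode(ph)  # raises on malformed entries
    dup = df.duplicated(subset=["icd_code", "vocabulary"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["icd_code", "vocabulary"]].drop_duplicates().values.tolist()
        raise ValidationError(f"duplicate (icd_code, vocabulary) keys in map: {pairs}")
    for col in ("exclude_low", "exclude_high"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    has_range = df["exclude_low"].notna() | df["exclude_high"].notna()
    if (has_range & (df["exclude_low"].isna() | df["exclude_high"].isna())).any():
        raise ValidationError("exclusion ranges must specify both exclude_low and exclude_high")
    bad = has_range & (df["exclude_low"] > df["exclude_high"])
    if bad.any():
        raise ValidationError(
            f"inverted exclusion ranges for phecodes: {sorted(df.loc[bad, 'phecode'].unique())}"
        )
    df["sex"] = df["sex"].fillna("").astype(str).str.strip().str.upper()
    if not set(df["sex"]) <= {"", "F", "M"}:
        raise ValidationError("sex restriction must be 'F', 'M' or empty")
    return df.reset_index(drop=True)


def load_phecode_map(path) -> PhecodeMap:
    """Read and validate a phecode map CSV.

    Expected header: ``icd_code,vocabulary,phecode,label,category,
    exclude_low,exclude_high,sex`` (the last three optional).
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ValidationError(f"unreadable phecode map {path}: {exc}") from exc
    return PhecodeMap(_validate_map_frame(df))


def map_records(records: pd.DataFrame, pmap: PhecodeMap) -> pd.DataFrame:
    """Person-by-phecode case indicators from long-format diagnosis records.

    ``records`` needs columns ``person_id``, ``code``, ``vocabulary``.  A
    person is a case for a phecode iff at least one of their records maps
    to it, so the result is invariant to record duplication and order.
    Codes absent from the map are counted and logged, not fatal.
    """
    for col in ("person_id", "code", "vocabulary"):
        if col not in records.columns:
            raise ValidationError(f"records table is missing column {col!r}")
    if len(records) == 0:
        return pd.DataFrame(index=pd.Index([], name="person_id"), columns=pmap.phecodes, dtype=bool)
    bad_vocab = sorted(set(records["vocabulary"]) - VOCABULARIES)
    if bad_vocab:
        raise ValidationError(f"unknown vocabulary labels in records: {bad_vocab}")
    rec = records[["person_id", "code", "vocabulary"]].copy()
    rec["code"] = [normalize_icd(c, v) for c, v in zip(rec["code"], rec["vocabulary"])]
    rec = rec.drop_duplicates()
    merged = rec.merge(
        pmap.table[["icd_code", "vocabulary", "phecode"]],
        left_on=["code", "vocabulary"],
        right_on=["icd_code", "vocabulary"],
        how="left",
    )
    n_unmapped = int(merged["phecode"].isna().sum())
    if n_unmapped:
        logger.info("map_records: %d record(s) with ICD codes absent from the map were skipped", n_unmapped)
    hits = merged.dropna(subset=["phecode"])
    indicators = (
        hits.assign(flag=True)
        .pivot_table(index="person_id", columns="phecode", values="flag", aggfunc="any", fill_value=False)
        .astype(bool)
    )
    indicators = indicators.reindex(columns=pmap.phecodes, fill_value=False)
    indicators.index.name = "person_id"
    indicators.columns.name = None
    return indicators.sort_index()


@dataclass(frozen=True)
class PhenotypeMatrix:
    """Person-by-phecode status matrix with per-phecode metadata.

    ``status`` holds CASE (1), CONTROL (0) or EXCLUDED (-1) per person and
    phecode; ``meta`` is indexed by phecode with ``label``, ``category``,
    ``n_case``, ``n_control``, ``n_excluded``.
    """

    status: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        counts = _tally(self.status)
        for col in ("n_case", "n_control", "n_excluded"):
            if not (self.meta[col] == counts[col]).all():
                raise ValidationError("phenotype metadata counts disagree with the status matrix")

    @property
    def n_individuals(self) -> int:
        return len(self.status)

    @property
    def phecodes(self) -> list[str]:
        return list(self.status.columns)

    def subset(self, person_ids) -> "PhenotypeMatrix":
        """Restrict to a sub-population, recomputing the counts."""
        status = self.status.loc[person_ids]
        meta = self.meta.copy()
        counts = _tally(status)
        meta[["n_case", "n_control", "n_excluded"]] = counts
        return PhenotypeMatrix(status=status, meta=meta)


def _tally(status: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "n_case": (status == CASE).sum(),
            "n_control": (status == CONTROL).sum(),
            "n_excluded": (status == EXCLUDED).sum(),
        }
    )


def build_phenotype_matrix(
    case_indicators: pd.DataFrame,
    pmap: PhecodeMap,
    population_ids: Sequence,
    sex: pd.Series | None = None,
) -> PhenotypeMatrix:
    """Assemble case/control/excluded statuses over the whole population.

    Every phecode in the map becomes a column.  Cases come from
    ``case_indicators`` (output of :func:`map_records`); persons who are
    not cases of a phecode but are cases of another phecode inside its
    exclusion range are marked EXCLUDED; everyone else is a control.  If a
    phecode's declared range does not cover the phecode itself, the range
    is widened to include it (with a warning).  ``sex`` (values 'F'/'M')
    enables sex-restricted phecodes: persons of the other sex are excluded.
    """
    population = pd.Index(population_ids, name="person_id")
    if population.has_duplicates:
        raise ValidationError("population ids contain duplicates")
    extra = case_indicators.index.difference(population)
    if len(extra):
        raise ValidationError(
            f"{len(extra)} person(s) in the case indicators are absent from the population"
        )
    info = pmap.phecode_info()
    phecodes = list(info.index)
    cases = case_indicators.reindex(index=population, columns=phecodes, fill_value=False).astype(bool)

    status = pd.DataFrame(CONTROL, index=population, columns=phecodes, dtype=np.int8)
    values = {ph: parse_phecode(ph) for ph in phecodes}
    case_arr = cases.to_numpy()

    for j, ph in enumerate(phecodes):
        lo, hi = info.loc[ph, "exclude_low"], info.loc[ph, "exclude_high"]
        excl = np.zeros(len(population), dtype=bool)
        if pd.notna(lo):
            if not (lo <= values[ph] <= hi):
                warnings.warn(
                    f"exclusion range ({lo}, {hi}) of phecode {ph} does not cover the "
                    "phecode itself; range auto-extended",
                    stacklevel=2,
                )
                lo, hi = min(lo, values[ph]), max(hi, values[ph])
            neighbours = [k for k, q in enumerate(phecodes) if k != j and lo <= values[q] <= hi]
            if neighbours:
                excl = case_arr[:, neighbours].any(axis=1)
        restriction = info.loc[ph, "sex"]
        if restriction and sex is not None:
            excl |= (sex.reindex(population).astype(str).str.upper() != restriction).to_numpy()
        col = status[ph].to_numpy()
        col[excl & ~case_arr[:, j]] = EXCLUDED
        col[case_arr[:, j]] = CASE
        status[ph] = col

    meta = info[["label", "category"]].copy()
    counts = _tally(status)
    meta[["n_case", "n_control", "n_excluded"]] = counts
    return PhenotypeMatrix(status=status, meta=meta)


def filter_min_cases(matrix: PhenotypeMatrix, threshold: int = 200) -> PhenotypeMatrix:
    """Drop phecodes with fewer than ``threshold`` cases (inclusive boundary).

    A phecode with exactly ``threshold`` cases is retained; the dropped
    phecodes are logged.
    """
    if threshold < 1:
        raise ValidationError(f"minimum case threshold must be >= 1, got {threshold}")
    keep = matrix.meta.index[matrix.meta["n_case"] >= threshold]
    dropped = sorted(set(matrix.meta.index) - set(keep))
    if dropped:
        logger.info(
            "filter_min_cases: dropped %d phecode(s) with < %d cases: %s",
            len(dropped), threshold, dropped,
        )
    return PhenotypeMatrix(status=matrix.status[list(keep)], meta=matrix.meta.loc[keep])
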