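"""Publication-style tables, Manhattan-plot data and the run manifest.

Display rounding follows the conventions of epidemiological association
tables: odds ratios and confidence limits to 2 decimals (half away from
zero), betas and standard errors to 3 decimals, p-values in scientific
notation with 3 significant digits.  Full-precision values always remain
available in the result TSVs; rounding happens only here.
"""

from __future__ import annotations

import datetime as _dt
import decimal
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .phewas_scan import bh_fdr

__all__ = [
    "round_half_away",
    "or_ci_string",
    "format_assoc_table",
    "manhattan_data",
    "RunManifest",
]

logger = logging.getLogger(__name__)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (0.845 -> 0.85, -0.845 -> -0.85)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def or_ci_string(or_: float, ci_low: float, ci_high: float, dash: str = "-") -> str:
    """Cell like ``0.89 (0.84-0.94)`` (en-dash available via ``dash``)."""
    return (
        f"{round_half_away(or_, 2):.2f} "
        f"({round_half_away(ci_low, 2):.2f}{dash}{round_half_away(ci_high, 2):.2f})"
    )


def _format_block(df: pd.DataFrame, dash: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "beta": [f"{round_half_away(b, 3):.3f}" if np.isfinite(b) else "NA" for b in df["beta"]],
            "se": [f"{round_half_away(s, 3):.3f}" if np.isfinite(s) else "NA" for s in df["se"]],
            "or_ci": [
                or_ci_string(o, lo, hi, dash) if np.isfinite(o) else "NA"
                for o, lo, hi in zip(df["or"], df["ci_low"], df["ci_high"])
            ],
            "p": [f"{p:.2E}" if np.isfinite(p) else "NA" for p in df["p"]],
        },
        index=df.index,
    )


def format_assoc_table(
    results: pd.DataFrame,
    style: str = "bmi_adjusted",
    results_no_bmi: Optional[pd.DataFrame] = None,
    dash: str = "-",
) -> str:
    """Association table text, sorted by p ascending (phecode as tiebreak).

    ``style='both'`` places the BMI-adjusted and BMI-unadjusted estimates
    side by side, matched on phecode.
    """
    if style not in ("bmi_adjusted", "both"):
        raise ValidationError(f"unknown table style {style!r}")
    if len(results) == 0:
        raise ValidationError("no results to format")
    if style == "both" and results_no_bmi is None:
        raise ValidationError("style 'both' needs the BMI-unadjusted results")
    df = results.sort_values(["p", "phecode"], kind="mergesort").reset_index(drop=True)
    main = _format_block(df, dash)
    header = ["phecode", "phenotype", "cases", "controls", "beta", "se", "or_95ci", "p"]
    cols = [
        df["phecode"], df["label"], df["n_case"].astype(str), df["n_control"].astype(str),
        main["beta"], main["se"], main["or_ci"], main["p"],
    ]
    if style == "both":
        other = results_no_bmi.set_index("phecode").reindex(df["phecode"]).reset_index()
        blk = _format_block(other, dash)
        header += ["beta_no_bmi", "se_no_bmi", "or_95ci_no_bmi", "p_no_bmi"]
        cols += [blk["beta"], blk["se"], blk["or_ci"], blk["p"]]
    lines = ["\t".join(header)]
    for i in range(len(df)):
        lines.append("\t".join(str(c.iloc[i]) for c in cols))
    return "\n".join(lines) + "\n"


def manhattan_data(results: pd.DataFrame, fdr_level: float = 0.05) -> pd.DataFrame:
    """Plot-ready scan data: phecode, category, -log10 p, significance flag.

    The significance flag equals the BH decision at ``fdr_level``
    recomputed from the scan's p-values.  Zero p-values (numeric
    underflow) are clipped to the smallest positive double and logged.
    """
    df = results.dropna(subset=["p"]).copy()
    p = df["p"].to_numpy(dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    n_zero = int((p == 0).sum())
    if n_zero:
        logger.warning("manhattan_data: clipped %d zero p-value(s) to the smallest positive double", n_zero)
        p = np.where(p == 0, np.nextafter(0.0, 1.0), p)
    q = bh_fdr(p)
    out = pd.DataFrame(
        {
            "phecode": df["phecode"].to_numpy(),
            "category": df["category"].to_numpy(),
            "neg_log10_p": -np.log10(p),
            "significant": q <= fdr_level,
        }
    )
    return out.sort_values(["category", "phecode"], kind="mergesort").reset_index(drop=True)


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    seed: Optional[int]
    stage: str
    version: str
    outputs: dict = field(default_factory=dict)  # path -> row count
    inputs: list = field(default_factory=list)
    timestamp: str = ""

    def record(self, path, n_rows: int) -> None:
        self.outputs[str(path)] = int(n_rows)

    def write(self, path) -> Path:
        import json

        self.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat()
        for out in self.outputs:
            if not Path(out).exists():
                raise ValidationError(f"manifest lists missing output file {out}")
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
        return path
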