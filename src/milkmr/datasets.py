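"""Bundled miniature datasets.

The package ships a miniature phecode map (30 ICD-9/ICD-10 codes covering
10 phecodes, with exclusion ranges for the diabetes, lipid, retinal and
hypertensive groups) for simulation and testing, and a table of published
per-50 g/day beta/SE estimates for milk-consumption MR, used as worked
examples for the beta/SE -> OR/CI conversion.  The full phecode catalogue
(~1850 phenotypes) is not bundled; a user-supplied map in the same CSV
schema can be loaded with :func:`milkmr.phecode_engine.load_phecode_map`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .phecode_engine import PhecodeMap, load_phecode_map

__all__ = ["phecode_map_mini", "phecode_map_mini_path", "reference_estimates"]


def phecode_map_mini_path():
    """Filesystem path of the bundled miniature phecode map CSV."""
    return resources.files("milkmr.data") / "phecode_map_mini.csv"


def phecode_map_mini() -> PhecodeMap:
    """Load the bundled 30-code / 10-phecode miniature map."""
    with resources.as_file(phecode_map_mini_path()) as path:
        return load_phecode_map(path)


def reference_estimates() -> pd.DataFrame:
    """Published per-50 g/day milk-consumption estimates (beta, SE, OR, CI).

    Columns: outcome, analysis, source, n_case, n_control, beta, se,
    or_printed, ci_low_printed, ci_high_printed.  Betas are log-odds per
    50 g/day of genetically predicted milk intake as printed (3 decimals);
    the OR/CI columns are the 2-decimal values printed alongside them.
    """
    with resources.as_file(resources.files("milkmr.data") / "reference_estimates.tsv") as path:
        return pd.read_csv(path, sep="\t")
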