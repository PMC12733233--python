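"""Publication-style association report tables.

Renders the scan output in the layout of the study's tables: rows grouped by
genetic model, a reference row printed as "1.00", odds ratios and confidence
bounds rounded half-up to two decimals, zero-cell rows rendered "0.00 (0.00)"
with the interval omitted, and the unadjusted / FDR-adjusted p-values as a
"P/FDR P" pair.  Rendering only rounds; every number is traceable to an
estimate computed upstream.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

_MODEL_ORDER = ("codominant", "dominant", "recessive", "overdominant", "log_additive")


def round_half_up(x: float, digits: int = 2) -> str:
    """Decimal half-up rounding (1.005 -> '1.01'), as printed tables use."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if math.isinf(x):
        return "inf"
    q = Decimal(1).scaleb(-digits)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_or_ci(or_, ci_low, ci_high) -> str:
    o = round_half_up(or_)
    if ci_low is None or (isinstance(ci_low, float) and math.isnan(ci_low)):
        return f"{o} (0.00)" if o == "0.00" else o
    return f"{o} ({round_half_up(ci_low)}; {round_half_up(ci_high)})"


def _p_pair(p, p_fdr) -> str:
    def fmt(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return ""
        return f"{v:.4g}"
    return f"{fmt(p)}/{fmt(p_fdr)}"


def render_assoc_table(results: pd.DataFrame, layout: str = "within_case") -> pd.DataFrame:
    """Rows grouped by SNP/outcome/model with a reference row per block.

    ``layout`` selects which family of the scan output to render
    ('case_control' or 'within_case'); rendering an empty selection yields an
    empty frame.
    """
    if layout not in ("case_control", "within_case"):
        raise ValueError(f"unknown layout {layout!r}")
    sub = results[results["family"] == layout] if "family" in results else results
    rows = []
    if sub.empty:
        return pd.DataFrame(
            columns=["snp", "outcome", "model", "contrast",
                     "n_level0", "n_level1", "OR (95% CI)", "P/FDR P"]
        )
    order = {m: i for i, m in enumerate(_MODEL_ORDER)}
    sub = sub.sort_values(
        ["snp", "outcome", "model"],
        key=lambda s: s.map(order) if s.name == "model" else s,
        kind="stable",
    )
    for (snp, outcome, model), block in sub.groupby(
        ["snp", "outcome", "model"], sort=False
    ):
        first = block.iloc[0]
        rows.append({
            "snp": snp, "outcome": outcome, "model": model,
            "contrast": "reference",
            "n_level0": first.get("n_unexposed_0"),
            "n_level1": first.get("n_unexposed_1"),
            "OR (95% CI)": "1.00",
            "P/FDR P": _p_pair(first.get("p"), first.get("p_fdr")),
        })
        for _, r in block.iterrows():
            rows.append({
                "snp": snp, "outcome": outcome, "model": model,
                "contrast": r["contrast"],
                "n_level0": r.get("n_exposed_0"),
                "n_level1": r.get("n_exposed_1"),
                "OR (95% CI)": format_or_ci(r["or"], r.get("ci_low"), r.get("ci_high")),
                "P/FDR P": "",
            })
    return pd.DataFrame(rows)


def write_report(table: pd.DataFrame, path, sep: str = "\t") -> None:
    table.to_csv(path, sep=sep, index=False)
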