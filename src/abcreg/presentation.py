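"""Full-level regression output tables.

Every level of every categorical variable gets its own printed row:
under abundance-based constraints the abundance-weighted estimates in
each block sum to zero, and under reference-group encoding the
reference level is printed explicitly as "0 (reference)" instead of
being silently dropped.  Rounding is for display only; a full-precision
CSV is always available alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constraints import SCHEME_RGE
from .design import (
    ROLE_CONTINUOUS,
    ROLE_DUMMY,
    ROLE_INTERACTION,
    ROLE_INTERCEPT,
)
from .estimation import FittedModel

P_FLOOR = 0.001  # p-values below this print as "<0.001"


def _fmt_p(p: float) -> str:
    return f"<{P_FLOOR}" if p < P_FLOOR else f"{p:.3f}"


def _fmt_est(est: float, se: float, nd: int = 3) -> str:
    return f"{est:.{nd}f} ({se:.{nd}f})"


@dataclass
class OutputTable:
    """Display table plus the full-precision coefficient frame."""

    rows: pd.DataFrame  # display rows: variable, estimate_se, p_value
    full: pd.DataFrame  # full-precision CoefficientTable
    footnote: str

    def to_text(self) -> str:
        width = max(len(str(v)) for v in self.rows["variable"]) + 2
        lines = [f"{'Variable':<{width}}{'Estimate (SE)':<18}p-value"]
        for _, r in self.rows.iterrows():
            lines.append(
                f"{r['variable']:<{width}}{r['estimate_se']:<18}{r['p_value']}"
            )
        lines.append("")
        lines.append(self.footnote)
        return "\n".join(lines)

    def to_markdown(self) -> str:
        lines = ["| Variable | Estimate (SE) | p-value |", "|---|---|---|"]
        for _, r in self.rows.iterrows():
            lines.append(
                f"| {r['variable']} | {r['estimate_se']} | {r['p_value']} |"
            )
        lines.append("")
        lines.append(self.footnote)
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        """Full-precision export; re-parsing reproduces the table."""
        self.full.to_csv(path, index=False)


def format_coefficient_table(
    tab: pd.DataFrame, fit: FittedModel, pi_source: str = "sample", ndigits: int = 3
) -> OutputTable:
    """Render a coefficient table in grouped, all-levels layout.

    Row order: intercept; continuous main effects; one block per
    categorical variable with every level; one block per (continuous,
    categorical) modifier pair with every level.
    """
    spec = fit.dm.spec
    disp = []

    def add(sub: pd.DataFrame, label=None):
        for _, r in sub.iterrows():
            disp.append(
                {
                    "variable": label if label is not None else r["name"],
                    "estimate_se": _fmt_est(r["estimate"], r["se"], ndigits),
                    "p_value": _fmt_p(r["p"]),
                }
            )

    def header(text: str):
        disp.append({"variable": text, "estimate_se": "", "p_value": ""})

    add(tab[tab["role"] == ROLE_INTERCEPT], "Intercept")
    for var in spec.continuous:
        add(tab[(tab["role"] == ROLE_CONTINUOUS) & (tab["continuous"] == var)], var)
    for name, levels in spec.categoricals:
        header(name)
        for i, lev in enumerate(levels):
            sub = tab[
                (tab["role"] == ROLE_DUMMY)
                & (tab["categorical"] == name)
                & (tab["level"] == lev)
            ]
            if fit.scheme == SCHEME_RGE and i == 0:
                disp.append(
                    {
                        "variable": f"  {lev}",
                        "estimate_se": "0 (reference)",
                        "p_value": "",
                    }
                )
            else:
                add(sub, f"  {lev}")
    for name, levels in spec.categoricals:
        for var in spec.modified_continuous(name):
            header(f"{var} x {name}")
            for i, lev in enumerate(levels):
                sub = tab[
                    (tab["role"] == ROLE_INTERACTION)
                    & (tab["categorical"] == name)
                    & (tab["level"] == lev)
                    & (tab["continuous"] == var)
                ]
                if fit.scheme == SCHEME_RGE and i == 0:
                    disp.append(
                        {
                            "variable": f"  {var}:{lev}",
                            "estimate_se": "0 (reference)",
                            "p_value": "",
                        }
                    )
                else:
                    add(sub, f"  {var}:{lev}")

    footnote = (
        f"Scheme: {fit.scheme.upper()}; n = {fit.n}; "
        f"group proportions: {pi_source}."
    )
    return OutputTable(rows=pd.DataFrame(disp), full=tab, footnote=footnote)


def abc_block_weighted_sums(fit: FittedModel, dist) -> dict[str, float]:
    """Abundance-weighted sum of each categorical block's estimates
    (zero under ABCs, up to rounding)."""
    out = {}
    for name, levels in fit.dm.spec.categoricals:
        marg = dist.marginal(name)
        s = 0.0
        for lev in levels:
            j = fit.dm.column_index(ROLE_DUMMY, categorical=name, level=lev)
            s += marg[lev] * fit.theta_hat[j]
        out[name] = s
        for var in fit.dm.spec.modified_continuous(name):
            s = 0.0
            for lev in levels:
                j = fit.dm.column_index(
                    ROLE_INTERACTION, continuous=var, categorical=name, level=lev
                )
                s += marg[lev] * fit.theta_hat[j]
            out[f"{var}:{name}"] = s
    return out


def path_to_csv(path_obj, out) -> None:
    """Long-format lambda-path export: (lambda, column, coefficient) plus
    group-specific slopes for every modifier pair."""
    frames = [path_obj.coef_frame().assign(kind="coefficient", level="")]
    spec = path_obj.dm.spec
    for name, _ in spec.categoricals:
        for var in spec.modified_continuous(name):
            st = path_obj.slope_table(var, name)
            frames.append(
                pd.DataFrame(
                    {
                        "lambda": st["lambda"],
                        "column": f"{var}:{name}",
                        "coefficient": st["slope"],
                        "kind": "slope",
                        "level": st["level"],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
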