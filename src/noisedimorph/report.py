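"""Text rendering of test results.

This is the only layer that rounds fractions to two decimals or prints
an empirical p-value of zero as "<1/n_sim"; everything upstream keeps
full machine precision.
"""

from __future__ import annotations

import pandas as pd

from .dispersal import DispersalTestResult
from .signed_rank import SignedRankResult


def render_p(p: float, n_sim: int) -> str:
    """Empirical p-value as text; a zero count renders as '<1/n_sim'."""
    if p == 0.0:
        return f"<{1 / n_sim:.4f}".rstrip("0")
    return f"{p:.4f}"


def signed_rank_frame(
    results: list[SignedRankResult],
    n_replicates: dict[str, object] | None = None,
) -> pd.DataFrame:
    """Machine-precision result table (one row per strain/genotype/color)."""
    rows = []
    for r in results:
        rows.append(
            {
                "label": r.label,
                "n_replicates": (n_replicates or {}).get(r.label, ""),
                "n_datapairs": r.n_pairs,
                "observed_w": r.observed_w,
                "sim_w_p5": r.p5,
                "sim_w_p95": r.p95,
                "p_upper": r.p_upper,
                "p_lower": r.p_lower,
            }
        )
    return pd.DataFrame(rows)


def render_signed_rank(results: list[SignedRankResult]) -> str:
    lines = ["label\tn_datapairs\tobserved_w\tsim_w[5th/95th]\tp_upper/p_lower"]
    for r in results:
        lines.append(
            f"{r.label}\t{r.n_pairs}\t{r.observed_w:.6g}\t"
            f"{r.p5:.6g}/{r.p95:.6g}\t"
            f"{render_p(r.p_upper, r.n_sim)}/{render_p(r.p_lower, r.n_sim)}"
        )
    return "\n".join(lines)


def dispersal_frame(results: list[DispersalTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subset": r.subset,
                "n": r.n,
                "observed_fraction": r.observed_fraction,
                "sim_fraction_p5": r.p5,
                "sim_fraction_p95": r.p95,
                "p_upper": r.p_upper,
                "p_lower": r.p_lower,
            }
            for r in results
        ]
    )


def render_dispersal(results: list[DispersalTestResult]) -> str:
    lines = ["subset\tn\tobserved\tsim[5th-95th]\tp_upper/p_lower"]
    for r in results:
        lines.append(
            f"{r.subset}\t{r.n}\t{r.observed_fraction:.2f}\t"
            f"{r.p5:.2f}/{r.p95:.2f}\t"
            f"{render_p(r.p_upper, r.n_sim)}/{render_p(r.p_lower, r.n_sim)}"
        )
    return "\n".join(lines)
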