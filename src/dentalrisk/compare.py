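"""Side-by-side classical-vs-Bayesian comparison table.

For each coefficient slot the table lines up the MLE estimate, its standard
error and 95% Wald interval against the posterior mean, posterior SD and
95% HPD interval, together with interval lengths and their differences.
Whether the credible interval is shorter is reported as an observed count,
never asserted: with a vague prior the two intervals are near-identical and
the direction can flip by Monte-Carlo noise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from dentalrisk.glm import ClassicalResults

__all__ = ["ComparisonTable", "compare"]


@dataclasses.dataclass(frozen=True)
class ComparisonTable:
    """Aligned classical and Bayesian inference per coefficient slot."""

    table: pd.DataFrame
    n_hpd_shorter: int

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def compare(
    fit: ClassicalResults,
    posterior_summary: pd.DataFrame,
    level: float = 0.95,
) -> ComparisonTable:
    """Build the comparison table from one classical fit and one posterior
    summary (as returned by :func:`dentalrisk.bayes.summarize`).

    Raises if the two sides do not share the same coefficient slots in the
    same order.
    """
    slots = tuple(fit.params.index)
    post_slots = tuple(posterior_summary.index)
    if slots != post_slots:
        raise ValueError(
            f"slot mismatch: classical {slots} vs posterior {post_slots}"
        )
    ci = fit.conf_int(level)
    wald_length = (ci["upper"] - ci["lower"]).to_numpy()
    hpd_lower = posterior_summary["hpd_lower"].to_numpy()
    hpd_upper = posterior_summary["hpd_upper"].to_numpy()
    hpd_length = hpd_upper - hpd_lower
    table = pd.DataFrame(
        {
            "slot": slots,
            "mle_estimate": fit.params.to_numpy(),
            "mle_se": fit.bse.to_numpy(),
            "wald_lower": ci["lower"].to_numpy(),
            "wald_upper": ci["upper"].to_numpy(),
            "wald_length": wald_length,
            "post_mean": posterior_summary["mean"].to_numpy(),
            "post_sd": posterior_summary["sd"].to_numpy(),
            "hpd_lower": hpd_lower,
            "hpd_upper": hpd_upper,
            "hpd_length": hpd_length,
        }
    ).set_index("slot")
    table["length_diff"] = table["wald_length"] - table["hpd_length"]
    table["se_diff"] = table["mle_se"] - table["post_sd"]
    n_shorter = int(np.sum(table["hpd_length"] < table["wald_length"]))
    return ComparisonTable(table=table, n_hpd_shorter=n_shorter)
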