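"""Two-group differential-expression screening.

Genes are called differentially expressed when they pass both a fold-change
gate (|log2FC| >= 1 by default) and a significance gate (two-sided p < 0.05
on a two-sample t statistic; Benjamini-Hochberg q optional). The t statistic
is a plain pooled-variance two-sample t by default, with Welch's unequal
variance form available; a small variance floor guards genes with zero
within-group spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, ValidationError

DE_COLUMNS = ["log2fc", "t", "p", "q", "direction", "is_de"]


@dataclass
class DEParams:
    """Thresholds and test choice for differential-expression calls.

    p_threshold / lfc_threshold gate the calls; ``use_adjusted`` switches
    the significance gate from raw p to BH q. ``var_floor`` is the minimum
    admissible (pooled or per-group) variance, preventing infinite t for
    genes with zero within-group spread.
    """

    p_threshold: float = 0.05
    lfc_threshold: float = 1.0
    use_adjusted: bool = False
    test: str = "pooled_t"  # or "welch_t"
    var_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.lfc_threshold <= 0:
            raise ValidationError("thresholds must be positive")
        if self.test not in ("pooled_t", "welch_t"):
            raise ValidationError(f"unknown test {self.test!r}")


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p elementwise)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(m: ExpressionMatrix, params: DEParams | None = None) -> pd.DataFrame:
    """Per-gene two-group test; returns a DE table indexed by gene.

    Columns: ``log2fc`` (mean case − mean control), ``t``, ``p`` (two-sided),
    ``q`` (BH), ``direction`` in {up, down, none}, ``is_de``.
    """
    params = params or DEParams()
    ctrl = m.values[m.samples_in("control")].to_numpy(dtype=float)
    case = m.values[m.samples_in("case")].to_numpy(dtype=float)
    n1, n2 = ctrl.shape[1], case.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 samples")

    mu1, mu2 = ctrl.mean(axis=1), case.mean(axis=1)
    v1 = ctrl.var(axis=1, ddof=1)
    v2 = case.var(axis=1, ddof=1)
    log2fc = mu2 - mu1

    if params.test == "pooled_t":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        sp2 = np.maximum(sp2, params.var_floor)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = np.full_like(se, n1 + n2 - 2)
    else:  # welch_t
        v1f = np.maximum(v1, params.var_floor)
        v2f = np.maximum(v2, params.var_floor)
        a, b = v1f / n1, v2f / n2
        se = np.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))

    t = log2fc / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    q = bh_adjust(p)

    sig = q < params.p_threshold if params.use_adjusted else p < params.p_threshold
    is_de = sig & (np.abs(log2fc) >= params.lfc_threshold)
    direction = np.where(is_de, np.where(log2fc > 0, "up", "down"), "none")

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "q": q,
            "direction": direction,
            "is_de": is_de,
        },
        index=m.values.index,
    )


def de_sets(table: pd.DataFrame) -> dict[str, set[str]]:
    """Partition the DE calls into up- and down-regulated id sets."""
    de = table[table["is_de"]]
    return {
        "up": set(de.index[de["direction"] == "up"]),
        "down": set(de.index[de["direction"] == "down"]),
    }
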