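"""Two-group differential expression on FPKM matrices.

Fold changes follow the convention log2(FPKM_first / FPKM_second) over group
means with a pseudocount; the test is Welch's t on log2(FPKM + pseudocount),
a documented stand-in for assembler-native DE models, with Benjamini-
Hochberg FDR control and calls at q < alpha. Externally computed p-values
(e.g. from Cuffdiff) can be injected so real pipeline output is honoured.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import ExpressionMatrix

DEFAULT_PSEUDOCOUNT = 0.25
DEFAULT_ALPHA = 0.05


def log2_fold_change(mean_a: float, mean_b: float, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2((mean_a + pseudocount) / (mean_b + pseudocount)).

    ``mean_a`` is the numerator group (first-listed; YY in the original
    breed comparison).
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("FPKM means must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return float(np.log2((mean_a + pseudocount) / (mean_b + pseudocount)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    expr: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    external_pvalues: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Per-feature two-group differential expression.

    Returns a data frame indexed by feature id with columns ``mean_a``,
    ``mean_b`` (raw FPKM group means; group a = ``expr.groups[0]``),
    ``log2fc``, ``p``, ``q`` and ``call`` in {up, down, ns}. ``up`` means
    higher in group a. Features with identical values in every sample get
    p = 1. When ``external_pvalues`` is given those p-values replace the
    built-in test (features absent from the map fall back to it).
    """
    if len(expr.groups) != 2:
        raise ValueError(f"need exactly two groups, got {expr.groups}")
    ga, gb = expr.groups
    a = expr.group_values(ga).to_numpy(dtype=float)
    b = expr.group_values(gb).to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >=2 samples")

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance ties -> no signal

    if external_pvalues:
        p = np.array(
            [
                float(external_pvalues.get(fid, pi))
                for fid, pi in zip(expr.feature_ids, p)
            ]
        )
        if np.any((p < 0) | (p > 1)):
            raise ValueError("external p-values must lie in [0, 1]")

    q = bh_adjust(p)
    call = np.where(q < alpha, np.where(log2fc > 0, "up", "down"), "ns")
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "call": call,
        },
        index=pd.Index(expr.feature_ids, name="feature_id"),
    )


def de_features(de: pd.DataFrame) -> list:
    """Feature ids called differentially expressed (q below alpha)."""
    return list(de.index[de["call"] != "ns"])
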