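"""Position-wise nucleotide enrichment between two aligned window sets.

The two-sample-logo statistic: for each signed window position (candidate
site at 0) and each nucleotide, compare the per-sequence presence
indicator between positive and negative sets with a Welch (unequal
variance) two-sample t-test.  Cells with p below alpha (default 0.05,
uncorrected; optional Bonferroni) are flagged enriched (positive
difference) or depleted (negative difference).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .windows import WindowSet

NUCLEOTIDES = "ACGU"


def _indicator_tensor(ws: WindowSet) -> np.ndarray:
    """(n, L, 4) 0/1 tensor of nucleotide presence."""
    seqs = ws.sequences()
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    return np.stack([arr == nt.encode() for nt in NUCLEOTIDES], axis=2).astype(float)


def enrichment(
    pos_set: WindowSet,
    neg_set: WindowSet,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-(position, nucleotide) enrichment table.

    Columns: position (signed, site at 0), nucleotide, freq_pos,
    freq_neg, difference (= freq_pos - freq_neg), t_statistic, p_value,
    significant.  Per position, frequencies sum to 1 within each class.
    """
    if not len(pos_set) or not len(neg_set):
        raise ValueError("both window sets must be non-empty")
    if pos_set.L != neg_set.L:
        raise ValueError(f"window lengths differ: {pos_set.L} vs {neg_set.L}")
    L = pos_set.L
    flank = L // 2

    a = _indicator_tensor(pos_set)  # (n_pos, L, 4)
    b = _indicator_tensor(neg_set)
    freq_pos = a.mean(axis=0)
    freq_neg = b.mean(axis=0)

    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on zero-variance cells
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    # both samples constant: equal means -> no evidence; unequal -> certain
    var_zero = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    same = var_zero & (freq_pos == freq_neg)
    diff_sign = np.sign(freq_pos - freq_neg)
    with np.errstate(invalid="ignore"):
        t = np.where(same, 0.0, np.where(var_zero, diff_sign * np.inf, t))
    p = np.where(same, 1.0, np.where(var_zero, 0.0, p))

    n_tests = L * 4
    threshold = alpha / n_tests if bonferroni else alpha

    records = []
    for j in range(L):
        for q, nt in enumerate(NUCLEOTIDES):
            records.append(
                {
                    "position": j - flank,
                    "nucleotide": nt,
                    "freq_pos": freq_pos[j, q],
                    "freq_neg": freq_neg[j, q],
                    "difference": freq_pos[j, q] - freq_neg[j, q],
                    "t_statistic": t[j, q],
                    "p_value": p[j, q],
                    "significant": bool(p[j, q] < threshold),
                }
            )
    return pd.DataFrame.from_records(records)


def logo_matrix(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Positions x nucleotides matrix of signed -log10 p for significant cells.

    Enriched cells are positive, depleted negative, non-significant 0 —
    a numeric stand-in for the two-sample logo consumable by standard
    logo plotters.
    """
    out = table.copy()
    with np.errstate(divide="ignore"):
        score = -np.log10(np.maximum(out["p_value"], np.finfo(float).tiny))
    out["logo"] = np.where(
        out["p_value"] < alpha, np.sign(out["difference"]) * score, 0.0
    )
    return out.pivot(index="position", columns="nucleotide", values="logo")
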