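"""Nonparametric multi-condition statistics over kernel parameters.

Each extracted parameter (amplitude, TTP, half-width, decay, return to
baseline, spike rate) is compared across the experimental conditions with
an omnibus Kruskal–Wallis test, followed by pairwise two-sided
Mann–Whitney U tests corrected with the Benjamini–Hochberg step-up
procedure (significance at adjusted p < 0.05).  The correction family is
the set of pairwise comparisons within one parameter.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kruskal_wallis",
    "pairwise_mwu_bh",
    "percent_change",
    "letter_groups",
]

ALPHA = 0.05
#: Largest per-group size for which the exact Mann–Whitney null
#: distribution is enumerated (ties force the normal approximation).
EXACT_MWU_MAX_N = 12


def kruskal_wallis(groups: dict[str, np.ndarray] | list) -> tuple[float, int, float]:
    """Rank-based omnibus test across k groups.

    Returns ``(H, df, p)`` with the tie-corrected H statistic, k−1 degrees
    of freedom and the chi-square p-value.  If every value is identical
    across all groups, H is 0 and p is 1.
    """
    if isinstance(groups, dict):
        samples = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        samples = [np.asarray(v, dtype=float) for v in groups]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    df = len(samples) - 1
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), df, float(p)


def pairwise_mwu_bh(
    groups: dict[str, np.ndarray],
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Pairwise two-sided Mann–Whitney U tests with BH correction.

    The exact null distribution is used when both groups have at most
    ``EXACT_MWU_MAX_N`` observations and there are no ties across the
    pair; otherwise the normal approximation with tie correction is used.
    Adjusted p-values are computed across the tested pairs (one family).

    Returns a DataFrame with columns group_a, group_b, n_a, n_b, U,
    p_raw, p_adj, significant.
    """
    if pairs is None:
        pairs = list(combinations(groups, 2))
    rows = []
    for a, b in pairs:
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if len(xa) == 0 or len(xb) == 0:
            raise ValueError(f"empty group in pair ({a}, {b})")
        has_ties = len(np.unique(np.concatenate([xa, xb]))) < len(xa) + len(xb)
        method = (
            "exact"
            if (len(xa) <= EXACT_MWU_MAX_N and len(xb) <= EXACT_MWU_MAX_N
                and not has_ties)
            else "asymptotic"
        )
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(xa),
                "n_b": len(xb),
                "U": float(res.statistic),
                "p_raw": float(res.pvalue),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        reject, p_adj, _, _ = multipletests(
            table["p_raw"].to_numpy(), alpha=alpha, method="fdr_bh"
        )
        table["p_adj"] = p_adj
        table["significant"] = reject
    else:
        table["p_adj"] = []
        table["significant"] = []
    return table


def percent_change(
    median_experimental: float, median_reference: float
) -> float:
    """Percent change of a condition median relative to the reference median.

    ``100 * (experimental - reference) / reference``; a zero reference is
    flagged as an error rather than returning an unbounded value.
    """
    if median_reference == 0:
        raise ZeroDivisionError(
            "percent change undefined for zero reference median"
        )
    return 100.0 * (median_experimental - median_reference) / median_reference


def letter_groups(
    labels: list[str], significant: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Compact letter display for pairwise significance (plot annotation).

    Greedy assignment: two conditions share a letter iff they are not
    significantly different.  Presentation plumbing for figure panels, not
    part of the inference.
    """
    differs = {
        frozenset(pair) for pair, sig in significant.items() if sig
    }
    letter_sets: list[set[str]] = []
    for lab in labels:
        placed = False
        for group in letter_sets:
            if all(frozenset((lab, other)) not in differs for other in group):
                group.add(lab)
                placed = True
        if not placed:
            letter_sets.append({lab})
    # second pass: absorb labels into groups created after they were placed
    changed = True
    while changed:
        changed = False
        for lab in labels:
            for group in letter_sets:
                if lab not in group and all(
                    frozenset((lab, other)) not in differs for other in group
                ):
                    group.add(lab)
                    changed = True
    letter_sets = [
        g for g in letter_sets
        if not any(g < other for other in letter_sets)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {lab: "" for lab in labels}
    for letter, group in zip(alphabet, letter_sets):
        for lab in labels:
            if lab in group:
                out[lab] += letter
    return out
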