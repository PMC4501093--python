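"""Tail enrichment of risk SNPs among low environmental-association p-values.

A disease's risk SNPs show collective environmental signal when more of
them than expected sit in the low tail (p < 0.05) of the genome-wide ranked
p-values for a variable.  The strength of that over-representation is

    enrichment = (n_r / n_nr) / (N_r / N_nr),

with n_r / n_nr the risk / non-risk SNPs inside the tail and N_r / N_nr the
totals among all scored SNPs.  Significance comes from a permutation test:
random same-size SNP sets are drawn from all scored SNPs, and the p-value
is the fraction of sets with strictly more tail SNPs than observed.  The
grid of disease x variable tests is Bonferroni-corrected with a default
cutoff of 0.00026.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .score_post import RankedPValues

__all__ = [
    "EnrichmentResult",
    "tail_counts",
    "enrichment_statistic",
    "permutation_test",
    "correct_enrichment",
    "evaluate_enrichment",
]

#: Default Bonferroni cutoff on permutation p-values across the
#: disease x variable grid (~0.05 over 21 diseases x 9 variables).
ENRICHMENT_CUTOFF = 0.00026
TAIL_THRESHOLD = 0.05


@dataclass
class EnrichmentResult:
    disease: str
    variable: str
    n_r: int
    n_nr: int
    N_r: int
    N_nr: int
    enrichment: float  # NaN when undefined (n_nr = 0 or N_r = 0)
    perm_p: float
    significant: bool = False


def tail_counts(
    pvals: RankedPValues,
    risk_ids: Sequence[str],
    variable: str,
    threshold: float = TAIL_THRESHOLD,
) -> tuple[int, int, int, int]:
    """(n_r, n_nr, N_r, N_nr): SNPs with p < threshold, split by risk
    membership, plus the totals.  Boundary p-values are outside the tail
    (strict <)."""
    table = pvals.table
    if table.empty:
        raise ValueError("empty score table")
    missing = set(risk_ids) - set(table.index)
    if missing:
        raise KeyError(f"risk SNPs absent from score table: {sorted(missing)[:5]}")
    p = table[variable]
    is_risk = table.index.isin(set(risk_ids))
    in_tail = (p < threshold).to_numpy()
    n_r = int(np.count_nonzero(in_tail & is_risk))
    n_nr = int(np.count_nonzero(in_tail & ~is_risk))
    return n_r, n_nr, int(is_risk.sum()), int((~is_risk).sum())


def enrichment_statistic(n_r: int, n_nr: int, N_r: int, N_nr: int) -> float:
    """(n_r/n_nr) / (N_r/N_nr); scale-free ratio of tail composition to
    overall composition.

    Returns 0.0 when no risk SNP is in the tail, NaN (an undefined-result
    flag, not an exception) when a denominator vanishes.
    """
    if N_r == 0 or N_nr == 0 or n_nr == 0:
        return float("nan")
    if n_r == 0:
        return 0.0
    return (n_r / n_nr) / (N_r / N_nr)


def permutation_test(
    pvals: RankedPValues,
    risk_ids: Sequence[str],
    variable: str,
    n_perm: int = 50_000,
    threshold: float = TAIL_THRESHOLD,
    seed: int = 0,
) -> float:
    """Permutation p: fraction of random same-size SNP sets with strictly
    more tail SNPs than the observed risk set.

    Random sets are drawn without replacement within a set, from all scored
    SNPs (risk SNPs included).  Seeded and reproducible.
    """
    n_r, _, N_r, N_nr = tail_counts(pvals, risk_ids, variable, threshold)
    n_total = N_r + N_nr
    if N_r >= n_total:
        raise ValueError("risk set must be smaller than the scored SNP pool")
    in_tail = (pvals.table[variable] < threshold).to_numpy()
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_perm, int(5e6) // max(n_total, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # vectorised distinct draws: top-N_r of random keys per row
        keys = rng.random((m, n_total))
        idx = np.argpartition(keys, N_r - 1, axis=1)[:, :N_r]
        counts = in_tail[idx].sum(axis=1)
        exceed += int(np.count_nonzero(counts > n_r))
        done += m
    return exceed / n_perm


def correct_enrichment(
    results: list[EnrichmentResult],
    cutoff: float = ENRICHMENT_CUTOFF,
) -> list[EnrichmentResult]:
    """Flag results with perm_p strictly below the Bonferroni cutoff."""
    for r in results:
        r.significant = bool(r.perm_p < cutoff)
    return results


def evaluate_enrichment(
    pvals: RankedPValues,
    risk_sets: dict[str, Sequence[str]],
    n_perm: int = 50_000,
    threshold: float = TAIL_THRESHOLD,
    cutoff: float = ENRICHMENT_CUTOFF,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Full disease x variable enrichment grid with permutation p-values."""
    results = []
    for di, (disease, ids) in enumerate(sorted(risk_sets.items())):
        for vi, variable in enumerate(pvals.table.columns):
            n_r, n_nr, N_r, N_nr = tail_counts(pvals, ids, variable, threshold)
            results.append(
                EnrichmentResult(
                    disease=disease,
                    variable=variable,
                    n_r=n_r,
                    n_nr=n_nr,
                    N_r=N_r,
                    N_nr=N_nr,
                    enrichment=enrichment_statistic(n_r, n_nr, N_r, N_nr),
                    perm_p=permutation_test(
                        pvals, ids, variable, n_perm=n_perm,
                        threshold=threshold, seed=seed + 1000 * di + vi,
                    ),
                )
            )
    return correct_enrichment(results, cutoff)
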