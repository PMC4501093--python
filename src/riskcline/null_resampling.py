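"""Frequency-matched resampling nulls for panel regressions.

Whether a risk panel's R² on a predictor is remarkable cannot be judged
against an analytic null: panel SNPs have a particular allele-frequency
spectrum, and frequency alone constrains how much a statistic can vary
across populations.  The null is therefore built empirically: every SNP of
the matrix is binned by global allele frequency (0.1-wide bins), each risk
SNP is replaced by a random SNP from its bin, the full
profile -> adjustment -> regression pipeline is run on the resampled set,
and the observed R² is ranked within 10,000 such resampled R² values.

The same resampled sets serve all predictors of a disease (so nulls across
predictors are dependent, as they should be), while diseases get
independent nulls.  Multiplicity across the 10 predictors x 2 statistics of
a disease is handled by Bonferroni (p < 0.05/20 by default) and by
Benjamini-Hochberg FDR at q = 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .allele_stats import (
    FrequencyMatrix,
    RiskSet,
    adjusted_profile,
    genomewide_baseline,
    risk_profile,
)
from .regression import batch_r_squared

__all__ = [
    "FrequencyBins",
    "NullDistribution",
    "EmpiricalResult",
    "bin_by_global_frequency",
    "resample_set",
    "build_null",
    "empirical_p",
    "observed_r_squared",
    "evaluate_panel",
    "correct_multiplicity",
]

#: Default Bonferroni fraction: 0.05 over 10 predictors x 2 statistics.
BONFERRONI_FRACTION = 0.0025
FDR_Q = 0.2


@dataclass
class FrequencyBins:
    """SNP pools partitioned by global allele frequency.

    Bins are half-open [0.0, 0.1), ..., [0.9, 1.0] (the top bin closed);
    ``bin_of[i]`` is the bin index of matrix row i, ``pools[b]`` the row
    indices in bin b.  Global frequency is the unweighted mean of the
    designated-allele frequency over populations (optionally a population
    subset, e.g. European populations only).
    """

    edges: np.ndarray
    bin_of: np.ndarray
    pools: list = field(repr=False)

    def bin_index(self, global_freq: float) -> int:
        return min(int(global_freq * 10.0), 9)


def bin_by_global_frequency(
    matrix: FrequencyMatrix,
    populations: Sequence[str] | None = None,
) -> FrequencyBins:
    """Bin every SNP of the matrix by its global allele frequency."""
    if matrix.n_snps == 0:
        raise ValueError("empty matrix")
    if populations is None:
        g = matrix.freq.mean(axis=1)
    else:
        cols = [matrix.populations.index(p) for p in populations]
        if not cols:
            raise ValueError("empty population subset for binning")
        g = matrix.freq[:, cols].mean(axis=1)
    bin_of = np.minimum((g * 10.0).astype(np.intp), 9)
    pools = [np.flatnonzero(bin_of == b) for b in range(10)]
    return FrequencyBins(edges=np.linspace(0.0, 1.0, 11), bin_of=bin_of, pools=pools)


def _draw_matched_rows(
    risk_rows: np.ndarray,
    bins: FrequencyBins,
    n_sets: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_sets, d) matrix of matched replacement rows.

    Each column replaces one risk SNP with a uniform draw from its frequency
    bin, excluding all of the disease's own risk SNPs; draws are distinct
    within a set.  Bins are disjoint, so distinctness only needs enforcing
    among same-bin columns; duplicates are redrawn (rare for pools much
    larger than the panel).
    """
    risk_set_rows = set(risk_rows.tolist())
    d = len(risk_rows)
    out = np.empty((n_sets, d), dtype=np.intp)
    risk_bins = bins.bin_of[risk_rows]
    for b in np.unique(risk_bins):
        cols = np.flatnonzero(risk_bins == b)
        pool = np.array([i for i in bins.pools[b] if i not in risk_set_rows], dtype=np.intp)
        k = len(cols)
        if len(pool) < k:
            raise ValueError(
                f"bin [{b / 10:.1f}, {(b + 1) / 10:.1f}) pool exhausted: "
                f"{len(pool)} candidates for {k} replacements"
            )
        draw = pool[rng.integers(0, len(pool), size=(n_sets, k))]
        if k > 1:  # redraw rows with within-set duplicates
            bad = np.flatnonzero((np.sort(draw, axis=1)[:, 1:] == np.sort(draw, axis=1)[:, :-1]).any(axis=1))
            for i in bad:
                draw[i] = rng.choice(pool, size=k, replace=False)
        out[:, cols] = draw
    return out


def resample_set(
    risk_set: RiskSet,
    bins: FrequencyBins,
    matrix: FrequencyMatrix,
    rng: np.random.Generator | int = 0,
) -> list[str]:
    """One frequency-matched replacement set for a disease's risk SNPs.

    Each replacement's global frequency lies in the same 0.1-wide bin as
    its risk SNP's; replacements are distinct and exclude the disease's own
    risk SNPs.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = _draw_matched_rows(matrix.rows(risk_set.snp_ids), bins, 1, rng)[0]
    return [matrix.snp_ids[i] for i in rows]


@dataclass
class NullDistribution:
    """Resampled R² values for one (disease, statistic, predictor) triple."""

    disease: str
    statistic: str
    predictor: str
    r_squared_samples: np.ndarray = field(repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.r_squared_samples, dtype=float)
        if s.ndim != 1 or len(s) == 0:
            raise ValueError("r_squared_samples must be a non-empty vector")
        if (s < 0).any() or (s > 1).any():
            raise ValueError("R² samples outside [0, 1]")
        self.r_squared_samples = s

    @property
    def n_sets(self) -> int:
        return len(self.r_squared_samples)


def _panel_stat_rows(matrix: FrequencyMatrix, rows: np.ndarray, statistic: str) -> np.ndarray:
    """(n_sets, n_pops) adjusted panel statistic for each row-set.

    Resampled panels use designated-allele orientation (no risk allele is
    defined for them); heterozygosity is orientation-free and the adjusted
    frequency statistic is orientation-symmetric around the baseline.
    """
    if statistic == "heterozygosity":
        per_snp = matrix.heterozygosity()
        base = per_snp.mean(axis=0)
    elif statistic == "risk_frequency":
        per_snp = matrix.freq
        base = per_snp.mean(axis=0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return per_snp[rows].mean(axis=1) - base[None, :]


def build_null(
    risk_set: RiskSet,
    matrix: FrequencyMatrix,
    predictors: pd.DataFrame,
    statistic: str = "heterozygosity",
    n_sets: int = 10_000,
    seed: int = 0,
    bins: FrequencyBins | None = None,
) -> dict[str, NullDistribution]:
    """Null R² distributions for one disease and statistic, per predictor.

    Every resampled set runs through the identical adjusted-statistic
    pipeline as the observed panel; the same ``n_sets`` resampled sets are
    reused across all predictor columns.  Seeded and reproducible.
    """
    if bins is None:
        bins = bin_by_global_frequency(matrix)
    if list(predictors.index) != list(matrix.populations):
        predictors = predictors.reindex(matrix.populations)
        if predictors.isna().any().any():
            raise ValueError("predictors missing populations of the matrix")
    rng = np.random.default_rng(seed)
    rows = _draw_matched_rows(matrix.rows(risk_set.snp_ids), bins, n_sets, rng)
    profiles = _panel_stat_rows(matrix, rows, statistic)
    out = {}
    for name in predictors.columns:
        x = predictors[name].to_numpy(dtype=float)
        out[name] = NullDistribution(
            disease=risk_set.disease,
            statistic=statistic,
            predictor=name,
            r_squared_samples=np.clip(batch_r_squared(profiles, x), 0.0, 1.0),
            seed=seed,
        )
    return out


def empirical_p(observed: float, null: NullDistribution | np.ndarray, plus_one: bool = False) -> float:
    """Fraction of null samples with R² strictly higher than observed.

    Ties count as not higher, and 0 is a possible output; ``plus_one``
    switches to the (k+1)/(n+1) estimator, which cannot return 0 (off by
    default).
    """
    samples = null.r_squared_samples if isinstance(null, NullDistribution) else np.asarray(null)
    if len(samples) == 0:
        raise ValueError("empty null distribution")
    k = int(np.count_nonzero(samples > observed))
    if plus_one:
        return (k + 1) / (len(samples) + 1)
    return k / len(samples)


@dataclass
class EmpiricalResult:
    disease: str
    statistic: str
    predictor: str
    observed_r_squared: float
    empirical_p: float
    bonferroni_significant: bool = False
    fdr_significant: bool = False


def observed_r_squared(
    risk_set: RiskSet,
    matrix: FrequencyMatrix,
    predictors: pd.DataFrame,
    statistic: str,
) -> dict[str, float]:
    """Adjusted-statistic R² of the observed panel against each predictor."""
    profile = adjusted_profile(risk_profile(matrix, risk_set), genomewide_baseline(matrix))
    col = "adj_heterozygosity" if statistic == "heterozygosity" else "adj_risk_freq"
    y = profile.table.loc[list(predictors.index), col].to_numpy()
    return {
        name: float(batch_r_squared(y[None, :], predictors[name].to_numpy(dtype=float))[0])
        for name in predictors.columns
    }


def evaluate_panel(
    risk_set: RiskSet,
    matrix: FrequencyMatrix,
    predictors: pd.DataFrame,
    statistics: Iterable[str] = ("heterozygosity", "risk_frequency"),
    n_sets: int = 10_000,
    seed: int = 0,
    bins: FrequencyBins | None = None,
) -> list[EmpiricalResult]:
    """Observed R² vs. its frequency-matched null for every predictor and
    statistic of one disease, with multiplicity flags."""
    if bins is None:
        bins = bin_by_global_frequency(matrix)
    results = []
    for si, statistic in enumerate(statistics):
        observed = observed_r_squared(risk_set, matrix, predictors, statistic)
        nulls = build_null(
            risk_set, matrix, predictors, statistic=statistic,
            n_sets=n_sets, seed=seed + si, bins=bins,
        )
        for name in predictors.columns:
            results.append(
                EmpiricalResult(
                    disease=risk_set.disease,
                    statistic=statistic,
                    predictor=name,
                    observed_r_squared=observed[name],
                    empirical_p=empirical_p(observed[name], nulls[name]),
                )
            )
    # count is correct by construction here, whatever statistics were requested
    return correct_multiplicity(results, expected_tests=len(results))


def correct_multiplicity(
    results: list[EmpiricalResult],
    bonferroni_fraction: float = BONFERRONI_FRACTION,
    fdr_q: float = FDR_Q,
    expected_tests: int = 20,
) -> list[EmpiricalResult]:
    """Flag one disease's results by Bonferroni and BH-FDR.

    Bonferroni: empirical p < ``bonferroni_fraction`` (default 0.05 over 10
    predictors x 2 statistics).  FDR: Benjamini-Hochberg at ``fdr_q`` across
    all of the disease's tests.
    """
    if len(results) != expected_tests:
        warnings.warn(
            f"expected {expected_tests} tests for one disease, got {len(results)}"
        )
    pvals = np.array([r.empirical_p for r in results])
    reject, *_ = multipletests(pvals, alpha=fdr_q, method="fdr_bh")
    for r, fdr_flag in zip(results, reject):
        r.bonferroni_significant = bool(r.empirical_p < bonferroni_fraction)
        r.fdr_significant = bool(fdr_flag)
    return results
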