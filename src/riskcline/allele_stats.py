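"""Per-population allelic statistics for disease risk-SNP panels.

For a disease with d risk SNPs, population j gets two panel statistics:

* average heterozygosity  sum_i 2 p_ij q_ij / d  (q = 1 - p), and
* average risk-allele frequency  sum_i p_ij / d,

where p_ij is the frequency of the *risk* allele of SNP i in population j.
The same two statistics computed over *all* SNPs of the matrix form a
genome-wide baseline capturing the drift signature of the serial-founder
expansion; subtracting the baseline from the panel statistic ("adjusted"
statistics) leaves the variation not accounted for by drift, which is what
gets regressed on climate variables downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyMatrix",
    "RiskSet",
    "AllelicProfile",
    "oriented_frequencies",
    "average_heterozygosity",
    "average_risk_frequency",
    "risk_profile",
    "genomewide_baseline",
    "adjusted_profile",
    "population_variance_of_mean_freq",
]


@dataclass
class FrequencyMatrix:
    """Frequencies of each SNP's designated allele across populations.

    ``freq[i, j]`` is the frequency of SNP ``snp_ids[i]``'s designated
    allele in population ``populations[j]``, in [0, 1].  Missing cells are
    rejected at construction (complete matrices are assumed throughout).
    """

    snp_ids: np.ndarray
    populations: list[str]
    freq: np.ndarray
    designated_allele: np.ndarray

    _row_of: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.designated_allele = np.asarray(self.designated_allele, dtype=object)
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape != (len(self.snp_ids), len(self.populations)):
            raise ValueError("freq shape does not match snp_ids x populations")
        if len(self.designated_allele) != len(self.snp_ids):
            raise ValueError("one designated allele per SNP required")
        if np.isnan(self.freq).any():
            raise ValueError("missing frequencies are not allowed")
        if (self.freq < 0).any() or (self.freq > 1).any():
            raise ValueError("frequencies outside [0, 1]")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp_id in matrix")
        self._row_of = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def rows(self, snp_ids) -> np.ndarray:
        """Row indices for the given SNP ids (KeyError on unknown id)."""
        return np.array([self._row_of[s] for s in snp_ids], dtype=np.intp)

    def heterozygosity(self) -> np.ndarray:
        """2 p (1 - p), elementwise; orientation-free."""
        return 2.0 * self.freq * (1.0 - self.freq)


@dataclass
class RiskSet:
    """One disease's risk SNPs with risk-allele orientation.

    ``members`` pairs each snp_id with its risk allele; when the risk allele
    differs from the matrix's designated allele, the frequency used is the
    complement 1 - p.
    """

    disease: str
    members: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError(f"risk set {self.disease!r} is empty")
        ids = [s for s, _ in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate snp_id in risk set {self.disease!r}")

    @property
    def d(self) -> int:
        return len(self.members)

    @property
    def snp_ids(self) -> list[str]:
        return [s for s, _ in self.members]


@dataclass
class AllelicProfile:
    """Per-population panel statistics, raw and baseline-adjusted.

    ``table`` is indexed by population with columns ``avg_heterozygosity``,
    ``avg_risk_freq`` and, after :func:`adjusted_profile`,
    ``adj_heterozygosity`` and ``adj_risk_freq``.
    """

    disease: str
    table: pd.DataFrame = field(repr=False)


def oriented_frequencies(matrix: FrequencyMatrix, risk_set: RiskSet) -> np.ndarray:
    """(d, n_populations) risk-allele frequencies, complementing where the
    risk allele is not the matrix's designated allele."""
    rows = matrix.rows(risk_set.snp_ids)
    p = matrix.freq[rows].copy()
    designated = matrix.designated_allele[rows]
    flip = np.array([ra != da for (_, ra), da in zip(risk_set.members, designated)])
    p[flip] = 1.0 - p[flip]
    return p


def average_heterozygosity(matrix: FrequencyMatrix, risk_set: RiskSet, population: str) -> float:
    """Mean of 2 p q over the panel's d SNPs in one population.

    Orientation-free: 2pq is invariant under p -> 1 - p.
    """
    j = matrix.populations.index(population)
    p = oriented_frequencies(matrix, risk_set)[:, j]
    return float(np.mean(2.0 * p * (1.0 - p)))


def average_risk_frequency(matrix: FrequencyMatrix, risk_set: RiskSet, population: str) -> float:
    """Mean risk-allele frequency over the panel's d SNPs in one population."""
    j = matrix.populations.index(population)
    p = oriented_frequencies(matrix, risk_set)[:, j]
    return float(np.mean(p))


def risk_profile(matrix: FrequencyMatrix, risk_set: RiskSet) -> AllelicProfile:
    """Panel statistics for every population at once."""
    p = oriented_frequencies(matrix, risk_set)
    het = (2.0 * p * (1.0 - p)).mean(axis=0)
    frq = p.mean(axis=0)
    table = pd.DataFrame(
        {"avg_heterozygosity": het, "avg_risk_freq": frq},
        index=pd.Index(matrix.populations, name="population"),
    )
    return AllelicProfile(risk_set.disease, table)


def genomewide_baseline(matrix: FrequencyMatrix) -> pd.DataFrame:
    """Per-population means of 2pq and of the designated-allele frequency
    over ALL SNPs of the matrix.

    The baseline uses each SNP's designated allele as stored; because the
    adjustment is a per-population location shift, the choice of genome-wide
    orientation does not affect which variables explain the adjusted
    statistics.
    """
    if matrix.n_snps == 0:
        raise ValueError("empty matrix")
    return pd.DataFrame(
        {
            "avg_het_all": matrix.heterozygosity().mean(axis=0),
            "avg_freq_all": matrix.freq.mean(axis=0),
        },
        index=pd.Index(matrix.populations, name="population"),
    )


def adjusted_profile(profile: AllelicProfile, baseline: pd.DataFrame) -> AllelicProfile:
    """Subtract the genome-wide baseline from the panel statistics.

    The difference removes the drift signature shared by all SNPs, leaving
    the panel-specific signal.
    """
    if set(profile.table.index) != set(baseline.index):
        raise ValueError("population sets of profile and baseline differ")
    base = baseline.reindex(profile.table.index)
    table = profile.table.copy()
    table["adj_heterozygosity"] = table["avg_heterozygosity"] - base["avg_het_all"]
    table["adj_risk_freq"] = table["avg_risk_freq"] - base["avg_freq_all"]
    return AllelicProfile(profile.disease, table)


def population_variance_of_mean_freq(
    matrix: FrequencyMatrix,
    risk_set: RiskSet,
    population: str,
    of_mean: bool = True,
) -> float:
    """Variance of the panel's risk-allele frequencies in one population.

    With ``of_mean=True`` (default) returns the sample variance across the d
    SNPs divided by d — the variance of the panel mean, whose inverse serves
    as a weight in weighted regressions.  ``of_mean=False`` returns the raw
    sample variance.
    """
    if risk_set.d < 2:
        raise ValueError("variance needs at least 2 panel SNPs")
    j = matrix.populations.index(population)
    p = oriented_frequencies(matrix, risk_set)[:, j]
    var = float(np.var(p, ddof=1))
    return var / risk_set.d if of_mean else var
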