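"""Post-processing of per-SNP environmental-association score tables.

Tables of per-SNP Bayes factors (one row per SNP, one column per climate
variable, as emitted by environmental-association scans such as Bayenv 2.0)
are averaged over replicate MCMC runs, concatenated across ascertainment
panels, and converted to ranked empirical p-values: a SNP's p for a
variable is the fraction of all scored SNPs whose score is at least as
large.  Ranked p-values are invariant under any strictly increasing
transform of the scores, making them robust to score-scale inflation; the
order of operations (average runs, combine panels, then rank) matters and
is preserved by the API.

For synthetic data, :func:`surrogate_scores` provides a per-SNP statistic
with the same interface — the |Pearson correlation| of a SNP's frequencies
with each variable across populations — so the enrichment stage is testable
without an external scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .allele_stats import FrequencyMatrix

__all__ = [
    "ScoreTable",
    "RankedPValues",
    "read_score_table",
    "write_score_table",
    "average_runs",
    "combine_panels",
    "ranked_pvalues",
    "surrogate_scores",
]


@dataclass
class ScoreTable:
    """Per-SNP x per-variable association scores (Bayes factors)."""

    snp_ids: np.ndarray
    variables: list[str]
    scores: np.ndarray = field(repr=False)
    panel: str = ""
    run: str = ""

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.snp_ids), len(self.variables)):
            raise ValueError("scores shape does not match snp_ids x variables")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        if (self.scores < 0).any():
            raise ValueError("scores must be non-negative")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp_id in score table")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class RankedPValues:
    """Empirical p per SNP x variable: p_i = #{k : score_k >= score_i} / N."""

    table: pd.DataFrame = field(repr=False)  # index snp_id, columns variables


def read_score_table(
    path: str | Path,
    snp_id_path: str | Path,
    variables: Sequence[str],
    panel: str = "",
    run: str = "",
) -> ScoreTable:
    """Read a whitespace-delimited score file plus its SNP-id sidecar.

    The score file has one row per SNP and one column per variable; the
    sidecar lists SNP ids, one per line, in row order.
    """
    snp_id_path = Path(snp_id_path)
    if not snp_id_path.exists():
        raise FileNotFoundError(f"missing SNP-id sidecar {snp_id_path}")
    ids = [ln.strip() for ln in snp_id_path.read_text().splitlines() if ln.strip()]
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != len(variables):
            raise ValueError(
                f"{path}:{lineno}: expected {len(variables)} columns, got {len(parts)}"
            )
        try:
            rows.append([float(v) for v in parts])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if len(rows) != len(ids):
        raise ValueError(f"{len(rows)} score rows but {len(ids)} SNP ids in sidecar")
    return ScoreTable(np.array(ids, dtype=object), list(variables), np.array(rows), panel, run)


def write_score_table(table: ScoreTable, path: str | Path, snp_id_path: str | Path) -> None:
    """Write the whitespace-delimited score file and its SNP-id sidecar."""
    with open(path, "w") as fh:
        for row in table.scores:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    Path(snp_id_path).write_text("\n".join(table.snp_ids) + "\n")


def average_runs(tables: Sequence[ScoreTable]) -> ScoreTable:
    """Element-wise mean over replicate runs of the same panel."""
    if len(tables) < 2:
        raise ValueError("need at least 2 runs to average")
    first = tables[0]
    for t in tables[1:]:
        if list(t.snp_ids) != list(first.snp_ids) or t.variables != first.variables:
            raise ValueError("runs differ in SNP ids or variables")
    mean = np.mean([t.scores for t in tables], axis=0)
    return ScoreTable(first.snp_ids.copy(), list(first.variables), mean, panel=first.panel, run="mean")


def combine_panels(tables: Sequence[ScoreTable]) -> ScoreTable:
    """Row-concatenate score tables of disjoint SNP sets (same variables)."""
    first = tables[0]
    for t in tables[1:]:
        if t.variables != first.variables:
            raise ValueError("panels differ in variables")
    ids = np.concatenate([t.snp_ids for t in tables])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate snp_id across panels")
    scores = np.vstack([t.scores for t in tables])
    return ScoreTable(ids, list(first.variables), scores, panel="combined", run=first.run)


def ranked_pvalues(table: ScoreTable) -> RankedPValues:
    """Per variable, p_i = #{k : score_k >= score_i} / N.

    Ties share the larger count (the most conservative rank); the unique
    maximum gets 1/N and ties at the minimum get 1.
    """
    n = table.n_snps
    out = np.empty_like(table.scores)
    for v in range(len(table.variables)):
        s = table.scores[:, v]
        order = np.sort(s)
        # count of scores >= s_i  =  N - (number strictly below s_i)
        below = np.searchsorted(order, s, side="left")
        out[:, v] = (n - below) / n
    return RankedPValues(
        pd.DataFrame(out, index=pd.Index(table.snp_ids, name="snp_id"), columns=table.variables)
    )


def surrogate_scores(matrix: FrequencyMatrix, climate: pd.DataFrame) -> ScoreTable:
    """|Pearson r| of each SNP's frequencies with each climate variable.

    A simple per-SNP environmental-association statistic for synthetic data;
    SNPs whose frequencies are flat across populations score 0.  Because
    downstream ranking is invariant to monotone transforms, |r| in [0, 1]
    serves directly as the score scale.
    """
    if list(climate.index) != list(matrix.populations):
        climate = climate.reindex(matrix.populations)
        if climate.isna().any().any():
            raise ValueError("climate table missing populations of the matrix")
    F = matrix.freq
    Fc = F - F.mean(axis=1, keepdims=True)
    fnorm = np.sqrt(np.einsum("ij,ij->i", Fc, Fc))
    scores = np.empty((matrix.n_snps, climate.shape[1]))
    for v, name in enumerate(climate.columns):
        x = climate[name].to_numpy(dtype=float)
        xc = x - x.mean()
        xnorm = float(np.sqrt(xc @ xc))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Fc @ xc) / (fnorm * xnorm)
        scores[:, v] = np.abs(np.where(fnorm > 0, r, 0.0))
    return ScoreTable(matrix.snp_ids.copy(), list(climate.columns), np.clip(scores, 0.0, 1.0), panel="surrogate")
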