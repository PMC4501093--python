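"""Synthetic serial-founder data with optional climate-coupled SNPs.

The generator produces the statistical structure the analysis assumes, so
every downstream stage can be exercised without external data:

* an allele-frequency matrix whose heterozygosity declines linearly along a
  chain of founder events (binomial drift, no mutation or migration);
* nine named climate variables, each a chosen loading on standardized
  distance plus Gaussian noise, emulating the partial collinearity of real
  climate with the migration path;
* risk-SNP panels of realistic sizes (7-41 SNPs), neutral or coupled to one
  climate variable by an additive frequency cline.

Under pure binomial resampling of 2N gametes per founding event, expected
heterozygosity decays by the factor (1 - 1/(2N)) per event, which yields the
near-linear decline with distance that the neutral regressions target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allele_stats import FrequencyMatrix, RiskSet
from .geodesy import PopulationPanel

__all__ = [
    "SimulationConfig",
    "ClineSpec",
    "CLIMATE_VARIABLES",
    "DEFAULT_CLIMATE_SPEC",
    "TABLE1_PANEL_SIZES",
    "simulate_serial_founder",
    "generate_climate",
    "inject_cline",
    "make_risk_sets",
]

#: The nine climate variables carried through the whole pipeline.
CLIMATE_VARIABLES = [
    "latitude",
    "longitude",
    "winter_temperature_min",
    "summer_temperature_max",
    "winter_precipitation",
    "summer_precipitation",
    "winter_radiation_flux",
    "winter_humidity",
    "summer_humidity",
]

#: Default distance loadings: moderate collinearity with the migration path
#: for most variables (longitude strongest, winter radiation weakest), each
#: variable scaled to ~unit variance.  Values are on standardized scales;
#: physical units are irrelevant to regressions on them.
DEFAULT_CLIMATE_SPEC: dict[str, dict[str, float]] = {
    "latitude": {"distance_loading": 0.60},
    "longitude": {"distance_loading": 0.74},
    "winter_temperature_min": {"distance_loading": 0.50},
    "summer_temperature_max": {"distance_loading": 0.40},
    "winter_precipitation": {"distance_loading": 0.25},
    "summer_precipitation": {"distance_loading": 0.30},
    "winter_radiation_flux": {"distance_loading": 0.09},
    "winter_humidity": {"distance_loading": 0.35},
    "summer_humidity": {"distance_loading": 0.30},
}
for _v in DEFAULT_CLIMATE_SPEC.values():
    _v.setdefault("noise_sd", math.sqrt(1.0 - _v["distance_loading"] ** 2))

#: 21 disease risk-panel sizes used as realistic fixture sizes.
TABLE1_PANEL_SIZES: dict[str, int] = {
    "Biliary liver cirrhosis": 41,
    "Alopecia areata": 41,
    "Prostate cancer": 39,
    "Systemic lupus erythematosus": 33,
    "Ulcerative colitis": 32,
    "Type 1 diabetes": 27,
    "Celiac disease": 26,
    "Parkinson's disease": 25,
    "Crohn's disease": 24,
    "Membranous nephropathy": 20,
    "Systemic sclerosis": 19,
    "Primary biliary cirrhosis": 15,
    "Colorectal cancer": 15,
    "Type 2 diabetes": 15,
    "Breast cancer": 14,
    "Melanoma": 14,
    "Rheumatoid arthritis": 14,
    "Asthma": 13,
    "Neuroblastoma": 10,
    "Polycystic ovary syndrome": 10,
    "Pancreatic cancer": 7,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the serial-founder chain.

    ``effective_size`` is the diploid size of each founding bottleneck;
    ``math.inf`` disables drift entirely (the no-drift limit).  Identical
    config + seed gives bit-identical output.
    """

    n_populations: int = 61
    n_snps: int = 10_000
    effective_size: float = 500
    n_founding_events_per_step: int = 1
    ancestral_freq_law: tuple = ("uniform", 0.05, 0.95)
    inter_population_distance_km: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 2:
            raise ValueError("n_populations must be >= 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not (self.effective_size >= 2):
            raise ValueError("effective_size must be >= 2")
        if self.n_founding_events_per_step < 1:
            raise ValueError("n_founding_events_per_step must be >= 1")


@dataclass(frozen=True)
class ClineSpec:
    """Additive frequency cline coupling a SNP subset to one climate variable.

    ``beta`` is the frequency shift per standard deviation of the variable;
    resulting frequencies are clamped to [0, 1].
    """

    snp_ids: tuple[str, ...]
    variable_name: str
    beta: float
    noise_sd: float = 0.0


def _draw_ancestral(law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        lo, hi = law[1], law[2]
        return rng.uniform(lo, hi, size=n)
    if kind == "fixed":
        return np.full(n, float(law[1]))
    raise ValueError(f"unknown ancestral frequency law {law!r}")


def simulate_serial_founder(config: SimulationConfig) -> tuple[FrequencyMatrix, PopulationPanel]:
    """Simulate the founder chain and return matrix plus panel.

    Population 0 holds ancestral frequencies; population k+1 arises from
    population k by ``n_founding_events_per_step`` rounds of binomial
    resampling of 2N gametes.  The panel records cumulative distance
    ``k * inter_population_distance_km``.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_snps, config.n_populations
    freq = np.empty((n, m))
    freq[:, 0] = _draw_ancestral(config.ancestral_freq_law, n, rng)
    drift = math.isfinite(config.effective_size)
    gametes = int(2 * config.effective_size) if drift else 0
    for k in range(1, m):
        p = freq[:, k - 1]
        if drift:
            for _ in range(config.n_founding_events_per_step):
                p = rng.binomial(gametes, p) / gametes
        freq[:, k] = p
    pops = [f"pop{k:03d}" for k in range(m)]
    snps = np.array([f"rs{i:07d}" for i in range(n)], dtype=object)
    matrix = FrequencyMatrix(
        snp_ids=snps,
        populations=pops,
        freq=freq,
        designated_allele=np.full(n, "A", dtype=object),
    )
    table = pd.DataFrame(
        {
            "region": "SYNTHETIC",
            "distance_km": np.arange(m) * config.inter_population_distance_km,
        },
        index=pd.Index(pops, name="population"),
    )
    return matrix, PopulationPanel(table)


def generate_climate(
    panel: PopulationPanel,
    spec: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Nine climate variables, each loaded on standardized distance.

    variable = distance_loading * z(distance) + Normal(0, noise_sd); zero
    loading gives a distance-independent variable.  Returns a DataFrame
    indexed by population with :data:`CLIMATE_VARIABLES` columns.
    """
    spec = DEFAULT_CLIMATE_SPEC if spec is None else spec
    rng = np.random.default_rng(seed)
    dist = panel.distances_km.to_numpy(dtype=float)
    z = (dist - dist.mean()) / dist.std()
    cols = {}
    for name in spec:
        loading = float(spec[name]["distance_loading"])
        noise_sd = float(spec[name].get("noise_sd", 0.0))
        cols[name] = loading * z + rng.normal(0.0, noise_sd, size=len(z)) if noise_sd > 0 else loading * z
    return pd.DataFrame(cols, index=panel.table.index)


def inject_cline(
    matrix: FrequencyMatrix,
    climate: pd.DataFrame,
    cline: ClineSpec,
    seed: int = 0,
) -> FrequencyMatrix:
    """Shift listed SNPs' frequencies along one climate variable.

    For each listed SNP and population j the frequency becomes
    clamp(p + beta * z_j + eps, 0, 1) with z the standardized variable and
    eps ~ Normal(0, noise_sd).  Unlisted SNPs are untouched.
    """
    if cline.variable_name not in climate.columns:
        raise KeyError(f"unknown climate variable {cline.variable_name!r}")
    rows = matrix.rows(cline.snp_ids)  # KeyError on unknown SNP
    rng = np.random.default_rng(seed)
    v = climate[cline.variable_name].to_numpy(dtype=float)
    z = (v - v.mean()) / v.std()
    freq = matrix.freq.copy()
    shift = cline.beta * z[None, :]
    if cline.noise_sd > 0:
        shift = shift + rng.normal(0.0, cline.noise_sd, size=(len(rows), len(z)))
    freq[rows] = np.clip(freq[rows] + shift, 0.0, 1.0)
    return FrequencyMatrix(
        snp_ids=matrix.snp_ids.copy(),
        populations=list(matrix.populations),
        freq=freq,
        designated_allele=matrix.designated_allele.copy(),
    )


def make_risk_sets(
    matrix: FrequencyMatrix,
    sizes: Sequence[int],
    cline_assignments: Mapping[int, Sequence[str]] | None = None,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> list[RiskSet]:
    """Disjoint risk-SNP panels of the requested sizes.

    ``cline_assignments`` maps a panel index to SNP ids (e.g. cline-injected
    ones) that must belong to that panel; remaining members are drawn
    uniformly without replacement from the unassigned pool.  Risk allele =
    designated allele.  Panel names mark neutral vs cline-coupled sets
    unless explicit ``names`` are given.
    """
    if sum(sizes) > matrix.n_snps:
        raise ValueError("requested panel sizes exceed the SNP pool")
    cline_assignments = dict(cline_assignments or {})
    rng = np.random.default_rng(seed)
    forced_all = [s for ids in cline_assignments.values() for s in ids]
    if len(set(forced_all)) != len(forced_all):
        raise ValueError("a SNP is assigned to more than one panel")
    forced_rows = set(matrix.rows(forced_all)) if forced_all else set()
    pool = np.array([i for i in range(matrix.n_snps) if i not in forced_rows], dtype=np.intp)
    free = rng.permutation(pool)
    alleles = {s: a for s, a in zip(matrix.snp_ids, matrix.designated_allele)}
    out, cursor = [], 0
    for idx, size in enumerate(sizes):
        forced = list(cline_assignments.get(idx, ()))
        if len(forced) > size:
            raise ValueError(f"panel {idx} smaller than its forced assignment")
        take = size - len(forced)
        chosen = list(free[cursor : cursor + take])
        cursor += take
        ids = forced + [matrix.snp_ids[i] for i in chosen]
        if names is not None:
            name = names[idx]
        else:
            tag = "cline" if forced else "neutral"
            name = f"disease{idx:02d}_{tag}"
        out.append(RiskSet(name, [(s, alleles[s]) for s in ids]))
    return out
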