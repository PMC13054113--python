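"""Synthetic Nellore-like populations for end-to-end testing of the pipeline.

Generates a multi-generation pedigree, gene-dropped SNP genotypes, contemporary
groups (farm x management group x birth year x season) and calving histories
from which the five binary stayability definitions are scored.  Breeding
values are built from marker effects, so genomic information is genuinely
informative for downstream single-step prediction.

The liability convention throughout is sigma_e^2 = 1; for a target liability
heritability h2 the additive variance is h2 / (1 - h2), so that
sigma_u^2 / (sigma_u^2 + sigma_e^2) = h2 holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .pedigree import Pedigree, UNKNOWN

#: months from conception to calving
GESTATION_MONTHS = 9
#: months between successive breeding opportunities (one season per year)
OPPORTUNITY_SPACING_MONTHS = 12

STAY_DEFINITIONS = {
    "stay48_2": (48, 2),
    "stay48_3": (48, 3),
    "stay54_2": (54, 2),
    "stay54_3": (54, 3),
    "stay72_3": (72, 3),
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic population.

    ``per_opportunity_base_rates`` are marginal conception probabilities per
    breeding season, calibrated once so the realized STAY48-2 incidence sits
    near 14% (the incidence scale reported for Nellore herds);
    ``heritability_liability`` is the per-opportunity liability heritability
    (reported range 0.16-0.22).
    """

    n_founders: int = 500
    n_generations: int = 4
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    heritability_liability: float = 0.20
    n_farms: int = 8
    n_mgmt_groups: int = 2
    years: tuple[int, int] = (2008, 2017)
    per_opportunity_base_rates: tuple[float, ...] = (0.17, 0.19, 0.26, 0.68, 0.76)
    sigma_cg2: float = 0.10
    missing_rate: float = 0.0
    prop_sires: float = 0.08
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 < self.heritability_liability < 1:
            raise ValueError("heritability_liability must be in (0, 1)")
        for name in ("n_founders", "n_generations", "n_snps", "n_farms", "n_mgmt_groups"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.missing_rate <= 0.1:
            raise ValueError("missing_rate must be in [0, 0.1]")
        if any(not 0 <= r <= 1 for r in self.per_opportunity_base_rates):
            raise ValueError("base rates must be probabilities")

    @property
    def sigma_u2(self) -> float:
        h2 = self.heritability_liability
        return h2 / (1.0 - h2)

    @property
    def sigma_e2(self) -> float:
        return 1.0


@dataclass
class SimTruth:
    """Simulation ground truth for parameter-recovery checks."""

    true_breeding_values: np.ndarray
    true_sigma_u2: float
    true_sigma_e2: float
    cg_effects: pd.Series
    marker_effects: np.ndarray


@dataclass
class CalvingHistory:
    """Ascending calving ages (months) of one female."""

    animal: str
    calving_ages_months: list[int]


@dataclass
class SimulatedPedigree(Pedigree):
    """Pedigree carrying the simulated covariates of each animal."""

    is_female: np.ndarray = None
    generation: np.ndarray = None
    birth_year: np.ndarray = None
    birth_month: np.ndarray = None
    farm: np.ndarray = None
    mgmt: np.ndarray = None

    @property
    def season(self) -> np.ndarray:
        # dry Apr-Sep, rainy Oct-Mar
        return np.where((self.birth_month >= 4) & (self.birth_month <= 9), "dry", "rainy")

    @property
    def cg_label(self) -> np.ndarray:
        return np.array(
            [
                f"F{f}_M{m}_Y{y}_{s}"
                for f, m, y, s in zip(self.farm, self.mgmt, self.birth_year, self.season)
            ],
            dtype=object,
        )


def _rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, salt)))


def simulate_pedigree(cfg: SimConfig) -> SimulatedPedigree:
    """Discrete-generation pedigree with a restricted sire pool.

    Each generation has ``n_founders`` animals; a small fraction of the
    previous generation's males (``prop_sires``) is used as sires, producing
    the half-sib family structure of a breeding program and, in small
    populations, nonzero inbreeding after a few generations.
    """
    rng = _rng(cfg, 1)
    per_gen = cfg.n_founders
    n = per_gen * cfg.n_generations
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    generation = np.repeat(np.arange(cfg.n_generations), per_gen)
    is_female = rng.random(n) < 0.5
    # guarantee each non-final generation has both sexes available for mating
    for g in range(cfg.n_generations):
        blk = slice(g * per_gen, (g + 1) * per_gen)
        if is_female[blk].all():
            is_female[g * per_gen] = False
        if not is_female[blk].any():
            is_female[g * per_gen] = True

    for g in range(1, cfg.n_generations):
        prev = np.arange((g - 1) * per_gen, g * per_gen)
        males = prev[~is_female[prev]]
        females = prev[is_female[prev]]
        n_sires = max(1, int(round(cfg.prop_sires * len(males))))
        sires = rng.choice(males, size=min(n_sires, len(males)), replace=False)
        blk = np.arange(g * per_gen, (g + 1) * per_gen)
        sire[blk] = rng.choice(sires, size=per_gen)
        dam[blk] = rng.choice(females, size=per_gen)

    y0, y1 = cfg.years
    span = (y1 - y0 + 1) / cfg.n_generations
    birth_year = (y0 + np.floor((generation + rng.random(n)) * span)).astype(int)
    birth_year = np.minimum(birth_year, y1)
    birth_month = rng.integers(1, 13, size=n)
    farm = rng.integers(0, cfg.n_farms, size=n)
    mgmt = rng.integers(0, cfg.n_mgmt_groups, size=n)
    ids = np.array([f"A{i + 1}" for i in range(n)], dtype=object)
    return SimulatedPedigree(
        animal_ids=ids,
        sire=sire,
        dam=dam,
        is_female=is_female,
        generation=generation,
        birth_year=birth_year,
        birth_month=birth_month,
        farm=farm,
        mgmt=mgmt,
    )


def simulate_genotypes(ped: Pedigree, cfg: SimConfig):
    """Gene-drop genotypes down the pedigree.

    Founder genotypes are Hardy-Weinberg draws at allele frequencies sampled
    uniformly within ``maf_range``; every non-founder receives one allele from
    each parent (heterozygous parents transmit either allele with probability
    1/2).  Returns ``(GenotypeMatrix, founder_freqs)``.
    """
    from .qc import MISSING, GenotypeMatrix

    rng = _rng(cfg, 2)
    n, m = ped.n, cfg.n_snps
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    codes = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        pat = _gamete(codes[s], rng) if s != UNKNOWN else (rng.random(m) < p).astype(np.int8)
        mat = _gamete(codes[d], rng) if d != UNKNOWN else (rng.random(m) < p).astype(np.int8)
        codes[i] = pat + mat
    if cfg.missing_rate > 0:
        mask = rng.random(codes.shape) < cfg.missing_rate
        codes[mask] = MISSING
    snp_ids = np.array([f"snp{j + 1}" for j in range(m)], dtype=object)
    # markers spread over 29 autosomes
    snp_map = pd.DataFrame(
        {
            "snp": snp_ids,
            "chrom": (np.arange(m) % 29 + 1).astype(str),
            "pos": (np.arange(m) // 29 + 1) * 10_000,
        }
    )
    g = GenotypeMatrix(np.asarray(ped.animal_ids), snp_ids, codes, snp_map)
    return g, p


def _gamete(parent_codes: np.ndarray, rng) -> np.ndarray:
    out = (parent_codes == 2).astype(np.int8)
    het = parent_codes == 1
    if het.any():
        out[het] = rng.random(int(het.sum())) < 0.5
    return out


def simulate_truth(ped: SimulatedPedigree, genotypes, founder_freqs, cfg: SimConfig) -> SimTruth:
    """True breeding values from marker effects plus contemporary-group effects.

    ``u_i = sum_j z_ij alpha_j`` with ``alpha_j ~ N(0, sigma_u2 / sum_j 2 p_j
    (1 - p_j))`` and ``z`` the genotype centered at founder frequencies, so
    ``var(u)`` among founders matches ``sigma_u2``.
    """
    rng = _rng(cfg, 3)
    p = founder_freqs
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    alpha = rng.normal(0.0, np.sqrt(cfg.sigma_u2 / denom), size=len(p))
    codes = genotypes.codes.astype(np.float64)
    codes[genotypes.codes == 5] = np.nan
    Z = np.nan_to_num(codes - 2.0 * p, nan=0.0)
    u = Z @ alpha
    labels = pd.unique(ped.cg_label)
    cg = pd.Series(rng.normal(0.0, np.sqrt(cfg.sigma_cg2), size=len(labels)), index=labels)
    return SimTruth(u, cfg.sigma_u2, cfg.sigma_e2, cg, alpha)


def simulate_calving_histories(
    ped: SimulatedPedigree, truth: SimTruth, cfg: SimConfig
) -> list[CalvingHistory]:
    """Per-female conception outcomes on the seasonal opportunity grid.

    At opportunity ``k`` the female conceives when ``mu_k + u_i + cg_i +
    eps_ik > 0`` with ``eps_ik ~ N(0, sigma_e2)``; ``mu_k`` is set by probit
    from the marginal base rate so realized incidences track the configured
    rates.  A conception at opportunity ``k`` yields a calving at
    ``exposure_age + 9 + 12 k`` months.
    """
    rng = _rng(cfg, 4)
    rates = np.clip(np.asarray(cfg.per_opportunity_base_rates, dtype=float), 1e-12, 1 - 1e-12)
    sd_total = np.sqrt(cfg.sigma_u2 + cfg.sigma_e2 + cfg.sigma_cg2)
    mu = ndtri(rates) * sd_total
    # map back through exact 0/1 rates
    mu = np.where(np.asarray(cfg.per_opportunity_base_rates) <= 0, -np.inf, mu)
    mu = np.where(np.asarray(cfg.per_opportunity_base_rates) >= 1, np.inf, mu)
    cg_eff = truth.cg_effects.reindex(ped.cg_label).to_numpy()
    females = np.flatnonzero(ped.is_female)
    exposure = rng.integers(10, 15, size=ped.n)
    histories = []
    for i in females:
        lia = mu + truth.true_breeding_values[i] + cg_eff[i] + rng.normal(0.0, 1.0, len(mu))
        ages = [
            int(exposure[i] + GESTATION_MONTHS + OPPORTUNITY_SPACING_MONTHS * k)
            for k in range(len(mu))
            if lia[k] > 0
        ]
        histories.append(CalvingHistory(ped.animal_ids[i], ages))
    return histories


def score_stayability(history: CalvingHistory, age_limit_months: int, min_calvings: int) -> int:
    """Score 2 (success) when at least ``min_calvings`` calvings occurred by
    ``age_limit_months``, else 1 (failure)."""
    if age_limit_months <= 0 or min_calvings <= 0:
        raise ValueError("age_limit_months and min_calvings must be positive")
    k = sum(1 for a in history.calving_ages_months if a <= age_limit_months)
    return 2 if k >= min_calvings else 1


def phenotype_table(ped: SimulatedPedigree, histories: list[CalvingHistory]) -> pd.DataFrame:
    """Score all five STAY definitions for every female with a history.

    ``record_year`` per trait (birth year plus the trait's age limit in whole
    years) drives the year-truncation used by LR validation.
    """
    pos = ped.positions([h.animal for h in histories])
    df = pd.DataFrame(
        {
            "animal": [h.animal for h in histories],
            "farm": ped.farm[pos],
            "mgmt": ped.mgmt[pos],
            "year": ped.birth_year[pos],
            "season": ped.season[pos],
            "cg": ped.cg_label[pos],
        }
    )
    for trait, (limit, k) in STAY_DEFINITIONS.items():
        df[trait] = [score_stayability(h, limit, k) for h in histories]
        df[f"record_year_{trait}"] = df["year"] + limit // 12
    return df


def simulate_threshold_phenotype(
    ped: SimulatedPedigree,
    truth: SimTruth,
    cfg: SimConfig,
    incidence: float = 0.14,
    salt: int = 5,
    females_only: bool = True,
) -> pd.DataFrame:
    """Single-threshold binary phenotype for model-based recovery studies.

    The one-opportunity special case of the calving model: score 2 when
    ``mu + u_i + cg_i + e_i > 0`` with ``e ~ N(0, 1)`` and ``mu`` chosen by
    probit so the marginal success rate is ``incidence``.  Unlike the
    composite STAY scores, this phenotype follows the threshold model exactly,
    so its liability heritability equals the configured one.
    ``females_only=False`` scores every animal, which maximizes the
    information on the additive variance in recovery studies.
    """
    rng = _rng(cfg, salt)
    sd_total = np.sqrt(cfg.sigma_u2 + cfg.sigma_e2 + cfg.sigma_cg2)
    mu = ndtri(incidence) * sd_total
    cg_eff = truth.cg_effects.reindex(ped.cg_label).to_numpy()
    females = np.flatnonzero(ped.is_female) if females_only else np.arange(ped.n)
    lia = mu + truth.true_breeding_values[females] + cg_eff[females]
    lia = lia + rng.normal(0.0, 1.0, len(females))
    df = pd.DataFrame(
        {
            "animal": ped.animal_ids[females],
            "farm": ped.farm[females],
            "mgmt": ped.mgmt[females],
            "year": ped.birth_year[females],
            "season": ped.season[females],
            "cg": ped.cg_label[females],
            "score": np.where(lia > 0, 2, 1),
        }
    )
    df["record_year"] = df["year"] + 2
    return df


def drop_small_cgs(phenos: pd.DataFrame, min_size: int = 3, cg_col: str = "cg") -> pd.DataFrame:
    """Drop records in contemporary groups with fewer than ``min_size`` records."""
    counts = phenos[cg_col].value_counts()
    keep = phenos[cg_col].map(counts) >= min_size
    return phenos[keep].reset_index(drop=True)


@dataclass
class SimDataset:
    ped: SimulatedPedigree
    genotypes: object
    founder_freqs: np.ndarray
    truth: SimTruth
    histories: list = field(default=None)
    phenotypes: pd.DataFrame = field(default=None)


def simulate_dataset(cfg: SimConfig, histories: bool = True) -> SimDataset:
    """Convenience wrapper producing a full coherent dataset for one seed."""
    ped = simulate_pedigree(cfg)
    geno, p = simulate_genotypes(ped, cfg)
    truth = simulate_truth(ped, geno, p, cfg)
    ds = SimDataset(ped, geno, p, truth)
    if histories:
        ds.histories = simulate_calving_histories(ped, truth, cfg)
        ds.phenotypes = phenotype_table(ped, ds.histories)
    return ds


# -- file formats -----------------------------------------------------------

def write_genotypes(g, path) -> None:
    """BLUPF90-style layout: animal ID, space, contiguous per-marker codes."""
    with open(path, "w") as fh:
        for aid, row in zip(g.animal_ids, g.codes):
            fh.write(f"{aid} {''.join(map(str, row))}\n")


def write_snp_map(g, path) -> None:
    g.snp_map.to_csv(path, index=False)


def write_phenotypes(phenos: pd.DataFrame, path) -> None:
    phenos.to_csv(path, index=False)
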