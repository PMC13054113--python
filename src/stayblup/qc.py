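"""Genotype quality control for SNP panels coded {0, 1, 2, 5 = missing}.

Filters, in a fixed logged order: sample call rate, marker call rate,
sex/mitochondrial chromosomes, duplicate map positions, Mendelian conflicts
against genotyped parents, minor allele frequency, and Hardy-Weinberg
equilibrium.  All marker statistics are computed on the sample-filtered
matrix *before* any marker is removed, so per-filter attribution depends on
filter order but the final retained set does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .pedigree import Pedigree, UNKNOWN

MISSING = 5

#: non-autosomal chromosome labels removed by default
EXCLUDED_CHROMS = frozenset({"X", "Y", "MT", "M", "30", "31", "32", "33"})


@dataclass
class GenotypeMatrix:
    """Animals x SNP codes with a marker map."""

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    codes: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError("codes shape does not match animal_ids x snp_ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, 5}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, animal_mask=None, snp_mask=None) -> "GenotypeMatrix":
        am = np.ones(self.n_animals, bool) if animal_mask is None else animal_mask
        sm = np.ones(self.n_snps, bool) if snp_mask is None else snp_mask
        return GenotypeMatrix(
            self.animal_ids[am],
            self.snp_ids[sm],
            self.codes[np.ix_(am, sm)],
            self.snp_map[self.snp_map["snp"].isin(self.snp_ids[sm])].reset_index(drop=True),
        )


def read_genotypes(path, map_path=None) -> GenotypeMatrix:
    """Read the two-column layout: animal ID then a contiguous code string."""
    ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise ValueError(f"expected 'ID codes' per line, got: {line[:60]!r}")
            ids.append(parts[0])
            rows.append(np.frombuffer(parts[1].encode(), dtype=np.uint8) - ord("0"))
    codes = np.vstack(rows).astype(np.int8)
    n_snps = codes.shape[1]
    if map_path is not None:
        snp_map = pd.read_csv(map_path, dtype={"chrom": str})
        snp_ids = snp_map["snp"].to_numpy(dtype=object)
        if len(snp_ids) != n_snps:
            raise ValueError("SNP map length does not match genotype columns")
    else:
        snp_ids = np.array([f"snp{j + 1}" for j in range(n_snps)], dtype=object)
        snp_map = pd.DataFrame({"snp": snp_ids, "chrom": "1", "pos": np.arange(1, n_snps + 1)})
    return GenotypeMatrix(np.array(ids, dtype=object), snp_ids, codes, snp_map)


@dataclass
class QCThresholds:
    """Default thresholds mirror routine beef-cattle panel cleaning."""

    sample_call_rate: float = 0.90
    marker_call_rate: float = 0.90
    maf: float = 0.05
    hwe_p: float = 1e-10
    mendel_rate: float = 0.01
    excluded_chroms: frozenset = EXCLUDED_CHROMS


#: marker filters in application order
MARKER_FILTERS = ("call_rate", "chromosome", "duplicate_position", "mendel", "maf", "hwe")


@dataclass
class QCReport:
    n_animals_in: int
    n_snps_in: int
    samples_removed: int
    marker_removed: dict = field(default_factory=dict)
    n_animals_out: int = 0
    n_snps_out: int = 0
    thresholds: QCThresholds = None

    def to_frame(self) -> pd.DataFrame:
        rows = [("samples_call_rate", self.samples_removed)]
        rows += [(f"markers_{k}", v) for k, v in self.marker_removed.items()]
        rows += [("animals_retained", self.n_animals_out), ("snps_retained", self.n_snps_out)]
        return pd.DataFrame(rows, columns=["filter", "count"])

    def __str__(self) -> str:
        lines = [f"samples in: {self.n_animals_in}, removed (call rate): {self.samples_removed}"]
        for k, v in self.marker_removed.items():
            lines.append(f"markers removed ({k}): {v}")
        lines.append(f"retained: {self.n_animals_out} animals x {self.n_snps_out} SNPs")
        return "\n".join(lines)


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Second-allele frequency per marker, missing codes excluded."""
    codes = g.codes
    obs = codes != MISSING
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        j = int(np.argmax(n_obs == 0))
        raise ValueError(f"marker {g.snp_ids[j]!r} has no observed genotypes")
    return (codes * obs).sum(axis=0) / (2.0 * n_obs)


def _hwe_pvalues(codes: np.ndarray) -> np.ndarray:
    """Chi-square (1 df, no continuity correction) Hardy-Weinberg test."""
    obs = codes != MISSING
    n = obs.sum(axis=0).astype(float)
    n0 = ((codes == 0) & obs).sum(axis=0)
    n1 = ((codes == 1) & obs).sum(axis=0)
    n2 = ((codes == 2) & obs).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (n1 + 2.0 * n2) / (2.0 * n)
        e0, e1, e2 = n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2
        stat = np.zeros(codes.shape[1])
        for o, e in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
            stat += term
    return chi2.sf(stat, df=1)


def _mendel_rates(codes: np.ndarray, animal_ids, ped: Pedigree) -> np.ndarray:
    """Per-marker rate of opposing homozygotes between genotyped parent-offspring pairs."""
    idx = {a: i for i, a in enumerate(animal_ids)}
    rows_c, rows_p = [], []
    for a, i in idx.items():
        pa = ped.index.get(a)
        if pa is None:
            continue
        for par in (ped.sire[pa], ped.dam[pa]):
            if par != UNKNOWN:
                j = idx.get(ped.animal_ids[par])
                if j is not None:
                    rows_c.append(i)
                    rows_p.append(j)
    if not rows_c:
        return np.zeros(codes.shape[1])
    C = codes[rows_c]
    P = codes[rows_p]
    valid = (C != MISSING) & (P != MISSING)
    conflict = (((C == 0) & (P == 2)) | ((C == 2) & (P == 0))) & valid
    n_valid = valid.sum(axis=0)
    return conflict.sum(axis=0) / np.maximum(n_valid, 1)


def apply_qc(
    g: GenotypeMatrix, ped: Pedigree | None = None, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the full marker/sample QC; see module docstring for the order."""
    th = thresholds or QCThresholds()
    report = QCReport(g.n_animals, g.n_snps, 0, thresholds=th)

    sample_cr = (g.codes != MISSING).mean(axis=1)
    keep_animals = sample_cr >= th.sample_call_rate
    report.samples_removed = int((~keep_animals).sum())
    codes = g.codes[keep_animals]
    animal_ids = g.animal_ids[keep_animals]
    if codes.shape[0] == 0:
        raise ValueError("no samples left after call-rate filtering")

    # all marker statistics on the sample-filtered, pre-marker-removal matrix
    obs = codes != MISSING
    call_rate = obs.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = (codes * obs).sum(axis=0) / np.maximum(2.0 * obs.sum(axis=0), 1.0)
    maf = np.minimum(p, 1.0 - p)
    hwe_p = _hwe_pvalues(codes)
    mendel = (
        _mendel_rates(codes, animal_ids, ped) if ped is not None else np.zeros(codes.shape[1])
    )
    chroms = g.snp_map.set_index("snp").reindex(g.snp_ids)["chrom"].astype(str).str.upper()
    on_bad_chrom = chroms.isin({c.upper() for c in th.excluded_chroms}).to_numpy()
    dup_drop = _duplicate_position_mask(g.snp_map, g.snp_ids, call_rate)

    fails = {
        "call_rate": call_rate < th.marker_call_rate,
        "chromosome": on_bad_chrom,
        "duplicate_position": dup_drop,
        "mendel": mendel > th.mendel_rate,
        "maf": maf < th.maf,
        "hwe": hwe_p < th.hwe_p,
    }
    removed = np.zeros(g.n_snps, dtype=bool)
    for name in MARKER_FILTERS:
        newly = fails[name] & ~removed
        report.marker_removed[name] = int(newly.sum())
        removed |= fails[name]

    keep_snps = ~removed
    if not keep_snps.any():
        raise ValueError("no markers left after QC")
    out = GenotypeMatrix(
        animal_ids,
        g.snp_ids[keep_snps],
        codes[:, keep_snps],
        g.snp_map[g.snp_map["snp"].isin(g.snp_ids[keep_snps])].reset_index(drop=True),
    )
    report.n_animals_out = out.n_animals
    report.n_snps_out = out.n_snps
    return out, report


def _duplicate_position_mask(snp_map, snp_ids, call_rate) -> np.ndarray:
    """Among markers sharing (chrom, pos), keep the one with the best call rate."""
    df = snp_map.set_index("snp").reindex(snp_ids)
    key = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
    drop = np.zeros(len(snp_ids), dtype=bool)
    order = np.lexsort((-call_rate, key.to_numpy()))
    seen = set()
    for j in order:
        k = key.iloc[j]
        if k in seen:
            drop[j] = True
        else:
            seen.add(k)
    return drop
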