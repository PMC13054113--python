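"""LR-method validation of genomic predictions.

Predictions from the whole dataset are compared with predictions from a
partial dataset truncated by record year, on focal animals: young genotyped
females whose own record falls in the removed window and whose progeny have
no records in the partial data.  Statistics (Legarra & Reverter's LR method):

    acc  = sqrt( cov(u_w, u_p) / ((1 - Fbar) sigma_u2) )
    bias = (mean(u_p) - mean(u_w)) / sigma_u
    b1   = cov(u_w, u_p) / var(u_p)          (dispersion; 1 is ideal)
    corr = cov / sqrt(var(u_w) var(u_p))

with sample moments (denominator n - 1) and Fbar the mean pedigree inbreeding
of the focal animals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .gibbs import GibbsConfig, run_gibbs
from .gmatrix import RelationshipSet
from .linear import ModelSpec, solve_mme
from .pedigree import Pedigree, UNKNOWN
from .scale import liability_to_observed


@dataclass
class ValidationReport:
    accuracy: float
    bias: float
    dispersion: float
    correlation: float
    n_focal: int
    model: str = ""
    trait: str = ""

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


def make_partial(
    phenos: pd.DataFrame,
    cutoff_years: int,
    ped: Pedigree,
    genotyped_ids,
    record_year_col: str = "record_year",
):
    """Split into whole/partial datasets and pick focal animals.

    Removes the last ``cutoff_years`` of record years.  Focal animals are
    genotyped females (all phenotyped animals are female for stayability)
    whose own record was removed and whose progeny contribute no record to
    the partial data.
    """
    if cutoff_years <= 0:
        raise ValueError("cutoff_years must be positive (no records removed otherwise)")
    years = phenos[record_year_col]
    cut = years.max() - cutoff_years
    partial = phenos[years <= cut].reset_index(drop=True)
    if partial.empty:
        raise ValueError("cutoff removes every record; use a smaller cutoff_years")
    removed = phenos[years > cut]
    genotyped = set(genotyped_ids)
    partial_animals = set(partial["animal"])

    # progeny with a partial record, per parent
    parents_with_partial_progeny = set()
    part_pos = ped.positions(partial["animal"])
    for i in part_pos:
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                parents_with_partial_progeny.add(ped.animal_ids[p])

    is_female = getattr(ped, "is_female", None)

    def female(a):
        return True if is_female is None else bool(is_female[ped.index[a]])

    focal = [
        a
        for a in removed["animal"]
        if a in genotyped
        and a not in partial_animals
        and a not in parents_with_partial_progeny
        and female(a)
    ]
    if not focal:
        raise ValueError("no focal animals; increase the data span or reduce cutoff_years")
    return phenos.reset_index(drop=True), partial, np.array(focal, dtype=object)


def lr_statistics(
    u_w: np.ndarray, u_p: np.ndarray, f_bar: float, sigma_u2_hat: float,
    model: str = "", trait: str = "",
) -> ValidationReport:
    """LR statistics on aligned whole/partial GEBV vectors of focal animals."""
    u_w = np.asarray(u_w, dtype=np.float64)
    u_p = np.asarray(u_p, dtype=np.float64)
    if u_w.shape != u_p.shape or u_w.ndim != 1 or len(u_w) < 2:
        raise ValueError("u_w and u_p must be aligned 1-d vectors of length >= 2")
    if sigma_u2_hat <= 0:
        raise ValueError("sigma_u2_hat must be positive")
    var_w = u_w.var(ddof=1)
    var_p = u_p.var(ddof=1)
    if var_w == 0 or var_p == 0:
        raise ValueError("zero variance in a GEBV vector")
    cov = float(np.cov(u_w, u_p, ddof=1)[0, 1])
    if cov < 0:
        warnings.warn("negative covariance between whole and partial GEBV; accuracy floored at 0")
    acc = float(np.sqrt(max(cov, 0.0) / ((1.0 - f_bar) * sigma_u2_hat)))
    bias = float((u_p.mean() - u_w.mean()) / np.sqrt(sigma_u2_hat))
    return ValidationReport(
        accuracy=acc,
        bias=bias,
        dispersion=float(cov / var_p),
        correlation=float(cov / np.sqrt(var_w * var_p)),
        n_focal=len(u_w),
        model=model,
        trait=trait,
    )


def run_lr_experiment(
    phenos: pd.DataFrame,
    ped: Pedigree,
    relset: RelationshipSet,
    trait: str,
    model: str,
    cutoff_years: int = 2,
    gibbs_cfg: GibbsConfig | None = None,
    h2_liability: float | None = None,
    record_year_col: str = "record_year",
    return_details: bool = False,
    sigma_u2_liability: float | None = None,
):
    """Whole/partial LR experiment for one trait and one model.

    Two-stage policy, mirroring routine practice: variance components are
    estimated once (threshold-model Gibbs on the whole data, or supplied via
    ``sigma_u2_liability``/``h2_liability``), then both the whole and the
    partial fit solve for breeding values with those components fixed, so the
    two predictions differ only in the data they see.  For the linear model
    the variance ratio is the liability heritability transformed to the
    observed scale at the whole-data incidence.  The accuracy denominator
    uses the whole-data variance estimate.
    """
    whole, partial, focal = make_partial(
        phenos, cutoff_years, ped, relset.genotyped_ids, record_year_col
    )
    gibbs_cfg = gibbs_cfg or GibbsConfig()
    spec_lia = ModelSpec(trait=trait, variance_ratio=1.0, scale="liability")

    su2_w = sigma_u2_liability
    if su2_w is None and (model == "threshold" or h2_liability is None):
        vc_chain = run_gibbs(whole, ped, relset.h_inv, spec_lia, gibbs_cfg, mode="threshold")
        su2_w = float(np.mean(vc_chain.samples["sigma_u2"]))
        if h2_liability is None:
            h2_liability = float(np.mean(vc_chain.samples["h2"]))
    if h2_liability is None and su2_w is not None:
        h2_liability = su2_w / (su2_w + 1.0)

    if model == "threshold":
        solve_cfg = replace(gibbs_cfg, sigma_u2_init=su2_w, sigma_e2_init=1.0)
        gebv_w = run_gibbs(
            whole, ped, relset.h_inv, spec_lia, solve_cfg,
            mode="threshold", fix_variances=True,
        ).gebv
        gebv_p = run_gibbs(
            partial, ped, relset.h_inv, spec_lia, solve_cfg,
            mode="threshold", fix_variances=True,
        ).gebv
        sigma_u2_obs = None
    elif model == "linear":
        alpha = float((whole[trait] == 2).mean())
        conv = liability_to_observed(h2_liability, alpha)
        sigma_u2_obs = conv.sigma_u2_obs
        spec_obs = ModelSpec(
            trait=trait, variance_ratio=conv.sigma_e2_obs / conv.sigma_u2_obs
        )
        gebv_w = solve_mme(whole, ped, relset.h_inv, spec_obs).gebv
        gebv_p = solve_mme(partial, ped, relset.h_inv, spec_obs).gebv
    else:
        raise ValueError(f"unknown model {model!r}")
    pos = ped.positions(focal)
    f_bar = float(ped.F[pos].mean())
    sigma_u2_hat = su2_w if model == "threshold" else sigma_u2_obs
    report = lr_statistics(
        gebv_w[pos], gebv_p[pos], f_bar, sigma_u2_hat, model=model, trait=trait
    )
    if return_details:
        return report, {
            "focal": focal,
            "gebv_whole": gebv_w,
            "gebv_partial": gebv_p,
            "focal_positions": pos,
            "sigma_u2_hat": sigma_u2_hat,
            "f_bar": f_bar,
        }
    return report
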