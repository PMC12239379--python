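"""Genotype-linked inference: QTL scans, triplet discovery, mediation.

The QTL scan is a fast matrix association of SNP dosages against phenotypes
(TI cytokine responses or per-probe methylation-change scores) after
two-stage residualization on age and sex.  SNPs associated with both the TI
outcome and a methylation change (p < 0.05 each) define candidate
SNP-probe-cytokine triplets, which are then subjected to bidirectional
causal mediation: Direction 1 treats the methylation change as the mediator
of the genetic effect on TI, Direction 2 swaps mediator and outcome.

Mediation uses the product-of-coefficients (quasi-Bayesian Monte Carlo)
approach for the linear no-interaction model pair

    m = a0 + a x + (covariates) + e1
    y = b0 + c' x + b m + (covariates) + e2

ACME draws are a^(s) * b^(s) with parameter vectors sampled from the
asymptotic normal of each OLS fit; the average direct effect is c'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError


def _residualize_age_sex(values: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Residualize columns of ``values`` (subjects x phenotypes) on age + sex."""
    x = np.column_stack([
        np.ones(len(covariates)),
        pd.to_numeric(covariates["age"]).to_numpy(dtype=float),
        (covariates["sex"] == "F").to_numpy(dtype=float),
    ])
    y = values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return pd.DataFrame(y - x @ beta, index=values.index, columns=values.columns)


def qtl_scan(
    dosages: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All-pairs linear association of SNP dosages with phenotypes.

    ``dosages`` is snp x (chrom, pos, subjects); ``phenotypes`` is
    subjects x phenotype.  Phenotypes are pre-residualized on age and sex
    when ``covariates`` (indexed by subject, with ``age`` and ``sex``) is
    given — a two-stage scheme, after which each (snp, phenotype) pair is a
    simple regression computed via cross-products with t and p on n-2 df.
    Monomorphic SNPs yield NA with a reason.
    """
    subj_cols = [c for c in dosages.columns if c not in ("chrom", "pos")]
    subjects = [s for s in subj_cols if s in phenotypes.index]
    if len(subjects) < 3:
        raise DomainError("qtl_scan: fewer than 3 shared subjects")
    ph = phenotypes.loc[subjects]
    if covariates is not None:
        ph = _residualize_age_sex(ph, covariates.loc[subjects])
    g = dosages[subjects].to_numpy(dtype=float)
    if np.isnan(g).any():
        means = np.nanmean(g, axis=1, keepdims=True)
        g = np.where(np.isnan(g), means, g)
    y = ph.to_numpy(dtype=float)
    n = len(subjects)
    gc = g - g.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=0, keepdims=True)
    sxx = np.sum(gc**2, axis=1)                       # per snp
    syy = np.sum(yc**2, axis=0)                       # per phenotype
    sxy = gc @ yc                                     # snp x phenotype
    mono = sxx == 0
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = sxy / sxx_safe[:, None]
    rss = syy[None, :] - beta * sxy
    rss = np.maximum(rss, 0.0)
    df = n - 2
    se = np.sqrt(rss / df / sxx_safe[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)  # underflow-safe minimum
    rows = []
    for i, snp in enumerate(dosages.index):
        for j, pheno in enumerate(ph.columns):
            if mono[i]:
                rows.append({"snp_id": snp, "phenotype": pheno, "beta": np.nan,
                             "se": np.nan, "t": np.nan, "p": np.nan,
                             "reason": "monomorphic"})
            else:
                rows.append({"snp_id": snp, "phenotype": pheno,
                             "beta": float(beta[i, j]), "se": float(se[i, j]),
                             "t": float(t[i, j]), "p": float(p[i, j]),
                             "reason": ""})
    return pd.DataFrame(rows)


def discover_triplets(
    qtl_ti: pd.DataFrame,
    qtl_dnamc: pd.DataFrame,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """SNPs associated with both TI and a methylation change at p < alpha.

    Cross-joins the significant rows of the two scans on snp_id; output is
    deterministically ordered by (snp_id, cytokine, probe).
    """
    ti_sig = qtl_ti[qtl_ti["p"] < alpha]
    dn_sig = qtl_dnamc[qtl_dnamc["p"] < alpha]
    merged = ti_sig.merge(dn_sig, on="snp_id", suffixes=("_ti", "_dnamc"))
    out = pd.DataFrame({
        "snp_id": merged["snp_id"],
        "cytokine": merged["phenotype_ti"],
        "probe_id": merged["phenotype_dnamc"],
        "p_ti": merged["p_ti"],
        "p_dnamc": merged["p_dnamc"],
    })
    return out.sort_values(["snp_id", "cytokine", "probe_id"]).reset_index(drop=True)


@dataclass
class MediationResult:
    """Quasi-Bayesian mediation estimates for one direction of one triplet."""

    direction: str                     # "D1" (mediator = DNAm-C) or "D2"
    acme: float
    acme_ci: tuple[float, float]
    acme_p: float
    ade: float
    ade_ci: tuple[float, float]
    ade_p: float
    total: float
    prop_mediated: float
    n_sims: int
    n_obs: int
    unstable_proportion: bool = False


def _sim_p(draws: np.ndarray) -> float:
    """Two-sided Monte-Carlo p with the add-one convention."""
    n = len(draws)
    lo = 1 + int(np.sum(draws <= 0))
    hi = 1 + int(np.sum(draws >= 0))
    return float(min(1.0, 2.0 * min(lo, hi) / (n + 1)))


def _ols(y: np.ndarray, x: np.ndarray):
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    b = xtx_inv @ (x.T @ y)
    resid = y - x @ b
    s2 = float(resid @ resid) / (n - p)
    return b, s2 * xtx_inv


def fit_mediation(
    x, m, y,
    covariates=None,
    *,
    n_sims: int = 1000,
    seed: int | None = None,
    rng=None,
    direction: str = "D1",
    min_obs: int = 30,
) -> MediationResult:
    """Causal mediation for one (exposure, mediator, outcome) triplet.

    Fits the mediator and outcome models by OLS, draws ``n_sims`` parameter
    vectors from each fit's asymptotic normal, and summarises the ACME draws
    a*b and ADE draws c'.  Point estimates are draw means, CIs the 2.5/97.5
    percentiles, p the two-sided simulation p (add-one convention), and the
    proportion mediated the median over draws of ACME/(ACME + ADE).  The
    proportion is flagged unstable when |total| < 2 SE(total).
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(x):
            cov = cov.T
    ok = (np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
          & np.isfinite(cov).all(axis=1))
    if ok.sum() < min_obs:
        raise DomainError(
            f"fit_mediation: only {int(ok.sum())} complete rows (< {min_obs})")
    x, m, y, cov = x[ok], m[ok], y[ok], cov[ok]
    ones = np.ones(len(x))
    xm = np.column_stack([ones, x, cov])             # mediator model design
    xy = np.column_stack([ones, x, m, cov])          # outcome model design
    try:
        bm, vm = _ols(m, xm)
        by, vy = _ols(y, xy)
    except np.linalg.LinAlgError as err:
        raise DomainError(f"fit_mediation: singular design ({err})") from None
    if rng is None:
        rng = np.random.default_rng(seed)
    a_draw = rng.multivariate_normal(bm, vm, size=n_sims, method="svd")[:, 1]
    out_draw = rng.multivariate_normal(by, vy, size=n_sims, method="svd")
    c_draw = out_draw[:, 1]
    b_draw = out_draw[:, 2]
    acme_draw = a_draw * b_draw
    total_draw = acme_draw + c_draw
    acme = float(acme_draw.mean())
    ade = float(c_draw.mean())
    total = float(total_draw.mean())
    total_se = float(total_draw.std())
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_draw = acme_draw / total_draw
    prop = float(np.median(prop_draw[np.isfinite(prop_draw)]))
    unstable = abs(total) < 2 * total_se
    return MediationResult(
        direction=direction,
        acme=acme,
        acme_ci=(float(np.percentile(acme_draw, 2.5)),
                 float(np.percentile(acme_draw, 97.5))),
        acme_p=_sim_p(acme_draw),
        ade=ade,
        ade_ci=(float(np.percentile(c_draw, 2.5)),
                float(np.percentile(c_draw, 97.5))),
        ade_p=_sim_p(c_draw),
        total=total,
        prop_mediated=prop,
        n_sims=n_sims,
        n_obs=int(ok.sum()),
        unstable_proportion=bool(unstable),
    )


def classify_directions(p1: float, p2: float, *, alpha: float = 0.05) -> str:
    if p1 < alpha and p2 >= alpha:
        return "unidirectional_D1"
    if p2 < alpha and p1 >= alpha:
        return "unidirectional_D2"
    if p1 < alpha and p2 < alpha:
        return "bidirectional"
    return "none"


def bidirectional_mediation(
    x, dnamc, ti,
    covariates=None,
    *,
    n_sims: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict:
    """Run mediation in both directions and triage the causal direction.

    Direction 1: mediator = methylation change, outcome = TI response.
    Direction 2: mediator = TI response, outcome = methylation change.
    Classification compares the two ACME p-values at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    d1 = fit_mediation(x, dnamc, ti, covariates, n_sims=n_sims, rng=rng,
                       direction="D1")
    d2 = fit_mediation(x, ti, dnamc, covariates, n_sims=n_sims, rng=rng,
                       direction="D2")
    return {
        "D1": d1,
        "D2": d2,
        "classification": classify_directions(d1.acme_p, d2.acme_p, alpha=alpha),
    }


def mediation_table(results: list[dict], triplets: pd.DataFrame) -> pd.DataFrame:
    """Flatten bidirectional results into the long output table."""
    rows = []
    for trip, res in zip(triplets.itertuples(index=False), results):
        for d in ("D1", "D2"):
            r: MediationResult = res[d]
            rows.append({
                "snp_id": trip.snp_id, "probe_id": trip.probe_id,
                "cytokine": trip.cytokine, "direction": d,
                "acme": r.acme, "acme_lo": r.acme_ci[0], "acme_hi": r.acme_ci[1],
                "acme_p": r.acme_p, "ade": r.ade, "total": r.total,
                "prop_mediated": r.prop_mediated,
                "unstable": r.unstable_proportion,
                "classification": res["classification"],
            })
    return pd.DataFrame(rows)


def cis_window_enrichment(
    cpg_annotation: pd.DataFrame,
    qtl_results: pd.DataFrame,
    snp_annotation: pd.DataFrame,
    *,
    window: int = 250_000,
    seed: int = 0,
) -> dict:
    """Compare cytokine-QTL p-values of cis SNPs against a random SNP set.

    A SNP is cis to a CpG when it lies on the same chromosome within
    ``window`` bases up- or downstream (inclusive bounds, 1-based
    coordinates).  A size-matched random SNP set is drawn (seeded) from the
    remaining SNPs and the two p-value sets are compared by a two-sample KS
    test; the QQ table holds the sorted quantiles of both.
    """
    snp_pos = snp_annotation[["chrom", "pos"]].copy()
    snp_pos["chrom"] = snp_pos["chrom"].astype(str)
    cis_ids: set = set()
    for _, row in cpg_annotation.iterrows():
        same = snp_pos[snp_pos["chrom"] == str(row["chromosome"])]
        hits = same[(same["pos"] - int(row["position"])).abs() <= window]
        cis_ids.update(hits.index)
    if not cis_ids:
        raise DomainError("cis_window_enrichment: no SNP in any cis window")
    pvals = qtl_results.set_index("snp_id")["p"]
    cis_p = pvals.reindex(sorted(cis_ids)).dropna().to_numpy()
    rest = pvals.index.difference(cis_ids)
    rng = np.random.default_rng(seed)
    pool = pvals.loc[rest].dropna()
    k = min(len(cis_p), len(pool))
    rand_p = pool.to_numpy()[rng.choice(len(pool), size=k, replace=False)]
    ks = stats.ks_2samp(cis_p, rand_p)
    qq = pd.DataFrame({
        "quantile": np.linspace(0, 1, 101),
        "cis_p": np.quantile(cis_p, np.linspace(0, 1, 101)),
        "random_p": np.quantile(rand_p, np.linspace(0, 1, 101)),
    })
    return {"cis_p": cis_p, "random_p": rand_p,
            "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
            "qq_table": qq, "n_cis": int(len(cis_p))}
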