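"""Per-probe regression machinery.

Longitudinal mixed-model EWAS (random subject intercept, REML), robust
regression of the trained-immunity outcome on methylation, the
residualize-and-difference association of methylation *changes* with the
outcome, Benjamini-Hochberg FDR, genomic inflation, seasonality covariates,
and the sensitivity refits (12-cell-type panel, seasonality, age subgroup).

The mixed model is fit by a dedicated profiled-REML solver for the
single-random-intercept structure: with V = sigma_e^2 (I + theta Z Z'), the
REML criterion is a one-dimensional function of theta whose GLS inner
problem has a closed form via per-subject aggregation.  This is exact (it
agrees with a generic mixed-model fitter to optimizer tolerance) and fast
enough to refit thousands of probes in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.robust.norms import HuberT
from statsmodels.robust.robust_linear_model import RLM
from statsmodels.stats.multitest import multipletests

from .exceptions import DomainError
from .preprocess import inverse_rank_normalize  # noqa: F401  (re-exported for designs)

SUGGESTIVE_P = 1e-5
SIGNIFICANT_Q = 0.05
CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.4549364...


# ---------------------------------------------------------------------------
# random-intercept REML


@dataclass
class RandomInterceptFit:
    params: np.ndarray
    cov_params: np.ndarray
    sigma2_e: float
    sigma2_u: float
    converged: bool
    singular: bool          # random-effect variance at the zero boundary
    n_obs: int

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))


def fit_random_intercept(
    y: np.ndarray, x: np.ndarray, groups: np.ndarray,
    *, theta_log_bounds: tuple[float, float] = (-12.0, 8.0),
) -> RandomInterceptFit:
    """REML fit of ``y = X b + u_group + e`` with a single random intercept.

    ``theta = sigma_u^2 / sigma_e^2`` is profiled: for fixed theta the GLS
    solution and residual quadratic form are computed with per-group sums
    (Woodbury identity on the block-diagonal V), and the scalar REML
    criterion is minimised by bounded search on log(theta).  A solution at
    the lower bound is flagged ``singular`` (variance component ~ 0).
    """
    n, p = x.shape
    if n <= p:
        raise DomainError("fit_random_intercept: more parameters than observations")
    order = np.argsort(groups, kind="stable")
    g = np.asarray(groups)[order]
    ys = y[order]
    xs = x[order]
    uniq, start = np.unique(g, return_index=True)
    counts = np.diff(np.append(start, n)).astype(float)
    idx = np.repeat(np.arange(len(uniq)), counts.astype(int))
    xg = np.zeros((len(uniq), p))
    np.add.at(xg, idx, xs)
    yg = np.bincount(idx, weights=ys)
    xtx = xs.T @ xs
    xty = xs.T @ ys
    yty = float(ys @ ys)

    def _solve(theta: float):
        w = theta / (1.0 + counts * theta)
        xtwx = xtx - (xg * w[:, None]).T @ xg
        xtwy = xty - (xg * w[:, None]).T @ yg
        ytwy = yty - float(w @ (yg * yg))
        b = np.linalg.solve(xtwx, xtwy)
        rss = ytwy - float(b @ xtwy)
        return b, xtwx, max(rss, 1e-300)

    def _negreml(log_theta: float) -> float:
        theta = np.exp(log_theta)
        _, xtwx, rss = _solve(theta)
        logdet_w = float(np.sum(np.log1p(counts * theta)))
        sign, logdet_x = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return np.inf
        return logdet_w + logdet_x + (n - p) * np.log(rss)

    res = optimize.minimize_scalar(
        _negreml, bounds=theta_log_bounds, method="bounded",
        options={"xatol": 1e-8})
    log_theta = float(res.x)
    singular = log_theta <= theta_log_bounds[0] + 0.05
    theta = 0.0 if singular else np.exp(log_theta)
    b, xtwx, rss = _solve(theta)
    s2e = rss / (n - p)
    cov = s2e * np.linalg.inv(xtwx)
    return RandomInterceptFit(b, cov, s2e, theta * s2e, bool(res.success),
                              singular, n)


# ---------------------------------------------------------------------------
# design construction


def build_design(
    samples: pd.DataFrame,
    *,
    covariates: tuple[str, ...] = ("age", "sex", "plate"),
    cell_fractions: pd.DataFrame | None = None,
    timepoints: tuple[str, ...] | None = None,
    include_seasonality: bool = False,
    subset: pd.Series | None = None,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Build the fixed-effect design matrix shared by all probes.

    Timepoint enters as an unordered factor with T0 as reference; sex as a
    female indicator; plate as drop-first dummies; cell fractions with the
    last column dropped (they sum to one); seasonality as the annual sin/cos
    harmonic of the collection date.  Returns (X, subject codes, names of the
    timepoint columns).
    """
    sheet = samples.set_index("sample_id", drop=False)
    if subset is not None:
        keep = subset.reindex(sheet.index).fillna(False).astype(bool)
        sheet = sheet.loc[keep]
    if timepoints is not None:
        sheet = sheet[sheet["timepoint"].isin(timepoints)]
        if sheet["timepoint"].nunique() < 2:
            raise DomainError("build_design: contrast needs >= 2 timepoints present")
    cols: dict[str, np.ndarray] = {"const": np.ones(len(sheet))}
    tp_levels = [t for t in ("T14", "T90") if (sheet["timepoint"] == t).any()]
    tp_names = []
    for t in tp_levels:
        name = f"tp_{t}"
        cols[name] = (sheet["timepoint"] == t).to_numpy(dtype=float)
        tp_names.append(name)
    for cov in covariates:
        if cov == "sex":
            cols["sex_F"] = (sheet["sex"] == "F").to_numpy(dtype=float)
        elif cov == "plate":
            levels = sorted(sheet["plate"].unique())[1:]
            for lev in levels:
                cols[f"plate_{lev}"] = (sheet["plate"] == lev).to_numpy(dtype=float)
        else:
            if cov not in sheet.columns:
                raise DomainError(f"build_design: covariate {cov!r} not in sample sheet")
            cols[cov] = pd.to_numeric(sheet[cov]).to_numpy(dtype=float)
    if cell_fractions is not None:
        cf = cell_fractions.reindex(sheet.index)
        if cf.isna().any().any():
            raise DomainError("build_design: cell fractions missing for some samples")
        for col in cf.columns[:-1]:  # drop last: fractions sum to one
            cols[f"cell_{col}"] = cf[col].to_numpy(dtype=float)
    if include_seasonality:
        terms = seasonality_terms(sheet["collection_date"])
        cols["season_sin"] = terms["season_sin"].to_numpy()
        cols["season_cos"] = terms["season_cos"].to_numpy()
    x = pd.DataFrame(cols, index=sheet.index)
    subj = pd.Categorical(sheet["subject_id"]).codes
    return x, subj, tp_names


# ---------------------------------------------------------------------------
# mixed-model EWAS


def fit_mixed_ewas(
    m_values: pd.DataFrame,
    samples: pd.DataFrame,
    *,
    covariates: tuple[str, ...] = ("age", "sex", "plate"),
    cell_fractions: pd.DataFrame | None = None,
    contrast: tuple[str, str] | None = None,
    include_seasonality: bool = False,
    subset: pd.Series | None = None,
    min_subjects: int = 10,
) -> pd.DataFrame:
    """Longitudinal EWAS with a random subject intercept.

    With ``contrast=None`` the overall time effect is the 2-df joint Wald
    test of the T14 and T90 terms and ``estimate`` is the T90 coefficient.
    With ``contrast=("T90", "T0")`` (etc.) only those two timepoints enter
    and the single timepoint coefficient is reported with a t-type test.
    Probes whose random-effect variance collapses to zero are refit by OLS
    with cluster-robust (by subject) standard errors and tagged in ``model``.

    Effects are on the M scale.
    """
    timepoints = None if contrast is None else tuple(sorted(contrast, key=_tp_order))
    x_df, subj, tp_names = build_design(
        samples, covariates=covariates, cell_fractions=cell_fractions,
        timepoints=timepoints, include_seasonality=include_seasonality,
        subset=subset)
    x = x_df.to_numpy()
    names = list(x_df.columns)
    sample_ids = x_df.index
    y_all = m_values.reindex(columns=sample_ids).to_numpy(dtype=float)
    n_subjects_design = len(np.unique(subj))
    if n_subjects_design < min_subjects:
        raise DomainError(
            f"fit_mixed_ewas: only {n_subjects_design} subjects in design")
    if contrast is None:
        joint_idx = [names.index(t) for t in tp_names]
        est_idx = names.index("tp_T90") if "tp_T90" in names else joint_idx[-1]
    else:
        if len(tp_names) != 1:
            raise DomainError("fit_mixed_ewas: pairwise contrast needs exactly one "
                              "non-reference timepoint in the data")
        est_idx = names.index(tp_names[0])
        joint_idx = [est_idx]

    full_rank = np.linalg.matrix_rank(x) == x.shape[1]
    rows = []
    for pi, probe in enumerate(m_values.index):
        y = y_all[pi]
        ok = np.isfinite(y)
        row = {"feature": probe, "estimate": np.nan, "se": np.nan,
               "stat": np.nan, "p": np.nan, "n_used": int(ok.sum()),
               "model": "na", "reason": ""}
        if ok.all() and full_rank:
            xs, ys, gs = x, y, subj
        else:
            xs, ys, gs = x[ok], y[ok], subj[ok]
            n_rep = np.unique(gs, return_counts=True)[1]
            if (n_rep >= 2).sum() < min_subjects or len(ys) <= x.shape[1]:
                row["reason"] = "insufficient_complete_observations"
                rows.append(row)
                continue
            if np.linalg.matrix_rank(xs) < xs.shape[1]:
                row["reason"] = "rank_deficient"
                rows.append(row)
                continue
        try:
            fit = fit_random_intercept(ys, xs, gs)
        except np.linalg.LinAlgError:
            row["reason"] = "rank_deficient"
            rows.append(row)
            continue
        if fit.singular:
            b, cov = _ols_cluster(ys, xs, gs)
            model = "ols_cluster"
        else:
            b, cov = fit.params, fit.cov_params
            model = "lmm_reml"
        row["estimate"] = b[est_idx]
        row["se"] = float(np.sqrt(cov[est_idx, est_idx]))
        if contrast is None and len(joint_idx) > 1:
            bb = b[joint_idx]
            vv = cov[np.ix_(joint_idx, joint_idx)]
            chi2 = float(bb @ np.linalg.solve(vv, bb))
            row["stat"] = chi2
            row["p"] = float(stats.chi2.sf(chi2, len(joint_idx)))
        else:
            t = row["estimate"] / row["se"]
            df = len(ys) - xs.shape[1]
            row["stat"] = t
            row["p"] = float(2.0 * stats.t.sf(abs(t), df))
        row["model"] = model
        row["n_used"] = len(ys)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature", drop=False)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out[["feature", "estimate", "se", "stat", "p", "q", "n_used",
                "model", "reason"]]


def _tp_order(tp: str) -> int:
    return {"T0": 0, "T14": 1, "T90": 2}[tp]


def _ols_cluster(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    """OLS with CR0 cluster-robust covariance (fallback for singular fits)."""
    b, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ b
    xtx_inv = np.linalg.inv(x.T @ x)
    meat = np.zeros((x.shape[1], x.shape[1]))
    for gval in np.unique(groups):
        sel = groups == gval
        s = x[sel].T @ resid[sel]
        meat += np.outer(s, s)
    return b, xtx_inv @ meat @ xtx_inv


# ---------------------------------------------------------------------------
# robust regression EWAS


def _rlm_fit(y: np.ndarray, x: np.ndarray, *, maxiter: int = 50,
             tol: float = 1e-8):
    model = RLM(y, x, M=HuberT(t=1.345))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=maxiter, tol=tol)
    converged = len(res.fit_history.get("deviance", [])) < maxiter
    return res, converged


def fit_robust_ewas(
    m_values: pd.DataFrame,
    ti: pd.Series,
    samples: pd.DataFrame,
    *,
    covariates: tuple[str, ...] = ("age", "sex", "plate"),
    cell_fractions: pd.DataFrame | None = None,
    subset: pd.Series | None = None,
) -> pd.DataFrame:
    """Robust (Huber) regression of the TI outcome on per-probe methylation.

    ``ti`` is the inverse-rank-normalized response indexed by subject;
    ``m_values`` holds one sample per subject (a single timepoint).  Huber
    M-estimation with tuning c = 1.345, IRLS to 1e-8 or 50 iterations;
    the reported coefficient is the methylation term.
    """
    x_df, _, _ = build_design(samples, covariates=covariates,
                              cell_fractions=cell_fractions, subset=subset)
    x_df = x_df.drop(columns=[c for c in x_df.columns if c.startswith("tp_")])
    sheet = samples.set_index("sample_id").loc[x_df.index]
    y = ti.reindex(sheet["subject_id"]).to_numpy(dtype=float)
    keep = np.isfinite(y)
    x0 = x_df.to_numpy()[keep]
    y0 = y[keep]
    ids = x_df.index[keep]
    m_all = m_values.reindex(columns=ids).to_numpy(dtype=float)
    rows = []
    for pi, probe in enumerate(m_values.index):
        mv = m_all[pi]
        ok = np.isfinite(mv)
        row = {"feature": probe, "estimate": np.nan, "se": np.nan,
               "stat": np.nan, "p": np.nan, "n_used": int(ok.sum()),
               "model": "rlm_huber", "reason": ""}
        if ok.sum() <= x0.shape[1] + 1:
            row["reason"] = "insufficient_complete_observations"
            rows.append(row)
            continue
        if np.nanstd(mv[ok]) == 0:
            row["reason"] = "constant predictor"
            rows.append(row)
            continue
        xx = np.column_stack([mv[ok], x0[ok]])
        res, converged = _rlm_fit(y0[ok], xx)
        t = res.params[0] / res.bse[0]
        row.update(estimate=float(res.params[0]), se=float(res.bse[0]),
                   stat=float(t),
                   p=float(2 * stats.norm.sf(abs(t))),
                   n_used=int(ok.sum()))
        if not converged:
            row["reason"] = "not_converged"
            warnings.warn(f"robust fit for probe {probe} did not converge")
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature", drop=False)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out[["feature", "estimate", "se", "stat", "p", "q", "n_used",
                "model", "reason"]]


# ---------------------------------------------------------------------------
# residualize-and-difference


def residualize_by_timepoint(
    m_values: pd.DataFrame,
    samples: pd.DataFrame,
    *,
    covariates: tuple[str, ...] = ("plate",),
    cell_fractions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Regress cell fractions and batch out of M values within each timepoint.

    Returns a matrix of OLS residuals (probe x sample), computed separately
    per timepoint so that timepoint-specific cell composition cannot leak
    into downstream change scores.  Residuals are orthogonal to the
    covariates by construction.
    """
    sheet = samples.set_index("sample_id", drop=False)
    out = pd.DataFrame(np.nan, index=m_values.index, columns=m_values.columns)
    for tp, grp in sheet.groupby("timepoint"):
        ids = grp.index.intersection(m_values.columns)
        if len(ids) == 0:
            continue
        x_df, _, _ = build_design(grp.loc[ids], covariates=covariates,
                                  cell_fractions=cell_fractions)
        x_df = x_df.drop(columns=[c for c in x_df.columns if c.startswith("tp_")])
        x = x_df.to_numpy()
        if x.shape[0] <= x.shape[1]:
            raise DomainError(
                f"residualize_by_timepoint: fewer samples than covariates at {tp}")
        y = m_values[ids].to_numpy(dtype=float).T  # samples x probes
        finite = np.isfinite(y).all(axis=1)
        if finite.all():
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta
        else:
            resid = np.full_like(y, np.nan)
            for j in range(y.shape[1]):
                okj = np.isfinite(y[:, j])
                if okj.sum() > x.shape[1]:
                    bj, *_ = np.linalg.lstsq(x[okj], y[okj, j], rcond=None)
                    resid[okj, j] = y[okj, j] - x[okj] @ bj
        out.loc[:, ids] = resid.T
    return out


def dnamc_association(
    residuals: pd.DataFrame,
    samples: pd.DataFrame,
    pair: tuple[str, str],
    ti: pd.Series,
    *,
    covariates: tuple[str, ...] = ("age", "sex"),
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Associate residualized methylation change (DNAm-C) with the TI outcome.

    ``pair = (later, earlier)``, e.g. ("T90", "T0"); the per-subject change
    is the difference of the residuals at the two timepoints, and the model
    is the same Huber robust regression with age and sex as covariates.
    """
    later, earlier = pair
    sheet = samples.set_index("sample_id", drop=False)
    by_tp = {tp: grp.set_index("subject_id")["sample_id"]
             for tp, grp in sheet.groupby("timepoint")}
    if later not in by_tp or earlier not in by_tp:
        raise DomainError(f"dnamc_association: timepoints {pair} not in sample sheet")
    shared = by_tp[later].index.intersection(by_tp[earlier].index)
    ti_sub = ti.reindex(shared)
    shared = shared[ti_sub.notna().to_numpy()]
    if len(shared) < min_pairs:
        raise DomainError(
            f"dnamc_association: only {len(shared)} complete pairs (< {min_pairs})")
    cols_l = by_tp[later].loc[shared]
    cols_e = by_tp[earlier].loc[shared]
    delta = (residuals[cols_l.to_numpy()].to_numpy(dtype=float)
             - residuals[cols_e.to_numpy()].to_numpy(dtype=float))
    dnamc = pd.DataFrame(delta, index=residuals.index, columns=shared)
    if np.nanstd(delta) == 0:
        raise DomainError("dnamc_association: constant predictor")
    subj_sheet = sheet.loc[cols_l.to_numpy()].copy()
    covs = {"const": np.ones(len(shared))}
    for cov in covariates:
        if cov == "sex":
            covs["sex_F"] = (subj_sheet["sex"] == "F").to_numpy(dtype=float)
        else:
            covs[cov] = pd.to_numeric(subj_sheet[cov]).to_numpy(dtype=float)
    x0 = pd.DataFrame(covs).to_numpy()
    y = ti.reindex(shared).to_numpy(dtype=float)
    rows = []
    for probe in dnamc.index:
        d = dnamc.loc[probe].to_numpy(dtype=float)
        ok = np.isfinite(d)
        row = {"feature": probe, "estimate": np.nan, "se": np.nan,
               "stat": np.nan, "p": np.nan, "n_used": int(ok.sum()),
               "model": "rlm_huber_dnamc", "reason": ""}
        if ok.sum() < min_pairs:
            row["reason"] = "insufficient_complete_observations"
        elif np.nanstd(d[ok]) == 0:
            row["reason"] = "constant predictor"
        else:
            xx = np.column_stack([d[ok], x0[ok]])
            res, converged = _rlm_fit(y[ok], xx)
            t = res.params[0] / res.bse[0]
            row.update(estimate=float(res.params[0]), se=float(res.bse[0]),
                       stat=float(t), p=float(2 * stats.norm.sf(abs(t))))
            if not converged:
                row["reason"] = "not_converged"
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature", drop=False)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out[["feature", "estimate", "se", "stat", "p", "q", "n_used",
                "model", "reason"]]


# ---------------------------------------------------------------------------
# multiplicity, inflation, seasonality


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NAs are excluded and re-inserted."""
    arr = np.asarray(pvals, dtype=float)
    ok = np.isfinite(arr)
    if np.any((arr[ok] < 0) | (arr[ok] > 1)):
        raise DomainError("bh_fdr: p-values outside [0, 1]")
    out = np.full(arr.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    return out


def compute_inflation(pvals, *, min_n: int = 100) -> float:
    """Genomic inflation factor: median chi2(1) quantile over its null median."""
    arr = np.asarray(pvals, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < min_n:
        raise DomainError(f"compute_inflation: need >= {min_n} p-values")
    if np.all(arr == arr[0]):
        warnings.warn("compute_inflation: degenerate p-value distribution")
    chi = stats.chi2.isf(np.median(arr), 1)
    return float(chi / CHI2_MEDIAN_1DF)


def seasonality_terms(dates) -> pd.DataFrame:
    """Annual harmonic encoding of collection dates: sin/cos of the year phase."""
    d = pd.to_datetime(pd.Series(dates))
    phase = 2 * np.pi * d.dt.dayofyear / 365.25
    return pd.DataFrame({"season_sin": np.sin(phase),
                         "season_cos": np.cos(phase)}, index=d.index)


# ---------------------------------------------------------------------------
# sensitivity wrappers


def sensitivity_refit(
    m_values: pd.DataFrame,
    samples: pd.DataFrame,
    base_results: pd.DataFrame,
    variant: str,
    *,
    covariates: tuple[str, ...] = ("age", "sex", "plate"),
    cell_fractions: pd.DataFrame | None = None,
    cell_fractions_12: pd.DataFrame | None = None,
    contrast: tuple[str, str] | None = None,
    suggestive_p: float = SUGGESTIVE_P,
) -> tuple[pd.DataFrame, dict]:
    """Refit the mixed-model EWAS under a sensitivity variant.

    ``variant`` is one of ``"cell12"`` (12-cell-type reference panel),
    ``"seasonality"`` (annual harmonic added to the covariates) or
    ``"age_gt_30"`` (subgroup of participants older than 30).  The report
    mirrors the concordance summaries of the primary analysis: fraction of
    base suggestive probes with the same effect direction and fraction
    remaining suggestive.
    """
    kwargs = dict(covariates=covariates, cell_fractions=cell_fractions,
                  contrast=contrast)
    if variant == "cell12":
        if cell_fractions_12 is None:
            raise DomainError("sensitivity_refit: cell12 variant needs the 12-type panel")
        kwargs["cell_fractions"] = cell_fractions_12
    elif variant == "seasonality":
        kwargs["include_seasonality"] = True
    elif variant == "age_gt_30":
        subset = samples.set_index("sample_id")["age"] > 30
        if not subset.any():
            raise DomainError("sensitivity_refit: empty age>30 subset")
        kwargs["subset"] = subset
    elif variant == "base":
        pass
    else:
        raise DomainError(f"sensitivity_refit: unknown variant {variant!r}")
    refit = fit_mixed_ewas(m_values, samples, **kwargs)
    top = base_results[base_results["p"] < suggestive_p]
    shared = top.index.intersection(refit.index)
    same_dir = (np.sign(top.loc[shared, "estimate"])
                == np.sign(refit.loc[shared, "estimate"]))
    retained = refit.loc[shared, "p"] < suggestive_p
    report = {
        "variant": variant,
        "n_base_suggestive": int(len(shared)),
        "frac_same_direction": float(same_dir.mean()) if len(shared) else np.nan,
        "frac_retained_suggestive": float(retained.mean()) if len(shared) else np.nan,
    }
    return refit, report
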