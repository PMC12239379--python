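"""Pre-modelling transformations and quality control.

Methylation is measured as a beta value (fraction methylated, in (0,1)) but
modelled on the M scale, its base-2 logit: M = log2(beta / (1 - beta)).  This
module holds the exact beta<->M transforms, Tukey outlier masking, whole-blood
cell-type deconvolution by constrained projection, the inverse-rank-normal
transform, the trained-immunity (TI) cytokine fold-change outcome, and the
PC-covariate association scan used to survey global structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DomainError

log = logging.getLogger(__name__)

#: default clamp applied to beta values of exactly 0 or 1 before the logit
BETA_EPS = 1e-6


@dataclass
class MethylationMatrix:
    """Probes x samples methylation values on a declared scale.

    ``values`` is a DataFrame with probe ids as the index and sample ids as
    columns; ``scale`` is ``"beta"`` or ``"M"``.  Optional probe annotation
    (chromosome/position/nearest gene) travels with the matrix.
    """

    values: pd.DataFrame
    scale: str = "beta"
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "M"):
            raise DomainError(f"scale must be 'beta' or 'M', got {self.scale!r}")
        if self.scale == "beta":
            vals = self.values.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                bad = np.nansum((vals < 0) | (vals > 1))
            if bad:
                raise DomainError(f"{bad} beta values outside [0, 1]")

    def to_m(self) -> "MethylationMatrix":
        if self.scale == "M":
            return self
        return MethylationMatrix(beta_to_m(self.values), "M", self.annotation)

    def to_beta(self) -> "MethylationMatrix":
        if self.scale == "beta":
            return self
        return MethylationMatrix(m_to_beta(self.values), "beta", self.annotation)


def beta_to_m(beta, eps: float = BETA_EPS):
    """Convert beta values to M values: M = log2(beta / (1 - beta)).

    Exact 0/1 values are clamped to ``eps`` / ``1 - eps`` with a warning;
    values outside [0, 1] raise :class:`DomainError`.  NA propagates.
    """
    arr = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nansum((arr < 0) | (arr > 1)):
            raise DomainError("beta values outside [0, 1]")
        n_clamped = int(np.nansum((arr == 0) | (arr == 1)))
    if n_clamped:
        warnings.warn(
            f"{n_clamped} beta values of exactly 0/1 clamped to [{eps}, {1 - eps}]",
            stacklevel=2,
        )
        arr = np.clip(arr, eps, 1 - eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2(arr / (1.0 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2**M / (1 + 2**M)."""
    arr = np.asarray(m, dtype=float)
    # logistic in base 2, written to avoid overflow for large |M|
    out = np.empty_like(arr, dtype=float)
    pos = arr >= 0
    with np.errstate(over="ignore", invalid="ignore"):
        out[pos] = 1.0 / (1.0 + np.exp2(-arr[pos]))
        e = np.exp2(arr[~pos])
        out[~pos] = e / (1.0 + e)
    out[np.isnan(arr)] = np.nan
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(out, index=m.index, name=m.name)
    if np.isscalar(m):
        return float(out)
    return out


def tukey_mask(values, k: float = 3.0):
    """Mask extreme outliers by the Tukey rule with extended fences.

    Values strictly below ``Q1 - k*IQR`` or strictly above ``Q3 + k*IQR``
    (k = 3 for "far out" outliers) are set to NaN.  Quartiles use the
    linear-interpolation (type-7) convention of :func:`numpy.nanquantile`.

    Returns ``(masked, mask)`` where ``mask`` is True at newly masked entries.
    """
    arr = np.asarray(values, dtype=float)
    obs = ~np.isnan(arr)
    if obs.sum() == 0:
        raise DomainError("tukey_mask: all values missing")
    if obs.sum() < 4:
        raise DomainError("tukey_mask: fewer than 4 non-missing values")
    q1, q3 = np.nanquantile(arr, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    with np.errstate(invalid="ignore"):
        mask = (arr < lo) | (arr > hi)
    masked = arr.copy()
    masked[mask] = np.nan
    if isinstance(values, pd.Series):
        return (
            pd.Series(masked, index=values.index, name=values.name),
            pd.Series(mask, index=values.index),
        )
    return masked, mask


def mask_matrix_outliers(matrix: pd.DataFrame, k: float = 3.0) -> pd.DataFrame:
    """Apply :func:`tukey_mask` probe-wise to a probes x samples matrix."""
    out = matrix.copy()
    vals = out.to_numpy(dtype=float)
    for i in range(vals.shape[0]):
        row = vals[i]
        if np.isfinite(row).sum() >= 4:
            vals[i], _ = tukey_mask(row, k=k)
    out.iloc[:, :] = vals
    return out


def inverse_rank_normalize(x, offset: float = 3.0 / 8.0):
    """Rank-based inverse normal transform with the Blom offset.

    z_i = Phi^-1((r_i - offset) / (n - 2*offset + 1)) with average ranks for
    ties; the default offset 3/8 gives the Blom variant standard in EWAS/GWAS.
    Missing values propagate.
    """
    arr = np.asarray(x, dtype=float)
    obs = ~np.isnan(arr)
    n = int(obs.sum())
    if n < 3:
        raise DomainError("inverse_rank_normalize: fewer than 3 non-missing values")
    vals = arr[obs]
    if np.all(vals == vals[0]):
        raise DomainError("inverse_rank_normalize: all values identical")
    ranks = stats.rankdata(vals, method="average")
    z = stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    out = np.full(arr.shape, np.nan)
    out[obs] = z
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    return out


def deconvolve_cells(
    betas: pd.DataFrame,
    reference: pd.DataFrame,
    *,
    sum_weight: float = 1e5,
) -> pd.DataFrame:
    """Estimate leukocyte fractions by reference-based constrained projection.

    Each sample's beta profile over the reference marker probes is modelled as
    a convex mixture of cell-type reference profiles: minimise ||x - R f||^2
    subject to f >= 0 and sum(f) = 1.  Solved as non-negative least squares on
    a system augmented with the row ``sum_weight * (1...1) f = sum_weight``,
    which enforces the simplex constraint to ~1e-10.

    Parameters
    ----------
    betas : probes x samples beta matrix (must contain the reference probes).
    reference : probes x cell-types mean beta profiles.
    """
    missing = reference.index.difference(betas.index)
    if len(missing):
        raise DomainError(
            f"deconvolve_cells: {len(missing)} reference probes absent from matrix"
        )
    ref = reference.loc[:, :].to_numpy(dtype=float)
    k = ref.shape[1]
    if ref.shape[0] < k:
        raise DomainError("deconvolve_cells: fewer marker probes than cell types")
    if np.linalg.matrix_rank(ref) < k:
        raise DomainError("deconvolve_cells: reference profiles are rank deficient")
    sub = betas.loc[reference.index]
    fracs = np.empty((sub.shape[1], k))
    aug_row = np.full((1, k), sum_weight)
    for j, col in enumerate(sub.columns):
        x = sub[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if ok.sum() < k:
            raise DomainError(
                f"deconvolve_cells: sample {col!r} has fewer observed marker "
                "probes than cell types"
            )
        a = np.vstack([ref[ok], aug_row])
        b = np.append(x[ok], sum_weight)
        f, _ = optimize.nnls(a, b)
        fracs[j] = f / f.sum()  # exact renormalisation of the ~1e-10 slack
    return pd.DataFrame(fracs, index=sub.columns, columns=reference.columns)


def compute_ti(
    cytokines: pd.DataFrame,
    *,
    batch_col: str = "batch",
) -> pd.DataFrame:
    """Compute the trained-immunity outcome from paired cytokine measurements.

    For each cytokine the raw response is ``log10(conc_T90 / conc_T0)``, the
    fold change in stimulated production three months after vaccination over
    baseline.  Batch effects are removed additively (residual on the batch
    factor plus the grand mean), then the corrected values are inverse-rank
    normalized.  Order: log10 -> batch residualization -> inverse rank.

    Parameters
    ----------
    cytokines : long table with columns ``subject_id``, ``cytokine``,
        ``conc_T0``, ``conc_T90`` and a batch label column.

    Returns
    -------
    DataFrame with columns subject_id, cytokine, ti_raw, ti_corrected, ti_norm.
    """
    required = {"subject_id", "cytokine", "conc_T0", "conc_T90", batch_col}
    miss = required - set(cytokines.columns)
    if miss:
        raise DomainError(f"compute_ti: missing columns {sorted(miss)}")
    df = cytokines.copy()
    incomplete = df["conc_T0"].isna() | df["conc_T90"].isna()
    if incomplete.any():
        dropped = df.loc[incomplete, "subject_id"].tolist()
        log.info("compute_ti: dropping %d subjects with missing pairs: %s",
                 len(dropped), dropped)
        df = df.loc[~incomplete]
    bad = (df["conc_T0"] <= 0) | (df["conc_T90"] <= 0)
    if bad.any():
        subjects = sorted(df.loc[bad, "subject_id"].unique().tolist())
        raise DomainError(f"compute_ti: nonpositive concentrations for subjects {subjects}")
    df = df.reset_index(drop=True)
    df["ti_raw"] = np.log10(df["conc_T90"] / df["conc_T0"])

    def _correct(group: pd.DataFrame) -> pd.Series:
        grand = group["ti_raw"].mean()
        batch_mean = group.groupby(batch_col)["ti_raw"].transform("mean")
        return group["ti_raw"] - batch_mean + grand

    parts = []
    for _, grp in df.groupby("cytokine", sort=False):
        corrected = _correct(grp)
        out = grp[["subject_id", "cytokine", "ti_raw"]].copy()
        out["ti_corrected"] = corrected
        try:
            out["ti_norm"] = inverse_rank_normalize(corrected.to_numpy())
        except DomainError:
            warnings.warn("compute_ti: degenerate fold changes; "
                          "normalized values set to NA")
            out["ti_norm"] = np.nan
        parts.append(out)
    return pd.concat(parts, ignore_index=True)


@dataclass
class PcaScanResult:
    """Output of :func:`pca_covariate_scan`."""

    p_values: pd.DataFrame            # PCs x covariates
    variance_ratio: pd.Series         # per-PC fraction of total variance
    scores: pd.DataFrame = field(repr=False)  # samples x PCs

    @property
    def cumulative_variance(self) -> float:
        return float(self.variance_ratio.sum())


def pca_covariate_scan(
    m_values: pd.DataFrame,
    covariates: pd.DataFrame,
    k: int = 30,
) -> PcaScanResult:
    """Associate top methylation PCs with sample covariates.

    PCA is run on the probe-centered M-value matrix (missing entries filled
    with the probe mean for the decomposition only); each of the top ``k``
    sample-space PCs is then tested against each covariate with a univariable
    linear model (numeric covariates: regression slope t-test; categorical
    covariates: the equivalent one-way F-test).  Constant covariates yield NA
    with a warning.
    """
    common = m_values.columns.intersection(covariates.index)
    if len(common) < 3:
        raise DomainError("pca_covariate_scan: fewer than 3 shared samples")
    x = m_values[common].to_numpy(dtype=float)
    if k > min(x.shape):
        raise DomainError(f"pca_covariate_scan: k={k} exceeds matrix rank bound")
    row_mean = np.nanmean(x, axis=1, keepdims=True)
    x = np.where(np.isnan(x), row_mean, x) - row_mean
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var_ratio = s**2 / np.sum(s**2)
    scores = (vt[:k].T * s[:k])  # samples x k
    pcs = [f"PC{i + 1}" for i in range(k)]
    score_df = pd.DataFrame(scores, index=common, columns=pcs)

    pvals = pd.DataFrame(index=pcs, columns=covariates.columns, dtype=float)
    for cov in covariates.columns:
        cvals = covariates.loc[common, cov]
        if cvals.nunique(dropna=True) < 2:
            warnings.warn(f"covariate {cov!r} is constant; association set to NA")
            continue
        for i, pc in enumerate(pcs):
            y = scores[:, i]
            if pd.api.types.is_numeric_dtype(cvals):
                ok = cvals.notna().to_numpy()
                res = stats.linregress(cvals.to_numpy(dtype=float)[ok], y[ok])
                pvals.loc[pc, cov] = res.pvalue
            else:
                groups = [y[(cvals == lev).to_numpy()] for lev in cvals.dropna().unique()]
                groups = [g for g in groups if len(g) > 0]
                pvals.loc[pc, cov] = stats.f_oneway(*groups).pvalue
    return PcaScanResult(pvals, pd.Series(var_ratio[:k], index=pcs), score_df)
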