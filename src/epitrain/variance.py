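"""Variance in the trained-immunity response explained by omics layers.

Implements the greedy Spearman scheme: per-layer candidate selection by
marginal Spearman association with the TI outcome (p < 0.05), collinearity
pruning at |rho| > 0.4 (dropping the member with the weaker TI association),
a multivariate OLS fit per layer and combined, adjusted R^2 as the measure
of explained variance, and a randomization null that repeats the whole
select -> prune -> fit pipeline on randomly drawn feature sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DomainError

SELECT_P = 0.05
COLLINEARITY_RHO = 0.4


def _spearman_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return np.nan, np.nan
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def select_layer_features(
    layer: pd.DataFrame,
    ti: pd.Series,
    *,
    p_threshold: float = SELECT_P,
    fixed_features: list[str] | None = None,
) -> list[str]:
    """Candidate predictors of a layer: marginal Spearman p < threshold.

    ``fixed_features`` bypasses the marginal screen — used for the
    methylation layer, where the externally supplied EWAS-significant CpG
    list is taken as-is.  Constant features are excluded.
    """
    if layer.shape[1] == 0:
        warnings.warn("select_layer_features: empty layer")
        return []
    if fixed_features is not None:
        return [f for f in fixed_features if f in layer.columns]
    y = ti.reindex(layer.index).to_numpy(dtype=float)
    selected = []
    for feat in layer.columns:
        x = layer[feat].to_numpy(dtype=float)
        _, p = _spearman_p(x, y)
        if np.isfinite(p) and p < p_threshold:
            selected.append(feat)
    return selected


def prune_collinear(
    layer: pd.DataFrame,
    candidates: list[str],
    ti: pd.Series,
    *,
    rho_threshold: float = COLLINEARITY_RHO,
) -> list[str]:
    """Greedy collinearity pruning within a layer.

    While any remaining candidate pair has Spearman |rho| > threshold, the
    pair with the largest |rho| is resolved by dropping the member with the
    weaker marginal TI association (larger Spearman p).  Iteration order is
    deterministic: descending |rho|, ties broken lexicographically by the
    feature-id pair; equal TI p drops the lexicographically later feature.
    The absolute correlation is used because anti-correlated duplicates are
    just as collinear as correlated ones.
    """
    cands = [c for c in candidates if c in layer.columns]
    if len(cands) < 2:
        return list(cands)
    y = ti.reindex(layer.index).to_numpy(dtype=float)
    ti_p = {}
    for feat in cands:
        _, p = _spearman_p(layer[feat].to_numpy(dtype=float), y)
        ti_p[feat] = p if np.isfinite(p) else np.inf
    sub = layer[cands]
    rho = sub.corr(method="spearman").abs()
    pairs = []
    for i, a in enumerate(cands):
        for b in cands[i + 1:]:
            r = rho.loc[a, b]
            if np.isfinite(r) and r > rho_threshold:
                pairs.append((float(r), a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = set(cands)
    for _, a, b in pairs:
        if a in alive and b in alive:
            if ti_p[a] < ti_p[b]:
                alive.discard(b)
            elif ti_p[b] < ti_p[a]:
                alive.discard(a)
            else:
                alive.discard(max(a, b))
    return [c for c in cands if c in alive]


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        raise DomainError("adjusted_r2: n must exceed p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fit_variance_model(features: pd.DataFrame, ti: pd.Series) -> dict:
    """OLS of the TI outcome on the selected features.

    Returns {"r2", "adj_r2", "n", "p"}; raises when the design is too wide
    (prune harder or select fewer features).
    """
    y = ti.reindex(features.index).to_numpy(dtype=float)
    x = features.to_numpy(dtype=float)
    ok = np.isfinite(y) & np.isfinite(x).all(axis=1)
    n, p = int(ok.sum()), x.shape[1]
    if p >= n - 1:
        raise DomainError(
            f"fit_variance_model: {p} features for {n} subjects; prune the "
            "candidate set further")
    res = sm.OLS(y[ok], sm.add_constant(x[ok])).fit()
    return {"r2": float(res.rsquared),
            "adj_r2": float(adjusted_r2(res.rsquared, n, p)),
            "n": n, "p": p}


def variance_report(
    layers: dict[str, pd.DataFrame],
    ti: pd.Series,
    *,
    fixed_features: dict[str, list[str]] | None = None,
    p_threshold: float = SELECT_P,
    rho_threshold: float = COLLINEARITY_RHO,
) -> dict:
    """Per-layer and combined explained variance via select -> prune -> fit.

    The combined model concatenates the per-layer pruned sets (cross-layer
    collinearity is deliberately left in place).  Layers whose pruned set is
    empty report adj R^2 of 0.
    """
    fixed_features = fixed_features or {}
    per_layer = {}
    combined_cols = []
    frames = []
    for name, layer in layers.items():
        cand = select_layer_features(layer, ti, p_threshold=p_threshold,
                                     fixed_features=fixed_features.get(name))
        pruned = prune_collinear(layer, cand, ti, rho_threshold=rho_threshold)
        entry = {"selected": cand, "pruned": pruned}
        if pruned:
            entry.update(fit_variance_model(layer[pruned], ti))
        else:
            entry.update({"r2": 0.0, "adj_r2": 0.0, "n": len(layer), "p": 0})
        per_layer[name] = entry
        if pruned:
            frames.append(layer[pruned].add_prefix(f"{name}:"))
            combined_cols.extend(pruned)
    if frames:
        combined = fit_variance_model(pd.concat(frames, axis=1, join="inner"), ti)
    else:
        combined = {"r2": 0.0, "adj_r2": 0.0, "n": len(ti), "p": 0}
    return {"layers": per_layer, "combined": combined}


def randomization_null(
    pool: pd.DataFrame,
    k: int,
    ti: pd.Series,
    *,
    B: int = 1000,
    seed: int = 0,
    observed_adj_r2: float | None = None,
    p_threshold: float = SELECT_P,
    rho_threshold: float = COLLINEARITY_RHO,
) -> dict:
    """Null distribution of adjusted R^2 from random feature draws.

    Each of the B draws samples ``k`` features from ``pool`` without
    replacement and runs the full select -> prune -> fit pipeline.  The
    empirical p for an observed value uses the add-one convention
    p = (1 + #{null >= observed}) / (B + 1).
    """
    if B < 1:
        raise DomainError("randomization_null: B must be >= 1")
    if pool.shape[1] < k:
        raise DomainError(
            f"randomization_null: pool has {pool.shape[1]} features (< k={k})")
    rng = np.random.default_rng(seed)
    null = np.zeros(B)
    cols = np.asarray(pool.columns)
    for b in range(B):
        draw = list(cols[rng.choice(len(cols), size=k, replace=False)])
        sub = pool[draw]
        cand = select_layer_features(sub, ti, p_threshold=p_threshold)
        pruned = prune_collinear(sub, cand, ti, rho_threshold=rho_threshold)
        if pruned:
            null[b] = fit_variance_model(sub[pruned], ti)["adj_r2"]
    out = {"null_mean": float(null.mean()),
           "null_q95": float(np.quantile(null, 0.95)),
           "null": null}
    if observed_adj_r2 is not None:
        out["empirical_p"] = float(
            (1 + np.sum(null >= observed_adj_r2)) / (B + 1))
    return out


def compute_prs(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.Series:
    """Polygenic score = sum of beta_j * dosage_j over the weighted SNPs.

    ``weights`` has columns ``snp`` and ``beta``; missing dosages are
    mean-imputed per SNP (logged via warning).
    """
    w = weights.set_index("snp")["beta"]
    shared = w.index.intersection(dosages.index)
    if len(shared) == 0:
        raise DomainError("compute_prs: no overlapping SNPs between weights and dosages")
    subj_cols = [c for c in dosages.columns if c not in ("chrom", "pos")]
    d = dosages.loc[shared, subj_cols].to_numpy(dtype=float)
    if np.isnan(d).any():
        warnings.warn("compute_prs: mean-imputing missing dosages")
        means = np.nanmean(d, axis=1, keepdims=True)
        d = np.where(np.isnan(d), means, d)
    score = w.loc[shared].to_numpy() @ d
    return pd.Series(score, index=subj_cols, name="prs")


def derive_prs_weights(
    dosages: pd.DataFrame,
    ti: pd.Series,
    *,
    subjects: list[str] | None = None,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Marginal per-SNP OLS weights from a training split.

    Regresses the TI outcome on each SNP dosage in the training subjects and
    keeps SNPs at p < threshold with their betas as PRS weights.
    """
    subj_cols = [c for c in dosages.columns if c not in ("chrom", "pos")]
    if subjects is not None:
        subj_cols = [s for s in subj_cols if s in set(subjects)]
    y = ti.reindex(subj_cols).to_numpy(dtype=float)
    rows = []
    for snp in dosages.index:
        g = dosages.loc[snp, subj_cols].to_numpy(dtype=float)
        ok = np.isfinite(g) & np.isfinite(y)
        if ok.sum() < 3 or np.std(g[ok]) == 0:
            continue
        res = stats.linregress(g[ok], y[ok])
        if res.pvalue < p_threshold:
            rows.append({"snp": snp, "beta": float(res.slope),
                         "p": float(res.pvalue)})
    return pd.DataFrame(rows, columns=["snp", "beta", "p"])
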