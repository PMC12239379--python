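"""Trajectory taxonomy, enrichment and replication of significant probes.

A probe's trajectory is the sign pair of its mean beta-value change at day 14
and day 90 relative to baseline: down_down (decreased at both), down_up
(decreased then increased), up_down, up_up, or flat when either delta is
exactly zero.  Baseline methylation state is tri-classed as hypo (<0.3),
intermediate, or hyper (>0.7) mean beta; directions of change are tested for
enrichment in the baseline classes with Fisher's exact test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import bh_fdr
from .exceptions import DomainError

TRAJECTORY_CLASSES = ("down_down", "down_up", "up_down", "up_up", "flat")


def classify_trajectory(d14, d90):
    """Map (delta14, delta90) sign pairs to trajectory classes.

    Scalars return a string; array input returns an object array.  A delta of
    exactly zero in either interval yields "flat"; NA yields NA.
    """
    d14a = np.asarray(d14, dtype=float)
    d90a = np.asarray(d90, dtype=float)
    scalar = d14a.ndim == 0
    d14a, d90a = np.atleast_1d(d14a), np.atleast_1d(d90a)
    out = np.empty(d14a.shape, dtype=object)
    for i, (a, b) in enumerate(zip(d14a, d90a)):
        if math.isnan(a) or math.isnan(b):
            out[i] = None
        elif a == 0 or b == 0:
            out[i] = "flat"
        else:
            out[i] = ("down" if a < 0 else "up") + "_" + ("down" if b < 0 else "up")
    return out[0] if scalar else out


def compute_deltas(
    betas: pd.DataFrame,
    samples: pd.DataFrame,
    *,
    baseline: str = "T0",
) -> pd.DataFrame:
    """Per-probe mean beta differences d14 = T14 - T0 and d90 = T90 - T0.

    Means are taken over subjects present at both the baseline and the later
    timepoint (paired means), on the beta scale.
    """
    sheet = samples.set_index("sample_id", drop=False)
    by_tp = {tp: grp.set_index("subject_id")["sample_id"]
             for tp, grp in sheet.groupby("timepoint")}
    if baseline not in by_tp:
        raise DomainError(f"compute_deltas: baseline {baseline!r} absent")
    out = {}
    for tp, label in (("T14", "d14"), ("T90", "d90")):
        if tp not in by_tp:
            out[label] = pd.Series(np.nan, index=betas.index)
            continue
        shared = by_tp[tp].index.intersection(by_tp[baseline].index)
        late = betas[by_tp[tp].loc[shared].to_numpy()].to_numpy(dtype=float)
        base = betas[by_tp[baseline].loc[shared].to_numpy()].to_numpy(dtype=float)
        out[label] = pd.Series(np.nanmean(late - base, axis=1), index=betas.index)
    df = pd.DataFrame(out)
    df["class"] = classify_trajectory(df["d14"].to_numpy(), df["d90"].to_numpy())
    return df


def classify_baseline(
    mean_beta,
    *,
    hypo_threshold: float = 0.3,
    hyper_threshold: float = 0.7,
):
    """Tri-class baseline methylation state from mean beta values."""
    arr = np.asarray(mean_beta, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.where(arr < hypo_threshold, "hypo",
                   np.where(arr > hyper_threshold, "hyper", "intermediate"))
    out = out.astype(object)
    out[np.isnan(arr)] = None
    return out[0] if scalar else out


@dataclass
class EnrichmentResult:
    table: np.ndarray
    odds_ratio: float
    p_value: float


def fisher_enrichment(table) -> EnrichmentResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    The two-sided p sums hypergeometric probabilities of all tables (with the
    observed margins) no more probable than the observed one; the reported
    odds ratio is the sample (cross-product) estimate.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise DomainError("fisher_enrichment: table must be 2x2")
    if np.any(tab < 0) or np.any(tab != np.floor(tab)):
        raise DomainError("fisher_enrichment: counts must be nonnegative integers")
    tab = tab.astype(int)
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    a, b, c, d = tab.ravel()
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(tab, float(odds), float(p))


def direction_baseline_enrichment(
    deltas: pd.Series,
    baseline_class: pd.Series,
) -> EnrichmentResult:
    """Enrichment of increased/decreased probes in hypo vs hyper baseline state.

    Builds the 2x2 table (rows: increased/decreased; columns: hypo/hyper,
    intermediate probes excluded) and applies :func:`fisher_enrichment`.
    """
    keep = baseline_class.isin(["hypo", "hyper"]) & (deltas != 0) & deltas.notna()
    d = deltas[keep]
    c = baseline_class[keep]
    table = [
        [int(((d > 0) & (c == "hypo")).sum()), int(((d > 0) & (c == "hyper")).sum())],
        [int(((d < 0) & (c == "hypo")).sum()), int(((d < 0) & (c == "hyper")).sum())],
    ]
    return fisher_enrichment(table)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Exact permutation p for Spearman rho at small n (<= 9)."""
    ry = stats.rankdata(y)
    rx = stats.rankdata(x)
    n = len(x)
    obs = abs(rho)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx[list(perm)], ry)[0, 1]
        count += abs(r) >= obs - 1e-12
        total += 1
    return count / total


def correlate_changes(
    cpg_deltas: pd.DataFrame,
    layer: pd.DataFrame,
    *,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Spearman-correlate per-subject CpG changes with another layer.

    Both inputs are subjects x features; every (CpG, layer feature) pair with
    at least ``min_pairs`` complete observations is tested (exact permutation
    p for n <= 9, t-approximation otherwise), and BH-FDR is applied across
    the whole pair grid.  Constant vectors are skipped with a reason.
    """
    shared = cpg_deltas.index.intersection(layer.index)
    rows = []
    for cpg in cpg_deltas.columns:
        x_full = cpg_deltas.loc[shared, cpg].to_numpy(dtype=float)
        for feat in layer.columns:
            y_full = layer.loc[shared, feat].to_numpy(dtype=float)
            ok = np.isfinite(x_full) & np.isfinite(y_full)
            row = {"cpg": cpg, "feature": feat, "n": int(ok.sum()),
                   "rho": np.nan, "p": np.nan, "reason": ""}
            if ok.sum() < min_pairs:
                row["reason"] = "insufficient_pairs"
            elif np.std(x_full[ok]) == 0 or np.std(y_full[ok]) == 0:
                row["reason"] = "constant vector"
            else:
                x, y = x_full[ok], y_full[ok]
                rho, p = stats.spearmanr(x, y)
                if len(x) <= 9:
                    p = _spearman_exact_p(x, y, rho)
                row["rho"], row["p"] = float(rho), float(p)
            rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out[["cpg", "feature", "n", "rho", "p", "q", "reason"]]


def replication_check(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    probes=None,
    *,
    alpha: float = 0.05,
) -> dict:
    """Direction-consistency and nominal-significance replication summary.

    ``discovery`` / ``replication`` are EWAS result tables indexed by probe
    with signed ``estimate`` and ``p`` columns.  "Nominal" replication
    requires p < alpha *and* a consistent direction of effect; ``n_fdr``
    additionally requires replication q < alpha (BH within the tested set).
    """
    if probes is None:
        probes = discovery.index
    probes = pd.Index(probes)
    shared = probes.intersection(discovery.index).intersection(replication.index)
    if len(shared) == 0:
        raise DomainError("replication_check: no overlapping probes")
    disc = discovery.loc[shared]
    repl = replication.loc[shared]
    same = np.sign(disc["estimate"]) == np.sign(repl["estimate"])
    repl_q = bh_fdr(repl["p"].to_numpy())
    nominal = same & (repl["p"] < alpha)
    fdr = same & (repl_q < alpha)
    return {
        "n_tested": int(len(shared)),
        "n_same_direction": int(same.sum()),
        "n_nominal": int(nominal.sum()),
        "n_fdr": int(fdr.sum()),
    }
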