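"""Empirical-Bayes moderated t / F differential expression with BH FDR.

The moderated t-statistic shrinks each peak cluster's sample variance
toward a pooled prior estimated from all clusters (Smyth's hierarchical
model: residual variances follow a scaled F distribution with prior
degrees of freedom d0 and prior variance s0^2, estimated by moment
matching on log variances).  P-values use a t distribution with d0 + d
degrees of freedom.  Benjamini-Hochberg step-up adjustment controls the
false discovery rate within each pairwise comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import IntensityMatrix, SpecError


@dataclass
class EBayesParams:
    d0: float        # prior degrees of freedom; may be +inf
    s0_sq: float     # prior variance

    def __post_init__(self) -> None:
        # d0 = 0 is admitted as the classical (no-moderation) limit
        if not (self.d0 >= 0):
            raise SpecError("prior degrees of freedom must be >= 0")
        if not (self.s0_sq >= 0):
            raise SpecError("prior variance must be >= 0")
        if self.d0 > 0 and not np.isinf(self.d0) and self.s0_sq == 0:
            raise SpecError("finite positive d0 requires s0_sq > 0")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_ebayes(s2: np.ndarray, df: float | np.ndarray) -> EBayesParams:
    """Estimate (d0, s0^2) by moment matching of log s^2 to a scaled F model.

    Uses the digamma/trigamma closed forms: with z = log s^2,
    E[z] = log s0^2 + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2)
    and Var[z] = trigamma(d/2) + trigamma(d0/2).  If the observed variance
    of z does not exceed the sampling floor trigamma(d/2), d0 = +inf and
    s0^2 is the geometric-mean variance.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (s2 > 0) & (df >= 1)
    if ok.sum() < 2:
        raise SpecError("need at least 2 clusters with positive variance and df >= 1")
    s2, df = s2[ok], df[ok]
    if np.all(s2 == s2[0]):
        # degenerate: no variance heterogeneity at all
        return EBayesParams(d0=float("inf"), s0_sq=float(s2[0]))
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = float("inf")
        s0_sq = float(np.exp(emean))
    return EBayesParams(d0=d0, s0_sq=s0_sq)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise SpecError("p must be one-dimensional")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise SpecError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _group_rows(matrix: IntensityMatrix, group: str) -> np.ndarray:
    mask = (matrix.samples["class_label"] == group).to_numpy()
    if not mask.any():
        raise SpecError(f"group {group!r} not present in the matrix")
    return mask


def moderated_t(matrix: IntensityMatrix, group_a: str, group_b: str,
                ebayes: EBayesParams | None = None,
                alpha: float = 0.05) -> pd.DataFrame:
    """Per-cluster moderated t-test of group_a vs group_b.

    Posterior variance s~^2 = (d0*s0^2 + d*s^2) / (d0 + d); the statistic
    is the mean difference over s~ * sqrt(1/nA + 1/nB), with d0 + d degrees
    of freedom (capped at 1e6 when d0 is infinite).  ``ebayes`` may carry
    d0 = 0 to recover the classical pooled t-test exactly.  Returns a table
    with group means (log2), log2 fold change, natural-scale FC, t, raw and
    BH-adjusted p, and a significance flag at ``alpha``.
    """
    X = matrix.values.to_numpy()
    ma, mb = _group_rows(matrix, group_a), _group_rows(matrix, group_b)
    na, nb = int(ma.sum()), int(mb.sum())
    if na < 2 or nb < 2:
        raise SpecError("both groups need at least 2 samples")
    A, B = X[ma], X[mb]
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    d = na + nb - 2
    s2 = (A.var(axis=0, ddof=1) * (na - 1) + B.var(axis=0, ddof=1) * (nb - 1)) / d
    if ebayes is None:
        ebayes = fit_ebayes(s2, d)
    d0, s0_sq = ebayes.d0, ebayes.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = 1e6
    elif d0 == 0:
        s2_post = s2
        df_total = d
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = min(d0 + d, 1e6)
    if np.any(s2_post <= 0):
        raise SpecError("zero posterior variance; cannot form the statistic")
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t = (mean_a - mean_b) / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_adj = bh_adjust(p)
    log2_fc = mean_a - mean_b
    return pd.DataFrame({
        "cluster_id": matrix.cluster_ids,
        "center_mz": [c.center_mz for c in matrix.clusters] if matrix.clusters
        else np.nan,
        "mean_a": mean_a, "mean_b": mean_b,
        "log2_fc": log2_fc, "fc": 2.0 ** log2_fc,
        "t": t, "p": p, "p_adj": p_adj,
        "significant": p_adj < alpha,
    })


def anova_f(matrix: IntensityMatrix, groups: list[str]) -> pd.DataFrame:
    """One-way ANOVA F across three or more groups, per cluster."""
    if len(groups) < 2:
        raise SpecError("need at least 2 groups")
    masks = [_group_rows(matrix, g) for g in groups]
    for g, m in zip(groups, masks):
        if m.sum() < 2:
            raise SpecError(f"group {g!r} has fewer than 2 samples")
    X = matrix.values.to_numpy()
    sub = [X[m] for m in masks]
    ns = np.array([len(s) for s in sub])
    n = ns.sum()
    k = len(groups)
    grand = np.vstack(sub).mean(axis=0)
    means = np.array([s.mean(axis=0) for s in sub])
    ss_between = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    ss_within = sum(((s - m) ** 2).sum(axis=0) for s, m in zip(sub, means))
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    F = np.where(np.isfinite(F), F, 0.0)
    p = stats.f.sf(F, df1, df2)
    return pd.DataFrame({"cluster_id": matrix.cluster_ids, "F": F, "p": p,
                         "p_adj": bh_adjust(p)})


def pairwise_de(matrix: IntensityMatrix, pairs: list[tuple] | None = None,
                alpha: float = 0.05) -> dict:
    """Moderated-t tables for each requested group pair.

    Each comparison forms its own BH family (adjustment within the pair).
    Default pairs: all unordered pairs of the class labels present.
    """
    present = [g for g in ("benign", "LMP", "cancer")
               if (matrix.samples["class_label"] == g).any()]
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1:]]
    out = {}
    for a, b in pairs:
        out[(a, b)] = moderated_t(matrix, a, b, alpha=alpha)
    return out


def top_table(result: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Top-n clusters sorted by adjusted p, then |log2 FC| descending."""
    ordered = result.sort_values(
        ["p_adj", "log2_fc"],
        key=lambda col: col if col.name == "p_adj" else -col.abs(),
        kind="stable")
    return ordered.head(n)[["cluster_id", "center_mz", "p_adj", "fc"]]


def match_peaks(clusters_a: list, clusters_b: list,
                tolerance_pct: float = 0.3) -> list[tuple]:
    """Greedy nearest-neighbor matching of two cluster lists by m/z.

    A pair matches when the absolute mass difference relative to the mean
    mass is at most ``tolerance_pct``/100; each cluster is used at most
    once and the closest pairs are matched first.
    """
    tol = tolerance_pct / 100.0
    cand = []
    for i, a in enumerate(clusters_a):
        mz_a = a.center_mz if hasattr(a, "center_mz") else float(a)
        for j, b in enumerate(clusters_b):
            mz_b = b.center_mz if hasattr(b, "center_mz") else float(b)
            rel = abs(mz_a - mz_b) / ((mz_a + mz_b) / 2.0)
            if rel <= tol:
                cand.append((rel, i, j))
    cand.sort()
    used_a, used_b, matches = set(), set(), []
    for rel, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((clusters_a[i], clusters_b[j], rel))
    return matches
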