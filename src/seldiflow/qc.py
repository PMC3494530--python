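"""Quality control: replicate reproducibility, chip-effect ANOVA,
hierarchical clustering with outlier flagging, and column z-scoring.

Spectrum-level screening replaces manual visual inspection with two
automated rules: a spectrum fails QC when its baseline accounts for more
than 90% of the raw total ion current (very high, irregular baseline) or
when its corrected TIC is non-positive.  Sample-level outliers are flagged
from the complete-linkage, Pearson-distance dendrogram: a sample whose
first merge happens above the 75th-percentile merge height plus three
inter-quartile ranges joins the tree too late to be trusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .io import IntensityMatrix, SpecError, Spectrum


@dataclass
class QCReport:
    replicate_stats: pd.DataFrame | None = None
    replicate_summary: dict = field(default_factory=dict)
    chip_anova: pd.DataFrame | None = None
    outliers: list = field(default_factory=list)
    excluded: list = field(default_factory=list)
    notes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# spectrum-level screening
# ---------------------------------------------------------------------------

def screen_spectrum(raw: Spectrum, baseline: np.ndarray,
                    max_baseline_fraction: float = 0.9) -> tuple[bool, str]:
    """Return (passes, reason). Fails on dominant or runaway baselines."""
    total = float(np.sum(raw.intensity))
    base = float(np.sum(baseline))
    corrected_tic = total - base
    if corrected_tic <= 0:
        return False, "non-positive corrected TIC"
    if total > 0 and base / total > max_baseline_fraction:
        return False, f"baseline fraction {base / total:.2f} of TIC"
    return True, ""


# ---------------------------------------------------------------------------
# replicate reproducibility
# ---------------------------------------------------------------------------

def replicate_reproducibility(matrix: IntensityMatrix) -> tuple[pd.DataFrame, dict]:
    """Pearson r and median per-peak CV for every technical replicate pair.

    r is computed on the log2 profiles; the coefficient of variation per
    peak is sd/mean on the natural intensity scale, summarized by its
    median across peaks.
    """
    meta = matrix.samples.reset_index(drop=True)
    vals = matrix.values.reset_index(drop=True).to_numpy()
    rows = []
    for (sid, surf), idx in meta.groupby(["sample_id", "surface"],
                                         sort=False).groups.items():
        idx = list(idx)
        if len(idx) < 2:
            continue
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                x, y = vals[idx[a]], vals[idx[b]]
                r = float(np.corrcoef(x, y)[0, 1]) if (x.std() > 0 and y.std() > 0) \
                    else float("nan")
                nat = 2.0 ** np.vstack([x, y])
                cv = nat.std(axis=0, ddof=1) / nat.mean(axis=0)
                rows.append({"sample_id": sid, "surface": surf,
                             "pearson_r": r, "median_cv": float(np.median(cv))})
    if not rows:
        warnings.warn("no replicate pairs found")
        return pd.DataFrame(columns=["sample_id", "surface", "pearson_r",
                                     "median_cv"]), {}
    stats_df = pd.DataFrame(rows)
    summary = {"median_r": float(stats_df["pearson_r"].median()),
               "median_cv": float(stats_df["median_cv"].median()),
               "n_pairs": len(stats_df)}
    return stats_df, summary


# ---------------------------------------------------------------------------
# chip-effect factorial ANOVA (type-II sums of squares)
# ---------------------------------------------------------------------------

def _design(groups: pd.Series) -> np.ndarray:
    """Treatment-coded dummy block (first level as reference)."""
    levels = sorted(groups.unique())
    cols = [(groups == lv).to_numpy(float) for lv in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(groups), 0))


def _rss(design: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sums of squares of Y's columns under a least-squares fit."""
    X = np.column_stack([np.ones(len(Y)), design])
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return (resid ** 2).sum(axis=0), rank


def chip_anova(matrix: IntensityMatrix) -> pd.DataFrame:
    """Per-cluster two-way ANOVA: patient status and chip as main effects.

    Type-II sums of squares (each main effect adjusted for the other), with
    the status x chip interaction tested only when replication within cells
    leaves residual degrees of freedom; otherwise the additive model's
    residual is the error term and the interaction column is NaN.
    A single chip degrades to one-way ANOVA on status with a warning.
    """
    meta = matrix.samples.reset_index(drop=True)
    Y = matrix.values.reset_index(drop=True).to_numpy()
    status = meta["class_label"]
    chip = meta["chip_id"].astype(str)
    n = len(meta)
    if status.nunique() < 2:
        raise SpecError("need at least 2 status groups")
    single_chip = chip.nunique() < 2
    if single_chip:
        warnings.warn("single chip: chip terms skipped, one-way ANOVA on status")

    Xs, Xc = _design(status), _design(chip)
    inter = np.column_stack([Xs[:, i] * Xc[:, j]
                             for i in range(Xs.shape[1])
                             for j in range(Xc.shape[1])]) \
        if Xs.shape[1] and Xc.shape[1] else np.empty((n, 0))

    rss_s, rank_s = _rss(Xs, Y)                     # status only
    out = {"cluster_id": matrix.cluster_ids}
    if single_chip:
        rss_null, rank_null = _rss(np.empty((n, 0)), Y)
        df_s = rank_s - rank_null
        df_err = n - rank_s
        F = ((rss_null - rss_s) / df_s) / (rss_s / df_err)
        from scipy import stats as _st
        out["p_status"] = _st.f.sf(F, df_s, df_err)
        out["p_chip"] = np.nan
        out["p_interaction"] = np.nan
        return pd.DataFrame(out)

    rss_c, rank_c = _rss(Xc, Y)                     # chip only
    add = np.column_stack([Xs, Xc])
    rss_a, rank_a = _rss(add, Y)                    # additive
    full = np.column_stack([add, inter])
    rss_f, rank_f = _rss(full, Y)                   # with interaction
    df_inter = rank_f - rank_a
    df_err_full = n - rank_f
    test_interaction = df_inter > 0 and df_err_full > 0
    if test_interaction:
        err_rss, err_df = rss_f, df_err_full
    else:
        err_rss, err_df = rss_a, n - rank_a
    if err_df <= 0:
        raise SpecError("no residual degrees of freedom for the ANOVA")

    from scipy import stats as _st
    df_status = rank_a - rank_c
    df_chip = rank_a - rank_s
    F_status = ((rss_c - rss_a) / df_status) / (err_rss / err_df)
    F_chip = ((rss_s - rss_a) / df_chip) / (err_rss / err_df)
    out["p_status"] = _st.f.sf(F_status, df_status, err_df)
    out["p_chip"] = _st.f.sf(F_chip, df_chip, err_df)
    if test_interaction:
        F_inter = ((rss_a - rss_f) / df_inter) / (rss_f / df_err_full)
        out["p_interaction"] = _st.f.sf(F_inter, df_inter, df_err_full)
    else:
        out["p_interaction"] = np.nan
    df = pd.DataFrame(out)
    if not test_interaction:
        df.attrs["note"] = ("interaction omitted: no within-cell replication "
                            "leaves residual degrees of freedom")
    return df


# ---------------------------------------------------------------------------
# hierarchical clustering and outlier flagging
# ---------------------------------------------------------------------------

def hcluster(matrix: IntensityMatrix, iqr_factor: float = 3.0):
    """Complete-linkage clustering on 1 - Pearson correlation distance.

    Returns (linkage matrix, leaf keys, outlier keys).  Constant rows have
    undefined correlation; they are flagged and excluded from the tree.
    A leaf is an outlier when its first merge height exceeds the 75th
    percentile of all merge heights plus ``iqr_factor`` x IQR.
    """
    vals = matrix.values.to_numpy()
    keys = list(matrix.values.index)
    if len(keys) < 3:
        raise SpecError("need at least 3 samples to cluster")
    row_sd = vals.std(axis=1)
    constant = row_sd == 0
    flagged = [keys[i] for i in np.flatnonzero(constant)]
    if flagged:
        warnings.warn(f"constant rows excluded from clustering: {flagged}")
    use = ~constant
    sub = vals[use]
    sub_keys = [k for k, u in zip(keys, use) if u]
    if len(sub_keys) < 3:
        raise SpecError("fewer than 3 non-constant samples")
    dist = pdist(sub, metric="correlation")   # = 1 - Pearson r
    Z = linkage(dist, method="complete")
    heights = Z[:, 2]
    q25, q75 = np.percentile(heights, [25, 75])
    fence = q75 + iqr_factor * (q75 - q25)
    n = len(sub_keys)
    first_merge = np.full(n, np.nan)
    for row_i, (a, b, h, _) in enumerate(Z):
        for leaf in (int(a), int(b)):
            if leaf < n and np.isnan(first_merge[leaf]):
                first_merge[leaf] = h
        # members of merged clusters already have a first-merge height
    outliers = [sub_keys[i] for i in np.flatnonzero(first_merge > fence)]
    return Z, sub_keys, sorted(set(outliers) | set(flagged))


def zscore_columns(matrix: IntensityMatrix) -> IntensityMatrix:
    """Center each column to mean 0 and scale to (sample) sd 1."""
    vals = matrix.values
    sd = vals.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise SpecError(f"zero-sd column(s): {list(zero.index)}")
    z = (vals - vals.mean(axis=0)) / sd
    return IntensityMatrix(values=z, samples=matrix.samples.copy(),
                           clusters=list(matrix.clusters))


def run_qc(matrix: IntensityMatrix, iqr_factor: float = 3.0) -> QCReport:
    """Full matrix-level QC: replicates, chip ANOVA, cluster outliers."""
    report = QCReport()
    stats_df, summary = replicate_reproducibility(matrix)
    report.replicate_stats = stats_df
    report.replicate_summary = summary
    try:
        report.chip_anova = chip_anova(matrix)
    except SpecError as exc:
        report.notes.append(f"chip ANOVA skipped: {exc}")
    try:
        _, _, outliers = hcluster(matrix, iqr_factor=iqr_factor)
        report.outliers = outliers
    except SpecError as exc:
        report.notes.append(f"clustering skipped: {exc}")
    report.excluded = list(report.outliers)
    return report


def exclude_samples(matrix: IntensityMatrix, keys: list[str]) -> IntensityMatrix:
    """Drop the given spectrum keys from the matrix (QC bookkeeping)."""
    keep = [k not in set(keys) for k in matrix.values.index]
    values = matrix.values.loc[keep]
    samples = matrix.samples.reset_index(drop=True).loc[keep].reset_index(drop=True)
    return IntensityMatrix(values=values, samples=samples,
                           clusters=list(matrix.clusters))
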