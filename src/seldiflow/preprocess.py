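"""Baseline correction and total-ion-current (TIC) normalization.

The baseline estimate is a morphological envelope: a rolling minimum over a
window expressed in Da (converted to points locally on the non-uniform TOF
grid) followed by a moving average of the same width.  TIC normalization
rescales each baseline-corrected spectrum so that its mean intensity over
the normalization mass range equals a common target; for an independent
validation cohort the target is frozen from the training cohort so that no
validation information enters the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import IntensityMatrix, SpecError, Spectrum, METADATA_COLUMNS

#: normalization mass windows (Da) per (specimen, surface)
DEFAULT_NORM_RANGES = {
    ("serum", "CM10"): (2000.0, 20000.0),
    ("serum", "Q10"): (1700.0, 20000.0),
    ("tissue", "CM10"): (2500.0, 50000.0),
    ("tissue", "Q10"): (2000.0, 50000.0),
}


@dataclass
class PreprocessParams:
    norm_range: tuple = (2000.0, 20000.0)
    baseline_window: float = 200.0     # Da
    norm_target: float | str = "cohort-mean"

    def __post_init__(self) -> None:
        lo, hi = self.norm_range
        if lo >= hi:
            raise SpecError("norm_range must satisfy lo < hi")
        if self.baseline_window <= 0:
            raise SpecError("baseline_window must be > 0")


def default_params(specimen: str, surface: str, **overrides) -> PreprocessParams:
    rng = DEFAULT_NORM_RANGES.get((specimen, surface))
    if rng is None:
        raise SpecError(f"no default normalization range for ({specimen}, {surface})")
    overrides.setdefault("norm_range", rng)
    return PreprocessParams(**overrides)


# ---------------------------------------------------------------------------
# variable-window range minimum (sparse table) and moving average
# ---------------------------------------------------------------------------

def _window_bounds(mz: np.ndarray, window: float):
    """Left/right (inclusive) index bounds of a +-window/2 Da neighborhood."""
    half = window / 2.0
    left = np.searchsorted(mz, mz - half, side="left")
    right = np.searchsorted(mz, mz + half, side="right") - 1
    return left, right


def _range_min(x: np.ndarray, left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Minimum of x over [left_i, right_i] for every i (sparse-table RMQ)."""
    n = len(x)
    lengths = right - left + 1
    kmax = int(np.floor(np.log2(lengths.max()))) if n else 0
    table = [x]
    for j in range(1, kmax + 1):
        prev = table[-1]
        step = 1 << (j - 1)
        table.append(np.minimum(prev[: len(prev) - step], prev[step:]))
    ks = np.floor(np.log2(lengths)).astype(int)
    out = np.empty(n, dtype=float)
    for k in np.unique(ks):
        sel = ks == k
        t = table[k]
        out[sel] = np.minimum(t[left[sel]], t[right[sel] - (1 << k) + 1])
    return out


def _range_mean(x: np.ndarray, left: np.ndarray, right: np.ndarray) -> np.ndarray:
    csum = np.concatenate([[0.0], np.cumsum(x)])
    return (csum[right + 1] - csum[left]) / (right - left + 1)


def subtract_baseline(spectrum: Spectrum, baseline_window: float = 200.0):
    """Return (baseline-corrected spectrum, baseline estimate).

    Rolling minimum then moving-average smoothing, both over
    ``baseline_window`` Da.  The corrected trace may contain negatives;
    downstream peak extraction applies the zero/negative substitution rule.
    """
    mz = spectrum.mz
    if baseline_window >= mz[-1] - mz[0]:
        raise SpecError("baseline_window larger than the spectrum span")
    left, right = _window_bounds(mz, baseline_window)
    rolled = _range_min(spectrum.intensity, left, right)
    baseline = _range_mean(rolled, left, right)
    corrected = spectrum.with_intensity(spectrum.intensity - baseline)
    return corrected, baseline


# ---------------------------------------------------------------------------
# TIC normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationResult:
    spectra: list
    coefficients: dict              # spectrum key -> multiplicative coefficient
    target: float                   # the (possibly frozen) mean-TIC target
    failed: list = field(default_factory=list)   # keys flagged QC-failed (TIC <= 0)


def spectrum_tic(spectrum: Spectrum, norm_range: tuple) -> float:
    """Mean baseline-corrected intensity over the normalization mass range."""
    lo, hi = norm_range
    a = np.searchsorted(spectrum.mz, lo, side="left")
    b = np.searchsorted(spectrum.mz, hi, side="right")
    if b <= a:
        raise SpecError(f"spectrum {spectrum.key} does not cover norm_range {norm_range}")
    return float(np.mean(spectrum.intensity[a:b]))


def tic_normalize(spectra: list, norm_range: tuple,
                  norm_target: float | str = "cohort-mean") -> NormalizationResult:
    """Scale spectra so each has the target mean TIC over ``norm_range``.

    ``norm_target`` is either "cohort-mean" (target = mean of all spectra's
    TICs — the training-cohort convention) or a fixed positive number (the
    frozen target when preprocessing a validation cohort).  Spectra with
    non-positive TIC are flagged as QC failures and returned unscaled with a
    NaN coefficient.
    """
    tics = np.array([spectrum_tic(s, norm_range) for s in spectra])
    ok = tics > 0
    if norm_target == "cohort-mean":
        if not ok.any():
            raise SpecError("no spectrum with positive TIC; cannot set target")
        target = float(np.mean(tics[ok]))
    else:
        target = float(norm_target)
        if target <= 0:
            raise SpecError("norm_target must be positive")
    scaled, coeffs, failed = [], {}, []
    for s, tic, good in zip(spectra, tics, ok):
        if not good:
            warnings.warn(f"{s.key}: non-positive TIC {tic:.4g}; flagged as QC-failed")
            failed.append(s.key)
            coeffs[s.key] = float("nan")
            scaled.append(s)
            continue
        c = target / tic
        coeffs[s.key] = c
        scaled.append(s.with_intensity(s.intensity * c))
    return NormalizationResult(spectra=scaled, coefficients=coeffs,
                               target=target, failed=failed)


# ---------------------------------------------------------------------------
# technical-replicate averaging
# ---------------------------------------------------------------------------

def average_replicates(matrix: IntensityMatrix) -> IntensityMatrix:
    """Average technical replicates: one row per sample_id (per surface).

    Values are arithmetic means of the log2 intensities.  Metadata collapse:
    fields that differ between replicates (chip, spot) are joined with "+";
    conflicting class labels are an error.
    """
    meta = matrix.samples.reset_index(drop=True)
    vals = matrix.values.reset_index(drop=True)
    group_keys = ["sample_id", "surface"]
    out_vals, out_meta = [], []
    for (sid, surf), idx in meta.groupby(group_keys, sort=False).groups.items():
        idx = list(idx)
        sub = meta.loc[idx]
        labels = sub["class_label"].unique()
        if len(labels) > 1:
            raise SpecError(
                f"sample {sid}: conflicting class labels {sorted(labels)}")
        row = {}
        for c in METADATA_COLUMNS:
            u = sub[c].unique()
            row[c] = u[0] if len(u) == 1 else "+".join(str(v) for v in u)
        row["replicate_index"] = 1
        out_meta.append(row)
        out_vals.append(vals.loc[idx].mean(axis=0))
    values = pd.DataFrame(out_vals).reset_index(drop=True)
    samples = pd.DataFrame(out_meta)
    values.index = [f"{r.sample_id}|{r.surface}|r1" for r in samples.itertuples()]
    return IntensityMatrix(values=values, samples=samples,
                           clusters=list(matrix.clusters))
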