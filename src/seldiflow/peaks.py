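"""Two-pass S/N peak detection, cross-spectrum clustering, matrix extraction.

Detection follows the classic ProteinChip-style parameterization: a first
pass at a high signal-to-noise threshold proposes peaks; candidates are
clustered across spectra within a relative mass window; clusters supported
by too few spectra are discarded; a second, lower-threshold pass fills in
support for the surviving clusters but cannot create new ones.  The
intensity matrix takes, per spectrum and cluster, the maximum
baseline-corrected normalized intensity inside the cluster window; zero or
negative values are replaced by half the minimum positive value of that
cluster, and everything is log2-transformed to stabilize variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .io import IntensityMatrix, SpecError, Spectrum, make_cluster_ids

#: ProteinChip-style detection settings: (first-pass S/N, min peak threshold
#: % of spectra, cluster mass window % of mass, second-pass S/N)
SERUM_SETTINGS = (5.0, 25.0, 0.3, 2.0)
TISSUE_SETTINGS = (5.0, 5.0, 0.3, 2.0)


@dataclass
class PeakDetectionParams:
    first_pass_snr: float = 5.0
    min_peak_threshold_pct: float = 25.0
    cluster_mass_window_pct: float = 0.3
    second_pass_snr: float = 2.0
    #: "half" = +-window_pct around the seed (total width 2x), "full" = the
    #: window percentage is the total width (+-window_pct/2)
    window_mode: str = "half"
    noise_window_frac: float = 0.02    # noise window = frac * local m/z
    noise_window_min_points: int = 50

    def __post_init__(self) -> None:
        if not (self.first_pass_snr >= self.second_pass_snr > 0):
            raise SpecError("need first_pass_snr >= second_pass_snr > 0")
        if not (0 < self.min_peak_threshold_pct <= 100):
            raise SpecError("min_peak_threshold_pct must be in (0, 100]")
        if self.cluster_mass_window_pct <= 0:
            raise SpecError("cluster_mass_window_pct must be > 0")
        if self.window_mode not in ("half", "full"):
            raise SpecError("window_mode must be 'half' or 'full'")

    @property
    def half_window_frac(self) -> float:
        w = self.cluster_mass_window_pct / 100.0
        return w if self.window_mode == "half" else w / 2.0

    @classmethod
    def for_specimen(cls, specimen: str, **overrides) -> "PeakDetectionParams":
        s = SERUM_SETTINGS if specimen == "serum" else TISSUE_SETTINGS
        values = dict(first_pass_snr=s[0], min_peak_threshold_pct=s[1],
                      cluster_mass_window_pct=s[2], second_pass_snr=s[3])
        values.update(overrides)
        return cls(**values)


@dataclass
class PeakCandidate:
    mz: float
    height: float
    snr: float


@dataclass
class PeakCluster:
    """Consensus peak: center m/z plus a shared relative-mass window."""

    id: str
    center_mz: float
    window: tuple
    support: float

    def contains(self, mz) -> np.ndarray:
        mz = np.asarray(mz)
        return (mz >= self.window[0]) & (mz <= self.window[1])


# ---------------------------------------------------------------------------
# noise estimation
# ---------------------------------------------------------------------------

def _detrend(x: np.ndarray) -> np.ndarray:
    """Remove slow residual structure (e.g. imperfect baseline subtraction)
    with a short moving median; sharp peaks survive nearly unchanged."""
    n = len(x)
    size = min(31, n if n % 2 == 1 else n - 1)
    return x - median_filter(x, size=max(3, size), mode="nearest")

def estimate_noise(spectrum: Spectrum, noise_window: float | None = None,
                   params: PeakDetectionParams | None = None) -> np.ndarray:
    """Local noise sd: 1.4826 x MAD of the median-detrended signal.

    The signal is detrended by subtracting a short moving median, then the
    median absolute deviation is computed in contiguous blocks spanning the
    noise window (in Da, floored at a minimum point count) and linearly
    interpolated back to every grid point.  Strictly positive (floor 1e-12).
    """
    params = params or PeakDetectionParams()
    detrended = _detrend(spectrum.intensity)
    mz = spectrum.mz
    n = len(detrended)

    noise = np.empty(n)
    centers, block_sds = [], []
    i = 0
    while i < n:
        w = noise_window if noise_window is not None else params.noise_window_frac * mz[i]
        j = int(np.searchsorted(mz, mz[i] + w, side="right"))
        j = max(j, i + params.noise_window_min_points)
        j = min(j, n)
        block = detrended[i:j]
        mad = np.median(np.abs(block - np.median(block)))
        centers.append(0.5 * (mz[i] + mz[j - 1]))
        block_sds.append(1.4826 * mad)
        if j >= n:
            break
        i = j
    if len(centers) == 1:
        noise[:] = block_sds[0]
    else:
        noise = np.interp(mz, centers, block_sds)
    return np.maximum(noise, 1e-12)


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def detect_peaks(spectrum: Spectrum, snr_threshold: float,
                 noise_window: float | None = None,
                 params: PeakDetectionParams | None = None) -> list[PeakCandidate]:
    """Local maxima of the 3-point-smoothed trace with S/N >= threshold.

    The numerator of the S/N ratio is the median-detrended height, so smooth
    residual structure left by baseline correction does not masquerade as
    signal; the reported candidate height is the corrected intensity itself.
    """
    x = spectrum.intensity
    n = len(x)
    if n < 3:
        return []
    smooth = x.copy()
    smooth[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    is_max = np.zeros(n, dtype=bool)
    is_max[1:-1] = (smooth[1:-1] > smooth[:-2]) & (smooth[1:-1] > smooth[2:])
    noise = estimate_noise(spectrum, noise_window=noise_window, params=params)
    detrended = _detrend(x)
    idx = np.flatnonzero(is_max)
    out = []
    for i in idx:
        snr = float(detrended[i]) / float(noise[i])
        if snr >= snr_threshold:
            out.append(PeakCandidate(mz=float(spectrum.mz[i]),
                                     height=float(x[i]), snr=float(snr)))
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _count_in_windows(sorted_mz: np.ndarray, half_frac: float):
    lo = np.searchsorted(sorted_mz, sorted_mz * (1 - half_frac), side="left")
    hi = np.searchsorted(sorted_mz, sorted_mz * (1 + half_frac), side="right")
    return hi - lo, lo, hi


def cluster_peaks(candidate_lists: list[list[PeakCandidate]],
                  params: PeakDetectionParams,
                  second_pass_lists: list[list[PeakCandidate]] | None = None
                  ) -> list[PeakCluster]:
    """Greedy cross-spectrum clustering of first-pass candidates.

    Repeatedly seed at the candidate m/z whose relative-mass window captures
    the most candidates (ties: lower m/z), absorb everything in the window,
    and set the cluster center to the median absorbed m/z.  Clusters with
    first-pass support below the minimum peak threshold are discarded.  A
    second-pass candidate list, when given, only updates the support of the
    surviving clusters; it cannot create clusters.
    """
    n_spectra = len(candidate_lists)
    if n_spectra == 0:
        return []
    half = params.half_window_frac
    mzs, owners = [], []
    for si, cands in enumerate(candidate_lists):
        for c in cands:
            mzs.append(c.mz)
            owners.append(si)
    clusters: list[PeakCluster] = []
    mzs = np.asarray(mzs)
    owners = np.asarray(owners)
    order = np.argsort(mzs, kind="stable")
    mzs, owners = mzs[order], owners[order]
    alive = np.ones(len(mzs), dtype=bool)
    while alive.any():
        cur_mz = mzs[alive]
        cur_owner = owners[alive]
        counts, lo, hi = _count_in_windows(cur_mz, half)
        seed = int(np.argmax(counts))  # ties -> first = lowest m/z
        sel = slice(lo[seed], hi[seed])
        absorbed_mz = cur_mz[sel]
        absorbed_owner = cur_owner[sel]
        center = float(np.median(absorbed_mz))
        support = len(np.unique(absorbed_owner)) / n_spectra
        clusters.append(PeakCluster(
            id="", center_mz=center,
            window=(center * (1 - half), center * (1 + half)),
            support=support))
        alive_idx = np.flatnonzero(alive)
        alive[alive_idx[sel]] = False
    clusters = [c for c in clusters
                if c.support * 100.0 >= params.min_peak_threshold_pct]
    clusters.sort(key=lambda c: c.center_mz)

    if second_pass_lists is not None and clusters:
        centers = np.array([c.center_mz for c in clusters])
        for ci, cl in enumerate(clusters):
            supporting = set()
            for si in range(n_spectra):
                for cand in candidate_lists[si]:
                    if cl.window[0] <= cand.mz <= cl.window[1]:
                        supporting.add(si)
                        break
            for si in range(n_spectra):
                if si in supporting:
                    continue
                for cand in second_pass_lists[si]:
                    if cl.window[0] <= cand.mz <= cl.window[1]:
                        supporting.add(si)
                        break
            cl.support = len(supporting) / n_spectra
        del centers
    ids = make_cluster_ids([c.center_mz for c in clusters])
    for cl, cid in zip(clusters, ids):
        cl.id = cid
    return clusters


def detect_and_cluster(spectra: list[Spectrum],
                       params: PeakDetectionParams) -> list[PeakCluster]:
    """Run both detection passes on all spectra and cluster the candidates."""
    first = [detect_peaks(s, params.first_pass_snr, params=params) for s in spectra]
    second = [detect_peaks(s, params.second_pass_snr, params=params) for s in spectra]
    return cluster_peaks(first, params, second_pass_lists=second)


# ---------------------------------------------------------------------------
# intensity matrix extraction
# ---------------------------------------------------------------------------

def extract_intensity_matrix(spectra: list[Spectrum], clusters: list[PeakCluster],
                             substitute_values: dict | None = None):
    """Build the samples x clusters log2 intensity matrix.

    Raw value = maximum corrected normalized intensity within the cluster
    window.  Per cluster, values <= 0 become half the minimum positive value
    of that cluster (or the frozen training constant when
    ``substitute_values`` is given); then log2.  Returns
    (IntensityMatrix, substitution constants used per cluster id).
    Clusters with no positive value in any spectrum are dropped with a warning.
    """
    if not clusters:
        raise SpecError("no clusters to extract")
    n, p = len(spectra), len(clusters)
    raw = np.empty((n, p))
    for i, s in enumerate(spectra):
        lo = np.searchsorted(s.mz, [c.window[0] for c in clusters], side="left")
        hi = np.searchsorted(s.mz, [c.window[1] for c in clusters], side="right")
        for j in range(p):
            if hi[j] <= lo[j]:
                raise SpecError(
                    f"spectrum {s.key} does not cover cluster {clusters[j].id}")
            raw[i, j] = np.max(s.intensity[lo[j]:hi[j]])

    keep, subs = [], {}
    for j, cl in enumerate(clusters):
        col = raw[:, j]
        if substitute_values is not None and cl.id in substitute_values:
            half_min = substitute_values[cl.id]
        else:
            pos = col[col > 0]
            if len(pos) == 0:
                warnings.warn(f"cluster {cl.id}: no positive intensity in any "
                              "spectrum; dropped")
                continue
            half_min = 0.5 * float(pos.min())
        col[col <= 0] = half_min
        subs[cl.id] = half_min
        keep.append(j)

    kept_clusters = [clusters[j] for j in keep]
    values = pd.DataFrame(np.log2(raw[:, keep]),
                          columns=[c.id for c in kept_clusters])
    samples = pd.DataFrame([{
        "sample_id": s.sample_id, "class_label": s.class_label,
        "specimen": s.specimen, "surface": s.surface, "cohort": s.cohort,
        "chip_id": s.chip_id, "spot": s.spot,
        "replicate_index": s.replicate_index} for s in spectra])
    values.index = [s.key for s in spectra]
    matrix = IntensityMatrix(values=values, samples=samples,
                             clusters=kept_clusters)
    return matrix, subs


# ---------------------------------------------------------------------------
# surface union
# ---------------------------------------------------------------------------

def combine_surfaces(matrix_cm10: IntensityMatrix,
                     matrix_q10: IntensityMatrix) -> IntensityMatrix:
    """Union of CM10 and Q10 peak intensities per sample.

    Columns are concatenated with surface-prefixed cluster ids
    ("CM10:M2773"); samples present on only one surface are dropped with a
    warning.  Row order follows the CM10 matrix.
    """
    a_ids = matrix_cm10.samples["sample_id"].tolist()
    b_ids = matrix_q10.samples["sample_id"].tolist()
    common = [sid for sid in a_ids if sid in set(b_ids)]
    if not common:
        raise SpecError("no samples shared between the two surfaces")
    dropped = (set(a_ids) | set(b_ids)) - set(common)
    if dropped:
        warnings.warn(f"combine_surfaces: dropped {len(dropped)} sample(s) "
                      "present on one surface only")

    def _rows(matrix, prefix):
        meta = matrix.samples.reset_index(drop=True)
        pos = {sid: i for i, sid in
               reversed(list(enumerate(meta["sample_id"])))}
        idx = [pos[sid] for sid in common]
        vals = matrix.values.reset_index(drop=True).loc[idx].reset_index(drop=True)
        vals.columns = [f"{prefix}:{c}" for c in vals.columns]
        return meta.loc[idx].reset_index(drop=True), vals

    meta_a, vals_a = _rows(matrix_cm10, "CM10")
    _, vals_b = _rows(matrix_q10, "Q10")
    values = pd.concat([vals_a, vals_b], axis=1)
    meta = meta_a.copy()
    meta["surface"] = "CM10+Q10"
    values.index = [f"{r.sample_id}|CM10+Q10|r{r.replicate_index}"
                    for r in meta.itertuples()]
    clusters = []
    for prefix, m in (("CM10", matrix_cm10), ("Q10", matrix_q10)):
        for cl in m.clusters:
            clusters.append(PeakCluster(id=f"{prefix}:{cl.id}",
                                        center_mz=cl.center_mz,
                                        window=cl.window, support=cl.support))
    return IntensityMatrix(values=values, samples=meta, clusters=clusters)
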