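"""Synthetic SELDI-like cohort generator with known ground truth.

Emulates a protein-profiling case/control study on ProteinChip arrays:
three patient classes (benign, LMP, cancer), one spectrum per sample per
surface, stratified allocation of samples to chips, technical replicates on
a subset of samples, per-chip intensity offsets, per-spectrum total-ion-
current scale factors, an exponentially decaying chemical-noise baseline
and additive detector noise.

All randomness derives from a single seed through ``numpy.random.SeedSequence``
spawn keys indexed by (sample, surface, replicate), so any subset of the
cohort is reproducible independently of generation order.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Spectrum, SpecError, validate_sample_table

CLASSES = ("benign", "LMP", "cancer")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Intensity effects (class differences, chip offsets, biological spread)
    act on the log2 amplitude of the underlying peaks; fold changes are
    natural-scale ratios applied to the cancer class relative to benign.
    """

    n_per_class: dict = field(default_factory=lambda: {"cancer": 53, "LMP": 18, "benign": 57})
    surfaces: tuple = ("CM10", "Q10")
    specimen: str = "serum"
    cohort: str = "training"
    mz_range: tuple = (1500.0, 20000.0)
    n_points: int = 8000
    resolution: float = 400.0          # peak FWHM = m/z / resolution
    n_background_peaks: int = 80
    n_marker_peaks: int = 10
    marker_fold_changes: tuple = (2.0, 2.0, 2.0, 2.0, 2.0, 0.5, 0.5, 0.5, 0.5, 0.5)
    lmp_profile: str = "benign-like"   # "benign-like" | "intermediate" | "distinct"
    bio_sd: float = 2.0 / 3.0          # between-sample log2 sd within class
    baseline: tuple = (50.0, 3000.0, 1.0)   # (amplitude A, decay tau Da, offset c)
    noise_sd: tuple = (0.5, 1e-5)      # sigma(m/z) = sigma0 + slope * m/z
    tic_scale_sd: float = 0.2          # log-normal sd of per-spectrum scale factor
    chip_capacity: int = 8             # spots per ProteinChip array
    chip_effect_sd: float = 0.3        # log2 sd of per-chip offsets (20% of peaks)
    chip_effect_frac: float = 0.2
    replicate_frac: float = 0.0625     # duplicates ~ one per two chips at capacity 8
    seed: int = 0
    #: seed of the peak landscape (positions, amplitudes, class means); a
    #: validation cohort shares the training cohort's structure_seed while
    #: drawing new patients under its own seed.  None = same as seed.
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.mz_range
        if lo <= 0 or lo >= hi:
            raise SpecError("mz_range must satisfy 0 < lo < hi")
        if any(fc <= 0 for fc in self.marker_fold_changes):
            raise SpecError("fold changes must be > 0")
        if len(self.marker_fold_changes) < self.n_marker_peaks:
            raise SpecError("need one fold change per marker peak")
        for name in ("bio_sd", "tic_scale_sd", "chip_effect_sd"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if self.lmp_profile not in ("benign-like", "intermediate", "distinct"):
            raise SpecError(f"unknown lmp_profile {self.lmp_profile!r}")


def serum_config(**overrides) -> SimConfig:
    """Serum-like training cohort: 53 cancer / 18 LMP / 57 benign, LMP ~ benign."""
    return SimConfig(**overrides)


def tissue_config(**overrides) -> SimConfig:
    """Tissue-like cohort: 40 cancer / 20 LMP / 24 benign, LMP distinct."""
    defaults = dict(
        n_per_class={"cancer": 40, "LMP": 20, "benign": 24},
        specimen="tissue", mz_range=(2000.0, 50000.0), lmp_profile="distinct")
    defaults.update(overrides)
    return SimConfig(**defaults)


@dataclass
class GroundTruth:
    """What was planted: marker positions, class means, chips, scale factors."""

    marker_mz: dict                 # surface -> array of marker m/z
    class_means: dict               # surface -> DataFrame (markers x classes, log2)
    background_mz: dict             # surface -> array of background m/z
    base_amplitude: dict            # surface -> array of log2 amplitudes (all peaks)
    chip_offsets: dict              # (surface, chip_id) -> array over all peaks
    scale_factors: dict             # spectrum key -> multiplicative factor
    samples: pd.DataFrame


# ---------------------------------------------------------------------------
# grid and rendering
# ---------------------------------------------------------------------------

def make_mz_grid(mz_range: tuple, n_points: int) -> np.ndarray:
    """TOF-like m/z grid: equal steps in time of flight, m/z proportional to t^2.

    Spacing therefore grows proportionally to sqrt(m/z).
    """
    lo, hi = mz_range
    if lo <= 0:
        raise SpecError("mz_range lower bound must be > 0")
    if n_points < 2:
        raise SpecError("n_points must be >= 2")
    t = np.linspace(math.sqrt(lo), math.sqrt(hi), n_points)
    return t * t


_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def render_spectrum(peaks, config: SimConfig, rng: np.random.Generator,
                    mz: np.ndarray | None = None, scale: float = 1.0) -> np.ndarray:
    """Render one intensity trace on the grid.

    ``peaks`` is a sequence of (m/z, log2 amplitude); peak height is
    2**amplitude, width FWHM = m/z / resolution.  Gaussian detector noise
    with sd sigma0 + slope*m/z is added after scaling; negative values are
    not clipped (handled downstream by baseline/zero rules).
    """
    if mz is None:
        mz = make_mz_grid(config.mz_range, config.n_points)
    lo, hi = config.mz_range
    signal = np.zeros_like(mz)
    for center, amp in peaks:
        if not (lo <= center <= hi):
            raise SpecError(f"peak at {center} outside mz_range {config.mz_range}")
        sigma = (center / config.resolution) * _FWHM_TO_SIGMA
        a = np.searchsorted(mz, center - 5 * sigma)
        b = np.searchsorted(mz, center + 5 * sigma)
        window = mz[a:b]
        signal[a:b] += (2.0 ** amp) * np.exp(-0.5 * ((window - center) / sigma) ** 2)
    A, tau, c = config.baseline
    signal += A * np.exp(-mz / tau) + c
    sigma0, slope = config.noise_sd
    noise_sd = sigma0 + slope * mz
    intensity = scale * signal
    if sigma0 > 0 or slope > 0:
        intensity = intensity + rng.normal(0.0, 1.0, size=mz.shape) * noise_sd
    return intensity


# ---------------------------------------------------------------------------
# chip allocation
# ---------------------------------------------------------------------------

def _spot_names(capacity: int) -> list[str]:
    if capacity <= 26:
        return list(string.ascii_uppercase[:capacity])
    return [f"s{i + 1}" for i in range(capacity)]


def assign_chips(samples: pd.DataFrame, chip_capacity: int,
                 replicate_frac: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Allocate samples to chips, stratified by class, and add replicate rows.

    Within each class, shuffled samples are dealt round-robin over the chips,
    so every chip's count for a class is within one sample of the cohort
    proportion.  A fraction ``replicate_frac`` of samples is duplicated with
    ``replicate_index`` 2 on a different spot (same chip when a spot is free,
    emulating intra-chip technical replicates).
    """
    if chip_capacity < 1:
        raise SpecError("chip_capacity must be >= 1")
    classes = sorted(samples["class_label"].unique())
    if chip_capacity < len(classes):
        raise SpecError("chip_capacity must be >= number of classes")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(samples)
    n_rep = int(round(replicate_frac * n))
    n_chips = max(1, math.ceil((n + n_rep) / chip_capacity))

    while True:
        chip_of = np.empty(n, dtype=int)
        offset = 0
        for cls in classes:
            idx = np.flatnonzero(samples["class_label"].to_numpy() == cls)
            idx = rng.permutation(idx)
            chip_of[idx] = (np.arange(len(idx)) + offset) % n_chips
            offset += len(idx)
        loads = np.bincount(chip_of, minlength=n_chips)
        if loads.max() <= chip_capacity:
            break
        n_chips += 1

    width = max(2, len(str(n_chips)))
    chip_names = [f"chip{i + 1:0{width}d}" for i in range(n_chips)]
    spots = _spot_names(chip_capacity)
    spot_cursor = np.zeros(n_chips, dtype=int)
    out = samples.copy().reset_index(drop=True)
    out["chip_id"] = [chip_names[c] for c in chip_of]
    out["spot"] = ""
    out["replicate_index"] = 1
    for i in range(n):
        c = chip_of[i]
        out.loc[i, "spot"] = spots[spot_cursor[c]]
        spot_cursor[c] += 1

    rep_rows = []
    if n_rep > 0:
        chosen = rng.choice(n, size=n_rep, replace=False)
        for i in sorted(chosen):
            home = chip_of[i]
            # prefer the sample's own chip (intra-chip replicate), else the
            # chip with the most free spots
            if spot_cursor[home] < chip_capacity:
                c = home
            else:
                c = int(np.argmin(spot_cursor))
                if spot_cursor[c] >= chip_capacity:
                    chip_names.append(f"chip{len(chip_names) + 1:0{width}d}")
                    spot_cursor = np.append(spot_cursor, 0)
                    c = len(chip_names) - 1
            row = out.iloc[i].copy()
            row["chip_id"] = chip_names[c]
            row["spot"] = spots[spot_cursor[c]]
            row["replicate_index"] = 2
            spot_cursor[c] += 1
            rep_rows.append(row)
    if rep_rows:
        out = pd.concat([out, pd.DataFrame(rep_rows)], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _draw_peak_positions(rng: np.random.Generator, mz_range: tuple, n_peaks: int,
                         min_rel_gap: float = 0.012) -> np.ndarray:
    """Log-uniform peak positions with a minimum relative spacing.

    The spacing floor (1.2% by default) keeps planted peaks resolvable and
    well outside the 0.3% clustering window, so cluster recovery against
    ground truth is unambiguous.
    """
    lo, hi = mz_range
    span = math.log(hi / lo)
    if n_peaks * math.log1p(min_rel_gap) > 0.9 * span:
        raise SpecError("too many peaks for mz_range at the required spacing")
    positions: list[float] = []
    attempts = 0
    while len(positions) < n_peaks:
        cand = lo * math.exp(rng.uniform(0.03 * span, 0.97 * span))
        if all(abs(cand - p) / ((cand + p) / 2) > min_rel_gap for p in positions):
            positions.append(cand)
        attempts += 1
        if attempts > 200 * n_peaks:
            raise SpecError("failed to place peaks at the required spacing")
    return np.sort(np.asarray(positions))


def _class_mean_table(config: SimConfig, marker_base: np.ndarray,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Per-class mean log2 amplitude for each marker peak.

    Cancer gets the configured fold change relative to benign.  LMP follows
    the chosen profile: identical to benign ("benign-like", the serum
    scenario), halfway shifts ("intermediate"), or its own shift pattern on
    alternating markers ("distinct", the tissue scenario).
    """
    k = config.n_marker_peaks
    shifts = np.log2(np.asarray(config.marker_fold_changes[:k], dtype=float))
    means = pd.DataFrame(index=range(k), columns=list(CLASSES), dtype=float)
    means["benign"] = marker_base
    means["cancer"] = marker_base + shifts
    if config.lmp_profile == "benign-like":
        means["LMP"] = marker_base
    elif config.lmp_profile == "intermediate":
        means["LMP"] = marker_base + shifts / 2.0
    else:  # distinct: LMP shifted on even markers where cancer is not, and
        # matches cancer on odd markers — separable from both classes
        lmp = marker_base.copy()
        lmp[0::2] += shifts[0::2] * rng.choice([-1.0, 1.0], size=len(lmp[0::2]))
        lmp[1::2] += shifts[1::2]
        means["LMP"] = lmp
    return means


def build_sample_table(config: SimConfig) -> pd.DataFrame:
    """Sample metadata rows (one per physical sample, before chip allocation)."""
    rows = []
    prefix = {"training": "T", "validation": "V"}.get(config.cohort, "S")
    i = 0
    for cls in CLASSES:
        for _ in range(int(config.n_per_class.get(cls, 0))):
            i += 1
            rows.append({
                "sample_id": f"{prefix}{i:03d}",
                "class_label": cls,
                "specimen": config.specimen,
                "cohort": config.cohort,
            })
    return pd.DataFrame(rows)


def generate_cohort(config: SimConfig):
    """Generate (spectra, sample table, ground truth) for one cohort.

    One spectrum per sample x surface x replicate.  Peak sets are drawn
    independently per surface (distinct chip chemistries retain different
    proteins).  A sample's biological peak amplitudes are shared between its
    technical replicates; measurement noise, chip offsets and the
    total-ion-current scale factor are per spectrum.
    """
    root = np.random.SeedSequence(config.seed)
    struct_rng = np.random.default_rng(root.spawn(1)[0])

    samples = build_sample_table(config)
    samples = assign_chips(samples, config.chip_capacity, config.replicate_frac,
                           seed=int(struct_rng.integers(2 ** 31)))
    validate_sample_table(samples.assign(
        surface=config.surfaces[0]) if "surface" not in samples else samples)

    n_total_peaks = config.n_background_peaks + config.n_marker_peaks
    structure_seed = (config.structure_seed if config.structure_seed is not None
                      else config.seed)
    marker_mz, class_means, background_mz, base_amp, chip_offsets = {}, {}, {}, {}, {}
    peak_mz = {}
    chips = sorted(samples["chip_id"].unique())
    for s_idx, surface in enumerate(config.surfaces):
        srng = np.random.default_rng(np.random.SeedSequence(
            structure_seed, spawn_key=(1000 + s_idx,)))
        pos = _draw_peak_positions(srng, config.mz_range, n_total_peaks)
        amp = srng.uniform(3.0, 6.5, size=n_total_peaks)
        marker_idx = np.sort(srng.choice(n_total_peaks, size=config.n_marker_peaks,
                                         replace=False))
        is_marker = np.zeros(n_total_peaks, dtype=bool)
        is_marker[marker_idx] = True
        peak_mz[surface] = pos
        marker_mz[surface] = pos[marker_idx]
        background_mz[surface] = pos[~is_marker]
        base_amp[surface] = amp
        class_means[surface] = _class_mean_table(config, amp[marker_idx], srng)
        class_means[surface].index = [f"{m:.4f}" for m in pos[marker_idx]]
        for c_idx, chip in enumerate(chips):
            crng = np.random.default_rng(np.random.SeedSequence(
                config.seed, spawn_key=(2000 + s_idx, c_idx)))
            offs = np.zeros(n_total_peaks)
            n_aff = int(round(config.chip_effect_frac * n_total_peaks))
            if n_aff and config.chip_effect_sd > 0:
                aff = crng.choice(n_total_peaks, size=n_aff, replace=False)
                offs[aff] = crng.normal(0.0, config.chip_effect_sd, size=n_aff)
            chip_offsets[(surface, chip)] = offs

    # biological per-sample amplitudes, shared across technical replicates
    sample_ids = samples.loc[samples["replicate_index"] == 1, "sample_id"].tolist()
    bio_dev = {}
    for j, sid in enumerate(sample_ids):
        brng = np.random.default_rng(np.random.SeedSequence(
            config.seed, spawn_key=(3000, j)))
        for surface in config.surfaces:
            bio_dev[(sid, surface)] = (
                brng.normal(0.0, config.bio_sd, size=n_total_peaks)
                if config.bio_sd > 0 else np.zeros(n_total_peaks))

    mz_grid = make_mz_grid(config.mz_range, config.n_points)
    spectra, scale_factors, sample_rows = [], {}, []
    for row_idx, row in enumerate(samples.itertuples()):
        for s_idx, surface in enumerate(config.surfaces):
            key_seq = np.random.SeedSequence(
                config.seed, spawn_key=(4000 + s_idx, row_idx))
            rng = np.random.default_rng(key_seq)
            scale = (math.exp(rng.normal(0.0, config.tic_scale_sd))
                     if config.tic_scale_sd > 0 else 1.0)
            amps = base_amp[surface].copy()
            cm = class_means[surface]
            # class effect on markers
            marker_sel = np.isin(peak_mz[surface], marker_mz[surface])
            amps[marker_sel] = cm[row.class_label].to_numpy()
            amps = amps + bio_dev[(row.sample_id, surface)]
            amps = amps + chip_offsets[(surface, row.chip_id)]
            intensity = render_spectrum(
                list(zip(peak_mz[surface], amps)), config, rng,
                mz=mz_grid, scale=scale)
            spec = Spectrum(
                sample_id=row.sample_id, mz=mz_grid, intensity=intensity,
                surface=surface, specimen=config.specimen, cohort=config.cohort,
                class_label=row.class_label, chip_id=row.chip_id, spot=row.spot,
                replicate_index=int(row.replicate_index))
            spectra.append(spec)
            scale_factors[spec.key] = scale
            meta = {c: getattr(row, c) for c in
                    ("sample_id", "class_label", "specimen", "cohort",
                     "chip_id", "spot", "replicate_index")}
            meta["surface"] = surface
            sample_rows.append(meta)

    table = pd.DataFrame(sample_rows)[
        ["sample_id", "class_label", "specimen", "surface", "cohort",
         "chip_id", "spot", "replicate_index"]]
    validate_sample_table(table)
    truth = GroundTruth(
        marker_mz=marker_mz, class_means=class_means,
        background_mz=background_mz, base_amplitude=base_amp,
        chip_offsets=chip_offsets, scale_factors=scale_factors,
        samples=samples)
    return spectra, table, truth
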