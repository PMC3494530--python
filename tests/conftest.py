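import numpy as np
import pandas as pd
import pytest

from seldiflow import IntensityMatrix, SimConfig, Spectrum, generate_cohort
from seldiflow.peaks import PeakCluster


def make_matrix(values, labels, chip_ids=None, sample_ids=None,
                replicate_index=None, surface="CM10", centers=None):
    """Build an IntensityMatrix straight from an array (test helper)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i:03d}" for i in range(n)]
    replicate_index = replicate_index or [1] * n
    chip_ids = chip_ids or ["chip01"] * n
    centers = centers if centers is not None else 2000.0 + 100.0 * np.arange(p)
    clusters = [PeakCluster(id=f"M{int(round(c))}", center_mz=float(c),
                            window=(c * 0.997, c * 1.003), support=1.0)
                for c in centers]
    samples = pd.DataFrame({
        "sample_id": sample_ids, "class_label": labels,
        "specimen": "serum", "surface": surface, "cohort": "training",
        "chip_id": chip_ids, "spot": ["A"] * n,
        "replicate_index": replicate_index})
    frame = pd.DataFrame(values, columns=[c.id for c in clusters])
    frame.index = [f"{s}|{surface}|r{r}" for s, r in
                   zip(sample_ids, replicate_index)]
    return IntensityMatrix(values=frame, samples=samples, clusters=clusters)


def small_sim_config(**overrides):
    defaults = dict(
        n_per_class={"cancer": 5, "benign": 5}, surfaces=("CM10",),
        n_points=2500, n_background_peaks=20, n_marker_peaks=4,
        marker_fold_changes=(2.0, 2.0, 0.5, 0.5), replicate_frac=0.2,
        seed=11)
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A small single-surface cohort with replicates, shared across tests."""
    cfg = small_sim_config()
    spectra, table, truth = generate_cohort(cfg)
    return cfg, spectra, table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
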