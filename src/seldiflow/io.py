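"""Data model and readers/writers for spectra, metadata and intensity matrices.

The canonical spectrum exchange format is a two-column CSV (m/z in Da,
intensity in arbitrary units).  mzML support covers single profile MS1
spectra only: a minimal lxml-based reader (64/32-bit floats, optional zlib
compression) and a writer emitting a standards-conformant document.
Intensity matrices are TSV with a metadata column block followed by one
column per peak cluster.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SURFACES = ("CM10", "Q10")
SPECIMENS = ("serum", "tissue")
COHORTS = ("training", "validation")
CLASS_LABELS = ("benign", "LMP", "cancer", "unknown")

#: metadata columns of a sample table / matrix row block, in canonical order
METADATA_COLUMNS = (
    "sample_id",
    "class_label",
    "specimen",
    "surface",
    "cohort",
    "chip_id",
    "spot",
    "replicate_index",
)


class SpecError(ValueError):
    """Raised when a spectrum, table or matrix violates its invariants."""


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """One m/z-intensity trace plus sample and chip metadata.

    Invariants: ``mz`` strictly increasing and positive, same length as
    ``intensity``, all intensities finite.  Enforced at construction.
    """

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    surface: str = "CM10"
    specimen: str = "serum"
    cohort: str = "training"
    class_label: str = "unknown"
    chip_id: str = ""
    spot: str = ""
    replicate_index: int = 1

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise SpecError("mz and intensity must be one-dimensional")
        if len(self.mz) != len(self.intensity):
            raise SpecError(
                f"length mismatch: {len(self.mz)} m/z vs {len(self.intensity)} intensities"
            )
        if len(self.mz) == 0:
            raise SpecError("no data points")
        if not np.all(np.isfinite(self.mz)) or np.any(self.mz <= 0):
            raise SpecError("m/z values must be finite and > 0")
        if np.any(np.diff(self.mz) <= 0):
            raise SpecError("m/z values must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise SpecError("intensities must be finite")
        if self.surface not in SURFACES:
            raise SpecError(f"unknown surface {self.surface!r}")
        if self.specimen not in SPECIMENS:
            raise SpecError(f"unknown specimen {self.specimen!r}")
        if self.class_label not in CLASS_LABELS:
            raise SpecError(f"unknown class label {self.class_label!r}")
        if self.replicate_index < 1:
            raise SpecError("replicate_index must be >= 1")

    @property
    def key(self) -> str:
        """Unique identifier of this physical spectrum."""
        return f"{self.sample_id}|{self.surface}|r{self.replicate_index}"

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


def _clean_mz(mz: np.ndarray, intensity: np.ndarray, source: str):
    """Sort ascending and average duplicated m/z values, warning on both."""
    if np.any(np.diff(mz) < 0):
        warnings.warn(f"{source}: m/z not sorted ascending; sorting")
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
    if np.any(np.diff(mz) == 0):
        warnings.warn(f"{source}: duplicated m/z values; averaging intensities")
        uniq, inverse = np.unique(mz, return_inverse=True)
        summed = np.bincount(inverse, weights=intensity)
        counts = np.bincount(inverse)
        mz, intensity = uniq, summed / counts
    return mz, intensity


def read_spectrum(path, dialect: str = "csv2col", metadata: dict | pd.Series | None = None) -> Spectrum:
    """Read one spectrum from ``path``.

    ``dialect`` is ``"csv2col"`` (two numeric columns, optional header) or
    ``"mzml"``.  ``metadata`` supplies the sample annotation fields.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv2col":
        mz, intensity = _read_csv2col(path)
    elif dialect == "mzml":
        mz, intensity = _read_mzml(path)
    else:
        raise SpecError(f"unknown dialect {dialect!r}")
    if len(mz) == 0:
        raise SpecError(f"{path}: no data points")
    mz, intensity = _clean_mz(mz, intensity, str(path))
    meta = dict(metadata) if metadata is not None else {}
    meta.setdefault("sample_id", path.stem)
    return Spectrum(mz=mz, intensity=intensity, **{k: v for k, v in meta.items() if k in (
        "sample_id", "surface", "specimen", "cohort", "class_label",
        "chip_id", "spot", "replicate_index")})


def _read_csv2col(path: Path):
    mz, intensity = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace("\t", ",").split(",") if p != ""]
            if len(parts) < 2:
                raise SpecError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                m, i = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # optional header line
                    continue
                raise SpecError(f"{path}:{lineno}: non-numeric row {line!r}") from None
            mz.append(m)
            intensity.append(i)
    return np.asarray(mz), np.asarray(intensity)


def write_spectrum(spectrum: Spectrum, path, dialect: str = "csv2col") -> None:
    """Write one spectrum as two-column CSV or as a minimal mzML document."""
    path = Path(path)
    if dialect == "csv2col":
        with open(path, "w") as fh:
            fh.write("mz,intensity\n")
            for m, i in zip(spectrum.mz, spectrum.intensity):
                fh.write(f"{m:.17g},{i:.17g}\n")
    elif dialect == "mzml":
        _write_mzml(spectrum, path)
    else:
        raise SpecError(f"unknown dialect {dialect!r}")


def _encode_binary(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


_MZML_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="seldiflow" version="0.1.0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="seldiflow">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="1" defaultDataProcessingRef="DP1">
      <spectrum index="0" id="scan=1" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""


def _write_mzml(spectrum: Spectrum, path: Path) -> None:
    mz_b64 = _encode_binary(spectrum.mz)
    int_b64 = _encode_binary(spectrum.intensity)
    path.write_text(_MZML_TEMPLATE.format(
        run_id=spectrum.sample_id or "run1",
        n=len(spectrum.mz),
        mz_len=len(mz_b64), mz_b64=mz_b64,
        int_len=len(int_b64), int_b64=int_b64,
    ))


def _decode_binary(node, ns: str) -> np.ndarray:
    accessions = {cv.get("accession") for cv in node.findall(f"{ns}cvParam")}
    blob = base64.b64decode((node.findtext(f"{ns}binary") or "").strip())
    if "MS:1000574" in accessions:          # zlib compression
        blob = zlib.decompress(blob)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(blob, dtype=dtype).astype(float)


def _read_mzml(path: Path):
    """Minimal mzML reader: first profile MS1 spectrum, 32/64-bit floats,
    optional zlib compression."""
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = root.tag.split("}")[0] + "}" if root.tag.startswith("{") else ""
    for spectrum in root.iter(f"{ns}spectrum"):
        level = None
        for cv in spectrum.findall(f"{ns}cvParam"):
            if cv.get("accession") == "MS:1000511":
                level = int(cv.get("value"))
        if level not in (None, 1):
            continue
        mz = intensity = None
        for arr in spectrum.iter(f"{ns}binaryDataArray"):
            accs = {cv.get("accession") for cv in arr.findall(f"{ns}cvParam")}
            if "MS:1000514" in accs:
                mz = _decode_binary(arr, ns)
            elif "MS:1000515" in accs:
                intensity = _decode_binary(arr, ns)
        if mz is not None and intensity is not None:
            return mz, intensity
    raise SpecError(f"{path}: no MS1 spectrum found")


# ---------------------------------------------------------------------------
# Sample tables
# ---------------------------------------------------------------------------

def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the invariants of a sample-metadata table and return it.

    One row per physical spectrum; ``sample_id`` must be unique within each
    ``(surface, replicate_index)`` combination.
    """
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise SpecError(f"sample table missing columns: {missing}")
    bad = set(table["class_label"]) - set(CLASS_LABELS)
    if bad:
        raise SpecError(f"unknown class labels: {sorted(bad)}")
    dup = table.duplicated(subset=["sample_id", "surface", "replicate_index"])
    if dup.any():
        raise SpecError(
            f"duplicate (sample_id, surface, replicate_index): "
            f"{table.loc[dup, 'sample_id'].tolist()}")
    return table


def read_sample_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"sample_id": str, "chip_id": str, "spot": str})
    table["replicate_index"] = table["replicate_index"].astype(int)
    return validate_sample_table(table)


def write_sample_table(table: pd.DataFrame, path) -> None:
    validate_sample_table(table)
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Intensity matrix
# ---------------------------------------------------------------------------

def make_cluster_ids(centers_mz: Sequence[float], prefix: str = "M") -> list[str]:
    """Deterministic cluster ids "M<rounded m/z>"; rounding ties get "a","b",...

    Ids are assigned in ascending m/z order, so ties are suffixed in m/z order.
    """
    centers = np.asarray(centers_mz, dtype=float)
    if np.any(np.diff(centers) < 0):
        raise SpecError("cluster centers must be sorted ascending before id assignment")
    rounded = np.round(centers).astype(int)
    ids = []
    for i, r in enumerate(rounded):
        same = np.flatnonzero(rounded == r)
        if len(same) == 1:
            ids.append(f"{prefix}{r}")
        else:
            suffix = chr(ord("a") + int(np.searchsorted(same, i)))
            ids.append(f"{prefix}{r}{suffix}")
    return ids


@dataclass
class IntensityMatrix:
    """Samples-by-peak-clusters table of log2 intensities.

    ``values`` rows are indexed by spectrum key and aligned with the
    ``samples`` metadata block (one row per spectrum, original order kept).
    ``clusters`` is the list of :class:`~seldiflow.peaks.PeakCluster`
    definitions behind the columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    clusters: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.samples):
            raise SpecError("values and samples row counts differ")
        if self.clusters and len(self.clusters) != self.values.shape[1]:
            raise SpecError("cluster list length != number of value columns")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise SpecError("intensity matrix contains non-finite values")
        vals = self.values.to_numpy()
        if vals.shape[1] and np.any(np.all(vals == 0.0, axis=0)):
            raise SpecError("intensity matrix has a constant-zero column")
        if self.values.columns.duplicated().any():
            raise SpecError("duplicate cluster ids")

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_rows(self, mask) -> "IntensityMatrix":
        return IntensityMatrix(
            values=self.values.loc[mask] if getattr(mask, "dtype", None) == bool
            else self.values.loc[mask],
            samples=self.samples.loc[np.asarray(mask)].reset_index(drop=True)
            if np.asarray(mask).dtype == bool
            else self.samples.set_index(self.values.index).loc[mask].reset_index(drop=True),
            clusters=list(self.clusters),
        )


def write_matrix(matrix: IntensityMatrix, path) -> None:
    """Write an intensity matrix as TSV (12 significant digits).

    Cluster definitions are preserved in ``# cluster`` comment lines so that
    :func:`read_matrix` reconstructs the full object.
    """
    if not np.all(np.isfinite(matrix.values.to_numpy())):
        raise SpecError("refusing to write matrix with non-finite values")
    path = Path(path)
    with open(path, "w") as fh:
        for cl in matrix.clusters:
            fh.write(
                "# cluster\t%s\t%.12g\t%.12g\t%.12g\t%.12g\n"
                % (cl.id, cl.center_mz, cl.window[0], cl.window[1], cl.support))
        header = list(METADATA_COLUMNS) + list(matrix.values.columns)
        fh.write("\t".join(header) + "\n")
        meta = matrix.samples
        vals = matrix.values.to_numpy()
        for i in range(len(meta)):
            row = [str(meta.iloc[i][c]) for c in METADATA_COLUMNS]
            row += ["%.12g" % v for v in vals[i]]
            fh.write("\t".join(row) + "\n")


def read_matrix(path) -> IntensityMatrix:
    from .peaks import PeakCluster

    path = Path(path)
    clusters = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("# cluster\t"):
                break
            _, cid, center, lo, hi, support = line.rstrip("\n").split("\t")
            clusters.append(PeakCluster(
                id=cid, center_mz=float(center),
                window=(float(lo), float(hi)), support=float(support)))
    table = pd.read_csv(path, sep="\t", comment="#",
                        dtype={"sample_id": str, "chip_id": str, "spot": str})
    meta = table[list(METADATA_COLUMNS)].copy()
    meta["replicate_index"] = meta["replicate_index"].astype(int)
    value_cols = [c for c in table.columns if c not in METADATA_COLUMNS]
    values = table[value_cols].astype(float)
    values.index = [
        f"{r.sample_id}|{r.surface}|r{r.replicate_index}" for r in meta.itertuples()]
    return IntensityMatrix(values=values, samples=meta, clusters=clusters)
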