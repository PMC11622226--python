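"""Flat binary datacube I/O for peak-picked mass spectrometry imaging data.

A *datacube* is the pixels-by-peaks intensity matrix of a peak-picked MSI
data set.  On disk it is a flat, row-major series of little-endian 32-bit
IEEE-754 floats (one spectrum per row) — ``n_spectra * n_peaks * 4`` bytes
exactly — accompanied by a JSON metadata sidecar describing the geometry:
the peak m/z axis, and the spatial regions (images) the spectrum rows are
partitioned into.

The same raw-float32 convention is used for principal-component score and
loading matrices (:class:`MatrixFile`).

Batched reading is the backbone of the out-of-core workflow: the reader
opens the file afresh for each batch and hands back an independent array,
so the peak resident footprint of a full pass is one batch, never the cube.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "DatacubeFormatError",
    "PeakList",
    "RegionInfo",
    "DatacubeMeta",
    "BatchPlan",
    "MatrixFile",
    "Datacube",
    "make_batch_plan",
    "write_datacube",
    "load_metadata",
    "open_datacube",
    "iter_batches",
    "write_matrix",
    "read_matrix",
    "load_matrix_meta",
    "convert_imzml",
]

VALUE_ENCODING = "float32 little-endian"
LAYOUT = "row-major, one spectrum per row"
_DTYPE = np.dtype("<f4")


class DatacubeFormatError(ValueError):
    """A datacube, matrix file, or sidecar violates the format contract."""


def _sidecar_path(bin_path: str | os.PathLike) -> Path:
    return Path(bin_path).with_suffix(".json")


@dataclass(frozen=True)
class PeakList:
    """The peak (feature) axis of a datacube.

    Parameters
    ----------
    mz_values:
        Peak centers in Da, strictly increasing, all positive.
    tolerance:
        Half-window used only when binning centroided imzML spectra onto
        this axis; interpreted in ``tolerance_unit``.
    tolerance_unit:
        ``"da"`` (absolute Daltons) or ``"ppm"`` (relative).
    """

    mz_values: tuple[float, ...]
    tolerance: float | None = None
    tolerance_unit: str = "da"

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz_values, dtype=float)
        if mz.size < 1:
            raise ValueError("peak list must contain at least one peak")
        if not np.all(mz > 0):
            raise ValueError("all m/z values must be positive")
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("m/z values must be strictly increasing")
        if self.tolerance_unit not in ("da", "ppm"):
            raise ValueError("tolerance_unit must be 'da' or 'ppm'")
        object.__setattr__(self, "mz_values", tuple(float(v) for v in mz))

    def __len__(self) -> int:
        return len(self.mz_values)

    def half_windows(self) -> np.ndarray:
        """Per-peak half-window in Da (requires ``tolerance``)."""
        if self.tolerance is None or self.tolerance <= 0:
            raise ValueError("peak list has no positive tolerance set")
        centers = np.asarray(self.mz_values)
        if self.tolerance_unit == "ppm":
            return centers * self.tolerance * 1e-6
        return np.full(centers.shape, float(self.tolerance))


@dataclass(frozen=True)
class RegionInfo:
    """One spatial region (a single image) within a multi-image cube."""

    label: str
    row_offset: int
    n_pixels: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError(f"region {self.label!r}: n_pixels must be >= 1")
        if self.row_offset < 0:
            raise ValueError(f"region {self.label!r}: negative row_offset")
        if self.width < 1 or self.height < 1:
            raise ValueError(f"region {self.label!r}: bad grid {self.width}x{self.height}")
        if self.width * self.height != self.n_pixels:
            raise ValueError(
                f"region {self.label!r}: grid {self.width}x{self.height} "
                f"does not hold {self.n_pixels} pixels"
            )


@dataclass(frozen=True)
class DatacubeMeta:
    """Validated metadata sidecar of a datacube."""

    n_spectra: int
    n_peaks: int
    peaks: PeakList
    regions: tuple[RegionInfo, ...]
    value_encoding: str = VALUE_ENCODING
    layout: str = LAYOUT

    def __post_init__(self) -> None:
        if self.n_spectra < 1 or self.n_peaks < 1:
            raise ValueError("n_spectra and n_peaks must be >= 1")
        if len(self.peaks) != self.n_peaks:
            raise ValueError(
                f"peak list length {len(self.peaks)} != n_peaks {self.n_peaks}"
            )
        if self.value_encoding != VALUE_ENCODING:
            raise DatacubeFormatError(f"unsupported value encoding {self.value_encoding!r}")
        regions = tuple(self.regions)
        object.__setattr__(self, "regions", regions)
        # regions must be ordered, non-overlapping, and tile [0, n_spectra)
        expect = 0
        for reg in regions:
            if reg.row_offset != expect:
                raise DatacubeFormatError(
                    f"region {reg.label!r} starts at row {reg.row_offset}, "
                    f"expected {expect} (regions must tile the cube)"
                )
            expect += reg.n_pixels
        if regions and expect != self.n_spectra:
            raise DatacubeFormatError(
                f"regions cover {expect} rows but cube has {self.n_spectra}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_spectra, self.n_peaks)

    @property
    def nbytes(self) -> int:
        """Exact binary size: n_spectra * n_peaks * 4 bytes."""
        return self.n_spectra * self.n_peaks * 4

    @property
    def size_mb(self) -> int:
        """Cube size in (decimal) megabytes, rounded to the nearest MB."""
        return round(self.nbytes / 1e6)

    def to_dict(self) -> dict:
        d = {
            "n_spectra": self.n_spectra,
            "n_peaks": self.n_peaks,
            "peak_mz": list(self.peaks.mz_values),
            "regions": [
                {
                    "label": r.label,
                    "row_offset": r.row_offset,
                    "n_pixels": r.n_pixels,
                    "width": r.width,
                    "height": r.height,
                }
                for r in self.regions
            ],
            "value_encoding": self.value_encoding,
            "layout": self.layout,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DatacubeMeta":
        try:
            peaks = PeakList(tuple(d["peak_mz"]))
            regions = tuple(
                RegionInfo(
                    label=str(r["label"]),
                    row_offset=int(r["row_offset"]),
                    n_pixels=int(r["n_pixels"]),
                    width=int(r["width"]),
                    height=int(r["height"]),
                )
                for r in d.get("regions", [])
            )
            return cls(
                n_spectra=int(d["n_spectra"]),
                n_peaks=int(d["n_peaks"]),
                peaks=peaks,
                regions=regions,
                value_encoding=d.get("value_encoding", VALUE_ENCODING),
                layout=d.get("layout", LAYOUT),
            )
        except KeyError as exc:
            raise DatacubeFormatError(f"metadata sidecar missing field {exc}") from exc


def default_meta(
    n_spectra: int,
    n_peaks: int,
    peak_mz: Sequence[float] | None = None,
    regions: Sequence[RegionInfo] | None = None,
) -> DatacubeMeta:
    """Build metadata with a placeholder m/z axis and a single flat region."""
    if peak_mz is None:
        peak_mz = [100.0 + i for i in range(n_peaks)]
    if regions is None:
        regions = [
            RegionInfo(
                label="all", row_offset=0, n_pixels=n_spectra, width=n_spectra, height=1
            )
        ]
    return DatacubeMeta(
        n_spectra=n_spectra,
        n_peaks=n_peaks,
        peaks=PeakList(tuple(peak_mz)),
        regions=tuple(regions),
    )


@dataclass(frozen=True)
class BatchPlan:
    """Partition of the spectrum rows into fixed-size batches."""

    batch_size: int
    n_batches: int
    last_batch_size: int

    def __post_init__(self) -> None:
        ok = (
            self.batch_size >= 1
            and self.n_batches >= 1
            and 1 <= self.last_batch_size <= self.batch_size
        )
        if not ok:
            raise ValueError(f"inconsistent batch plan {self}")

    @property
    def n_rows(self) -> int:
        return (self.n_batches - 1) * self.batch_size + self.last_batch_size

    def bounds(self) -> Iterator[tuple[int, int]]:
        """Yield (row_offset, n_rows) per batch, in row order."""
        for i in range(self.n_batches):
            off = i * self.batch_size
            rows = self.last_batch_size if i == self.n_batches - 1 else self.batch_size
            yield off, rows


def make_batch_plan(n_spectra: int, batch_size: int) -> BatchPlan:
    """Plan full coverage of ``n_spectra`` rows in batches of ``batch_size``."""
    if n_spectra < 1 or batch_size < 1:
        raise ValueError("n_spectra and batch_size must be >= 1")
    batch_size = min(batch_size, n_spectra)
    n_batches = -(-n_spectra // batch_size)
    last = n_spectra - (n_batches - 1) * batch_size
    return BatchPlan(batch_size=batch_size, n_batches=n_batches, last_batch_size=last)


@dataclass(frozen=True)
class Datacube:
    """Handle to an on-disk datacube: binary path plus validated metadata."""

    bin_path: Path
    meta: DatacubeMeta

    @property
    def shape(self) -> tuple[int, int]:
        return self.meta.shape

    def read_all(self) -> np.ndarray:
        """One-shot whole-cube read (naive; resident footprint is the cube)."""
        with open(self.bin_path, "rb") as fh:
            data = np.fromfile(fh, dtype=_DTYPE, count=self.meta.n_spectra * self.meta.n_peaks)
        return data.reshape(self.meta.shape)


def write_datacube(
    values: np.ndarray, meta: DatacubeMeta, path: str | os.PathLike
) -> Datacube:
    """Write ``values`` as ``<path>.bin`` + ``<path>.json`` (or to ``*.bin`` given).

    Values are cast to little-endian float32; the written file is exactly
    ``n_spectra * n_peaks * 4`` bytes and round-trips bit-exactly.
    """
    values = np.asarray(values)
    if values.ndim != 2 or values.shape != meta.shape:
        raise ValueError(f"values shape {values.shape} != metadata shape {meta.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("datacube values must be finite")
    path = Path(path)
    bin_path = path if path.suffix == ".bin" else path.with_suffix(".bin")
    data = np.ascontiguousarray(values, dtype=_DTYPE)
    with open(bin_path, "wb") as fh:
        data.tofile(fh)
    with open(_sidecar_path(bin_path), "w") as fh:
        json.dump(meta.to_dict(), fh, indent=1)
    return Datacube(bin_path=bin_path, meta=meta)


def load_metadata(path: str | os.PathLike) -> DatacubeMeta:
    """Load and validate a sidecar; enforce the byte-length invariant.

    ``path`` may point at the ``.bin`` file, the ``.json`` sidecar, or the
    common stem.  A length mismatch signals a corrupt or truncated cube and
    raises :class:`DatacubeFormatError`.
    """
    path = Path(path)
    bin_path = path if path.suffix == ".bin" else path.with_suffix(".bin")
    sidecar = _sidecar_path(bin_path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    with open(sidecar) as fh:
        meta = DatacubeMeta.from_dict(json.load(fh))
    actual = bin_path.stat().st_size
    if actual != meta.nbytes:
        raise DatacubeFormatError(
            f"{bin_path}: file is {actual} bytes but metadata declares "
            f"{meta.n_spectra} x {meta.n_peaks} x 4 = {meta.nbytes} bytes"
        )
    return meta


def open_datacube(path: str | os.PathLike) -> Datacube:
    """Open a cube, validating metadata and binary length."""
    path = Path(path)
    bin_path = path if path.suffix == ".bin" else path.with_suffix(".bin")
    return Datacube(bin_path=bin_path, meta=load_metadata(bin_path))


def _read_rows(bin_path: Path, n_peaks: int, row_offset: int, n_rows: int) -> np.ndarray:
    """Read a contiguous block of spectrum rows into a fresh array.

    The file is opened and closed per call, so nothing from previous reads
    stays resident: the reader's peak footprint is one block.
    """
    try:
        with open(bin_path, "rb") as fh:
            fh.seek(row_offset * n_peaks * 4)
            block = np.fromfile(fh, dtype=_DTYPE, count=n_rows * n_peaks)
    except OSError as exc:
        raise OSError(f"I/O failure reading rows at offset {row_offset}: {exc}") from exc
    if block.size != n_rows * n_peaks:
        raise DatacubeFormatError(
            f"short read at row offset {row_offset}: "
            f"got {block.size} values, expected {n_rows * n_peaks}"
        )
    return block.reshape(n_rows, n_peaks)


def iter_batches(
    cube: Datacube, plan: BatchPlan
) -> Iterator[tuple[int, np.ndarray]]:
    """Yield ``(row_offset, batch)`` over the cube in row order.

    Every row is yielded exactly once; each batch is an independent array
    so consumed batches are immediately reclaimable (peak resident footprint
    O(batch_size x n_peaks), never O(n_spectra x n_peaks)).
    """
    if plan.n_rows != cube.meta.n_spectra:
        raise ValueError(
            f"batch plan covers {plan.n_rows} rows, cube has {cube.meta.n_spectra}"
        )
    for off, rows in plan.bounds():
        yield off, _read_rows(cube.bin_path, cube.meta.n_peaks, off, rows)


# ---------------------------------------------------------------------------
# Score / loading matrix files


@dataclass(frozen=True)
class MatrixFile:
    """Raw float32 matrix on disk (scores or loadings) with a JSON sidecar."""

    path: Path
    n_rows: int
    n_cols: int
    role: str  # "scores" | "loadings"
    value_encoding: str = VALUE_ENCODING


def write_matrix(
    values: np.ndarray, path: str | os.PathLike, role: str = "scores"
) -> MatrixFile:
    """Write a float32 LE row-major matrix + sidecar; bit-exact round trip."""
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError("matrix must be 2-D")
    path = Path(path)
    bin_path = path if path.suffix == ".bin" else path.with_suffix(".bin")
    data = np.ascontiguousarray(values, dtype=_DTYPE)
    with open(bin_path, "wb") as fh:
        data.tofile(fh)
    mf = MatrixFile(path=bin_path, n_rows=values.shape[0], n_cols=values.shape[1], role=role)
    with open(_sidecar_path(bin_path), "w") as fh:
        json.dump({"n_rows": mf.n_rows, "n_cols": mf.n_cols, "role": mf.role}, fh)
    return mf


def load_matrix_meta(path: str | os.PathLike) -> MatrixFile:
    path = Path(path)
    bin_path = path if path.suffix == ".bin" else path.with_suffix(".bin")
    sidecar = _sidecar_path(bin_path)
    with open(sidecar) as fh:
        d = json.load(fh)
    mf = MatrixFile(
        path=bin_path, n_rows=int(d["n_rows"]), n_cols=int(d["n_cols"]), role=str(d["role"])
    )
    actual = bin_path.stat().st_size
    if actual != mf.n_rows * mf.n_cols * 4:
        raise DatacubeFormatError(
            f"{bin_path}: {actual} bytes != declared {mf.n_rows}x{mf.n_cols}x4"
        )
    return mf


def read_matrix(
    mf: MatrixFile | str | os.PathLike,
    row_offset: int = 0,
    n_rows: int | None = None,
) -> np.ndarray:
    """Read a matrix file (optionally a row window) as float32."""
    if not isinstance(mf, MatrixFile):
        mf = load_matrix_meta(mf)
    if n_rows is None:
        n_rows = mf.n_rows - row_offset
    if row_offset < 0 or row_offset + n_rows > mf.n_rows:
        raise ValueError("requested row window outside matrix")
    return _read_rows(mf.path, mf.n_cols, row_offset, n_rows)


# ---------------------------------------------------------------------------
# imzML import


def convert_imzml(
    imzml_path: str | os.PathLike,
    peaks: PeakList,
    out_path: str | os.PathLike,
    region_label: str = "imzml",
) -> Datacube:
    """Bin a centroided imzML file onto a peak list and write a datacube.

    Each imzML spectrum becomes one cube row; cell (i, j) sums the centroid
    intensities of spectrum i whose m/z lies within ``peaks.mz_values[j] ±
    tolerance``.  Where windows overlap, a centroid is assigned to the
    nearest peak center (ties to the lower index).  Spectra keep imzML pixel
    order; the region grid is derived from the imzML x/y coordinate extents
    when the pixels fill a full grid, else the region is stored flat.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    centers = np.asarray(peaks.mz_values)
    half = peaks.half_windows()
    # overlap detection is informational: assignment is always nearest-center
    overlapping = bool(np.any(centers[:-1] + half[:-1] > centers[1:] - half[1:]))

    parser = ImzMLParser(str(imzml_path))
    n_spectra = len(parser.coordinates)
    if n_spectra == 0:
        raise ValueError("imzML file contains no spectra")
    cube = np.zeros((n_spectra, len(centers)), dtype=np.float64)
    for i in range(n_spectra):
        mzs, intensities = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=float)
        intensities = np.asarray(intensities, dtype=float)
        if mzs.size == 0:
            continue
        # nearest center; ties (exact midpoint) go to the lower index
        idx = np.searchsorted(centers, mzs)
        idx_lo = np.clip(idx - 1, 0, len(centers) - 1)
        idx_hi = np.clip(idx, 0, len(centers) - 1)
        d_lo = np.abs(mzs - centers[idx_lo])
        d_hi = np.abs(mzs - centers[idx_hi])
        nearest = np.where(d_lo <= d_hi, idx_lo, idx_hi)
        inside = np.abs(mzs - centers[nearest]) <= half[nearest]
        np.add.at(cube[i], nearest[inside], intensities[inside])

    xs = [c[0] for c in parser.coordinates]
    ys = [c[1] for c in parser.coordinates]
    width = max(xs) - min(xs) + 1
    height = max(ys) - min(ys) + 1
    if width * height != n_spectra:
        width, height = n_spectra, 1
    region = RegionInfo(
        label=region_label, row_offset=0, n_pixels=n_spectra, width=width, height=height
    )
    meta = DatacubeMeta(
        n_spectra=n_spectra, n_peaks=len(centers), peaks=peaks, regions=(region,)
    )
    out = write_datacube(cube, meta, out_path)
    if overlapping:
        import warnings

        warnings.warn(
            "peak windows overlap; centroids were assigned to the nearest center",
            stacklevel=2,
        )
    return out
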