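"""Synthetic MSI-like datacubes with planted low-rank structure.

Real peak-picked MSI cubes are, to a good approximation, a handful of
spatially coherent chemical patterns plus detector noise on a positive
baseline.  The generator emulates exactly that:

    X = b + sum_i lambda_i * u_i v_i^T + sigma * eps

with ``u_i`` unit-norm, zero-mean, spatially smooth per-region pattern
vectors (orthogonalized low-frequency Gaussian random fields), ``v_i``
orthonormal loading rows, a geometric singular spectrum
``lambda_i = lambda_0 * gamma^(i-1)``, and i.i.d. standard-normal noise.
Pattern vectors are centered before orthogonalization, so the planted
per-feature variance decomposes exactly as
``sum_i lambda_i^2 v_if^2 / (N-1) + sigma^2`` in expectation.

Everything is reproducible from the seed; the same spec generates
bit-identical cubes.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage

from .datacube import (
    Datacube,
    DatacubeMeta,
    PeakList,
    RegionInfo,
    write_datacube,
    write_matrix,
)

__all__ = ["SyntheticSpec", "GroundTruth", "synthesize", "generate_datacube", "make_fixture_suite"]


def _grid_for(n_spectra: int) -> tuple[int, int]:
    """Pick a near-square (width, height) with width*height == n_spectra."""
    h = int(np.sqrt(n_spectra))
    while h > 1 and n_spectra % h:
        h -= 1
    return n_spectra // h, h


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic cube.

    ``sing0`` (lambda_0) defaults to ``20 * noise_sd * sqrt(n_spectra)`` so
    the leading pattern has a per-pixel amplitude around 20 sigma — a
    strongly structured, MSI-like cube.  ``baseline`` defaults to 3 sigma
    so most intensities are positive without clipping (clipping would
    distort the planted covariance).
    """

    n_spectra: int
    n_peaks: int
    rank: int = 8
    decay: float = 0.7  # gamma of the geometric singular spectrum
    noise_sd: float = 1.0
    sing0: float | None = None
    baseline: float | None = None
    regions: tuple[tuple[str, int, int], ...] | None = None  # (label, width, height)
    seed: int = 0
    smooth_sigma: float | None = None  # pattern correlation length, pixels

    def __post_init__(self) -> None:
        if self.rank > min(self.n_spectra, self.n_peaks):
            raise ValueError("rank exceeds min(n_spectra, n_peaks)")
        if self.rank < 0 or self.noise_sd < 0 or not 0 < self.decay < 1:
            raise ValueError("invalid spec: need rank >= 0, sigma >= 0, 0 < gamma < 1")
        if self.regions is not None:
            total = sum(w * h for _, w, h in self.regions)
            if total != self.n_spectra:
                raise ValueError(f"region grids hold {total} pixels, need {self.n_spectra}")

    @property
    def lambda0(self) -> float:
        if self.sing0 is not None:
            return self.sing0
        return 20.0 * max(self.noise_sd, 1e-12) * float(np.sqrt(self.n_spectra))

    @property
    def offset(self) -> float:
        return 3.0 * self.noise_sd if self.baseline is None else self.baseline

    @property
    def singular_spectrum(self) -> np.ndarray:
        return self.lambda0 * self.decay ** np.arange(self.rank)

    def region_infos(self) -> tuple[RegionInfo, ...]:
        layout = self.regions
        if layout is None:
            w, h = _grid_for(self.n_spectra)
            layout = (("all", w, h),)
        infos = []
        off = 0
        for label, w, h in layout:
            infos.append(RegionInfo(label=label, row_offset=off, n_pixels=w * h, width=w, height=h))
            off += w * h
        return tuple(infos)


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a synthetic cube."""

    loadings: np.ndarray  # rank x F, rows orthonormal
    patterns: np.ndarray  # N x rank, columns orthonormal, zero-mean
    singular_spectrum: np.ndarray  # length rank

    def save(self, path: str | os.PathLike) -> None:
        path = Path(path)
        write_matrix(self.loadings, path.with_suffix(".bin"), role="loadings")
        with open(path.with_suffix(".truth.json"), "w") as fh:
            json.dump({"singular_spectrum": self.singular_spectrum.tolist()}, fh)


def _smooth_fields(
    rng: np.random.Generator, regions: tuple[RegionInfo, ...], rank: int, sigma: float | None
) -> np.ndarray:
    """N x rank stack of per-region low-frequency random fields."""
    cols = []
    for _ in range(rank):
        parts = []
        for reg in regions:
            s = sigma if sigma is not None else max(min(reg.width, reg.height) / 8.0, 1.0)
            fld = rng.standard_normal((reg.height, reg.width))
            fld = ndimage.gaussian_filter(fld, sigma=s, mode="nearest")
            parts.append(fld.ravel())
        cols.append(np.concatenate(parts))
    return np.column_stack(cols)


def synthesize(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth, DatacubeMeta]:
    """Draw one cube in memory; returns (values, truth, metadata)."""
    rng = np.random.default_rng(spec.seed)
    regions = spec.region_infos()
    n, f, r = spec.n_spectra, spec.n_peaks, spec.rank

    if r > 0:
        raw = _smooth_fields(rng, regions, r, spec.smooth_sigma)
        raw -= raw.mean(axis=0)  # zero-mean before QR keeps u_i zero-mean
        u, _ = np.linalg.qr(raw)
        v, _ = np.linalg.qr(rng.standard_normal((f, r)))
        v = v.T  # r x F, rows orthonormal
        lam = spec.singular_spectrum
        signal = (u * lam) @ v
    else:
        u = np.zeros((n, 0))
        v = np.zeros((0, f))
        lam = np.zeros(0)
        signal = np.zeros((n, f))

    x = spec.offset + signal
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal((n, f))
    x = x.astype(np.float32)

    mz = tuple(100.0 + 5.0 * i for i in range(f))
    meta = DatacubeMeta(n_spectra=n, n_peaks=f, peaks=PeakList(mz), regions=regions)
    truth = GroundTruth(loadings=v, patterns=u, singular_spectrum=lam)
    return x, truth, meta


def generate_datacube(
    spec: SyntheticSpec, path: str | os.PathLike, save_truth: bool = False
) -> tuple[Datacube, GroundTruth]:
    """Draw a cube from ``spec`` and write it in datacube format."""
    x, truth, meta = synthesize(spec)
    cube = write_datacube(x, meta, path)
    if save_truth:
        stem = Path(path)
        stem = stem.with_suffix("") if stem.suffix else stem
        truth.save(stem.parent / (stem.name + "_truth"))
    return cube, truth


#: Named fixture recipes covering the main downstream code paths.
FIXTURE_SPECS: Mapping[str, SyntheticSpec] = {
    "tiny": SyntheticSpec(n_spectra=100, n_peaks=5, rank=3, seed=101),
    "medium": SyntheticSpec(n_spectra=50_000, n_peaks=100, rank=15, decay=0.7, seed=42),
    "rank1": SyntheticSpec(n_spectra=400, n_peaks=8, rank=1, noise_sd=0.0, baseline=0.0, seed=7),
    "zero_variance": SyntheticSpec(
        n_spectra=200, n_peaks=6, rank=0, noise_sd=0.0, baseline=1.0, seed=0
    ),
    "two_region": SyntheticSpec(
        n_spectra=1200,
        n_peaks=12,
        rank=4,
        seed=13,
        regions=(("left", 20, 30), ("right", 30, 20)),
    ),
}


def make_fixture_suite(
    out_dir: str | os.PathLike, names: tuple[str, ...] | None = None
) -> dict[str, dict]:
    """Generate the named fixture cubes under ``out_dir`` with a manifest.

    Each manifest entry records the spec seed, the shape, and a SHA-256
    checksum of the binary so regeneration can be verified.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for name in names or tuple(FIXTURE_SPECS):
        spec = FIXTURE_SPECS[name]
        cube, truth = generate_datacube(spec, out_dir / name)
        digest = hashlib.sha256(cube.bin_path.read_bytes()).hexdigest()
        manifest[name] = {
            "path": str(cube.bin_path),
            "n_spectra": spec.n_spectra,
            "n_peaks": spec.n_peaks,
            "rank": spec.rank,
            "seed": spec.seed,
            "sha256": digest,
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
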