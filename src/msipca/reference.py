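"""Exact and subsampled PCA comparators plus accuracy metrics.

These back the validation of the incremental fit: an in-memory dense-SVD
PCA (deliberately naive — it loads the whole cube), a pixel-subsampling
PCA that estimates the loadings from a small random fraction of spectra
(default 6.5%), and the metrics used to compare models and score sets:
sign-aligned per-component MSE and r^2, score differences as a percent of
the reference component's range, and principal angles between subspaces.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .datacube import Datacube, MatrixFile
from .ipca import IPCAModel, apply_sign_convention, transform_incremental

__all__ = [
    "ComparisonReport",
    "exact_pca",
    "subsampled_pca",
    "align_signs",
    "loading_metrics",
    "score_difference_percent",
    "principal_angles",
    "compare_loadings",
]

#: Pixel fraction of the subsampling comparator.
DEFAULT_SUBSAMPLE_FRACTION = 0.065

#: 1-based component ranges over which grouped mean r^2 is reported.
R2_GROUPS = ((1, 10), (11, 20), (21, 30))


def _model_from_matrix(x: np.ndarray, k: int, n_seen: int | None = None) -> IPCAModel:
    """Dense centered SVD of an in-memory float32 matrix -> model."""
    n, f = x.shape
    if k > f:
        raise ValueError(f"k={k} exceeds {f} features")
    if n < k:
        raise ValueError(f"{n} spectra < k={k}")
    x = np.ascontiguousarray(x, dtype=np.float32)
    mean = x.mean(axis=0, dtype=np.float64)
    m2 = np.sum((x.astype(np.float64) - mean) ** 2, axis=0)
    x_c = x - mean.astype(np.float32)
    _, s, vt = scipy.linalg.svd(x_c, full_matrices=False, overwrite_a=True)
    vt = apply_sign_convention(vt)
    n_eff = n if n_seen is None else n_seen
    ev = (s[:k].astype(np.float64)) ** 2 / (n - 1)
    total = float(np.sum(m2)) / (n - 1)
    ratio = np.clip(ev / total, 0.0, 1.0) if total > 0 else np.zeros_like(ev)
    return IPCAModel(
        n_seen=n_eff,
        n_features=f,
        k=k,
        mean=mean,
        total_variance=m2 / (n - 1),
        singular_values=s[:k].astype(np.float64),
        components=vt[:k].astype(np.float32),
        explained_variance=ev,
        explained_variance_ratio=ratio,
    )


def exact_pca(cube: Datacube, k: int | None = None) -> IPCAModel:
    """Naive full-memory PCA: load the whole cube, center, dense SVD.

    Shares the model container and sign convention with the incremental
    fit so the two are directly comparable.  Intentionally makes no
    attempt to bound memory — that is the point of comparison.
    """
    x = cube.read_all()
    if k is None:
        k = cube.meta.n_peaks
    return _model_from_matrix(x, k)


def subsampled_pca(
    cube: Datacube,
    fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    seed: int | None = None,
    k: int | None = None,
    scores_path: str | os.PathLike | None = None,
) -> tuple[IPCAModel, MatrixFile | None]:
    """PCA of a uniform random pixel subsample; scores for *all* pixels.

    ``floor(fraction * n_spectra)`` rows are drawn without replacement
    (seeded), the model is a dense PCA of that subsample (its mean centers
    every pixel), and, when ``scores_path`` is given, scores for the full
    cube are produced with the incremental transform.
    """
    meta = cube.meta
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if k is None:
        k = meta.n_peaks
    n_sample = int(np.floor(fraction * meta.n_spectra))
    if n_sample < k:
        raise ValueError(f"subsample of {n_sample} rows is smaller than k={k}")
    if fraction == 1.0:
        sub = cube.read_all()
    else:
        rng = np.random.default_rng(seed)
        rows = np.sort(rng.choice(meta.n_spectra, size=n_sample, replace=False))
        full = cube.read_all()  # comparator is in-memory by design
        sub = full[rows]
    model = _model_from_matrix(sub, k)
    scores = None
    if scores_path is not None:
        scores = transform_incremental(cube, model, scores_path)
    return model, scores


def align_signs(reference: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Flip components of ``other`` so each has nonnegative dot with the reference."""
    reference = np.asarray(reference)
    other = np.asarray(other)
    if reference.shape != other.shape:
        raise ValueError(f"shape mismatch {reference.shape} vs {other.shape}")
    dots = np.einsum("ij,ij->i", reference.astype(np.float64), other.astype(np.float64))
    signs = np.where(dots < 0, -1.0, 1.0)
    return other * signs[:, None].astype(other.dtype)


@dataclass
class ComparisonReport:
    """Per-component accuracy of one model/score set against a reference.

    ``per_component_r2`` entries are NaN where a component vector has zero
    variance (r^2 undefined), never 0.
    """

    per_component_r2: list[float]
    per_component_mse: list[float]
    grouped_r2: dict[str, float] = field(default_factory=dict)
    score_diff_stats: dict[int, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_component_r2": self.per_component_r2,
            "per_component_mse": self.per_component_mse,
            "grouped_r2": self.grouped_r2,
            "score_diff_stats": {
                str(c): list(v) for c, v in self.score_diff_stats.items()
            },
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_csv(self, path: str | os.PathLike) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["component", "r2", "mse"])
            for i, (r2, mse) in enumerate(
                zip(self.per_component_r2, self.per_component_mse), start=1
            ):
                w.writerow([i, r2, mse])


def loading_metrics(
    a: np.ndarray, b: np.ndarray, groups: Sequence[tuple[int, int]] = R2_GROUPS
) -> ComparisonReport:
    """Sign-aligned per-component MSE and squared Pearson r^2 of loadings.

    Callers align signs first (:func:`align_signs`); both metrics are
    symmetric in the arguments.  Grouped means cover 1-based component
    ranges (by default 1-10, 11-20, 21-30), restricted to components
    present; NaN entries (zero-variance vectors) are excluded from means.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    mse = np.mean((a - b) ** 2, axis=1)
    r2 = np.full(a.shape[0], np.nan)
    for i in range(a.shape[0]):
        sa, sb = a[i].std(), b[i].std()
        if sa > 0 and sb > 0:
            r2[i] = np.corrcoef(a[i], b[i])[0, 1] ** 2
    grouped: dict[str, float] = {}
    for lo, hi in groups:
        window = r2[lo - 1 : min(hi, a.shape[0])]
        window = window[~np.isnan(window)]
        if window.size:
            grouped[f"{lo}-{hi}"] = float(window.mean())
    return ComparisonReport(
        per_component_r2=[float(v) for v in r2],
        per_component_mse=[float(v) for v in mse],
        grouped_r2=grouped,
    )


def score_difference_percent(
    scores_ref: np.ndarray, scores_other: np.ndarray, component: int
) -> tuple[np.ndarray, tuple[float, float]]:
    """Per-pixel score difference as a percent of the reference PC's range.

    ``component`` is the 1-based principal-component number.  Returns the
    per-pixel percentages ``100 (ref - other) / (max(ref) - min(ref))`` and
    their (min%, max%).  Signs must be aligned beforehand.
    """
    scores_ref = np.asarray(scores_ref, dtype=np.float64)
    scores_other = np.asarray(scores_other, dtype=np.float64)
    if scores_ref.shape != scores_other.shape:
        raise ValueError(f"shape mismatch {scores_ref.shape} vs {scores_other.shape}")
    if not 1 <= component <= scores_ref.shape[1]:
        raise ValueError(f"component {component} out of range")
    ref = scores_ref[:, component - 1]
    other = scores_other[:, component - 1]
    rng = ref.max() - ref.min()
    if rng == 0:
        raise ValueError(f"component {component} has zero range in the reference")
    pct = 100.0 * (ref - other) / rng
    return pct, (float(pct.min()), float(pct.max()))


def principal_angles(subspace_a: np.ndarray, subspace_b: np.ndarray) -> np.ndarray:
    """Principal angles (radians, nondecreasing) between two row-orthonormal bases."""
    a = np.asarray(subspace_a, dtype=np.float64)
    b = np.asarray(subspace_b, dtype=np.float64)
    for name, m in (("a", a), ("b", b)):
        gram = m @ m.T
        if not np.allclose(gram, np.eye(m.shape[0]), atol=1e-4):
            raise ValueError(f"subspace_{name} rows are not orthonormal")
    if a.shape[1] != b.shape[1]:
        raise ValueError("subspaces live in different feature spaces")
    sv = scipy.linalg.svd(a @ b.T, compute_uv=False)
    return np.sort(np.arccos(np.clip(sv, 0.0, 1.0)))


def compare_loadings(
    reference: IPCAModel,
    other: IPCAModel,
    n_components: int | None = None,
) -> ComparisonReport:
    """Sign-align ``other`` to ``reference`` and compute loading metrics."""
    k = min(reference.k, other.k)
    if n_components is not None:
        k = min(k, n_components)
    ref = reference.components[:k]
    oth = align_signs(ref, other.components[:k])
    return loading_metrics(ref, oth)
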