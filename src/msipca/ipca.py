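"""Incremental PCA (sequential Karhunen-Loeve) for out-of-core datacubes.

The fit visits the cube in batches of ``d`` spectra.  Per batch it

1. updates running first/second moments (pooled mean/variance),
2. centers the batch by its own column mean,
3. stacks ``[diag(s) V ; X_c ; c]`` where ``c`` is the mean-correction row
   ``sqrt(N d / (N + d)) (mu - mu_b)``, and
4. takes a thin SVD of the stack, retaining the top-k singular values and
   right singular vectors.

Per-iteration cost is O(d F^2) time and O(d F) space (F = number of peaks),
so RAM is governed by the batch size, never the cube.  Batch data and all
SVD inputs stay in float32 for speed and footprint; the scalar/row
accumulators (N, mean, squared deviations) are kept in float64 so that
running moments stay exact far beyond 10^7 rows, at a negligible cost of
two extra float64 rows.

The default batch size is the heuristic 19x the number of peaks, clipped
to the cube length.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.linalg

from .datacube import (
    BatchPlan,
    Datacube,
    MatrixFile,
    _read_rows,
    make_batch_plan,
    write_matrix,
)

__all__ = [
    "FitState",
    "IPCAModel",
    "default_batch_size",
    "update_mean_var",
    "partial_fit",
    "fit",
    "finalize_explained_variance",
    "transform_incremental",
    "apply_sign_convention",
    "save_model",
    "load_model",
]

#: Heuristic batches-per-feature multiplier for the default batch size.
BATCH_HEURISTIC_FACTOR = 19


def default_batch_size(
    n_peaks: int, n_spectra: int, factor: int = BATCH_HEURISTIC_FACTOR
) -> int:
    """Heuristic batch size: ``factor`` (default 19) times the peak count.

    Clipped to ``n_spectra`` so a short cube is one batch; when
    ``n_spectra >= n_peaks`` the result is never below ``n_peaks`` (the
    first-batch SVD must see at least as many rows as features retained).
    """
    if n_peaks < 1 or n_spectra < 1:
        raise ValueError("n_peaks and n_spectra must be >= 1")
    return min(factor * n_peaks, n_spectra)


def apply_sign_convention(components: np.ndarray) -> np.ndarray:
    """Make each component's largest-|entry| loading positive (ties: lowest index).

    PCA loadings are sign-arbitrary; a fixed deterministic convention makes
    models comparable across batch orders and implementations.
    """
    comp = np.array(components, copy=True)
    idx = np.argmax(np.abs(comp), axis=1)
    flip = comp[np.arange(comp.shape[0]), idx] < 0
    comp[flip] *= -1
    return comp


@dataclass
class FitState:
    """Running state of an incremental fit.

    ``n_seen`` rows processed; ``mean``/``m2`` float64 per-feature running
    mean and accumulated squared deviations; ``singular_values`` (length k,
    nonincreasing) and ``components`` (k x F, rows orthonormal) from the
    rank-limited SVD.
    """

    n_features: int
    k: int
    n_seen: int = 0
    mean: np.ndarray | None = None
    m2: np.ndarray | None = None
    singular_values: np.ndarray | None = None
    components: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.k < 1 or self.k > self.n_features:
            raise ValueError(f"k={self.k} out of range [1, {self.n_features}]")
        if self.mean is None:
            self.mean = np.zeros(self.n_features, dtype=np.float64)
        if self.m2 is None:
            self.m2 = np.zeros(self.n_features, dtype=np.float64)


def update_mean_var(
    n_seen: int, mean: np.ndarray, m2: np.ndarray, batch: np.ndarray
) -> tuple[int, np.ndarray, np.ndarray]:
    """Pooled (Chan) update of running mean and squared deviations.

    Returns ``(N', mean', m2')`` for the union of the seen rows and the
    batch; agrees exactly with one-pass statistics in exact arithmetic.
    """
    batch = np.asarray(batch)
    if not np.all(np.isfinite(batch)):
        raise ValueError("batch contains non-finite values")
    d = batch.shape[0]
    if d < 1:
        raise ValueError("batch must contain at least one row")
    mu_b = batch.mean(axis=0, dtype=np.float64)
    m2_b = np.sum((batch.astype(np.float64) - mu_b) ** 2, axis=0)
    if n_seen == 0:
        return d, mu_b, m2_b
    n_new = n_seen + d
    delta = mean - mu_b
    mean_new = (n_seen * mean + d * mu_b) / n_new
    m2_new = m2 + m2_b + delta**2 * (n_seen * d / n_new)
    return n_new, mean_new, m2_new


def partial_fit(state: FitState, batch: np.ndarray) -> FitState:
    """One sequential Karhunen-Loeve update; returns the mutated state."""
    batch = np.ascontiguousarray(batch, dtype=np.float32)
    if batch.ndim != 2 or batch.shape[1] != state.n_features:
        raise ValueError(
            f"batch shape {batch.shape} incompatible with F={state.n_features}"
        )
    if not np.all(np.isfinite(batch)):
        raise ValueError("batch contains non-finite values")
    d = batch.shape[0]
    first = state.n_seen == 0
    if first and d < state.k:
        raise ValueError(
            f"first batch has {d} rows < k={state.k}; enlarge the first batch"
        )

    mu_b = batch.mean(axis=0, dtype=np.float64)
    x_c = batch - mu_b.astype(np.float32)
    if first:
        stack = x_c
    else:
        n, dd = state.n_seen, d
        corr = np.sqrt(n * dd / (n + dd)) * (state.mean - mu_b)
        stack = np.vstack(
            [
                (state.singular_values[:, None] * state.components).astype(np.float32),
                x_c,
                corr.astype(np.float32)[None, :],
            ]
        )
    _, s, vt = scipy.linalg.svd(stack, full_matrices=False, overwrite_a=True)
    vt = apply_sign_convention(vt)
    state.singular_values = s[: state.k].astype(np.float64)
    state.components = vt[: state.k].astype(np.float32)
    state.n_seen, state.mean, state.m2 = update_mean_var(
        state.n_seen, state.mean, state.m2, batch
    )
    return state


def finalize_explained_variance(state: FitState) -> tuple[np.ndarray, np.ndarray]:
    """Explained variance ``s_i^2/(N-1)`` and its ratio of total variance.

    Ratios are clamped to [0, 1]; a zero-variance cube yields all-zero
    ratios rather than NaN.
    """
    if state.n_seen < 2:
        raise ValueError("explained variance needs at least 2 rows seen")
    ev = state.singular_values**2 / (state.n_seen - 1)
    total = float(np.sum(state.m2)) / (state.n_seen - 1)
    if total > 0:
        ratio = np.clip(ev / total, 0.0, 1.0)
    else:
        ratio = np.zeros_like(ev)
    return ev, ratio


@dataclass(frozen=True)
class IPCAModel:
    """Frozen result of a fit: loadings, spectrum, and variance summaries."""

    n_seen: int
    n_features: int
    k: int
    mean: np.ndarray  # float64, length F
    total_variance: np.ndarray  # float64 per-feature variance m2/(N-1)
    singular_values: np.ndarray  # length k, nonincreasing
    components: np.ndarray  # k x F float32, rows orthonormal
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @classmethod
    def from_state(cls, state: FitState) -> "IPCAModel":
        ev, ratio = finalize_explained_variance(state)
        return cls(
            n_seen=state.n_seen,
            n_features=state.n_features,
            k=state.k,
            mean=state.mean.copy(),
            total_variance=state.m2 / (state.n_seen - 1),
            singular_values=state.singular_values.copy(),
            components=state.components.copy(),
            explained_variance=ev,
            explained_variance_ratio=ratio,
        )


def _fit_bounds(n_spectra: int, batch_size: int, k: int) -> list[tuple[int, int]]:
    """Batch bounds, enlarging the first batch to k rows when needed."""
    first = max(batch_size, k)
    first = min(first, n_spectra)
    bounds = [(0, first)]
    off = first
    while off < n_spectra:
        rows = min(batch_size, n_spectra - off)
        bounds.append((off, rows))
        off += rows
    return bounds


def fit(
    cube: Datacube,
    k: int | None = None,
    batch_size: int | None = None,
) -> IPCAModel:
    """Fit incremental PCA over an on-disk cube, one batch resident at a time.

    ``k`` defaults to the number of peaks (all components); ``batch_size``
    defaults to the 19x-peaks heuristic.  Peak additional footprint is
    O(batch_size x F + k x F) values, independent of ``n_spectra``.
    """
    meta = cube.meta
    if k is None:
        k = meta.n_peaks
    if batch_size is None:
        batch_size = default_batch_size(meta.n_peaks, meta.n_spectra)
    if meta.n_spectra < k:
        raise ValueError(f"cube has {meta.n_spectra} spectra < k={k}")
    state = FitState(n_features=meta.n_peaks, k=k)
    for off, rows in _fit_bounds(meta.n_spectra, batch_size, k):
        batch = _read_rows(cube.bin_path, meta.n_peaks, off, rows)
        partial_fit(state, batch)
    return IPCAModel.from_state(state)


def _transform_block(
    cube: Datacube, model: IPCAModel, off: int, rows: int
) -> np.ndarray:
    batch = _read_rows(cube.bin_path, cube.meta.n_peaks, off, rows)
    x_c = batch - model.mean.astype(np.float32)
    return x_c @ model.components.T  # float32 GEMM, fixed summation order


def transform_incremental(
    cube: Datacube,
    model: IPCAModel,
    out_path: str | os.PathLike,
    batch_size: int | None = None,
    concurrency: int = 1,
) -> MatrixFile:
    """Project the cube onto the loadings, writing scores batch by batch.

    Scores are ``(X - mean) V^T`` in float32, written at matching row
    offsets.  ``concurrency`` > 1 computes that many batches in worker
    threads; each batch's arithmetic is unchanged, so the output is
    bitwise identical to the sequential run, with peak footprint
    proportional to the concurrency level.
    """
    meta = cube.meta
    if model.n_features != meta.n_peaks:
        raise ValueError(
            f"model has {model.n_features} features, cube has {meta.n_peaks}"
        )
    if concurrency < 1:
        raise ValueError("concurrency must be >= 1")
    if batch_size is None:
        batch_size = default_batch_size(meta.n_peaks, meta.n_spectra)
    plan = make_batch_plan(meta.n_spectra, batch_size)

    out_path = Path(out_path)
    bin_path = out_path if out_path.suffix == ".bin" else out_path.with_suffix(".bin")
    with open(bin_path, "wb") as fh:
        fh.truncate(meta.n_spectra * model.k * 4)

    bounds = list(plan.bounds())
    scores_mm = np.memmap(
        bin_path, dtype="<f4", mode="r+", shape=(meta.n_spectra, model.k)
    )
    try:
        if concurrency == 1:
            for off, rows in bounds:
                scores_mm[off : off + rows] = _transform_block(cube, model, off, rows)
        else:
            from concurrent.futures import ThreadPoolExecutor

            with ThreadPoolExecutor(max_workers=concurrency) as pool:
                # process in waves of `concurrency` batches so at most that
                # many batches (+ their scores) are resident at once
                for i in range(0, len(bounds), concurrency):
                    wave = bounds[i : i + concurrency]
                    results = list(
                        pool.map(
                            lambda b: _transform_block(cube, model, b[0], b[1]), wave
                        )
                    )
                    for (off, rows), block in zip(wave, results):
                        scores_mm[off : off + rows] = block
        scores_mm.flush()
    finally:
        del scores_mm

    mf = MatrixFile(path=bin_path, n_rows=meta.n_spectra, n_cols=model.k, role="scores")
    with open(bin_path.with_suffix(".json"), "w") as fh:
        json.dump({"n_rows": mf.n_rows, "n_cols": mf.n_cols, "role": mf.role}, fh)
    return mf


# ---------------------------------------------------------------------------
# Model persistence


def save_model(model: IPCAModel, path: str | os.PathLike) -> None:
    """Persist loadings as a k x F float32 matrix file plus a model JSON."""
    path = Path(path)
    stem = path.with_suffix("") if path.suffix else path
    write_matrix(model.components, stem.parent / (stem.name + "_loadings.bin"), role="loadings")
    doc = {
        "n_seen": model.n_seen,
        "n_features": model.n_features,
        "k": model.k,
        "mean": model.mean.tolist(),
        "total_variance": model.total_variance.tolist(),
        "singular_values": model.singular_values.tolist(),
        "explained_variance": model.explained_variance.tolist(),
        "explained_variance_ratio": model.explained_variance_ratio.tolist(),
    }
    with open(stem.with_suffix(".model.json"), "w") as fh:
        json.dump(doc, fh)


def load_model(path: str | os.PathLike) -> IPCAModel:
    from .datacube import read_matrix

    path = Path(path)
    stem = path.name
    for suffix in (".model.json", ".json"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    stem_path = path.parent / stem
    with open(stem_path.with_suffix(".model.json")) as fh:
        doc = json.load(fh)
    components = read_matrix(stem_path.parent / (stem_path.name + "_loadings.bin"))
    return IPCAModel(
        n_seen=int(doc["n_seen"]),
        n_features=int(doc["n_features"]),
        k=int(doc["k"]),
        mean=np.asarray(doc["mean"], dtype=np.float64),
        total_variance=np.asarray(doc["total_variance"], dtype=np.float64),
        singular_values=np.asarray(doc["singular_values"], dtype=np.float64),
        components=components,
        explained_variance=np.asarray(doc["explained_variance"], dtype=np.float64),
        explained_variance_ratio=np.asarray(doc["explained_variance_ratio"], dtype=np.float64),
    )
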