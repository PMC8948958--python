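"""Spectral pre-treatment: ROI crop, fluorescence baseline correction,
wavenumber alignment, and vector normalization.

The stages run in that fixed order (the order in which the artifacts enter
the data: the fluorescence background sits under everything, laser-drift
shifts act on the corrected bands, and normalization must come last so the
other stages see raw intensities).  :func:`preprocess_dataset` enforces it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Spectrum, SpectraDataset

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "crop_roi",
    "fit_baseline",
    "subtract_baseline",
    "align_to_reference",
    "vector_normalize",
    "preprocess_dataset",
]


@dataclass
class PreprocessConfig:
    """Settings for the pre-treatment chain.

    roi: closed wavenumber interval kept for analysis (cm^-1).
    poly_order: order of the baseline polynomial (5 matches broad
        chlorophyll fluorescence).
    max_baseline_iter / baseline_tol: stopping rule of the iterative
        peak-suppressed fit.
    reference_index: spectrum all others are aligned to (first by default).
    max_shift: largest admissible wavenumber shift (cm^-1).
    """

    roi: tuple = (200.0, 1800.0)
    poly_order: int = 5
    max_baseline_iter: int = 100
    baseline_tol: float = 1e-6
    reference_index: int = 0
    max_shift: float = 10.0

    def __post_init__(self):
        if self.roi[0] >= self.roi[1]:
            raise ValueError("roi low must be < high")
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")


def crop_roi(dataset: SpectraDataset, roi=(200.0, 1800.0)) -> SpectraDataset:
    """Restrict the dataset to grid points inside the closed interval
    ``roi``; labels are untouched.  Raises if no point survives."""
    low, high = roi
    keep = (dataset.grid >= low) & (dataset.grid <= high)
    if not keep.any():
        raise ValueError(
            f"ROI [{low}, {high}] does not overlap grid "
            f"[{dataset.grid[0]}, {dataset.grid[-1]}]"
        )
    return SpectraDataset(dataset.grid[keep], dataset.matrix[:, keep], dataset.labels)


def fit_baseline(spectrum: Spectrum, poly_order: int = 5,
                 max_iter: int = 100, tol: float = 1e-6) -> np.ndarray:
    """Iterative peak-suppressed polynomial baseline (modified polyfit).

    Repeatedly (1) least-squares fit a polynomial of ``poly_order`` to the
    working signal, (2) clamp the working signal to the fitted curve
    wherever it exceeds it, until the curve's relative change falls below
    ``tol`` or ``max_iter`` is reached.  Peaks are progressively excluded
    from the fit without any peak annotation; a peak-free polynomial input
    is a fixed point.  Returns the baseline curve.
    """
    x = spectrum.wavenumbers
    y = spectrum.intensities.astype(float)
    if x.size < poly_order + 1:
        raise ValueError(
            f"need at least {poly_order + 1} points for order {poly_order}"
        )
    # fit on a scaled axis for conditioning
    mid, half = 0.5 * (x[0] + x[-1]), 0.5 * (x[-1] - x[0]) or 1.0
    u = (x - mid) / half
    vand = np.polynomial.polynomial.polyvander(u, poly_order)
    pinv = np.linalg.pinv(vand)  # one factorization serves every iteration
    if not np.all(np.isfinite(pinv)):
        raise ValueError("singular baseline fit (degenerate grid)")
    work = y.copy()
    curve = np.zeros_like(y)
    scale = max(np.max(np.abs(y)), 1e-300)
    for _ in range(max_iter):
        new_curve = vand @ (pinv @ work)
        delta = np.max(np.abs(new_curve - curve)) / scale
        curve = new_curve
        work = np.minimum(work, curve)
        if delta < tol:
            break
    return curve


def subtract_baseline(spectrum: Spectrum, baseline: np.ndarray) -> Spectrum:
    """Subtract a baseline curve; grid and metadata unchanged."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != spectrum.intensities.shape:
        raise ValueError("baseline length does not match spectrum")
    return Spectrum(spectrum.wavenumbers, spectrum.intensities - baseline,
                    dict(spectrum.meta))


def _estimate_shift(ref: np.ndarray, sig: np.ndarray, spacing: float,
                    max_shift: float) -> float:
    """Shift (cm^-1) maximizing the cross-correlation of ``sig`` with
    ``ref``, refined to sub-grid resolution by a parabola through the three
    correlations around the best integer lag."""
    ref_c = ref - ref.mean()
    sig_c = sig - sig.mean()
    if not ref_c.any() or not sig_c.any():
        logger.warning("flat spectrum in alignment; shift set to 0")
        return 0.0
    max_lag = int(np.floor(max_shift / spacing))
    if max_lag == 0:
        return 0.0
    full = np.correlate(sig_c, ref_c, mode="full")  # index n-1+lag
    n = ref.size
    lags = np.arange(-max_lag, max_lag + 1)
    window = full[n - 1 - max_lag: n + max_lag]
    best = int(np.argmax(window))
    lag = lags[best]
    # parabolic refinement on the discrete correlation peak
    frac = 0.0
    if 0 < best < window.size - 1:
        y0, y1, y2 = window[best - 1], window[best], window[best + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            frac = 0.5 * (y0 - y2) / denom
            frac = float(np.clip(frac, -0.5, 0.5))
    return (lag + frac) * spacing


def align_to_reference(dataset: SpectraDataset, reference_index: int = 0,
                       max_shift: float = 10.0) -> SpectraDataset:
    """Align every spectrum to the reference spectrum's wavenumber axis.

    For each spectrum a scalar shift delta (|delta| <= ``max_shift``) is
    estimated by cross-correlation with the reference, then the spectrum is
    linearly interpolated onto the reference grid after moving its axis by
    -delta.  The reference spectrum is returned unchanged.  Estimated
    shifts are stored in a ``wavenumber_shift`` label column.
    """
    if not 0 <= reference_index < dataset.n_spectra:
        raise IndexError(f"reference_index {reference_index} out of range")
    grid = dataset.grid
    spacing = float(np.median(np.diff(grid)))
    ref = dataset.matrix[reference_index]
    out = np.empty_like(dataset.matrix)
    shifts = np.zeros(dataset.n_spectra)
    for i in range(dataset.n_spectra):
        if i == reference_index:
            out[i] = ref
            continue
        delta = _estimate_shift(ref, dataset.matrix[i], spacing, max_shift)
        shifts[i] = delta
        # the spectrum's true axis is grid - delta; resample onto grid
        out[i] = np.interp(grid, grid - delta, dataset.matrix[i])
    labels = dataset.labels.copy()
    labels["wavenumber_shift"] = shifts
    return SpectraDataset(grid, out, labels)


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Center the intensities on their mean, then divide by the Euclidean
    length of the centered vector; the result has mean 0 and length 1.
    Constant spectra (zero length after centering) are rejected."""
    centered = spectrum.intensities - spectrum.intensities.mean()
    norm = np.linalg.norm(centered)
    if norm == 0:
        raise ValueError("constant spectrum cannot be vector-normalized")
    return Spectrum(spectrum.wavenumbers, centered / norm, dict(spectrum.meta))


def preprocess_dataset(dataset: SpectraDataset,
                       config: PreprocessConfig | None = None) -> SpectraDataset:
    """Run the full chain crop -> baseline -> align -> normalize."""
    config = config or PreprocessConfig()
    ds = crop_roi(dataset, config.roi)
    corrected = np.empty_like(ds.matrix)
    for i in range(ds.n_spectra):
        spec = ds.spectrum(i)
        baseline = fit_baseline(spec, config.poly_order,
                                config.max_baseline_iter, config.baseline_tol)
        corrected[i] = subtract_baseline(spec, baseline).intensities
    ds = SpectraDataset(ds.grid, corrected, ds.labels)
    ds = align_to_reference(ds, config.reference_index, config.max_shift)
    normalized = np.empty_like(ds.matrix)
    for i in range(ds.n_spectra):
        normalized[i] = vector_normalize(ds.spectrum(i)).intensities
    return SpectraDataset(ds.grid, normalized, ds.labels)
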