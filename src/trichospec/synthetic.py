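"""Synthetic trichome Raman spectra with a planted class structure.

Real cannabis trichome spectra are dominated by a handful of cannabinoid
bands riding on a broad chlorophyll-fluorescence background.  The generator
reproduces that structure — Lorentzian (or Gaussian) bands, a random
nonnegative 5th-order polynomial baseline, wavenumber jitter, iid detector
noise — and the sampling hierarchy of the study design it emulates:
for every variety, three trichome heads are "measured" at twenty points
each (60 spectra per class), with one multiplicative brightness effect
shared by all spectra of a trichome.

Class differences are planted as band-specific amplitude multipliers and
small center shifts (:class:`ClassEffect`), so downstream discriminant
analysis has a known ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Spectrum, SpectraDataset

__all__ = [
    "Band",
    "ClassEffect",
    "GeneratorDesign",
    "make_band_library",
    "default_class_effects",
    "default_design",
    "generate_spectrum",
    "generate_dataset",
]


@dataclass(frozen=True)
class Band:
    """One Raman band: center and FWHM in cm^-1, peak amplitude in
    arbitrary intensity units, a free-text vibrational assignment, and the
    line shape (``"lorentzian"`` — the natural Raman line shape — or
    ``"gaussian"``)."""

    center: float
    fwhm: float
    amplitude: float
    assignment: str = ""
    shape: str = "lorentzian"

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown shape {self.shape!r}")

    def profile(self, grid: np.ndarray, center: float | None = None,
                amplitude: float | None = None) -> np.ndarray:
        """Evaluate the band on ``grid``, optionally overriding center or
        amplitude (used when class effects shift/scale it)."""
        c = self.center if center is None else center
        a = self.amplitude if amplitude is None else amplitude
        x = 2.0 * (grid - c) / self.fwhm
        if self.shape == "lorentzian":
            return a / (1.0 + x * x)
        return a * np.exp(-np.log(2.0) * x * x)


@dataclass(frozen=True)
class ClassEffect:
    """Per-class band perturbations: amplitude multipliers (> 0) and center
    shift offsets (cm^-1), both keyed by the band center they apply to.
    Offsets must stay small relative to the band width (< 2 x FWHM)."""

    class_label: str
    amplitude_multipliers: Mapping[float, float] = field(default_factory=dict)
    shift_offsets: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(m <= 0 for m in self.amplitude_multipliers.values()):
            raise ValueError("amplitude multipliers must be > 0")

    def validate_against(self, bands: Sequence[Band]) -> None:
        widths = {b.center: b.fwhm for b in bands}
        for center, off in self.shift_offsets.items():
            fwhm = widths.get(center)
            if fwhm is not None and abs(off) >= 2 * fwhm:
                raise ValueError(
                    f"shift offset {off} at {center} cm^-1 exceeds 2 x fwhm ({fwhm})"
                )

    @classmethod
    def identity(cls, class_label: str) -> "ClassEffect":
        return cls(class_label)


@dataclass
class GeneratorDesign:
    """The acquisition design the generator emulates.

    ``classes`` maps class label -> genetics level ("Indica" or "Sativa").
    Per class, ``trichomes_per_class`` x ``points_per_trichome`` spectra are
    produced (default 3 x 20 = 60).  ``grid`` spans the chemometric region
    of interest, 200-1800 cm^-1 at 1 cm^-1 by default.  ``noise_sd`` is the
    iid intensity noise, ``trichome_effect_sd`` the spread of the
    per-trichome multiplicative brightness factor, ``shift_sd`` the spread
    of the per-spectrum wavenumber drift.
    """

    classes: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_CLASSES))
    trichomes_per_class: int = 3
    points_per_trichome: int = 20
    grid_low: float = 200.0
    grid_high: float = 1800.0
    grid_step: float = 1.0
    baseline_coeffs_range: tuple = (-0.8, 0.8)
    noise_sd: float = 0.01
    trichome_effect_sd: float = 0.05
    shift_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.trichomes_per_class < 0 or self.points_per_trichome < 0:
            raise ValueError("counts must be >= 0")
        if self.grid_low >= self.grid_high:
            raise ValueError("grid_low must be < grid_high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_high - self.grid_low) / self.grid_step)) + 1
        return self.grid_low + self.grid_step * np.arange(n)


#: Default study layout: four Sativa varieties and one Indica.
DEFAULT_CLASSES = (
    ("AmnesiaHaze", "Sativa"),
    ("AmnesiaHazeHypro", "Sativa"),
    ("OriginalAmnesia", "Sativa"),
    ("YGriega", "Sativa"),
    ("BlackDomina", "Indica"),
)

# Cannabinoid fingerprint library.  The assigned bands (600-1800 cm^-1)
# carry most of the intensity; the CH2-scissor band at 1438 cm^-1 is the
# global maximum, which makes it the natural normalization band.  The
# low-wavenumber entries are weak skeletal/ring deformation features whose
# amplitudes the class effects perturb.
_BAND_TABLE = (
    # center, fwhm, amplitude, assignment
    (1666, 12.0, 0.75, "C=C stretch (cannabinoids)"),
    (1634, 10.0, 0.20, "C=C stretch shoulder"),
    (1623, 12.0, 0.70, "C=C stretch (cannabinoids)"),
    (1600, 10.0, 0.45, "C=C stretch shoulder"),
    (1595, 8.0, 0.18, "aromatic ring stretch shoulder"),
    (1570, 10.0, 0.35, "C=C stretch shoulder"),
    (1495, 8.0, 0.12, "ring stretch shoulder"),
    (1438, 14.0, 1.00, "CH2 scissor bending (cannabinoids)"),
    (1386, 8.0, 0.14, "CH2/CH3 bending shoulder"),
    (1360, 8.0, 0.15, "CH2 bending shoulder"),
    (1324, 8.0, 0.15, "CH2 bending"),
    (1313, 8.0, 0.18, "CH2 bending"),
    (1297, 12.0, 0.55, "CH2 bending (cannabinoids)"),
    (1275, 8.0, 0.20, "CH2 bending shoulder"),
    (1187, 10.0, 0.25, "CH2 twist / C-O-H stretch (xylan)"),
    (1114, 10.0, 0.22, "CH2 twist / C-O-C symmetric (cellulose)"),
    (1079, 10.0, 0.30, "C-C stretch, alkyl"),
    (981, 8.0, 0.12, "ring deformation"),
    (836, 10.0, 0.20, "CH3 rocking"),
    (786, 10.0, 0.18, "CH2 rocking"),
    (570, 8.0, 0.10, "skeletal deformation"),
    (404, 7.0, 0.10, "skeletal deformation"),
    (380, 7.0, 0.10, "skeletal deformation"),
    (360, 8.0, 0.12, "skeletal deformation"),
    (350, 8.0, 0.15, "skeletal deformation"),
    (340, 6.0, 0.09, "lattice/skeletal mode"),
    (330, 6.0, 0.08, "lattice/skeletal mode"),
    (317, 6.0, 0.07, "lattice/skeletal mode"),
    (310, 6.0, 0.08, "lattice/skeletal mode"),
    (291, 6.0, 0.08, "lattice/skeletal mode"),
    (285, 8.0, 0.10, "lattice/skeletal mode"),
)


def make_band_library() -> list[Band]:
    """The default cannabinoid band library.

    Contains the assigned fingerprint bands (1666, 1623, 1600, 1570, 1438,
    1297, 1187, 1114, 1079, 836, 786 cm^-1) plus weak low-wavenumber
    skeletal features; 1438 cm^-1 (CH2 scissor) is the most intense band.
    """
    return [Band(c, f, a, assignment) for c, f, a, assignment in _BAND_TABLE]


# Discriminating-band lists planted per class.  The Indica variety differs
# from the Sativa group at low-wavenumber skeletal bands (346-362 region and
# neighbours) plus 785 and 1296-1300/1324; each Sativa variety differs at
# its own fingerprint subset.
_CLASS_EFFECT_BANDS = {
    "BlackDomina": (350, 360, 285, 291, 310, 317, 330, 340, 380, 404, 570, 786, 1297, 1324),
    "OriginalAmnesia": (1079, 1114, 1187, 1297),
    "AmnesiaHazeHypro": (1360, 1438, 1634, 1666),
    "YGriega": (1313, 1386, 1570, 1595),
    "AmnesiaHaze": (981, 1275, 1495, 1595),
}

DEFAULT_EFFECT_SIZE = 1.5


def default_class_effects(effect_size: float = DEFAULT_EFFECT_SIZE) -> dict[str, ClassEffect]:
    """Default planted effects: each class multiplies the amplitudes of its
    discriminating bands by ``effect_size`` (x1.5 by default)."""
    return {
        label: ClassEffect(label, {c: effect_size for c in centers})
        for label, centers in _CLASS_EFFECT_BANDS.items()
    }


def default_design(seed: int = 0, **overrides) -> GeneratorDesign:
    """The study-design defaults (5 classes x 3 trichomes x 20 points)."""
    return GeneratorDesign(seed=seed, **overrides)


def _baseline_curve(grid: np.ndarray, coeffs: Sequence[float]) -> np.ndarray:
    """Evaluate polynomial baseline coefficients on the normalized axis
    u = (x - mid)/halfspan in [-1, 1] (keeps coefficients O(1))."""
    coeffs = np.asarray(coeffs, dtype=float)
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("non-finite baseline coefficients")
    mid = 0.5 * (grid[0] + grid[-1])
    half = 0.5 * (grid[-1] - grid[0]) or 1.0
    u = (grid - mid) / half
    return np.polynomial.polynomial.polyval(u, coeffs)


def _draw_baseline_coeffs(rng: np.random.Generator, grid: np.ndarray,
                          coeff_range: tuple) -> np.ndarray:
    """Draw random 5th-order baseline coefficients whose curve is
    nonnegative over the grid (reject/resample; the constant term is drawn
    positive and large enough that rejection is rare)."""
    low, high = coeff_range
    scale = max(abs(low), abs(high))
    for _ in range(500):
        coeffs = rng.uniform(low, high, size=6)
        coeffs[0] = rng.uniform(1.0, 4.0) * scale
        curve = _baseline_curve(grid, coeffs)
        if curve.min() >= 0:
            return coeffs
    coeffs[0] -= curve.min()  # pragma: no cover - essentially unreachable
    return coeffs


def generate_spectrum(
    grid: np.ndarray,
    bands: Sequence[Band],
    class_effect: ClassEffect | None = None,
    baseline_coeffs: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    global_shift: float = 0.0,
    seed: int | np.random.Generator | None = None,
    amplitude_scale: float = 1.0,
    meta: Mapping | None = None,
) -> Spectrum:
    """Render one spectrum: sum of (possibly class-perturbed) bands, plus a
    polynomial baseline and iid Gaussian noise.  Identical seeds give
    bit-identical output."""
    grid = np.asarray(grid, dtype=float)
    if grid.size >= 2 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid not increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mult = class_effect.amplitude_multipliers if class_effect else {}
    offs = class_effect.shift_offsets if class_effect else {}
    intensities = np.zeros_like(grid)
    for band in bands:
        center = band.center + offs.get(band.center, 0.0) + global_shift
        amplitude = band.amplitude * mult.get(band.center, 1.0) * amplitude_scale
        intensities += band.profile(grid, center=center, amplitude=amplitude)
    if baseline_coeffs is not None:
        intensities += _baseline_curve(grid, baseline_coeffs)
    if noise_sd > 0:
        intensities += rng.normal(0.0, noise_sd, size=grid.size)
    return Spectrum(grid, intensities, dict(meta or {}))


def generate_dataset(
    design: GeneratorDesign,
    band_library: Sequence[Band] | None = None,
    class_effects: Mapping[str, ClassEffect] | None = None,
) -> SpectraDataset:
    """Generate the full hierarchical dataset described by ``design``.

    Every class contributes ``trichomes_per_class x points_per_trichome``
    spectra.  Each trichome draws one multiplicative brightness factor
    (1 + N(0, trichome_effect_sd)) shared by its spectra; each spectrum
    draws its own baseline, wavenumber shift (N(0, shift_sd)) and noise.
    Random streams are derived per spectrum from the master seed with
    counter-based spawn keys, so any subset is reproducible.
    """
    bands = make_band_library() if band_library is None else list(band_library)
    if class_effects is None:
        class_effects = default_class_effects()
    effects = {
        label: class_effects.get(label, ClassEffect.identity(label))
        for label in design.classes
    }
    for eff in effects.values():
        eff.validate_against(bands)
    grid = design.grid
    rows, records = [], []
    for ci, (label, genetics) in enumerate(design.classes.items()):
        for t in range(design.trichomes_per_class):
            t_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=design.seed, spawn_key=(ci, t))
            )
            t_factor = max(1.0 + t_rng.normal(0.0, design.trichome_effect_sd), 0.1)
            for p in range(design.points_per_trichome):
                s_rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=design.seed, spawn_key=(ci, t, p))
                )
                coeffs = _draw_baseline_coeffs(s_rng, grid, design.baseline_coeffs_range)
                shift = s_rng.normal(0.0, design.shift_sd) if design.shift_sd > 0 else 0.0
                spec = generate_spectrum(
                    grid, bands, effects[label],
                    baseline_coeffs=coeffs,
                    noise_sd=design.noise_sd,
                    global_shift=shift,
                    seed=s_rng,
                    amplitude_scale=t_factor,
                )
                rows.append(spec.intensities)
                records.append({
                    "class": label,
                    "genetics": genetics,
                    "trichome_id": f"{label}-T{t}",
                    "point_id": p,
                })
    matrix = np.array(rows, dtype=float).reshape(len(rows), grid.size)
    labels = pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=["class", "genetics", "trichome_id", "point_id"]
    )
    return SpectraDataset(grid, matrix, labels)
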