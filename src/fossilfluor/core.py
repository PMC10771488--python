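"""Domain data model for spectrally resolved fluorescence image stacks.

A microspectroscopic acquisition is a 3-D array of photon counts indexed
``(row, col, channel)`` together with a wavelength axis: every pixel carries a
full emission spectrum.  The types here — :class:`SpectralAxis`,
:class:`SpectralStack`, :class:`ElementarySpectrum`, :class:`EndmemberMatrix`,
:class:`AbundanceMaps`, :class:`PolygonROI` — are the vocabulary shared by the
unmixing solvers, the endmember-determination workflow, the synthetic scene
generator and the readers/writers.

Coordinate convention: 0-based ``(row, col)``, row 0 at the top.  A pixel
belongs to a polygon ROI iff its *center* ``(row + 0.5, col + 0.5)`` lies
inside the polygon, with the boundary counted as inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import shapely

from .errors import (
    AxisError,
    CollinearityError,
    EmptyBandError,
    EmptyROIError,
    IncompatibleTilesError,
)

__all__ = [
    "SpectralAxis",
    "SpectralStack",
    "ExcitationSeries",
    "ElementarySpectrum",
    "EndmemberMatrix",
    "AbundanceMaps",
    "PolygonROI",
    "BandAverage",
    "UNCONSTRAINED",
    "NONNEGATIVE",
    "pixel_spectrum",
    "roi_mean_spectrum",
    "band_average_map",
    "stitch_maps",
]

#: Constraint-mode flags used throughout the package.
UNCONSTRAINED = "unconstrained"
NONNEGATIVE = "nonnegative"

_AXIS_MATCH_TOL_NM = 0.01


@dataclass(frozen=True)
class SpectralAxis:
    """Emission-wavelength axis: channel centers (nm) plus nominal bandwidth.

    The detector assigns one wavelength channel per sensor row, so centers are
    strictly increasing and uniformly spaced; the spacing must agree with the
    nominal bandwidth to within 1%.
    """

    centers: np.ndarray
    bandwidth_nm: float

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size < 2:
            raise AxisError("axis needs at least 2 channel centers")
        if not np.all(np.isfinite(centers)):
            raise AxisError("axis centers must be finite")
        deltas = np.diff(centers)
        if np.any(deltas <= 0):
            raise AxisError("axis centers must be strictly increasing")
        if self.bandwidth_nm <= 0:
            raise AxisError("bandwidth_nm must be positive")
        if np.max(np.abs(deltas - self.bandwidth_nm)) > 0.01 * self.bandwidth_nm:
            raise AxisError(
                "axis spacing is not uniform / does not match bandwidth_nm"
            )

    @property
    def n_channels(self) -> int:
        return int(self.centers.size)

    @property
    def span_nm(self) -> float:
        """Width of the covered window: last−first center plus one bandwidth."""
        return float(self.centers[-1] - self.centers[0] + self.bandwidth_nm)

    def band_indices(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of channels whose centers lie in the closed band [lo, hi]."""
        if lo_nm > hi_nm:
            raise ValueError(f"lo_nm={lo_nm} exceeds hi_nm={hi_nm}")
        idx = np.nonzero((self.centers >= lo_nm) & (self.centers <= hi_nm))[0]
        if idx.size == 0:
            raise EmptyBandError(
                f"no channel center in [{lo_nm}, {hi_nm}] nm "
                f"(axis covers {self.centers[0]}–{self.centers[-1]} nm)"
            )
        return idx

    def matches(self, other: "SpectralAxis", tol_nm: float = _AXIS_MATCH_TOL_NM) -> bool:
        return (
            self.n_channels == other.n_channels
            and bool(np.all(np.abs(self.centers - other.centers) <= tol_nm))
        )

    def __eq__(self, other) -> bool:  # value semantics
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return (
            self.bandwidth_nm == other.bandwidth_nm
            and self.centers.shape == other.centers.shape
            and bool(np.array_equal(self.centers, other.centers))
        )

    def __hash__(self):
        return hash((self.centers.tobytes(), self.bandwidth_nm))


@dataclass
class SpectralStack:
    """One field of view: photon counts indexed (row, col, channel).

    ``excitation_nm`` records the two-photon excitation wavelength the stack
    was acquired at; it drives the SHG excitation rule and excitation-series
    analyses.  ``meta`` is free-form provenance (scenario, seed, file origin).
    """

    intensities: np.ndarray
    axis: SpectralAxis
    excitation_nm: float
    pixel_size_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise ValueError("intensities must be 3-D (rows, cols, channels)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if np.any(arr < 0):
            raise ValueError("photon counts must be >= 0")
        if arr.shape[2] != self.axis.n_channels:
            raise AxisError(
                f"channel dimension {arr.shape[2]} != axis channels "
                f"{self.axis.n_channels}"
            )
        self.intensities = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[2]


@dataclass
class ExcitationSeries:
    """Ordered stacks of one FOV acquired at increasing excitation wavelengths."""

    stacks: list[SpectralStack]

    def __post_init__(self):
        if not self.stacks:
            raise ValueError("series must contain at least one stack")
        shapes = {s.shape for s in self.stacks}
        if len(shapes) != 1:
            raise ValueError(f"all stacks must share spatial dims, got {shapes}")
        exc = [s.excitation_nm for s in self.stacks]
        if any(b <= a for a, b in zip(exc, exc[1:])):
            raise ValueError("excitation_nm values must be strictly increasing")

    @property
    def excitations(self) -> list[float]:
        return [s.excitation_nm for s in self.stacks]

    def __iter__(self):
        return iter(self.stacks)

    def __len__(self):
        return len(self.stacks)


class ElementarySpectrum:
    """A pure (max-normalized) emission spectrum of one fluorescent species.

    Values are nonnegative and, once finalized, peak at exactly 1.  An
    all-zero spectrum is permitted only as a *zeroed* placeholder — this is how
    the SHG endmember is represented at excitation wavelengths where no second
    harmonic is generated.
    """

    def __init__(self, name: str, values, axis: SpectralAxis, *, normalize: bool = False):
        values = np.asarray(values, dtype=float).copy()
        if values.ndim != 1 or values.size != axis.n_channels:
            raise AxisError(
                f"spectrum '{name}' length {values.size} != axis channels "
                f"{axis.n_channels}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"spectrum '{name}' has non-finite values")
        if np.any(values < 0):
            raise ValueError(f"spectrum '{name}' has negative values")
        peak = values.max()
        if normalize and peak > 0:
            values = values / peak
            peak = 1.0
        if peak != 0 and abs(peak - 1.0) > 1e-9:
            raise ValueError(
                f"spectrum '{name}' is not max-normalized (max={peak!r}); "
                "pass normalize=True to rescale"
            )
        self.name = str(name)
        self.values = values
        self.axis = axis

    @property
    def is_zeroed(self) -> bool:
        return bool(np.all(self.values == 0))

    @property
    def peak_nm(self) -> float:
        """Wavelength of the maximum channel (nan for a zeroed spectrum)."""
        if self.is_zeroed:
            return float("nan")
        return float(self.axis.centers[int(np.argmax(self.values))])

    @classmethod
    def zeroed(cls, name: str, axis: SpectralAxis) -> "ElementarySpectrum":
        return cls(name, np.zeros(axis.n_channels), axis)

    def __repr__(self):
        state = "zeroed" if self.is_zeroed else f"peak {self.peak_nm:g} nm"
        return f"ElementarySpectrum({self.name!r}, {state})"


class EndmemberMatrix:
    """The m x l mixing matrix of elementary spectra used by the solvers.

    Columns are :class:`ElementarySpectrum` objects on one shared axis with
    unique names.  Construction checks identifiability: the non-zeroed columns
    must be linearly independent (smallest singular value > 1e-8 x largest).
    Zeroed columns (see the SHG excitation rule) are excluded from the rank
    check and from the design matrix; their abundance is reported as 0.
    """

    _RANK_RTOL = 1e-8

    def __init__(self, spectra: Sequence[ElementarySpectrum]):
        spectra = list(spectra)
        if not spectra:
            raise ValueError("need at least one elementary spectrum")
        axis = spectra[0].axis
        for s in spectra[1:]:
            if not axis.matches(s.axis, tol_nm=1e-9):
                raise AxisError(f"spectrum '{s.name}' is on a different axis")
        names = [s.name for s in spectra]
        if len(set(names)) != len(names):
            raise ValueError(f"endmember names are not unique: {names}")
        self.spectra = spectra
        self.axis = axis
        self._check_rank()

    def _check_rank(self):
        active = self.active_matrix
        if active.shape[1] == 0:
            return
        if active.shape[1] > active.shape[0]:
            raise CollinearityError(
                f"{active.shape[1]} endmembers on {active.shape[0]} channels "
                "cannot be linearly independent"
            )
        sv = np.linalg.svd(active, compute_uv=False)
        if sv[-1] <= self._RANK_RTOL * sv[0]:
            pair = self._most_collinear_pair()
            msg = "endmember columns are linearly dependent"
            if pair:
                msg += f"; offending pair: {pair[0]!r} vs {pair[1]!r}"
            raise CollinearityError(msg, pair=pair)

    def _most_collinear_pair(self) -> tuple[str, str] | None:
        names = self.active_names
        if len(names) < 2:
            return None
        cols = self.active_matrix
        norms = np.linalg.norm(cols, axis=0)
        unit = cols / np.where(norms == 0, 1.0, norms)
        gram = np.abs(unit.T @ unit)
        np.fill_diagonal(gram, 0.0)
        i, j = np.unravel_index(np.argmax(gram), gram.shape)
        return (names[i], names[j])

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.spectra]

    @property
    def n_endmembers(self) -> int:
        return len(self.spectra)

    @property
    def matrix(self) -> np.ndarray:
        """Full m x l matrix, zeroed columns included (as zeros)."""
        return np.column_stack([s.values for s in self.spectra])

    @property
    def zeroed_names(self) -> list[str]:
        return [s.name for s in self.spectra if s.is_zeroed]

    @property
    def active_names(self) -> list[str]:
        return [s.name for s in self.spectra if not s.is_zeroed]

    @property
    def active_indices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.spectra) if not s.is_zeroed], dtype=int
        )

    @property
    def active_matrix(self) -> np.ndarray:
        """Design matrix restricted to non-zeroed columns."""
        active = [s.values for s in self.spectra if not s.is_zeroed]
        if not active:
            return np.empty((self.axis.n_channels, 0))
        return np.column_stack(active)

    def __getitem__(self, name: str) -> ElementarySpectrum:
        for s in self.spectra:
            if s.name == name:
                return s
        raise KeyError(name)

    def zero_column(self, name: str) -> "EndmemberMatrix":
        """Return a copy with column ``name`` replaced by a zeroed spectrum."""
        spectra = [
            ElementarySpectrum.zeroed(s.name, s.axis) if s.name == name else s
            for s in self.spectra
        ]
        return EndmemberMatrix(spectra)

    def __repr__(self):
        return f"EndmemberMatrix({self.names}, m={self.axis.n_channels})"


class AbundanceMaps:
    """Per-endmember 2-D abundance coefficient maps plus a residual-norm map.

    The primary product of unmixing a stack.  NaN marks canvas pixels not
    covered by any tile after stitching; everywhere else abundances are finite
    (and nonnegative when ``constraint == "nonnegative"``).
    """

    def __init__(self, maps: dict[str, np.ndarray], residual: np.ndarray, constraint: str):
        if constraint not in (UNCONSTRAINED, NONNEGATIVE):
            raise ValueError(f"unknown constraint flag: {constraint!r}")
        if not maps:
            raise ValueError("need at least one abundance map")
        residual = np.asarray(residual, dtype=float)
        shape = residual.shape
        clean = {}
        for name, arr in maps.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"map '{name}' shape {arr.shape} != residual shape {shape}"
                )
            if constraint == NONNEGATIVE and np.any(arr[np.isfinite(arr)] < 0):
                raise ValueError(f"nonnegative-constrained map '{name}' has values < 0")
            clean[name] = arr
        if np.any(residual[np.isfinite(residual)] < 0):
            raise ValueError("residual map has negative entries")
        self.maps = clean
        self.residual = residual
        self.constraint = constraint

    @property
    def names(self) -> list[str]:
        return list(self.maps)

    @property
    def shape(self) -> tuple[int, int]:
        return self.residual.shape

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of canvas pixels not covered by any tile."""
        return np.isnan(self.residual)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


class PolygonROI:
    """A manually delineated polygonal region of interest, in pixel units.

    Vertices are ``(row, col)`` pairs; the polygon is implicitly closed and
    must be simple (non-self-intersecting).
    """

    def __init__(self, vertices: Iterable[tuple[float, float]], label: str = ""):
        verts = [(float(r), float(c)) for r, c in vertices]
        if len(verts) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        poly = shapely.Polygon(verts)
        if not poly.is_valid:
            raise ValueError(f"polygon ROI {label!r} is self-intersecting or degenerate")
        if poly.area == 0:
            raise ValueError(f"polygon ROI {label!r} has zero area")
        self.vertices = verts
        self.label = str(label)
        self._poly = poly

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask: center (row+0.5, col+0.5) inside, boundary in."""
        rows, cols = shape
        rr, cc = np.mgrid[0:rows, 0:cols]
        pts = shapely.points(rr + 0.5, cc + 0.5)
        return shapely.covers(self._poly, pts)

    def __repr__(self):
        return f"PolygonROI({self.label!r}, {len(self.vertices)} vertices)"


# ---------------------------------------------------------------------------
# spectrum / map utilities


def pixel_spectrum(stack: SpectralStack, row: int, col: int) -> np.ndarray:
    """Return the length-m emission spectrum S at one pixel (copied)."""
    rows, cols = stack.shape
    if not (0 <= row < rows and 0 <= col < cols):
        raise IndexError(f"pixel ({row}, {col}) outside stack of shape {(rows, cols)}")
    return stack.intensities[row, col, :].copy()


def roi_mean_spectrum(stack: SpectralStack, roi: PolygonROI) -> np.ndarray:
    """Channel-wise mean spectrum over the pixels inside a polygon ROI.

    This is the averaging used to produce per-ROI emission spectra: for each
    wavelength channel, the arithmetic mean of the intensities of every pixel
    whose center falls inside the polygon.
    """
    mask = roi.mask(stack.shape)
    n = int(mask.sum())
    if n == 0:
        raise EmptyROIError(
            f"ROI {roi.label!r} contains no pixel centers on a {stack.shape} stack"
        )
    return stack.intensities[mask].mean(axis=0)


class BandAverage(NamedTuple):
    """A band-average visualization map plus the channels that produced it."""

    image: np.ndarray
    n_channels: int
    lo_nm: float
    hi_nm: float


def band_average_map(stack: SpectralStack, lo_nm: float, hi_nm: float) -> BandAverage:
    """Per-pixel mean intensity over channels with centers in [lo, hi] nm.

    Both endpoints are included: a band from 600 to 650 nm on a 1 nm axis
    averages 51 channels.
    """
    idx = stack.axis.band_indices(lo_nm, hi_nm)
    image = stack.intensities[:, :, idx].mean(axis=2)
    return BandAverage(image=image, n_channels=int(idx.size), lo_nm=lo_nm, hi_nm=hi_nm)


def stitch_maps(
    tiles: Sequence[AbundanceMaps],
    offsets: Sequence[tuple[int, int]],
) -> AbundanceMaps:
    """Place abundance-map tiles from adjacent FOVs on one common canvas.

    ``offsets[i]`` is the integer (row, col) position of tile i's top-left
    pixel.  Non-overlapping pixels are copied; overlapping pixels are averaged
    arithmetically; canvas pixels covered by no tile are NaN (missing, not 0).
    Offsets may be negative — the canvas origin shifts so everything fits.
    """
    if len(tiles) == 0:
        raise ValueError("need at least one tile")
    if len(tiles) != len(offsets):
        raise ValueError("one offset per tile required")
    ref = tiles[0]
    for t in tiles[1:]:
        if t.names != ref.names:
            raise IncompatibleTilesError(
                f"endmember names differ: {t.names} vs {ref.names}"
            )
        if t.constraint != ref.constraint:
            raise IncompatibleTilesError(
                f"constraint flags differ: {t.constraint} vs {ref.constraint}"
            )
    offs = [(int(r), int(c)) for r, c in offsets]
    min_r = min(r for r, _ in offs)
    min_c = min(c for _, c in offs)
    offs = [(r - min_r, c - min_c) for r, c in offs]
    height = max(r + t.shape[0] for (r, _), t in zip(offs, tiles))
    width = max(c + t.shape[1] for (_, c), t in zip(offs, tiles))

    count = np.zeros((height, width))
    sums = {name: np.zeros((height, width)) for name in ref.names}
    res_sum = np.zeros((height, width))
    for (r0, c0), tile in zip(offs, tiles):
        h, w = tile.shape
        sl = (slice(r0, r0 + h), slice(c0, c0 + w))
        count[sl] += 1
        res_sum[sl] += tile.residual
        for name in ref.names:
            sums[name][sl] += tile[name]

    with np.errstate(invalid="ignore"):
        covered = count > 0
        maps = {
            name: np.where(covered, s / np.maximum(count, 1), np.nan)
            for name, s in sums.items()
        }
        residual = np.where(covered, res_sum / np.maximum(count, 1), np.nan)
    return AbundanceMaps(maps=maps, residual=residual, constraint=ref.constraint)
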