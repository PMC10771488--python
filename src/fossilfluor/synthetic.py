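"""Ground-truthed synthetic microspectroscopy scenes.

Real specimens (leaf compressions in rock matrix, plant inclusions in Baltic
amber, silicified wood thin sections) cannot ship with a software package, so
this module generates spectrally resolved stacks with *known* abundance
fields and endmembers that mimic the spectral situations those specimens
present:

- a sharp matrix emission near 640 nm overlapping a broad leaf emission near
  630 nm (the hard two/three-endmember separations);
- excitation-dependent amber emission (peak shifts red and narrows as the
  excitation wavelength rises from 760 to 960 nm) with lignin-like (560 nm)
  and chlorophyll-derivative/tannin-like (650 nm) inclusions, including a
  zone where the two overlap spatially;
- silicified wood: two broad silica spectra peaking near 550 and 570 nm on a
  cellular lattice, sparse 650 nm spots, and a narrow second-harmonic line at
  half the excitation wavelength present only at 920 nm excitation.

The detector model is Poisson shot noise on the expected counts plus
additive Gaussian read noise, clipped at zero.  All randomness flows from
one explicit seed; identical (scenario, shape, seed) calls reproduce
identical scenes bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    ElementarySpectrum,
    EndmemberMatrix,
    PolygonROI,
    SpectralAxis,
    SpectralStack,
)

__all__ = [
    "NoiseParams",
    "SyntheticScene",
    "default_axis",
    "coarse_axis",
    "excitation_series_wavelengths",
    "make_gaussian_spectrum",
    "make_shg_spectrum",
    "make_amber_spectrum",
    "make_scene",
    "render_stack",
    "SCENARIOS",
]

SCENARIOS = (
    "matrix_only",
    "leaf_on_matrix",
    "leaf_three_layer",
    "amber_inclusion",
    "silicified_wood",
)

#: Gaussian widths (sigma, nm) for the two qualitative breadth classes.
SHARP_SIGMA_NM = 10.0
BROAD_SIGMA_NM = 30.0
SHG_WIDTH_NM = 5.0

#: Excitation-series design: 760 nm start, 40 nm steps, 960 nm end — six scans.
EXCITATION_START_NM = 760.0
EXCITATION_STEP_NM = 40.0
EXCITATION_STOP_NM = 960.0

#: Amber emission trend endpoints over the excitation range.
AMBER_MU_NM = (490.0, 560.0)
AMBER_SIGMA_NM = (45.0, 25.0)

_WINDOW_NM = (460.0, 660.0)  # covers every generated endmember peak


def default_axis() -> SpectralAxis:
    """200 channels of 1 nm bandwidth spanning the 200 nm default window."""
    lo, hi = _WINDOW_NM
    centers = np.arange(lo, hi, 1.0)
    return SpectralAxis(centers=centers, bandwidth_nm=1.0)


def coarse_axis() -> SpectralAxis:
    """40 channels of 5 nm bandwidth over the same window (amber preset)."""
    lo, hi = _WINDOW_NM
    centers = lo + 5.0 * np.arange(40) + 2.5
    return SpectralAxis(centers=centers, bandwidth_nm=5.0)


def excitation_series_wavelengths(
    start_nm: float = EXCITATION_START_NM,
    step_nm: float = EXCITATION_STEP_NM,
    stop_nm: float = EXCITATION_STOP_NM,
) -> tuple[float, ...]:
    """Excitation wavelengths of one series (endpoints inclusive)."""
    n = int(round((stop_nm - start_nm) / step_nm)) + 1
    return tuple(start_nm + step_nm * i for i in range(n))


@dataclass(frozen=True)
class NoiseParams:
    """Detector model: counts ~ Poisson(exposure_scale * expected) + read noise.

    ``exposure_scale`` multiplies the unit-normalized forward model into
    expected photon counts (default 1e4 ≈ well-exposed peak counts);
    ``read_noise_sd`` is the additive Gaussian sd in counts.
    """

    exposure_scale: float = 1e4
    read_noise_sd: float = 3.0
    enabled: bool = True

    def __post_init__(self):
        if self.exposure_scale <= 0:
            raise ValueError("exposure_scale must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")


@dataclass
class SyntheticScene:
    """Ground truth for one synthetic FOV.

    ``true_abundances`` maps endmember name -> 2-D nonnegative field;
    ``reference_rois`` are scenario-aware polygons (substrate-only regions,
    inclusion regions, a uniform patch) that tests and the CLI can reuse.
    """

    true_abundances: dict[str, np.ndarray]
    endmembers: EndmemberMatrix
    noise: NoiseParams
    seed: int
    scenario: str
    excitation_nm: float
    reference_rois: dict[str, PolygonROI] = dataclass_field(default_factory=dict)

    def __post_init__(self):
        shapes = {a.shape for a in self.true_abundances.values()}
        if len(shapes) != 1:
            raise ValueError("abundance fields must share one shape")
        for name, arr in self.true_abundances.items():
            if np.any(arr < 0):
                raise ValueError(f"true abundance field '{name}' has negatives")
        if set(self.true_abundances) != set(self.endmembers.names):
            raise ValueError("abundance fields must match endmember names")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.true_abundances.values())).shape


# ---------------------------------------------------------------------------
# spectra


def make_gaussian_spectrum(
    mu_nm: float, sigma_nm: float, axis: SpectralAxis, name: str = ""
) -> ElementarySpectrum:
    """Max-normalized Gaussian emission band sampled at the channel centers."""
    if sigma_nm <= 0:
        raise ValueError("sigma_nm must be > 0")
    x = (axis.centers - mu_nm) / sigma_nm
    values = np.exp(-0.5 * x * x)
    return ElementarySpectrum(name or f"G{mu_nm:g}", values, axis, normalize=True)


def make_shg_spectrum(
    excitation_nm: float, axis: SpectralAxis, width_nm: float = SHG_WIDTH_NM,
    name: str = "SHG",
) -> ElementarySpectrum:
    """Second-harmonic line: a narrow band at half the excitation wavelength.

    SHG is a coherent signal at twice the optical frequency — i.e. half the
    excitation wavelength — so 920 nm excitation puts the line at 460 nm.
    Raises if the half-wavelength falls outside the emission window (no SHG
    is then observable, e.g. 760 nm excitation with a 460–660 nm window).
    """
    peak = excitation_nm / 2.0
    if not (axis.centers[0] <= peak <= axis.centers[-1]):
        raise ValueError(
            f"SHG peak {peak:g} nm (half of {excitation_nm:g} nm) is outside "
            f"the {axis.centers[0]:g}-{axis.centers[-1]:g} nm window"
        )
    return make_gaussian_spectrum(peak, width_nm, axis, name=name)


def make_amber_spectrum(
    excitation_nm: float, axis: SpectralAxis, name: str = "Amber"
) -> ElementarySpectrum:
    """Excitation-dependent amber emission.

    As the excitation wavelength rises from 760 to 960 nm the emission peak
    shifts linearly to longer wavelengths (490 -> 560 nm) and the band
    narrows (sigma 45 -> 25 nm) — strictly monotone in both.
    """
    lo, hi = EXCITATION_START_NM, EXCITATION_STOP_NM
    if not (lo <= excitation_nm <= hi):
        raise ValueError(f"excitation {excitation_nm} nm outside [{lo}, {hi}] nm")
    t = (excitation_nm - lo) / (hi - lo)
    mu = AMBER_MU_NM[0] + t * (AMBER_MU_NM[1] - AMBER_MU_NM[0])
    sigma = AMBER_SIGMA_NM[0] + t * (AMBER_SIGMA_NM[1] - AMBER_SIGMA_NM[0])
    return make_gaussian_spectrum(mu, sigma, axis, name=name)


# ---------------------------------------------------------------------------
# geometry helpers


def _texture(rng: np.random.Generator, shape, lo=0.7, hi=1.3, smooth=4.0) -> np.ndarray:
    """Smooth multiplicative field in [lo, hi] emulating thickness/preservation."""
    raw = gaussian_filter(rng.standard_normal(shape), smooth)
    rmin, rmax = raw.min(), raw.max()
    if rmax == rmin:
        return np.full(shape, 0.5 * (lo + hi))
    return lo + (hi - lo) * (raw - rmin) / (rmax - rmin)


def _ellipse_mask(shape, center_frac, radii_frac) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    r0, c0 = center_frac[0] * rows, center_frac[1] * cols
    ra, ca = radii_frac[0] * rows, radii_frac[1] * cols
    return ((rr + 0.5 - r0) / ra) ** 2 + ((cc + 0.5 - c0) / ca) ** 2 <= 1.0


def _rect_roi(r0, c0, r1, c1, label) -> PolygonROI:
    return PolygonROI([(r0, c0), (r0, c1), (r1, c1), (r1, c0)], label=label)


def _corner_rois(shape, label_prefix="substrate", n=5) -> dict[str, PolygonROI]:
    """Five small substrate patches: four corners plus one edge midpoint."""
    rows, cols = shape
    h, w = max(rows // 8, 3), max(cols // 8, 3)
    spots = [
        (1, 1),
        (1, cols - 1 - w),
        (rows - 1 - h, 1),
        (rows - 1 - h, cols - 1 - w),
        (1, (cols - w) // 2),
    ]
    return {
        f"{label_prefix}_{i + 1}": _rect_roi(r, c, r + h, c + w, f"{label_prefix}_{i + 1}")
        for i, (r, c) in enumerate(spots[:n])
    }


# ---------------------------------------------------------------------------
# scenes


def make_scene(
    scenario: str,
    shape: tuple[int, int] = (64, 64),
    axis: SpectralAxis | None = None,
    excitation_nm: float = 760.0,
    seed: int = 0,
    noise: NoiseParams | None = None,
) -> SyntheticScene:
    """Build the ground-truth abundance fields and endmembers of one scenario.

    Scenarios: ``matrix_only``, ``leaf_on_matrix``, ``leaf_three_layer``,
    ``amber_inclusion``, ``silicified_wood``.  Shape must be at least 16x16.
    Abundance fields carry a smooth seeded texture (0.7–1.3) so recovery
    statistics are well defined even for a single-material scene.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    rows, cols = shape
    if rows < 16 or cols < 16:
        raise ValueError("shape must be at least 16x16")
    axis = axis or default_axis()
    noise = noise or NoiseParams()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))

    fields: dict[str, np.ndarray] = {}
    spectra: list[ElementarySpectrum] = []
    rois: dict[str, PolygonROI] = {}

    if scenario == "matrix_only":
        spectra = [make_gaussian_spectrum(640.0, SHARP_SIGMA_NM, axis, "matrix")]
        fields = {"matrix": _texture(rng, shape)}
        rois.update(_corner_rois(shape))

    elif scenario == "leaf_on_matrix":
        spectra = [
            make_gaussian_spectrum(640.0, SHARP_SIGMA_NM, axis, "matrix"),
            make_gaussian_spectrum(630.0, BROAD_SIGMA_NM, axis, "leaf"),
        ]
        leaf = _ellipse_mask(shape, (0.5, 0.5), (0.32, 0.28))
        fields = {
            "matrix": _texture(rng, shape) * (1.0 - 0.7 * leaf),
            "leaf": _texture(rng, shape) * leaf,
        }
        rois.update(_corner_rois(shape))
        rois["leaf"] = _rect_roi(
            rows * 0.42, cols * 0.42, rows * 0.58, cols * 0.58, "leaf"
        )

    elif scenario == "leaf_three_layer":
        spectra = [
            make_gaussian_spectrum(640.0, SHARP_SIGMA_NM, axis, "matrix"),
            make_gaussian_spectrum(620.0, BROAD_SIGMA_NM, axis, "leaf_exterior"),
            make_gaussian_spectrum(635.0, BROAD_SIGMA_NM, axis, "leaf_interior"),
        ]
        outer = _ellipse_mask(shape, (0.5, 0.5), (0.36, 0.32))
        inner = _ellipse_mask(shape, (0.5, 0.5), (0.22, 0.19))
        rim = outer & ~inner
        fields = {
            "matrix": _texture(rng, shape) * (1.0 - 0.7 * outer),
            "leaf_exterior": _texture(rng, shape) * rim,
            "leaf_interior": _texture(rng, shape) * inner,
        }
        rois.update(_corner_rois(shape))
        rois["interior"] = _rect_roi(
            rows * 0.44, cols * 0.44, rows * 0.56, cols * 0.56, "interior"
        )

    elif scenario == "amber_inclusion":
        spectra = [
            make_amber_spectrum(excitation_nm, axis, "Amber"),
            make_gaussian_spectrum(560.0, BROAD_SIGMA_NM, axis, "Lignin"),
            make_gaussian_spectrum(650.0, BROAD_SIGMA_NM, axis, "ChlorophyllDerivatives_Tannins"),
        ]
        lignin = _ellipse_mask(shape, (0.5, 0.38), (0.24, 0.22))
        chl = _ellipse_mask(shape, (0.5, 0.62), (0.24, 0.22))
        # the two inclusion fields overlap spatially between the blob centers
        fields = {
            "Amber": _texture(rng, shape),
            "Lignin": _texture(rng, shape) * lignin,
            "ChlorophyllDerivatives_Tannins": _texture(rng, shape) * chl,
        }
        rois.update(_corner_rois(shape))
        rois["lignin_only"] = _rect_roi(
            rows * 0.42, cols * 0.22, rows * 0.58, cols * 0.34, "lignin_only"
        )
        rois["chl_only"] = _rect_roi(
            rows * 0.42, cols * 0.66, rows * 0.58, cols * 0.78, "chl_only"
        )
        rois["overlap"] = _rect_roi(
            rows * 0.44, cols * 0.46, rows * 0.56, cols * 0.54, "overlap"
        )

    elif scenario == "silicified_wood":
        spectra = [
            make_gaussian_spectrum(550.0, BROAD_SIGMA_NM, axis, "S550"),
            make_gaussian_spectrum(570.0, BROAD_SIGMA_NM, axis, "S570"),
            make_gaussian_spectrum(650.0, BROAD_SIGMA_NM, axis, "ChMi650"),
        ]
        cell = max(min(rows, cols) // 6, 4)
        rr, cc = np.mgrid[0:rows, 0:cols]
        walls = (rr % cell < 2) | (cc % cell < 2)  # cellular lattice
        lumens = ~walls
        sparse = np.zeros(shape, dtype=bool)
        n_spots = max((rows * cols) // 400, 3)
        for _ in range(n_spots):
            r0 = rng.integers(2, rows - 2)
            c0 = rng.integers(2, cols - 2)
            sparse |= _ellipse_mask(shape, ((r0 + 0.5) / rows, (c0 + 0.5) / cols), (2.2 / rows, 2.2 / cols))
        fields = {
            "S550": _texture(rng, shape) * walls,
            "S570": _texture(rng, shape) * lumens,
            "ChMi650": 0.6 * _texture(rng, shape) * sparse,
        }
        if float(excitation_nm) == 920.0:
            spectra.append(make_shg_spectrum(excitation_nm, axis))
            fields["SHG"] = 0.8 * _texture(rng, shape) * walls
        rois.update(_corner_rois(shape, label_prefix="wall"))
        rois["lumen"] = _rect_roi(rows * 0.05, cols * 0.05, rows * 0.2, cols * 0.2, "lumen")

    endmembers = EndmemberMatrix(spectra)
    return SyntheticScene(
        true_abundances=fields,
        endmembers=endmembers,
        noise=noise,
        seed=int(seed),
        scenario=scenario,
        excitation_nm=float(excitation_nm),
        reference_rois=rois,
    )


def render_stack(scene: SyntheticScene) -> SpectralStack:
    """Render a scene through the forward model S = E k (+ detector noise).

    The expected spectrum of every pixel is ``exposure_scale * (E @ k_true)``.
    With noise enabled, counts are drawn Poisson(expected) plus Gaussian read
    noise, clipped at zero.  The RNG is fully determined by the scene seed.
    """
    E = scene.endmembers.matrix  # (m, l)
    names = scene.endmembers.names
    K = np.stack([scene.true_abundances[n] for n in names], axis=-1)  # (r, c, l)
    expected = scene.noise.exposure_scale * (K @ E.T)  # (r, c, m)
    if scene.noise.enabled:
        rng = np.random.default_rng(np.random.SeedSequence([scene.seed, 1]))
        counts = rng.poisson(expected).astype(float)
        if scene.noise.read_noise_sd > 0:
            counts += rng.normal(0.0, scene.noise.read_noise_sd, size=counts.shape)
        counts = np.clip(counts, 0.0, None)
    else:
        counts = expected
    return SpectralStack(
        intensities=counts,
        axis=scene.endmembers.axis,
        excitation_nm=scene.excitation_nm,
        meta={
            "scenario": scene.scenario,
            "seed": scene.seed,
            "noise_enabled": scene.noise.enabled,
            "exposure_scale": scene.noise.exposure_scale,
            "read_noise_sd": scene.noise.read_noise_sd,
        },
    )
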