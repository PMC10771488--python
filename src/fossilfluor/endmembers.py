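"""Determination of elementary spectra (endmembers) from ROI spectra.

The workflow mirrors how pure spectral signatures are obtained in practice
when no reference compounds are available:

1. image regions containing *substrate only* (rock matrix, amber resin,
   silica), average each ROI's spectrum, then average those ROI means with
   equal weight — the substrate elementary spectrum;
2. for ROIs drawn around embedded plant features, fit the composite ROI
   spectrum as a nonnegative combination of the substrate spectrum and one
   or more Gaussian emission bands; subtracting the fitted substrate part
   leaves a substrate-free *candidate* spectrum;
3. group candidates from all fields of view by similarity of emission peak
   and breadth (FWHM);
4. average each group, max-normalize, and assemble the endmember matrix with
   the substrate prepended.

A separate rule handles second harmonic generation: the SHG endmember is
only physical at excitation wavelengths where the half-wavelength line was
actually detected; at any other excitation its column is zeroed out and its
abundance reported as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .core import (
    NONNEGATIVE,
    ElementarySpectrum,
    EndmemberMatrix,
    ExcitationSeries,
    PolygonROI,
    SpectralAxis,
    SpectralStack,
    roi_mean_spectrum,
)
from .errors import CollinearityError, DecompositionError
from .unmixing import SpectralUnmixer, _lawson_hanson, unmix_stack

__all__ = [
    "GaussianComponent",
    "CandidateSpectrum",
    "EndmemberExtractor",
    "substrate_spectrum",
    "decompose_roi_spectrum",
    "group_candidates",
    "finalize_endmembers",
    "apply_excitation_rule",
    "excitation_profile",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = 2*sqrt(2 ln 2) * sigma


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian emission band used to strip the substrate from a composite."""

    mu_nm: float
    sigma_nm: float
    amplitude: float

    def __post_init__(self):
        if self.sigma_nm <= 0:
            raise ValueError("sigma_nm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def sample(self, axis: SpectralAxis) -> np.ndarray:
        x = (axis.centers - self.mu_nm) / self.sigma_nm
        return self.amplitude * np.exp(-0.5 * x * x)

    @property
    def fwhm_nm(self) -> float:
        return FWHM_FACTOR * self.sigma_nm


@dataclass
class CandidateSpectrum:
    """A substrate-free ROI spectrum awaiting grouping.

    ``values`` is the composite minus the fitted substrate contribution,
    clipped at zero (negative residual channels are measurement noise).
    """

    values: np.ndarray
    axis: SpectralAxis
    peak_nm: float
    fwhm_nm: float
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("candidate values must be >= 0")
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be > 0")


def _spectrum_peak_fwhm(values: np.ndarray, axis: SpectralAxis) -> tuple[float, float]:
    """Peak wavelength (argmax channel) and interpolated FWHM of a spectrum.

    Half-maximum crossings are located by linear interpolation; if the curve
    never falls below half maximum on one side (truncated at the window
    edge), the window edge is used for that side.
    """
    values = np.asarray(values, dtype=float)
    i_max = int(np.argmax(values))
    peak = float(axis.centers[i_max])
    vmax = values[i_max]
    if vmax <= 0:
        raise ValueError("cannot measure FWHM of an all-zero spectrum")
    half = vmax / 2.0

    def _cross(idx_range, edge):
        prev_i = i_max
        for i in idx_range:
            if values[i] < half:
                lam0, lam1 = axis.centers[i], axis.centers[prev_i]
                v0, v1 = values[i], values[prev_i]
                return float(lam0 + (half - v0) / (v1 - v0) * (lam1 - lam0))
            prev_i = i
        return float(edge)

    left = _cross(range(i_max - 1, -1, -1), axis.centers[0] - axis.bandwidth_nm / 2)
    right = _cross(range(i_max + 1, len(values)), axis.centers[-1] + axis.bandwidth_nm / 2)
    fwhm = max(right - left, axis.bandwidth_nm)  # never below one channel width
    return peak, fwhm


# ---------------------------------------------------------------------------
# step 1: substrate


def substrate_spectrum(
    stacks: Sequence[SpectralStack],
    rois: Sequence[PolygonROI],
    name: str = "substrate",
) -> ElementarySpectrum:
    """Average substrate-only ROI spectra into one elementary spectrum.

    Each ROI is averaged over its pixels first; the per-ROI means are then
    averaged with equal weight per ROI — *not* weighted by pixel count — and
    the result max-normalized.  Fewer than five substrate ROIs triggers a
    warning (spectra from a handful of regions may not average out local
    heterogeneity of the matrix).

    ``stacks`` may hold a single stack (every ROI is taken on it) or exactly
    one stack per ROI.
    """
    if len(rois) == 0:
        raise ValueError("need at least one substrate ROI")
    if len(stacks) == 1:
        stacks = list(stacks) * len(rois)
    if len(stacks) != len(rois):
        raise ValueError("provide one stack, or exactly one stack per ROI")
    axis = stacks[0].axis
    for s in stacks[1:]:
        if not axis.matches(s.axis, tol_nm=1e-9):
            raise ValueError("all substrate stacks must share one axis")
    if len(rois) < 5:
        warnings.warn(
            f"only {len(rois)} substrate ROI(s); at least 5 are recommended",
            stacklevel=2,
        )
    means = [roi_mean_spectrum(stack, roi) for stack, roi in zip(stacks, rois)]
    avg = np.mean(means, axis=0)
    return ElementarySpectrum(name, avg, axis, normalize=True)


# ---------------------------------------------------------------------------
# step 2: substrate-plus-Gaussians decomposition


def _design(axis, substrate_values, comps_mu_sigma):
    cols = [substrate_values]
    for mu, sigma in comps_mu_sigma:
        x = (axis.centers - mu) / sigma
        cols.append(np.exp(-0.5 * x * x))
    return np.column_stack(cols)


def _fit_fixed_count(composite, substrate, axis, n_gauss, mu0, sigma0, rng):
    """Variable-projection fit with exactly ``n_gauss`` Gaussians.

    The outer nonlinear problem is over (mu_j, sigma_j) only; for any shape
    parameters the nonnegative amplitudes (substrate coefficient a0 and the
    Gaussian amplitudes) are the inner NNLS solution.  Three jittered
    restarts guard against poor seeding.
    """
    lo_mu = axis.centers[0] - 50.0
    hi_mu = axis.centers[-1] + 50.0
    scale = float(np.max(composite)) or 1.0

    def amplitudes(theta):
        pairs = [(theta[2 * j], theta[2 * j + 1]) for j in range(n_gauss)]
        A = _design(axis, substrate.values, pairs)
        coef, _ = _lawson_hanson(A, composite, max_iter=200 * (n_gauss + 1), kkt_tol_factor=1e-12)
        return A, coef

    def resid(theta):
        A, coef = amplitudes(theta)
        return (A @ coef - composite) / scale

    best = None
    theta0 = []
    for j in range(n_gauss):
        theta0 += [mu0[j], sigma0[j]]
    starts = [np.asarray(theta0, dtype=float)]
    for _ in range(2):
        jit = starts[0].copy()
        jit[0::2] += rng.uniform(-15, 15, size=n_gauss)
        jit[1::2] *= rng.uniform(0.6, 1.6, size=n_gauss)
        starts.append(jit)
    lb = [lo_mu, 0.5] * n_gauss
    ub = [hi_mu, 200.0] * n_gauss
    for start in starts:
        start = np.clip(start, lb, ub)
        try:
            sol = least_squares(resid, start, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
        except Exception:  # singular inner problem for a pathological start
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.cost < 1e-20:
            break
    if best is None:
        raise DecompositionError(
            f"Gaussian decomposition with {n_gauss} component(s) did not converge",
            diagnostics={"n_gaussians": n_gauss, "starts": len(starts)},
        )
    A, coef = amplitudes(best.x)
    rnorm = float(np.linalg.norm(A @ coef - composite))
    comps = [
        GaussianComponent(mu_nm=float(best.x[2 * j]), sigma_nm=float(best.x[2 * j + 1]),
                          amplitude=float(coef[1 + j]))
        for j in range(n_gauss)
    ]
    return float(coef[0]), comps, rnorm


def decompose_roi_spectrum(
    composite: np.ndarray,
    substrate: ElementarySpectrum,
    max_gaussians: int = 3,
    improvement_tol: float = 0.05,
    random_state: int = 0,
    source: str = "",
) -> tuple[float, list[GaussianComponent], CandidateSpectrum]:
    """Fit composite ≈ a0·substrate + Σ aj·G(λ; μj, σj) with a0, aj >= 0.

    Gaussians are added one at a time (up to ``max_gaussians``); an extra
    component is kept only while it improves the residual norm by more than
    ``improvement_tol`` (default 5%) relative.  Peak positions are seeded at
    the largest residual maxima of the substrate-only fit, widths at 20 nm.

    Returns ``(a0, components, candidate)`` where the candidate is the
    composite minus the fitted substrate contribution, clipped at zero, with
    its peak wavelength and FWHM measured.
    """
    composite = np.asarray(composite, dtype=float)
    axis = substrate.axis
    if composite.shape != (axis.n_channels,):
        raise ValueError("composite length must equal the axis channel count")
    if max_gaussians < 1:
        raise ValueError("max_gaussians must be >= 1")
    rng = np.random.default_rng(random_state)

    # substrate-only baseline (nonnegative coefficient)
    A0 = substrate.values[:, None]
    coef0, _ = _lawson_hanson(A0, composite, max_iter=100, kkt_tol_factor=1e-12)
    a0_only = float(coef0[0])
    resid0 = composite - a0_only * substrate.values
    rnorm0 = float(np.linalg.norm(resid0))
    norm_c = float(np.linalg.norm(composite))

    if rnorm0 <= 1e-9 * max(norm_c, 1.0):
        # composite is pure substrate: keep zero Gaussians
        candidate = _make_candidate(composite, a0_only, substrate, axis, source)
        return a0_only, [], candidate

    # seed peak locations from the residual of the current fit
    best_a0, best_comps, best_rnorm = a0_only, [], rnorm0
    residual = resid0
    mu_seeds: list[float] = []
    for n_gauss in range(1, max_gaussians + 1):
        mu_seeds.append(float(axis.centers[int(np.argmax(residual))]))
        sigma_seeds = [20.0] * n_gauss
        a0, comps, rnorm = _fit_fixed_count(
            composite, substrate, axis, n_gauss, mu_seeds, sigma_seeds, rng
        )
        improvement = (best_rnorm - rnorm) / best_rnorm if best_rnorm > 0 else 0.0
        if improvement <= improvement_tol:
            break
        best_a0, best_comps, best_rnorm = a0, comps, rnorm
        model = a0 * substrate.values + sum(c.sample(axis) for c in comps)
        residual = composite - model
        mu_seeds = [c.mu_nm for c in comps]
        if best_rnorm <= 1e-9 * max(norm_c, 1.0):
            break

    candidate = _make_candidate(composite, best_a0, substrate, axis, source)
    return best_a0, best_comps, candidate


def _make_candidate(composite, a0, substrate, axis, source) -> CandidateSpectrum:
    values = np.clip(composite - a0 * substrate.values, 0.0, None)
    if np.max(values) > 0:
        peak, fwhm = _spectrum_peak_fwhm(values, axis)
    else:  # pure-substrate ROI: degenerate candidate, peak at argmax(=first)
        peak, fwhm = float(axis.centers[0]), float(axis.bandwidth_nm)
    return CandidateSpectrum(values=values, axis=axis, peak_nm=peak, fwhm_nm=fwhm, source=source)


# ---------------------------------------------------------------------------
# step 3: grouping


def group_candidates(
    candidates: Sequence[CandidateSpectrum],
    peak_tol_nm: float = 10.0,
    width_tol_frac: float = 0.25,
) -> list[list[CandidateSpectrum]]:
    """Single-linkage grouping of candidates by peak position and breadth.

    Two candidates link iff their peak wavelengths differ by at most
    ``peak_tol_nm`` *and* their FWHMs differ by at most ``width_tol_frac``
    of the pair's mean FWHM.  Groups are the connected components of the
    link graph, returned sorted by ascending mean peak wavelength (content
    is independent of the input order).
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("need at least one candidate")
    n = len(cands)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = cands[i], cands[j]
            mean_w = 0.5 * (a.fwhm_nm + b.fwhm_nm)
            if (
                abs(a.peak_nm - b.peak_nm) <= peak_tol_nm
                and abs(a.fwhm_nm - b.fwhm_nm) <= width_tol_frac * mean_w
            ):
                parent[find(i)] = find(j)

    groups: dict[int, list[CandidateSpectrum]] = {}
    for i, c in enumerate(cands):
        groups.setdefault(find(i), []).append(c)
    out = list(groups.values())
    out.sort(key=lambda g: float(np.mean([c.peak_nm for c in g])))
    return out


# ---------------------------------------------------------------------------
# step 4: finalize


def finalize_endmembers(
    groups: Sequence[Sequence[CandidateSpectrum]],
    substrate: ElementarySpectrum,
    names: Sequence[str],
) -> EndmemberMatrix:
    """Average each group, max-normalize, and prepend the substrate.

    ``names`` labels the columns: the first entry names the substrate, the
    rest the groups in order.  Construction of the matrix performs the full
    rank check; proportional group means raise a collinearity error naming
    the offending pair.
    """
    if len(names) != len(groups) + 1:
        raise ValueError(
            f"need {len(groups) + 1} names (substrate + {len(groups)} groups), "
            f"got {len(names)}"
        )
    spectra = [ElementarySpectrum(names[0], substrate.values, substrate.axis)]
    for name, group in zip(names[1:], groups):
        if not group:
            raise ValueError(f"group for {name!r} is empty")
        mean = np.mean([c.values for c in group], axis=0)
        spectra.append(ElementarySpectrum(name, mean, substrate.axis, normalize=True))
    return EndmemberMatrix(spectra)  # raises CollinearityError if degenerate


# ---------------------------------------------------------------------------
# excitation handling


def apply_excitation_rule(
    endmembers: EndmemberMatrix,
    excitation_nm: float,
    shg_name: str = "SHG",
    shg_excitations: Iterable[float] = (920.0,),
) -> EndmemberMatrix:
    """Zero the SHG column at excitations where no second harmonic appears.

    Second harmonic generation emits at exactly half the excitation
    wavelength; if the current excitation is not one at which the SHG line
    was detected (by default only 920 nm), the SHG elementary spectrum is
    set to all zeros, excluding it from the design matrix — its abundance is
    then reported as 0.  Idempotent; a matrix without an SHG column is
    returned unchanged.
    """
    if shg_name not in endmembers.names:
        return endmembers
    if float(excitation_nm) in {float(e) for e in shg_excitations}:
        return endmembers
    if shg_name in endmembers.zeroed_names:
        return endmembers
    return endmembers.zero_column(shg_name)


def excitation_profile(
    series: ExcitationSeries,
    endmembers_per_excitation: Mapping[float, EndmemberMatrix],
    roi: PolygonROI,
) -> pd.DataFrame:
    """ROI-mean abundance of each endmember as a function of excitation.

    Each stack in the series is unmixed (non-negativity constrained) with the
    endmember matrix supplied for its excitation wavelength; the mean
    abundance over the ROI is tabulated per endmember.  Rows are ordered by
    excitation; endmembers absent at some excitation appear as NaN there.
    """
    rows = {}
    for stack in series:
        exc = stack.excitation_nm
        try:
            E = endmembers_per_excitation[exc]
        except KeyError:
            raise KeyError(f"no endmember matrix supplied for excitation {exc} nm")
        maps = unmix_stack(stack, E, constraint=NONNEGATIVE)
        mask = roi.mask(stack.shape)
        if not mask.any():
            raise ValueError(f"ROI {roi.label!r} is empty on the {exc} nm stack")
        rows[exc] = {name: float(maps[name][mask].mean()) for name in maps.names}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "excitation_nm"
    return df


# ---------------------------------------------------------------------------
# estimator facade


class EndmemberExtractor(BaseEstimator):
    """End-to-end elementary-spectrum workflow as a scikit-learn estimator.

    Parameters mirror the workflow defaults: ``max_gaussians`` per composite
    fit, the 5% residual-improvement stop, and the grouping tolerances
    (peak within 10 nm, FWHM within 25% of the pair mean).

    ``fit(stacks, substrate_rois=..., candidate_rois=...)`` runs substrate
    averaging, per-ROI decomposition, grouping and finalization.  Fitted
    attributes: ``substrate_``, ``candidates_``, ``groups_``, and
    ``endmembers_`` (the finalized :class:`EndmemberMatrix`).
    """

    def __init__(
        self,
        max_gaussians: int = 3,
        improvement_tol: float = 0.05,
        peak_tol_nm: float = 10.0,
        width_tol_frac: float = 0.25,
        substrate_name: str = "substrate",
        random_state: int = 0,
    ):
        self.max_gaussians = max_gaussians
        self.improvement_tol = improvement_tol
        self.peak_tol_nm = peak_tol_nm
        self.width_tol_frac = width_tol_frac
        self.substrate_name = substrate_name
        self.random_state = random_state

    def fit(
        self,
        stacks: Sequence[SpectralStack],
        y=None,
        *,
        substrate_rois: Sequence[PolygonROI],
        candidate_rois: Sequence[PolygonROI],
        group_names: Sequence[str] | None = None,
    ) -> "EndmemberExtractor":
        stacks = list(stacks)
        self.substrate_ = substrate_spectrum(
            stacks, list(substrate_rois), name=self.substrate_name
        )
        self.decompositions_ = []
        cands = []
        for roi in candidate_rois:
            composite = roi_mean_spectrum(stacks[0], roi) if len(stacks) == 1 else None
            if composite is None:
                # with several stacks, average the ROI over every stack it hits
                composite = np.mean([roi_mean_spectrum(s, roi) for s in stacks], axis=0)
            a0, comps, cand = decompose_roi_spectrum(
                composite,
                self.substrate_,
                max_gaussians=self.max_gaussians,
                improvement_tol=self.improvement_tol,
                random_state=self.random_state,
                source=roi.label,
            )
            self.decompositions_.append((roi.label, a0, comps))
            if np.max(cand.values) > 0:
                cands.append(cand)
        self.candidates_ = cands
        if cands:
            self.groups_ = group_candidates(
                cands, peak_tol_nm=self.peak_tol_nm, width_tol_frac=self.width_tol_frac
            )
        else:
            self.groups_ = []
        if group_names is None:
            group_names = [
                f"component_{int(round(np.mean([c.peak_nm for c in g])))}nm"
                for g in self.groups_
            ]
        names = [self.substrate_name, *group_names]
        self.endmembers_ = finalize_endmembers(self.groups_, self.substrate_, names)
        return self
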