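# fossilfluor

Pixel-level linear spectral unmixing for two-photon fluorescence
microspectroscopy — built for the study of fossil plants (leaf compressions
in rock matrix, plant inclusions in amber, silicified wood), where the faint
emission of preserved organic material must be separated from a bright,
spectrally overlapping substrate.

## Who it is for

Researchers analyzing spectrally resolved fluorescence image stacks: each
pixel of a field of view carries a full emission spectrum (typically 200
wavelength channels of ~1 nm bandwidth). Given a small set of *elementary
spectra* (endmembers) — the pure, max-normalized emission profiles of the
materials present — the package maps out how much each material contributes
at every pixel.

## The model

The measured spectrum **S** (length *m*) of one pixel follows the linear
mixture model

```
S = s̄̄ · k + n
```

where **s̄̄** is the *m* × *l* matrix of max-normalized elementary spectra,
**k** the abundance vector and **n** noise. Abundances are estimated per
pixel by least squares, `min_k ‖S − s̄̄·k‖₂²`, in two variants:

- **UCLS** — the unconstrained estimate `k = (s̄̄ᵀs̄̄)⁻¹ s̄̄ᵀ S`, evaluated
  through a QR least-squares factorization. Closed-form and fast, but
  abundances may come out negative.
- **NNLS (default)** — the same problem under the abundance non-negativity
  constraint (ANC), solved by Lawson–Hanson active-set iteration. With
  several spectrally overlapping endmembers the unconstrained estimate
  escalates pixel-to-pixel noise in the abundance maps severely; the ANC
  suppresses it (the package quantifies this with
  `compare_constraints`).

Elementary spectra are determined from the data themselves: substrate-only
regions are averaged at the ROI level into a substrate spectrum; composite
ROI spectra over plant features are decomposed as a nonnegative combination
of the substrate plus Gaussian emission bands; the substrate-free candidate
spectra are grouped by peak wavelength and breadth, averaged, and
max-normalized. A dedicated rule handles second harmonic generation (SHG):
the SHG endmember — a narrow line at exactly half the excitation wavelength
(460 nm at 920 nm excitation) — is zeroed out at excitations where no second
harmonic is generated.

The `synthetic` module generates ground-truthed scenes (five scenarios
mirroring the fossil settings above) so the whole pipeline is testable
without specimen data.

## Worked example

```python
import fossilfluor as ff

scene = ff.make_scene("amber_inclusion", shape=(48, 48), excitation_nm=760.0, seed=0)
stack = ff.render_stack(scene)
maps = ff.unmix_stack(stack, scene.endmembers)          # ANC (NNLS) by default

roi = scene.reference_rois["overlap"]                   # lignin + chl/tannins overlap zone
mask = roi.mask(stack.shape)
for name in maps.names:
    est = maps[name][mask].mean() / scene.noise.exposure_scale
    true = scene.true_abundances[name][mask].mean()
    print(f"{name:32s} recovered {est:6.3f}   truth {true:6.3f}")
print(f"mean residual norm in ROI: {maps.residual[mask].mean():.1f} counts")
```

prints

```
Amber                            recovered  0.973   truth  0.972
Lignin                           recovered  1.184   truth  1.185
ChlorophyllDerivatives_Tannins   recovered  1.113   truth  1.113
mean residual norm in ROI: 1492.3 counts
```

Even in the zone where the lignin-like and chlorophyll-derivative/tannin-like
inclusions overlap spatially *and* all three emissions overlap spectrally,
the constrained unmixing recovers each material's mean abundance to within
the Poisson noise of the simulated detector; the residual norm (~1.5 × 10³
counts against per-channel signals of ~10⁴) is pure shot noise.

The same pipeline is scriptable from the shell:

```
fossilfluor simulate amber_inclusion --shape 64x64 --seed 0 --out run/
fossilfluor unmix run/stack_exc760nm.tif run/truth/endmembers_exc760nm.csv --out run/maps/
fossilfluor bandmap run/stack_exc760nm.tif --lo 600 --hi 650 --out run/band.tif
```

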