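# Methods

## The measurement problem

A neonatal cardiomyocyte in culture beats without appreciably moving its
outer boundary; the contraction is visible only as a displacement of the
granular interior (myofibrils in development). Any per-frame scalar that
tracks "how rearranged is the interior relative to rest" is therefore a
contractility readout. `cardiotrace` uses the magnitude of the polar
Fourier transform (PFT) of the masked cell as the per-frame descriptor
and the Pearson correlation against a reference frame as the scalar.
Working in the spectral domain suppresses pixel noise, and using the
*polar* magnitude makes the descriptor covariant under rotation (a
rotation of the image permutes rays without changing their content), so
the readout does not depend on how the cell happens to be oriented.

## Pseudo-polar transform

The frequency square `[-π, π]²` is sampled on 2N concentric squares
crossed by 2N slope-equispaced rays, in two subnets:

* BV ("basically vertical"): `ξ_y = πl/N`, `ξ_x = 2πml/N²`,
  `l ∈ [-N, N)`, `m ∈ [-N/2, N/2)`;
* BH ("basically horizontal"): the same with the roles of `ξ_x`, `ξ_y`
  exchanged and `m ∈ (-N/2, N/2]`.

The published definitions typeset the BH index ranges inconsistently; the
ranges above mirror BV, give each subnet exactly `2N x N` points, avoid
duplicating the two diagonal rays, and reproduce the expected counts (16
rays and 8 squares at N = 8, measured geometrically in the tests).

With centered pixel coordinates `x, y ∈ [-N/2, N/2)` the transform
factors: a length-2N FFT along one axis evaluates the `πl/N` frequencies;
along the other axis the frequencies `2πml/N²` form, for each `l`, a
geometric progression with an `l`-dependent step. These are evaluated
with a Bluestein (chirp) scheme written to run batched over all `l` in
three FFTs (scipy's `czt` computes the same quantity but one frequency
step at a time; it serves as an independent cross-check in the tests).
The result is exact to rounding error — the brute-force `O(N⁴)`
nonuniform DFT oracle agrees to ~1e-13 on random images — at
`O(N² log N)` cost.

Centering convention: the spatial origin is the pixel at index `N/2`, so
the `l = 0` samples all equal the plain pixel sum and conjugate symmetry
`F(-ξ) = conj(F(ξ))` holds exactly for real frames. The coincident
`l = 0` points are collapsed to a single stored sample wherever the
spectrum is consumed.

## Polar resampling

Two 1-D interpolation stages take the pseudo-polar samples to a true
polar grid (equiangular rays, concentric circles of radius `π|l|/N`):

1. **Rotate the rays.** For each square level the known samples are
   slope-equispaced; the targets are the equiangular ray directions
   `tan(πm/2N)`. The four edges of a square level form a *closed*
   contour, and the samples are equispaced in the contour parameter, so
   the default interpolant is the band-limited (trigonometric) one: FFT
   of the loop samples, evaluated at the target contour positions. (A
   per-edge periodic interpolant would be ill-posed — one edge is not a
   period of the underlying trigonometric polynomial — which is why the
   contour formulation is used. A periodic cubic spline over the same
   contour is available as `kernel="cubic"`.) The outermost square level
   has only two of its four edges on the grid (`l` stops at `N - 1`);
   the missing half is completed by conjugate symmetry, which is exact
   for real frames.
2. **Circle the squares.** Along each ray the stage-1 samples sit at
   radii `(πλ/P)·R(m)` with `R(m) = √(1 + tan²(πm/2N)) ∈ [1, √2]`; a
   cubic spline along each full *diameter* (both opposite rays, 2P+1
   samples) is evaluated at the exact circle radii `πl/N`. The radial
   slice of a 2-D spectrum is not periodic over the sampled window, so a
   spline — not a trigonometric interpolant — is the appropriate kernel
   here. All targets are interior to the sampled diameter; no
   extrapolation occurs.

Accuracy is controlled by two integer oversampling factors (default 2x
each): radial oversampling zero-pads the image from N to P = rN before
the pseudo-polar transform (denser square levels), angular oversampling
computes `a·P` rays per subnet (denser contour samples). On white-noise
8x8 images the worst-case error against direct evaluation at the polar
frequencies is ~19% at 1x, ~0.6% at the default 2x, and falls
monotonically through 4x; smooth images do much better. The interpolation
operators depend only on `(N, r, a, kernel)` and are cached, so video
analysis pays the setup cost once.

The output layout is `(2N+1) x (2N+1)`: rows are signed radial levels
`l ∈ [-N, N]`, columns are the 2N ray angles `-π/4 + (j+1)π/(2N)` plus
one wrap-around column (first ray advanced by π, i.e. the first column
with rows reversed). The `+N` row equals the conjugate of the `-N` row
for real input. The published construction reports the same `(2N+1)²`
size without fixing the index bookkeeping; this layout is this package's
declared convention, recorded in the JSON sidecar of every exported
spectrum so it is invertible downstream.

## Contraction trace and event detection

Per frame: mask (zeroing the background), polar FFT, magnitude,
flattened over the distinct non-origin grid points. The similarity of
frame k is the Pearson correlation of its descriptor with the reference
frame's; `contraction = 1 - similarity`. Choices that matter:

* **Magnitude, not complex values:** magnitudes are invariant to the
  spatial shifts and rotations that do not constitute contraction.
* **DC excluded, Pearson-normalized:** multiplying all frames by a gain
  leaves the trace unchanged to machine precision; a uniform intensity
  offset added inside the mask is *nearly* cancelled (the mask indicator
  leaks a little energy into nonzero frequencies; measured effect on
  similarity is ~1e-3 per 0.3 offset on unit-range frames).
* **Reference frame:** first frame by default (recordings conventionally
  start at rest); `reference="rest"` instead picks the frame closest to
  the per-pixel temporal median, for recordings that begin mid-beat.

Event detection (the published work plots the trace but states no
detection rule, so this is this package's procedure, all parameters
configurable): baseline = running median (2 s window); noise = 1.4826 x
MAD of the baseline-removed trace; peaks = local maxima exceeding
`baseline + 5·noise`, separated by at least half the stimulation period
(0.5 s if the pacing rate is unknown). Because neonatal beats have a
plateau, the raw argmax within a plateau is noise-driven; the reported
`peak_frame` is the *center* of the contiguous region at ≥ 90% of the
peak amplitude, which is stable to within a frame. Onset and end are the
nearest crossings of `baseline + 10%` of the amplitude on either side.
Metrics: beat rate = events / trace duration; time to peak, plateau
duration (the ≥ 90% region), and relaxation times to 50% and 90%
recovery, averaged over events. The 50%/90% endpoints quantify the
characteristically slow neonatal relaxation with two standard numbers.

## Synthetic recordings

The generator renders what the method assumes: an irregular star-convex
blob (smoothed random harmonic perturbation of a disk, radius ~0.33 N)
filled with band-passed granular texture (difference of Gaussians, σ = 1
and 3 px, rescaled to [0.2, 1]), with *immobile boundary*. During a beat
the texture at radial fraction `q = r/ρ(φ)` is displaced inward by
`A·a(t)·4q(1-q)` pixels — zero at the centroid and exactly zero at the
boundary. Frames are bilinear samples of the resting texture under the
displacement map; Gaussian noise (σ = 0.01 of the texture range) is
added inside the mask only.

The activation `a(t)` is piecewise per stimulated beat: linear rise
(0.3 s), plateau (0.25 s), exponential decay (τ = 0.25 s). Defaults
follow the acquisition protocol of the target experiments — 30 fps
recordings, field stimulation at 0.3 Hz (period 3.33 s), 30 s duration
(hence nine beats) — with kinetics chosen once as realistic neonatal
twitch values: slow activation, a distinct plateau, slow relaxation,
with the pulse (~1.7 s above 1% of peak) fully contained in one pacing
period. Ground truth is closed-form: onset `k/f_stim`, activation peak
at the plateau center, 50% recovery at `rise + plateau + τ·ln 2` past
onset. A `phase_jitter_s` option desynchronizes granule activation (a
smooth random spatial lag field) for robustness experiments; it is off
by default.

What the generator does **not** emulate: phase-contrast optics (halos,
shade-off), focus drift, stage vibration, photobleaching, multi-cell
fields, or genuinely asynchronous myofibril recruitment beyond the
jitter option. Passing tests therefore demonstrate correctness of the
*pipeline* under the stated motion model, not performance bounds on
arbitrary laboratory footage; on real data the mask quality and the
at-rest reference choice are the operator-controlled degrees of freedom.

Note the trace amplitude is a correlation deficit, not a length change:
it grows monotonically with the internal displacement amplitude
(verified over 0.5–4 px) but nonlinearly, so amplitudes are comparable
within a recording protocol, not across arbitrary magnifications.

## Numerical choices and problem sizes

* Oracle agreement tolerance 1e-9 absolute on unit-scale images (double
  precision with `O(N log N)` accumulation leaves ~4 orders of margin).
* Polar accuracy asserted at ≤ 5% (worst-case, white-noise input) at the
  default 2x/2x oversampling; measured ~0.6%.
* Default analysis frame size 64 px (transform ~70 ms/frame after plan
  setup); the multi-seed recovery tests use 48 px / 10 s recordings and
  the full-protocol test uses 64 px / 30 s — sizes at which every
  stage's behavior is already asymptotic.
* Trace CSV numbers are written with 9 significant digits so reruns are
  byte-identical.
* Degenerate inputs: constant (zero-variance) spectra raise a distinct
  error rather than returning NaN; a single-frame stack yields the
  trivial trace; a flat trace yields zero events, which is a valid
  result, not an error.

## Known limitations

* The inverse polar transform is out of scope (the descriptor is used
  for correlation only, never inverted).
* Video containers require an imageio decoder plugin at runtime;
  multi-page TIFF is the only format guaranteed by the core
  dependencies, and the one used for all fixtures.
* The similarity is a *global* statistic over the masked region; two
  spatially distinct motions of equal spectral impact are not
  distinguished.
* Absolute force, shortening in micrometers, and sarcomere-length
  estimation are outside what a correlation trace can provide.
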