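# Methods

## Physical model

Phase-based MREPT reconstructs conductivity from the transceive phase
φtr = φ+ + φ−, relying on the half-phase assumption (φ+ ≈ φtr/2, valid at
moderate field strength) and negligible longitudinal field variation. Under
these assumptions the phase obeys, with γ = 1/σ [Ω·m],

    ∇φtr·∇γ + γ∇²φtr − ρ∇²γ = 2ωμ0 ,

whose ρ = 0 form is the convection–reaction equation and whose ∇γ = 0 limit
gives the pointwise std-EPT formula σ = ∇²φtr/(2ωμ0). The viscosity term
−ρ∇²γ damps the spurious oscillations of the convection–reaction solve at
the cost of contrast; ρ is therefore the central trade-off parameter.

The acquisition constant is 2ωμ0 with ω = 2π·f, f = 127.78 MHz (3 T) by
default, μ0 = 4π·10⁻⁷ H/m; at these values 2ωμ0 ≈ 2017.8. All operators
consume the physical pixel spacing (default 2 mm), so ρ values transfer
between grids that honor their spacing.

## Discretization

The stabilized system is assembled with central differences on the 5-point
stencil: for unknown pixel (i, j),

    center:  ∇²φ + 2ρ(1/dx² + 1/dy²)
    east/west:  ±(∂φ/∂x)/(2dx) − ρ/dx²
    north/south: ±(∂φ/∂y)/(2dy) − ρ/dy²
    rhs: 2ωμ0 − (known-γ neighbor contributions)

Phase derivatives come from 3-point central stencils (one-sided,
second-order at the outermost ring) or from a separable Savitzky–Golay fit
(default window 5, order 2, scipy `mode="interp"` edge policy — the window
size and edge policy are free choices here; order 2 is required for second
derivatives). The numerical baseline takes the full 3-pixel padding ring as
Dirichlet knowns and solves for the interior ROI with a direct sparse LU.
Nonphysical γ ≤ 0 pixels are flagged, never clipped; display clipping to
[0, 5] S/m is presentation only.

## Synthetic data

The generator emulates the measurement geometry used throughout: a 36×36
grid at 2 mm spacing whose 3-pixel reference ring (1.0 S/m) encloses a
30×30 ROI. The default phantom holds a 0.5 S/m brain-average background, a
CSF-like 1.8 S/m circle (r = 8 mm), a white-matter-like 0.3 S/m circle
(r = 7 mm) and a tumor-like 1.2 S/m circle (r = 3 mm; the tumor study
sweeps 2/4/6 mm sizes, read as diameters by default). Inclusions rasterize
by strict pixel-center-in-circle membership; later inclusions override
earlier ones.

The forward phase solves the divergence form ∇·(γ∇φ) = 2ωμ0 (the
self-adjoint counterpart of the reconstruction PDE) with φ = 0 on the outer
border, a 5-point stencil and arithmetic-mean face conductivities. Because
the reconstructions use only derivatives of φ, the border gauge is
immaterial; it is fixed for determinism. By default the solve runs on a 2×
refined mesh (nearest-neighbor σ upsampling) and block-averages back, so
reconstruction tests do not commit the inverse crime of inverting the exact
discretization that generated the data; `refine=1` is reserved for
discrete-consistency tests, where the forward and inverse stencils coincide
wherever γ is locally constant.

Noise is i.i.d. zero-mean Gaussian in radians with std 1/(2·SNR) — absolute,
not relative to the phase magnitude, following the usual transceive-phase
noise convention. An optional Gaussian pre-filter (σ = 1 pixel, reflective
borders) is available as a denoising step.

What the generator does **not** emulate: electromagnetic field structure
(birdcage-coil B1 inhomogeneity), the half-phase approximation error,
spatially correlated or Rician noise, partial-volume effects, and scanner
phase-unwrapping artifacts. Passing tests therefore demonstrate the
correctness and relative noise robustness of the solvers on self-consistent
phase data, not end-to-end accuracy on scanner measurements.

## Physics-informed reconstruction

A coordinate network maps pixel centers, normalized to [0,1]² over the full
padded grid, to φ̂tr: four bias-free fully connected layers of 50 sigmoid
neurons plus a 1-neuron output, also sigmoid, rescaled to the measured
phase's [min, max] (7,650 parameters). Kaiming-uniform initialization
(±1/√fan_in), deterministic per seed. Since the measured phase is the only
phase available at inference, its (noisy) extrema define the output range.

Spatial derivatives are exact: value, gradient and second-derivative
streams are forward-propagated through the layers (sigmoid derivatives in
closed form), with chain-rule factors 1/L and 1/L² converting normalized to
physical derivatives. The streams are stacked along the batch axis so each
layer is one matrix product; the recombination is a single fused tape node
whose backward pass uses s''' = s'(1−6v+6v²).

The stabilized system assembled from these derivatives is solved sparsely
inside the training graph. The backward pass is the adjoint method: solving
Aᵀλ = ḡ gives ∂/∂b = λ and ∂/∂A_ij = −λ_i γ_j on the sparsity pattern, so
gradients with respect to the weights and ρ are exact (verified against
finite differences). ρ = lo + (hi−lo)·sigmoid(θρ) with bounds [1e-6, 0.01]:
the lower bound keeps the viscosity term alive, the upper bound is the
largest artifact-free value; θρ starts at 0, i.e. ρ at the bounds'
midpoint 0.0050005 (the initialization inside the bounds is a free choice;
the midpoint is the symmetric one).

**Boundary split.** The outermost 1-pixel ring closes the stencil as
Dirichlet data; the remaining padding pixels stay unknowns and form the
boundary-loss evaluation ring. If the whole padding ring were imposed, the
boundary loss would be identically zero and carry no gradient. For the std
variant (no Dirichlet needed) the whole padding ring is evaluated.

**Losses.** The phase loss is MSE + (1−SSIM) with the standard windowed
SSIM (11×11 Gaussian, σ = 1.5 px, K1 = 0.01, K2 = 0.03, data range =
reference max−min, window-radius border cropped from the mean) — identical
parameters to the evaluation metric. The boundary loss is MSE + (1−SSIM)
over the evaluation ring; a windowed SSIM is ill-defined on a 2-pixel ring
(windows would be dominated by non-ring pixels and no reference exists off
the ring), so the ring SSIM uses the global-statistics form with the known
ring conductivity magnitude as data range — identical constant rings then
score exactly 1.

**Schedule.** Full-batch Adam, lr 0.001, λ = (100, 0) for the first
10,000 of 60,000 iterations by default (phase fitting only; the PDE solve
is skipped and instrumented to prove it), then λ = (100, 1). ρ receives
gradient only in stage 2. The returned model is the snapshot minimizing the
weighted total loss, tracked over stage-2 iterations — stage-1 totals
(λ2 = 0) are a different objective and are compared only in pure phase-fit
runs. A singular solve during training logs the event and skips that
iteration's update (transient ill-conditioning early in stage 2) rather
than aborting; a non-finite loss aborts with a diagnostic.

## Evaluation

SSIM (parameters above, reference = ground truth), MAE [S/m], Pearson
correlations of horizontal line profiles (interior rows at 1/4, 1/2, 3/4
height), and per-tissue mean/std from the label map. All reconstruction
metrics are evaluated over the interior ROI only: the padding ring is
imposed as known by Dirichlet-based methods and would inflate scores, so
metric rows fill non-interior pixels from the reference before the
windowed SSIM, keeping ring estimates out of interior windows. A constant
reference map (zero data range) scores 1 against maps equal to numerical
precision and is an error otherwise.

## Experiment harness

Experiments are paired: every method at a given (SNR, trial) consumes the
identical noisy phase, with child seeds spawned deterministically from the
master seed per (SNR, trial). The noise sweep covers SNR 200→20 in steps of
10 with five trials by default; the ρ-transfer mode re-uses the ρ learned
by PINN stab-EPT in the numerical solver at the same (SNR, trial). The
tumor study rebuilds the default phantom per tumor size at a fixed site and
reports per-tissue statistics plus the profile through the tumor-center
row.

## Problem sizes and scaled defaults

The PINN experiment defaults use 5,000 iterations (2,000 phase-fit) on the
36×36 phantom — enough for the phase fit to converge and the ranking
against the numerical baseline to stabilize, at a few minutes per run on
one CPU; the full 60,000-iteration schedule remains the `PINNConfig`
default for single reconstructions and is available everywhere via config.
The five-seed SNR-100 study used by the acceptance checks runs at these
scaled settings.

## Known limitations

* 2-D single-slice only; no B1-magnitude information, so complex
  permittivity is out of scope.
* The forward simulator shares the reconstruction's physical assumptions;
  it validates solvers, not the assumptions themselves.
* The learned ρ is a single global scalar; spatially varying viscosity is
  not modeled.
* With severe noise (SNR < 50) the network's low-pass bias over-smooths
  fine structure; small (≤ 2 mm) inclusions lose contrast under the
  diffusion term.
* The numerical std-EPT masks near-zero-Laplacian pixels as NaN; metric
  rows substitute 0 S/m at masked pixels.
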