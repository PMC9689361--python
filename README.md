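# mrept — phase-based MR electrical properties tomography

Tissue conductivity σ is a quantitative marker that can flag non-calcified
cancerous tissue. MR electrical properties tomography (MREPT) estimates σ
from an MRI-measurable quantity alone: the transceive phase φtr of the B1
field. This package implements, on 2-D phase maps, the three reconstruction
families used in phase-based MREPT, together with a self-contained synthetic
phantom and forward simulator so every component can be exercised without
scanner or electromagnetic-simulation data. It is written for researchers
working on noise-robust EPT reconstruction.

## Methods

With γ = 1/σ, ω the Larmor angular frequency and μ0 the vacuum permeability:

* **std-EPT** — assumes local homogeneity (∇γ = 0):
  σ = ∇²φtr / (2ωμ0), a pointwise formula that is exact for homogeneous
  media and noise-sensitive through the Laplacian.
* **stab-EPT** — keeps the convection term and adds an artificial-diffusion
  (viscosity) stabilizer with coefficient ρ:

      ∇φtr·∇γ + γ∇²φtr − ρ∇²γ = 2ωμ0

  discretized with central differences into a sparse 5-point system
  A γ = b, with the reference padding ring (known conductivity surrounding
  the ROI) as Dirichlet data. ρ = 0 recovers the unstabilized
  convection–reaction (cr-EPT) form.
* **PINN stab-EPT / std-EPT** — a coordinate network φ̂tr(x, y) (four
  bias-free sigmoid layers of 50 neurons, output rescaled to the measured
  phase range) is trained on a *single* phase map. Its exact automatic-
  differentiation derivatives ∇φ̂tr, ∇²φ̂tr replace numerical
  differentiation inside the stab-EPT system, which is solved *inside* the
  training graph (adjoint backward pass), so the loss

      λ1 [MSE + (1−SSIM)](φ̂tr, φtr)  +  λ2 [MSE + (1−SSIM)](σ̂, σ_ring)

  trains both the network and a sigmoid-bounded diffusion coefficient
  ρ ∈ [1e-6, 0.01]. Training is two-stage full-batch Adam (lr 0.001):
  phase fitting only with λ = (100, 0), then joint fitting with
  λ = (100, 1); the minimum-loss snapshot is returned.

The synthetic generator builds piecewise-constant brain-like phantoms
(background, circular tissue/tumor inclusions, 3-pixel padding ring of
known conductivity) and synthesizes φtr by solving the divergence form
∇·(γ∇φ) = 2ωμ0 on a refined mesh, then adds Gaussian phase noise of
standard deviation 1/(2·SNR) radians.

## Worked example

```python
import numpy as np
from mrept import (AcquisitionSpec, EPTOptions, PINNConfig, add_phase_noise,
                   build_phantom, default_phantom_spec, reconstruct,
                   solve_forward_phase, ssim, train_pinn)

acq = AcquisitionSpec()                      # 127.78 MHz (3 T), mu0
truth, labels, masks = build_phantom(default_phantom_spec())
clean = solve_forward_phase(truth, acq, refine=2)
noisy = add_phase_noise(clean, snr=100, seed=0)

num = reconstruct(noisy, masks, acq, EPTOptions(formulation="stab", rho=0.001))
cfg = PINNConfig(iterations=5000, stage1_iterations=2000, seed=0)
log, res = train_pinn(noisy, 1.0, masks, acq, cfg)

print("phase SSIM: noisy %.4f -> network %.4f"
      % (ssim(noisy, clean), ssim(res.phase_pred, clean)))
print("sigma SSIM: numerical %.4f, PINN %.4f | learned rho %.5f"
      % (ssim(num, truth, region=masks.interior),
         ssim(res.sigma, truth, region=masks.interior), res.rho))
```

Output (a few minutes on one CPU):

```
phase SSIM: noisy 0.9858 -> network 0.9977
sigma SSIM: numerical 0.0128, PINN 0.5884 | learned rho 0.00859
```

The network's spectral bias filters the phase noise (SSIM against the
noise-free phase rises from 0.986 to 0.998), and the physics-informed
reconstruction retains the conductivity structure that the numerical solve
loses entirely at SNR 100; the trainable diffusion coefficient climbs
toward its 0.01 upper bound, where the solve is most stable.

A command-line interface mirrors the library:

```sh
mrept simulate --snr 100 --seed 0 --out runs/sim
mrept reconstruct --phase runs/sim/phase.nii --method stab --rho 0.001 --out runs/sigma.nii
mrept pinn --phase runs/sim/phase.nii --iterations 5000 --stage1 2000 --out runs/pinn
mrept sweep --seed 0 --out runs/sweep
```

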