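# shearflux

Filter-space-technique (FST) analysis of the turbulent energy flux that
centimeter-scale swimmers (zooplankton such as *Artemia salina*) generate
inside a background hydrodynamic shear — and of how the *geometry* between
the swimmer's agitation and the shear decides whether that flux runs
toward larger or smaller scales, intensifying or attenuating the shear.

It is written for experimentalists and modellers working on biogenic
turbulence and quasi-2D laboratory flows: it takes time-resolved 2D
velocity fields (or particle tracks) and returns spectral flux curves,
tensor eigenframes and shear-modification diagnostics, and it ships a
synthetic-data generator and a minimal pseudo-spectral solver so the whole
chain runs end to end with no external data.

## The analysis

Low-pass filtering a velocity field at a cutoff scale `L` suppresses all
motion on scales below `L`.  The energy exchanged across that scale is the
work of the turbulent stress against the filtered rate of strain:

    Q(L) = -tau_ij(L) S_ij(L),      tau_ij(L) = (u_i u_j)^(L) - u_i^(L) u_j^(L)

with `Q < 0` an inverse flux (energy to larger scales) and `Q > 0` a
forward flux.  In 2D incompressible flow this is identically

    Q(L) = -2 lambda_tau lambda_S cos(2 theta)

where `lambda_tau`, `lambda_S` are the largest eigenvalues of the
deviatoric stress and strain tensors and `theta` is the angle between
their extensional eigenvectors — `cos(2 theta)` is the *efficiency* of
the transfer.  A uniform shear has its extensional eigenvector at 45° to
the cross-stream axis; a swimmer sheds a jet opposite its swimming
direction, whose stress eigenvector lies along that direction.  The angle
`theta_s` between swimming direction and shear eigenvector therefore
controls everything: `theta_s < pi/4` gives inverse flux (the shear is
fed and intensifies), `theta_s > pi/4` gives forward flux (the shear is
drained and weakens), and `theta_s = pi/4` gives no net transfer.

The net flux reported by default is `Qs`, built from the subgrid-scale
Reynolds stress `tau_S = ((u - u^L)(u - u^L))^L`, which dominates the net
transfer and avoids near-boundary contamination by the Leonard and cross
terms; the Galilean-invariant (Germano) decomposition is also provided.

## Worked example

```sh
python analysis/01_characterize_shear.py
python analysis/02_swimmer_flux_curves.py --seed 0
python analysis/03_jet_shear_modification.py --seed 0
python analysis/04_ptv_fidelity.py
```

The first script characterizes the synthetic shear (v ramping −1.2 to
+1.2 cm/s across 7 cm, sampled at dx = 0.07 cm):

```
extensional strain eigenvector: 45.000000 deg from x-axis (uniform over 10201 nodes)
mean velocity gradient P = 0.342857 1/s (endpoints +/-1.2 cm/s over 7.0 cm)
u_rms = 0.6997 cm/s (ideal linear profile: v_max/sqrt(3) = 0.6928)
```

The second runs the five-case suite (swimmer jet at `theta_s` = 0, π/4,
π/2, the jet without shear, and the pure shear) and averages `Qs(L)` over
filter scales between the swimmer-body scale and the shear scale:

```
band-averaged Qs over L in [1, 4] cm (cm^2/s^3):
     jet_only: -5.179e-03  (inverse)
   pure_shear: -1.188e-06  (inverse)
      theta_0: -1.169e-02  (inverse)
     theta_45: -5.282e-03  (inverse)
     theta_90: +1.122e-03  (forward)
```

The aligned swimmer doubles the inverse flux of the bare jet; the
anti-aligned swimmer flips it forward; the neutral angle sits at the
jet-only level; the laminar shear itself carries nothing.  (The bare jet
is itself weakly inverse — 2D flow cascades upward on its own.)

The third script closes the loop dynamically in the quasi-2D solver: a
pulsed force-free jet dipole angled at `theta_s` inside a Kolmogorov
shear band, against a paired no-jet reference:

```
seed 0  theta_s =    0:  P~ = 1.00239  (shear intensified)
seed 0  theta_s = pi/4:  P~ = 1.00011  (shear intensified)
seed 0  theta_s = pi/2:  P~ = 0.99752  (shear attenuated)
```

`P~` is the mean velocity gradient normalized by the no-jet reference:
inverse flux strengthens the shear, forward flux weakens it.

The fourth script validates the PTV emulation round trip (9,000 tracers
per frame at 60 fps reconstruct the field to 0.37 % of u_rms; the error
is monotone in seeding density).

## Layout

- `src/shearflux/` — fields & I/O, filtering, tensor decompositions,
  flux, shear metrics, synthetic data, solver, pipeline, CLI
- `analysis/` — numbered narrative drivers (see worked example)
- `tests/` — unit, property and end-to-end acceptance tests
- `docs/methods.md` — models, parameters, numerics, limitations
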