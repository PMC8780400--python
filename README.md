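# retinet

A simulator and analysis toolkit for a piecewise-linear model of the
layered retina: bipolar (B), amacrine (A) and retinal ganglion (RG)
cells on square lattices, with rectified chemical synapses, optional gap
junctions and gain control, and linear–nonlinear–Poisson (LNP) spike
generation at the ganglion output. It is aimed at computational
neuroscientists who want an analytically tractable counterpart to
detailed retina simulators: every quantity the package computes
numerically also has a closed-form or oracle counterpart it is tested
against.

## The model in brief

Bipolar cells are driven by the stimulus through causal space–time
receptive-field kernels, `V_drive = K_B ∗ S`, injected as the forcing
`F = V_drive/τ_B + dV_drive/dt`. The joint voltage dynamics

    dX/dt = T⁻¹X + W·R(X) + F(t)

use sign-constrained weights (A→B, A→G inhibitory; B→A, B→G excitatory)
and linear rectifiers `R(v) = max(v − θ, 0)` on every synapse. Because
the rectifiers are piecewise linear, phase space splits into
`2^(N_B+N_A)` domains on which the flow is affine,
`dX/dt = L(n)X + C(n) + F(t)`; the toolkit integrates the network by
chaining these affine flows across threshold-crossing events and
exposes the transport operators `L(n)` directly.

On top of that structure it provides:

* **Receptive fields from eigenmodes** — in the non-rectified regime the
  ganglion receptive field is
  `K_G = Σ_βγ P_αβ P⁻¹_βγ (λ_β + 1/τ_Bγ) (e_β ∗ K_Bγ)` with
  `e_β(t) = e^{λ_β t}H(t)`; the package assembles it, quantifies
  space–time separability (`σ₂/σ₁` of the unfolded kernel) and scans for
  temporal resonances created by complex eigenvalue pairs.
* **Correlations** — stationary voltage covariances under white-noise
  forcing (Lyapunov solve cross-checked against the eigenmode sum),
  drive/forcing covariances from receptive-field overlap, LNP firing
  rates `Φ((m−θ_G)/√(σ_G²+σ_net²))` and pairwise joint spike
  probabilities by Gauss–Hermite quadrature, plus the
  decorrelation-by-nonlinearity diagnostic.
* **A spiking chain for linear response** — a generalized
  integrate-and-fire (gIF) network with spike-history-dependent
  conductances (α-kernels), used to measure empirically how a weak
  moving stimulus perturbs firing rates *and* correlations, with
  bootstrap confidence bands and a convolution-linearity check.

## Worked example

```python
import numpy as np
from retinet import RetinaParams, build_transport_operator
from retinet.config import build_kernels
from retinet.dynamics import DomainIndex
from retinet.fixtures import default_geometry, generate_pooling_connectivity
from retinet.spectral import decompose, rg_kernel, separability_index
from retinet.correlations import spike_correlation_pipeline

# a 0.1 mm patch: 9 bipolar, 4 amacrine, 4 ganglion cells
geom = default_geometry(edge_mm=0.1, nb_row=3, na_row=2, ng_row=2)
conn = generate_pooling_connectivity(geom, pooling_radius=0.03,
                                     w_ab=0.03, w_ba=0.03, jitter=0.3, seed=2)
params = RetinaParams(tau_b=12.0, tau_a=9.0, tau_g=6.0,
                      theta_g=0.3, sigma_g=0.4)

# receptive field of one ganglion cell from the network eigenmodes
dom0 = DomainIndex(eta=(0,) * (conn.nb + conn.na))
dec = decompose(build_transport_operator(dom0, params, conn))
kernels = build_kernels({"sigma_center": 0.015, "sigma_surround": 0.03,
                         "w_surround": 0.3}, geom)
ts = np.arange(0.0, 150.0, 0.1)
kern = rg_kernel(dec, kernels, conn.n_total - 1, 12.0, ts)
print(f"separability index sigma2/sigma1: {separability_index(kern):.3f}")

# ganglion spike statistics under white network noise
stats = spike_correlation_pipeline(params, conn, sigma_s=0.02)
print("firing probabilities:", np.round(stats["rates"], 4))
```

Output:

```
separability index sigma2/sigma1: 0.197
firing probabilities: [0.293  0.2794 0.2703 0.2643]
```

The separability index of 0.197 says the lateral amacrine coupling makes
this cell's receptive field strongly non-separable (a one-to-one pooled
cell without lateral input scores ~1e-15, i.e. exactly separable). The
firing probabilities are per-observation LNP spiking probabilities of
the four ganglion cells at rest under the configured noise; with the
same network the pairwise spike covariances are non-zero only because
the amacrine layer (and shared pooling) correlates the underlying
voltages.

A `retinet` console script exposes the main workflows
(`simulate`, `rf`, `resonance`, `correlations`, `gif-response`) over
YAML configurations; see `retinet --help`.

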