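# Methods

## The model

`retinet` implements a mathematically tractable model of the inner retina:
three square lattices of cells — bipolar (B), amacrine (A) and ganglion
(G) — on a shared field of view. Only ganglion cells spike; B and A cells
interact through graded voltages. The stimulus `S(x, y, t)` (black-and-white
contrast) reaches each bipolar cell through a causal space–time receptive
field kernel `K_B`:

    V_drive,i(t) = (K_Bi * S)(x_i, y_i, t),

and enters the voltage dynamics as the forcing
`F_i = V_drive,i / τ_B + dV_drive,i/dt`, chosen so that an uncoupled B cell
tracks its drive exactly. The joint voltage dynamics are

    τ_B dV_B/dt-like equations with
    dV_Bi/dt = −V_Bi/τ_Bi + Σ_j W_BiAj N_A(V_Aj) + F_i(t)
    dV_Aj/dt = −V_Aj/τ_Aj + Σ_i W_AjBi N_B(V_Bi)
    dV_Gk/dt = −V_Gk/τ_Gk + Σ_i W_GkBi N_B(V_Bi) + Σ_j W_GkAj N_A(V_Aj)

with sign-constrained weights (A→B and A→G inhibitory, B→A and B→G
excitatory) and linear rectifiers `N(v) = max(v − θ, 0)` on every chemical
synapse. Ganglion output is linear–nonlinear–Poisson (LNP): the
instantaneous spiking probability is the standard Gaussian CDF of
`(V_G − θ_G)/σ_G`.

Because the rectifiers are piecewise linear, the phase space splits into
`2^(N_B+N_A)` convex domains indexed by the pattern `η` of rectified
cells. Inside a domain the flow is affine, `dX/dt = L(n)X + C(n) + F(t)`,
where the transport operator `L(n)` zeroes the output columns of
rectified cells and `C(n)` collects the `−θ` offsets of the cells that
still transmit. `C(n)` is derived directly from the rectifier algebra:
the constant in a receiving cell's row is `−θ_pre · Σ (still-transmitting
presynaptic weights)`, which is nonzero in ganglion rows too whenever the
thresholds are nonzero, and vanishes identically when `θ_A = θ_B = 0`.

Two extensions preserve piecewise linearity:

* **Gap junctions** — symmetric electric coupling `g_BiAj = g_AjBi`
  between B and A cells adds linear cross terms and shortens the
  effective time constants, `1/τ' = 1/τ + (Σ_j g)/C`.
* **Gain control** — each B cell carries an activity
  `da/dt = −a/τ_a + h_B N_B(V_B)` gating its synaptic output. The smooth
  gain `G(a) = 1/(1+a⁶)` (0 for `a<0`) is replaced, in the
  piecewise-linear formalism, by a step gain equal to 1 on `[0, θ_a]`
  (θ_a = 2/3 from a linear interpolation of the smooth gain) and 0
  beyond it. The boundary value `G(0) = 1` is the one consistent with
  both the step interval and the reduction to the plain dynamics when
  `h_B = 0`. The activity rows add eigenvalues `−1/τ_a` with generalized
  eigenvectors (a Jordan block), so propagation always uses the matrix
  exponential, never an eigendecomposition.

## Integration

`integrate_pwl` is event-driven: within a domain the affine flow is
advanced by an adaptive stiff-capable solver (LSODA by default); the
threshold-crossing surfaces are solver events located by root finding,
far below the configured `event_tol` (default `1e-9 · τ_min` for grouping
simultaneous crossings). All cells crossing within that window flip in
one event — the domain label is a function of the state, not of event
ordering. A voltage hysteresis of `1e-11` (relative to the threshold
scale) on the event functions suppresses the degenerate re-triggering
that otherwise occurs when the state sits exactly on a switching surface
(e.g. the all-zero rest state with vanishing thresholds). A cell exactly
at threshold transmits zero under either label, so the boundary
convention is measure-zero. Runs that exceed 100 000 events abort with a
chattering diagnostic.

Within-domain solutions are also available in closed form
(`segment_solution`): matrix-exponential propagation plus the forcing
convolution. For the piecewise-linear drive representation (below) the
convolution is evaluated *exactly* per grid interval with endpoint-weight
matrices built from `∫ e^{Lu} du` and `∫ u e^{Lu} du`; for arbitrary
forcing it falls back to adaptive vector quadrature. The same machinery
implements the domain-chain identity: the state at every domain entry
equals `Σ_m H_m^k Φ_m`, with `H` the (non-commuting) product of segment
exponentials and `Φ_m` the per-segment forcing integrals.

With noise (`σ_S > 0`) the integrator switches to fixed-step
Euler–Maruyama (step ≤ `τ_min/50`) with per-step domain re-evaluation:
white-noise paths cross thresholds densely, so exact event location is
ill-posed. By default the noise drives only B rows (A and G cells have no
direct stimulus input); the full-vector variant exists for
Ornstein–Uhlenbeck validation.

**Drive representation.** Drives are sampled on a uniform master grid
(default 0.05–0.1 ms) and linearly interpolated; the interpolant — with
its exact piecewise-constant derivative — *is* the forcing consumed by
all code paths. This makes the event-driven run, the dense nonlinear
reference and the spectral closed form mutually consistent to solver
precision rather than to interpolation accuracy.

## Spectral analysis and receptive fields

In the non-rectified regime the deviation from rest is a convolution
over the eigenmodes of the rest operator `L(0)`. With right/left
eigenvectors `P`, `P⁻¹` and eigenvalues `λ_β`,

    X_α(t) = V_drive,α(t)
           + Σ_βγ P_αβ P⁻¹_βγ (λ_β + 1/τ_Bγ) ∫ e^{λ_β (t−s)} V_drive,γ(s) ds,

the mode weight arising from integrating the drive-derivative part of
the forcing by parts. Identifying terms gives every cell's receptive
field: `K_α = Σ_βγ P_αβ P⁻¹_βγ (λ_β + 1/τ_Bγ) (e_β * K_Bγ)` with
`e_β(t) = e^{λ_β t} H(t)`. Conjugate mode pairs combine to a real kernel
(asserted to a `1e-10` residue). Space–time separability is quantified
as `σ₂/σ₁` of the (space × time)-unfolded kernel; lateral connectivity
generically makes this strictly positive, while one-to-one pooling
without lateral coupling gives a numerically rank-1 (separable) kernel.

Exactly repeated eigenvalues are *not* grounds for refusing the spectral
path: uncoupled ganglion cells sharing `τ_G` always produce them with a
perfectly conditioned eigenbasis. The spectral assembly instead refuses
when the decomposition is defective — reconstruction error above `1e-8`
or eigenvector condition number above `1e8` — and exponential-based
propagation must be used.

**Certified linear regime.** The weak-stimulus analyses require the
trajectory to stay in the rest domain. With zero thresholds the rest
state sits exactly on the switching surface, so the shipped fixtures add
a constant background drive that moves the operating point into the
interior; a run is *certified* when it produces zero crossing events,
and `certify_weak_amplitude` halves the stimulus until that holds.
Resonance scans use periodic raised-cosine flash trains (fundamental-
dominated pulse spectra) on top of such a background, measure the
steady-state peak-to-peak ganglion amplitude after a settling window,
and refuse if any rectification occurs.

## Correlations and spike statistics

Under white-noise forcing the non-rectified network is a multivariate
Ornstein–Uhlenbeck process. The stationary covariance is computed two
ways — the continuous-time Lyapunov equation `LΣ + ΣLᵀ = −σ_S²Q` and the
eigenmode sum `−σ_S² Σ_ab (w_a Q w_bᵀ)/(λ_a + λ_b) v_a v_bᵀ` — and the
two must agree to `1e-8`. The lag convention is
`C(t, t') = Cov(X(t), X(t')) = Σ e^{Lᵀ(t'−t)}` for `t' ≥ t`; it is fixed
by the scalar OU closed form `σ²/(2s)` and validated against simulation,
and every exported covariance records the convention. Drive and forcing
covariances induced by receptive-field overlap are evaluated by direct
quadrature (spatial product integral × temporal overlap; the forcing
version carries the four `1/τ`-weighted kernel/derivative terms) and
occupy only the B block of the matrix.

Spike statistics pass the Gaussian voltage law through the LNP
nonlinearity: rates are `Φ((m − θ_G)/√(σ_G² + σ_net²))` — intrinsic and
network variances add — and pairwise joint spike probabilities are 2-D
Gaussian integrals along the principal axes of the 2×2 voltage
covariance (rotation by the covariance eigenbasis; the principal-axis
factors are the square roots of its eigenvalues, a choice arbitrated by
the Monte-Carlo oracle). The integrals use tensorised Gauss–Hermite
quadrature starting at order 40; the order is doubled until a further
doubling changes the result by less than `1e-10`, and the computation
errors out (rather than returning an unconverged value) if that never
happens — which occurs when the network standard deviation dwarfs
`σ_G`, making the sigmoid an effective step function. Passing two
jointly Gaussian signals through any nonlinearity can only shrink their
correlation; the decorrelation table verifies `|ρ_out| ≤ |ρ_in|` by 2-D
quadrature.

## The spiking chain (gIF) and empirical linear response

The spiking module is a generalized integrate-and-fire network whose
synaptic conductances depend on the whole spike history through causal
α-kernels (`e^{−t/τ}` or `t e^{−t/τ}`): every past presynaptic spike adds
an exponentially decaying conductance increment, giving the process
(truncated) unbounded memory. The simulator uses a fixed step equal to
the conductance bin (default 0.1 ms; statistics are usually re-binned to
1 ms) with exact recursive trace updates that match the direct α-kernel
sum to `1e-12`; memory truncation at `20·τ_syn` is bounded by the
exponential tail. Spikes reset the voltage to `V_reset`; no further
refractoriness is modelled. Per-trial noise streams derive
deterministically from the master seed, so identical configurations
reproduce rasters bit for bit.

The linear-response experiment runs a chain of 20 neurons with
nearest-neighbour excitatory and second-nearest inhibitory synapses
(inhibition through negative reversal potentials) under a travelling
Gaussian current bump. The shipped parameter set
(`chain_experiment_defaults`) was chosen once to give asynchronous,
fluctuation-driven spontaneous activity near 8 Hz with inhibition strong
enough to resolve: leak time constant 10 ms, threshold at ≈ 2σ of the
free membrane noise, conductance maxima 0.02 (exc, reversal +2) and 0.3
(inh, reversal −3), synaptic τ 5 ms, bump speed 0.03 sites/ms and width
0.8 sites. No claim is made of matching any published tuning.

`empirical_response` estimates `δμ[f](t)`: the trial-averaged observable
under stimulation minus its time-averaged spontaneous mean, with
bootstrap-over-trials confidence bands; observables are per-neuron rates
and centred lagged pair products. The analytic linear-response kernel is
deliberately not implemented; linearity is validated *structurally*:
`linearity_check` compares `‖δμ(2A) − 2δμ(A)‖/‖δμ(2A)‖` against a noise
floor defined as the 95th percentile of the same statistic under pure
trial resampling. At the calibrated weak amplitude (0.04) the residual
sits at the floor; at ten times that amplitude it rises clearly above
it. Lateral inhibition is tested with paired sign tests on spike counts
pooled over the passage windows of the interior sites: elevation at the
stimulated site, suppression two sites *ahead* of the bump. The trailing
flank is contaminated by the just-stimulated neighbours' decaying
excitation, so suppression on both sides is established by running the
bump in both directions and testing each leading flank.

## Synthetic fixtures: what they emulate, and what they do not

The lattice generator places B/A/G cells on square lattices (possibly of
different pitch — coordinates, not indices, are matched), pools B→G and
A→G with Gaussian weights, couples B↔A between neighbours with the
mandatory signs, and optionally jitters weights with a seeded generator.
Defaults describe a ~0.1 mm patch with 25 µm bipolar pitch — a caricature
of inner-retina circuitry, not a fit to any species. Random test
networks draw half-normal signed weights and halve the lateral coupling
until the rest operator is stable. Passing tests on these fixtures shows
that the algebra and the numerics are right; it does not show that the
model reproduces real retinal data: there are no photoreceptor or
horizontal-cell dynamics, no colour, no cell-type diversity, no synaptic
plasticity, and the noise model is Gaussian and stationary.

## Numerical choices and limitations

* Default tolerances: event-driven integration `rtol 1e-10 / atol 1e-12`
  (DOP853 at `1e-12/1e-14` where the domain-chain identity is checked);
  quadrature `1e-12`; kernel grids `τ_min/20`.
* Kernel truncation: temporal supports are `12·τ` for the biphasic
  lobes and `5σ` spatially; both leave relative tail mass below `1e-5`.
* The stochastic (Euler–Maruyama) path carries O(dt) weak bias; its
  validations use 3-standard-error bands plus a small bias allowance.
* Closed-form covariances for the *randomly switching* rectified regime
  are out of scope; only the fixed-domain projection result (rectified
  cells drop out of the covariance of the remaining network, equal to
  the covariance of the reduced network) is implemented and tested.
* When the rest state of `L(0)` falls outside the rest domain the code
  warns and proceeds; no attractor classification is attempted.
* A single amacrine threshold is implemented; extending to several
  A-cell families with distinct thresholds would only enlarge the label
  alphabet.
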