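# Methods

This note records the models implemented in `mea3d`, the parameter
choices that matter, the numerical decisions, and what the synthetic
data generator does and does not emulate.

## Electrode geometry

An electrode is idealised as a vertical gold cylinder (diameter d,
height H = 300 µm by default) on a 200 µm pad, with SU-8 insulation in
two parts: a cone of height 50 µm whose outer radius tapers linearly
from a 100 µm base diameter down to the sleeve radius, and an annular
sleeve of constant thickness t extending a height h up the shaft.  The
exposed (electrochemical) surface is the bare shaft above the sleeve
plus the end cap:

    A_exp = π d (H − h_cone − h) + π d²/4.

Two modelling conventions follow from how these electrodes are built:
the conical base is always insulating (the bases and edges are coated in
every variant), so the exposed length excludes the cone even at h = 0;
and the pad is bonded flat to the substrate, contributing to neither the
exposed area nor the buckling column.  At the maximum insulation height
(h = 250 µm on a 300 µm electrode) only the end cap remains exposed; we
adopt this end-cap-only reading of "only the tip is exposed" since the
alternative (a fixed tip length of 20–30 µm) is not expressible on the
same design grid.  Degenerate limits (zero cone height, zero sleeve
thickness) are accepted so the bare-column closed forms can be tested.

Internally everything is SI; micrometres, kΩ/MΩ and µV/mV appear only at
the user-facing interfaces.

## Impedance model

Impedance at the measurement frequency (1 kHz by default) is a series
pair:

* **Interface**: a constant-phase element, Z_s(f) = 1/(Q (j2πf)^α), per
  unit area, divided by A_exp.  Gold in 0.9% NaCl is pinned at
  Q = 0.40 S·s^α/m² (40 µS·s^α/cm²) and α = 0.9 — literature-typical
  values for a bare polycrystalline gold/saline interface; both are
  config-overridable.  At 1 kHz this gives |Z_s| ≈ 9.5 Ω·cm².
* **Spreading resistance** into the bath (σ = 1.6 S/m for 0.9% NaCl at
  room temperature): the Newman disc formula 1/(4σa) when only the end
  cap is exposed (bare length ≤ core radius a), otherwise the
  grounding-rod form (ln(4l/a) − 1)/(2πσl).  We use the Dwight/Sunde
  variant *with* the −1 term: the package's own finite-volume Laplace
  solver (exact to 0.05% on a coaxial-cylinder benchmark) shows the
  simpler ln(4l/a) form overestimates rod resistance by 30–40% at the
  slendernesses on the design grid, while the −1 form agrees to 6–14%.

The counter electrode and leads are neglected — the counter's area is
~10³ × the microelectrode's, so its interfacial term vanishes in series.
The magnitude |Z| is reported together with its phase and both series
parts.

Because the interfacial term dominates everywhere on the design grid,
|Z| is essentially inversely proportional to exposed area: it falls with
diameter, falls as insulation height falls, and is *independent* of SU-8
thickness (the jacket never touches the exposed metal in this geometry),
which is the model's account of the "small variation with thickness"
observed in the full simulations.

### Known limitation: the insulation-height curve

With these pinned parameters the design-grid extremes land at ≈23 kΩ
(50 µm, fully exposed) and ≈12.2 MΩ (10 µm, cap only) — the right order
and span for this class of device.  However, no series CPE + spreading
circuit can simultaneously reproduce a ~270× full-grid impedance span
and a ~3× span along the 50 µm insulation-height curve, because the
exposed area changes 17× along that curve.  The reference full-physics
simulations report both; our cap-only endpoint for the 50 µm electrode
computes to ≈490 kΩ rather than ≈150 kΩ.  We leave this documented
rather than re-tuning Q or α, which would degrade the grid extremes.

### Finite-volume Laplace oracle

`fd_spreading_oracle` solves the axisymmetric conduction problem on the
r–z half-plane of the stated bath (1 mm diameter × 1 mm tall cylinder;
no-flux top and bottom; grounded circumference; exposed metal as a 1 V
equipotential; the insulated body as a 10⁻⁹-conductivity region) with
node-centred finite volumes, harmonic-mean face conductivities, and
half-cells on the boundary rows.  Resistance is V/I with I summed over
the driven surface.  Convergence under grid refinement is monotone.

The closed forms assume their classical boundary conditions — a disc or
rod on an insulating plane bounding a conductive half space — so the
oracle is validated on configurations that realise them: a disc flush
with the bath floor (an electrode shorter than one grid cell degenerates
to this) and bare rods standing on the floor.  For a *protruding*
electrode tip deep in the bath the half-space assumption does not hold
(the exposed tip radiates into nearly full space) and the closed forms
overestimate spreading resistance by up to ~50%.  Since spreading is a
few percent of |Z| everywhere on the grid, this bias is immaterial to
the impedance results.  Bath-size insensitivity ("semi-infinite"
behaviour) holds only when the domain grows in radius and height
together; widening a fixed-height bath leaves a two-dimensional radial
far field whose resistance grows logarithmically without bound.

## Buckling model

The composite column is a fixed-free (cantilever) Euler–Bernoulli beam:
clamped at the pad, free at the tip, compressed by an axial tip load, so
the uniform-column limit is P_cr = π²EI/(4L²) (effective length 2L).
Gold and SU-8 are perfectly bonded concentric sections, so rigidities
add: EI(z) = E_Au I_core + E_SU8 I_annulus, with E_Au = 79 GPa,
E_SU8 = 4 GPa (overridable; Poisson ratios 0.44/0.22 are carried for
completeness but unused by the beam model).  The section profile
discretises the cone taper piecewise.

Critical loads solve K_e φ = P K_g φ with cubic Hermite elements and the
consistent geometric stiffness for uniform axial compression (valid for
a tip load, where the axial force is constant along the column).  At 50
elements the uniform-column eigenvalue is within 0.5% of the closed
form (and within ~10⁻⁹ in practice); a transfer-matrix solver for
stepped columns — an independent formulation using the exact
beam-column solution per segment and a boundary-determinant search —
agrees within 1% on two-segment columns.

**Applied load.** The reference description applies "1 mN/m²" to the
tip, but 1 mN/m² on a ≤ 2×10⁻⁹ m² cap is ~10⁻¹² N, which would produce
critical load factors of order 10⁹–10¹¹, not the published order
1–10².  The stated load cannot be reconciled with the published factor
range, so the package defaults to a direct 1 mN tip force — a magnitude
that puts the weakest design's factor near unity — and keeps
`pressure_on_tip` available.  Published *trends* (factor rising with
diameter, SU-8 thickness and height) and the load-independence of
factor *ratios* are what the model is validated against; with the 1 mN
default the grid factors span ≈1.5 to ≈800.

Shear deformation is neglected (slenderness L/d ≥ 6 everywhere on the
grid); post-buckling, insertion mechanics and fatigue are out of scope.

## Synthetic recordings

`mea3d.synth` emulates the two recording configurations of interest —
an 8×8 in-vitro grid at 500 µm pitch and an 8-channel in-vivo strip at
350 µm pitch — with one integer seed driving all randomness:

* **Baseline noise**: an equal-power mix of white and 1/f Gaussian
  noise, per channel, rescaled exactly so the mean peak-to-peak over
  non-overlapping 100 ms windows equals the configured level (default
  20 µV, the device-class in-vitro baseline; 50–70 µV emulates planar
  electrodes).  The 100 ms window and the 50/50 spectral mix are our
  choices; real baselines also carry line hum and perfusion artefacts
  that are not modelled.
* **Ictal bursts**: an ~80 Hz carrier under a raised-cosine envelope
  (100 ms ramps), plateau peak-to-peak configurable (3.2 mV in the
  in-vitro scenario, 0.5 mV in vivo).  Each channel's onset is delayed
  by distance-to-focus / propagation speed (default 10⁴ µm/s, i.e.
  10 mm/s, mid-range for cortical seizure propagation), so array-level
  propagation is in the ground truth.
* **HFO events**: Gaussian-windowed sinusoids (Gabor atoms, σ = span/6,
  ≥ 4 cycles enforced) at scheduled channels/times; ripples near 120 Hz,
  fast ripples near 400 Hz in the presets.
* **Spikes**: biphasic (sharp negative, smaller positive rebound) ~1 ms
  waveforms.

The generator is purely additive: a run minus its noise-only twin
reproduces the event waveforms bit-exactly, and every injected event is
a ground-truth row.  The default rate is 2 kHz so the 250–500 Hz band
sits strictly below Nyquist; 1 kHz (matching hardware that samples
there) is selectable, with the caveat that the fast-ripple band then
ends exactly at Nyquist.  Passing tests on this generator demonstrate
the *analysis chain's* correctness against known ground truth; they do
not certify detector performance on biological recordings, whose noise
is nonstationary and whose HFO morphology is more varied.

## Analysis chain

* **Filters**: Hamming windowed-sinc FIR, odd length, default 513 taps
  at 2 kHz scaled proportionally with rate; half-amplitude points at the
  band edges, > 40 dB one octave out.  Applied forward–backward
  (`filtfilt`), so event timestamps carry no group delay at the cost of
  squaring the passband gain.
* **HFO detection** (our criteria — reference workflows filter and
  inspect visually): sliding-RMS envelope (10 ms window) of the
  band-filtered trace; threshold = baseline mean + 5 SD from an
  event-free baseline window; events must last ≥ 4 cycles of the band
  centre; gaps shorter than the envelope window are merged; the reported
  time is the envelope peak.  At these defaults the false-positive rate
  on noise alone is ≲ 1 event/min/channel.
* **SNR**: max peak-to-peak in the seizure-onset window over the mean
  100 ms-windowed peak-to-peak of the inter-ictal stretches.  The
  windowed mean is our operationalisation of "mean noise"; it makes the
  statistic gain-invariant and reproduces the expected value exactly on
  constructed amplitudes (3.2 mV over 20 µV → 160).
* **Spikes**: negative-going crossings of −k·SD (default k = 5, SD from
  a baseline stretch), one timestamp per refractory period (1 ms).
* **Latency map**: per channel, the start of the first envelope
  excursion sustained ≥ 4 cycles (the sustain requirement rejects
  isolated noise blips that would otherwise corrupt the map); latencies
  are relative to the earliest channel, ordering ties broken by channel
  id.  Because the threshold is derived per channel from its own
  baseline, the map is invariant to per-channel gain.

## Problem sizes and runtime

The shipped tests and the acceptance script run at desk scale by
construction: the 72-point design grid evaluates in milliseconds
(impedance) and a few seconds (buckling at 40–60 elements); the
finite-volume solves use 10⁴–10⁵ nodes (seconds each); synthetic
recordings are 2–64 channels × 4–60 s at 2 kHz.  These sizes were chosen
as the smallest that exercise every claim — grid extremes, convergence
orders, detector operating points — and the whole suite completes in
well under a minute plus a few seconds of sparse solves.
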