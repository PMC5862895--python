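# Methods

This note documents the models implemented in `cardioflow`, the choices made
where the underlying physics leaves the design open, and what the synthetic
data can and cannot establish about real lungs.

## Scope and units

The package analyses cardiogenic oscillations (CO) — the airflow driven
mechanically by the beating heart — alongside mechanical ventilation (MV) in
the mouse lung, from regional tissue expansion through airway flow,
pendelluft decomposition, and virtual gas-tracer washout. All lengths are mm,
times ms, volumes mm^3, pressures cmH2O. One mm^3/ms equals one ml/s, so
flows are reported in ml/s without conversion.

## Synthetic data generators

**Airway tree.** A full binary tree of straight cylinders: radii and lengths
shrink geometrically, daughters tilt by a branch angle about a seeded random
azimuth. The defaults (trachea radius 0.6 mm, radius ratio 0.83 per
generation) put generation-14 terminal diameters at ~88 um, inside the
85–100 um band where high-resolution mouse lung CT loses the airways. The
tree is deliberately idealised: no monopodial branching, no lobar anatomy,
and self-intersection is not prevented (it does not affect any computation on
the tree graph).

**Ventilation waveform.** A pressure-controlled ventilator is modelled as a
first-order system driven by a square pressure wave (10 cmH2O inflation,
2 cmH2O PEEP, 120 ms inspiration, 280 ms expiration), evaluated in its
periodic steady state so every cycle closes exactly. Time constants default
to one third of each phase.

**Regional expansion field.** One tissue region per terminal airway, with
baseline volumes splitting the functional residual capacity (default 0.5 ml)
log-normally. Each region's volume is

    V_i(t) = V0_i * (1 + s * w_i * w(t - d_i) + a_i * sin(w_c t - k * r_i))

where `w` is the normalised ventilation waveform, `d_i` a small per-region
time shift (default SD 3 ms) emulating regional time-constant heterogeneity —
the physical source of the small pendelluft seen under pure MV — and the
cardiac term has amplitude `a_i = A exp(-r_i / lambda)` decaying with distance
`r_i` from the heart locus (default lambda = 3 mm) and a travelling phase lag
`k * r_i` (default 1.5 rad/mm). The phase lag encodes that the heart
compresses adjacent tissue first while displaced gas reaches remote regions
later; without it the cardiac field is spatially synchronous and, by
continuity, can produce no pendelluft at all. The ventilation scale `s` is
calibrated by root finding so the summed regional tidal volume matches the
requested target (0.2 ml MV tidal by default; the cardiac amplitude is
likewise calibrated to a 0.06 ml summed cardiac tidal, ~6% of a ~1 ml total
lung capacity). The heart-to-ventilation frequency ratio defaults to 3.0
(integer, so the composite field is periodic over one ventilation cycle); an
incommensurate value such as 3.07 is accepted when decorrelated phases are
wanted.

**Speckle phantoms.** Band-passed white noise (difference of Gaussians,
blob scale ~4–8 voxels) warped through a known displacement field with cubic
splines and grid wrapping, so integer shifts reproduce `np.roll` exactly and
the stored field is the ground truth for velocimetry recovery tests.

**Acquisition log.** Frames at 50 fps, ventilation triggers at the 400 ms
cycle, quasi-periodic R-peaks (default 130 ms, mouse heart rate) with
Gaussian jitter, and the pressure-controlled airway pressure trace.

## Double gating

Frames are binned by elapsed cycle fraction, computed in [0, 1) with a
half-open convention, into 19 ventilation bins (from the trigger train) and
independently into 8 cardiac bins (from the R-peaks, interpreted as
RR-interval fraction — robust to heart-rate drift). Cardiac bins only accept
frames at airway pressure strictly below 4 cmH2O, restricting cardiac data to
approximately end-expiratory inflation. Frames before the first trigger are
reported as unbinnable; frames after the last trigger extrapolate with the
median cycle length and are flagged.

## Velocimetry and expansion

Displacement per 32^3-voxel interrogation window (16-voxel pitch; 480 um
windows every 240 um at 15 um voxels) is the circular cross-correlation peak
of the mean-subtracted windows, computed in the frequency domain, with a
three-point Gaussian fit per axis for sub-voxel refinement and lowest-offset-
norm tie-breaking. Flat and masked-out windows are flagged invalid rather
than returned as zero. The integer peak is stored alongside the refined
estimate: for exact integer motion the integer peak is exact, while the
Gaussian refinement carries a small bias (window-edge asymmetry of the local
correlation), typically well under 0.1 voxel.

Expansion is det(I + grad u) − 1 with gradients from central differences on
the region lattice (one-sided at edges). The determinant is exact at finite
strain and reduces to the divergence for small strains; the choice is
recorded here because either reading of "local gradients" is defensible.
Invalid regions poison every stencil that uses them, and a region with no
displacement of its own is never assigned an expansion.

## Airflow and pendelluft

Each region maps to the terminal airway whose distal end-point is nearest
(ties to the lower airway id). Terminal flow is the time derivative of the
summed region volumes (periodic central differences; second-order, so a
sinusoid sampled at n phases/cycle is recovered to (2*pi/n)^2/6, ~1.8% at the
19-phase gating resolution). Flows propagate to the root by continuity,
Q_parent = Q_childA + Q_childB, in post-order; with the positive-direction
convention trachea -> periphery the decomposition at each bifurcation is

    Q_tot = |Q_A| + |Q_B| + |Q_C|,  Q_bulk = |Q_A + Q_B + Q_C|,
    Q_pend = Q_tot − Q_bulk.

Components are averaged over the cycle by trapezoidal integration and summed
over all bifurcations (a per-generation breakdown is also reported, since
whole-tree aggregation could defensibly be restricted to a generation range).

## Gas-tracer transport

**Geometry.** Airways become straight cylinders; each terminal gains a
trumpet section whose total cross-sectional area grows toward the periphery
following a per-generation table (area and length for generations 14–23),
ending in a well-mixed acinar compartment with the deepest generation's area
and volume. The default table is a constructed, mouse-scale representative
profile (area factor 2 * 0.85^2 ~ 1.45 per generation, lengths decaying by
0.88) — it is synthetic, clearly configurable, and not a published
morphometric dataset. Each trumpet is rescaled so its entrance area matches
its terminal airway, keeping A(z) continuous. For scaled-down trees (fewer
than 14 generations) the compartment volumes are rescaled so conduits plus
compartments reproduce the target FRC; at full scale (2^14 terminals) the
generation-23 rule alone gives a realistic distal volume share, and the
rescaling is the scaled-down analogue of that property.

**Advection.** Quasi-steady Poiseuille flow: u(r, z, t) = 2 Q(t)/A(z) * (1 −
(r/R(z))^2), with Q linearly interpolated in time and the relative radius r/R
held fixed along trumpets (quasi-1D continuity scaling; the in-trumpet
profile shape is not observable and parabolic is retained). The axial
position integrates with RK4; r and theta are untouched by advection. The
Womersley number is computed per conduit and a warning is emitted at alpha >=
1 (mouse trachea at 150 breaths/min gives alpha ~ 0.6, so the quasi-steady
profile is justified). A tracer crossing an airway end mid-step is routed to
a candidate airway with probability proportional to the outgoing flows, keeps
its relative radius, redraws theta, and spends its remaining step time
(overshoot distance over exit speed) in the new airway at that airway's own
speed — a first-order approximation of the exact crossing time. If no
candidate carries flow away from the junction (transient continuity
violation) the tracer is held at the junction and the event is logged.

**Trachea boundary.** Time-integrated *inspiratory* inflow, in units of the
tracer volume quantum, injects its integer part as fresh (Type B) tracers at
the opening, the fractional remainder carrying over; tracers advected out of
the opening are removed and tallied by type. Only positive inflow
accumulates: expired gas is carried away by the ventilator circuit and is not
re-inhaled, and the expiratory outflow is already accounted for by the
physical removal of tracers — subtracting it from the accumulator as well
would double-count and permanently starve injection after the first breath.

**Compartment exchange.** Tracers advected past a trumpet's distal end join
the compartment tally and leave the kinematics. Accumulated outflux volume
(compartment into airway) releases its integer part in quanta, with types
drawn hypergeometrically from the tally; releases from an empty compartment
release nothing and are logged.

**Diffusion.** Random walks: per sub-step (duration tau = dt/100 by default)
each tracer moves |N(0, sigma)| with sigma^2 = 6 D tau in a direction uniform
on the sphere, so the simulated MSD per sub-step is 6 D tau, the
three-dimensional Einstein relation (descriptions of this class of model
sometimes quote a standard deviation of "6Dt", which is dimensionally
inconsistent; the Einstein-relation scale is used here and verified by the
MSD oracle, and it is configurable for sensitivity checks). D defaults to
0.23 cm^2/s, the self-diffusivity of nitrogen at body temperature. A move
crossing the wall is redrawn with a fresh direction up to 20 times, then the
sub-step is forfeited (logged). A move crossing an airway end at a
bifurcation chooses among the three junction airways with probability
proportional to cross-sectional area, preserving mass continuity in the
zero-flow limit.

Two diffusion boundary rules go beyond a literal one-way reading:

- *Trachea reservoir exchange.* A tracer diffusing out of the opening is
  removed and replaced one-for-one by a Type B tracer at the opening: the
  atmosphere acts as an infinite fresh-gas reservoir at equal density. This
  is what makes a zero-flow lung wash out by diffusion at all and gives the
  DIFF state a finite fresh-gas concentration (so the CARD:DIFF ratio is
  finite).
- *Compartment diffusive exchange.* A tracer diffusing into a compartment
  exchanges one-for-one with the tally (the newcomer joins; one tracer drawn
  from the updated tally is released at the mouth). Diffusion carries no net
  volume, and a one-way tally would act as a ratchet that pumps tracers into
  the acini, starves the airways, and breaks the uniform tracer density the
  volume-based bookkeeping relies on. Advective crossings keep the
  volume-based rules above.

With these rules tracer accounting is exact at every step:
N_airways + N_compartments + N_expired = N_seeded + N_injected.

**Time step.** dt defaults to a tenth of the shortest conduit transit time at
peak flow; the washout runs in this package use dt = 0.5–2 ms on the bundled
scenarios, for which halving dt changes the sampled concentration curves by
less than the Monte-Carlo spread at the tracer counts used.

## Washout states and mixing ratios

DIFF (zero flow), CARD (cardiogenic flows only), VENT (ventilation only) and
BOTH (summed terminal flows, propagated — flow propagation is linear, so this
equals summing everywhere) all run with diffusion on. The lung starts full of
Type A; the resident fraction among lung tracers (airways + compartment
tallies), sampled once per ventilation cycle at end inspiration (the instant
of maximum lung volume; DIFF and CARD sample the same clock instants for
comparability), is the washout curve. Mixing enhancement is
fraction_B_with / fraction_B_without (CARD:DIFF and BOTH:VENT); 0/0 samples
are flagged undefined rather than interpolated.

## The bundled mouse-like scenario

A 5-generation tree (16 terminals) stands in for the full segmented tree,
with FRC 0.5 ml, MV tidal 0.2 ml, summed cardiac tidal 0.06 ml, heart rate
3x the 150/min ventilation rate, and compartments rescaled to the FRC. At
this scale: the cardiac flow field carries an order-of-magnitude larger
pendelluft fraction than ventilation; the global (tracheal) cardiac tidal
volume is a fraction of the summed regional one, because pendelluft
redistributes volume internally; CARD enhances mixing strongly relative to
DIFF while BOTH barely improves on VENT. These orderings are the validated
claims. The *magnitudes* (e.g. the size of the CARD:DIFF ratio) are not
transferable to the real mouse: a 16-terminal tree has far shorter and wider
gas paths than 2^14 terminals, which shifts the advection–diffusion balance,
and the washout is correspondingly faster in all states. Simulations use
1000–1500 tracers and 10–15 cycles, sizes at which the Monte-Carlo spread of
the sampled fractions is a few percent.

## What passing tests show — and what they do not

The synthetic fields are built from the same waveform family the analysis
assumes, with exact analytic derivatives; they validate the machinery
(gating arithmetic, correlation recovery, continuity propagation,
decomposition identities, transport statistics, conservation) rather than
the biology. Real data add segmentation error, reconstruction artefacts,
non-cylindrical airways, cardiac-phase-dependent airway geometry, and image
noise, none of which are emulated beyond optional speckle noise. Gas exchange
across the air/blood barrier is deliberately out of scope, as are turbulence
and secondary bifurcation flows (relevant at human, not mouse, scale).

## Known limitations

- The junction-crossing residual advance is first order in the step; tracers
  crossing several junctions in one step accumulate small timing errors
  (bounded by the routing iteration cap, after which a tracer holds at a
  junction for the rest of the step, logged).
- Diffusive wall interaction redraws the whole sub-step direction rather
  than reflecting at the exact collision point; with 100 sub-steps per step
  the residual bias on confined MSD is below the Monte-Carlo noise at the
  tracer counts used here.
- The trumpet model is quasi-1D: radial structure inside an acinar subtree
  is not represented, and the compartment is perfectly mixed.
- Sub-voxel velocimetry bias under pure integer motion is non-zero (of
  order 0.01–0.1 voxel) because window edges break the local correlation
  symmetry; the integer peak itself is exact.
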