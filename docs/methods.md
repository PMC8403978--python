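# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the design decisions taken where several conventions were defensible.

## Coordinate conventions and geometry

All analysis happens in the *pore frame*: the affine transform defined by
the geometry's `axis_origin`/`axis_direction` maps the pore axis onto z,
so arbitrarily oriented inputs are supported. Axial positions are reported
relative to the membrane mid-plane. Units are Å and ps throughout; angles
are degrees in all outputs and radians internally.

Boxes are orthorhombic with periodic boundaries in all three directions;
every inter-molecular distance (neighbour search, hydrogen-bond candidate
pairs, per-step displacements) uses the minimum-image convention. Hydrogen
sites are stored unwrapped relative to their oxygen on load, so a molecule
is never split across a boundary.

Pore occupancy is decided by the oxygen alone: a molecule is inside iff
its pore-frame z lies in the closed slab `[membrane_z_min, membrane_z_max]`
and its radius satisfies `r <= R + radial_margin`. All boundaries are
closed; `radial_margin` (default 0 Å) exists because contact-layer oxygens
can sit marginally outside the nominal wall radius in tight pores, and
silently dropping them would bias contact-layer statistics. Whether to use
a margin is a per-run choice, surfaced in the configuration.

## Binning

Annular bins use the exact volume π(r_out² − r_in²)·Δz, so the density
counting identity Σ ρ_b·V_b·n_frames = (counted molecule-frames) holds to
machine precision, and 2-D (r, z) cells marginalise exactly onto the
radial profile. When R is not a multiple of dr the outermost bin is
shortened so the volumes still sum to πR²L exactly. Defaults: dr = 0.1 Å
for radial profiles and dz = 0.2 Å for 2-D maps — fine enough to resolve
~2.5 Å molecular layers with ≥ 25 bins per layer while keeping desk-scale
statistics per bin.

## Layer segmentation

Layers are defined by the minima of the radial density. Because minima
read off a plotted profile by eye are not reproducible, the rule here is
deterministic: smooth ρ(r) with a centred moving average (odd window,
default 5 bins, edge-padded), locate interior minima with a prominence of
at least 5% of the smoothed maximum, break exact ties toward the larger
radius, and cap the partition at three layers (inner / middle / contact),
discarding surplus minima in increasing-prominence order. The outermost
region is always `contact` when more than one layer exists. With no
interior minimum the whole pore becomes a single layer labelled `inner`
(the bulk-like default) and a warning is emitted. A configuration override
can replace the automatic boundaries entirely.

## Orientation (β)

The bisector is the normalised sum of the two O→H unit vectors. β is the
angle between the bisector's projection onto the base plane (normal to the
axis, through the oxygen) and the outward radial direction; cos β is
signed, +1 pointing at the wall. β is undefined on the axis (r < 10⁻³ Å)
or when the bisector is axial (squared projection < 10⁻⁶); such records
are *excluded*, not zero-filled, because assigning 0 would bias the
innermost bins. ⟨|cos β|⟩ is computed from the same record set as
⟨cos β⟩. Empty bins are reported as missing (NaN), never as zero.

## Tetrahedrality (γ, q)

The four nearest neighbours of each in-pore oxygen are found among *all*
molecules of the frame — reservoir water included — under minimum image;
restricting candidates to in-pore water would artificially distort
coordination at the pore mouths. Exact distance ties break toward the
lower molecule id (deterministic across platforms). The six pair angles γ
at the central oxygen feed both P(γ) and

    q = 1 − (3/8) Σ_{i<j} (cos γ_ij + 1/3)²,

one consistent convention for both observables. The production search is
a periodic k-d tree; an all-images O(N) per-centre brute force ships in
the package as the test oracle and is compared exactly against the tree on
random frames. Histogram defaults: 2° bins for γ, 0.02 for q — fine
enough to resolve peak positions a few degrees (or a few hundredths in q)
apart. The layer of a record is taken from the central oxygen's
instantaneous radius.

## Hydrogen bonds

Donor–acceptor criterion: O–O ≤ 3.5 Å (minimum image) and the angle
between the donor O–H bond and the donor→acceptor O–O vector ≤ 30°, both
boundaries closed (a 1e−9 float tolerance guards exact-boundary fixtures).
The angle is donor-centred, not the acceptor-centred supplement. The
criterion is evaluated per O–H pair, so a molecule can in principle donate
through both hydrogens to one acceptor, and both bonds are kept if both
pass — documented so counts are reproducible. n_HB is donated plus
accepted bonds. Bonds are typed by the instantaneous layers of the two
oxygens; `external` wins when either molecule is outside the pore, pairs
involving the middle layer are labelled `middle_<other>`, and the
remaining mixed pair is `contact_inner`. Candidate pairs come from a
periodic k-d tree; the O(N²) all-ordered-pairs oracle is shipped for
tests.

## Dynamics (S(t), restricted MSD)

Residence intervals are maximal runs of consecutive in-pore frames;
continuity is assessed at the stored-frame resolution, so excursions
between stored frames are invisible — unavoidable with sampled
trajectories. Both estimators average over time origins spaced
`origin_stride` frames (default 10) apart.

S(t): a molecule survives lag t from origin t₀ iff one residence interval
covers [t₀, t₀+t]. Only origins whose full lag window fits inside the
trajectory are used (default maximum lag: half the trajectory); this keeps
the origin set identical at every lag, making S(0) = 1 and monotone
non-increase structural rather than approximate, and avoids the spurious
late-lag decay a truncation-blind estimator shows even in a sealed pore.

Restricted MSD: for each lag, the squared pore-frame oxygen displacement
is averaged over all (origin, molecule) pairs whose residence interval
covers the window — a per-pair average, so values are comparable across
systems with different N. Displacements are unwrapped by accumulating
per-frame minimum-image steps; imaging the end-to-end displacement alone
is wrong whenever a resident molecule travels farther than half a box
edge. The axial (z) and planar (xy) components are reported separately
and sum to the total identically. Layer-resolved MSD conditions on layer
membership at the *origin frame* only (plus continuous pore residence);
requiring continuous layer residence would bias toward immobile
molecules. Plateau estimates are means over the final 20% of lags, also
reported as linear distances √MSD. For molecules equilibrated uniformly
in a sealed cylinder the closed-form plateaus are R² (planar) and L²/6
(axial), and these — not any empirical reference — are what the tests
check against.

## Synthetic generators

The generators emulate the statistical structure each stage consumes, with
exact ground truth; they make no claim of physical realism (no
intermolecular forces outside the fixtures). All molecules carry a rigid
internal geometry (O–H 1.0 Å, H–O–H 109.47°) — generator constants chosen
so orientation and hydrogen-bond operators receive realistic three-site
water, not force-field claims. Fixed seed ⇒ byte-identical output.

- `uniform_gas`: independent uniform positions and orientations per
  frame. `fill="pore"` gives the flat-profile density anchor N/(πR²L);
  `fill="box"` spreads molecules over the whole box so in-pore centres
  see isotropic neighbourhoods and the ideal-gas anchors ⟨q⟩ = 0,
  ⟨cos β⟩ = 0, ⟨|cos β|⟩ = 2/π hold without wall or pore-mouth bias. The
  pore-filling gas deliberately *retains* that bias — a wall-adjacent
  centre misses neighbours on the wall side, exactly as confined water
  does — which is why its contact-layer mean q sits below zero.
- `layered_shells`: Gaussian radial shells (default radii 0/4.0/7.5 Å,
  width 0.5 Å, populated in proportion to circumference), optional axial
  modulation of the outermost shell by 1 + depth·cos(2πkz/L + π) — the π
  phase puts all k peaks interior to the slab — and optional tangential
  orientation bias in the outer shell with tunable noise.
- `brownian_pore`: Euler–Maruyama free diffusion with mirror reflection
  at the axial faces (measure-preserving in 1D) and Metropolis-style
  rejection at the radial wall — a proposed move ending at r > R is
  discarded. Endpoint-mirroring at a curved wall biases the stationary
  distribution at finite step size (measured ≈ −9% on E|Δxy|² at
  σ = 2 Å, R = 7 Å), whereas rejection leaves the uniform distribution
  exactly stationary, so the closed-form plateaus hold at any step size.
  Optional memoryless escape: each in-pore molecule teleports to a static
  reservoir position with per-frame probability p (and re-enters with the
  same probability), making residence intervals geometric,
  S(t) = (1−p)^{t/Δt}.
- `tetra_fixture` / `hbond_fixture` / `lattice_fixture`: exact-geometry
  configurations — regular-tetrahedron (q = 1) and collinear (q = −3)
  five-molecule clusters spaced so each centre's neighbours are its own
  cluster; dimers straddling each hydrogen-bond criterion boundary
  (including the closed boundaries at exactly 3.5 Å and 30.0°); and a
  proton-ordered diamond-cubic lattice (A sublattice donates along two
  bond directions, B along the other two) in which every molecule engages
  exactly four hydrogen bonds under full periodicity.

What passing tests show — and what they do not: the generators validate
the *estimators* (binning, bookkeeping, restriction logic, criterion
boundaries, closed-form limits), not the physics of real confined water.
Real MD data has correlated positions, finite-temperature disorder and
genuine wall structure; quantitative observables of real systems (peak
heights, n_HB versus temperature, plateau distances) are outside what
synthetic data can certify.

## Statistical checks and problem sizes

Stochastic assertions use three-standard-error bands with error bars that
are rigorous under the generator: molecules are independent by
construction, so standard errors are taken across molecules (MSD
plateaus) or across non-overlapping origin windows with stride ≥ the
maximum tested lag (survival), never across correlated lags. Default
problem sizes — a few hundred molecules, a few hundred frames for
dynamics; a few thousand molecule-frames for profiles; 10⁵–10⁶ draws for
the sampling anchors — were chosen so those bands resolve the target
values to a few percent on a single CPU in seconds.

## Known limitations

- Only orthorhombic boxes and straight cylindrical pores; no velocity
  handling; no energetic hydrogen-bond definitions; no diffusion-constant
  fitting.
- Layer counts are capped at three; pores with more than three density
  shells would need the override mechanism.
- The survival/MSD estimators see only stored frames; fast recrossings at
  the pore mouth between frames are counted as continuous residence.
- The summary-schema check validates required keys and types (a minimal
  in-package checker), not the full JSON-Schema vocabulary.
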