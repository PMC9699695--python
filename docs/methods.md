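# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not
emulate, and the design decisions that were genuinely open.

## Units and conventions

All lengths are nm, times ns, pressures bar, forces/tensions pN,
hydrophobicities kcal/mol; the conversion constants live in
`poremetrics.units` (1 bar·nm² = 0.1 pN; 1 pN·nm = 10⁻²¹ J). Frames are
0-indexed and all intervals are half-open `[start, end)`. Two reference
temperatures are exposed: 310.15 K, the physiological simulation
temperature, and 298.15 K, the standard temperature used when quoting
energies in kBT (the conventional "21 kBT per nm of edge" figure
reproduces at 298.15 K — kB·298.15 K = 4.116×10⁻²¹ J — and comes out as
20.2 kBT at 310.15 K; sources rarely state which temperature such
round numbers assume, so both are first-class parameters).

## Edge tension (`edge_mechanics`)

The estimator assumes the fixed-edge-length protocol: a bilayer ribbon
whose two open edges run along *z*, the box length along *z* fixed, the
two remaining dimensions pressure-coupled to 1 bar. The tension per
unit edge length is γ = (1/n_edges)·⟨Lx·Ly·[(Pxx+Pyy)/2 − Pzz]⟩ with
n_edges = 2; the sign convention makes γ positive when the normal
pressure is tensile relative to the lateral pressures, which is tied to
this rotated-box geometry. The default analysis discards the
equilibration head of the series and keeps a trailing window (e.g. the
last 500 ns of a 530 ns run).

The statistical error is the standard error over non-overlapping block
means. The default is 10 blocks over the retained span — a conservative
choice for correlated MD data, where the block length must exceed the
correlation time. On the *white-noise* validation fixtures the
correlation time is zero, so any block length is statistically valid
and the limiting factor becomes the degrees of freedom of the SEM
estimate itself: with b blocks, the |γ̂ − γ|/SEM statistic is
t-distributed with b−1 dof, and P(|t₉| > 3) ≈ 1.5% would make a 3·SEM
band fail a ≥99% coverage check for dof reasons alone. The validation
suite therefore uses 100 blocks (P(|t₉₉| > 3) ≈ 0.3%) on those
fixtures; this is a property of the check, not a tuning of the
estimator.

Continuum bookkeeping on top of γ: the free energy released by
shortening an edge by Δℓ is γ·Δℓ; a circular patch of diameter D
becomes unstable toward vesiculation when π·D·γ exceeds 8π·κ, i.e.
Dc = 8κ/γ and κ_max(D) = D·γ/8. The relation is implemented literally
as printed. Note that for D = 20 nm and γ = 86.4 pN it yields
κ_max ≈ 216 pN·nm ≈ 50 kBT at 310 K, not the ~26 kBT sometimes quoted
for that system (which matches the patch *radius* near 298 K); the
formula here is the literal one and no further claim is attached to it.

The generator `synth_pressure_series` plants a mean anisotropy
Δ = n_edges·γ_true/(0.1·Lx·Ly) on otherwise i.i.d. normal pressures, so
the estimator's expectation is exactly γ_true; with γ_true = 86.4 pN
and a 20 nm box this puts ⟨Pzz⟩ at −3.32 bar. It emulates only the
stationary production segment: no equilibration drift, no pressure
autocorrelation, constant box. Passing the recovery tests therefore
shows estimator correctness and calibrated errors on stationary data,
not robustness to the slowly relaxing starts of real runs (that is what
the discard window is for).

## Lipid contacts (`lipid_contacts`)

A contact is defined on minimum heavy-atom distances: lipid *headgroup*
heavy atoms (hydrogens excluded) versus protein heavy atoms, minimum
image in x, y, z. Detection uses a strict ≤ 0.36 nm cutoff — 0.36 nm is
in, 0.37 nm is out. Durations use the dual-cutoff scheme: an interval
opens at ≤ 0.36 nm and closes at the first frame above 0.50 nm.
Intervals separated by even a single above-release frame are not
merged; with release = detection the scheme degenerates to
single-cutoff segmentation, which gives the shortest possible
durations (residence is monotone in the release cutoff). Occupancy
analysis conventionally drops the first 500 ns of production;
duration counting runs on full trajectories. Both windows are explicit
parameters.

Neighbor search is a periodic KD-tree (scipy `cKDTree` with `boxsize`)
— O(N log N) build, O(1) expected query at fixed density; the test
suite pins it against an independent all-pairs minimum-image oracle on
dense random frames.

Enrichment of species s is (share of lipid–protein contact pairs made
by s) / (mole fraction of s in the inner leaflet); 1 means binding in
proportion to abundance. A species absent from the leaflet has
undefined enrichment and is reported as NaN.

A lipid is *bridging* at a frame iff it has at least one contact with
each of two **adjacent** subunits in that frame (double-sided tape
across the oligomer interface). Adjacency is consecutive subunits
around the arc, closed for rings; lipids touching two non-adjacent
subunits are counted separately rather than mixed in, since interface
bridging is the mechanically meaningful case and adjacency is otherwise
a free choice. Whether bridging should count whole-lipid atoms instead
of headgroup heavy atoms is not fixed by convention; the default keeps
the same headgroup-heavy rule as the contact counting so the two
statistics compose.

## Ion transport (`ion_transport`)

Permeation uses full-traversal counting: a three-state machine per ion
(outside/inside the slab, remembering the entry face) records an event
only when the ion enters through one face and leaves through the other.
This is robust to interfacial dithering, which midplane-crossing
counters overcount. The slab is bounded by the per-leaflet mean
phosphate planes, held fixed over the analysis window — per-frame
boundaries would generate spurious events under membrane undulation
(the choice is switchable by passing different boundaries). z series
are unwrapped with a Lz/2 jump threshold before counting, and face
crossings are classified by the side convention z ≥ plane, so samples
landing exactly on a boundary stay consistent across segments. Events
record the last frame outside before entry and the first frame outside
after exit.

Water-column continuity splits the slab into 0.3 nm bins (≈ one water
diameter) and requires every bin to hold at least one water oxygen
within the pore cylinder radius; reported gaps are the empty bins.

## Pore and membrane geometry (`pore_geometry`)

*Pore radius.* Lipid heavy atoms within ±1 nm of the membrane midplane
are rasterized onto a 0.5 nm (x, y) grid; the pore radius is the radius
of the largest disc centered at the pore center (protein centroid, or
box center) that contains no occupied cell. Accuracy is one grid cell.
Radii below 1.5 nm are reported as "no pore": at that scale a void is
indistinguishable from packing gaps in the raster. The corresponding
width of a pore is lipid-edge-to-lipid-edge (the lipid-free region),
not protein-to-protein.

*Crown deformation.* Headgroup z of one leaflet is binned radially
about the ring center; the far-field reference is the count-weighted
mean z over the outermost quarter of radii. The crown height is the
apex height above the reference, with the apex obtained by linear
extrapolation to r = 0 through the two innermost populated bins at
their radial centroids — for a profile that keeps rising toward the
center, taking the maximum bin mean instead would bias the amplitude
low by about half a bin width times the slope.

*Hairpin tilt.* Angle between the base→tip centroid vector and the
membrane plane (90° = membrane normal, 0° = in-plane), per subunit.

*Circularity and cracks.* Subunit globular-domain centroids are fit
with the algebraic (Kåsa) circle fit — closed form, deterministic,
residual ~10⁻¹⁵ for exact circles. An adjacent interface is cracked at
the first frame where its inter-subunit globular heavy-atom contact
count (0.36 nm cutoff) stays below 5 for at least 50 consecutive
frames; threshold and persistence are configurable because published
crack times generally come without a stated criterion. A threshold of
0 can never crack (counts are non-negative).

*Thinning.* Per (x, y) bin, mean outer-leaflet minus mean inner-leaflet
headgroup z; bins missing either leaflet are NaN, never zero, and the
bulk reference is the median over finite bins.

## Hydrophobicity (`hydrophobicity`)

The shipped scale is the Eisenberg consensus scale (kcal/mol per
residue); scores of residue stretches are plain sums, so they are
additive and permutation-invariant, and the empty sequence scores 0.
Alternative published variants can be loaded from a two-column TSV.
Relative hydrophilicity of two (negative-scoring) sheet linings is
100·(|A|/|B| − 1); when either score is non-negative the phrase "more
hydrophilic" does not apply and the raw signed ratio is returned with a
warning. The built-in strand tables hold the pore-facing residues of
the human GSDMD and mouse GSDMA3 β3/β5/β7/β8 strands.

## Composition planning (`composition`)

Leaflet recipes are mole-percent tables with formal charges; printed
tables often sum to 99.9 or 100.1 from rounding, so percents are
normalized to 100 before apportionment. Integer counts use the
largest-remainder (Hamilton) method — floor all quotas, then hand the
remaining lipids to the largest fractional remainders, ties broken by
table order. This choice reproduces the 99-lipid inner-leaflet census
of the asymmetric plasma-membrane mimetic exactly, including the
single-lipid species, and guarantees |count/n − pct/100| ≤ 1/n.

Salt follows a sodium-first protocol: Na⁺ at the requested molarity
relative to the water count (c·n_water/55.5 M — water-based molarity;
box-volume molarity is an alternative convention, switchable by
adjusting the count), then the neutralizing ion on top: excess Cl⁻ when
the system-plus-sodium charge is positive, extra Na⁺ otherwise.

Leaflet rebalancing after clash-driven lipid deletion treats sterols
and phospholipids as independent groups: for each group, the leaflet
that lost fewer members loses randomly chosen (seeded) survivors until
the group's losses match across leaflets. Different seeds change which
lipids go, never how many.

## Synthetic systems (`synthetic`)

Generators are pure functions of their arguments plus one explicit
integer seed (numpy `default_rng`); identical seeds give byte-identical
serialized fixtures, and every generator returns a `GroundTruth` with
the planted parameters. Systems are built from pseudo-atoms: single
headgroup beads on two leaflet planes with short jittered tail chains
filling the core, bead-cluster globular domains on a ring with two-bead
hairpins, single-bead lipids in contact schedules. This is sufficient
because every analysis operator consumes only positions, heavy-atom
flags and species/leaflet/subunit labels.

What the fixtures deliberately do not emulate: thermal roughness of
leaflet surfaces, lipid conformational disorder, protein flexibility,
pressure autocorrelation, or solvent beyond the water columns the
transport tests need. Green tests on these fixtures demonstrate the
correctness of the operators against known truth — not the scientific
conclusions one would draw from μs-scale simulations, which are out of
scope here.

Specific planted constructions:

- membrane patches place lipids by rejection sampling (uniform with a
  0.45 nm minimum spacing, ~0.65 nm² per lipid capacity check); a pore
  is a lipid-free disc whose rim is exact (tail jitter is projected
  back outside), a crown raises lipids inside the ring radius linearly,
  `crown·(1 − r/R)` — the real deformation shape is not parameterized
  by any published profile, so the linear cone is a recorded free
  choice — and a thinned annulus pulls both leaflet planes toward the
  midplane by a factor.
- rings/arcs place n subunits at equal angular spacing over an arc
  fraction; interface bead stacks at each subunit boundary give
  adjacent subunits ~10 heavy-atom contacts, so crack detection has a
  clean baseline, and the crack trajectory rigidly rotates the
  out-board sub-arc so exactly one interface opens at the planted
  frame.
- ion paths are piecewise-linear z trajectories per path class (full
  crossings, rebounds, 50-fold face dithering, a traversal wrapped
  through the periodic boundary), wrapped into the box before return.

## Pipeline and CLI

`run_pipeline` executes named stages in the requested order from a flat
key-value config (YAML on disk); every parameter has a recorded
default, the report carries a config hash and the seed, and re-running
an identical config reproduces identical outputs. The CLI (`poremetrics
<subcommand>`) is a thin wrapper over the same library calls; outputs
are TSV with `#` header comments and JSON summaries only.

## Validation problem sizes

The shipped test suite runs at desk scale: 200 replicates × 50 000
frames for estimator recovery, 50 random dense frames for the contact
oracle, 1000-frame crack trajectories, 3–5 seeds per planted geometry.
These sizes give comfortable statistical margins for every check while
keeping the full suite around ten seconds.

## Known limitations

- GRO/PDB parsing covers the fixed-column coordinate subsets only — no
  topology, no velocities, no multi-model PDB.
- The pore-radius raster assumes one pore, roughly centered; multiple
  pores or strongly off-center pores need an explicit center argument.
- Crown and thinning profiles assume the membrane normal is z.
- Enrichment uses a single-frame leaflet census; flip-flop during a
  trajectory is not tracked.
- The permeation state machine assumes ions are point-sampled densely
  enough that a single inter-frame segment does not cross more than one
  slab *pair* of faces in opposite directions; pathological sampling
  coarser than the slab width will undercount in both implementations
  and oracle alike.
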