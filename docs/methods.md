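# Methods

## Model and measurement pipeline

A conformation is a set of oriented piecewise-linear curves in nm: two
strand curves per duplex (one point per base pair, strands at ±1 nm
around the duplex axis) and derived midpoint/axis curves. All
topological quantities reduce to the Gauss linking integral evaluated
in closed form for straight-segment pairs (the signed solid angle of
the spherical quadrilateral spanned by the four endpoint directions,
divided by 4π). This is exact per pair and O(n²) per curve pair, which
keeps a full 2000×2000 contribution matrix under a second with the
numba kernels. Writhe is the same kernel applied to distinct segment
pairs of one curve (each unordered pair counted twice); twist sums the
signed rotation of the strand-offset vector about the local axis
tangent with parallel transport across tangent changes. On closed
duplexes the three satisfy Lk = Tw + Wr to better than 0.05 turns,
which the test suite uses as an internal cross-check between three
independent code paths.

### Decomposition of a replication intermediate

Both parental strands are closed circles through the two fork
junctions. Splitting the segment indices at the forks partitions the
full matrix sum into the three block sums (unreplicated, wrapping,
replicated); region charges are reported relative to the relaxed
baseline of the unreplicated region, n_unrep/h, so the three charges
add up to the molecule's ΔLk. Components 1/2 and 4/5 are computed from
direct geometric definitions — twist of the unreplicated region about
its axis, and the linking number of the two daughter midpoint curves,
each closed by the straight virtual segment joining its endpoints
through the fork region — with the region-charge residuals assigned to
components 2 and 5 respectively. This keeps the five-component sum
equal to ΔLk to 1e−6 by construction. Note that the daughter-axis
linking absorbs any writhe of the braid centerline: if the precatenated
braid is itself plectonemically folded, that folding appears inside
component 4 and component 5 carries only the small residual. Matrix
band structure (secondary diagonals = plectonemic branches) is a
separate diagnostic: off-band charge is projected onto the cyclic
anti-diagonal coordinate (i + j) mod n, where each interwound branch
forms one ridge; cyclic runs above 35% of the profile maximum are
counted as bands, gated on at least one turn of total off-band charge.
Branches placed exactly half a contour apart alias onto one coordinate
— a known limitation of this projection.

### Collisions

Collision sites live on reduced midpoint curves: base-pair midpoints
subsampled every 10 nt (one helical turn), three curves for an RI
(unreplicated, daughter 1, daughter 2). The distance landscape is the
clamped minimum distance between reduced segments; the printed
line–line formula is a special case that fails when the closest-feet
fall outside the short segments, so the clamped form is used
throughout. Events are strict local minima against all eight index
neighbours (cyclic on closed curves; plateau ties keep the
lexicographically smallest pair) within the 10 nm cutoff. The
contour-separation exclusion (147 bp ≈ one persistence length,
configurable) is measured through the molecular graph — along a curve,
or through a fork junction for sites on different curves — which also
suppresses trivial "events" where the three duplexes meet at a fork.
Chirality and sign follow the crossing-geometry rules: with the view
axis from the underlying to the overlying site, the counter-clockwise
line angle carrying the underlying tangent onto the overlying one is
left-handed below 90° and right-handed above; the sign is + when the
overlying tangent rotates counter-clockwise onto the underlying one.
The viewer orientation is fixed by the physical coupling that
negatively supercoiled DNA shows right-handed crossings of negative
sign — the implementation reproduces this coupling on generated
fixtures, and mirror images flip both labels. Types: both sites
unreplicated → 1; mixed → 2; both replicated → 3 when the
braid-coordinate separation (arc position along the replicated region
from fork 1) is within 100 bp, else 4.

## The synthetic generator

The generator is the study-condition stage: it builds conformations
whose measured topology equals a prescription, at the sizes used
throughout (2000 bp circles; 1491/509 bp early-stage RIs with region
charges −12/+2 and total ΔLk = −10; 504/1506 bp late-stage RIs with
−2/+12 and +10; helical repeat 10.5 bp/turn, rise 0.34 nm/bp, duplex
radius 1 nm, superhelix radius 4.5 nm, braid radius 4 nm).

Circles are planar axes with strands wound by a twist-free
(parallel-transport) frame; plectonemic molecules use a hub circle with
interwound arms whose rotation count is iterated against the measured
writhe (about 60% of ΔLk as writhe, the rest as twist), and the strand
winding integer is corrected once against the measured Lk, which is
then exact (Lk of closed curves is quantized). Negative ΔLk yields
right-handed interwinding.

For RIs, the daughter duplexes are *launched from the parental strand
endpoints with matching offset phases* ("fork flow-through"). This
choice matters: the Gauss block charge of a region closed at both forks
is quasi-quantized, and with arbitrary fork geometry the construction
knobs move it only in near-integer jumps (strand passages at the fork
as end phases swing). With flow-through anchoring, extra twist wound
into the unreplicated strands drains continuously through the fork into
the other blocks — the geometric analogue of fork rotation — so a
secant iteration on the unreplicated winding plus an integer braid
winding lands the prescribed charges in a few O(n²) measurements.
Consequences worth knowing: feasible prescriptions have near-integer
region charges (the in-vivo partitions are integers), and a prescribed
nonzero wrapping charge is rejected — a braid wound around the folded
unreplicated arm links it zero times net, so wrapping cannot be built
in directly; it emerges dynamically under fork-free relaxation, as it
does in the underlying biology.

Two geometric refinements serve the collision analysis. The superhelix
radius is modulated peristaltically (one pinch of ~1.2 nm per projected
crossing, and one per precatenane turn along the braid): an ideal
interwound pair is equidistant along its whole contact line, so the
local-minimum rule would count discretization ripples instead of
crossings; the pinches localize the close approaches where a thermally
fluctuating plectoneme would have them, giving one juxtaposition per
crossing. And the braid hairpin's two legs are held 19 nm apart so the
only sub-cutoff daughter–daughter approaches are the braid contacts
themselves.

What the generator does *not* emulate: thermal ensembles and their
fluctuation statistics, sequence effects, bending/torsional energetics,
or the equilibrium partitioning of stress after deproteinization (the
initial in-vivo partitions are the targets; relaxation dynamics are the
Monte-Carlo module's job). Passing tests on these fixtures validate the
measurement pipeline and conservation laws, not thermodynamic
observables of real DNA.

## Monte-Carlo relaxer

Moves: crankshaft rotations of 4–50-point axis sub-chains about the
chord through their endpoints (strands carried rigidly; pivot bonds are
preserved exactly); twist-slide moves that rotate strand offsets about
local tangents with ramped edges (twist must be explicitly mobile in a
rigid-strand representation); and, with free forks, fork-swivel moves
that twist the unreplicated duplex through a fork with a 30-point ramp
while counter-rotating the first ~6 points of both daughters about the
fork tangent. Acceptance is purely constraint-based — the goal is
topology-preserving mixing, not thermodynamics.

The strand-passage guard is layered: a 2.0 nm hard core between axis
points more than 12 points apart along the molecular contour (1.45 nm
in the 5–12 band, where superhelix caps legitimately bend close); banded
hard cores between parental A and B strand points (0.95 / 0.80 /
0.60 nm by contour band — these are the only passages that change
Lk(A, B)); a 1.05 nm stretch limit on strand bonds at move junctions
(junction torsion is the local passage channel); and a 0.35 nm per-move
displacement cap so no segment can tunnel between checks. The contour
metric runs through the fork junctions and across the few-nm fork gap.
Under this guard the measured Lk of a closed molecule and the total ΔLk
of an RI are conserved to ~1e−10 over 1e5 moves; with forks held fixed
the per-region charges are conserved to better than 0.3 turns, and with
free forks they drift (by several tenths of a turn over 1e5 moves at
n = 2000) while the total stays pinned — the deproteinization behaviour
at the heart of the analysis.

Pseudo-time is the attempted-move count; the relaxer reports six
snapshots by default.

## Numerical choices and problem sizes

Degenerate segment pairs (coplanar, touching) return zero charge or
raise, as appropriate; quadrature cross-checks in the tests run to
1e−6. Open-curve writhe uses the virtual closure segment implied by
treating the polyline as closed. Matrix storage is dense (n ≤ ~4 k).
Tests and the acceptance script run at the full molecule sizes
(n = 2000/2010) for everything O(n²), and use an 840 bp supercoiled
circle and 210 bp relaxed circles for the million-move conservation and
White-identity batteries, where the property being checked is
size-independent; conservation on the full-size RI runs at 1e5 moves.
All randomness flows from explicit integer seeds; identical seed and
configuration reproduce conformations and reports bit-for-bit.

## Known limitations

Region-charge prescriptions are quasi-quantized (see above); wrapping
cannot be prescribed, only evolved; the band-counting diagnostic
aliases branch pairs half a contour apart; collision counts on
generated fixtures reflect the constructed pinch geometry, not thermal
statistics; the excluded-volume guard is a vetted heuristic (empirically
passage-free over the tested move budgets), not a formal proof of
topological invariance; and the oxDNA reader assumes the classic
4-column topology format with placeholder bases.
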