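# ritopo

Topological analysis of circular DNA and replication intermediates on
coarse-grained 3D conformations: Gauss-linking contribution matrices,
the five-component decomposition of the linking-number difference,
juxtaposition (collision) detection with chirality and topological
sign, and a seeded generator of conformations with prescribed topology.

## Who this is for

People studying how superhelical stress distributes in partially
replicated circular DNA — the state of a plasmid caught between
initiation and termination, with two replication forks separating an
unreplicated parental duplex from two newly made daughter duplexes.
The library takes piecewise-linear strand curves (its own synthetic
conformations, or oxDNA-format trajectories from molecular-dynamics
engines) and measures their topology.

## The quantities it computes

For two closed oriented curves *A*, *B* (the parental strands of a
duplex), the linking number is the Gauss double integral

    Lk = (1 / 4π) ∮_A ∮_B  (r_B − r_A) · (dr_B × dr_A) / |r_B − r_A|³ ,

evaluated in closed form per straight-segment pair; each pair's solid
angle Ω_ij / 4π is an entry of the n×n **contribution matrix**, whose
total is Lk exactly. Relaxed B-DNA has Lk0 = N/10.5 for N base pairs;
the **linking-number difference** ΔLk = Lk − Lk0 and **superhelical
density** σ = ΔLk/Lk0 quantify torsional stress, with
Lk = Tw + Wr (White's identity) splitting it into strand twist and
axis writhe.

A replication intermediate keeps each parental strand as the closed
concatenation of an unreplicated part (a1, b1) and a replicated part
(a2, b2, one in each daughter duplex). Partitioning the matrix index
set at the forks splits Lk into three block sums — unreplicated
(a1·b1), wrapping (a1·b2 + a2·b1) and replicated (a2·b2) — and five
components of ΔLk:

1. ΔTw of the unreplicated region,
2. Wr of the unreplicated region,
3. wrapping between the regions,
4. precatenation of the two daughter duplexes (linking of their
   midpoint curves, each closed through the fork junctions),
5. plectonemes of precatenanes (the replicated-region remainder).

**Collisions** are pairs of contour-distal duplex sites within 10 nm —
the footprint of a protein bridging two DNA sites, the substrate
geometry of a type II topoisomerase. Sites live on reduced midpoint
curves (one point per 10 bp), events are strict local minima of the
segment-pair distance landscape outside a persistence-length contour
exclusion, classified into four types (unreplicated×unreplicated,
inter-region, precatenane, plectoneme-of-precatenanes) and assigned a
chirality (left/right) and a topological sign (+/−).

## Worked example

```python
from ritopo import decompose_ri, early_invivo_config, make_ri

ri = make_ri(early_invivo_config(seed=1))   # 2 kb, 25% replicated, in vivo
dec = decompose_ri(ri)
print(dec.q_unrep, dec.q_wrap, dec.q_rep, dec.delta_lk_total)
```

prints (seed 1):

```
-12.06  +0.12  +1.94  -10.000
```

i.e. the generated molecule carries −12 turns of superhelical stress in
its unreplicated region, +2 turns of right-handed precatenanes in the
replicated region, essentially no inter-region wrapping, and a total
linking-number difference of exactly −10 (an integer, because both
parental strands are covalently closed). `examples/` contains five
short scripts covering the supercoiled-circle diagnostics, the
decomposition, collision tallies (early stage: 8 right-handed negative
type-1 events from the plectonemic unreplicated region; late stage: 12
right-handed type-3 events from the precatenanes), fork-free
Monte-Carlo relaxation, and oxDNA file I/O. A thin CLI (`ritopo
generate|analyze|matrix|collisions|relax`) wraps the same calls.

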