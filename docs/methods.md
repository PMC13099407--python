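# Methods

## Model

An atomic structure is reduced to an undirected simple graph over its
protein heavy atoms; atoms `i, j` are connected iff their Euclidean distance
is strictly below the cutoff (default 7.0 Å). For each atom the graphlet
degree vector (GDV) counts occurrences of the 15 automorphism orbits of the
connected graphlets on 2–4 nodes, under induced-subgraph semantics (a
triangle is never also counted as a 3-path). Flexibility is the linear form

    RMSF_i = n + Σ_{k=0..14} β_k · O_{i,k}

applied to transformed counts: `log(1+x)` per entry, then a per-protein
z-score per orbit column (sample sd, `n−1`; columns with zero variance map
to zeros). Raw reference fluctuations are transformed with a plain `log`
(they are positive by construction) followed by the same per-protein
z-score. Predictions therefore live on a dimensionless normalized-log
scale; no back-transform to Å is attempted because the per-protein scale is
not identifiable from coordinates, and all evaluation is by Spearman rank
correlation at Cα atoms, which is invariant to any strictly increasing
per-protein transform.

The shipped consensus coefficients (intercept 0, fifteen β values, orbit
order O0..O14) were obtained by averaging fits across three MD replicates
of a globular-protein training corpus; `published_model()` returns them and
`save_model`/`load_model` serialize models as JSON with the transform
conventions recorded alongside.

## Orbit counting

Two independent counters are maintained.

*Fast path* (`count_orbits`). Orbits 0–3 come from degrees and per-edge
common-neighbor counts (`o2 = C(d,2) − t`, `o1 = Σ_{u∈N(v)}(d_u−1) − 2t`).
For the eleven 4-node orbits the counter accumulates per-node *non-induced*
marked-pattern counts: closed-form sparse-matrix expressions (via `A²`) for
paths, stars, cycles, tailed triangles and diamond hubs, plus one compiled
(numba) kernel that enumerates triangles and 4-cliques with sorted-adjacency
merges for the two patterns that need explicit enumeration (diamond rims and
`K4`). Non-induced counts are converted to induced orbit counts with an
11×11 integer pattern-containment matrix. That matrix is not hardcoded: it
is derived at runtime by enumerating, for every 4-node graphlet and marked
node, the spanning edge subsets isomorphic to each marked pattern. Ordered
by edge count the matrix is unit-triangular, so its inverse is integer and
the conversion is exact. Complexity is dominated by the `A²` product and the
per-edge common-neighborhood work; no step enumerates 4-subsets of a dense
graph and no dense N×N matrix is formed anywhere (neighbor search is a
KD-tree).

*Oracle* (`count_orbits_bruteforce`). Enumerates all 2/3/4-subsets with
bitset adjacency, keeps connected induced subgraphs and classifies node
roles through a lookup derived from the taxonomy. For connected graphs on
≤ 4 nodes the sorted degree sequence identifies the graph and a node's
degree identifies its orbit, which makes the classification exact without
per-subset isomorphism search; the only zero-free degree sequence of a
disconnected 4-node graph, `(1,1,1,1)`, is absent from the lookup and is
thereby rejected. The taxonomy itself (9 graphlets, 15 orbits, canonical
order: size, then edge count, then maximum degree; orbits within a graphlet
by ascending degree) is generated by exhaustive edge-subset enumeration and
permutation-based isomorphism/automorphism search at import time.

The two counters agree exactly on every random graph tested (the suite
checks >100 seeded Erdős–Rényi graphs, n ∈ [5, 40], p ∈ {0.1, 0.3, 0.5}),
and both satisfy the combinatorial identities Σo0 = 2|E|, Σo3 = 3·triangles,
o2+o3 = C(deg,2), o1+2·o3 = Σ_{u∈N(v)}(deg(u)−1).

## By-parts computation

Residues are split, in file order, into consecutive cores of `chunk_size`
(default 100) residues; each core is augmented with an environment of whole
residues having any atom within `surround_radius` of the core's anchor
atoms, the subgraph over core ∪ environment is built and counted, and core
rows are concatenated. Anchors are the core Cα atoms by default (the
memory-lean convention for the 12–15 Å operating range). Because orbits of
a node depend only on nodes within three edges and every edge is shorter
than the cutoff, any atom that can influence a core atom lies within
`3 × cutoff` of it; when `surround_radius ≥ 3 × cutoff` the implementation
therefore anchors on *all* core atoms, which makes the environment provably
sufficient and the decomposition bit-identical to the all-at-once result.
(Anchoring such a wide surround only on Cα atoms could miss influencing
atoms by up to the intra-residue atom–Cα distance; widening the anchor set
rather than padding the radius keeps the stated 21 Å guarantee exact.) At
12–15 Å discrepancies are confined to atoms within 21 Å of atoms excluded
from their part — the suite checks this confinement explicitly on a
3000-atom structure.

## Ensembles and evaluation

Multi-model files are superposed by iterative least-squares rigid fitting:
each model is Kabsch-fitted (SVD with a determinant constraint that forbids
reflections) onto the current mean structure over a mask (Cα by default),
the mean is recomputed, and the loop stops when the mean moves < 1e-6 Å RMS
or after 10 rounds. RMSF is the per-atom RMS displacement from that atom's
mean position across models; the representative conformer minimizes masked
RMSD to the mean (ties break to the lowest index). Scores are Spearman
correlations with average-rank ties at Cα positions; constant profiles give
NaN with a warning, NaN scores are excluded from summaries with an explicit
tally, and negative-rho proteins are flagged as outliers. Best-of-replicates
takes the per-protein maximum before summarizing. The globularity filter
accepts a structure when its mass-unweighted radius of gyration satisfies
`Rg < N^0.6` for `N` distinct residues, with the companion size condition
`N > 50` reported alongside.

## Synthetic data

The fixture generators emulate what the pipeline actually consumes —
packing geometry — with 4 pseudo-atoms per residue (one named CA), not
chemistry: an ideal α-helix (rise 1.5 Å, 100°/residue, radius 2.3 Å, seeded
jitter), an extended rod (3.5 Å/residue by default; deliberately
non-globular), uniform spherical clouds at protein-like residue density
(0.009 residues/Å³ ≈ 110 Å³ per residue, adjustable), and a two-domain
concatenation. All generators are seed-deterministic to the byte.

The training-set generator (`synth_flex_dataset`) draws real orbit counts
from synthetic structures and sets the reference to
`features·β_true + N(0, noise_sd)` in the normalized-log space where the
model lives (default β_true = the published coefficients, noise sd 0.1,
50 proteins × 125 residues = 500 atoms). Its structure stream alternates
*loose* clouds (density log-uniform in 0.0008–0.0025 residues/Å³) with
*loose* rods (pitch 4.0–5.5 Å): a single geometric family leaves the
log-orbit features nearly collinear (in smooth geometric graphs every orbit
tracks local density, and notably `o3` is almost a function of `o0` and
`o2` through `o2+o3 = C(d,2)`), whereas mixing packing regimes of different
dimensionality at moderate contact density keeps all fifteen coefficients
identifiable by OLS. By default the reference is stored on the normalized
scale; `reference_kind="raw"` exponentiates it instead, which exercises the
full log/z target path but multiplies each protein's coefficients by an
unidentifiable positive scale (the z-score divides by the realized sd of
the protein's log-reference), so exact coefficient recovery is only a
meaningful claim for normalized references — raw-reference fits are checked
for directional agreement. What passing these tests shows is that the
estimator and transforms are correct; synthetic clouds do not reproduce
secondary-structure correlations, side-chain chemistry or MD force-field
behavior, so they say nothing about accuracy on real proteins.

## Numerical and design choices

- Strict inequality `d < cutoff`; the comparison is made on squared
  distances, so a pair at exactly 7.0 Å is excluded without sqrt rounding.
- Node set: heavy atoms of standard amino acids from ATOM records;
  hydrogens, waters, hetero-compounds dropped; among alternate locations
  the highest-occupancy conformer wins, ties to the first encountered.
  All retained chains form one graph unless a chain filter is given.
- Predicted values written to PDB are clamped to the fixed-width B-factor
  range [−99.99, 999.99].
- Zero-variance feature or target columns map to zeros; degeneracy is
  judged with a relative tolerance (an all-identical column can produce an
  sd of ~1e-16 in floating point).
- OLS uses `lstsq`; a rank-deficient design is reported with a warning and
  solved minimum-norm.
- CV folds: protein ids shuffled with the user seed and dealt round-robin
  into k folds; atoms of one protein never straddle folds.
- The CLI defaults to by-parts computation above 2000 atoms, surround 15 Å,
  cores of 100 residues; `--surround 21` selects the exact regime.
- Problem sizes in the test suite (3000-atom decomposition check, 50×500
  recovery experiment, n ≤ 40 oracle graphs) are chosen to exercise every
  code path at desk scale while keeping the whole suite near ten seconds.

## Known limitations

- Only PDB input is parsed (single- and multi-model); mmCIF completeness,
  ligand/nucleic-acid graphs and symmetry mates are out of scope.
- Size-5 graphlets (orbits 15–72), weighted and directed graphlets are not
  implemented.
- Predictions are relative within one protein; absolute Å-scale fluctuation
  amplitudes are not recoverable from coordinates alone.
- Binary MD trajectory formats are not read; frames must arrive as
  multi-model PDB.
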