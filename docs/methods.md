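# Methods

This note documents the models and algorithms `threadfold` implements,
the parameter choices that matter, the synthetic study conditions the
validation runs under, and the limits of what that validation shows.

## Structures and secondary structure

The universal container is the Cα trace: ordered Cα coordinates,
residue identities, an optional three-state secondary-structure string
and an optional per-residue score (pLDDT on input, ResFscore on
output). Physically parsed chains must have consecutive Cα–Cα
distances in (2.0, 4.5) Å unless a chain break is flagged. Reading
goes through gemmi (PDB and mmCIF; altlocs resolved to highest
occupancy, ties to the first encountered; residues lacking a Cα are
dropped with a warning; an all-zero B-factor column is treated as "no
confidence information" rather than pLDDT 0). Writing emits Cα-only
PDB, optionally with a score in the B-factor column scaled to [0, 100].

Secondary structure is assigned from Cα geometry alone with
P-SEA-style window rules on the i→i+2 and i→i+3 distances (helix:
d2 ∈ [4.9, 6.1] Å and d3 ∈ [4.4, 6.2] Å; strand: d2 ≥ 6.2 Å and
d3 ≥ 9.0 Å; otherwise coil). Using distances only makes the
assignment rigid-motion invariant by construction. An externally
supplied 8-state DSSP string overrides the computation (H/G/I→H,
E/B→E, rest→C). The thresholds were set once against ideal helix,
strand and self-avoiding-walk fixtures; they over-assign helix at the
edges of loops, which is acceptable because segmentation for pathway
analysis normally runs on the designed or DSSP string when one exists.

Complexes are handled by concatenating chains with a 21-residue
Gly-Gly-Ser repeat linker (7×GGS). Linker residues get placeholder
coordinates on the straight segment between the flanking termini and
are flagged as chain breaks; profile construction then forces their
pair histograms into the overflow bin so the distance cut-off excludes
them from all scoring.

## Superposition and structural alignment

Rigid fits use the Kabsch SVD solution with the determinant sign fix.
TM-score uses d0 = 1.24·(L_norm − 15)^⅓ − 1.8, clamped to ≥ 0.5 Å
(the standard clamp for L_norm ≤ 21). The TM-optimal superposition of
a fixed correspondence is approximated by the usual iterative scheme:
Kabsch fits on shrinking subsets of residues within a distance cutoff
(starting at max(d0, 3.5 Å), relaxed by 0.5 Å when a subset collapses
below 3 residues), seeded from the full correspondence and from
half- and quarter-length contiguous fragments, keeping the best TM
over all rounds.

The sequence-order structural aligner is deliberately a simplified
TM-align analogue, not a reimplementation: seed correspondences
(gapless diagonals at several offsets plus a DP over secondary-
structure matches) are refined by alternating a Kabsch fit with a
correspondence rebuild by global DP on the transformed distance
matrix, cell score 1/(1+(d/d0)²) and linear gap penalty 0.6
(TM-align's published gap magnitude), for at most 20 rounds each. The
best result by TM-score normalized by the first structure wins, and a
correspondence shorter than 5 residues is an alignment failure. The
reported rotation/translation is the TM-optimal subset fit of the
final correspondence, not the full-correspondence least-squares fit —
with divergent peripheral regions the latter drags the frame away from
the conserved core, which would corrupt the residue-frequency scores
downstream. Determinism comes from fixed seed order and tie-breaking;
there is no randomness anywhere in the aligner.

## Distance binning and profiles

Distances bin into 36 × 0.5 Å bins over [2, 20) Å plus one overflow
bin for ≥ 20 Å (37 total); distances under 2 Å clamp to bin 0, and
bin centers sit at 2 + 0.5·t + 0.25 Å. Structure profiles aggregate,
for every centroid residue pair covered on both sides by a member's
alignment, the member's own Cα distance; pairs gapped in a member do
not count toward that pair's total, and never-observed pairs keep an
empty histogram with count 0. Distance profiles are emulated from a
structure by discretizing a Gaussian of width σ around each true
distance (σ = 0 gives point masses); mass beyond 20 Å accumulates in
the overflow bin.

Peaks are strict local maxima over the interior bins (plateaus take
the leftmost bin — determinism, and shorter distances are better
constrained; absent neighbours count as −∞, so flat histograms have
no peaks; the overflow bin never yields a peak). Peaks below
p_min = 0.05 are dropped; survivors sort by probability. Defaults
k_a = 3 query peaks and k_b = 2 template peaks balance sensitivity to
bimodal flexible regions against noise; all three are config-exposed
because no canonical values exist for emulated predictions. Profiles
serialize to an HDF5 container (datasets `P` and `counts`, bin-scheme
attributes) and to a plain-text `n m bin prob` exchange format.

## Master library

Greedy incremental clustering scans structures by length descending
(ties by id) — the CD-HIT discipline transplanted to structure space.
The first unassigned structure seeds a cluster; each later structure
joins the first seed whose membership score reaches the threshold
(0.8), else seeds a new cluster. The membership score is
min(TM normalized by seed, TM normalized by candidate): symmetric and
conservative, so a short fragment cannot join a long seed on the
short normalization alone. First-fit matches the incremental scan; a
best-fit flag exists. Library extension keeps existing seeds fixed
and lets unmatched newcomers seed new clusters, which can only
over-segment relative to clustering the union from scratch (checked
as a property test). An exact-sequence dedup pass is provided
separately and keeps the first occurrence.

## Three-track alignment

The score of query *a* against template *b* is
alignScore = (S_align + S_gap)/S_tot with

* S_align: over ordered aligned residue pairs (n, m) ↔ (n′, m′), the
  best peak product p·q·w_seq(|n−m|)·w_dist(|d_p−d_q|)·w_cut, maximized
  over the k_a × k_b peak combinations;
* w_seq = 0.5 / 0.75 / 1 for |n−m| < 12 / < 24 / ≥ 24;
* w_dist = 1 / 0.5 / 0.25 for Δd ≤ 5 / ≤ 8 / > 8 Å;
* w_cut = 1 only when the largest *selected* peak distance is below
  λ = 20 Å on both sides (at λ = 20 this reduces to "both sides have
  any peak", since the overflow bin yields none; smaller λ values
  tighten it);
* S_gap = −(1.0 per gap run + 0.1 per gap position), the affine gap
  model (the gap treatment is otherwise unconstrained, so both knobs
  are config-exposed);
* S_tot: the same sum over the query side alone — top histogram
  probability per pair, w_cut evaluated on the query only — making
  alignScore ≤ 1 with equality exactly for gap-free perfect
  self-matches.

Sums run over ordered pairs, diagonal excluded (a residue has no
distance to itself); both numerator and normalizer use the same
convention, so the self-alignment identity is exact.

The single pass has three levels. Level 3 scores one
(query pair, template pair) hypothesis by the peak product. Level 2
fills the protein-specific matrix M[n, n′] with a monotone DP (gaps
free) over the ordered contact partners of n versus those of n′, where
a contact is a pair with peaks and selected-peak distance < λ — this
sparsification bounds the cost near O(L_q·L_t·c²) for mean contact
count c. Level 1 is a global Needleman–Wunsch with affine gaps over M
(terminal gaps penalized); the final scores are then recomputed from
the alignment per the definitions above. An all-zero matrix (or a
zero S_align) returns the empty alignment with alignScore 0. The DP
inner loops are numba-compiled; both levels are verified against
explicit enumeration of all monotone alignments/matchings on small
instances.

Library search is two-stage: the query is aligned to every cluster
seed's multi-peak structure profile, the best N_clu clusters (default
10) are kept, and their members are re-aligned using single-peak
point-mass profiles of each member structure (a single structure has
one observed distance per pair). Members are returned sorted by
alignScore.

## Quality scoring and ranking

DMScore compresses an L×L nonnegative deviation matrix into (0, 1]:
mean over off-diagonal entries of 1/(1+(d_ij/d*)²) with
d* = log(ε + |i−j|), ε = 10⁻³. The log scale removes the trivial
size dependence; at |i−j| = 1, d* ≈ ε so adjacent-residue terms
vanish unless their deviation is exactly 0 — the formula's literal
behaviour, preserved as such.

The learned deviation predictor that would feed DMScore in a
production system is replaced by a deterministic geometric surrogate
behind a one-line scorer interface: for each pair of aligned
residues, the deviation estimate is |template Cα distance − nearest
query peak distance| (pairs without query peaks are excluded through
a validity mask that also fixes the normalizer); the deviation matrix
is indexed by consecutive aligned positions. On a σ = 0 self-profile
the estimates are bounded by the 0.25 Å bin-discretization error, so
the self template scores > 0.9.

Ranking fuses the two scores as
rankScore = alignScore² + (1 − alignScore)·pDMScore — implemented
exactly as that quadratic-in-alignScore form — with ties broken by
alignScore then id. Only the N_pDM best templates by alignScore
(default 10) receive a quality score; the rest keep
rankScore = alignScore².

## Folding pathways

Each of the top N_t homolog templates (default 50; config-exposed) is
structurally aligned and superposed onto the target. A target residue
aligned at deviation d contributes 1 / 0.75 / 0.25 / 0 for
d ≤ 2 / ≤ 4 / ≤ 5 / > 5 Å; unaligned residues contribute 0 (the
"otherwise" branch), and templates weight uniformly. ResFscore is the
per-residue mean. The target splits into maximal secondary-structure
runs; loop runs of ≤ 4 residues merge into the preceding structured
segment (else the following one), keeping the structured type — the
merge direction and all tie rules are fixed for determinism.

Intermediate selection takes segments with average ResFscore ≥ I_cut,
starting at I_cut = 0.4 and walking in 0.02 steps (up when the
selected length exceeds 0.75·L, down when below 0.25·L; the selected
set shrinks monotonically in I_cut, so the walk is directed and
terminates within 50 steps). The 0.02 grid can step over a feasible
threshold that lies strictly between two segment averages, so when
the walk fails the implementation sweeps the distinct segment-average
values — the only points where the selection can change — and returns
an in-window selection whenever one exists anywhere in [0, 1]. If no
threshold satisfies the window, the closest selection is returned
with an explicit infeasibility flag. The folding order is the
segments sorted by average ResFscore descending, ties to the
N-terminal segment; intermediate segments are labelled as forming
first.

## Synthetic study conditions

The generator emulates exactly the statistical structure the method
assumes: idealized Cα geometry (helix: 1.5 Å rise, 100°/residue,
2.3 Å radius; strand: 3.4 Å-rise zigzag; loops: self-avoiding 3.8 Å
random walks; 2.5 Å clash limit, Cα-only realism being sufficient for
distance-based scoring), families sharing a noisy conserved core with
per-member re-sampled peripheral segments, hinge-rotated alternate
conformations that make flexible-region histograms bimodal, and
randomized member sequences (homologs diverge in sequence). The
benchmark library uses 6 folds × 5 members of ~80 residues with
0.5 Å member coordinate noise and 0.5 Å profile smear; folds come
from structurally distinct topology archetypes so that between-fold
TM-scores stay far below the 0.8 clustering threshold by
construction. Core-recovery families have a 42-residue three-helix
core and a 30-residue re-sampled periphery (core fraction 0.62,
inside the selection window). All generation is reproducible from
(seed, spec).

What passing these conditions shows: the scoring identities, DP
optimality, clustering and selection logic are implemented correctly,
and the pipeline's discrimination works when the modelling assumptions
hold exactly. What it does not show: performance on real predicted
distance distributions (whose error is neither Gaussian nor
independent), on real fold space (where between-fold similarity is
continuous rather than engineered), or with a trained quality
predictor. The validation is a correctness and behaviour argument,
not a benchmark claim.

## Numerical choices and limitations

* Distances are Cα–Cα throughout; 1-based residue positions in every
  interface, 0-based bin indices.
* Histogram normalization tolerance 1e-6; score identity tolerances
  1e-9 (exact identities) and 1e-6 (geometric identities).
* Validation problem sizes (80-residue structures, 20 replicates,
  200 enumeration instances, 1000 fuzz tables) were chosen as the
  smallest sizes at which the tested properties are non-trivial.
* The aligner is desk-scale: exact on self/rigid cases and monotone
  under noise, but it is not TM-align and makes no claim of optimal
  alignments on hard remote pairs; non-sequential (permuted)
  alignment is out of scope.
* Peak-count and threshold defaults (k_a, k_b, p_min, N_clu, N_pDM,
  N_t) have no canonical published values for emulated inputs; all
  are config-exposed and the defaults are stated here rather than
  asserted by tests.
* The pLDDT filter passes structures lacking any confidence score
  (with a warning), since experimental structures carry none.
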