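# Methods

## Model

Two proteins are reduced to their ordered Cα traces, `a_1..a_m` and
`b_1..b_n` (Å). An alignment is a one-to-one partial matching `w` of
residues of A to residues of B with fixed cardinality `k`; its quality
under a rigid motion `T` is the RMSD over matched pairs. The alignment
problem is posed as a bilevel program: the outer (master) problem searches
over `T`, and its objective

    F(T) = sqrt( z*(T) / k ),
    z*(T) = min_w Σ_{(i,j) ∈ w} || T(a_i) − b_j ||²   s.t. w one-to-one, |w| = k

is the optimum of a k-cardinality linear assignment problem (k-LAP) over
squared distances. Because the inner problem is solved exactly at every
evaluation, assignment and superposition are optimized simultaneously
rather than alternately, and because the k-LAP carries no order
constraint, the optimal matching may be non-sequential — circular
permutations are handled natively.

Assumptions: single chains, one conformer, rigid bodies (no hinge or
loop flexibility), Cα-only geometry.

## Exact subproblem

The k-LAP is reduced to a square linear assignment problem of size
`(m + n − k)`: the `m` real rows are joined by `n − k` dummy rows and the
`n` real columns by `m − k` dummy columns; real–dummy entries cost 0 and
dummy–dummy entries carry the prohibitive finite cost `1 + k·max(c)`,
which makes any optimum use exactly `k` real–real matches. The square
problem is solved with `scipy.optimize.linear_sum_assignment`
(Jonker–Volgenant style, exact); when `k = min(m, n)` the rectangular
solver is used directly. Exactness is verified in the test suite against
exhaustive enumeration on all instances with `m, n ≤ 7`. Ties between
equally cheap assignments are resolved arbitrarily by the solver; the
objective — the only quantity fed back to the master problem — is unique.

## Master search

`F` is piecewise-smooth (kinks where the optimal assignment switches) and
highly multi-modal in the rotation angles, so the master problem is
solved derivative-free under a fixed evaluation budget. The default
engine is deterministic given a seed and runs four phases:

1. **Design.** The zero-angle (centroid-coincidence) candidate is always
   evaluated first, followed by the four principal-axes superposition
   hypotheses — the proper rotations mapping A's inertia axes onto B's,
   one per sign combination. These structured seeds matter: the strongest
   decoy minima of `F` are 180° flips about the inertia axes, which
   preserve the second moments of the cloud, and the hypotheses place one
   candidate near the global basin whenever the moments are informative.
   The remainder of the design (capped at 96 points) comes from a
   scrambled Sobol sequence mapped to Haar-uniform rotations (Shoemake's
   quaternion construction), so coverage is even over SO(3) rather than
   over the Euler box. If the caller restricts the angle bounds, plain
   box sampling is used instead.
2. **Zoom.** The six best design points each receive 12 local samples
   within a 25° rotation ball (translations, in 6-DOF mode, within 15%
   of the box), exploiting the broad funnel that surrounds good
   superpositions.
3. **Polish.** Nelder-Mead from the incumbent, restarted while it keeps
   improving. On the smooth region where the assignment has locked in,
   this converges far faster than direct search.
4. **Continuation.** Remaining budget is spent on further Sobol chunks
   (32 points), re-zooming and re-polishing whenever the incumbent
   improves. Budget exhaustion is the normal exit.

The design size is capped independently of the budget and every phase is
deterministic, so the evaluation sequence at budget `b` is a prefix of
the sequence at any larger budget — the returned best-so-far `F` is
provably non-increasing in the budget, a property the tests assert.

**Degrees of freedom.** For proteins of similar size the translation is
eliminated by pinning the centroids (both structures pre-centered once;
the search runs over the three angles). This 3-DOF mode is the default,
with a default budget of 100 evaluations per k (configurable; the
recovery tests use 300). The 6-DOF mode adds the translation with bounds
equal to the centroid-difference vector ± half the larger bounding-box
diagonal per axis, and wants a larger budget (default 1000).

## Choice of k and termination

Similar proteins align over ≥ 85% of the smaller chain, so k is swept
from `round(1.00·L_min)` down to `round(0.85·L_min)` in steps of
`max(1, round(0.01·L_min))` (at most 16 master searches per pair). Each k
gets an independent, identically seeded search. The sweep stops at the
first k whose SAS_f falls below 4 Å — the cutoff that separates the
empirically disjoint similar/dissimilar score distributions — otherwise
the explored alignment with the lowest SAS_f is returned and the pair is
flagged dissimilar. Ties are broken by larger fragment length, then
lower RMSD.

## Scores

With `N_match = k` and `L_min = min(L_A, L_B)`:

    SAS   = 100 · RMSD / N_match
    SI    = RMSD · L_min / N_match
    SAS_f = 100 · RMSD / N_f

`N_f` (total fragment length) sums maximal runs `(i, j), (i+1, j+1), …`
— consecutive in both chains with a common offset — of length ≥ 5;
shorter runs count zero. For a fully sequential alignment composed of
such fragments, SAS_f equals SAS. A matching whose runs are all shorter
than five residues has `N_f = 0`; it is flagged *disordered* and SAS_f
is reported as +∞ (serialized as null in JSON). Two conventions are
deliberate: anti-parallel runs `(i+1, j−1)` do **not** count toward N_f
(continuous fragments in the fragment-scoring literature are
co-directional), and SI weights by the smaller protein's length, per its
original definition. Lower is better for all three; 4 Å is the
similar/dissimilar cutoff.

## Sequential extraction

The largest sequential alignment inside a non-sequential one — the
maximum subset of pairs strictly increasing in both chains — is found by
the classic quadratic dynamic program: `len[i]` is the longest sequential
sub-alignment terminating at aligned residue i of A, `prev[i]`
back-points to its predecessor, and backtracking from the maximal `len`
yields the subset. Ties among equal-length predecessors go to the
smallest index, making the output deterministic (the optimal cardinality
is unaffected; the tests verify it against an independent exact
maximum-clique solver on the comparability graph). The extracted subset
is re-scored under the same transform; the transform is not re-optimized.

## Synthetic structures

The fixture generator emulates single-chain Cα traces so the whole
pipeline is testable without downloads:

* **helix** — ideal α-helix (rise 1.5 Å, 100°/residue, radius 2.3 Å;
  consecutive spacing ≈ 3.83 Å). Note its approximate screw symmetry.
* **coil** — self-avoiding persistent random walk with exact 3.8 Å steps,
  ≥ 2.8 Å non-consecutive separation, confined to a sphere of radius
  `4.2·n^(1/3)` Å. The confinement reproduces the empirical compactness
  of single-domain globular proteins (Rg ≈ 2.2·N^0.38 Å, about 10 Å at
  n = 60), which sets the difficulty of rotational search: an extended
  walk has unrealistically tiny basins, an over-packed ball is
  rotationally near-degenerate under non-sequential matching.
* **hairpin** — two antiparallel strands joined by a two-residue turn.

`perturb` derives a second structure with recorded ground truth by
applying, in order: deletions, a circular permutation (residue *order*
is cut and rotated; coordinates stay put — precisely the non-sequential
challenge), a rigid motion, and isotropic Gaussian jitter.

What the fixtures do not model: real secondary-structure statistics,
side chains, sequence identity, conformational (hinge) change, missing
density, or crystallographic artifacts. Passing the recovery tests
therefore demonstrates correctness of the optimization and scoring
machinery on protein-scale geometry, not benchmark performance on real
PDB pairs — for that, run the aligner on downloaded structures
(`scripts/run_pairs.py`).

## Numerical choices and edge cases

* Rotation convention: extrinsic X-then-Y-then-Z
  (`R = R_z·R_y·R_x`), radians internally, degrees at the CLI. Any fixed
  convention spans SO(3); results do not depend on the choice.
* Angles normalized to [−π, π); candidate angles outside the box are
  wrapped (the objective is periodic), translations clipped.
* Costs are kept in Å² without scaling so `F = sqrt(z/k)` needs no unit
  juggling; the dummy-block cost `1 + k·max(c)` is finite to keep the
  LAP solver numerically safe.
* Structures below 5 residues are rejected with guidance (N_f, hence
  SAS_f, is undefined below the fragment threshold).
* Residues lacking a Cα are skipped at parse time; the first listed
  altLoc is kept; only the first MODEL of multi-model files is read;
  HETATM records are ignored. Alignment indices are 1-based positions
  along the parsed chain, with author numbering carried along in
  reports.
* Problem sizes in the test suite — n = 60 backbones, budgets of 300
  evaluations (3-DOF) and 600 (6-DOF), 10–20 seeds per property, 200
  enumeration instances with m, n ≤ 7, 1000 extraction instances with
  ≤ 12 pairs — were chosen to exercise every code path at protein-like
  scale while keeping the default suite in the seconds-to-a-minute
  range on one core.

## Known limitations

* The master search is a global heuristic: it carries no optimality
  certificate, and sufficiently symmetric point sets (long ideal
  helices, near-spherical clouds) can defeat the inertia-axes seeding
  and land in a decoy superposition within small budgets.
* Independent per-k searches ignore the warm-start structure of the
  sweep; this costs a constant factor of work but keeps runs
  reproducible and k-separable.
* Bond-level flexibility (hinges, loop remodeling) is out of scope; a
  conformational change between the two structures will split the
  alignment rather than bend it.
* One chain per structure; oligomeric and multi-domain assemblies must
  be aligned chain by chain or pre-sliced with the residue-range
  selector.
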