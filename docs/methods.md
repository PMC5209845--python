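# Methods

This note documents the models, numerical choices and limitations of
`cellsym`. Everything stated here is computed by the package's tests or
by `scripts/acceptance.py`; nothing is an external empirical claim.

## Shape space and superimposition

Configurations are ordered sets of k 2-D landmarks. Generalized
Procrustes analysis (GPA) centers each configuration, scales it to unit
centroid size (sizes are retained separately for allometry), and
iterates: rotate each configuration to the current consensus by ordinary
Procrustes, recompute the consensus as the coordinate-wise mean.
Convergence is declared when the consensus RMS change falls below
`tol = 1e-10` (default `max_iter = 100`); both steps are coordinate
descent on the total Procrustes sum of squares, so the per-iteration SS
history is non-increasing, which the tests assert. On realistic shape
variation convergence takes fewer than ten iterations; a run that
exhausts `max_iter` is flagged `converged = False` rather than raised.

Rotations are strictly proper (det +1); in 2-D the optimal rotation has
the closed form atan2(M01 − M10, M00 + M11) with M = AᵀB. Mirroring is
never performed implicitly by alignment — a symmetry analysis is
meaningless if the superimposition silently reflects — but only through
explicit `RelabelMap`s (coordinate mirror plus an involutive landmark
relabeling).

After alignment, coordinates are orthogonally projected onto the Kendall
tangent plane at the consensus. All Procrustes distances (PD) in the
package are tangent-space Euclidean distances in a joint superimposition;
the tests verify agreement with full ordinary-Procrustes distances to 1%
at small shape variation.

**Orientation of the symmetry frame.** GPA fixes orientation only up to
one global rotation, while the character projectors mirror across the
*coordinate* axes. The object-symmetry pipeline therefore rotates the
whole aligned dataset by the (proper) ordinary-Procrustes rotation of the
consensus onto the unit-size template before projecting. This uniform
rotation changes no shape relationship; omitting it mixes the subspaces
almost arbitrarily, which the single-component generator tests would
catch immediately.

## Symmetry as characters of (Z₂)^m

Every analysis of symmetric structure in the package is phrased through
the reflection group generated by its mirror axes: the biradial full-cell
group (axes: semicell, left–right), the 3-axis LLS lobule group (+
intra-lobe) and the 4-axis ULS group (+ main incision, minor incisions).
The 2^m characters — ±1 sign patterns over the axes — are enumerated
programmatically (graded by the number of −1 axes, then axis order) rather
than hand-coded, eliminating transcription errors in the 16-effect ULS
bookkeeping; the tests verify exact integer orthogonality of the sign
matrix and closure under pointwise products.

Characters serve double duty:

* as **subspace projectors** on full-cell shape space,
  P<sub>χ</sub> = (1/2^m) Σ<sub>g</sub> χ(g) T<sub>g</sub>, with
  T<sub>g</sub> the labeled reflections (idempotent, mutually
  annihilating, complete — asserted at 1e-10);
* as **ANOVA effects** over the 2^m symmetry-equivalent lobule positions,
  each non-trivial character splitting the positions into two equal
  groups.

For the ULS the two intra-3rd-order-lobule asymmetries are mapped as:
"type I" = the minor-incision character (position groups {b1, b4} vs
{b2, b3}) and "type II" = the product of the minor- and main-incision
characters ({b1, b3} vs {b2, b4}). This follows from the group action:
the minor-incision reflection swaps b1↔b2 and b3↔b4, the main-incision
reflection swaps b1↔b4 and b2↔b3, so position bits are (main, minor) =
(+,+), (+,−), (−,−), (−,+) for b1..b4. The choice is a labeling
convention only; it permutes row names, not sums of squares.

## Object symmetry

n cells → 4n orbit configurations (identity, vertical, horizontal, both,
each relabeled) → joint GPA → template-frame rotation → grand-mean
centering → projection into the four character subspaces. Subspace sums
of squares are computed inside the projections (their PCA eigenvalues sum
to the subspace SS); a joint PCA is reported as well, with every joint
axis classified to the subspace holding ≥ 99% of its squared norm and a
degeneracy warning for mixed axes. Per-cell subspace magnitudes use the
identity orbit copy (any copy gives identical magnitudes by projector
orthogonality — asserted, not assumed), and their four squared values sum
to the cell's squared distance from the grand mean.

The magnitudes enter a one-way repeated-measures ANOVA (components fixed,
cells as subjects): F = MS_components / MS_residual on
(3, 3(n−1)) df, Tukey HSD via the studentized range on MS_residual.
The implementation is cross-checked against `statsmodels.AnovaRM`, and
its type-I error is calibrated by simulation. The published
worked-example ledger (between 0.0093/3, within 0.0162/268, individuals
0.0051/67) reconstructs F = 56.14, matching the printed 56.2 to the
2-significant-figure precision of the printed sums of squares.

Input to this analysis is one configuration per cell; the two
digitisation replicates are averaged after per-cell rigid alignment. The
matching analysis, by contrast, keeps both replicates — its error stratum
is defined by them.

## Matching symmetry (nested Procrustes ANOVA)

Lobules are extracted as 7-landmark configurations (complete cell ×
position × replicate crossing), mirrored once per −1 axis bit of their
position to a common orientation class (an odd number of mirrors is a
reflection, an even number a proper rotation that GPA removes), and
jointly aligned. With ȳ the replicate-averaged position shapes:

* SS_individual = rP Σ_c ‖ȳ_c − ȳ‖², df n − 1;
* SS_χ = rP Σ_c ‖c_χ,c‖² with c_χ,c = (1/P) Σ_p χ(p) ȳ_c,p, df n
  (one contrast per cell — the effects are nested within individuals
  because semicell/side identity is arbitrary in these cells);
* SS_error = replicate deviations about cell × position means,
  df nP(r − 1).

The character basis makes the decomposition an orthogonal transform, so
SS conservation holds to float precision on every run (asserted at 1e-8
inside the function itself), and the df ledger is structural:
(n−1) + (2^m −1)·n + nP(r−1) = nPr − 1. A brute-force oracle (explicit
two-group mean fits per cell and effect) reproduces every SS at 1e-8.

Pseudo-F ratios pool the *other* nested asymmetric effects:
F_ind = MS_ind / [Σ_χ SS_χ / Σ_χ df_χ], and for each χ the pool excludes
the tested effect (and always excludes individual and error). p-values
and Z scores come from permutation distributions of MS_effect/MS_error
(both scales of the observed statistic are computed; the comparison is
like-with-like on the error scale): nested effects permute position
labels within cells with replicate pairs kept together (the restricted
scheme; unrestricted shuffling is available via `permutation="full"`),
the individual effect shuffles whole replicate-pair units across the
cell × position grid. p = (1 + #{F* ≥ F_obs}) / (n_perm + 1), so the
minimum at 999 permutations is 0.001; Z = (F_obs − mean F*)/sd F* on the
raw F* distribution. Type-I error of both the nested and the individual
test is calibrated to [0.03, 0.07] at α = 0.05 on exchangeable
(digitisation-noise-only) populations.

Caveat: when strong symmetric cell-level variation is present, the
within-cell label permutation redistributes some of it into asymmetric
contrasts, which makes the nested tests conservative rather than liberal;
the calibration above therefore uses the clean exchangeable null.

## Post-hoc semicell bootstrap

Per lobule role: replicate-average, average the two same-semicell copies,
take the tangent PD between the two semicell averages; the observed value
is the mean over cells. The inter-cell pool holds PDs between
semicell-averaged role configurations of all distinct cell pairs with
both cross-semicell pairings (2·C(n,2) = 4556 values at n = 68), sorted
so the pooled set is invariant to which semicell is labeled "first".
Bootstrap proper (draws of n with replacement, 999 means); the reported
statistic is the rank of the observed mean in that distribution. At
n = 4 cells the bootstrap rank agrees with the exactly enumerated
percentile (12⁴ draws) within Monte-Carlo error; under exchangeable
semicells the rank is uniform (KS-tested), and a shared cell-level
deviation drives it to the bottom of the distribution.

## Integration

Each of the 26 units is GPA-aligned as its own dataset across all cells
and replicates; tangent coordinates are replicate-averaged (integration
is a between-cell analysis — measurement error would only attenuate
covariances) and allometry-corrected by least-squares regression of every
tangent coordinate on the unit's own centroid size (whole-cell size and
no correction are options), residuals re-centered on the consensus.

Two-block PLS takes the SVD of the cross-covariance matrix of two
column-centered blocks; the PLS correlation is the Pearson correlation of
the first score pair, reported non-negative with the raw sign kept in
metadata. The RV coefficient is tr(S_XY S_YX) / √(tr(S²_XX) tr(S²_YY)).
Permutation tests shuffle one block's specimen order (999 default).
Tested properties: SW1 covariance bounds a 10⁴-direction random search,
Σ singular values² = tr(S_XY S_YX), RV(X,X) = 1, univariate RV = r²,
rotation invariance, calibrated type-I error.

Quadrant identity is inherently ambiguous, so quadrant-level runs are
averaged over correspondence classes into role-pair matrices (roles: a1,
a2, b1..b4, polar). Two matrices are produced: *within-semicell* (same
quadrant pairs, 4 runs per role pair, diagonal masked; polar pairs each
quadrant's unit with its own semicell's apex) and *cross-semicell* (upper
quadrants × lower quadrants, 4 runs — 8 for unordered distinct role pairs
— with the diagonal meaningful: the same role on opposite semicells;
polar × polar has the single run up × lp). PLS correlations and RV are
averaged per class; permutation p-values are reported per run with the
class median — no combined test is invented. Both matrices are invariant
to relabeling the quadrants, which the tests assert by reflecting whole
populations. The Mantel test between the PLS and RV matrices correlates
off-diagonal upper-triangle entries (Pearson; Spearman would be a trivial
variant) with a simultaneous row/column permutation null.

## Synthetic populations

The generator is the package's study-condition stand-in for a real
twice-digitised population; its defaults are fixed once:

| component | default | rationale |
|---|---|---|
| n_cells / n_replicates | 68 / 2 | study design |
| template | 208 landmarks: 4 × (2 LLS + 4 ULS) × 7 lobule + 2 × 7 polar + 26 outline/isthmus, exactly biradial, ~120 μm across | design counts |
| sd_symmetric (full cell) | 0.75 μm | with the three asymmetric sds below, reproduces the reported ordering and rough proportions of the four subspace shares (semicell ≫ symmetric ≫ left-right ≳ transversal) |
| sd semicell / left-right / transversal | 1.45 / 0.60 / 0.52 μm | as above |
| LLS lobule characters | symmetric 0.55, semicell 0.45, intra-lobe 0.45, others 0.15 μm | individual, inter-semicell and intra-lobe rows dominate the nested ANOVA, as in the motivating data |
| ULS lobule characters | symmetric 0.55, semicell 0.42, minor-incision 0.42, others 0.15 μm | as above ("type I" dominant) |
| log-size sd / allometric slope | 0.08 / 15 | mild allometry, ~±16% size range |
| sd_measurement_error | 0.18 μm per coordinate | error stratum ≈ 1–2% of total SS (same order as published error shares) |
| rigid motion | rotation U[0, 2π), translation U[−30, 30]² | GPA must remove it; tests assert it does |

Deviations are drawn *in the character basis* (projector images for
full-cell components; canonical-frame deltas planted per position with
the character's sign and the unit's local frame for lobule components),
so injected components are exactly orthogonal and the ledger gives exact
per-cell ground truth; reconstruction of every configuration from ledger
components is asserted at 1e-10. Optional `SharedFactor`s plant a latent
score per (cell, semicell) into chosen lobule roles to create known
integration structure.

What the generator does **not** emulate: correlated digitisation error
along outlines, directional asymmetry (inherently unidentifiable here),
biologically structured covariance beyond the planted components, and any
morphogenetic mechanism. Passing tests therefore demonstrate correctness
of the estimators and calibration of the tests under known truth — not
biological conclusions about real populations.

## Numerical choices and degenerate inputs

* GPA tol 1e-10 / max_iter 100; consensus = mean of aligned copies.
* PCA tie-breaking: descending eigenvalue, largest-magnitude loading
  positive.
* Joint-PCA subspace classification threshold: 99% of axis norm.
* p-value convention: add-one numerator and denominator.
* A population with zero shape variation (total tangent SS at float-noise
  level, < 1e-12 per configuration) reports R² = 0 for every effect
  rather than noise ratios; degenerate permutation nulls warn and report
  the floor p.
* Zero size variance makes allometry correction the identity (with a
  warning); zero-variance blocks make RV undefined (an error).
* Problem sizes in the test suite are chosen for sub-two-minute suite
  runs: structural and worked-example checks run at the full study scale
  (68 cells), simulation calibrations use 6–16 cells with 99–199
  permutations and 100–1200 replicates per claim.

## Known limitations

* 2-D landmarks only; no semilandmark sliding; no image processing.
* The permutation scheme of the original distance-based implementation
  this models is not published; restricted within-cell permutation is the
  primary scheme here and unrestricted shuffling a flag — they are not
  claimed equivalent.
* Thin-plate-spline deformation grids are out of scope; PC loadings are
  exported for external visualization instead.
* The matrix correlation between PLS and RV integration matrices is
  descriptive; with 21 role pairs its power is limited.
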