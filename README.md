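# cellsym

Shape asymmetry and morphological integration of biradially symmetric
cells, by landmark-based geometric morphometrics.

Unicellular desmids of the genus *Micrasterias* are built from two
mirror-image semicells, each split by a second mirror axis into two
quadrants, with every quadrant carrying a hierarchy of terminal lobules.
`cellsym` implements the complete analysis kit for asking how such a cell's
shape variation distributes over its symmetry axes and how strongly its
repeated parts covary:

* **Object symmetry.** Each 208-landmark cell configuration is expanded
  into its four-fold orbit under the labeled reflections of the biradial
  group (identity, vertical mirror, horizontal mirror, both), all copies
  are jointly superimposed by generalized Procrustes analysis (GPA), and
  the tangent-space variation is split into the four orthogonal character
  subspaces of (Z₂)²: totally symmetric, inter-semicell, left–right, and
  transversal. Per-cell subspace magnitudes are compared by one-way
  repeated-measures ANOVA with Tukey HSD.
* **Matching symmetry.** The 7-landmark terminal lobules (8 per cell in
  the lower lateral sublobe, LLS; 16 in the upper, ULS) are mirrored to a
  common orientation, jointly aligned, and decomposed by a nested
  Procrustes ANOVA whose factors are the characters of the 3-axis (LLS)
  or 4-axis (ULS) reflection group: one symmetric individual effect plus
  2^m − 1 asymmetric effects nested within cells, with an exact
  (Parseval) sum-of-squares decomposition, pooled pseudo-F ratios,
  permutation p-values and Z effect sizes.
* **Post-hoc semicell test.** Per lobule role, the mean intra-cell tangent
  Procrustes distance between opposite-semicell averages is ranked inside
  a bootstrap distribution of inter-cell means.
* **Integration.** Every one of the 26 per-cell units (24 terminal
  lobules + 2 polar-lobe apexes) is its own GPA dataset; after allometry
  correction (multivariate regression of shape on centroid size),
  pairwise two-block partial least squares (singular warps), RV
  coefficients and permutation tests are averaged over the
  quadrant-ambiguity classes into role-pair integration matrices, which
  are compared by a Mantel test.
* **Synthetic populations.** Because analyses of this kind need data with
  known truth, `cellsym` ships a generator that plants variance
  components directly in the character basis of each symmetry group
  (plus allometry, digitisation error, and random rigid motions) and
  returns a complete per-cell ground-truth ledger.

The statistic at the core of the matching analysis: for a character χ of
the position group, the per-cell component is
c<sub>χ</sub> = (1/P) Σ<sub>p</sub> χ(p) ȳ<sub>p</sub> over the P
replicate-averaged position shapes ȳ<sub>p</sub>, with
SS<sub>χ</sub> = r·P·Σ<sub>cells</sub>‖c<sub>χ</sub>‖² on n degrees of
freedom (r digitisation replicates, n cells). Character orthogonality
makes Σ<sub>χ</sub> SS<sub>χ</sub> + SS<sub>error</sub> = SS<sub>total</sub>
exact. Each effect is tested with
F = MS<sub>χ</sub> / [Σ<sub>χ′≠χ</sub> SS<sub>χ′</sub> / Σ<sub>χ′≠χ</sub> df<sub>χ′</sub>]
against the pooled remaining nested asymmetric effects.

## Worked example

```python
import cellsym as cs

template = cs.make_template()                     # 208-landmark biradial template
population = cs.simulate_population(template, seed=1)   # 68 cells x 2 digitisations

# object symmetry: subspace shares and repeated-measures ANOVA
cells = cs.cell_mean_configurations(population)
sym = cs.object_symmetry_analysis(cells, template, cell_ids=population.cell_ids)
for name, share in sym.decomposition.proportions.items():
    print(f"{name:>20s}: {100 * share:.1f}%")

# matching symmetry: nested Procrustes ANOVA of the LLS terminal lobules
table, dataset = cs.matching_anova(population, "LLS", n_perm=999, seed=1)
print(table.frame[["source", "df", "ss", "r2", "f", "p"]].round(3).to_string(index=False))

# post-hoc bootstrap on semicell Procrustes distances for the basal lobule
res = cs.bootstrap_intercell_test(dataset, "a1", n_boot=999, seed=1)
print(f"role a1: observed mean PD {res.observed:.3f}, rank {res.rank}/999")
```

prints

```
           symmetric: 35.4%
            semicell: 46.2%
          left-right: 9.8%
 semicell*left-right: 8.6%
                                     source   df      ss    r2     f     p
                                 Individual   67  69.820 0.208 1.893 0.001
                   Inter-semicell asymmetry   68  89.105 0.266 3.093 0.001
                       Left-right asymmetry   68  14.766 0.044 0.358 1.000
                       Intra-lobe asymmetry   68  60.254 0.180 1.792 0.001
                      Transversal asymmetry   68  13.098 0.039 0.316 1.000
              Intra-lobe and Inter-semicell   68  56.868 0.169 1.664 0.001
                  Intra-lobe and Left-right   68  14.622 0.044 0.355 1.000
                 Intra-lobe and Transversal   68  13.267 0.040 0.320 1.000
[Total asymmetry nested within individuals]  476 261.978 0.781   NaN   NaN
                          Measurement error  544   3.735 0.011   NaN   NaN
                                      Total 1087 335.533 1.000   NaN   NaN
role a1: observed mean PD 0.717, rank 861/999
```

Reading the output: inter-semicell asymmetry is the dominant asymmetric
component of both the full-cell subspace shares (46.2%) and the lobule
ANOVA (R² = 0.266, significant at the 1/(999+1) permutation floor),
followed by asymmetry between adjacent lobules of a quadrant (18.0%);
left–right and transversal effects stay at pseudo-F < 1. The degrees of
freedom are forced by the design (67 for the individual effect, 68 per
nested effect, 476 pooled, 544 for the two-digitisation error stratum,
1087 total for 1088 lobule configurations). The bootstrap rank 861/999
says the basal lobules of opposite semicells are, in this simulated
population, not more similar than basal lobules of different cells.

A command-line interface mirrors the library
(`cellsym simulate | object-symmetry | matching-anova | posthoc |
integration | mantel | full`); `cellsym full --n-cells 68 --seed 1 --out
run/` writes every analysis table as CSV plus a JSON run manifest.

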