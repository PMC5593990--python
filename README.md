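# macroqg

Comparative quantitative genetics on phylogenies: multivariate tests of
genetic drift versus natural selection, and reconstruction of net
directional selection gradients along every branch of a tree.

`macroqg` is aimed at evolutionary morphologists who have specimen-level
measurements (e.g. dozens of linear cranial distances across thousands of
museum specimens), a dated phylogeny, and an ecological character such as
diet, and who want to ask: *could the observed species divergence have been
produced by drift alone, and if not, how strong was selection and where on
the tree did it act?*

## The model

Under multivariate genetic drift, the between-species covariance of mean
phenotypes is proportional to the (additive-genetic) within-group
covariance:

```
B = G (t / Ne)
```

with the pooled within-group phenotypic matrix **W** standing in for **G**
under the usual proportionality assumption. Two complementary per-node
tests probe this proportionality:

* **Regression test** — project species means on the principal components
  of **W** and regress log between-group variances on log eigenvalues:
  `ln(B_i) = ln(t/Ne) + b ln(W_i)`. Drift predicts slope `b = 1`; a 95% CI
  excluding 1 rejects drift. Between-group variances are computed from
  phylogenetic independent contrasts (PIC), so phylogenetic
  pseudo-replication is removed.
* **Correlation test** — under drift, scores on distinct (orthogonal) PCs
  of **W** stay uncorrelated; under diversifying selection `B = G C G`,
  where **C** is the covariance of selection gradients, so correlated PC
  scores (tested on PIC, Bonferroni-controlled) indicate co-selection.

Where drift is rejected, the strength of selection on each branch follows
from Lande's multivariate equation,

```
beta = W^-1 * dz
```

with `dz` the change in reconstructed ancestral means along the branch
(linear parsimony by default, ML-Brownian for comparison) and **W** the
pooled matrix of the parent node, eigenvalue-extended before inversion so
trailing noise eigenvalues do not dominate `beta`. The reported magnitude is
the Euclidean norm of the mean-standardized gradient — dimensionless and
comparable across branches. Diet categories are fitted with Mk models
(ER/SYM/ARD, AIC-compared) so selection peaks can be read against dietary
transitions.

Because no suitable empirical dataset ships with the package, a first-class
synthetic-data generator (`macroqg.simulate`) produces trees, trait
evolution under drift / selection-pulse / co-selection regimes,
specimen-level samples with sex and locality effects plus duplicate
digitization, and Mk-evolving diet states; every stage of the pipeline is
calibrated against it.

## Worked example

```python
import numpy as np
from macroqg import (SimConfig, Pulse, CovMatrix, make_within_cov,
                     simulate_tree, simulate_means, project_scores,
                     regression_test, reconstruct_parsimony,
                     branch_selection_gradients, selection_profile)

# a 30-species radiation with one strong selection pulse on a random branch
cfg = SimConfig(seed=4, n_tips=30, p=10,
                pulses=(Pulse(branch="random", direction="pc1", intensity=8.0),))
tree = simulate_tree(cfg)
means = simulate_means(tree, cfg)
w = CovMatrix(make_within_cov(10), role="W")

# drift test at the root
proj = project_scores(means.tip_means(tree), w)
res = regression_test(tree, tree.root, proj)
print(f"slope b = {res.slope:.3f}  95% CI [{res.ci_low:.3f}, {res.ci_high:.3f}]"
      f"  reject drift: {res.reject_regression}")

# selection magnitudes along every branch
states = reconstruct_parsimony(tree, means.tip_means(tree))
grads = branch_selection_gradients(tree, states,
                                   {n.label: w for n in tree.postorder()})
profile = selection_profile(tree, grads).sort_values("magnitude")
print(profile.tail(3).to_string(index=False))
print("true pulsed branch:", means.pulse_branches[0][:2])
```

Output:

```
slope b = 1.279  95% CI [0.808, 1.751]  reject drift: False
parent child   length  midpoint_time  magnitude
    34    35 4.392281      23.464509  22.460843
    55    56 7.913339      21.245128  25.420379
    40    41 0.306168      23.048318  79.507706
true pulsed branch: ('40', '41')
```

The pulsed branch (40 → 41) carries a mean-standardized selection magnitude
about three times the largest background value, and the root-level
regression slope stays statistically compatible with 1 (a single pulsed
internal branch barely moves the clade-wide slope; the branch-level profile
is the tool that localizes selection).

A command-line interface mirrors the library:

```sh
macroqg simulate --outdir data --seed 1
macroqg all --tree-path data/tree.nwk --specimen-path data/specimens.csv \
            --diet-path data/diet.csv --outdir results
```

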