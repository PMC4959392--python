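# pavd — interaction-resolution pathway activity and sample distances

`pavd` quantifies the activity of a biological pathway in a **single
expression sample** not as one number, but as a probability distribution
over candidate network structures: the pathway's *normal* genetic network
(all known interactions functioning) plus one *disturbed* variant per
interaction, in which that interaction is silenced.  Comparing these
distributions between samples gives a true metric on samples — the
**pathway activity vector distance (PAVd)** — which drives downstream
subtype discovery: hierarchical clustering of a patient cohort,
annotation enrichment of the resulting groups, and ranking of the pathways
whose activity patterns distinguish two groups.

The intended users are computational biologists clustering cancer (or
other disease) expression cohorts who want cluster *explanations* at the
resolution of individual genetic interactions ("this group behaves as if
the SIRPG–CD47 interaction were silenced") rather than gene-level signatures.

## The model

Each pathway `PA_i` is a discrete random variable whose possible values are
candidate Bayesian-network structures `g_1 … g_N` over the pathway's genes
(binary expressed/not-expressed nodes): `g_1` is the normal network with
all `E` catalog interactions, and each of the `E` variants removes exactly
one edge, so `N = E + 1`.  Structures are scored on the binarized cohort
`D` with the BDeu marginal likelihood (Bayesian Dirichlet equivalent
uniform; equivalent sample size `ess`, default 1).  A single sample scored
alone is uninformative under the uniform prior, so the per-sample structure
likelihood is a leave-one-out ratio

    P(g_k | s_j) = BDeu(g_k | D) / BDeu(g_k | D − {s_j})

which equals the posterior-predictive probability of sample `s_j` under
structure `g_k` given the rest of the cohort.  Normalizing
`[L_1 … L_N]` over the candidates yields the **pathway activity
distribution** `Pr(PA_i, s_j)`; collecting it over all `A` pathways yields
the sample's **pathway activity vector** `PAV(s_j, PA)` and, over `S`
samples, the `A × S` activity matrix `R`.

Samples are compared with

    PAVd(s_l, s_m) = Σ_{i=1..A} √( JS( Pr(PA_i|s_l) ‖ Pr(PA_i|s_m) ) )

where `JS` is the Jensen–Shannon divergence (base 2).  Because `√JS` is a
metric on probability distributions, `PAVd` is a metric on samples:
non-negative, symmetric, zero iff equal, triangle inequality.  The cohort
is then grouped by complete-linkage hierarchical clustering of the PAVd
matrix, groups are characterized by one-sided hypergeometric enrichment of
sample annotations (e.g. tumor stage), and pathways are ranked by the
`√JS` between two groups' average activity distributions.

## Worked example

A cohort of 220 samples is simulated from a two-gene adhesion pathway with
a single interaction CD47→SIRPG: 180 samples with the interaction intact
(child copies parent with probability 0.95), 40 with it silenced.

```python
import numpy as np
from pavd import (PathwayNetwork, SyntheticCohortSpec, sample_cohort,
                  build_families, compute_activity_matrix, distance_matrix,
                  group_average_distribution)

pathway = PathwayNetwork("REG_CELL_CELL_ADHESION", ("CD47", "SIRPG"),
                         (("CD47", "SIRPG"),))
spec = SyntheticCohortSpec(
    pathways=[pathway],
    group_mechanisms={"intact": {},
                      "disturbed": {"REG_CELL_CELL_ADHESION": ("CD47", "SIRPG")}},
    group_sizes={"intact": 180, "disturbed": 40},
    beta=0.95, seed=7,
)
data, truth, gene_sets, catalog = sample_cohort(spec)
families = build_families(gene_sets, catalog, data)
R = compute_activity_matrix(families, data)
for name in ("intact", "disturbed"):
    group = [s for s in data.sample_ids if truth[s] == name]
    avg = group_average_distribution(R, "REG_CELL_CELL_ADHESION", group)
    print(name, dict(zip(avg.candidate_labels, np.round(avg.probs, 3))))
```

prints

```
intact {'Normal': 0.619, 'CD47->SIRPG': 0.381}
disturbed {'Normal': 0.451, 'CD47->SIRPG': 0.549}
```

The intact group's average activity distribution favors the normal network
(0.619), while the disturbed group shifts its mass to the variant with the
CD47→SIRPG interaction silenced (0.549) — the method recovers *which*
interaction is disturbed, not merely that the pathway differs.  On the same
cohort the mean PAVd between groups (0.180) exceeds the mean within the
intact group (0.053).

## Command line

Every stage is also a CLI subcommand operating on plain-text files
(GMT gene sets, SIF interactions, TSV matrices):

```sh
pavd discretize --in expr.tsv --out binary.tsv --seed 0
pavd build    --gmt sets.gmt --sif interactions.sif --binary binary.tsv --out families.json
pavd score    --families families.json --binary binary.tsv --out activity.txt
pavd distance --activity activity.txt --out distances.tsv
pavd cluster  --distances distances.tsv --k 2 --out clusters.tsv --dendrogram tree.nwk
pavd enrich   --clusters clusters.tsv --annotations stages.tsv --out enrichment.tsv
pavd rank     --activity activity.txt --clusters clusters.tsv --out ranked.tsv
```

An sklearn-style estimator wraps the whole pipeline for programmatic use:
`PAVdClustering(gene_sets, interactions, n_clusters=2).fit_predict(binary)`.

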