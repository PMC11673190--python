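# retronet

Distance-based classification of retroelements from sequence similarity
networks, and insertion-age dating from long-terminal-repeat divergence.

## The problem

LTR retrotransposons and related reverse-transcribing viruses are
conventionally classified by phylogenies of their reverse-transcriptase (RT)
protein. An alternative, alignment-light view is the **sequence similarity
network (SSN)**: one node per RT protein, an edge between every pair whose
evolutionary distance *d* is small enough, weighted *w* = 1/*d*. Clusters of
the network — read off either as **modularity communities (MC)** or as
**connected components (CC)** — can then be compared against the
phylogenetic taxonomy with the **Rand index**, the fraction of sequence
pairs on which two partitions agree (plain form *R* ∈ [0, 1], or the
Hubert–Arabie chance-corrected *adjusted* form).

Separately, because the two LTRs flanking a retroelement are identical at
the moment of insertion and diverge afterwards, the **Kimura two-parameter
(K2P)** distance between the 5ʹ- and 3ʹ-LTR of each element,

d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),

with *P* and *Q* the transition and transversion mismatch proportions,
dates each insertion: a population with many near-zero LTR divergences is
still actively proliferating.

`retronet` implements both analyses end to end — distances (uncorrected-*p*,
Poisson-corrected, K2P), SSN construction with a weight threshold τ
(default 0.666), MC/CC clustering, Rand-index scoring, a neighbor-joining
taxonomy baseline, an LTR seed-and-extend detector with divergence
profiling, and a synthetic retroelement generator with recorded ground
truth that makes every stage testable.

## Worked example

Simulate five RT superfamilies (16 members each, within-family divergence
0.05 substitutions/site), then classify:

```bash
retronet simulate rt --groups 5 --size 16 --seed 7 --outdir sim
retronet classify --alignment sim/rt_proteins.fasta \
                  --taxonomy sim/taxonomy.tsv --seed 7 --outdir out
cat out/cluster_report.tsv
```

```
method  n_clusters  modularity  rand_unadjusted  rand_adjusted
MC      5           0.799497    1.0              1.0
CC      5                       1.0              1.0
tree-cut 5                      1.0              1.0
```

Both clustering schemes recover the five simulated families exactly
(adjusted Rand 1.0 against the ground-truth taxonomy); the MC partition has
modularity 0.80 on the thresholded network. `out/` also contains the PHYLIP
distance matrix, the edge list, per-method partition tables, the NJ tree in
newick, and a manifest of SHA-256 checksums — reruns with the same seed are
byte-identical.

LTR dynamics on simulated elements:

```bash
retronet simulate elements --count 60 --seed 3 --outdir sime
retronet dynamics --elements sime/elements.fasta --outdir outd
cat outd/activity.json
```

```json
{"n": 60, "n_saturated": 0, "mean": 0.0288, "median": 0.0092,
 "recent_cutoff": 0.01, "recent_fraction": 0.567, "call": "active", ...}
```

All 60 LTR pairs are detected; 57% have K2P divergence below 0.01, so the
population is called actively proliferating.

The clustering step is also available as a scikit-learn estimator:

```python
from retronet import SSNClustering
est = SSNClustering(tau=0.666, method="mc", random_state=0).fit(D)  # D: square distances
est.labels_, est.modularity_, est.n_clusters_
```

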