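# otuclust

Greedy, radius-bounded clustering of highly similar DNA sequences —
dereplicating amplicon read sets (for example 16S rRNA surveys) into
OTUs at a user-chosen similarity threshold, with mathematically explicit
guarantees about what each cluster contains.

## Who this is for

Microbiome and metagenomics workflows that need to collapse hundreds of
thousands of near-duplicate reads into clusters at high stringency
(s ≥ 0.9), where the *meaning* of a cluster matters: every member is
provably within the threshold of its representative, and no two
representatives are within the threshold of each other. The package is a
library plus a small command-line tool.

## The model

The distance between two reads is the unit-cost edit distance of a
semi-global alignment: mismatches and gaps cost 1, matches 0, and gaps
at the ends of the *shorter* sequence can be free. By default alignments
are anchored at the 5' end and free at the 3' end, matching amplicon
reads that start at a common primer and differ in how far they extend;
global and fully-free policies are available. Similarity between reads
of cost *c* with shorter length *L* is

    s = 1 − c / L,

so a threshold *s* grants a read of length *L* an integer radius
⌊(1 − s)·L⌋ around its representative.

Clustering is greedy: the longest unclustered read seeds a cluster,
*every* unclustered read within its radius is recruited (the search is
exact, not heuristic), and the loop repeats. The output is therefore

1. **valid** — each member within its radius of the representative,
2. **exact** — representatives pairwise farther apart than the threshold,
3. optionally **well separated** — representatives pairwise farther than
   *twice* the radius (reads that block this are emitted as labeled
   singleton leftovers).

Three mechanisms keep the exact search fast: candidates are sorted
lexicographically so that a shared prefix is aligned once (an implicit
trie walked with a stack of dynamic-programming rows); each row only
computes cells that can still stay within the radius, and a dead prefix
skips every candidate that shares it; and a *completely sensitive*
k-mer screen discards whole sub-lists first — if
pos(spectrum_k(s) − spectrum_k(q)) > k·d then s cannot sit within d of
any substring of q, and a pair within d is never screened out. A lossy
`--approximate-filter` variant prunes harder and may split clusters.
Each cluster also yields a star multiple alignment (members reconciled
around the representative), in which no two rows differ column-wise by
more than twice the cluster radius.

## Worked example

```python
from otuclust import (CloudConfig, ClusterParams, generate_clouds,
                      greedy_cluster)

reads, truth = generate_clouds(CloudConfig(seed=7))   # 10 templates x 21 reads
clustering = greedy_cluster(reads, ClusterParams(similarity=0.99))
print(len(reads), len(clustering))
```

Running `python examples/01_cluster_reads.py` (the same computation plus
the truth comparison) prints:

```
reads: 210
clusters found: 10 (planted: 10)
partition matches planted truth: True
first cluster: representative C000, 21 members
```

210 synthetic reads (10 random ~200–260 bp templates, each with 20 noisy
copies at 0.5% per-base error) collapse to exactly the 10 planted
clusters at 99% similarity, and the membership partition equals the
generator's ground truth. `examples/02_threshold_search.py` shows the
exact radius search and how much work the filter and prefix sharing
save; `examples/03_star_msa.py` prints a per-cluster star alignment and
its worst pairwise column distance.

The same run from the shell:

```
otuclust-sim --n-centers 10 --cloud-size 20 --seed 7 -o reads.fasta --truth truth.tsv
otuclust reads.fasta -s 0.99 -k 3 > reads.cluster
```

`reads.cluster` holds one cluster per line: tab-separated read ids,
representative first. `--well-separated`, `--approximate-filter`,
`--global` / `--free-both-ends`, and `--msa-dir DIR` (one aligned FASTA
per cluster) select the variants.

## Layout

```
src/otuclust/
  seqio.py       FASTA in/out, cluster file, canonical orderings
  pairalign.py   banded threshold-limited edit distance + traceback
  triesearch.py  exact radius search over the implicit trie
  kmerfilter.py  k-mer spectra, sensitivity screen, filter tree
  clusterer.py   greedy clustering, well-separated variant
  starmsa.py     star multiple alignments
  simulate.py    synthetic center+cloud generator with ground truth
  cli.py         otuclust / otuclust-sim entry points
```
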