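# clonetrace

Lineage tracing of tumor cell clones through transcribed lentiviral
barcodes. Cells are labelled once, at low multiplicity of infection, with a
library of semi-random 265-nt barcodes expressed in the 3′ UTR of a marker
transcript; every descendant cell then reports its clonal identity in
ordinary RNA sequencing reads. `clonetrace` implements the computational
side of such an experiment for people studying clonal selection under
therapy — in particular drug-tolerant persister (DTP) biology, where a
minority of lineages survives treatment, persists through minimal residual
disease, and regrows the tumor.

The package covers five stages, each usable on its own:

- **Library design** (`clonetrace.libdesign`): IUPAC pattern spaces,
  uniform barcode sampling, and the two design constraints that make clonal
  interpretation valid — the multi-integration fraction at a given MOI,
  P(K ≥ 2 | K ≥ 1) under K ~ Poisson(m), and the expected number of
  barcode collisions among n cells drawing from a library of size L.
- **Tag extraction** (`clonetrace.extract`): scans each read (both strands)
  for the fixed 33-nt vector anchor `CAGATCTTAGCCACTTTTTAAAAGAAAAGGGGG`
  allowing up to 2 mismatches, cuts out the 15-nt clone tag abutting the
  anchor, collapses sequencing-error tags by directional adjacency
  (Hamming ≤ 1, count(a) ≥ 2·count(b) − 1), tabulates per-cell tag support,
  calls one clone per cell, and reconstructs full-length 265-nt barcodes by
  anchored majority vote.
- **Clone dynamics** (`clonetrace.dynamics`): clone proportions over the
  sampling grid (days 0, 21, 57, 91), normalization to tumor volume and
  transcriptional activity, Shannon diversity H = −Σ pᵢ ln pᵢ with
  Hutcheson's two-sample t-test, and fate classification by competing
  nonlinear least-squares fits of A·e^(−kt) (Sensitive) versus A·e^(+kt)
  (Persister) with an RSS < 0.1 rule on the max-scaled trajectory;
  consistently low-abundance or ambiguous clones are Multi-fate.
- **CNV burden** (`clonetrace.cnv`): per-cell CNV score — the fraction of
  genes whose inferred copy-number value lies strictly outside [0.9, 1.1] —
  and per-group Spearman correlation between CNV and expression.
- **Spatial statistics** (`clonetrace.spatial`): patch-based co-localization
  of two imaging channels (4×4 … 10×10 grids, presence binarization, Fisher's
  exact test) and global Moran's I with a permutation null.

A sixth module, `clonetrace.synth`, generates synthetic reads, trajectories,
CNV matrices and point patterns with ground truth, so the whole pipeline is
testable end to end without any external data.

## Worked example

Simulate 300 clones (100 per fate) over days 0/21/57/91 with 5% log-normal
observation noise, classify their fates, and compare diversity between the
pre-treatment and endpoint samples:

```python
from clonetrace import (DynamicsSimConfig, simulate_clone_dynamics,
                        classify_fates_table, shannon_index, hutcheson_test)

sim = simulate_clone_dynamics(DynamicsSimConfig(seed=1))
fates = classify_fates_table(sim.proportions, sim.contexts)
print(fates["fate"].value_counts().to_string())

counts0 = (sim.proportions[0.0] * 1_000_000).round()
counts91 = (sim.proportions[91.0] * 1_000_000).round()
print(f"Shannon H day 0: {shannon_index(counts0).H:.3f}  "
      f"day 91: {shannon_index(counts91).H:.3f}")
res = hutcheson_test(counts0, counts91)
print(f"Hutcheson t = {res.t:.1f}, p = {res.p:.3g}")
```

prints

```
fate
Sensitive    100
Persister    100
MultiFate    100
Shannon H day 0: 4.721  day 91: 3.853
Hutcheson t = 686.3, p = 0
```

All 300 simulated clones are recovered with their true fate label; clonal
diversity drops from 4.72 to 3.85 nats as sensitive lineages are eliminated
and a few fast-growing persisters take over, and Hutcheson's test calls that
drop significant at these (deep-sequencing-scale) counts. The fraction of
initial clones still detected at the endpoint is a single call:
`survival_fraction(tags_day0, tags_day91)`, e.g. 1,127 initial clone tags of
which 261 survive gives 23%.

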