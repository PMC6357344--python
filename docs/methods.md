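# Methods

## Model and assumptions

The sample is a mixture of `I` tumor sub-clones `S_0..S_{I-1}` in
proportions `r_i` (Σr = 1) related by a **linear** phylogeny: `S_0` is the
founding clone and each `S_{i+1}` derives from `S_i` by acquiring new
somatic SNVs.  Three constraints follow and are enforced everywhere:

- **One hit** — a locus mutates at most once during the evolution and
  never reverts.
- **Inheritance** — a mutation present on haplotype `k` of clone `i` is
  present on haplotype `k` of every clone `j > i`.
- **Heterozygosity at origination** — a new mutation lands on exactly one
  of the two haplotypes, so no site is homozygous-mutant in the clone
  where it arises.  (Sites observed with VAF ≈ 1 would be homozygous
  founding mutations; they carry no linkage information and are flagged
  and excluded from phasing.)

Consequently a site arising in clone `s` has expected allele frequency
`V_p = ½·Σ_{i≥s} r_i` in the pooled reads, which is what makes the clonal
structure identifiable from VAFs alone, and the `2I` clonal haplotypes
are fully determined by (a) one haplotype of the youngest clone and (b)
the per-site origin labels `sub(j)` — the basis of the final
reconstruction step.

Copy-number variation, structural variation, allelic imbalance, indels
and branching phylogenies are out of scope; the error model is a uniform
per-base substitution rate `ε`.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `epsilon` (ε) | 0.01 | per-base error probability used in the edge weights; matches the simulator's default substitution rate. |
| `Cov` | 2 | minimum pair support for a phasing edge. In the stripped graph the threshold applies to the depth that **survives** stripping, since that is the pair's coverage in the separated data. |
| `delta` (δ) | 0.1 | strict threshold on the stripped weight; an edge needs `|W′| > δ`. |
| adaptive floors | Cov 1, δ 0.025 | when sites remain unattached, both thresholds are halved (at most twice, never below the floors) and the extension retried — trading precision for a lower false-negative rate. |
| `max_clusters` | 6 | BIC model-selection range for the VAF mixture. |
| `min_separation` | 0.05 | clusters whose means are closer than this are merged before labelling; ~the binomial VAF standard deviation at 100× depth, so BIC cannot split one clone's scatter into two. Ignored when the clone count is fixed by the caller. |
| `hom_threshold` | 0.9 | VAF above which a site is flagged homozygous-founding and excluded from phasing. |
| germline / somatic rate | 0.001 / 0.01 per bp | simulator defaults: the study's stated mutation rates. |
| proportions | 3:5:2 | simulator default clone mixture. |
| libraries | 1000 bp @100×, 1500/2000 bp @50×, 250 bp reads | the base library (first) is used for VAF estimation; the longer-insert libraries bridge distant site pairs. Insert SD defaults to 5% of the mean. |

## Numerical and algorithmic choices

- **Weight algebra.**  `f_A + f_B = 1` identically (the two coefficients
  sum to 1 and `N^A + N^B = |F|`), so `W ∈ [−1, 1]`; `W = 0` exactly at
  `ε = 0.5` or balanced counts.  The δ comparison uses a `1e-12`
  tolerance so a weight computed as exactly δ is excluded regardless of
  float rounding.
- **Greedy order and ties.**  Short-chain construction processes VPEs
  longest-first (ties: higher multiplicity, then lexicographic states);
  the spanning forest seeds each component at the vertex with the largest
  summed incident `|W|` and breaks equal-weight ties by larger support,
  then smaller site index.  All orderings are total, so output is
  byte-reproducible for a fixed seed.
- **Seed phase.**  Absolute phase is unobservable; each component's seed
  is anchored to state B and every reported quantity is invariant to a
  global flip per fragment.
- **Stripping.**  For a pair whose origin clones are `a ≤ m`, clones
  below `a` contribute all their reads to the cis class (they read (A,A)
  on both haplotypes) and clones in `[a, m)` split evenly between the
  classes, so the default mode subtracts
  `P^A = |F|(Σ_{i<a} r_i + ½Σ_{a≤i<m} r_i)` and `P^B = |F|·½Σ_{a≤i<m} r_i`,
  clamping at zero.  An alternative `"as-printed"` mode applies the
  level-`k` formulas whose two sums total `|F|` under normalized
  proportions (annihilating the counts after clamping); it is retained
  for fidelity experiments and is not the default.
- **Stripped-edge reliability.**  Clamping saturates `|W′|` at 1, so the
  weight alone cannot rank stripped edges; edges are therefore ranked by
  surviving informative depth on ties, and the `Cov` threshold applies to
  that surviving depth.  Both choices follow from treating the stripped
  counts as the pair's coverage in the separated data.
- **Trees are never merged** during the extension: an edge joining two
  already-phased trees is skipped.  Fragment boundaries therefore reflect
  the founding-clone components, and each fragment's phase stays
  internally consistent.
- **Fragments require ≥ 2 sites.**  An isolated vertex carries no linkage
  information, so it counts as unplaced in the recognition rate.
- **Degenerate inputs.**  Zero-depth sites get undefined VAF and are
  excluded; a single-valued VAF vector yields one clone; an empty graph
  yields singleton trees and no fragments; pairs with no support raise
  rather than producing a 0/0 weight.

## The accuracy metric

"Accuracy" is the fraction of *placed* sites whose inferred origin clone
equals the truth **and** whose haplotype side matches, after choosing per
fragment the global flip that maximizes matches.  The flip freedom is
forced by physics (absolute phase is unobservable); everything else is
strict, so a site clustered into the wrong clone counts as wrong even
when its phase is right.

## What the simulator does and does not emulate

It emulates: Poisson-distributed SNV counts at the stated rates, the
linear-inheritance haplotype structure, clone sampling in proportion
`r_i`, per-library insert-size normality (truncated at twice the read
length), uniform substitution errors, and exact fold-coverage targets.
The reference is uniform random DNA and reads are emitted pre-aligned at
their true coordinates.

It does **not** emulate: reference gaps and repeats (hence no mapping
ambiguity), alignment or duplicate artifacts, indels, quality-score
structure, GC bias, or normal-cell contamination.  Passing tests
therefore demonstrate the algorithm's behavior under its own model
assumptions, not robustness to real-data artifacts — in particular, real
alignments would add switch errors near repeats that no test here can
reveal.

One measurable consequence: at the study's mutation rates the mean site
spacing (~91 bp) is far below the 250 bp read length, so even the base
library alone links nearly every site and the recognition rate stays
near 100% under any library subset.  Dropping the long-insert libraries
shows up instead as more, shorter fragments (tens of fragments with a
longest span of ~30 kb versus ~2 fragments spanning ~200 kb with three
libraries).

## Known limitations

- Phase errors cascade: each site's state is fixed by the single greedy
  attachment edge, so one wrong-sign edge flips its entire downstream
  subtree.  Among correctly clustered sites, phase accuracy plateaus
  around 0.90–0.93 even with noise-free reads, and increasing coverage
  does not remove the effect (it merges trees, letting cascades reach
  further).  Global refinement (MEC-style optimization) is deliberately
  out of scope.
- VAF clustering errors (~5% of sites at 100× with the default mixture)
  propagate: a mislabelled site is stripped with the wrong level and is
  scored against the wrong clone.
- Proportions are estimated once from cluster means and never
  re-estimated during stripping.
- The problem sizes used by the validation scripts (200 kb reference,
  5 + 12 + 3 replicates) were chosen so a full replicate takes seconds;
  the per-base parameters are the study conditions and are not scaled.
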