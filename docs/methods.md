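# Methods

## Model and procedure

`pathcover` treats a pathway purely as a set of gene symbols and a pathway
collection as a family of such sets over a universe *U* = ∪ s<sub>i</sub>.
Redundancy reduction is cast as (approximate) set cover: select pathways
greedily until the covered genes reach a target, valuing candidates by one
of three rules.

* **standard**: v<sub>i</sub> = |s<sub>i</sub> ∩ R|, the classic greedy set
  cover. It inherits the H(max |s<sub>i</sub>|) approximation guarantee of
  greedy set cover relative to the optimal cover size (asserted in the test
  suite against brute-force optima on small instances).
* **proportional**: v<sub>i</sub> = |s<sub>i</sub> ∩ R|/|s<sub>i</sub>| +
  1/(||s<sub>i</sub>| − m̄|·k), where m̄ is the mean pathway size of the
  *input* collection and k = 10 000. The first term is scale-free in [0,1];
  the second is a pure tie-break (≤ 1/(0.5k) = 2·10⁻⁵ at the default k, so
  it can never override a first-term gap ≥ 3·10⁻⁴) pulling the choice
  toward mean-sized pathways, which is what controls size dispersion.
* **hitting**: genes are valued by rarity, v<sub>j</sub> = 1/f<sub>j</sub>
  with f<sub>j</sub> the number of pathways containing gene *j*, and
  v<sub>i</sub> = (Σ<sub>j∈s<sub>i</sub>∩R</sub> v<sub>j</sub>)/|s<sub>i</sub>|.
  A pathway scores 1 only when all its genes are uncovered and unique to
  it. Rewarding rare genes front-loads the forced selections and empirically
  leaves the lowest residual overlap.

m̄ and f<sub>j</sub> are computed once over the full input collection and
frozen; they describe the data set, not the shrinking candidate pool. Only
*candidates* — pathways with at least one uncovered gene — are ever scored,
for all three rules, so every selection makes progress (and the
proportional tie-break cannot resurrect an exhausted pathway).

**Gene coverage (GC).** The loop stops once |C| ≥ ceil(GC·|U|), GC ∈ (0,1].
The last steps of a full cover are the most redundancy-expensive (few
candidates remain for the last few genes), so GC = 0.95 or 0.99 buys a
disproportionately cleaner cover. The ceiling is computed as
`ceil(GC·|U| − 1e-9)` to keep binary representations of fractions like 0.95
from bumping the integer target.

**Enrichment set cover.** Enriched pathways arrive scored; their value is
(1 − p<sub>i</sub>)·b with b = 1 iff the pathway still holds an uncovered
DE gene. Repeated argmax is equivalent to one walk down the
(p-value, id)-sorted list keeping each pathway iff b = 1 when reached; the
equivalence is asserted against a literal argmax implementation. All set
logic is restricted to s<sub>i</sub> ∩ DE — non-DE members of an enriched
pathway play no role. No significance threshold is applied inside the
module; callers pre-filter (conventionally adjusted p < 0.05). The
coverage-fraction denominator is the DE genes mappable to ≥ 1 enriched
pathway — DE genes outside every enriched pathway cannot be covered by any
selection and would only add a constant to both sides of any comparison.

## Numerical choices

* Scores are doubles; two scores tie when |a − b| ≤ 10⁻¹²·max(1, |a|, |b|).
  Hitting sums use `math.fsum`, which is correctly rounded and therefore
  independent of summation order, so the incremental engine and any
  from-scratch rescoring agree bitwise on equal gene multisets.
* Deterministic tie policy (default): max score, then max newly-covered
  count, then lexicographically smallest pathway id. The published
  algorithms leave ties unspecified; this default is an artifact decision
  chosen for reproducibility. `tie_policy="random"` (seed mandatory)
  samples uniformly among score-tied candidates, reproducing the
  observation that early random choices can change proportional covers.
* The engine keeps a per-pathway residual gene set updated through an
  inverted gene→pathway index; correctness is guarded by an oracle test
  against a naive full-rescan reference over randomized instances.
* An uncoverable residue (possible only when the caller restricts the
  universe) terminates the run with a `complete=False` flag and a warning
  string rather than an exception.
* Reduction percentages are returned unrounded; reports round to whole
  percent. Normalisation is by (original − 1): a fully discrete collection
  has overlap score exactly 1, so 1 is the floor of the scale — this is the
  only normalisation consistent with reporting a disjoint result as 100%.
* Overlap score of a cover result counts only genes covered by it; with
  GC < 1 the uncovered genes are excluded from the mean (a membership count
  of 0 would push scores below the discrete floor of 1).
* Pathway-size SD is the sample SD (n − 1); immaterial at realistic scale.
* Jaccard histogram: 20 right-closed bins on [0,1] by default; exactly-zero
  pairs are counted in the first bin and additionally reported separately,
  since disjoint pairs dominate sparse collections.

## The synthetic generator

No public snapshot of an aggregated collection ships with the package;
benchmarks are generated. The generator emulates the three structural
features the algorithms feed on:

1. **Latent functional modules** — disjoint blocks of 4–30 synthetic genes
   (`G000001`…; no biological identity claimed). Default 120 modules,
   ~2 000 genes.
2. **Module-built pathways** — with probability `overlap_intensity` (0.95)
   a pathway samples modules and takes a random 30–100% portion of each
   until a log-normal size target is met (mu = 3.0, sigma = 1.1: median
   ≈ 20 genes, heavy right tail into the hundreds, echoing real aggregated
   resources). Partial capture models arbitrary pathway boundaries; module
   reuse yields the long-tailed gene-frequency distribution. Heavy-tail
   size draws exceeding the module pool are clamped to it.
   The remaining pathways are built from fresh pathway-private genes,
   mimicking content (e.g. small-molecule pathways) nearly disjoint from
   the rest of an aggregate.
3. **Subset redundancy** — with probability `subset_rate` (0.15) a pathway
   is a strict random subset of an earlier one.

Source labels are sampled with weights shaped like a real aggregate
(Reactome-dominated). The default `cpdb_like` recipe (600 pathways) yields
overlap scores of ~5.5–7 — a scaled-down analogue of the ~12 observed in
real aggregates — and generation is a pure function of the recipe: same
recipe, byte-identical GMT.

An enrichment study designates modules as perturbed: DE genes are drawn
from those modules plus a uniform noise fraction (default 150 DE genes,
15% noise), and every pathway gets a one-sided hypergeometric
over-representation p-value for its DE overlap given (|U|, |DE|,
|s<sub>i</sub>|). The hypergeometric tail is the canonical
over-representation model; tool-specific refinements such as
transcript-length bias correction are deliberately not emulated — the
downstream cover only needs a realistic joint structure of p-values and
gene sets.

**What passing tests show — and don't.** The generator reproduces
heterogeneous sizes, frequency tails, partial overlap and subset nesting,
so algorithmic claims (oracle equivalence, approximation bounds, coverage
contracts, the qualitative ordering of the three algorithms) transfer to
real collections, which satisfy the same set-theoretic premises. It does
not reproduce real identifier namespaces, curation biases, inter-database
correlation of pathway boundaries, or enrichment-tool-specific p-value
artifacts, so exact magnitudes measured here (e.g. a 78% reduction at full
coverage) are properties of the synthetic conditions, not predictions for
any particular database snapshot.

## Benchmark scale and test design

The behavioral-signature comparison runs on ten seeded instances of the
600-pathway benchmark (seeds 0–9) and asserts each signature — standard
needs fewest pathways, proportional has the tightest size SD, hitting the
lowest residual overlap, and GC = 0.95 never increases residual overlap —
on a strict majority of instances. Signatures of stochastic algorithms on
stochastic data are majority claims: the proportional-vs-hitting size-SD
margin, in particular, is a few percent, and the winner can flip on an
individual draw. Oracle-equivalence and optimality-bound suites use 100 and
50 randomized instances of up to 50 pathways / 200 genes and 12 pathways
respectively, sizes at which the naive rescan and exhaustive enumeration
references stay fast.

## Known limitations

* Greedy covers carry no optimality guarantee beyond the harmonic bound of
  the standard rule; proportional and hitting are heuristics with no bound.
* GMT parsing recovers pathway provenance only when the description field
  names a known source database; otherwise pathways are labelled "unknown".
* Gene identifiers are matched as exact case-sensitive strings (an
  `uppercase=True` parse flag normalises case); cross-namespace mapping is
  out of scope.
* Enrichment p-values are consumed, never computed or corrected; inputs are
  assumed already adjusted for multiple testing.
* The pairwise Jaccard distribution is O(n²) in pathway count — fine for
  collections of thousands, not for hundreds of thousands.
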