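# Methods

## Network construction

The connection weight between two cortical parcels is the density of
connecting fibers: the count of fibers whose two endpoints fall in the
two (distinct) parcels, divided by the mean of the parcels' total
boundary-voxel volumes, `W_ij = C_ij / ((V_i + V_j)/2)`, in fibers per
mm³. "Mean volume of the two parcels" admits a second reading — the
mean volume *per voxel* — but that would make weights independent of
parcel size and defeat the density rationale, so the total-volume
reading is used. Fibers with both endpoints in one parcel carry no
inter-parcel information and are discarded (counted and reported).
Repeat scans are combined by the elementwise arithmetic mean of the
per-scan weight matrices.

Node merging to a coarser scale has two modes. With boundary-voxel
volumes supplied, fiber counts are recovered by inverting the density
formula, pooled across merge groups, group volumes summed, and the
formula re-applied — this commutes exactly with construction from
pre-merged endpoint records (property-tested). Without volumes, group
weights are summed; this is an approximation and is documented as such.
Edges internal to a merge group become self-connections and are
dropped. Merge tables must use the same pattern in both hemispheres;
asymmetry is a warning by default, an error on request.

## Thresholding and tie-breaking

A weighted network is binarised by retaining its `k` top-ranked
connections. Equal weights — overwhelmingly the exact zeros that
probabilistic tractography leaves between unconnected parcels — are
ranked uniformly at random. One complete tie-broken ranking is drawn
per (network, seed) and re-used for every `k`, so thresholded edge sets
are nested across densities; drawing fresh ranks per density would
break nestedness and add spurious variability between adjacent
densities. Each subject × pipeline gets a deterministic substream
derived from the master seed and stable label hashes, so results do not
depend on process state or subject ordering.

The density sweep is O(T) rather than O(T²): with nested rankings an
edge is present in both networks at density `k` iff the later of its
two rank positions is below `k`, so all intersection sizes follow from
one cumulative histogram of pairwise rank maxima.

## Significance versus chance

For two independent equal-density networks E[DC] = d = k/T (validated
by Monte-Carlo in the acceptance suite), so at each interior density
the per-subject DCs are tested against d with a one-sample two-tailed
Student t-test (sample sd, n−1 df). p-values are computed via the
log survival function and reported as −log₁₀ p; real peaks reach
p ≈ 10⁻⁵⁰, far beyond naive `1 − cdf` arithmetic. Conventions for
degenerate inputs, which the underlying test leaves undefined:

* zero sample variance at the null mean → t = 0, p = 1;
* zero sample variance off the null mean → the sentinel −log₁₀ p = 350,
  flagged `degenerate`. A sample sd below 1e−12 counts as zero
  (identical values can leave ~1e−17 residual sd through float
  accumulation, which would otherwise masquerade as t ≈ 10¹²);
* k = 0 is assigned DC = 1 by convention (two empty networks are
  identical) and, like k = T, is excluded from significance analysis —
  the chance DC is exactly 0 or 1 there and the null is degenerate.

The subject bootstrap resamples subjects with replacement (1000 times
by default) and recomputes the curve per resample; the bootstrap mean
and SE are stored next to the point estimate (the two are plotted
interchangeably in practice; both are emitted). Degenerate resamples
are excluded from the bootstrap moments — the sentinel is a flag, not a
number, and with 5 subjects the ~0.8% of all-identical resamples would
otherwise dominate every SE — and their fraction is reported. Note the
bootstrap mean of −log₁₀ p carries the usual resampling bias of a
nonlinear statistic; it stabilises as resamples grow but does not
converge to the point estimate.

Peak detection takes the global argmax of the point-estimate −log₁₀ p
over eligible densities, excluding the boundaries and any
degenerate-flagged density (where the sentinel would otherwise always
win). Ties break toward the sparser density — the more specific
consensus. No multiple-testing correction is applied across densities:
a single global maximum is selected, and this caveat is inherited by
any interpretation of the peak's p-value.

## Consensus network and graph metrics

At the peak density each subject's convergent edge set is the
intersection of the two pipelines' binary networks; prevalence of an
edge is the fraction of subjects whose convergent set contains it, and
the group consensus network keeps prevalence-1 edges. Binary metrics
follow Brain-Connectivity-Toolbox-compatible conventions, pinned here
because formulations diverge in degenerate cases:

* **PL** — mean shortest-path length over reachable ordered pairs;
  unreachable pairs are counted and reported, not averaged as
  infinities (consensus networks at density ~0.1 can be disconnected);
* **CC** — mean over nodes of 2·triangles/(deg·(deg−1)); nodes of
  degree < 2 contribute 0;
* **Geff** — mean inverse shortest-path length over ordered pairs with
  1/∞ = 0;
* **Leff** — mean over nodes of the global efficiency of the subgraph
  induced by the node's neighbours; < 2 neighbours contributes 0;
* **AS** — Pearson correlation of endpoint degrees with every
  undirected edge contributing both orientations; undefined (NaN, with
  a warning) for degree-regular graphs.

Implementations use BFS distance matrices (scipy.sparse.csgraph) and
are verified against independent brute-force oracles (triangle
enumeration, edge-list correlation, networkx efficiencies) to 1e−12 on
random graphs. Summary tables report mean ± sample sd across subjects
per pipeline, dropping undefined values and reporting their count.

## Synthetic cohort generator

The generator emulates, at matrix level, two probabilistic-tractography
pipelines applied to the same repeat-scan cohort. Per subject:

* a cohort-wide planted core adjacency, hemisphere-symmetric by
  construction (mirror orbits of node pairs under L/R exchange,
  homotopic pairs used to fix parity), with exactly
  `round(core_density · T)` edges;
* core pair log-weights ~ Normal(0, 0.25), shared by both pipelines —
  true anatomy seen by both, with deliberately modest spread so the
  ordering *within* the core is not reproducible between pipelines
  (rank agreement below the core density decays, as it should);
* spurious (non-core) log-weights ~ −2.5 + 0.8·(√(1−w)·shared +
  √w·own): each algorithm disperses fibers differently, so spurious
  weights reproduce across pipelines only partially. The
  pipeline-specific share w is drawn per subject from Beta(mean 0.5,
  sd 0.22) — cohorts genuinely differ in how much their spurious
  structure agrees — and is scaled down with the pipeline noise level
  so that zero pipeline noise yields identical pipelines;
* independent pipeline log-noise N(0, `pipeline_noise_sd`) on every
  pair. The default 0.35 was calibrated once by bisection against the
  Monte-Carlo Spearman estimate to give inter-pipeline rank correlation
  ≈ 0.7 on subject-mean networks, and frozen;
* scan log-noise N(0, 0.2) shared by both pipelines (a repeat scan is
  one acquisition fed to both reconstructions) and independent across
  scans;
* exact zeros on the weakest-observed non-core pairs of each pipeline
  — tractography zeros are the connections a pipeline failed to find,
  so the two zero sets overlap without coinciding (uniform random
  zeroing caps the attainable Spearman near 0.55, visibly below real
  pipeline pairs). The subject zero fraction is Beta(mean 0.4, sd
  0.12); per-subject sparsity heterogeneity is a documented feature of
  real cohorts and supplies the between-subject DC variance at high
  densities.

All draws come from keyed substreams of a single seed
(`SeedSequence(seed, spawn_key=…)`), so enlarging a cohort never
perturbs existing subjects and cohorts are bitwise reproducible.

A null variant (`generate_null_cohort`) shares nothing between
pipelines: no planted contrast, independent latents, independent scan
noise, all pairs zero-eligible. Under it the thresholded networks are
independent at every density and the significance test's type-I error
is close to nominal (measured ≈ 0.054 pooled over densities; the small
excess is the t-test's own small-sample behaviour on the discrete DC
values at low k).

What the generator does *not* emulate: image-space tractography,
distance-dependent weight decay, spatial autocorrelation of weights,
anatomically structured (rather than random) cores, and
subject-specific true networks beyond weight resampling. Passing tests
therefore demonstrate that the analysis machinery is correct and
well-calibrated under a plausible statistical model of paired
reconstructions — not that any particular empirical network is
anatomically valid.

## Problem sizes and defaults

Defaults mirror a repeat-scan cohort analysed at a common 34-node
scale: T = 561 pair densities swept in full (`k = 1…T−1`; a stride
option exists for large T with a warning that peak resolution
coarsens), 3 scans, 1000 bootstrap resamples. Simulation-based checks
use 10-subject cohorts, 100 cohorts for planted-density recovery
(≥ 90% of peaks within ±0.05 of the planted 0.196) and 200 null
cohorts for type-I calibration; the calibration check compares the
pooled rejection fraction with 0.05 using its Monte-Carlo 3-SE
clustered at cohort level, since densities within a cohort are strongly
dependent (nested thresholds, shared subjects).
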