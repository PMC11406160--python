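# Methods

## Model

`thermoweb` links three well-established empirical regularities into one
predictive chain and asks what that chain implies for the structure of a
consumer–resource interaction network under warming.

1. **Allometric trait scaling.** A biomechanical trait — here maximum bite
   force `F` (mN) — scales with body mass `m` (mg) as a power law,
   `F = a·m^x`. The exponent `x` reflects the geometry of the underlying
   mechanism: traits limited by linear dimensions scale with `x ≈ 1/3`, by
   cross-sectional area (muscle force) with `x ≈ 2/3`, by volume with
   `x ≈ 1`.
2. **Temperature–size response.** Ectotherm body size declines with
   developmental temperature. We model this as a multiplicative factor
   `α` per +1 °C applied to body *mass*, compounded geometrically over a
   temperature change `ΔT`: `m(ΔT) = m₀·α^ΔT`. Compounding (rather than a
   linear decrement) preserves positivity at any `ΔT` and reduces to the
   one-degree factor at `ΔT = 1`. Combining 1 and 2, the trait changes by
   `(α^ΔT)^x`; for a 10 % per-degree mass loss (`α = 0.9`) the per-degree
   trait penalty spans ≈3.45 % (`x = 1/3`) to 10 % (`x = 1`).
   If one instead reads `α` as acting on a *linear* body dimension, the
   mass factor is `α³`; the package applies `α` to mass, and a user holding
   length-based data should cube their factor before configuring the rule.
3. **Q10 thermal performance.** Muscle-driven rate performance rises with
   temperature with a Q10 of roughly two, `P(T) = P_ref·Q10^((T−T_ref)/10)`,
   until it plateaus. The plateau is modelled as a hard cap applied inside
   the exponent (`min(T, T_plateau)`), which keeps the curve continuous at
   the plateau. Both the exact geometric per-degree factor (`2^0.1 ≈ 1.0718`)
   and the common linearised reading (`(Q10−1)/10 = 10 %/°C`) are exposed,
   because both appear in the applied literature. The Q10 model is provided
   at the trait level; the network construction uses only the size-mediated
   pathway (bite force is a force capacity, which is far less
   temperature-sensitive than rate traits).

**Feasibility networks.** Given consumers with bite-force allometries and
resources with required cutting forces `F_cut` (mN), the bipartite
feasibility network at temperature `T` contains the edge (consumer,
resource) iff the consumer's size-adjusted bite force is ≥ `F_cut`. Exact
equality produces an edge (the `≥` convention is a deliberate tie-break;
the boundary set has measure zero under continuous traits). Edge weights
are the force surplus in mN, not interaction frequencies — the model
predicts *mechanical possibility*, not realised diet. Resource abundance,
when supplied, is carried through but never gates edge existence.

Because warming with `α < 1` and `x > 0` only shrinks bite forces, the
edge set at a hotter temperature is always a subset of the edge set at a
colder one. All monotonicity results downstream (non-increasing degree and
generality, the subset identity for turnover) are consequences of this
nestedness, and the temperature at which a given edge disappears has the
closed form `ΔT* = ln(F_cut/F_bite,0) / (x·ln α)`.

## Metrics

* **Degree** — number of resources feasible for a consumer. **Generality**
  — arithmetic mean consumer degree (default; a weighted variant using the
  exponential of the Shannon entropy of edge weights is available, but the
  unweighted mean is the reported index since surplus weights are a
  modelling by-product, not observed interaction frequencies).
  **Connectance** — realised fraction of possible links.
* **Robustness.** Resources are removed one at a time; a consumer goes
  secondarily extinct when its degree reaches zero (no energetic
  threshold). The surviving consumer fraction is recorded after every
  removal, the point (0, 1) is prepended, and `R` is the trapezoidal area
  under the curve of surviving fraction vs removal fraction, so `R ∈ [0, 1]`
  with closed forms `R = 0.5` for the 1×1 single-edge network and `R = 0.75`
  for one consumer linked to both of two resources. Strategies: uniform
  random order (curves averaged pointwise over replicates, seeded),
  most-connected-first, and toughest-resource-first (descending cutting
  force). For deterministic strategies ties are broken by node order, and
  the removal order is computed once from the initial network — valid here
  because secondary extinctions (consumers reaching degree zero) cannot
  change the relative degree of the remaining resources. Consumer-side
  removal is available behind a flag, with roles mirrored.
  Consumers isolated in the *initial* network count as extinct from the
  first measured step; the prepended (0, 1) start point is kept so curves
  from different networks remain comparable.
* **Link turnover** between layers — Jaccard dissimilarity of edge sets,
  defined as 0 when both layers are empty. For nested layers it reduces to
  `1 − |E_hot|/|E_cold|`, which tests cross-check against the generic
  formula.

## Hypothesis evaluation

The sweep evaluates three directional claims about warming:

* **H1** (guild generality declines): Spearman rank correlation of the
  generality series against temperature is negative. Spearman is used
  because the series are step-shaped; constant series yield an undefined
  correlation and count as *not supported*.
* **H2** (individual degrees decline): at least one consumer's degree
  series is non-constant and every non-constant series correlates
  negatively with temperature. The reported statistic is the fraction of
  consumers with declining degree.
* **H3** (degree change differs among consumers): the range of
  per-consumer total degree losses (first layer minus last) is > 0.
  Per-consumer losses are reported together with baseline bite forces so
  the dependence on initial condition is inspectable.

Verdicts are sign-based with the statistic attached; no p-values are
reported by default because, given the traits, the series are deterministic
— there is no sampling error for a test to quantify.

## Synthetic communities

The generator emulates the statistical shape of the data the analysis
needs, not any particular measured dataset:

| parameter | default | unit | rationale |
|---|---|---|---|
| `n_consumers` | 3 | — | a few replicate colonies of one species |
| `n_resources` | 100 | — | a local plant community |
| `consumer_mass_median` / `_sigma` | 10 / 0.3 | mg / log-sd | ant-worker scale, moderate colony variation |
| `allometry_prefactor` / `_exponent` | 10 / 2⁄3 | mN·mg^−x / — | muscle cross-section scaling; forces of tens of mN |
| `cutting_force_median` / `_sigma` | 40 / 0.6 | mN / log-sd | right-skewed leaf-toughness spread straddling the bite range |
| `alpha` | 0.98 | per °C | ≈2 % mass loss per °C, the realistic insect magnitude |
| grid | 20→30 °C, 0.5 °C | — | ecologically plausible warming envelope |

Both masses and cutting forces are log-normal (`median·exp(σZ)`), chosen
because the quantities are strictly positive and right-skewed; the
configured medians are distribution medians exactly. Defaults were chosen
once so that the baseline network has intermediate connectance (neither
empty nor complete) and force ranges overlap.

What the generator does **not** emulate: co-occurrence and phenology
(every resource is available to every consumer), behavioural selectivity
among accessible resources, abundance dynamics, changes in resource
penetrability with climate, phylogenetic or spatial structure, and
measurement error in traits. Passing tests therefore demonstrate that the
pipeline's mathematics and bookkeeping are correct under its assumptions —
not that real communities will show these responses; the hypothesis
verdicts on synthetic data are the model's idealised predictions, intended
as a template for comparison against field data.

## Numerical and design choices

* Feasibility ties (`bite == cut`) include the edge; documented above.
* Trait-matching recovery returns, per consumer, the interval
  `[max cut among linked, min cut among unlinked)`; 0 replaces the lower
  bound for linkless consumers and +inf the upper bound for consumers
  linked to everything. For any network built by the constructor the true
  bite force lies in this interval by construction.
* The temperature grid parser accepts `start:stop:step` inclusive of both
  endpoints within a 1e−9 floating tolerance.
* Sweeps require a strictly ascending grid; running a grid that excludes
  the rule's reference temperature is allowed (layers are well defined at
  any temperature).
* Robustness Monte-Carlo is vectorised over replicates via each consumer's
  extinction step (the maximum removal position among its resources), which
  makes 10⁴ replicates on small networks effectively free.
* Reports are byte-deterministic for fixed seeds (manifest replay
  reproduces all CSV/JSON outputs identically); the PNG plot is excluded
  from the byte-level guarantee.

## Problem sizes

Unit and property tests run on communities up to 50 consumers × 200
resources, 100-replicate sweeps, and exhaustive robustness enumeration on
networks with ≤5 resources (all removal orders); the full suite completes
in a few seconds. The verification script exercises 100 random communities
for oracle equivalence, 100 random sweeps for nestedness, 10,000
Monte-Carlo robustness replicates against exhaustive enumeration, and
≥1000 trait-matching trials.

## Known limitations

* One trophic level of cascades only: secondary extinctions do not trigger
  further removals on the resource side.
* The Q10 pathway and the size pathway are not coupled (no
  temperature-dependent bite force beyond the size effect).
* Edge weights (force surplus) are a mechanical margin, not an interaction
  rate; weighted generality should be interpreted accordingly.
* Networks read back from edge-list TSVs lose isolated nodes and node
  traits (the format stores links only), so toughest-resource-first
  robustness is unavailable on re-imported edge lists.
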