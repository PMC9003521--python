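# Methods

## The simulated annotation process

The simulator models an expert who never inspects single images unless
forced to: decisions are made on whole clusters and on batches of ranked
candidates, and the expert's judgment is replaced by a threshold oracle on
the gold labels. One outer iteration is

1. **cluster** the unassigned pool (S-k-means, PL-k-means or HDBSCAN*);
2. **validate** every candidate cluster: purity = fraction of members with
   the majority gold label (majority ties broken by the lexicographically
   smallest label). Purity ≥ `t_v` accepts the cluster (1 click) and removes
   each mismatching member (1 click + a rejection record each); purity
   < `t_v` deletes it (1 click, a rejection record for every member).
   Accepted clusters therefore start growing perfectly pure, with their
   centroid recomputed from the survivors;
3. **grow** each newly accepted cluster: candidates are the pool objects
   without a rejection record for this cluster, ordered by Euclidean
   distance to the centroid (ties by object id) and cut into batches of
   `batch_size`. The fitting/non-fitting boundary over batches is located by
   exponential search (probes 1, 2, 4, 8, …, clamped to the list end)
   followed by binary search on the open interval between the last fitting
   and first non-fitting probe; every probe costs one click. A probed batch
   with purity ≥ `t_gp` fits; purity in `[t_gu, t_gp)` accepts the batch
   after per-object removals (1 click each) and switches to a linear scan of
   the following batches; purity < `t_gu` is non-fitting and records a
   rejection for the whole batch. Unprobed batches inside the accepted
   region join unseen — that is the precision/efficiency trade at the heart
   of the approach. If a pass grew the cluster by more than
   `regrow_trigger ×` its size at the start of the pass, the centroid is
   recomputed and growing restarts (at most `max_regrows` times).

The loop carries the rejection matrix across iterations and stops at
`max_iterations`, at `completeness_stop`, or when an iteration assigns
nothing new.

Assumptions worth stating: the gold labeling is treated as the single valid
truth (no interchangeable labels, no annotator noise); batch purity is
judged against the label fixed at validation time; and the accept oracle is
assumed monotone along the distance ranking, which is what makes
exponential/binary search admissible. Real users violate all three mildly.

## Clusterers

* **S-k-means** — Lloyd iteration (k-means++ seeding, empty clusters
  re-seeded with the point farthest from its current centroid, stop on
  stable assignment or `max_iter = 100`), then each cluster keeps only its
  `max(1, ⌈p_core·m⌉)` members nearest the centroid (ties by ascending
  object id; the floor of 1 prevents cluster annihilation; centroids are not
  recomputed by shrinking). Reference-scale defaults k = 1000,
  p_core = 0.01.
* **PL-k-means** — same engine with three constraints: validated members are
  frozen to their cluster; a free object is assigned to the nearest centroid
  among clusters not in its rejection set (rejected everywhere ⇒ stays
  unassigned); each centroid is recomputed from the `⌈(1−p_noise)·m⌉`
  members closest to the *previous* center. The cluster budget at outer
  iteration *i* is `k0 + i·kΔ` in total (new clusters = budget minus
  validated, clamped to the number of free objects). Only new clusters are
  shrunk; validated clusters are returned intact so that confirmed work is
  never undone, and they may absorb late-assigned free objects. Defaults
  k0 = 500, kΔ = 100, p_noise = 0.1, p_core = 0.01.
* **HDBSCAN\*** — adapter over `sklearn.cluster.HDBSCAN` with
  `cluster_selection_method="leaf"` and `min_samples = neighborhood_k`
  (default 8). The minimum cluster size is `max(2, round(m0 · γ^i))` with
  m0 = 128 and decay γ = 0.5 per iteration, so halving reaches the floor in
  log2(m0) rounds; density-noise points stay unassigned and centroids are
  member means.

All distances are Euclidean throughout, matching the similarity search of
the growing step.

## Simulator parameters

| parameter | default | meaning |
|---|---|---|
| `t_v` | 0.85 | cluster validation purity threshold (≥ is accepted; inclusive so a 17/20 cluster passes the printed boundary) |
| `t_gp` | 0.75 | batch purity at/above which a batch is accepted whole |
| `t_gu` | 0.55 | batch purity below which a batch is rejected |
| `batch_size` | 50 | candidates per batch, as hard-coded in the interactive tool |
| `max_iterations` | 12 | outer-loop cap |
| `completeness_stop` | 0.99 | assigned fraction that ends the run |
| `regrow_trigger` | 1.0 | growth factor (relative to pass-start size) that triggers centroid recomputation and a grow restart |
| `max_regrows` | 2 | restarts per cluster per iteration |

Click model: 1 click per cluster accept/reject, 1 per batch probe, 1 per
single-object removal. Clicks are recorded per phase (validation, growing)
in the trace so alternative weightings can be evaluated by replaying it.

## Synthetic data

The generator emulates exactly the premise the approach rests on: compact,
well-separated, spherical classes of equal variance in low dimension. Class
centers are drawn isotropically and rescaled so the minimum pairwise center
distance equals `separation × σ` (σ = 1, dimensionless coordinates), making
"well-separated" a controlled parameter. Options add class-size imbalance,
diffuse background noise (uniform in the inflated bounding box of the
centers, one unique singleton label each, so no clusterer can legitimately
group it) and sub-class structure (a class split into two half-separated
Gaussians whose labels share a parent prefix, emulating interchangeable
labels that depress measurable completeness).

What it does **not** model — and what passing tests therefore do not show —
are the features of real deep embeddings: anisotropic and heavy-tailed
classes, manifold curvature, class overlap, label noise, and the dependence
of geometry on the feature extractor. Results on generated data bound the
behavior of the machinery, not of any real dataset.

`pca_reduce` (mean-centering + principal components, no whitening, since
whitening would distort the Euclidean geometry used everywhere downstream)
and a stratified `split_train_test` support the NCC-F1 evaluation of
user-supplied embeddings.

## Numerical choices

* Retention counts use `⌈q·m − 10⁻⁹⌉`; the epsilon guards against binary
  float artifacts of decimal quantiles (0.1 × 100 is not 10 in IEEE 754).
* k-means++ seeding falls back to uniform choice among unchosen points when
  all residual distances are zero (duplicate-heavy data, k close to n).
* Assignment ties (equidistant centroids) resolve to the lowest cluster
  column; shrink ties resolve by ascending object id.
* All randomness flows through `numpy.random.default_rng` on explicit
  seeds; per-iteration clusterer seeds are derived via `SeedSequence`, so
  every stage is a pure function of (inputs, seed).

## Scaled benchmark conditions

Desk-scale experiments (tests and `scripts/acceptance.py`) use 20 classes ×
100 objects, d = 32, separation 10. Clusterer settings are scaled from the
reference configuration by ratio: S-k-means k = 60 (≈ 3× the class count,
the reference ratio) with p_core = 0.01; PL-k-means k0 = 30, kΔ = 10;
HDBSCAN* keeps neighborhood_k = 8 with m0 = 64 so the initial minimum
cluster size does not exceed the class size. On this benchmark a full
S-k-means run sorts ≈ 9–10 objects per click at ≈ 98–99% mean per-cluster
precision and completeness ≈ 1.0.

## Known limitations

* With 100-object classes against 50-object batches, the single batch that
  straddles a class boundary is a large fraction of the cluster; when its
  purity still clears `t_gp` it is absorbed whole, foreign members
  included. This caps desk-scale precision of the k-means variants around
  98–99% even on perfectly separated data. The effect shrinks linearly with
  class size and is negligible at realistic dataset sizes, where the same
  mechanism costs well under 1%.
* The grower may re-probe a batch already seen as non-fitting when a mixed
  batch flips it into linear mode mid-binary-search; this costs an extra
  click, mirroring a user revisiting a page, and is rare under monotone
  orderings.
* The final naming/hierarchy step of the interactive workflow (agglomerative
  arrangement of validated clusters) is out of scope, as is any training of
  feature extractors.
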