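# Methods

`netjack` quantifies how sensitive intracranial-EEG (iEEG) functional-network
statistics are to *which electrode contacts happen to be implanted*. The
pipeline builds coherence networks from multichannel recordings, computes
standard weighted graph metrics, deletes contacts under several schemes, and
summarizes the consequences as reliabilities, agreement measures, and
patient-specific jackknife confidence sets and intervals.

## Signal conditioning and coherence networks

Recordings are contacts x samples matrices at a known sampling rate (512 Hz
is the default, matching common clinical acquisition). Conditioning applies,
in order:

1. **Common average reference** — subtract the across-contact mean at every
   timepoint, removing shared reference noise.
2. **Elliptic bandpass 5–115 Hz + 60 Hz notch** — order-4 elliptic filter
   (0.5 dB passband ripple, 40 dB stopband attenuation) and a Q = 30 IIR
   notch, both applied forward-backward for zero phase. The filter family
   and cutoffs are fixed by the analysis design; order/ripple/Q are
   conventional defaults and are exposed as keyword arguments.
3. **AR prewhitening** — each channel is replaced by the residuals of an
   autoregressive fit (least squares on the lagged design matrix, order 1
   by default, configurable). This flattens the spectrum so that coherence
   is not dominated by shared slow dynamics. The output loses `order`
   samples per channel.

Networks are built per analysis window (1 s by default; 2 s supported) as
band-averaged **multitaper magnitude-squared coherence**: DPSS tapers with
time-bandwidth product NW = 2 and 3 tapers (≈2 Hz smoothing on a 1-s
window), cross-spectra averaged over tapers, coherence averaged over the FFT
bins inside the band (inclusive bounds). Default band is high gamma
(95–105 Hz); beta (15–25 Hz) is the standard sensitivity band. Windows are
anchored so they *begin* at the requested offset from the marked seizure
onset (offsets −10, −5, 0, +5, +10 s by default).

Optional density thresholding zeroes edges strictly below the weight `w`
that achieves a target density (0.5 by convention); ties at `w` are
retained, so heavily tied matrices can overshoot the target — this is
reported with a warning rather than broken by arbitrary tie-splitting.

## Graph metrics

All metrics operate on symmetric, nonnegative, zero-diagonal adjacency
matrices. Conventions that the literature leaves open are fixed as follows:

- **Shortest paths** use edge length 1/weight (stronger coherence = shorter
  path); zero weights are non-edges. Global efficiency is the mean inverse
  shortest-path length over ordered pairs, with disconnected pairs
  contributing 0. Betweenness is raw per-pair counts (unnormalized), with a
  `normalized=True` option.
- **Synchronizability** is λ2/λmax of the weighted Laplacian L = D − A.
  It is defined as 0 for disconnected networks (λ2 = 0) and edgeless
  networks (λmax = 0); subsampling can and does produce both. Consequently
  **control centrality** — the relative change in synchronizability when a
  contact is deleted — equals −1 exactly when that deletion disconnects the
  network, and is undefined (raises) when the parent network already has
  zero synchronizability; downstream ensemble code drops such iterations
  and reports the count.
- **Transitivity and clustering** use the weighted triplet formulas with
  weights normalized by the network maximum before the cube-root geometric
  mean (the Brain Connectivity Toolbox convention, which reproduces the
  verbal triplet definition on unit-weight fixtures).
- **Eigenvector centrality** is the leading eigenvector of A (nonnegative,
  unit 2-norm). On disconnected input it is computed on the full matrix
  with a warning, since rejecting it would make jackknife ensembles
  unusable.
- **Regional control centrality** grows a region from each seed contact
  (seed + nearest neighbors by Euclidean distance, ties to the lowest
  index) and deletes it; the minimizing region is the most synchronizing
  candidate resection site. Region size conventionally equals the number
  of resected contacts.

## Subsampling schemes and robustness statistics

Four removal schemes: uniformly **random** removal of round(f·N) contacts
(f ∈ {0.2, 0.4, 0.6, 0.8}, 1000 iterations by default), deterministic
**contiguous** removal of each contact's spatial neighborhood (one set per
seed contact), **SOZ-targeted** removal of exactly the seizure-onset-zone
contacts, and **SOZ-sparing** removal of random size-matched sets outside
the onset zone (degenerating to the single all-non-SOZ removal when the
onset zone outnumbers the rest). Removal counts are round(f·N), minimum 1,
capped so ≥2 contacts remain; iteration i of a stochastic scheme draws from
an independent substream keyed by (master seed, scheme, i).

**Reliability** R = σT²/(σT²+σE²). For nodal metrics, σE² is each contact's
variance across the iterations in which it was retained (contacts retained
in <2 iterations are excluded with a warning — deletion-induced missingness
is handled by exclusion, not imputation), averaged over contacts; σT² is the
across-contact variance within an iteration, averaged over iterations. For
global metrics, σE² averages per-patient across-iteration variances and σT²
averages within-iteration across-patient variances. Variances use the
unbiased (n−1) denominator. Computing σT² on the *subsampled* networks
avoids the size-induced bias that using the original network would create.

**Agreement** a compares one subsample to the original network: Spearman ρ
over retained contacts (nodal; average ranks for ties) or −|(m_new −
m_old)/m_old| (global; 0 iff exact agreement). Distance–agreement
association is Spearman ρ between a and the removed-set-to-SOZ centroid
distance, Fisher-transformed (atanh) for cohort t-tests; |ρ| = 1 is
rejected as an error rather than reported as ±∞.

Cohort comparisons use the Friedman test across metrics (scipy), with post
hoc pairwise tests on the Friedman mean ranks (normal approximation) under
Šidák adjustment when the omnibus test is significant; one-sample and
paired t-tests are plain scipy calls. Bonferroni correction for the eight
metrics gives α = 0.05/8 = 0.00625.

## Jackknife confidence sets and intervals

The jackknife removes 20% of contacts at random (simulating minor
implantation variability), recomputes a statistic, and repeats (1000
iterations by default). For a nodal metric, each iteration's argmax contact
(argmin for control centrality; ties to the lowest index) is tallied; the
**95% confidence contact set** accumulates contacts in descending count
order until ≥95% of occurrences are covered (greedy, so minimal under that
rule — the ≥ threshold is a deliberate choice). For regional control
centrality the tally counts region *membership*, so the set measures the
spatial spread of candidate resection regions; the reported ratio divides
the set size by the region size (1 = the same region always wins). For
global metrics, the **95% confidence interval** is the 2.5th–97.5th
percentile span (linear interpolation between order statistics). Iterations
where a statistic is undefined are dropped and counted; coverage uses the
surviving denominator.

## Synthetic data

Real iEEG lives on clinical portals, so every stage is validated on
simulated data with known ground truth.

- **Recordings**: contacts partitioned into coupling blocks; each block
  shares one latent source (white Gaussian noise bandpass-filtered to the
  analysis band by an order-4 zero-phase Butterworth, unit variance) plus
  i.i.d. Gaussian sensor noise (σ = 0.5 by default, giving high in-band
  within-block coherence while between-block coherence stays at the
  finite-sample chance level). No 1/f background, no seizure dynamics, no
  volume conduction: the generator emulates exactly the feature coherence
  estimation relies on (band-limited correlated activity), so passing tests
  demonstrate correctness of the estimator and statistics, not realism of
  seizure biology.
- **Layouts**: planar grids at 10-mm pitch (the clinical grid standard)
  with a contiguous onset zone grown from a random seed contact by
  nearest-neighbor accretion (ties to the lowest index); resected flags
  default to the onset zone.
- **Adjacency fixtures**: complete graphs and paths (closed-form metric
  values), i.i.d. uniform matrices, and a stylized coherence model with
  two-level block structure plus per-node coupling propensities (edge ij
  scaled by √(u_i·u_j), u ~ U(0.4, 1)). The propensities reproduce the
  strong node-strength heterogeneity of empirical coherence networks;
  without them nodal true-score variance is unrealistically small and
  reliabilities collapse toward 0.5.
- **Cohorts**: independent patients with contact counts drawn uniformly
  from a configurable range (16–118 mirrors observed implants; the test
  suite uses 16–40 with 10 patients and 1000 iterations to keep the
  betweenness/control-centrality cost of ~20,000 subnetwork evaluations at
  desk scale).

All generators are deterministic functions of integer seeds; derived
substreams use `numpy.random.default_rng([master, tag, index])`.

## Numerical choices and limitations

- Laplacian eigenratios clamp λ2 below 1e−12·λmax to exact 0 (disconnection
  detection); synchronizability is clipped to [0, 1].
- Adjacency symmetry is enforced to 1e−10 at construction; file round-trips
  preserve weights to ≤1e−12 (17 significant digits on disk).
- Degenerate rank correlations (constant vectors) are dropped from means
  with a warning and counted, never silently imputed.
- The percentile rule, tie-breaks, and the ≥95% threshold are stated
  conventions; alternatives (nearest-rank percentiles, > threshold) would
  shift results by at most one order statistic or one contact.
- Cohort-level numbers from the clinical study (mean reliabilities per
  metric, median confidence-set sizes) depend on the patient data and are
  not reproduced here; the suite checks the definitional fixed points,
  oracle equivalence of every metric, recovery of planted coherence
  structure, and the qualitative monotonicity of reliability in removal
  fraction.
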