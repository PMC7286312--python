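# netjack

Robustness of intracranial-EEG functional-network statistics to incomplete
electrode sampling.

Clinical iEEG implants cover only part of the brain, and the set of
electrode contacts differs from patient to patient for surgical rather than
scientific reasons. Network analyses of seizures — coherence adjacency
matrices, graph metrics, virtual-resection localizations — are therefore
computed on an arbitrary spatial sample of the true epileptic network.
`netjack` asks, and answers quantitatively: *how much would the result
change if a slightly different set of contacts had been implanted?* It is
aimed at epilepsy network researchers and anyone doing graph analysis on
spatially subsampled functional networks.

## What it computes

Given a recording (contacts × samples) or a precomputed adjacency matrix:

1. **Functional networks** — common average reference, elliptic bandpass
   5–115 Hz + 60 Hz notch, AR(1) prewhitening, then band-averaged
   multitaper magnitude-squared coherence (high gamma 95–105 Hz by default)
   on 1-s windows around seizure onset; optional thresholding to density
   0.5.
2. **Graph metrics** — global: efficiency E = (1/N(N−1)) Σ 1/σᵢⱼ,
   synchronizability Sync = λ₂/λ_max of the weighted Laplacian L = D − A,
   weighted transitivity T = Στ_Δ/Στ; nodal: strength sᵢ = Σⱼ Aᵢⱼ,
   eigenvector centrality (λx = Ax), betweenness, control centrality
   cᵢ = (Sync_new − Sync_old)/Sync_old, clustering coefficient, and
   regional control centrality for contiguous contact regions.
3. **Subsampling** — random removal of 20–80% of contacts (1000 iterations),
   contiguous spatial-neighborhood removal, and removals that target or
   spare the clinician-defined seizure onset zone.
4. **Robustness statistics** — reliability R = σ_T²/(σ_T² + σ_E²) per
   metric, rank stability (mean Spearman ρ vs. the original network),
   agreement a (Spearman ρ for nodal, −|Δm/m| for global metrics),
   distance-to-onset-zone associations, and Friedman/Šidák cohort tests.
5. **Jackknife confidence** — per patient, the 95% confidence contact set
   for the optimum of each nodal metric and the 95% confidence interval
   for each global metric, from 1000 random 20% removals.

A synthetic-data module generates recordings with known block-coherence
structure, grid layouts with a contiguous onset zone, and multi-patient
cohorts, so the whole pipeline is testable without clinical data.

## Worked example

```python
import numpy as np
import netjack as nj

layout = nj.simulate_layout(6, 6, 10.0, n_soz=5, seed=42)
rec, truth = nj.simulate_recording(layout, n_blocks=3, duration=2.0, seed=42)
rec = nj.prewhiten_ar(nj.bandpass_and_notch(nj.common_average_reference(rec)))
net = nj.multitaper_coherence_network(rec, window_start=0.5, band=nj.HIGH_GAMMA)
print(f"synchronizability: {nj.synchronizability(net):.3f}")

ens = nj.random_subsample(net, 0.2, n_iter=1000, seed=42)
vals = nj.nodal_metric_ensemble(net, ens, "node_strength")
rep = nj.reliability_nodal(vals, metric="node_strength", removal_fraction=0.2)
print(f"node-strength reliability at 20% removal: R = {rep.R:.3f}")

cs = nj.jackknife_nodal_confidence_set(net, "node_strength", seed=42)
print("95% confidence contact set:",
      [net.labels[i] for i in cs.contacts], f"(coverage {cs.coverage:.3f})")
ci = nj.jackknife_global_interval(net, "synchronizability", seed=42)
print(f"synchronizability 95% CI: [{ci.lo:.3f}, {ci.hi:.3f}]"
      f" (width {ci.width:.3f}, point {ci.point_value:.3f})")
```

Output:

```
synchronizability: 0.662
node-strength reliability at 20% removal: R = 0.860
95% confidence contact set: ['E003', 'E009', 'E011'] (coverage 0.962)
synchronizability 95% CI: [0.644, 0.675] (width 0.031, point 0.662)
```

Reading: removing a random 20% of this simulated grid leaves 86% of the
node-strength variance attributable to real across-contact differences
(R = 0.860). The contact with the highest strength is stable — three
contacts account for >95% of the "strongest contact" identities across
1000 subsamples — and the global synchronizability moves only within
[0.644, 0.675].

The same pipeline is available from the shell:

```sh
netjack simulate --rows 6 --cols 6 --n-soz 5 --seed 42 --out-dir work/
netjack network work/recording.csv --eec 0.5 --out work/adj.csv
netjack metrics work/adj.csv --out work/metrics.json
netjack reliability work/adj.csv --fraction 0.2 --out work/reliability.csv
netjack jackknife work/adj.csv --fraction 0.2 --n-iter 1000 --out work/jk.json
```

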