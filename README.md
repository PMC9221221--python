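# topochron

Spatiotemporal analysis of supercoiling-coupled gene expression on
circular bacterial chromosomes.

During growth in batch culture, the global superhelical density σ of the
bacterial chromosome traces a temporal gradient: negative supercoiling
rises sharply after nutritional shift-up (σ ≈ −0.07…−0.08, about 8
superhelical turns per kb at h = 10.5 bp/turn) and then relaxes toward
stationary phase (σ ≈ −0.03, about 3 turns/kb). The chromosome also
carries a spatial gradient: G/C-rich, thermodynamically stable DNA near
the replication origin (OriC) grades into A/T-rich DNA near the terminus
(Ter) on both replichores. Because promoters differ in the superhelical
density at which they fire best — and those optima track local duplex
stability — the two gradients couple: as the DNA relaxes, maximal
transcription sweeps from OriC-proximal toward Ter-proximal genes,
ordering gene expression in space and time.

`topochron` provides the analysis chain for this picture, for
computational biologists working with time-resolved expression data on
bacteria (or synthetic emulations of it):

- **`thermo`** — windowed free melting energy (fME) profiles of a
  circular genome from unified nearest-neighbor ΔG°₃₇ stacking
  parameters; per-gene fME and distance-to-OriC; σ ↔ turns/kb
  conversion.
- **`tcds`** — signed transcription-coupled supercoil-diffusion (TCDS)
  scores at gene promoters: each expressed neighbor within 10 kb
  contributes its abundance, exponentially damped with distance
  (λ = 2.5 kb) and signed by the twin-domain rule (5′ end facing the
  promoter → negative supercoils, 3′ end → positive).
- **`trajectories`** — group-relative expression curves, expression-
  weighted fME / distance-to-OriC curves, (0;1) normalization, random-
  remapping SD envelopes, and the promoter-optimum trend statistic
  (Spearman ρ of distance-from-OriC vs. optimal σ over characterized
  promoters).
- **`simulate`** — a fully seeded synthetic growth-cycle generator
  (gradient genome, paired strand-aware genes, σ(t) schedule, Gaussian
  σ-response expression with lognormal noise) that serves as test bed
  and ground truth.
- **`pipeline` / `topochron` CLI** — one-command orchestration
  (simulate → thermo → tcds → trajectories → summary/figure) with full
  provenance headers and byte-reproducible outputs.

## Worked example

Simulate the default growth cycle (1 Mb circular genome, 400 genes,
0–420 min every 10 min, seed 1) and measure the timing chain:

```python
import numpy as np
from scipy import stats
import topochron as tc
from topochron.tcds import tcds_matrix, group_mean_tcds
from topochron.thermo import gene_ori_distance
from topochron.trajectories import group_relative_expression

bundle = tc.simulate(tc.SimConfig(seed=1))

dist = np.array([gene_ori_distance(g, bundle.genome) for g in bundle.genes])
rho, _ = stats.spearmanr(bundle.truth.peak_time, dist)
print(f"peak time vs distance-from-OriC: Spearman rho = {rho:.4f}")

tmat = tcds_matrix(bundle.genes, bundle.expression)
hyp = group_mean_tcds(tmat, bundle.truth.label_set("hyp"))
rel = group_mean_tcds(tmat, bundle.truth.label_set("rel"))
mid = (hyp.timepoints >= 100) & (hyp.timepoints <= 300)
print(f"mid-exponential mean TCDS: hyp = {hyp.values[mid].mean():.3f}, "
      f"rel = {rel.values[mid].mean():.3f}")

hyp_expr = group_relative_expression(bundle.truth.label_set("hyp"), bundle.expression)
rel_expr = group_relative_expression(bundle.truth.label_set("rel"), bundle.expression)
print(f"relative-expression peaks: hyp at {hyp_expr.argmax_time():.0f} min, "
      f"rel at {rel_expr.argmax_time():.0f} min")
```

Output:

```
peak time vs distance-from-OriC: Spearman rho = 0.9995
mid-exponential mean TCDS: hyp = -0.491, rel = 0.151
relative-expression peaks: hyp at 60 min, rel at 420 min
```

Read: genes reach maximal expression almost exactly in order of their
distance from OriC (ρ ≈ 1); genes activated by hyper-negative
supercoiling (hyp) sit in divergent neighborhoods and feel net negative
TCDS while relaxation-activated (rel) genes feel net positive TCDS; and
the hyp class peaks at the σ minimum (60 min) while the rel class peaks
at the relaxed end of the cycle.

The same run from the shell:

```bash
topochron run --seed 1 --out run1/
topochron report --dir run1/     # writes run1/report.png
```

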