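# loopmed

Causal mediation analysis of miRNA–TF–gene closed regulatory loops.

In many regulatory networks a miRNA targets both a transcription factor
(TF) and a gene that the TF also targets, forming a closed triangular
loop. The question this package answers, loop by loop: is the miRNA's
influence on the gene *direct*, or is it *mediated* by the TF? `loopmed`
is written for systems biologists analysing paired miRNA/mRNA expression
(the motivating system is retinal ischemia–reperfusion injury in rat,
with injured-vs-sham arrays at multiple time points), but every stage
works on any expression matrices plus regulator→target tables.

## The model

With X the miRNA, M the TF and Y the gene, three regressions

    Y = β₁ + c X + e₁
    M = β₂ + a X + e₂
    Y = β₃ + c′X + b M + e₃

decompose the total effect c = a·b + c′ into the average causal
mediation effect (ACME = a·b, the part routed through the TF) and the
average direct effect (ADE = c′). Loops are classified by which effect
is significant: **M_T** (TF-mediated, ACME only), **M_M** (miRNA-only,
ADE only), **M_TM** (both), or UNEXPLAINED. The pipeline around the
model:

1. **Preprocess** — 75th-percentile/median normalisation, Welch t +
   Benjamini–Hochberg differential expression at |fold change| ≥ 2 and
   corrected p ≤ 0.05, least-squares time-point imputation, probe
   collapsing.
2. **Loop inference** — exact triple join of the miRNA- and TF-target
   tables over the differentially expressed entities.
3. **Edge screening** — Pearson + distance correlation per edge; loops
   kept when all three edges pass the distance-correlation t-test
   (p ≤ 0.05); Pearson routes each model to a linear or cubic-spline fit.
4. **Mediation** — ACME/ADE/TE per loop, nonparametric bootstrap
   (1000 draws) for intervals and p-values, Sobel standard error, and a
   sensitivity analysis of the ACME against hidden confounding.
5. **Classification & motifs** — class counts and direction tables,
   top-effect extraction, and network-motif detection (exact ESU
   enumeration, canonical integer motif ids, degree-preserving null
   ensemble, z ≥ 2 / p ≤ 0.05 / count ≥ 5).

A seeded synthetic-data generator plants triads with known coefficients,
fold changes and decoy edges, so every stage is testable against exact
truth without any external download. See `docs/methods.md` for the full
statistical account.

## Worked example

```python
import numpy as np
from loopmed import mediate, sensitivity

rng = np.random.default_rng(0)
n = 200
x = rng.normal(size=n)                             # miRNA
m = 0.9 * x + 0.5 * rng.normal(size=n)             # TF      (a = 0.9)
y = 0.4 * x + 1.1 * m + 0.5 * rng.normal(size=n)   # gene    (c' = 0.4, b = 1.1)

r = mediate(x, m, y, n_boot=1000, seed=7)
print(r.acme, r.acme_ci, r.acme_p)
```

Running `python examples/03_mediate_one_loop.py` (the same data) prints:

```
ACME = 1.003  (true a*b = 0.99), 95% CI [0.855, 1.170], p = 0.0020
ADE  = 0.380  (true c' = 0.40), 95% CI [0.231, 0.520], p = 0.0020
TE   = 1.383  = ACME + ADE (exact OLS identity)
Sobel SE of ACME = 0.074
ACME at rho=0 equals the point estimate: 1.003
rho at which ACME would vanish: 0.766
```

Both effects are significant, so this loop is co-mediated (M_TM): the
TF carries about 70% of the miRNA's total influence on the gene, and the
conclusion would survive hidden mediator–outcome confounding up to an
error correlation of ~0.77. The other scripts in `examples/` walk
through loop inference, screening, cohort classification, motif
detection and the end-to-end pipeline; each prints the numbers it
computes and what they mean.

A thin CLI mirrors the stages
(`loopmed simulate | infer-loops | screen | motifs | run-all`):

```sh
loopmed run-all --seed 1 --out runs/demo
```

writes per-stage TSVs, a class-count summary and a reproducibility
manifest; reruns are byte-identical.

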