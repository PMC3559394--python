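# pcmckit

Post-conflict / matched-control (PC–MC) analysis of **consolation** and
**reconciliation** in primate groups, with an agent-based synthetic-colony
generator for validating every stage of the pipeline.

## The problem

After an aggressive conflict, do uninvolved bystanders offer the victim
stress-alleviating contact (consolation)? Do former opponents reunite
(reconciliation)? The standard field design observes the victim for ten
minutes right after each conflict (the PC follow) and again on a matched
conflict-free occasion (the MC follow: same victim, 1–2 days later, same
time of day ±1 h, both opponents within 10 m, focal conflict-free for
≥10 min). Each PC/MC pair is labelled

* **attracted** — first qualifying contact earlier in the PC, or only in the PC,
* **dispersed** — earlier in the MC, or only in the MC,
* **neutral** — same time in both (1-s resolution), or neither,

and analysed with per-focal Wilcoxon signed-rank tests, the contact
tendency `TCT = 100·(A − D)/N`, Kaplan–Meier/log-rank comparison of
censored first-contact latencies, binomial mixed models (logit link,
Laplace ML, crossed random intercepts for victim, aggressor, bystander,
group and conflict) with exhaustive AIC model selection, Gaussian mixed
models on per-dyad tendencies, and self-directed-behaviour stress proxies
(scratch bouts/min, groom s/min) with Bonferroni-corrected comparisons
(α = 0.016 for the three planned contrasts).

The package is aimed at behavioural biologists who want these analyses as
tested, reusable, seedable code — plus a generator that emulates the data
structure of a large bonobo-sanctuary study (two mixed-age groups, 36
non-infant subjects, ~0.79 conflicts per observation hour, published
victim/aggressor class shares and intensity distribution), so that every
estimator can be checked against known ground truth.

## Worked example

```python
from pcmckit.synthetic_colony import simulate_colony
from pcmckit.pcmc import (RelationshipSelector, label_dataset,
                          focal_proportions, tendency_scores)
from pcmckit.postconflict_stats import wilcoxon_paired, logrank_compare

dataset, affinity, truth = simulate_colony(hours=453.0, seed=1)
records = label_dataset(dataset, RelationshipSelector("consolation_any_bystander"))
props = focal_proportions(records)
w = wilcoxon_paired(props["prop_attracted"], props["prop_dispersed"])
lr = logrank_compare(records, fit_curves=False)
```

prints (via the obvious f-strings):

```text
analyzed PC/MC pairs : 347
attracted            : 47.4% of pairs per focal
dispersed            : 13.4% of pairs per focal
Wilcoxon             : Z = 4.22, n = 30, p = 2.45e-06
mean TCT             : 34.0%
log-rank (PC vs MC)  : chi2 = 62.8, p = 2.25e-15
```

Read: in a simulated 453-hour campaign, 347 conflicts had valid matched
controls; bystander contact reached victims earlier in post-conflict
follows than in matched controls for far more pairs than the reverse
(attracted ≫ dispersed, per-focal Wilcoxon), the mean triadic contact
tendency was ~34%, and the latency distributions differ strongly
(log-rank) — the signature of consolation. The `truth` dict holds every
latent generator parameter for recovery checks.

The same stages are scriptable from the shell:

```sh
pcmckit simulate --out data/ --seed 1 --hours 453
pcmckit validate --dataset data/
pcmckit pcmc     --dataset data/ --mode consolation --group-by victim --out labels.csv
pcmckit metrics  --dataset data/ --out metrics/
pcmckit stats    --dataset data/ --out report/
pcmckit glmm     --table metrics/opportunities.csv --out model_report.json
pcmckit run-all  --out results/ --seed 1
```

`run-all` produces the four-CSV dataset, labels, affiliation and
opportunity tables, a JSON report mirroring a post-conflict study's
results sections, survival/bar figures, and a manifest with per-stage
timings and SHA-256 checksums (identical config + seed ⇒ identical
checksums).

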