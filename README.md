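# rnatrends

Age-trend analysis of bulk RNA production in **housekeeping (HG)** versus
**integrative (IntG)** gene compartments, for multi-tissue mouse RNA-seq
time courses such as the GSE132040 cohort (17 tissues, ages
1–27 months, 5–6 animals per tissue × age).

The biological question is whether transcriptional resources are
redistributed between the two functional halves of the genome during
ontogenesis: the conserved housekeeping genes that maintain cellular
infrastructure, and the integrative genes that build and run the
differentiated organism. The package partitions the gene universe from an
HRT-Atlas-style housekeeping list, aggregates per-age mean production
across tissues with a replicate-variability filter, and tests whether the
two compartments age at different rates.

## Model and statistics

For a gene group, the per-age series is
$\bar y_a = \frac{1}{|G|}\sum_{g \in G} \bar x_{g a}$, where
$\bar x_{ga}$ averages gene $g$ over all valid (tissue, animal) samples at
age $a$; a cell (gene, tissue, age) is valid if its replicate coefficient
of variation $\mathrm{sd}/\mathrm{mean} < 1$. Trends are ordinary least
squares on the per-age means, $\bar y_a = \alpha + \beta\, a$, with the
usual $t = \hat\beta/\mathrm{se}(\hat\beta)$ ($n-2$ df) and Pearson $r$.
Two groups' slopes are compared with the pooled-variance slope-homogeneity
test (the ANCOVA interaction F):

$$F = \frac{(\hat\beta_1-\hat\beta_2)^2}{s^2\,(1/S_{xx,1}+1/S_{xx,2})},
\qquad s^2 = \frac{\mathrm{RSS}_1+\mathrm{RSS}_2}{n_1+n_2-4},$$

with $(1,\,n_1+n_2-4)$ df. Trends are additionally fitted on the two
closed segments around the a-priori 9-month breakpoint (the physiological
peak of development), and the HG/IntG ratio of group means is tracked
across the four ontogenesis stages (I: 1–6, II: 6–15, III: 15–21,
IV: 21–27 months). A synthetic-cohort generator with piecewise-linear
group trends, log-normal tissue and replicate noise and known ground truth
makes the whole pipeline testable without the deposited data.

## Worked example

The published per-age group means ship with the package
(`rnatrends.reference`); the desk-scale analysis reproduces the study's
statistics from them:

```sh
$ python analysis/01_fit_reference_trends.py
HG   : slope -1.5424/mo  t -4.46  p 0.0021  r -0.84
IntG : slope -0.3408/mo  t -3.02  p 0.0166  r -0.73
slope homogeneity: F 10.92  df (1,16)  p 0.0045
segment 1-9: HG -3.0446  IntG -0.9222  F 0.86 df (1,4) p 0.4067
segment 9-27: HG -1.3055  IntG -0.2354  F 2.56 df (1,10) p 0.1406
```

Housekeeping production falls 1.54 units per month over the whole
observation window — three times steeper before the 9-month peak
(−3.04/month) than after (−1.31/month) — while integrative production is
much flatter (−0.34/month); the F of 10.92 on (1,16) df says the two
compartments' overall slopes genuinely differ. The ratio trajectory makes
the same point in scale-free form:

```sh
$ python analysis/02_ratio_stages.py
ratio slope 1-9 months : +0.0027/mo
ratio slope 9-18 months: -0.0106/mo
...
```

The HG/IntG ratio drifts up slightly while the body is being built, then
shifts toward the integrative compartment after growth completes. The
remaining drivers (`analysis/03`–`06`) exercise the same pipeline on
synthetic cohorts: end-to-end reports, parameter recovery, F-test
calibration (empirical type-I rate 0.057 at nominal 0.05 over 1000
replicates) and block trajectories.

As a library:

```python
from rnatrends import reference, fit_line, compare_slopes

hg = reference.hg_reference_series()
ig = reference.intg_reference_series()
comp = compare_slopes(fit_line(hg.ages, hg.mean), fit_line(ig.ages, ig.mean))
print(comp.f, comp.df2, comp.p)   # 10.92 16 0.0045
```

A `rnatrends` console script exposes the stages (`run`, `partition`,
`summarize`, `trends`, `ratio`, `blocks`, `simulate`); `rnatrends run
--config config.yaml --out report/` executes the full pipeline and writes
a deterministic, machine-readable report bundle.

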