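# ampbias

Probe-level bias correction for expression microarray data generated with
the **two-cycle IVT RNA labeling** protocol.

Two-cycle amplification (needed when only nanograms of RNA are available)
systematically depresses probe intensities as a function of the probe's
position on its transcript: RNA degradation during the long in-vitro
transcription steps eats both ends, and random-primer first-strand
synthesis in the second cycle truncates the 5' side. `ampbias` is for
analysts who have probe-level PM/MM intensities (exported from CEL files to
a plain table) and want to remove this positional bias *before* standard
preprocessing (PDNN, RMA, dChip), plus for methodologists who want the
generative model itself.

## Model

A transcript occupies `[0, L]` (0 = 3' end). The surviving fragment
shortens three times: cycle-1 degradation `A1 ~ U[0, a]`,
`B1 ~ U[L−b, L]`; random-primer truncation `A2 = A1`, `B2 ~ U[A1, B1]`;
cycle-2 degradation `A3 ~ U[A2, A2+a]`, `B3 ~ U[B2−b, B2]`. The
**retaining rate** `p_i(z)` is the probability that position `z` is still
covered after stage `i`:

    p1(z) = min(z/a, 1) · min((L−z)/b, 1)

in closed form, and `p2(z) = P(A3 ≤ z ≤ B3)` by deterministic quadrature
(cross-validated against a Monte-Carlo trajectory simulation). Observed
intensities follow `PM_i = IPS·p(z_i) + ε_i` with Gaussian noise; the
probe-set intensity is estimated by maximum likelihood,

    IPS = Σ PM_i·p(z_i) / Σ p(z_i)²,

and each probe is corrected (default mode) as
`PM_i' = IPS + (PM_i − IPS·p(z_i))`. The package also implements the
evaluation statistics (per-probe-set CV with a paired one-sided Wilcoxon
test, inter-sample correlation, average-linkage clustering), a
lowess-reweighting "Curve Adjustment" baseline, qPCR degradation
proportions (`R = 2^−ΔCT`, `DP = 1 − R/max R`), and a synthetic-data
generator with ground truth. See `docs/methods.md` for assumptions,
parameter defaults and limitations.

## Worked example

Simulate a two-cycle dataset, fit the degradation limits from it, correct
it, and evaluate the correction — all from the shell (the same operations
are available as library functions):

```sh
ampbias simulate --n-sets 2000 --seed 7 --out probes.tsv --truth-out truth.tsv
ampbias fit-params --probes probes.tsv --a-grid 200:400:50 --b-grid 100:300:50 --out fitted.yaml
ampbias adjust --probes probes.tsv --a 300 --b 200 --out adjusted.tsv
ampbias evaluate --before probes.tsv --after adjusted.tsv --out-prefix eval
```

which prints:

```
INFO ampbias: wrote 22000 probe rows to probes.tsv
INFO ampbias: fitted a=300 b=200 (sse=52.91) -> fitted.yaml
INFO ampbias: adjusted 22000 probe rows (mle-residual mode) -> adjusted.tsv
INFO ampbias: median CV 0.6457 -> 0.0877 (p = 0)
```

Reading the numbers: the fit recovered the generating degradation limits
(`a = 300`, `b = 200` bp) exactly from the mean intensity-by-position
profile. Before correction, the probes of a typical probe set — which all
measure the same transcript — disagreed by 65% of their mean (median CV
0.646, driven by the position bias); after correction they disagree by 9%,
which is the simulated noise floor. The Wilcoxon p-value for the paired CV
decrease across 2,000 probe sets underflows to 0. `eval_report.tsv` holds
the same numbers as a table, and `adjusted.tsv` carries per-probe
`p_retain`, `pm_adj`, the per-set `ips` estimate, and quality flags.

Library equivalent:

```python
from ampbias import (DegradationParams, retaining_rate_curve,
                     SyntheticSpec, generate_dataset, adjust_table,
                     evaluate_adjustment)

params = DegradationParams(L=1000, a=300, b=200)
curve = retaining_rate_curve(params, cycle=2, grid_step=2.0)
probes, truth = generate_dataset(SyntheticSpec(n_probe_sets=2000, seed=7))
adjusted = adjust_table(probes, curve)
report = evaluate_adjustment(probes, adjusted)
print(report.median_cv_before, report.median_cv_after)  # 0.6457 0.0877
```

## Input format

Long-format TSV, one row per probe per sample, columns
`sample_id  probeset_id  probe_id  z  pm` (optional `mm`, `present`), where
`z` is the distance (bp) of the probe's middle nucleotide from the
transcript's 3' end. Binary CEL/CDF parsing is deliberately out of scope —
export to this table with your converter of choice. qPCR input is
`transcript_id  amplicon_id  start_5prime  sample  ct`.

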