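# itasense

Sensitivity comparison for **indirect task advantages (ITAs)**.

In paradigms like contextual cueing, implicit recognition is often inferred
from a clear reaction-time (RT) effect paired with chance-level explicit
recognition. That reasoning is flawed: a large mean RT effect divided by the
large trial-by-trial RT variability can correspond to the same weak
single-trial sensitivity that the explicit task shows. `itasense` implements
the appropriate test — comparing the *sensitivities* underlying both tasks:

- **Direct sensitivity** — d' from explicit-report hit/false-alarm rates.
- **Indirect sensitivity, trial-level** — a per-participant median-split
  ideal observer on search-task RTs: trials faster than the participant's
  own median are predicted "repeated", and the resulting classification
  rates yield d'. Optimal for log-normal RTs.
- **Indirect sensitivity, summary-level** — an unbiased d' estimate from a
  reported paired t statistic, `d' = t * c(N, K, q2)`, with a gamma-ratio
  bias correction from noncentral-t theory and a variance-ratio assumption
  `q2` (between-subject effect variance over trial-level variance, default
  0.09); `q2` can itself be estimated from trial data.
- **Inference** — paired group tests with confidence intervals, one-sided
  JZS Bayes factors (point null vs. Cauchy(0, 1/sqrt(2)) truncated to
  positive effects), per-participant bootstrap ITA tests with an exact
  binomial CI on the significant proportion, and funnel-plot coordinates.
- **Simulation** — single-source (null-ITA) and dual-source generative
  models for calibration, power and estimator-recovery studies.

## CLI

```bash
# reanalyse studies from reported statistics (t, N, K, q2, HR, FA)
ita from-summary --input studies.csv --out report.json --funnel funnel.csv

# trial-level analysis from search + recognition CSVs
ita from-trials --search search.csv --recognition recognition.csv \
    --epochs last --individual --seed 1 --out report.json

# estimate the variance ratio q2 from trial data
ita estimate-q2 --search search.csv

# generate a synthetic experiment from a YAML config
ita simulate --config sim.yaml --out-dir simdata/

# reformat a JSON report
ita report --input report.json --format markdown --out report.md
```

Trial CSVs use fixed columns `participant,epoch,block,condition,rt_ms[,correct]`
with `condition` in `{repeated,new}`; recognition CSVs use
`participant,condition,response` with `response` in `{old,new}`; summary CSVs
use `label,t,N,K,q2,hr,fa,n_direct_signal,n_direct_noise` (blank `q2` falls
back to 0.09).

## Conventions worth knowing

- Extreme classification rates are handled with the log-linear correction
  (+0.5 to all four cells), exposed as a parameter.
- Median-split ties (RT equal to the median) are predicted "new".
- `q2 < 0` estimates are reported unclamped (keeps the numerator unbiased)
  but clamped to 0 with a warning when fed into the t-to-d' constant.
- The SE attached to a t-based d' uses the closed-form SD of a
  moment-matched noncentral t scaled by the estimator constant. Published
  reanalyses use a different (supplement-derived) SE convention, so the SE,
  CI and p of that particular worked example differ slightly here; the
  point estimates and the Bayes factor agree exactly.
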