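# faersig

Disproportionality signal detection on FAERS spontaneous-report data, built
for pharmacovigilance analyses of the kind used to study drug–adverse-event
associations such as fluoroquinolone-associated tendonitis and tendon
rupture.

The FDA Adverse Event Reporting System (FAERS) is a spontaneous reporting
system: millions of voluntarily submitted adverse-event reports, with no
exposure denominator. Safety signals are therefore screened by
*disproportionality*: for a drug–event pair, the deduplicated report universe
is split into a 2×2 table

|                | target event | other events |
|----------------|--------------|--------------|
| **target drug** (primary suspect) | a | b |
| **other drugs**                   | c | d |

with N = a+b+c+d and expected count E = (a+b)(a+c)/N, and four classical
statistics are computed:

* **ROR** = ad/bc, with 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
  signal when n ≥ 3 and the CI lower bound exceeds 1.
* **PRR** = [a/(a+b)] / [c/(c+d)], with Yates-corrected χ²; signal when
  n ≥ 3, PRR ≥ 2 and χ² ≥ 4.
* **IC** (BCPNN information component) = log₂((a+0.5)/(E+0.5)); IC025 is
  Norén's lower credibility bound IC − 3.3(a+0.5)^−1/2 − 2.0(a+0.5)^−3/2;
  signal when IC025 > 0.
* **EBGM** in the shrinkage-free closed form a/E, with one-sided lower bound
  EBGM05 = EBGM·exp(−1.64·√(1/a+1/b+1/c+1/d)); signal when EBGM05 > 2.

A pair is a *positive signal* when any one algorithm meets its criterion.
Around this core the package provides the full workflow: parsing the
"$"-delimited FAERS ASCII quarterly packages, the FDA-recommended
deduplication (latest FDA_DT per CASEID, highest PRIMARYID on ties,
deleted-case removal), primary-suspect cohort extraction against a drug
lexicon and target MedDRA Preferred Terms, stratified screens (sex, age band,
administration route), clinical-characteristics and serious-outcome tables,
and time-to-onset quartiles and histograms. A synthetic FAERS-quarter
generator with planted signals makes every stage testable without
downloading FAERS.

## Worked example

Generate one synthetic quarter with the default planted fluoroquinolone
signals and run the pipeline:

```python
from faersig.synthetic import SynthConfig, generate_quarter
from faersig.pipeline import PipelineConfig, run_pipeline

cfg = SynthConfig(n_reports=20_000, seed=42)
generate_quarter(cfg, "2016Q1", "demo_q")            # writes DEMO16Q1.txt ...
res = run_pipeline(PipelineConfig(quarters={"2016Q1": "demo_q"},
                                  output_dir="demo_out"))
print(res.signals.query("stratum_axis == 'none'").round(2))
```

which prints (columns abridged):

```
         drug          event  n   ror  ror_lo95  ror_hi95   prr   chi2    ic  ic025  ebgm  ebgm05  flag_any
ciprofloxacin tendon_rupture  8 30.49     13.59     68.38 29.39 145.41  3.31   2.10 22.51   11.45      True
ciprofloxacin     tendonitis 23 59.02     34.66    100.49 52.81 711.62  4.32   3.62 33.89   21.71      True
 levofloxacin tendon_rupture  8 40.30     17.90     90.72 38.39 193.40  3.46   2.25 29.33   14.87      True
 levofloxacin     tendonitis 10 24.03     12.01     48.11 22.64 156.61  3.36   2.29 19.20   10.74      True
 moxifloxacin tendon_rupture  0   NaN       NaN       NaN  0.00   0.00 -0.33 -10.65   NaN     NaN     False
 moxifloxacin     tendonitis  4 18.16      6.43     51.29 17.28  43.31  2.59   0.83 16.25    6.82      True
```

Each row is one drug–event pair screened against the 19,961 deduplicated
reports of the quarter (20,986 raw report versions minus 986 duplicates and
39 deleted cases — the flow counts land in `flowchart_counts.json`). `n` is
cell a, the number of deduplicated reports naming the drug as primary suspect
together with the event; the planted pairs are recovered as positive signals,
while the moxifloxacin–tendon-rupture pair drew no reports at this scale and
stays undefined (NaN) rather than being continuity-corrected. The output
directory also receives `table1_characteristics.csv`,
`table3_route_signals.csv` (oral/intravenous strata), `table4_onset.csv`
(onset quartiles by the median-of-halves rule), `figure2_histogram.csv`,
`outcomes.csv` and `metadata.json` recording every threshold and formula
variant used.

The same two steps are available from the shell:

```sh
faersig simulate --out demo_q --label 2016Q1 --n-reports 20000 --seed 42
faersig run --archive 2016Q1=demo_q --out demo_out
```

Real FAERS quarters (the ASCII packages from the FDA download site,
2016+ layout) can be pointed to the same `--archive LABEL=DIR` interface.

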