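# mistrans-sga

Quantitative analysis for genetic-interaction screens of mistranslating
tRNAs in *Saccharomyces cerevisiae*. A tRNA-Ser variant carrying a proline
anticodon (tS(UGG) with a stabilizing G26A mutation) inserts serine at
proline codons; this package implements the computational side of asking
*which genetic backgrounds care, and how much, as a function of
mistranslation frequency*:

* **SGA interaction scoring** — colony-array normalization, single- and
  double-mutant fitness estimation from quadruplicate 1,536-format plates,
  and interaction scores under the multiplicative model
  ε = W<sub>AB</sub> − W<sub>A</sub>·W<sub>B</sub>, with one-sample t-tests
  per allele and Benjamini–Hochberg FDR control. Negative calls require
  ε < −0.2 and q < 0.05.
* **Spot-assay validation** — observed double-mutant growth versus the
  multiplicative expectation W<sub>A</sub>·W<sub>B</sub> from the single
  mutants; slower-than-expected growth validates a hit.
* **Growth kinetics** — logistic fits
  N(t) = K / (1 + ((K−N₀)/N₀)·e^(−rt)) to OD₆₀₀ series, doubling time
  ln 2 / r.
* **Mistranslation frequency** — Pro→Ser substitution frequency from
  peptide-spectrum-match tables (−10.0207 Da diagnostic mass shift), with
  1% PSM-level FDR filtering and the sibling-peptide qualification rule.
* **Dose–response classification** — normalized growth across the low /
  medium / high mistranslation constructs (nominal 0.9% / 3.5% / 5.6%
  versus the 0.3% wild-type-tRNA background), expressed relative to the
  wild-type strain and classified into four response categories
  (proportional, threshold, uniform, low-sensitive).
* **Synthetic data** — generators for all four input kinds with planted
  ground truth (interaction scores, substitution rate, doubling times,
  dose factors), so every stage is testable end to end without downloads.

## Worked example

Simulate a 1,000-allele screen with 20 planted interactions (ε = −0.4)
and score it:

```sh
mistrans-sga simulate screen --n-alleles 1000 --n-interactions 20 \
    --eps -0.4 --seed 11 --outdir sim
mistrans-sga score --plates sim/double_plates.tsv --key sim/array_key.tsv \
    --control-plates sim/control_plates.tsv \
    --query-plates sim/query_plates.tsv --mode gradient --out hits.tsv
```

```
screen with 1000 alleles -> sim
1000 alleles scored, 20 negative calls -> hits.tsv
```

All 20 planted interactions are recalled and no null allele is called
(the recovered mean ε for the planted set is −0.40 ± 0.05). The same
library surface is available in Python:

```python
from mistrans_sga import ProteomeScenario, simulate_psms, frequency

records, truth = simulate_psms(ProteomeScenario(seed=2, rate=0.049))
print(frequency(records).frequency_pct)   # 5.17 (planted 4.9, binomial noise)
```

Measured inputs work the same way through `read_plate_table`,
`read_psm_table`, `read_od_table` and `read_spot_table`; the
`mistrans-sga pipeline` command chains scoring, validation and
dose-response profiling and writes a provenance manifest.

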