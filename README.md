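# oxiseq

Differential RNA-oxidation analysis for 8-oxoG RIP-seq experiments.

Oxidative stress leaves chemical marks on RNA, most prominently
8-oxo-7,8-dihydroguanosine (8-oxoG). In an 8-oxoG RIP-seq experiment the
rRNA-depleted RNA pool of each culture is split into an **input** fraction
(total transcript abundance) and an **IP** fraction (anti-8-oxoG antibody
pulldown), sequenced, and quantified per transcript — here for two exposure
conditions, clean air (CA) and a formaldehyde-exposed culture (FA), in
biological replicates. `oxiseq` answers the question such a design is built
for: *which transcripts become more heavily oxidized under exposure than
they are at baseline?*

## The statistic

For each condition the pulldown is normalized against its matched input via
a negative-binomial Wald contrast (IP vs input), giving per-transcript
log<sub>2</sub> fold changes FA<sub>log2FC</sub> and CA<sub>log2FC</sub>.
The differential-oxidation statistic is the ratio of ratios

```
Δlog2FC = FA_log2FC − CA_log2FC        (log2FC values of exactly 0.00 are
                                        first raised to 0.01)
```

A transcript is called **oxidation-enriched** when

1. its IP/input enrichment is significant (BH-adjusted p < 0.05) in at
   least one condition, and
2. Δlog2FC > 2 — i.e. the FA fold change exceeds the CA fold change more
   than 4-fold —

or when it is detected in every FA library and in no CA library (FA-only
transcripts are enriched by definition). A parallel branch contrasts the
two input fractions (FA_IN vs CA_IN) for standard differential expression
(p_adj < 0.05, |log2FC| > 2), and the two branches intersect into the
headline **oxidized ∧ downregulated** class. No direct IP-vs-IP comparison
is made: pulldown counts are only interpretable relative to matched input.

The NB engine (median-of-ratios size factors, moment-based dispersion with
across-transcript moderation, Wald test on group means, BH correction) is
implemented in the package and documented in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a 2 condition × 2 fraction × 2 replicate experiment with 60
transcripts planted at +4 log2 units of FA-specific pulldown enrichment,
9 FA-only transcripts and 20 + 20 planted up/down DE transcripts, then fit:

```sh
cat > sim.yaml <<EOF
n_transcripts: 2000
n_enriched: 60
n_de_up: 20
n_de_down: 20
fa_only_count: 9
EOF
oxiseq simulate --config sim.yaml --seed 7 --out sim/
oxiseq run --counts sim/counts.tsv --samples sim/samples.tsv --out results/
```

which prints

```
Differential RNA-oxidation analysis (8-oxoG RIP-seq)
========================================================
transcripts analysed          2000
libraries                     8
enrichment gate               p_adj < 0.05 in >=1 condition
delta cutoff                  |delta_log2fc| > 2.0  (ratio > 4)
DE gates                      p_adj < 0.05, |log2FC| > 2.0
--------------------------------------------------------
candidates (p_adj gate)       67
oxidation-enriched            69  (FA-only: 9)
oxidation-depleted            0
upregulated                   29
downregulated                 19
oxidized & downregulated      0
```

Reading: 69 enriched calls ≈ the 60 planted transcripts plus the 9 FA-only
ones; the 29 upregulated calls are the 20 planted up-transcripts plus the
9 FA-only transcripts (absent under CA, expressed under FA, hence also DE);
19 of the 20 planted down-transcripts were recovered. Result tables
(`oxidation_enrichment.tsv`, `differential_expression.tsv`,
`qc_summary.tsv`) and a run manifest land in `results/`.

The same analysis is available as a library, statsmodels-style:

```python
from oxiseq import OxidationRIPSeq, SimConfig, simulate_experiment

counts, truth = simulate_experiment(SimConfig(seed=7))
res = OxidationRIPSeq(counts).fit()
print(res.summary())
res.enrichment          # per-transcript delta table
res.regulation          # DE calls + oxidation_class
```

`oxiseq report` tabulates a result set against GMT gene sets; with no
arguments it runs on the packaged two-pathway report table:

```
Chromatin modifying enzymes: 21 transcript rows, 13 with DE p_adj < 0.05
DNA damage response, signal transduction by p53 class mediator: 10 transcript rows, 4 with DE p_adj < 0.05
```

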