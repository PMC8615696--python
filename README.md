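# sigmatch

Signature-matching drug repurposing: rank a compound library by how well
each compound's transcriptional signature *reverses* a disease expression
state, enrich the shortlist for mechanisms of action, and re-rank the
survivors by predicted blood–brain-barrier (BBB) penetration.

## Who this is for

Computational pharmacologists running connectivity-mapping screens
against LINCS-L1000-style drug signature libraries: a disease signature
(up/down differentially expressed gene sets, e.g. a CREEDS-style entry)
is compared against thousands of drug perturbation signatures, looking
for compounds whose *down*-regulated genes coincide with the disease's
*up*-regulated genes. For CNS indications the hits are then filtered by a
QSAR-predicted BBB-penetration probability.

## The method

**Signatures.** A drug perturbation with control and treatment replicates
yields a characteristic-direction coefficient vector

&nbsp;&nbsp;&nbsp;&nbsp;b ∝ Σ<sub>γ</sub>⁻¹ (μ<sub>t</sub> − μ<sub>c</sub>),&nbsp;&nbsp;
Σ<sub>γ</sub> = (1−γ) Σ̂<sub>pooled</sub> + γ ν I,&nbsp;&nbsp;
ν = tr(Σ̂<sub>pooled</sub>)/p,

a regularized linear-discriminant direction in gene space, unit-norm and
oriented so positive coefficients mean "up in treatment". Up/down DEG
sets are called by a two-sided z-test on the standardized coefficients at
p < 0.01.

**Reversal score.** For disease signature i and drug signature j,

&nbsp;&nbsp;&nbsp;&nbsp;J(S<sub>i</sub><sup>up</sup>, S<sub>j</sub><sup>dn</sup>) =
|S<sub>i</sub><sup>up</sup> ∩ S<sub>j</sub><sup>dn</sup>| / |S<sub>i</sub><sup>up</sup> ∪ S<sub>j</sub><sup>dn</sup>|.

Per drug, only the best-scoring condition (cell line × dose × time)
counts; with several disease signatures the per-signature best scores are
averaged, and drugs are ranked by that average.

**Downstream.** The top-k (default 100) drugs are tested for
mechanism-of-action enrichment (upper-tail hypergeometric test,
Benjamini–Hochberg adjusted), then re-ranked by an externally supplied
BBB probability in [−1, 1] and truncated to the top n (default 10). A
per-candidate report gives the overlap between the candidate's
down-genes and the disease up-genes with its hypergeometric p-value.

Because real LINCS/CREEDS/admetSAR inputs need downloads, the package
ships a synthetic generator that emulates all of them at desk scale with
planted ground truth (reversal drugs, an enriched MOA class, BBB-high
compounds), so the whole screen is testable end to end.

## Worked example

```bash
sigmatch simulate --seed 5 --mode sets --outdir data
cat > config.yaml <<EOF
disease_up_gmt: data/disease_up.gmt
disease_down_gmt: data/disease_down.gmt
library_mode: sets
library_up_gmt: data/library_up.gmt
library_down_gmt: data/library_down.gmt
metadata_tsv: data/library_metadata.tsv
moa_tsv: data/moa.tsv
bbb_tsv: data/bbb.tsv
outdir: results
top_k: 100
retain_n: 10
EOF
sigmatch run-all --config config.yaml
```

prints the stage counts

```json
{
  "disease_signatures": 2,
  "drug_signatures": 1200,
  "drugs_scored": 300,
  "shortlist": 100,
  "retained": 10
}
```

and writes four tables under `results/`. The MOA enrichment
(`moa_enrichment.tsv`) puts the planted mechanism class on top — all 5 of
its members sit in the 100-drug shortlist against a 300-drug background:

```
term         k  K   n    N    p_value   p_adjusted
planted_moa  5  5   100  300  0.00384   0.0423
moa_00       19 41  100  300  0.04439   0.2442
```

The BBB screen (`bbb_top.tsv`) retains the 10 shortlisted drugs with the
highest BBB probability; the 5 planted reversal drugs (here DRUG0141,
DRUG0165, DRUG0208, DRUG0284, DRUG0298, `average_score` ≈ 0.27–0.33
versus ≈ 0.02 for background drugs) all survive because the generator
also plants them as BBB-permeable:

```
rank  drug_id   average_score  bbb_probability
1     DRUG0298  0.331          0.957
2     DRUG0276  0.020          0.928
3     DRUG0128  0.019          0.905
4     DRUG0284  0.268          0.887
5     DRUG0165  0.318          0.885
...
```

`sigmatch report --drug DRUG0298 ...` then prints the candidate's
overlap with the disease up-genes and its hypergeometric p-value. With
`--mode expression` the generator instead emits replicated GCT matrices
and the pipeline computes characteristic-direction signatures itself
(`sigmatch signatures`, or `library_mode: expression` in the config).

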