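# contextpp

Quantitative prediction of canonical microRNA (miRNA) targeting efficacy in
mammalian mRNAs, for computational biologists studying post-transcriptional
regulation: which mRNAs will a given miRNA (or siRNA) repress, and by how
much?

MicroRNAs repress mRNAs mainly through Watson–Crick pairing between the
miRNA *seed* (nucleotides 2–7/2–8) and complementary sites in 3′ UTRs. The
canonical site types, from strongest to weakest, are the **8mer** (match to
nt 2–8 plus an A opposite position 1), **7mer-m8** (nt 2–8), **7mer-A1**
(nt 2–7 plus the A), **6mer** (nt 2–7) and **offset-6mer** (nt 3–8). Not all
sites of a type are equally effective: their context — local AU content,
structural accessibility, distance from the UTR ends, seed-pairing
thermodynamics, transcriptome-wide target-site abundance, and more —
modulates repression.

## The model

Each site receives a **context++ score (CS)**: a site-type-specific linear
model over 14 features, each trimmed-scaled by its training 5th/95th
percentiles,

```
CS = min(cap, b0 + Σ_f  b_f · x_f),     cap = −0.03 / −0.02 / −0.01 / 0
                                         for 8mer / 7mer-m8 / 7mer-A1 / 6mer
```

CS is in log2 fold-change units: 2^CS is the predicted fraction of mRNA
remaining. The 14 features are TA_3UTR, SPS, sRNA1, sRNA8, site8, local_AU,
3P_score, SA, min_dist, P_CT, len_ORF, len_3UTR, off6m and ORF8m.

Because genes express alternative tandem 3′-UTR isoforms, each site is
weighted by its **affected isoform ratio (AIR)** — the fraction of 3′-UTR
molecules containing it, estimated from 3P-seq cleavage/polyadenylation tag
profiles. All sites of a family on one transcript combine through the
cumulative recursion (sites numbered from the distal end, C₀ = 0):

```
C_i  = C_{i−1} + (1 − 2^CS_i)(AIR_i − C_{i−1})
CWCS = log2(1 − C_n)
```

The **cumulative weighted context++ score (CWCS)** is the predicted log2 of
the remaining mRNA fraction under the joint action of all sites; it equals
the abundance-weighted expectation over isoforms of the product of per-site
effects.

The training pipeline is also implemented: PLSR-based removal of
sRNA-independent batch structure from fold-change compendia
(mask → filter → kNN-impute → residualize, then no-site median centering),
bootstrap stepwise-AIC feature selection (70/30 stratified splits), and
per-site-type OLS fits with the score caps. The packaged coefficient table
is trained on the synthetic compendium (the published coefficient release is
not redistributable) and is labeled accordingly; the packaged scaling table
carries the published percentile anchors.

## Worked example

Everything runs end-to-end on synthetic data — no downloads:

```
contextpp simulate --config sim.yaml --seed 7 --outdir demo
contextpp sites  --transcripts demo/transcripts.fa --annotation demo/annotation.tsv \
                 --families demo/families.tsv --out demo/sites.tsv
contextpp score  --transcripts demo/transcripts.fa --annotation demo/annotation.tsv \
                 --families demo/families.tsv --clusters demo/clusters.tsv \
                 --out demo/predictions.tsv
```

with `sim.yaml` containing `n_transcripts: 30`, `n_mirnas: 3`,
`n_experiments: 3`, `utr3_log10_mean: 2.8`. The site table classifies each
seed match (1-based inclusive coordinates):

```
transcript_id  family_id  site_type     start_1based  end_1based  region
tx0000         fam02      8mer          23            30          utr3
tx0000         fam02      offset-6mer   52            57          utr3
```

and the prediction table ranks transcripts by CWCS, most repressed first:

```
transcript_id  gene_id  family_id  member                  n_sites  cwcs     percentile
tx0027         g0027    fam01      ACCGCUCCGGGGUUUGGCUCAU  2        -0.6733  100.0000
tx0029         g0029    fam01      ACCGCUCCGGGGUUUGGCUCAU  2        -0.6147  80.0000
tx0014         g0014    fam02      AUGAACAAGUCUUUGCGCCCAU  2        -0.5027  100.0000
```

`cwcs = -0.6733` predicts that fam01 targeting leaves 2^−0.67 ≈ 63% of
tx0027's mRNA, i.e. ~37% repression from its two sites; the percentile
ranks the prediction within its family (100 = most repressed). Targets
whose only canonical site is a 6mer contribute to CWCS but are not listed.

The same workflow is available as library calls (`find_sites`,
`build_profile`, `feature_vector`, `family_transcript_score`,
`normalize_compendium`, `StepwiseAICRegressor`, …); the estimators follow
scikit-learn conventions (`fit`/`predict`/`get_params`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
simulates 1000 random 3′ UTRs each carrying one planted 8mer site, scores
every site with the packaged model, and reports the maximum per-site
context++ score observed (together with the number of sites scored) as
JSON. Everything is recomputed at run time from the given seed.
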