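# Methods

This note records the modeling choices behind the package: what each
component computes, the defaults and why, what the synthetic-data generator
does and does not emulate, and the numerical decisions made where the
design was genuinely open.

## Site discovery

Site signatures are derived from the family seed (miRNA nt 2–8) by reverse
complement, with the position-1 adenosine appended on the target 3′ side.
Every occurrence of the 6mer core (match to nt 2–7) is classified into
exactly one canonical type by checking the flanking nucleotides: an m8
match 5′ of the core and/or an A 3′ of it promote the call to 7mer-m8,
7mer-A1 or 8mer. Offset-6mers (match to nt 3–8) are reported only where no
canonical call covers any part of the locus; partial overlaps are
suppressed (configurable), since the published filtering rule does not
address them. Overlapping distinct loci are resolved by type priority
(8mer > 7mer-m8 > 7mer-A1 > 6mer > offset-6mer), ties to the 5′-most locus.
Sites starting within the first 15 nt of the 3′ UTR sit in the path of the
ribosome and are excluded from scoring by default. Any window containing N
is no match. Internally all coordinates are 0-based half-open; emitted
tables are 1-based inclusive.

The target-site-abundance census counts 6mer-core occurrences at distinct
offsets over all annotated 3′ UTRs (subsuming 7–8mer loci). This set is a
design decision: it is consistent with the published log10 ranges
(roughly 3.1–3.9 for a transcriptome-scale annotation), and the exact
counted set is not restated in the source material.

## Features

Nine continuous features are trimmed-scaled per site type as
`(x − p5)/(p95 − p5)` with the packaged percentile anchors; values are
deliberately **not clipped**, so out-of-range raw values scale outside
[0, 1]. Counts (off6m, ORF8m) and nucleotide identities (sRNA1, sRNA8,
site8; expanded to A/C/G indicators against a U reference) pass through.

* **SPS** — nearest-neighbor free energy (37 °C) of a perfect seed:target
  helix over nt 2–8 (8mer/7mer-m8) or nt 2–7 (7mer-A1/6mer), from an
  embedded Watson–Crick stack table (Turner-style values, no initiation
  term). The nt 2–7 span for the A1/6mer types is inferred from the
  distinct published percentile ranges for those types.
* **local_AU** — A/U fraction over 30-nt flanks on each side of the site,
  the k-th nucleotide from the boundary weighted 1/k; truncated flanks are
  renormalized; N in a flank gives a missing value.
* **3P_score** — the miRNA 3′ region (nt ≥ 9) is slid at offsets −4..+4
  against the 16 nt 5′ of the seed pairing; the best contiguous
  Watson–Crick run scores 1.0 per pair at miRNA nt 13–16 and 0.5 elsewhere,
  minus 0.5·|offset|, floored at 0. The constants are config-exposed
  defaults for the cited scheme.
* **SA** — log10 of the probability that the 14-nt window centered on the
  match to miRNA nt 7–8 is unpaired, truncated at UTR ends.
* **min_dist / len_3UTR / off6m** — isoform-aware: computed per tandem
  isoform and averaged with abundances renormalized over the isoforms
  containing the site. min_dist uses the site's closest edge (an open
  choice; the midpoint alternative differs by <4 nt on a log10 scale).
* **P_CT** — consumed from a lookup keyed by (transcript, family, site
  start); sites without an entry, and all sites of families not broadly
  conserved, get 0.
* For 8mer/7mer-m8 sites the target position-8 identity is the Watson–Crick
  complement of sRNA position 8, so site8 is exactly collinear with sRNA8
  there; the fitting helpers drop aliased columns (coefficient 0), matching
  the NA-for-aliased convention of R's `lm`.

## Structural accessibility backend

ViennaRNA is not assumed. The default backend is a simplified McCaskill
partition function: one stacking-free energy term per pair (GC −3.0,
AU −2.0, GU −1.0 kcal/mol), minimum hairpin loop 3 nt, maximal pair span
40 nt, folding a local segment of ~80 nt around the query window (the local
analogue of a sliding folding window). The unpaired probability of a window
is the ratio of the partition function with pairs touching the window
forbidden to the unconstrained one. Within this model the recursion is
exact — the test suite checks it against exhaustive enumeration of all
legal structures to 1e-9 on sequences ≤ 18 nt — but its absolute
probabilities are systematically lower than a full Turner-model RNAplfold
run; for bit-compatible reproduction of a published pipeline, a reader for
RNAplfold `_lunp` files plugs in as an alternative provider. Scores from
the two backends should not be mixed with a single scaling table.

## Isoform profiles

Per-dataset 3P-seq tag totals per transcript are upper-quartile normalized
(factor = 75th percentile of per-transcript totals over transcripts with
≥1 tag, linear interpolation — the interpolation convention is an open
choice). Factors are divided by their geometric mean so they only rescale
datasets against each other: pooled counts keep the raw tag scale, on which
the fixed pseudocounts are defined (0.1 tag to the longest tandem isoform,
5 to the longest annotated isoform), and a single dataset gets factor 1.
A site "exists in" an isoform iff the isoform end ≥ the site end. AIR is
the summed abundance of containing isoforms; ORF sites have AIR 1.

## Scoring and aggregation

Per-site scores are capped at −0.03/−0.02/−0.01/0 (8mer/7mer-m8/7mer-A1/
6mer), making each site-type model piece-wise linear. The cumulative
recursion `C_i = C_{i−1} + (1 − 2^CS_i)(AIR_i − C_{i−1})` runs over sites
ordered distal → proximal (AIR nondecreasing; violations raise, as they
indicate mis-sorted input) and `CWCS = log2(1 − C_n)`. The recursion is
equivalent to the explicit abundance-weighted expectation over isoforms of
the product of per-site remaining fractions; the tests enforce agreement to
1e-12. Per family the mature member with the most negative CWCS represents
the family; per gene the transcript with the most 3P-seq tags is the
representative. 6mer-only targets are excluded from listings but their
contribution stays in CWCS. The score percentile of a prediction is 100×
the fraction of same-family predictions equally or less repressive (best =
100) — a convention chosen to match the public "score percentile" semantics,
which the source does not define.

## Compendium normalization

Per experiment i, leave-one-out: (i) predictor cells of genes with a
canonical 7–8 nt site to that predictor column's sRNA are masked, so true
repression measured twice is not treated as bias; (ii) genes missing in the
response or in >50% of predictor columns are dropped (exactly 50% is
retained); (iii) remaining holes are kNN-imputed (k=20, nan-Euclidean over
jointly observed columns with the sqrt rescaling); (iv) the response is
replaced by its residual from a PLSR fit (NIPALS), the component count
chosen as the smallest within one standard error of the minimum 10-fold
cross-validated RMSEP ("an appropriate number" is all the source states).
Residualization precedes centering on the no-site median (the source lists
centering under dataset processing; the order is configurable). Diagnostics
carry the inter-experiment Spearman matrices before/after.

## Training

AIC is −2 ln L + 2k with the Gaussian OLS likelihood and is **minimized**
(the source says "maximized", which contradicts the printed definition; the
definition wins). Stepwise search is bidirectional from an intercept-only
start (full-model start available), deterministic given column order, with
the RSS floored at a perfect-fit tolerance (TSS·1e-12) so noiseless
responses do not over-select on rounding noise. Bootstrap selection draws
70% of each experiment's rows without replacement, B=1000 at full scale
(B=100 in the scaled-down test runs), records held-out r², and defines
the robust set as features selected in ≥99% of samples for ≥2 site types.
Note the selection frequency of a truly uninformative feature within one
fixed dataset is bimodal — roughly 16% of datasets realize a spurious
|t| > √2 and then select the feature in nearly all resamples — so only the
robust-set rule, not a per-feature frequency bound, separates signal from
noise on a single dataset. Final per-site-type models are OLS on the full
data with 95% coefficient CIs; caps are attached after fitting (whether
caps applied before or after test-set r² is open; they are applied to final
scores).

## Synthetic data

The generator states one world and keeps it: ~1 kb log-normal 3′ UTRs
(log10 mean 3.0, sd 0.25), GC 0.4, 150-nt 5′ UTRs, 900-nt ORFs, 1–4 tandem
isoform ends with Dirichlet(1) abundances, 3 tag datasets of depth 100 per
transcript, Gaussian noise sd 0.1 log2 units, rank-2 batch structure whose
gene loadings are standardized 3′-UTR length and AU content with
study-shared experiment loadings (emulating protocol-dependent biases), and
an optional positive offset for targets of designated endogenous families.
UTR and ORF backgrounds are scrubbed of spurious seed matches before
planting, and flanking nucleotides of planted sites are pinned, so the
planted registry is exactly what site discovery recovers; decoy
offset-6mers and ORF 8mers are planted to give those count features
variation. Planted fold-change effects are linear in the *computed* scaled
features under a stated truth model with caps disabled — so the training
closure (simulate → normalize → select → fit) can recover the truth
exactly up to noise. What the generator does **not** emulate: realistic
sequence composition (codon structure, repeats), shared seed families
across species, CLIP-style measurement error, or correlated multi-isoform
expression shifts between conditions; a green closure test therefore
establishes the correctness of the pipeline's statistics, not biological
performance.

The packaged coefficient table is an OLS fit of the 14 features on a
2400-transcript, 16-experiment synthetic compendium after normalization
(`scripts/make_shipped_model.py`, fixed seed); it is a clearly labeled
synthetic stand-in for a published coefficient release, with the published
caps and scaling anchors attached. Its coefficient signs follow the
established directions (longer UTR/ORF protective; accessibility, local
AU, 3′ pairing, seed stability, conservation repressive).

## Known limitations

* The accessibility energy model is deliberately minimal; absolute SA
  values are shifted relative to a Turner-model pipeline and only the
  packaged anchors' ordering carries over.
* Genome-scale UTR extension, P_CT computation from alignments, and
  non-canonical site classes (3′-compensatory, centered, cleavage) are out
  of scope; P_CT is an input column.
* Desk-scale synthetic transcriptomes make TA_3UTR raw values far below the
  packaged anchors, so scaled TA is strongly negative there — harmless for
  linear models but visible in feature tables.
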