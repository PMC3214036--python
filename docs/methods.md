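# Methods

## Essentiality classification

Essentiality of a human gene is inferred from the phenotype of its mouse
ortholog's targeted deletion (a null allele). Phenotype reports are matched
case-insensitively against a configurable set of lethal-term stems,
defaulting to `embryonic lethal`, `prenatal lethal`, `perinatal lethal`,
`postnatal lethal` and the generic `lethality` — substring stems rather than
exact terms, because phenotype vocabularies phrase lethality both ways round
("embryonic lethality", "lethality, embryonic"). The decision rule is:

* **lethal** — any report matches a lethal stem (*any-lethal-wins*: a gene
  with both lethal and viable allele reports is lethal; this deterministic
  precedence replaces manual redundancy curation, which is not
  reproducible);
* **viable** — at least one report, none lethal;
* **unknown** — no knockout report at all.

Crossing this with disease status gives the DL/DV/DU/L/V partition. The key
design commitment is that DU is a first-class group: genes without knockout
data are never folded into the viable class. Conditional knockouts and
incomplete-penetrance lethality have no special handling — whether they
count as lethal is controlled entirely by the lethal-term set, which is a
run-config parameter.

Tabulated shares are reported as percentages: integer precision in the
main report and one decimal in machine-readable output, rounded half-up
(2.5 → 3). The genome size used for genome-wide rates (housekeeping
contrast) is a config parameter, default 24,789 — it cannot be inferred
from input files, which cover only annotated genes.

## Interaction network statistics

The interaction network is a simple undirected graph: self-interactions are
dropped, duplicate pairs in either order collapse, and sources are pooled
as a plain union without evidence weighting. Category subnetworks follow
two membership rules: **one-or-both** (an edge survives if at least one
endpoint is a category member) is used for all quantitative statistics;
**both** (both endpoints members) is exported only for visualization.
Degrees, averages and component statistics are computed *within* the
extracted subnetwork over interacting proteins only; the maximum degree is
taken over all subnetwork nodes, including non-member interaction partners.
The largest connected component is chosen by node count, with ties broken
by edge count and then by lexicographically smallest member — ties are
essentially impossible at realistic scale, but the rule makes outputs
deterministic.

Degree distributions are compared with two-sided Wilcoxon–Mann–Whitney and
Kolmogorov–Smirnov tests. Degree data are heavily tied, and the standard
exact rank-sum distribution assumes continuity, so for small samples (up to
50,000 group assignments) the WMW p-value is computed by full enumeration
of assignments using midranks, which is exact under any tie pattern; larger
samples use the tie-corrected normal approximation.

## Enrichment machinery

Every enrichment is a 2×2 contrast — group members versus a background
minus the group, by term presence — tested with a two-sided Fisher exact
test. The implementation enumerates the hypergeometric support with integer
binomial coefficients and compares probability-mass numerators as exact
integers, so ties in the "at least as unlikely" criterion are resolved
exactly and the p-value is correct to the rounding of a single final
division. The chi-square test (used for large genome-scale tables)
delegates to scipy, without Yates correction by default.

Benjamini–Hochberg adjustment is the step-up procedure
q(i) = min over j ≥ i of p(j)·m/j, applied per namespace × group family —
the most conservative family structure consistent with correcting each
reported comparison set separately. Note that BH is *not* idempotent
(re-adjusting adjusted values rescales them again); the tested guarantees
are dominance (q ≥ p), rank-monotonicity, order-invariance and agreement
with an independent implementation.

The gene universe for an enrichment is restricted to background genes
carrying at least one annotation in the namespace under test, since
annotation coverage is partial and unannotated genes are uninformative
about term composition. The default background is the disease gene set
(the natural contrast for disease-class and compartment profiles of
disease-gene subgroups); `all_genes` is available for genome-style
contrasts such as the housekeeping analysis.

## Mechanism text classification

Two independent classifiers label each free-text disease record gain /
loss / other ("other" covers translocations and chimeric proteins, held in
the model as the `neutral` class):

* **Lexicon word score** — count tokens matching each category's word stems
  by token-prefix match (stem `activat` hits "activation", "activating");
  the argmax category wins. Ties and all-zero scores map to
  `unclassified`, which is excluded from proportion denominators. The
  shipped default lexicon (`essgenes/data/lexicon.yaml`) seeds each
  category with canonical discriminating words (deficiency; neomorphic,
  activation; translocation) plus documented common stems; it is data, not
  code, and users can substitute their own.
* **Naive Bayes** — multinomial over a filtered vocabulary: words with
  document frequency ≥ 0.5 of training documents are excluded, as are
  words occurring in training documents of every class (neither can
  discriminate). Likelihoods interpolate class word frequencies with the
  uniform distribution, p(w|c) = (f(w|c) + α/V)/(1+α) with α = 1 by
  default. This formulation was chosen over raw-count additive smoothing
  because it makes the model an exact function of per-class frequencies:
  replicating the training corpus leaves priors and likelihoods unchanged,
  and the smoothing strength does not drift with corpus size.

Corpus-level proportions are reported per essentiality group for each
method, together with the simple agreement rate of the two methods on
mutually classified records. Records of genes carrying any polygenic
disease association are dropped under the default `monogenic_only` filter
(genicity is a gene-level label here, so the filter operates on the
record's gene).

## Inheritance modes

Any allele with a described inheritance pattern counts, so one gene can
appear in both the AD and AR categories; duplicate association rows are
idempotent (set semantics per gene × mode). Proportions use
genes-with-any-inheritance-annotation as the denominator, because
annotation is partial; they are per gene-category, not per allele, and
need not sum to one. X-linked inheritance is a single category, not
subdivided by dominance. The dominant-vs-recessive contrast is a Fisher
test on (group vs comparison set) × (AD vs AR gene counts); the comparison
set defaults to all other disease genes pooled and can be narrowed to a
single group (e.g. DL vs DV).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with every latent variable recorded as ground truth:

1. each gene is latently lethal with `p_lethal` = 0.66 (the lethal fraction
   of reported knockouts) and receives a knockout report with
   `knockout_coverage` = 0.4 (the coverage observed among disease genes);
2. disease status is Bernoulli with odds multiplied by
   `lethal_disease_odds_multiplier` = 5 for lethal genes — the ratio implied
   by the observed group sizes (673/626 lethal vs 120/552 viable odds);
3. one cellular compartment per gene, drawn from essentiality-conditioned
   vectors (nucleus 0.58 for lethal vs 0.10 for viable genes; the nuclear
   concentration of essential proteins is the planted localization effect);
4. interaction edges follow a Chung–Lu fitness model: gene weight
   w = `degree_base`·exp(`beta_lethal`·1[lethal] + `beta_nuclear`·1[nuclear]),
   edge probability min(1, w_i·w_j/Σw). Both effects default to 0.5 on the
   log scale (≈ the observed lethal/viable average-degree ratio 3.9/2.3).
   Chung–Lu was chosen over preferential attachment because expected
   degrees are ≈ w in closed form, so network statistics can be checked
   against a brute-force expectation;
5. disease classes, inheritance modes and genicity are drawn from
   group-conditioned categorical vectors (cancer and multi-tissue classes
   and AD inheritance tilted toward lethal disease genes, AR toward
   viable; X below 10% everywhere; monogenic:polygenic ≈ 0.80:0.15);
6. each disease gene gets one text record: true class from the 70/10/20
   loss/gain/other `mechanism_mix`, tokens of Poisson length
   (`doc_length_mean` = 40) in which the true class's keywords carry
   `keyword_emission_odds` = 5:1 odds per word against a background
   vocabulary. Keyword emission is class-specific — other classes'
   keywords are not emitted spuriously. The vocabulary is synthetic
   (`w0001` …) with the matching lexicon emitted alongside, so classifier
   recovery is testable without English-language assumptions.

The default universe is `n_genes` = 4000, sized so that the planted effects
are detectable with comfortable power by the group contrasts the analysis
actually runs; smaller universes are used throughout the test suite where
only structural properties are at stake. All randomness flows from a single
seed through per-stage child streams, so identical configs regenerate
byte-identical files.

A separate deterministic fixture (`make_reference_fixture`) reproduces
the reference group sizes exactly (673/120/1172 disease genes, 626/552
non-disease knockouts, 64 of 609 housekeeping genes in DU against a
24,789-gene genome) so the tabulation stage can be checked against its exact
percentages without any randomness.

### What the generator does not emulate

Real interaction networks have heavy-tailed degree distributions, modular
community structure and study-bias correlations between annotation density
and interaction count; the generator's Chung–Lu model has none of these
beyond the two planted covariates. Real phenotype vocabularies, OMIM prose
and GO term structure are far richer than the synthetic stand-ins. Passing
recovery tests therefore shows that the pipeline detects the planted
effects under the assumed generative structure — it does not validate the
biological conclusions on real resources, which would require the live
databases.

## Validation strategy

* Deterministic fixture: tabulations reproduce the reference percentages
  exactly; chi-square on its two 2×2 contingency tables clears p < 0.05.
* Oracles: network summaries against an independent BFS/degree
  recomputation on random graphs; the Fisher p against exhaustive
  rational-arithmetic enumeration for every table with margins ≤ 30
  (agreement to 1e-12); the small-sample WMW p against full
  rank-assignment enumeration; BH against hand-applied step-up values and
  statsmodels.
* Calibration: on no-effect synthetic annotations the q < 0.05 call rate
  stays within the FDR bound; the WMW rejection rate on
  identically-distributed samples sits at the nominal α.
* Recovery: over 50 seeds at default effect sizes the pipeline detects
  lethal-disease enrichment, the DL > DV connectivity gap, DL nuclear
  over-representation (genome background), and the DL dominant-inheritance
  excess (DL vs DV) in ≥ 90% of seeds; on separable corpora both text
  classifiers agree with ground truth on ≥ 95% of records.

The DL nuclear and inheritance recovery checks deliberately use the
genome-wide background and the DL-vs-DV contrast respectively: the DU
group is itself mostly latently lethal, so a rest-of-disease background
shares the planted signal and would dilute any effect size worth
simulating.

## Known limitations

* Identifier reconciliation is out of scope: inputs must already share one
  identifier namespace, and no symbol/accession mapping is attempted.
* MeSH/disease-class construction and GO graph propagation are out of
  scope; class labels and slimmed annotations arrive pre-flattened.
* The DU group's essentiality is never predicted, only kept separate.
* Network and figure values computed from live resources are snapshot
  dependent (they change with every database release), and no canonical
  lexicon or training corpus exists for the mechanism classifiers. The
  acceptance machinery therefore substitutes exact oracles and recovery
  properties for snapshot-dependent numbers.
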