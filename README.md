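# essgenes

Essentiality-stratified characterization of human disease genes.

## The problem

Most surveys of human disease genes treat them as one homogeneous group, or
split them into "essential" and "non-essential" by lumping every gene
without a reported mouse knockout into the non-essential class. Because
only a small minority of mouse genes have been knocked out, that lumping
systematically overstates the non-essential share of disease genes and
distorts every downstream comparison.

`essgenes` implements the stratified analysis that avoids this: human genes
are classified by the phenotype of their mouse ortholog's targeted deletion
into

| group | definition |
|-------|------------|
| DL    | disease gene, ortholog knockout lethal ("disease lethal" — essential) |
| DV    | disease gene, ortholog knockout viable |
| DU    | disease gene, no knockout reported (kept **separate**, never merged into DV) |
| L / V | non-disease genes with lethal / viable knockouts |

and each group is then profiled along the axes where essential and
non-essential disease genes differ:

* **Protein–protein interaction connectivity** — per-group subnetworks under
  the one-or-both-endpoints rule, with degree, component and
  largest-connected-component statistics, and degree-distribution
  comparisons by Wilcoxon–Mann–Whitney and Kolmogorov–Smirnov tests.
* **Annotation enrichment** — disease classes and GO-slim style namespaces,
  tested per term as a 2×2 contrast of group vs background by Fisher's
  exact test (computed with exact integer arithmetic), with
  Benjamini–Hochberg FDR per namespace × group family.
* **Disease mechanism** — free-text records classified gain / loss / other
  by two independent methods (a stem-matching lexicon word score and a
  naive-Bayes classifier with frequent- and shared-word exclusion), with
  their agreement reported.
* **Mode of inheritance** — AD / AR / X tallies per group (a gene with both
  dominant and recessive alleles counts in both categories) and the
  dominant-vs-recessive Fisher contrast.

A synthetic-data generator (`essgenes.synth`) emits the complete flat-file
input set from a generative model with known ground truth — latent
essentiality, disease enrichment among lethal genes, a Chung–Lu interaction
network whose expected degree depends on lethality and nuclear
localization, group-tilted class/inheritance labels, and keyword-emitting
mechanism texts — so the whole pipeline can be exercised and validated
without any external database.

## Worked example

```python
import essgenes as eg

# A deterministic fixture with the reference group sizes used for validation
classified = eg.classify(eg.make_reference_fixture().gene_table())
counts = eg.tabulate(classified)
print({g.value: n for g, n in counts.counts.items() if n})
print(f"lethal share among known-essentiality disease genes: {counts.lethal_share_known:.1f}%")
print(f"lethal share among all knockouts: {counts.lethal_share_all_knockouts:.1f}%")
hk = eg.housekeeping_overlap(classified, genome_size=24789)
print(f"housekeeping: DU {hk.du_housekeeping_pct:.1f}% vs genome {hk.genome_housekeeping_pct:.1f}%")
```

prints

```
{'V': 552, 'L': 626, 'DV': 120, 'DL': 673, 'DU': 1172, 'NONDISEASE_UNKNOWN': 545}
lethal share among known-essentiality disease genes: 84.9%
lethal share among all knockouts: 65.9%
housekeeping: DU 5.5% vs genome 2.5%
```

Of the 793 disease genes with a knockout report, 673 (85%) are lethal —
far above the 66% lethal rate of knockouts overall — and the unknown-class
DU genes carry more than twice the genome-wide housekeeping rate,
both signs that essential genes are a major, under-annotated fraction of
disease genes.

The same analysis runs on generated data with known truth:

```python
ds = eg.generate(eg.SyntheticConfig(seed=42))
c2 = eg.classify(ds.gene_table())
net = eg.build_network(ds.edges)
print(eg.export_subnetworks(c2, net).to_string(index=False))
```

```
group  proteins  interactions  max_degree  avg_degree  components  lcc_protein_pct  lcc_interaction_pct  lcc_avg_degree
   DL      2446          3334          16         2.7          11             99.0                 99.0             2.7
   DV       415           331           9         1.6          84              6.0                  7.0             1.9
    L      2384          3100          18         2.6           9             99.0                 99.0             2.6
    V      1492          1375          11         1.8         133             59.0                 65.0             2.0
   DU      3159          5396          19         3.4           8             99.0                100.0             3.4
```

The planted effects surface exactly as in real data: DL proteins are more
connected than DV proteins, and the DL group is over-represented in the
nucleus (`eg.class_term_enrichment(c2, ds.annotations, [eg.Group.DL],
background="all_genes")` puts the nucleus term at q ≈ 2e-12, direction
"over").

A command-line interface wraps every stage
(`essgenes classify/network/enrich/mechanism/inherit/simulate/run`); the
full pipeline runs from one YAML config:

```sh
essgenes simulate --seed 42 -o inputs/
printf 'input_dir: inputs\noutput_dir: out\n' > run.yaml
essgenes run --config run.yaml
```

which writes `table1.tsv`, `table2.tsv`, per-namespace enrichment tables,
`mechanism.tsv`, `inheritance.tsv` and a `summary.json` with the headline
shares.

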