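"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emits the full flat-file input set (orthology, knockout
phenotypes, disease associations, housekeeping list, PPI edge list,
annotations, free-text mechanism records) together with the latent ground
truth for every gene and record, so every pipeline stage can be exercised
and checked against known parameters without any external resource.

The generative model, stage by stage:

1.  Every gene has a latent essentiality (lethal with ``p_lethal``); a
    knockout report exists with probability ``knockout_coverage`` and
    reveals it through phenotype term strings.
2.  Disease status is Bernoulli with odds = base odds ×
    ``lethal_disease_odds_multiplier`` for lethal genes — disease genes are
    enriched for essential orthologs.
3.  Each gene draws one cellular compartment from an essentiality-
    conditioned distribution (nuclear proteins concentrate among lethal
    genes).
4.  PPI edges follow a Chung–Lu fitness model: gene ``g`` has weight
    ``w_g = degree_base · exp(beta_lethal·1[lethal] + beta_nuclear·1[nuclear])``
    and pair ``(i, j)`` is an edge independently with probability
    ``min(1, w_i·w_j / Σw)``. Expected degrees are then ≈ ``w_g`` in closed
    form, which is what makes the network statistics testable against a
    brute-force expectation.
5.  Disease classes, inheritance modes and genicity are drawn from
    group-conditioned categorical distributions (dominant inheritance and
    cancer/multi-tissue classes tilted toward lethal disease genes).
6.  Each disease gene gets one free-text record whose true mechanism class
    is drawn from ``mechanism_mix``; tokens are a bag of Poisson-length
    draws in which the true class's keywords carry
    ``keyword_emission_odds : 1`` odds per word against a background
    vocabulary. Keywords are class-specific (other classes' keywords are
    not emitted). The vocabulary is synthetic (``w0001`` …), and the
    matching lexicon is emitted alongside the corpus.

All randomness flows from one seed through per-stage child streams, so
regenerating the dataset with the same config is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as eio
from .io import (
    AnnotationTable,
    DiseaseAssociation,
    EdgeList,
    EdgePair,
    GeneRecord,
    GeneTable,
    TextRecord,
)
from .mechanism import Lexicon

COMPARTMENTS = ("nucleus", "cytoplasm", "plasma membrane", "extracellular region", "mitochondrion")
DISEASE_CLASSES = ("multiple_tissues", "cancer", "neurological", "immune", "cardiovascular", "metabolic")

_LETHAL_PHENOTYPES = ("embryonic lethality", "prenatal lethality", "perinatal lethality", "postnatal lethality")
_VIABLE_PHENOTYPES = ("abnormal gait", "reduced body weight", "abnormal coat appearance", "no abnormal phenotype detected")


def _check_probs(name: str, vec: dict) -> None:
    vals = list(vec.values())
    if any(v < 0 or v > 1 for v in vals):
        raise ValueError(f"{name}: probabilities must lie in [0, 1]")
    if abs(sum(vals) - 1.0) > 1e-9:
        raise ValueError(f"{name}: probability vector must sum to 1 (got {sum(vals)!r})")


@dataclass
class SyntheticConfig:
    """Parameters of the generative model; defaults are the reference conditions.

    Rates mirror the magnitudes the real inputs exhibit: ~2/3 of reported
    knockouts lethal, ~40% knockout coverage among disease genes, a
    roughly five-fold disease-odds multiplier for lethal genes (the ratio
    implied by the reference group sizes), a ~2.5% housekeeping rate, degree
    effects of e^0.5 for lethality (the lethal-vs-viable average-degree
    ratio) and for nuclear localization, a 70/10/20 loss/gain/other
    mechanism mix, and dominant-tilted inheritance for lethal disease genes.
    """

    n_genes: int = 4000
    knockout_coverage: float = 0.4
    p_lethal: float = 0.66
    disease_rate_base: float = 0.18
    lethal_disease_odds_multiplier: float = 5.0
    housekeeping_rate: float = 0.025
    degree_base: float = 3.0
    beta_lethal: float = 0.5
    beta_nuclear: float = 0.5
    compartment_probs: dict = field(
        default_factory=lambda: {
            "lethal": {
                "nucleus": 0.58,
                "cytoplasm": 0.20,
                "plasma membrane": 0.12,
                "extracellular region": 0.05,
                "mitochondrion": 0.05,
            },
            "viable": {
                "nucleus": 0.10,
                "cytoplasm": 0.25,
                "plasma membrane": 0.35,
                "extracellular region": 0.20,
                "mitochondrion": 0.10,
            },
        }
    )
    disease_class_probs: dict = field(
        default_factory=lambda: {
            "lethal": {
                "multiple_tissues": 0.30,
                "cancer": 0.16,
                "neurological": 0.10,
                "immune": 0.09,
                "cardiovascular": 0.13,
                "metabolic": 0.22,
            },
            "viable": {
                "multiple_tissues": 0.12,
                "cancer": 0.04,
                "neurological": 0.22,
                "immune": 0.22,
                "cardiovascular": 0.05,
                "metabolic": 0.35,
            },
        }
    )
    mechanism_mix: dict = field(default_factory=lambda: {"loss": 0.70, "gain": 0.10, "neutral": 0.20})
    keyword_emission_odds: float = 5.0
    inheritance_probs: dict = field(
        default_factory=lambda: {
            "lethal": {"AD": 0.60, "AR": 0.32, "X": 0.08},
            "viable": {"AD": 0.30, "AR": 0.62, "X": 0.08},
        }
    )
    genicity_probs: dict = field(
        default_factory=lambda: {"monogenic": 0.80, "polygenic": 0.15, "unknown": 0.05}
    )
    doc_length_mean: float = 40.0
    n_background_words: int = 500
    n_keywords_per_class: int = 10
    orthology_coverage_uncovered: float = 0.5
    multi_disease_prob: float = 0.3
    training_label_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        scalars = {
            "knockout_coverage": self.knockout_coverage,
            "p_lethal": self.p_lethal,
            "disease_rate_base": self.disease_rate_base,
            "housekeeping_rate": self.housekeeping_rate,
            "orthology_coverage_uncovered": self.orthology_coverage_uncovered,
            "multi_disease_prob": self.multi_disease_prob,
            "training_label_fraction": self.training_label_fraction,
        }
        for name, v in scalars.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v!r}")
        for side in ("lethal", "viable"):
            _check_probs(f"compartment_probs[{side}]", self.compartment_probs[side])
            _check_probs(f"disease_class_probs[{side}]", self.disease_class_probs[side])
            _check_probs(f"inheritance_probs[{side}]", self.inheritance_probs[side])
        _check_probs("mechanism_mix", self.mechanism_mix)
        _check_probs("genicity_probs", self.genicity_probs)
        if self.degree_base <= 0 or self.keyword_emission_odds <= 0 or self.doc_length_mean <= 0:
            raise ValueError("degree_base, keyword_emission_odds and doc_length_mean must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")


@dataclass
class SyntheticDataset:
    """A generated input set plus the latent truth behind it."""

    config: Optional[SyntheticConfig]
    orthology: dict[str, str]
    phenotypes: dict[str, set[str]]
    associations: list[DiseaseAssociation]
    housekeeping: set[str]
    edges: EdgeList
    annotations: Optional[AnnotationTable]
    records: list[TextRecord]
    lexicon: Optional[Lexicon]
    ground_truth_genes: Optional[pd.DataFrame]
    ground_truth_records: Optional[pd.DataFrame]

    def gene_table(self) -> GeneTable:
        """The joined per-gene view, identical to reading the written files back."""
        disease_genes = {a.gene_id for a in self.associations}
        universe = set(self.orthology) | disease_genes | self.housekeeping
        records = {}
        for gid in sorted(universe):
            mg = self.orthology.get(gid, "")
            records[gid] = GeneRecord(
                gene_id=gid,
                mouse_ortholog=mg,
                ko_phenotypes=frozenset(self.phenotypes.get(mg, ())) if mg else frozenset(),
                is_disease=gid in disease_genes,
                is_housekeeping=gid in self.housekeeping,
            )
        return GeneTable(records)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        eio.write_orthology(out / "orthology.tsv", self.orthology)
        eio.write_phenotypes(out / "phenotypes.tsv", self.phenotypes)
        eio.write_disease_associations(out / "disease.tsv", self.associations)
        eio.write_housekeeping_list(out / "housekeeping.txt", self.housekeeping)
        eio.write_edge_list(out / "ppi.tsv", self.edges)
        if self.annotations is not None:
            eio.write_annotations(
                out / "annotations.tsv",
                self.annotations,
                eio.annotations_from_associations(self.associations),
            )
        eio.write_text_records(out / "records.tsv", self.records)
        if self.lexicon is not None:
            import yaml

            with open(out / "lexicon.yaml", "w", encoding="utf-8") as fh:
                yaml.safe_dump({c: sorted(s) for c, s in self.lexicon.stems.items()}, fh)
        if self.ground_truth_genes is not None:
            self.ground_truth_genes.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        if self.ground_truth_records is not None:
            self.ground_truth_records.to_csv(out / "ground_truth_records.tsv", sep="\t", index=False)


def expected_mean_degree(weights: np.ndarray) -> float:
    """Brute-force expected mean degree of the fitness model: (2/n)·Σ_{i<j} p_ij."""
    s = weights.sum()
    n = len(weights)
    total = 0.0
    for i in range(n):
        p = np.minimum(1.0, weights[i] * weights[i + 1 :] / s)
        total += p.sum()
    return 2.0 * total / n


def _sample_edges(weights: np.ndarray, rng: np.random.Generator, block: int = 512) -> list[tuple[int, int]]:
    """Independent Bernoulli edges with p = min(1, w_i w_j / Σw), i < j."""
    n = len(weights)
    s = weights.sum()
    out: list[tuple[int, int]] = []
    for start in range(0, n, block):
        stop = min(start + block, n)
        p = np.minimum(1.0, np.outer(weights[start:stop], weights) / s)
        u = rng.random(p.shape)
        rows, cols = np.nonzero(u < p)
        for r, c in zip(rows, cols):
            i = start + int(r)
            if i < c:
                out.append((i, int(c)))
    return out


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one complete dataset from the generative model."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_gene, rng_net, rng_assoc, rng_text = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    n = config.n_genes
    width = max(5, len(str(n)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n)]

    # --- stage 1/2: latent essentiality, knockout coverage, disease status
    lethal = rng_gene.random(n) < config.p_lethal
    covered = rng_gene.random(n) < config.knockout_coverage
    base_odds = config.disease_rate_base / (1.0 - config.disease_rate_base)
    odds = np.where(lethal, base_odds * config.lethal_disease_odds_multiplier, base_odds)
    disease = rng_gene.random(n) < odds / (1.0 + odds)
    housekeeping_mask = rng_gene.random(n) < config.housekeeping_rate

    # --- stage 3: compartments
    comp_idx = np.empty(n, dtype=int)
    for side, mask in (("lethal", lethal), ("viable", ~lethal)):
        probs = np.array([config.compartment_probs[side][c] for c in COMPARTMENTS])
        k = int(mask.sum())
        comp_idx[mask] = rng_gene.choice(len(COMPARTMENTS), size=k, p=probs / probs.sum())
    compartment = np.array(COMPARTMENTS, dtype=object)[comp_idx]
    nuclear = compartment == "nucleus"

    # orthology / phenotypes
    has_ortholog = covered | (rng_gene.random(n) < config.orthology_coverage_uncovered)
    orthology = {g: f"m{g[1:]}" for g, h in zip(gene_ids, has_ortholog) if h}
    phenotypes: dict[str, set[str]] = {}
    for i, g in enumerate(gene_ids):
        if not covered[i]:
            continue
        pool = _LETHAL_PHENOTYPES if lethal[i] else _VIABLE_PHENOTYPES
        terms = {pool[int(rng_gene.integers(len(pool)))]}
        if rng_gene.random() < 0.3:  # a second, non-lethal allele report
            terms.add(_VIABLE_PHENOTYPES[int(rng_gene.integers(len(_VIABLE_PHENOTYPES)))])
        phenotypes[orthology[g]] = terms

    # --- stage 4: Chung-Lu network
    weights = config.degree_base * np.exp(
        config.beta_lethal * lethal.astype(float) + config.beta_nuclear * nuclear.astype(float)
    )
    edge_idx = _sample_edges(weights, rng_net)
    edges = EdgeList([EdgePair(gene_ids[i], gene_ids[j], "sim") for i, j in edge_idx])

    # --- annotations (cellular compartment namespace)
    annotations = AnnotationTable(namespace="cellular_component")
    for g, c in zip(gene_ids, compartment):
        annotations.add(g, str(c))

    # --- stage 5: disease associations
    classes = list(DISEASE_CLASSES)
    modes = list(eio.INHERITANCE_MODES)
    gens = list(eio.GENICITIES)
    associations: list[DiseaseAssociation] = []
    disease_gene_ids = [g for g, d in zip(gene_ids, disease) if d]
    lethal_by_gene = dict(zip(gene_ids, lethal))
    d_counter = 0
    for g in disease_gene_ids:
        side = "lethal" if lethal_by_gene[g] else "viable"
        cls_p = np.array([config.disease_class_probs[side][c] for c in classes])
        inh_p = np.array([config.inheritance_probs[side][m] for m in modes])
        gen_p = np.array([config.genicity_probs[x] for x in gens])
        n_assoc = 1 + int(rng_assoc.random() < config.multi_disease_prob)
        for _ in range(n_assoc):
            d_counter += 1
            associations.append(
                DiseaseAssociation(
                    gene_id=g,
                    disease_id=f"D{d_counter:06d}",
                    disease_class=classes[int(rng_assoc.choice(len(classes), p=cls_p / cls_p.sum()))],
                    inheritance_mode=modes[int(rng_assoc.choice(len(modes), p=inh_p / inh_p.sum()))],
                    genicity=gens[int(rng_assoc.choice(len(gens), p=gen_p / gen_p.sum()))],
                )
            )

    housekeeping = {g for g, h in zip(gene_ids, housekeeping_mask) if h}

    # --- stage 6: mechanism texts (one record per disease gene)
    lexicon = Lexicon(
        {
            cat: {f"{cat}kw"}
            for cat in ("gain", "loss", "neutral")
        }
    )
    background = [f"w{i + 1:04d}" for i in range(config.n_background_words)]
    keywords = {
        cat: [f"{cat}kw{i + 1:02d}" for i in range(config.n_keywords_per_class)]
        for cat in ("gain", "loss", "neutral")
    }
    mix_cats = ("loss", "gain", "neutral")
    mix_p = np.array([config.mechanism_mix[c] for c in mix_cats])
    kw_mass = config.n_keywords_per_class * config.keyword_emission_odds
    p_keyword = kw_mass / (kw_mass + config.n_background_words)
    records: list[TextRecord] = []
    truth_rows = []
    for g in disease_gene_ids:
        true_cat = mix_cats[int(rng_text.choice(len(mix_cats), p=mix_p / mix_p.sum()))]
        length = max(1, int(rng_text.poisson(config.doc_length_mean)))
        is_kw = rng_text.random(length) < p_keyword
        toks = [
            keywords[true_cat][int(rng_text.integers(config.n_keywords_per_class))]
            if kw
            else background[int(rng_text.integers(config.n_background_words))]
            for kw in is_kw
        ]
        labeled = rng_text.random() < config.training_label_fraction
        rid = f"R{g[1:]}"
        records.append(TextRecord(rid, g, " ".join(toks), true_cat if labeled else None))
        truth_rows.append({"record_id": rid, "gene_id": g, "true_class": true_cat, "labeled": labeled})

    ground_truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "lethal": lethal,
            "covered": covered,
            "disease": disease,
            "housekeeping": housekeeping_mask,
            "compartment": compartment,
            "weight": weights,
        }
    )
    ground_truth_records = pd.DataFrame(
        truth_rows, columns=["record_id", "gene_id", "true_class", "labeled"]
    )
    return SyntheticDataset(
        config=config,
        orthology=orthology,
        phenotypes=phenotypes,
        associations=associations,
        housekeeping=housekeeping,
        edges=edges,
        annotations=annotations,
        records=records,
        lexicon=lexicon,
        ground_truth_genes=ground_truth_genes,
        ground_truth_records=ground_truth_records,
    )


def make_reference_fixture() -> SyntheticDataset:
    """A deterministic fixture with the reference group sizes.

    673 disease-lethal, 120 disease-viable and 1172 disease-unknown genes;
    626 non-disease lethal and 552 non-disease viable knockouts (totals 1299
    lethal / 672 viable); 609 housekeeping genes of which 64 fall in the
    disease-unknown set, against a 24,789-gene genome. Tabulating this
    fixture reproduces the headline shares exactly (85% lethal among
    known-essentiality disease genes, 66% lethal among all knockouts, 34%/6%
    DL/DV shares, 5.5% vs 2.5% housekeeping rates). No randomness involved.
    """
    sizes = {"DL": 673, "DV": 120, "DU": 1172, "L": 626, "V": 552}
    ids = {k: [f"{k}{i + 1:04d}" for i in range(n)] for k, n in sizes.items()}

    orthology: dict[str, str] = {}
    phenotypes: dict[str, set[str]] = {}
    for grp in ("DL", "DV", "L", "V"):
        for g in ids[grp]:
            m = f"m{g}"
            orthology[g] = m
            phenotypes[m] = (
                {"embryonic lethality"} if grp in ("DL", "L") else {"abnormal gait"}
            )

    associations = [
        DiseaseAssociation(gene_id=g, disease_id=f"OMIM{g}")
        for grp in ("DL", "DV", "DU")
        for g in ids[grp]
    ]
    housekeeping = set(ids["DU"][:64]) | {f"HK{i + 1:04d}" for i in range(545)}

    return SyntheticDataset(
        config=None,
        orthology=orthology,
        phenotypes=phenotypes,
        associations=associations,
        housekeeping=housekeeping,
        edges=EdgeList([]),
        annotations=None,
        records=[],
        lexicon=None,
        ground_truth_genes=None,
        ground_truth_records=None,
    )
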