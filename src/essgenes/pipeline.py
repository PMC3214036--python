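"""One-command orchestration of the whole analysis on a directory of inputs.

Stages run in method order — classification, network statistics, annotation
enrichment, mechanism text classification, inheritance tallies — each
emitting a plain TSV, plus one JSON summary with the headline shares and a
log of per-stage row counts. All outputs are deterministic functions of the
inputs and the config, so re-running yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as eio
from .classify import (
    DEFAULT_GENOME_SIZE,
    DEFAULT_LETHAL_TERMS,
    Group,
    classify,
    group_counts_frame,
    housekeeping_overlap,
    round_half_up,
    tabulate,
)
from .inheritance import dominant_vs_recessive_test, inheritance_frame, tally
from .mechanism import Lexicon, calls_frame, classify_corpus, default_lexicon, train_nb
from .network import build_network, export_subnetworks
from .stats import chi_square_2x2, class_term_enrichment, enrichment_frame

logger = logging.getLogger("essgenes")

#: Annotation namespaces tested for enrichment when present in the inputs.
ENRICHMENT_NAMESPACES = ("disease_class", "cellular_component", "molecular_function", "biological_process")


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, loadable from YAML."""

    input_dir: str
    output_dir: str
    genome_size: int = DEFAULT_GENOME_SIZE
    lethal_terms: list[str] = field(default_factory=lambda: sorted(DEFAULT_LETHAL_TERMS))
    background: str = "all_disease"
    fdr_alpha: float = 0.05
    genicity_filter: str = "monogenic_only"
    lexicon_path: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError(f"fdr_alpha must lie in (0, 1), got {self.fdr_alpha}")
        indir = Path(self.input_dir)
        for name in ("orthology.tsv", "phenotypes.tsv", "disease.tsv", "housekeeping.txt", "ppi.tsv"):
            if not (indir / name).is_file():
                raise FileNotFoundError(f"missing input file: {indir / name}")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the JSON summary."""
    config.validate()
    indir, outdir = Path(config.input_dir), Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    logger.info("run config %s on %s", config.digest(), indir)

    summary: dict = {"config_hash": config.digest(), "stages": {}}

    # --- classification
    stage = "classification"
    try:
        table = eio.read_gene_table(
            indir / "orthology.tsv", indir / "phenotypes.tsv", indir / "disease.tsv", indir / "housekeeping.txt"
        )
        classified = classify(table, config.lethal_terms)
        counts = tabulate(classified)
        hk = housekeeping_overlap(classified, config.genome_size)
        group_counts_frame(counts).to_csv(outdir / "table1.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc
    hk_chi2_stat, hk_chi2_p = chi_square_2x2(hk.table)
    summary["stages"][stage] = {"n_genes": len(table)}
    summary["headline_shares_pct"] = {
        "lethal_share_known_disease": _r(counts.lethal_share_known),
        "lethal_share_all_knockouts": _r(counts.lethal_share_all_knockouts),
        "dl_share_of_disease": _r(counts.dl_share_of_disease),
        "dv_share_of_disease": _r(counts.dv_share_of_disease),
    }
    summary["housekeeping"] = {
        "du_pct": round_half_up(hk.du_housekeeping_pct, 1),
        "genome_pct": round_half_up(hk.genome_housekeeping_pct, 1),
        "table": hk.table,
        "chi2_p": hk_chi2_p,
    }
    logger.info("classified %d genes; counts %s", len(table), {g.value: c for g, c in counts.counts.items()})

    # --- network
    stage = "network"
    try:
        edges = eio.read_edge_list(indir / "ppi.tsv")
        network = build_network(edges)
        table2 = export_subnetworks(classified, network, outdir)
        table2.to_csv(outdir / "table2.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc
    summary["stages"][stage] = {
        "raw_pairs": len(edges),
        "proteins": network.number_of_nodes(),
        "interactions": network.number_of_edges(),
    }

    # --- enrichment
    stage = "enrichment"
    try:
        assocs = eio.read_disease_associations(indir / "disease.tsv")
        namespaces: dict[str, eio.AnnotationTable] = {}
        dc = eio.annotations_from_associations(assocs)
        if dc.entries:
            namespaces["disease_class"] = dc
        ann_path = indir / "annotations.tsv"
        if ann_path.is_file():
            for ns in ENRICHMENT_NAMESPACES[1:]:
                t = eio.read_annotations(ann_path, ns)
                if t.entries:
                    namespaces[ns] = t
        n_results = 0
        for ns, ann in namespaces.items():
            results = class_term_enrichment(classified, ann, [Group.DL, Group.DV, Group.DU], config.background)
            enrichment_frame(results).to_csv(outdir / f"enrichment_{ns}.tsv", sep="\t", index=False)
            n_results += len(results)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc
    summary["stages"][stage] = {"namespaces": sorted(namespaces), "n_tests": n_results}

    # --- mechanism
    stage = "mechanism"
    records_path = indir / "records.tsv"
    records = eio.read_text_records(records_path) if records_path.is_file() else []
    if not any(r.known_label for r in records):
        logger.info("mechanism stage skipped: no labeled records to train on")
    else:
        try:
            if config.lexicon_path:
                lexicon = Lexicon.from_yaml(config.lexicon_path)
            elif (indir / "lexicon.yaml").is_file():
                lexicon = Lexicon.from_yaml(indir / "lexicon.yaml")
            else:
                lexicon = default_lexicon()
            model = train_nb([r for r in records if r.known_label])
            corpus = classify_corpus(records, lexicon, model, classified, assocs, config.genicity_filter)
            calls_frame(corpus).to_csv(outdir / "mechanism.tsv", sep="\t", index=False)
            corpus.proportions.to_csv(outdir / "mechanism_proportions.tsv", sep="\t", index=False)
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc
        summary["stages"][stage] = {
            "n_records": len(records),
            "method_agreement": corpus.agreement_rate,
        }

    # --- inheritance
    stage = "inheritance"
    try:
        inh = tally(classified, assocs)
        inheritance_frame(inh).to_csv(outdir / "inheritance.tsv", sep="\t", index=False)
        try:
            odds, p = dominant_vs_recessive_test(inh, Group.DL)
            summary["inheritance_dl_ad_vs_ar"] = {"odds_ratio": odds, "p": p}
        except ValueError:
            summary["inheritance_dl_ad_vs_ar"] = None  # empty margin: no annotated modes
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc
    summary["stages"][stage] = {
        "n_annotated_genes": sum(gi.n_annotated for gi in inh.per_group.values())
    }

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _r(x: Optional[float]) -> Optional[float]:
    return None if x is None else round_half_up(x, 1)
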