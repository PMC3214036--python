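"""Essentiality classification of human genes from mouse knockout phenotypes.

Human orthologs of mouse genes whose targeted deletion is lethal are treated
as essential. Disease genes split into DL (lethal ortholog knockout), DV
(viable knockout) and DU (no knockout reported); non-disease genes with
knockout data are L or V, and the remainder have unknown essentiality. The
key point of the grouping is that DU is kept separate: lumping unreported
genes into the viable class overstates the non-essential share of disease
genes, because only a small minority of mouse genes have been knocked out.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Iterator, Optional

from .io import GeneRecord, GeneTable

#: Lethal-phenotype stems, matched case-insensitively as substrings of
#: phenotype term strings. Phenotype vocabularies phrase lethality both ways
#: round ("embryonic lethality", "lethality, embryonic"), so the generic
#: "lethality" stem backstops the stage-specific stems.
DEFAULT_LETHAL_TERMS = frozenset(
    {
        "embryonic lethal",
        "prenatal lethal",
        "perinatal lethal",
        "postnatal lethal",
        "lethality",
    }
)

#: Human genome size used for genome-wide rates (protein-coding loci count
#: contemporary with the housekeeping list). Configurable; never inferred
#: from input files, which cover only annotated genes.
DEFAULT_GENOME_SIZE = 24789


class Group(str, enum.Enum):
    """Essentiality groups. D (all disease) is the union DL ∪ DV ∪ DU."""

    V = "V"
    L = "L"
    DV = "DV"
    DL = "DL"
    DU = "DU"
    NONDISEASE_UNKNOWN = "NONDISEASE_UNKNOWN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


DISEASE_GROUPS = (Group.DL, Group.DV, Group.DU)


class Essentiality(str, enum.Enum):
    LETHAL = "lethal"
    VIABLE = "viable"
    UNKNOWN = "unknown"


def is_lethal(
    phenotype_terms: Iterable[str],
    lethal_terms: Iterable[str] = DEFAULT_LETHAL_TERMS,
) -> Essentiality:
    """Decide lethality from a gene's knockout phenotype reports.

    Any-lethal-wins: one lethal report among several alleles/papers makes the
    gene lethal (a deterministic stand-in for the original manual redundancy
    removal). A gene with reports but no lethal match is viable; a gene with
    no reports at all has unknown essentiality.
    """
    stems = [t.lower() for t in lethal_terms]
    if not stems:
        raise ValueError("lethal-term set must be non-empty")
    terms = list(phenotype_terms)
    if not terms:
        return Essentiality.UNKNOWN
    for term in terms:
        low = term.lower()
        if any(stem in low for stem in stems):
            return Essentiality.LETHAL
    return Essentiality.VIABLE


@dataclass
class ClassifiedGeneTable:
    """A GeneTable plus the per-gene essentiality group assignment."""

    table: GeneTable
    groups: dict[str, Group]

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.table)

    def group_of(self, gene_id: str) -> Group:
        return self.groups[gene_id]

    def members(self, group: Group) -> set[str]:
        return {g for g, grp in self.groups.items() if grp is group}

    def disease_genes(self) -> set[str]:
        return {g for g, grp in self.groups.items() if grp in DISEASE_GROUPS}


def classify(
    table: GeneTable,
    lethal_terms: Iterable[str] = DEFAULT_LETHAL_TERMS,
) -> ClassifiedGeneTable:
    """Assign every gene its essentiality group.

    Disease genes land in exactly one of DL/DV/DU; non-disease genes in
    L/V/NONDISEASE_UNKNOWN. The assignment of one gene depends only on its
    own record, so the grouping is a partition and edits are local.
    """
    stems = tuple(lethal_terms)
    groups: dict[str, Group] = {}
    for rec in table:
        ess = is_lethal(rec.ko_phenotypes, stems)
        if rec.is_disease:
            groups[rec.gene_id] = {
                Essentiality.LETHAL: Group.DL,
                Essentiality.VIABLE: Group.DV,
                Essentiality.UNKNOWN: Group.DU,
            }[ess]
        else:
            groups[rec.gene_id] = {
                Essentiality.LETHAL: Group.L,
                Essentiality.VIABLE: Group.V,
                Essentiality.UNKNOWN: Group.NONDISEASE_UNKNOWN,
            }[ess]
    return ClassifiedGeneTable(table, groups)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (2.5 -> 3), as used in the report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class GroupCounts:
    """Group sizes plus the headline shares, as percentages.

    Shares are ``None`` when their denominator is empty. ``lethal_share_known``
    is DL/(DL+DV) — the lethal fraction of disease genes whose essentiality is
    known; ``lethal_share_all_knockouts`` is (DL+L)/(DL+L+DV+V) over every gene
    with a knockout report; the two disease shares are over all disease genes.
    """

    counts: dict[Group, int] = field(default_factory=dict)
    lethal_share_known: Optional[float] = None
    lethal_share_all_knockouts: Optional[float] = None
    dl_share_of_disease: Optional[float] = None
    dv_share_of_disease: Optional[float] = None

    @property
    def n_disease(self) -> int:
        return sum(self.counts.get(g, 0) for g in DISEASE_GROUPS)


def _pct(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def tabulate(classified: ClassifiedGeneTable) -> GroupCounts:
    """Count genes per group and derive the headline percentage shares."""
    counts = {g: 0 for g in Group}
    for grp in classified.groups.values():
        counts[grp] += 1
    dl, dv, du = counts[Group.DL], counts[Group.DV], counts[Group.DU]
    l_total = counts[Group.L] + dl
    v_total = counts[Group.V] + dv
    d_total = dl + dv + du
    return GroupCounts(
        counts=counts,
        lethal_share_known=_pct(dl, dl + dv),
        lethal_share_all_knockouts=_pct(l_total, l_total + v_total),
        dl_share_of_disease=_pct(dl, d_total),
        dv_share_of_disease=_pct(dv, d_total),
    )


@dataclass
class HousekeepingOverlap:
    """DU × housekeeping contingency table against the whole genome.

    ``table`` rows are (DU, not-DU), columns (housekeeping, not housekeeping);
    the not-DU row is completed against the configured genome size, since the
    genome-wide housekeeping rate is a property of the genome, not of the
    genes that happen to appear in the input files.
    """

    table: list[list[int]]
    du_housekeeping_pct: float
    genome_housekeeping_pct: float
    odds_ratio: Optional[float]


def housekeeping_overlap(
    classified: ClassifiedGeneTable,
    genome_size: int = DEFAULT_GENOME_SIZE,
) -> HousekeepingOverlap:
    if genome_size < len(classified):
        raise ValueError(
            f"genome size {genome_size} smaller than the {len(classified)} observed genes"
        )
    du = classified.members(Group.DU)
    hk_all = {r.gene_id for r in classified if r.is_housekeeping}
    a = len(du & hk_all)  # DU and housekeeping
    b = len(du) - a  # DU, not housekeeping
    c = len(hk_all) - a  # housekeeping outside DU
    d = genome_size - len(du) - c
    du_pct = _pct(a, a + b) or 0.0
    genome_pct = _pct(a + c, genome_size) or 0.0
    odds = (a * d) / (b * c) if b * c > 0 else None
    return HousekeepingOverlap([[a, b], [c, d]], du_pct, genome_pct, odds)


def group_counts_frame(counts: GroupCounts):
    """Tabulated counts and shares as a tidy DataFrame (machine-readable, 1 dp)."""
    import pandas as pd

    rows = [{"group": g.value, "n_genes": counts.counts.get(g, 0)} for g in Group]
    shares = {
        "lethal_share_known_pct": counts.lethal_share_known,
        "lethal_share_all_knockouts_pct": counts.lethal_share_all_knockouts,
        "dl_share_of_disease_pct": counts.dl_share_of_disease,
        "dv_share_of_disease_pct": counts.dv_share_of_disease,
    }
    df = pd.DataFrame(rows)
    for k, v in shares.items():
        df[k] = "" if v is None else round_half_up(v, 1)
    return df
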