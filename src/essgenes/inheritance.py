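"""Mode-of-inheritance tallies per essentiality group.

Every allele with a described inheritance pattern counts, so a gene with
distinct dominant and recessive mutations appears in both the AD and the AR
category. Proportions are therefore over category assignments within the set
of genes that carry any inheritance annotation, and need not sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .classify import ClassifiedGeneTable, Group, DISEASE_GROUPS
from .io import DiseaseAssociation, INHERITANCE_MODES
from .stats import fisher_2x2


@dataclass
class GroupInheritance:
    counts: dict[str, int]  # mode -> number of genes with >=1 allele of that mode
    n_annotated: int  # genes in the group with any inheritance annotation

    def proportion(self, mode: str) -> Optional[float]:
        if self.n_annotated == 0:
            return None
        return self.counts[mode] / self.n_annotated


@dataclass
class InheritanceTally:
    per_group: dict[Group, GroupInheritance]


def tally(classified: ClassifiedGeneTable, associations: Sequence[DiseaseAssociation]) -> InheritanceTally:
    """Count, per group, genes with ≥1 AD / AR / X allele.

    Duplicate association rows are harmless (set semantics per gene × mode);
    genes without any annotated mode do not enter the denominators.
    """
    gene_modes: dict[str, set[str]] = {}
    for a in associations:
        if a.inheritance_mode:
            gene_modes.setdefault(a.gene_id, set()).add(a.inheritance_mode)

    per_group: dict[Group, GroupInheritance] = {}
    for group in list(DISEASE_GROUPS) + [Group.L, Group.V]:
        members = classified.members(group)
        annotated = {g for g in members if gene_modes.get(g)}
        counts = {m: sum(1 for g in annotated if m in gene_modes[g]) for m in INHERITANCE_MODES}
        per_group[group] = GroupInheritance(counts, len(annotated))
    return InheritanceTally(per_group)


def dominant_vs_recessive_test(
    tally_result: InheritanceTally,
    group: Group = Group.DL,
    versus: Optional[Group] = None,
) -> tuple[float, float]:
    """Fisher test of AD-vs-AR balance in one group against a comparison set.

    Rows of the 2×2 are (group, comparison), columns (AD assignments, AR
    assignments). ``versus=None`` compares against all other disease groups
    pooled; passing a Group compares against that group alone.
    Returns ``(odds_ratio, p)``.
    """
    g = tally_result.per_group[group]
    if versus is None:
        others = [tally_result.per_group[x] for x in DISEASE_GROUPS if x is not group]
    else:
        others = [tally_result.per_group[versus]]
    ad_rest = sum(o.counts["AD"] for o in others)
    ar_rest = sum(o.counts["AR"] for o in others)
    table = [[g.counts["AD"], g.counts["AR"]], [ad_rest, ar_rest]]
    if any(sum(row) == 0 for row in table) or any(
        table[0][j] + table[1][j] == 0 for j in range(2)
    ):
        raise ValueError(f"empty margin in AD/AR contrast for {group.value}: {table}")
    return fisher_2x2(table)


def inheritance_frame(tally_result: InheritanceTally):
    """Tally as a tidy DataFrame (one row per group)."""
    import pandas as pd

    rows = []
    for group, gi in tally_result.per_group.items():
        row: dict[str, object] = {"group": group.value, "n_annotated": gi.n_annotated}
        for m in INHERITANCE_MODES:
            row[f"{m}_count"] = gi.counts[m]
            prop = gi.proportion(m)
            row[f"{m}_proportion"] = "" if prop is None else prop
        rows.append(row)
    return pd.DataFrame(rows)
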