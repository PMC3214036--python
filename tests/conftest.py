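import pytest

import essgenes as eg
from essgenes.io import DiseaseAssociation, GeneRecord, GeneTable


def make_gene_table(spec):
    """Build a GeneTable from (gene_id, phenotypes, is_disease, is_housekeeping) tuples."""
    records = {}
    for gid, phen, disease, hk in spec:
        records[gid] = GeneRecord(
            gene_id=gid,
            mouse_ortholog=f"m_{gid}" if phen else "",
            ko_phenotypes=frozenset(phen),
            is_disease=disease,
            is_housekeeping=hk,
        )
    return GeneTable(records)


@pytest.fixture
def twelve_gene_table():
    """4 disease-lethal, 2 disease-viable, 3 disease-unknown, 2 lethal, 1 viable."""
    spec = (
        [(f"dl{i}", {"embryonic lethality"}, True, False) for i in range(4)]
        + [(f"dv{i}", {"abnormal gait"}, True, False) for i in range(2)]
        + [(f"du{i}", set(), True, False) for i in range(3)]
        + [(f"l{i}", {"prenatal lethality"}, False, False) for i in range(2)]
        + [("v0", {"reduced body weight"}, False, False)]
    )
    return make_gene_table(spec)


@pytest.fixture
def twelve_gene_classified(twelve_gene_table):
    return eg.classify(twelve_gene_table)


@pytest.fixture(scope="session")
def reference_fixture_classified():
    dataset = eg.make_reference_fixture()
    return eg.classify(dataset.gene_table())


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared by read-only tests."""
    return eg.generate(eg.SyntheticConfig(n_genes=800, seed=11))


def assoc(gene_id, disease_id="d1", **kw):
    return DiseaseAssociation(gene_id=gene_id, disease_id=disease_id, **kw)
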