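import numpy as np
import pandas as pd
import pytest

from cnvar.io_preprocess import AbundanceMatrix

# Tiny cellular_component ontology: a mitochondrion subtree (chain of depth 3
# and a diamond), an unrelated nucleus branch, an obsolete term and a term in
# another namespace.
TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: GO:0005575
name: cellular_component
namespace: cellular_component

[Term]
id: GO:0005739
name: mitochondrion
namespace: cellular_component
is_a: GO:0005575

[Term]
id: GO:0005743
name: mitochondrial inner membrane
namespace: cellular_component
is_a: GO:0005739

[Term]
id: GO:0005747
name: respiratory chain complex I
namespace: cellular_component
is_a: GO:0005743

[Term]
id: GO:0099999
name: diamond term
namespace: cellular_component
is_a: GO:0005743
relationship: part_of GO:0005747

[Term]
id: GO:0005634
name: nucleus
namespace: cellular_component
is_a: GO:0005575

[Term]
id: GO:0031965
name: nuclear membrane
namespace: cellular_component
relationship: part_of GO:0005634

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0999001
name: defunct organelle
namespace: cellular_component
is_obsolete: true
"""

TOY_GAF = """\
!gaf-version: 2.1
UniProtKB\tP00001\tMITO1\t\tGO:0005747\tPMID:1\tIDA\t\tC\t\t\tprotein\ttaxon:9606\t20180101\tUniProt
UniProtKB\tP00002\tMITO2\t\tGO:0005743\tPMID:1\tIEA\t\tC\t\t\tprotein\ttaxon:9606\t20180101\tUniProt
UniProtKB\tP00003\tNUC1\t\tGO:0031965\tPMID:1\tIDA\t\tC\t\t\tprotein\ttaxon:9606\t20180101\tUniProt
UniProtKB\tP00004\tNOTME\tNOT\tGO:0005739\tPMID:1\tIDA\t\tC\t\t\tprotein\ttaxon:9606\t20180101\tUniProt
UniProtKB\tP00005-2\tISO\t\tGO:0005634\tPMID:1\tIDA\t\tC\t\t\tprotein\ttaxon:9606\t20180101\tUniProt
"""


@pytest.fixture
def toy_obo(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


@pytest.fixture
def toy_gaf(tmp_path):
    path = tmp_path / "toy.gaf"
    path.write_text(TOY_GAF)
    return path


def make_matrix(values: dict, conditions: dict, proteins=None) -> AbundanceMatrix:
    """Build an AbundanceMatrix from {sample: column values} plus
    {sample: condition}; replicate indices are assigned per condition in
    sample order."""
    df = pd.DataFrame(values)
    if proteins is not None:
        df.index = pd.Index(proteins, name="protein")
    else:
        df.index = pd.Index([f"p{i}" for i in range(len(df))], name="protein")
    seen: dict = {}
    rows = []
    for s in df.columns:
        cond = conditions[s]
        seen[cond] = seen.get(cond, 0) + 1
        rows.append((s, cond, seen[cond]))
    design = pd.DataFrame(rows, columns=["sample", "condition", "replicate"]).set_index("sample")
    return AbundanceMatrix(values=df, design=design)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
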