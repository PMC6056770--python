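"""Protein-to-compartment assignment from GO cellular-component terms.

Ten canonical compartments are defined by their root GO terms; each root is
expanded to the full set of offspring terms (transitive closure over is_a and
part_of within the cellular_component namespace), and a protein belongs to a
compartment when any of its GO terms falls inside the expanded set. A protein
may belong to several compartments and then takes part in each compartment's
analysis independently. A two-column custom grouping (e.g. a curated organelle
catalogue or protein-complex membership) can replace GO entirely.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass

import networkx as nx
import obonet
import pandas as pd

from cnvar.errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: Root GO cellular-component terms of the ten canonical compartments.
TEN_COMPARTMENTS: dict[str, tuple[str, ...]] = {
    "nucleus": ("GO:0005634",),
    "cytoplasm": ("GO:0005737",),
    "mitochondrion": ("GO:0005739",),
    "extracellular": ("GO:0005576", "GO:0031012", "GO:0044421", "GO:0044420"),
    "peroxisome": ("GO:0005777",),
    "lysosome": ("GO:0005764",),
    "endoplasmic_reticulum": ("GO:0005783",),
    "golgi_apparatus": ("GO:0005794",),
    "cell_membrane": ("GO:0005886",),
    "nuclear_membrane": ("GO:0031965",),
}

#: The four compartments that cover ~96% of annotated proteins in typical data.
FOUR_MAJOR_COMPARTMENTS: tuple[str, ...] = (
    "nucleus", "cytoplasm", "mitochondrion", "extracellular",
)

_OFFSPRING_RELATIONS = ("is_a", "part_of")


@dataclass
class CompartmentDefinition:
    """A named compartment: root GO term(s) plus the expanded offspring set."""

    name: str
    roots: tuple[str, ...]
    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms.issuperset(self.roots):
            raise ConfigurationError(
                f"compartment {self.name}: expanded set must contain its roots"
            )


@dataclass
class CompartmentAnnotation:
    """protein id -> set of compartment (or custom group) names."""

    mapping: dict[str, frozenset[str]]
    provenance: str = "go"  # "go" or "custom"

    def compartments(self) -> list[str]:
        names: set[str] = set()
        for s in self.mapping.values():
            names |= s
        return sorted(names)

    def proteins_in(self, compartment: str) -> list[str]:
        return [p for p, s in self.mapping.items() if compartment in s]

    def get(self, protein: str) -> frozenset[str]:
        return self.mapping.get(protein, frozenset())


def parse_ontology(obo_path) -> nx.DiGraph:
    """Parse an OBO ontology into a child->parent DAG.

    Only the ``cellular_component`` namespace is kept, with ``is_a`` and
    ``part_of`` edges; obsolete terms are excluded.
    """
    try:
        graph = obonet.read_obo(obo_path, ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise InputError(f"cannot parse OBO file {obo_path}: {exc}") from exc

    cc = nx.DiGraph()
    for node, data in graph.nodes(data=True):
        if data.get("namespace", "cellular_component") != "cellular_component":
            continue
        cc.add_node(node, name=data.get("name", ""))
    for child, parent, key in graph.edges(keys=True):
        if key in _OFFSPRING_RELATIONS and child in cc and parent in cc:
            cc.add_edge(child, parent, relation=key)
    if not nx.is_directed_acyclic_graph(cc):
        raise InputError("ontology contains cyclic is_a/part_of relations")
    return cc


def collect_offspring(graph: nx.DiGraph, roots) -> frozenset[str]:
    """Roots plus every term from which a root is reachable via is_a/part_of.

    Edges point child -> parent, so the offspring of a root are exactly the
    nodes with a directed path to it.
    """
    terms: set[str] = set()
    for root in roots:
        if root not in graph:
            raise ConfigurationError(f"root term {root} absent from ontology")
        terms.add(root)
        terms |= nx.ancestors(graph, root)
    return frozenset(terms)


def build_compartment_definitions(
    graph: nx.DiGraph,
    compartments: dict[str, tuple[str, ...]] | None = None,
) -> list[CompartmentDefinition]:
    """Expand compartment root terms against an ontology graph."""
    compartments = compartments if compartments is not None else TEN_COMPARTMENTS
    return [
        CompartmentDefinition(name=name, roots=tuple(roots),
                              terms=collect_offspring(graph, roots))
        for name, roots in compartments.items()
    ]


def read_gaf(
    gaf_path,
    evidence_codes: set[str] | None = None,
    strip_isoform_suffix: bool = True,
) -> dict[str, set[str]]:
    """Read a GAF 2.x association file into protein -> GO term sets.

    Uses the DB object id (column 2) and GO id (column 5); rows with a NOT
    qualifier are skipped. ``evidence_codes``, when given, restricts rows to
    those evidence codes (e.g. experimental codes only); by default all rows
    count. ``strip_isoform_suffix`` folds "P12345-2" into "P12345".
    """
    opener = gzip.open if str(gaf_path).endswith(".gz") else open
    terms: dict[str, set[str]] = {}
    with opener(gaf_path, "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7:
                raise InputError(f"malformed GAF row: {line[:80]!r}")
            qualifier, go_id, evidence = cols[3], cols[4], cols[6]
            if "NOT" in qualifier.split("|"):
                continue
            if evidence_codes is not None and evidence not in evidence_codes:
                continue
            protein = cols[1]
            if strip_isoform_suffix:
                protein = _strip_isoform(protein)
            terms.setdefault(protein, set()).add(go_id)
    if not terms:
        raise InputError(f"no usable associations in {gaf_path}")
    return terms


def _strip_isoform(identifier: str) -> str:
    head, sep, tail = identifier.rpartition("-")
    if sep and tail.isdigit():
        return head
    return identifier


def assign_compartments(
    protein_terms: dict[str, set[str]],
    definitions: list[CompartmentDefinition],
) -> CompartmentAnnotation:
    """Assign each protein every compartment whose expanded term set its GO
    terms intersect. Proteins with no match get an empty set (they stay in the
    whole-proteome background but join no compartment model)."""
    mapping = {
        protein: frozenset(
            d.name for d in definitions if terms & d.terms
        )
        for protein, terms in protein_terms.items()
    }
    n_empty = sum(1 for s in mapping.values() if not s)
    if n_empty:
        logger.info("%d of %d proteins match no compartment", n_empty, len(mapping))
    return CompartmentAnnotation(mapping=mapping, provenance="go")


def restrict_exclusive(
    ann: CompartmentAnnotation, compartments=None
) -> CompartmentAnnotation:
    """Keep only proteins annotated to exactly one compartment within the
    given set; used for the compartment-exclusive model-robustness check."""
    universe = set(compartments) if compartments is not None else set(ann.compartments())
    mapping = {}
    for protein, comps in ann.mapping.items():
        inside = comps & universe
        if len(inside) == 1:
            mapping[protein] = frozenset(inside)
    return CompartmentAnnotation(mapping=mapping, provenance=ann.provenance)


def load_custom_groups(path) -> CompartmentAnnotation:
    """Load a two-column (protein, group) table as a custom annotation.

    Groups behave exactly like compartments downstream, enabling curated
    organelle catalogues or protein-complex groupings. Blank lines are
    skipped with a warning.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    mapping: dict[str, set[str]] = {}
    n_blank = 0
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 0:
                n_blank += 1
                continue
            if len(parts) < 2:
                raise InputError(f"custom group row needs 2 columns: {line!r}")
            protein, group = parts[0], parts[1]
            if protein.lower() == "protein" and group.lower() == "group":
                continue  # header
            mapping.setdefault(protein, set()).add(group)
    if n_blank:
        logger.warning("skipped %d blank lines in %s", n_blank, path)
    if not mapping:
        raise InputError(f"no groups found in {path}")
    return CompartmentAnnotation(
        mapping={p: frozenset(g) for p, g in mapping.items()},
        provenance="custom",
    )


def coverage_summary(
    ann: CompartmentAnnotation,
    protein_terms: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Annotation coverage report: fractions of proteins with no GO terms,
    any cellular-component term, any of the ten compartments, and any of the
    four major compartments."""
    proteins = list(ann.mapping)
    n = len(proteins)
    has_cc = {
        p: bool(protein_terms.get(p)) if protein_terms is not None else bool(ann.mapping[p])
        for p in proteins
    }
    ten = set(TEN_COMPARTMENTS)
    four = set(FOUR_MAJOR_COMPARTMENTS)
    rows = [
        ("none", sum(1 for p in proteins if not has_cc[p])),
        ("any_cc", sum(1 for p in proteins if has_cc[p])),
        ("ten_compartments", sum(1 for p in proteins if ann.mapping[p] & ten)),
        ("four_major", sum(1 for p in proteins if ann.mapping[p] & four)),
    ]
    return pd.DataFrame(
        {"category": [r[0] for r in rows],
         "n_proteins": [r[1] for r in rows],
         "fraction": [r[1] / n if n else 0.0 for r in rows]}
    )
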