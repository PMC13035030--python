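"""GEXF 1.3 export/import of semantic networks.

The writer is deliberately minimal and canonical: nodes and edges are
emitted in lexicographic order, numbers in shortest round-trip form and
no timestamps are written, so identical inputs serialize to
byte-identical files.  Node attributes carried: ``size`` (double, the
lemma frequency) and ``modularity_class`` (long, the cluster id).
External tools (e.g. graph visualizers) handle layout; none is stored.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from lxml import etree

from .errors import ValidationError
from .network import Partition, SemanticNetwork

GEXF_NS = "http://gexf.net/1.3"
_E = "{%s}" % GEXF_NS


def _fmt(x: float) -> str:
    xf = float(x)
    return str(int(xf)) if xf.is_integer() else repr(xf)


def write_gexf(
    network: SemanticNetwork,
    partition: Partition | Mapping[str, int],
    path: str | Path,
) -> None:
    """Write an undirected weighted GEXF 1.3 file.

    The partition must cover every network node (an empty or partial
    partition is an error); re-reading with :func:`read_gexf`
    reproduces nodes, edges, weights and attributes exactly.
    """
    assignment = (
        partition.assignment if isinstance(partition, Partition) else partition
    )
    for node in network.nodes:
        if node not in assignment:
            raise ValidationError(f"node {node!r} missing from partition")

    root = etree.Element(_E + "gexf", nsmap={None: GEXF_NS}, version="1.3")
    graph = etree.SubElement(
        root, _E + "graph", defaultedgetype="undirected", mode="static"
    )
    attrs = etree.SubElement(graph, _E + "attributes", attrib={"class": "node"})
    etree.SubElement(attrs, _E + "attribute", id="0", title="size", type="double")
    etree.SubElement(
        attrs, _E + "attribute", id="1", title="modularity_class", type="long"
    )
    nodes_el = etree.SubElement(graph, _E + "nodes")
    for lemma in sorted(network.nodes):
        node_el = etree.SubElement(nodes_el, _E + "node", id=lemma, label=lemma)
        values = etree.SubElement(node_el, _E + "attvalues")
        etree.SubElement(
            values, _E + "attvalue", attrib={"for": "0", "value": _fmt(network.nodes[lemma])}
        )
        etree.SubElement(
            values, _E + "attvalue", attrib={"for": "1", "value": str(assignment[lemma])}
        )
    edges_el = etree.SubElement(graph, _E + "edges")
    for i, (a, b) in enumerate(sorted(network.edges)):
        etree.SubElement(
            edges_el, _E + "edge", id=str(i), source=a, target=b,
            weight=_fmt(network.edges[(a, b)]),
        )
    Path(path).write_bytes(
        etree.tostring(
            root, xml_declaration=True, encoding="UTF-8", pretty_print=True
        )
    )


def read_gexf(path: str | Path) -> tuple[SemanticNetwork, dict[str, int]]:
    """Read back a GEXF file written by :func:`write_gexf`."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    graph = root.find(_E + "graph")
    if graph is None:
        raise ValidationError(f"{path}: no <graph> element")
    nodes: dict[str, float] = {}
    assignment: dict[str, int] = {}
    for node_el in graph.find(_E + "nodes").iterfind(_E + "node"):
        lemma = node_el.get("id")
        size = 0.0
        for val in node_el.iter(_E + "attvalue"):
            if val.get("for") == "0":
                size = float(val.get("value"))
            elif val.get("for") == "1":
                assignment[lemma] = int(val.get("value"))
        nodes[lemma] = size
    edges: dict[tuple[str, str], float] = {}
    for edge_el in graph.find(_E + "edges").iterfind(_E + "edge"):
        a, b = edge_el.get("source"), edge_el.get("target")
        edges[(a, b)] = float(edge_el.get("weight", "1"))
    return SemanticNetwork(nodes=nodes, edges=edges), assignment
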