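"""The FAIR Data Point hierarchy: build, emit, and crawl.

An FDP exposes metadata as a four-level tree — FDP root, catalogs, datasets,
distributions — each level published as its own linked-data document that
links both its parent and its children, so humans and harvesters can
navigate in either direction and progressively collect metadata without
ever opening the data itself.

The twist this package exists for: plain FDP/DCAT dataset metadata says
nothing about *content*, so a harvester cannot tell a potato
multi-environment trial from any other spreadsheet.  We therefore embed a
MIAPPE investigation summary (investigation id/title/description, study
summaries, observed variables, biological-material summary) into the
dataset-level document.  The only cross-link between the generic and the
MIAPPE block is Dataset -> Investigation; the embedded block is a findability
summary, not the full metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Callable, Iterable, Optional, Union
from urllib.parse import quote

from rdflib import Graph, Literal, URIRef

from .model import Investigation, PhenofairError
from .rdf import parse_turtle, serialize_turtle
from .vocab import (
    CHILD_PREDICATES,
    DCAT,
    DCTERMS,
    GEO,
    LEVEL_CLASSES,
    PPEO,
    RDF,
    UriPolicy,
)

__all__ = [
    "FDP_LEVELS",
    "FdpNode",
    "DatasetSummary",
    "build_fdp",
    "validate_tree",
    "embed_investigation",
    "emit_level_graph",
    "emit_level_document",
    "emit_tree",
    "crawl_fdp",
    "file_fetcher",
    "http_fetcher",
]

FDP_LEVELS = ("fdp_root", "catalog", "dataset", "distribution")
_NEXT_LEVEL = dict(zip(FDP_LEVELS[:-1], FDP_LEVELS[1:]))
_CLASS_TO_LEVEL = {cls: lvl for lvl, cls in LEVEL_CLASSES.items()}


@dataclass
class FdpNode:
    """One level of the FDP tree.

    ``parent_id`` is the declared parent (empty for the root); ``children``
    is filled by :func:`build_fdp`.  ``media_type`` and ``access_url`` are
    meaningful on distributions (a file URL or a SPARQL endpoint URL);
    ``embedded_investigation`` only on datasets.
    """

    id: str
    level: str
    title: str
    description: str = ""
    theme: str = ""
    parent_id: str = ""
    media_type: str = ""
    access_url: str = ""
    embedded_investigation: Optional[Investigation] = None
    children: list["FdpNode"] = field(default_factory=list)

    def walk(self) -> Iterable["FdpNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def find(self, node_id: str) -> "FdpNode":
        for n in self.walk():
            if n.id == node_id:
                return n
        raise PhenofairError(f"no FDP node with id {node_id!r}")

    def strip_embedded(self) -> "FdpNode":
        """Copy of the tree with embedded investigations removed (what a
        crawler reconstructs; embedded content is returned as summaries)."""
        return replace(self, embedded_investigation=None,
                       children=[c.strip_embedded() for c in self.children])


def build_fdp(
    root: FdpNode,
    catalogs: Iterable[FdpNode] = (),
    datasets: Iterable[FdpNode] = (),
    distributions: Iterable[FdpNode] = (),
) -> FdpNode:
    """Assemble and validate the tree from nodes carrying parent references.

    Refuses (naming the offending node) orphans, level skips, duplicate
    ids, a root with a parent, and non-root nodes without a parent.
    Children are ordered by id at every level.
    """
    nodes = [root, *catalogs, *datasets, *distributions]
    by_id: dict[str, FdpNode] = {}
    for n in nodes:
        if n.level not in FDP_LEVELS:
            raise PhenofairError(f"node {n.id!r}: unknown level {n.level!r}")
        if n.id in by_id:
            raise PhenofairError(f"duplicate FDP node id {n.id!r}")
        if n.embedded_investigation is not None and n.level != "dataset":
            raise PhenofairError(
                f"node {n.id!r}: embedded investigation on level {n.level!r} "
                "(datasets only)")
        by_id[n.id] = n
        n.children = []

    if root.level != "fdp_root":
        raise PhenofairError(f"root node {root.id!r} has level {root.level!r}")
    if root.parent_id:
        raise PhenofairError(f"root node {root.id!r} declares a parent")

    for n in nodes:
        if n is root:
            continue
        if not n.parent_id:
            raise PhenofairError(f"node {n.id!r} is an orphan (no parent)")
        parent = by_id.get(n.parent_id)
        if parent is None:
            raise PhenofairError(
                f"node {n.id!r} references unknown parent {n.parent_id!r}")
        if _NEXT_LEVEL.get(parent.level) != n.level:
            raise PhenofairError(
                f"node {n.id!r}: level {n.level!r} cannot sit under "
                f"{parent.level!r} (level skip)")
        parent.children.append(n)
    for n in nodes:
        n.children.sort(key=lambda c: c.id)

    validate_tree(root)
    return root


def validate_tree(root: FdpNode) -> None:
    """Navigation closure: every node reachable from the root, levels
    consistent, parent back-references correct."""
    seen: set[str] = set()
    for n in root.walk():
        if n.id in seen:
            raise PhenofairError(f"cycle or duplicate at node {n.id!r}")
        seen.add(n.id)
        for c in n.children:
            if c.parent_id != n.id:
                raise PhenofairError(
                    f"node {c.id!r} parent reference {c.parent_id!r} does not "
                    f"match its position under {n.id!r}")
            if _NEXT_LEVEL.get(n.level) != c.level:
                raise PhenofairError(
                    f"node {c.id!r}: level {c.level!r} under {n.level!r}")


# ---------------------------------------------------------------------------
# emission


def _mint(policy: UriPolicy, node_id: str) -> URIRef:
    return policy.mint("fdp", node_id)


def _embed_summary(g: Graph, dnode: URIRef, inv: Investigation,
                   policy: UriPolicy) -> None:
    """The MIAPPE block of a dataset document: enough to decide relevance
    without opening a distribution."""
    inode = policy.mint("investigation", inv.id)
    g.add((dnode, PPEO.hasInvestigation, inode))  # the single cross-link
    g.add((inode, RDF.type, PPEO.Investigation))
    g.add((inode, DCTERMS.identifier, Literal(inv.id)))
    g.add((inode, PPEO.miappeVersion, Literal(inv.miappe_version)))
    if inv.title:
        g.add((inode, DCTERMS.title, Literal(inv.title)))
    if inv.description:
        g.add((inode, DCTERMS.description, Literal(inv.description)))

    for s in inv.studies:
        snode = policy.mint("study", s.id)
        g.add((inode, PPEO.hasStudy, snode))
        g.add((snode, RDF.type, PPEO.Study))
        g.add((snode, DCTERMS.identifier, Literal(s.id)))
        if s.title:
            g.add((snode, DCTERMS.title, Literal(s.title)))
        if s.country_code:
            g.add((snode, PPEO.countryCode, Literal(s.country_code)))
        if isinstance(s.start_date, date):
            g.add((snode, PPEO.startDate, Literal(s.start_date)))
        if isinstance(s.end_date, date):
            g.add((snode, PPEO.endDate, Literal(s.end_date)))
        if s.latitude is not None:
            g.add((snode, GEO.lat, Literal(float(s.latitude))))
        if s.longitude is not None:
            g.add((snode, GEO.long, Literal(float(s.longitude))))

    for v in inv.observed_variables:
        vnode = policy.mint("variable", v.id)
        g.add((inode, PPEO.hasObservedVariable, vnode))
        g.add((vnode, RDF.type, PPEO.ObservedVariable))
        g.add((vnode, DCTERMS.identifier, Literal(v.id)))
        if v.name:
            g.add((vnode, PPEO.variableName, Literal(v.name)))
        if v.trait:
            g.add((vnode, PPEO.trait, Literal(v.trait)))

    # biological-material summary: a count plus the originating populations
    g.add((inode, PPEO.materialCount,
           Literal(len(inv.biological_materials))))
    for src in sorted({m.material_source for m in inv.biological_materials
                       if m.material_source}):
        g.add((inode, PPEO.materialSource, Literal(src)))


def emit_level_graph(node: FdpNode, policy: UriPolicy) -> Graph:
    """The metadata graph of one node: its own descriptors, a link to its
    parent (if any), links to all its children, and — for datasets with an
    embedded investigation — the MIAPPE summary block."""
    g = Graph()
    uri = _mint(policy, node.id)
    g.add((uri, RDF.type, LEVEL_CLASSES[node.level]))
    g.add((uri, DCTERMS.identifier, Literal(node.id)))
    g.add((uri, DCTERMS.title, Literal(node.title)))
    if node.description:
        g.add((uri, DCTERMS.description, Literal(node.description)))
    if node.theme:
        g.add((uri, DCAT.theme, Literal(node.theme)))
    if node.parent_id:
        g.add((uri, DCTERMS.isPartOf, _mint(policy, node.parent_id)))
    child_pred = CHILD_PREDICATES.get(node.level)
    for c in node.children:
        g.add((uri, child_pred, _mint(policy, c.id)))
    if node.level == "distribution":
        if node.access_url:
            g.add((uri, DCAT.accessURL, URIRef(node.access_url)))
        if node.media_type:
            g.add((uri, DCAT.mediaType, Literal(node.media_type)))
    if node.embedded_investigation is not None:
        _embed_summary(g, uri, node.embedded_investigation, policy)
    return g


def emit_level_document(node: FdpNode, policy: UriPolicy) -> str:
    """Deterministic Turtle text for one node's document."""
    return serialize_turtle(emit_level_graph(node, policy))


def embed_investigation(dataset_node: FdpNode, inv: Investigation,
                        policy: UriPolicy = UriPolicy()) -> Graph:
    """Attach a MIAPPE investigation to a dataset node and return the
    dataset's two-part metadata graph (generic DCAT block + MIAPPE block).

    Refuses any node that is not dataset-level.
    """
    if dataset_node.level != "dataset":
        raise PhenofairError(
            f"cannot embed an investigation at level {dataset_node.level!r} "
            f"(node {dataset_node.id!r}); datasets only")
    dataset_node.embedded_investigation = inv
    return emit_level_graph(dataset_node, policy)


def emit_tree(root: FdpNode, out_dir: Union[str, Path],
              policy: UriPolicy) -> dict[str, Path]:
    """Write one Turtle document per node; returns node URI -> file path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for n in root.walk():
        p = out_dir / f"{quote(n.id, safe='')}.ttl"
        p.write_text(emit_level_document(n, policy), encoding="utf-8")
        paths[str(_mint(policy, n.id))] = p
    return paths


# ---------------------------------------------------------------------------
# crawling


@dataclass(frozen=True)
class DatasetSummary:
    """What a crawler learns about a dataset from its embedded MIAPPE block
    alone — the basis for deciding relevance without opening distributions."""

    dataset_id: str
    investigation_id: str
    investigation_title: str
    investigation_description: str
    study_ids: tuple[str, ...]
    variable_ids: tuple[str, ...]
    material_count: int
    material_sources: tuple[str, ...]


def file_fetcher(paths: dict[str, Path]) -> Callable[[str], str]:
    """Fetcher over documents on disk, keyed by node URI (inverse of
    :func:`emit_tree`'s return value)."""
    def fetch(locator: str) -> str:
        p = paths.get(str(locator))
        if p is None:
            raise PhenofairError(f"no document for locator {str(locator)!r}")
        return p.read_text(encoding="utf-8")
    return fetch


def http_fetcher(timeout: float = 10.0) -> Callable[[str], str]:
    """Fetcher over HTTP(S) locators."""
    import urllib.request

    def fetch(locator: str) -> str:
        with urllib.request.urlopen(locator, timeout=timeout) as resp:
            return resp.read().decode("utf-8")
    return fetch


def _read_node(doc: Graph) -> tuple[FdpNode, list[str], Optional[DatasetSummary]]:
    """Parse one level document into a node, its child locators, and (for
    datasets with a MIAPPE block) a summary."""
    uri = level = None
    for s, _, cls in doc.triples((None, RDF.type, None)):
        if cls in _CLASS_TO_LEVEL:
            uri, level = s, _CLASS_TO_LEVEL[cls]
            break
    if uri is None:
        raise PhenofairError("document contains no FDP-level node")

    def lit(s, p) -> str:
        v = doc.value(s, p)
        return "" if v is None else str(v)

    parent = doc.value(uri, DCTERMS.isPartOf)
    access = doc.value(uri, DCAT.accessURL)
    node = FdpNode(
        id=lit(uri, DCTERMS.identifier),
        level=level,
        title=lit(uri, DCTERMS.title),
        description=lit(uri, DCTERMS.description),
        theme=lit(uri, DCAT.theme),
        parent_id="" if parent is None else str(doc.value(parent, DCTERMS.identifier)
                                                or _id_from_uri(parent)),
        media_type=lit(uri, DCAT.mediaType),
        access_url="" if access is None else str(access),
    )
    child_pred = CHILD_PREDICATES.get(level)
    children = [] if child_pred is None else sorted(
        str(c) for c in doc.objects(uri, child_pred))

    summary = None
    inode = doc.value(uri, PPEO.hasInvestigation)
    if inode is not None:
        count = doc.value(inode, PPEO.materialCount)
        summary = DatasetSummary(
            dataset_id=node.id,
            investigation_id=lit(inode, DCTERMS.identifier),
            investigation_title=lit(inode, DCTERMS.title),
            investigation_description=lit(inode, DCTERMS.description),
            study_ids=tuple(sorted(
                str(doc.value(s, DCTERMS.identifier))
                for s in doc.objects(inode, PPEO.hasStudy))),
            variable_ids=tuple(sorted(
                str(doc.value(v, DCTERMS.identifier))
                for v in doc.objects(inode, PPEO.hasObservedVariable))),
            material_count=0 if count is None else int(count),
            material_sources=tuple(sorted(
                str(x) for x in doc.objects(inode, PPEO.materialSource))),
        )
    return node, children, summary


def _id_from_uri(uri: URIRef) -> str:
    from urllib.parse import unquote
    return unquote(str(uri).rsplit("/", 1)[-1])


@dataclass
class CrawlResult:
    root: FdpNode
    summaries: dict[str, DatasetSummary]
    warnings: list[str]


def crawl_fdp(root_locator: str, fetch: Callable[[str], str]) -> CrawlResult:
    """Breadth-first traversal from the root document.

    ``fetch`` maps a locator (node URI) to Turtle text — file-backed or
    HTTP-backed.  An unreachable root is a failure; an unreachable child is
    recorded as a warning and skipped, so a partly-down FDP still yields
    everything reachable.  Dataset summaries are harvested from embedded
    MIAPPE blocks along the way.
    """
    root_locator = str(root_locator)
    try:
        root_doc = parse_turtle(fetch(root_locator))
    except Exception as exc:
        raise PhenofairError(f"FDP root unreachable at {root_locator!r}: {exc}")

    root, child_locators, _ = _read_node(root_doc)
    summaries: dict[str, DatasetSummary] = {}
    warnings: list[str] = []
    queue: list[tuple[FdpNode, list[str]]] = [(root, child_locators)]
    while queue:
        parent, locators = queue.pop(0)
        for loc in locators:
            try:
                doc = parse_turtle(fetch(loc))
                node, grandchildren, summary = _read_node(doc)
            except Exception as exc:
                warnings.append(f"unreachable child {loc!r} of {parent.id!r}: {exc}")
                continue
            parent.children.append(node)
            if summary is not None:
                summaries[node.id] = summary
            queue.append((node, grandchildren))
    for n in root.walk():
        n.children.sort(key=lambda c: c.id)
    return CrawlResult(root=root, summaries=summaries, warnings=warnings)
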