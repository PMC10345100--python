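"""Vocabulary configuration and URI minting.

The phenotyping vocabulary follows PPEO (the ontology implementation of
MIAPPE) and the weather vocabulary follows the AEMET weather ontology of
the Spanish Meteorological Office.  Neither pins a normative namespace for
every term this package emits, so the term IRIs are configuration: the
defaults below form the bundled mapping table, and a deployment may swap
any namespace without touching the graph shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from urllib.parse import quote, unquote

from rdflib import Namespace, URIRef
from rdflib.namespace import DCAT, DCTERMS, RDF, RDFS, XSD  # re-exported

__all__ = [
    "PPEO", "AEMET", "GEO", "FDPO", "DCAT", "DCTERMS", "RDF", "RDFS", "XSD",
    "WEATHER_PROPERTY_TERMS", "LEVEL_CLASSES", "CHILD_PREDICATES",
    "UriPolicy", "DEFAULT_BASE_URI", "NAMESPACE_BINDINGS",
]

PPEO = Namespace("http://purl.org/ppeo/PPEO.owl#")
AEMET = Namespace("http://aemet.linkeddata.es/ontology#")
GEO = Namespace("http://www.w3.org/2003/01/geo/wgs84_pos#")
FDPO = Namespace("https://w3id.org/fdp/fdp-o#")

# rdf:type per FDP level; catalog/dataset/distribution reuse DCAT2 classes so
# generic harvesters degrade gracefully.
LEVEL_CLASSES = {
    "fdp_root": FDPO.FAIRDataPoint,
    "catalog": DCAT.Catalog,
    "dataset": DCAT.Dataset,
    "distribution": DCAT.Distribution,
}
# parent-level -> predicate linking to children
CHILD_PREDICATES = {
    "fdp_root": DCAT.catalog,
    "catalog": DCAT.dataset,
    "dataset": DCAT.distribution,
}

# AEMET-style property terms for the two daily weather variables used here.
WEATHER_PROPERTY_TERMS: dict[str, URIRef] = {
    "daily_mean_temperature_C": AEMET["dailyMeanTemperature"],
    "photoperiod_hours": AEMET["photoperiod"],
}
_TERM_TO_WEATHER_VARIABLE = {v: k for k, v in WEATHER_PROPERTY_TERMS.items()}

DEFAULT_BASE_URI = "https://fdp.example.org/id/"

# prefix -> namespace, used for deterministic Turtle abbreviation
NAMESPACE_BINDINGS: dict[str, Namespace] = {
    "ppeo": PPEO,
    "aemet": AEMET,
    "geo": GEO,
    "fdpo": FDPO,
    "dcat": Namespace(str(DCAT)),
    "dct": Namespace(str(DCTERMS)),
    "rdf": Namespace(str(RDF)),
    "rdfs": Namespace(str(RDFS)),
    "xsd": Namespace(str(XSD)),
}


@dataclass(frozen=True)
class UriPolicy:
    """Mints stable absolute URIs as ``base/{type-tag}/{encoded-id}``.

    Percent-encoding the id (with no safe characters) makes minting
    injective on (type tag, id): the tag segment never contains ``/`` and
    the id segment cannot smuggle one in.  Blank nodes are never used —
    FAIR Data Point harvesting needs every node to be re-referenceable.
    """

    base_uri: str = DEFAULT_BASE_URI

    def __post_init__(self) -> None:
        if "://" not in self.base_uri:
            raise ValueError(f"base_uri must be absolute: {self.base_uri!r}")
        if not self.base_uri.endswith("/"):
            object.__setattr__(self, "base_uri", self.base_uri + "/")

    def mint(self, type_tag: str, identifier: str) -> URIRef:
        if not type_tag or "/" in type_tag:
            raise ValueError(f"bad type tag: {type_tag!r}")
        return URIRef(f"{self.base_uri}{type_tag}/{quote(identifier, safe='')}")

    def parse(self, uri: URIRef) -> tuple[str, str]:
        """Inverse of :meth:`mint`; raises ``ValueError`` for foreign URIs."""
        text = str(uri)
        if not text.startswith(self.base_uri):
            raise ValueError(f"URI {text!r} not under base {self.base_uri!r}")
        rest = text[len(self.base_uri):]
        tag, _, encoded = rest.partition("/")
        if not tag or not _:
            raise ValueError(f"URI {text!r} lacks a type-tag/id path")
        return tag, unquote(encoded)


def weather_variable_for_term(term: URIRef) -> str:
    return _TERM_TO_WEATHER_VARIABLE[term]
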