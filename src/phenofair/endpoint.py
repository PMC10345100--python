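"""A small local SPARQL endpoint and a uniform SELECT client.

The endpoint wraps an rdflib graph behind the SPARQL 1.1 protocol
(GET ``?query=`` / POST form or ``application/sparql-query``), answering
with SPARQL JSON results — enough for the integration milestones to treat
"a local graph" and "a SPARQL endpoint" interchangeably, and for two
endpoints (phenotypic + weather) to be queried in federation by the client.

:func:`sparql_select` is the single entry point the milestones use: it
accepts either an ``rdflib.Graph`` or an endpoint URL and returns rows of
plain Python values (URIs as strings, numeric literals as floats, date
literals as ``datetime.date``), identical for both source kinds.

A plain-document server for FDP level documents is included for serving a
built FDP tree over HTTP.
"""

from __future__ import annotations

import json
import threading
import urllib.parse
import urllib.request
from datetime import date
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Optional, Union

from rdflib import Graph, Literal, URIRef

from .model import PhenofairError

__all__ = ["sparql_select", "LocalSparqlEndpoint", "DocumentServer"]

_NUMERIC_SUFFIXES = ("#double", "#decimal", "#integer", "#float", "#int",
                     "#long", "#nonNegativeInteger")


def _json_binding_to_python(b: dict) -> Union[str, float, date]:
    if b["type"] == "uri":
        return b["value"]
    dt = b.get("datatype", "")
    if dt.endswith(_NUMERIC_SUFFIXES):
        return float(b["value"])
    if dt.endswith("#date"):
        return date.fromisoformat(b["value"])
    return b["value"]


def _term_to_python(term) -> Union[str, float, date, None]:
    if term is None:
        return None
    if isinstance(term, URIRef):
        return str(term)
    if isinstance(term, Literal):
        v = term.toPython()
        if isinstance(v, bool):
            return float(v)
        if isinstance(v, (int, float)):
            return float(v)
        if isinstance(v, date):
            return v
        return str(v)
    return str(term)


def sparql_select(source: Union[Graph, str], query: str) -> list[dict]:
    """Run a SELECT against a local graph or a remote endpoint URL.

    Returns one dict per result row, mapping variable names to Python
    values; unbound variables are absent from the row.  Network problems
    and query-shape problems raise distinguishable errors
    (:class:`PhenofairError` prefixed ``endpoint unreachable`` vs the
    underlying query error).
    """
    if isinstance(source, Graph):
        result = source.query(query)
        rows = []
        for binding in result:
            row = {}
            for var, term in zip(result.vars, binding):
                if term is not None:
                    row[str(var)] = _term_to_python(term)
            rows.append(row)
        return rows

    params = urllib.parse.urlencode({"query": query})
    url = f"{source}?{params}"
    req = urllib.request.Request(
        url, headers={"Accept": "application/sparql-results+json"})
    try:
        with urllib.request.urlopen(req, timeout=30) as resp:
            payload = json.loads(resp.read().decode("utf-8"))
    except (urllib.error.URLError, OSError) as exc:
        raise PhenofairError(f"endpoint unreachable: {source} ({exc})") from exc
    rows = []
    for binding in payload["results"]["bindings"]:
        rows.append({var: _json_binding_to_python(b)
                     for var, b in binding.items()})
    return rows


class _SparqlHandler(BaseHTTPRequestHandler):
    server_version = "phenofair-sparql/0.1"

    def log_message(self, *args):  # keep test output quiet
        pass

    def _answer(self, query: Optional[str]) -> None:
        if not query:
            self.send_error(400, "missing query parameter")
            return
        try:
            result = self.server.graph.query(query)  # type: ignore[attr-defined]
            body = result.serialize(format="json")
        except Exception as exc:
            self.send_error(400, f"query failed: {exc}")
            return
        self.send_response(200)
        self.send_header("Content-Type", "application/sparql-results+json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def do_GET(self) -> None:
        parsed = urllib.parse.urlparse(self.path)
        qs = urllib.parse.parse_qs(parsed.query)
        self._answer(qs.get("query", [None])[0])

    def do_POST(self) -> None:
        length = int(self.headers.get("Content-Length", 0))
        body = self.rfile.read(length).decode("utf-8")
        ctype = self.headers.get("Content-Type", "")
        if ctype.startswith("application/sparql-query"):
            query = body
        else:
            qs = urllib.parse.parse_qs(body)
            query = qs.get("query", [None])[0]
        self._answer(query)


class LocalSparqlEndpoint:
    """Serve one rdflib graph over the SPARQL protocol on localhost.

    The graph can be swapped (``load``) between requests, so one server can
    play the part of many logical endpoints in sequence.  Usable as a
    context manager.
    """

    def __init__(self, graph: Optional[Graph] = None):
        self._server = ThreadingHTTPServer(("127.0.0.1", 0), _SparqlHandler)
        self._server.graph = graph if graph is not None else Graph()
        self._thread = threading.Thread(target=self._server.serve_forever,
                                        daemon=True)
        self._started = False

    def start(self) -> "LocalSparqlEndpoint":
        if not self._started:
            self._thread.start()
            self._started = True
        return self

    def load(self, graph: Graph) -> None:
        self._server.graph = graph

    @property
    def url(self) -> str:
        host, port = self._server.server_address
        return f"http://{host}:{port}/sparql"

    def stop(self) -> None:
        if self._started:
            self._server.shutdown()
            self._started = False
        self._server.server_close()

    def __enter__(self) -> "LocalSparqlEndpoint":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()


class _DocumentHandler(BaseHTTPRequestHandler):
    def log_message(self, *args):
        pass

    def do_GET(self) -> None:
        text = self.server.documents.get(self.path)  # type: ignore[attr-defined]
        if text is None:
            self.send_error(404, f"no document at {self.path}")
            return
        body = text.encode("utf-8")
        self.send_response(200)
        self.send_header("Content-Type", "text/turtle; charset=utf-8")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)


class DocumentServer:
    """Serve FDP level documents (path -> Turtle text) over local HTTP."""

    def __init__(self, documents: dict[str, str], port: int = 0):
        self._server = ThreadingHTTPServer(("127.0.0.1", port), _DocumentHandler)
        self._server.documents = documents
        self._thread = threading.Thread(target=self._server.serve_forever,
                                        daemon=True)
        self._started = False

    def start(self) -> "DocumentServer":
        if not self._started:
            self._thread.start()
            self._started = True
        return self

    @property
    def base_url(self) -> str:
        host, port = self._server.server_address
        return f"http://{host}:{port}"

    def stop(self) -> None:
        if self._started:
            self._server.shutdown()
            self._started = False
        self._server.server_close()

    def __enter__(self) -> "DocumentServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()
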