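"""Semantic annotation and publishing of feature results.

Feature values become an RDF graph whose shape mirrors the standard
radiomics provenance layout: each feature node is typed by its ontology
code (an IBSI identifier where one is bundled, otherwise a deterministic
local-namespace IRI), carries its numeric value and label, and links to
its VOI; the VOI links to the patient node, and all features of a run
share one software node and one settings node.  Graphs serialize to
N-Triples or Turtle and can be queried with basic graph patterns
(conjunctive triple patterns with ``?var`` variables — full SPARQL is
delegated to external stores via the serialized files).
"""

from __future__ import annotations

import csv as _csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef, XSD

from .features import FeatureResult

log = logging.getLogger(__name__)

__all__ = [
    "RO",
    "LOCAL",
    "FO",
    "MappingTable",
    "default_mapping",
    "map_feature",
    "CaseProvenance",
    "build_graph",
    "serialize",
    "parse_graph",
    "to_csv",
    "parse_query",
    "query",
    "ccc",
]

RO = Namespace("http://www.radiomics.org/RO/")  # Radiomics Ontology codes
FO = Namespace("https://w3id.org/fairomics/vocab#")  # predicates
LOCAL = Namespace("https://w3id.org/fairomics/local/")  # fallback codes + instances

_PREFIXES = {"ro": RO, "fo": FO, "local": LOCAL, "rdf": RDF, "rdfs": RDFS, "xsd": XSD}


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.strip().lower()).strip("_")


@dataclass
class MappingTable:
    """native feature name -> ontology code (IBSI where known)."""

    rows: dict[str, tuple[str, str]] = field(default_factory=dict)  # name -> (code, source)

    def add(self, native_name: str, code: str, source: str = "user") -> None:
        if native_name in self.rows:
            raise ValueError(f"duplicate mapping for {native_name!r}")
        self.rows[native_name] = (code, source)

    @classmethod
    def from_csv(cls, path) -> "MappingTable":
        table = cls()
        with open(path, newline="") as fh:
            for row in _csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                table.add(row[0].strip(), row[1].strip())
        return table


def default_mapping() -> MappingTable:
    """Bundled table for the 105-feature panel.

    Only codes with an established IBSI identifier are emitted as ``ro:``
    codes; the remaining panel features use deterministic local codes,
    flagged with source ``"local"``.
    """
    from .features import PANEL

    table = MappingTable()
    ibsi = {
        ("firstorder", "Entropy"): "TLU2",  # intensity histogram entropy
        ("glcm", "Joint Entropy"): "TU9B",
    }
    for family, names in PANEL.items():
        for name in names:
            key = f"{family}/{name}"
            if (family, name) in ibsi:
                table.add(key, ibsi[(family, name)], source="ibsi")
            else:
                table.add(key, f"{family}_{_slug(name)}", source="local")
    return table


def map_feature(name: str, table: MappingTable | None = None) -> URIRef:
    """Resolve a native feature name to its ontology IRI.

    Unknown names fall back to a deterministic local IRI derived from the
    normalized name, with a warning.
    """
    table = table or default_mapping()
    if name in table.rows:
        code, source = table.rows[name]
        return RO[code] if source == "ibsi" else LOCAL[code]
    log.warning("feature %r has no ontology mapping; using local IRI", name)
    return LOCAL[_slug(name)]


@dataclass(frozen=True)
class CaseProvenance:
    patient_id: str
    voi_name: str
    software_name: str = "fairomics"
    software_version: str = "0.1.0"
    software_language: str = "Python"
    settings: dict = field(default_factory=dict)  # bin width, spacing, ...


def _literal(value: float) -> Literal:
    # repr keeps 15+ significant digits and round-trips exactly
    return Literal(repr(float(value)), datatype=XSD.double)


def build_graph(
    features: list[FeatureResult],
    case: CaseProvenance,
    table: MappingTable | None = None,
    graph: Graph | None = None,
) -> Graph:
    """Assemble the provenance triple graph for one VOI's features."""
    if not features:
        raise ValueError("cannot build a graph from an empty feature list")
    if not case.patient_id:
        raise ValueError("missing patient id; the graph would be unlinkable")
    table = table or default_mapping()
    g = graph if graph is not None else Graph()
    for prefix, ns in _PREFIXES.items():
        g.bind(prefix, ns)

    patient = LOCAL[f"patient/{_slug(case.patient_id)}"]
    g.add((patient, RDF.type, FO.Patient))
    g.add((patient, FO.patientID, Literal(case.patient_id)))

    voi = LOCAL[f"patient/{_slug(case.patient_id)}/voi/{_slug(case.voi_name)}"]
    g.add((voi, RDF.type, FO.VolumeOfInterest))
    g.add((voi, RDFS.label, Literal(case.voi_name)))
    g.add((voi, FO.ofPatient, patient))

    run_fp = features[0].config_fingerprint or "default"
    run_tag = f"{run_fp}-{_slug(case.software_name)}-{_slug(case.software_version)}"
    software = LOCAL[f"software/{run_tag}"]
    g.add((software, RDF.type, FO.Software))
    g.add((software, FO.softwareName, Literal(case.software_name)))
    g.add((software, FO.softwareVersion, Literal(case.software_version)))
    g.add((software, FO.programmingLanguage, Literal(case.software_language)))

    settings = LOCAL[f"settings/{run_tag}"]
    g.add((settings, RDF.type, FO.ExtractionSettings))
    for key, val in sorted(case.settings.items()):
        g.add((settings, FO[_slug(key)], Literal(str(val))))

    for f in features:
        node = LOCAL[
            f"patient/{_slug(case.patient_id)}/voi/{_slug(case.voi_name)}/"
            f"run/{run_tag}/{f.family}/{_slug(f.name)}"
        ]
        code_iri = RO[f.ibsi_code] if f.ibsi_code else map_feature(f"{f.family}/{f.name}", table)
        g.add((node, RDF.type, code_iri))
        g.add((node, RDFS.label, Literal(f"{f.family}: {f.name}")))
        g.add((node, FO.hasValue, _literal(f.value)))
        if f.units:
            g.add((node, FO.hasUnits, Literal(f.units)))
        g.add((node, FO.ofVOI, voi))
        g.add((node, FO.computedBy, software))
        g.add((node, FO.usedSettings, settings))
    return g


def serialize(g: Graph, path, fmt: str = "turtle") -> Path:
    if fmt not in ("turtle", "ntriples"):
        raise ValueError("format must be 'turtle' or 'ntriples'")
    path = Path(path)
    g.serialize(destination=str(path), format="nt" if fmt == "ntriples" else "turtle")
    return path


def parse_graph(path, fmt: str | None = None) -> Graph:
    g = Graph()
    if fmt is None:
        fmt = "nt" if str(path).endswith(".nt") else "turtle"
    g.parse(str(path), format=fmt)
    return g


def to_csv(features: list[FeatureResult], case: CaseProvenance, path=None) -> pd.DataFrame:
    """Flat-table export: one row per (patient, VOI, feature)."""
    table = default_mapping()
    rows = []
    for f in features:
        key = f"{f.family}/{f.name}"
        code, source = table.rows.get(key, (_slug(key), "local"))
        rows.append(
            {
                "patient_id": case.patient_id,
                "voi": case.voi_name,
                "family": f.family,
                "name": f.name,
                "ibsi_code": code if source == "ibsi" else "",
                "value": repr(float(f.value)),
            }
        )
    df = pd.DataFrame(rows, columns=["patient_id", "voi", "family", "name", "ibsi_code", "value"])
    if path is not None:
        df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# basic-graph-pattern query engine


def _parse_term(token: str, prefixes: dict):
    if token.startswith("?"):
        return ("var", token[1:])
    if token.startswith("<") and token.endswith(">"):
        return ("term", URIRef(token[1:-1]))
    if token.startswith('"'):
        return ("term", Literal(token.strip('"')))
    if token == "a":
        return ("term", RDF.type)
    if ":" in token:
        prefix, local = token.split(":", 1)
        if prefix in prefixes:
            return ("term", prefixes[prefix][local])
        raise ValueError(f"unknown prefix {prefix!r} in {token!r}")
    raise ValueError(f"malformed term {token!r} (IRI, prefixed name, ?var or \"literal\")")


def parse_query(text: str, prefixes: dict | None = None) -> list[tuple]:
    """Parse whitespace-separated triple patterns, '.'-terminated."""
    prefixes = {**_PREFIXES, **(prefixes or {})}
    patterns = []
    for clause in re.split(r"\s*\.\s*(?=(?:[^\"]*\"[^\"]*\")*[^\"]*$)", text.strip()):
        clause = clause.strip()
        if not clause:
            continue
        tokens = re.findall(r'"[^"]*"|\S+', clause)
        if len(tokens) != 3:
            raise ValueError(f"pattern needs 3 terms, got {len(tokens)}: {clause!r}")
        patterns.append(tuple(_parse_term(t, prefixes) for t in tokens))
    return patterns


def query(g: Graph, patterns, prefixes: dict | None = None) -> pd.DataFrame:
    """Exact basic-graph-pattern join over the graph.

    ``patterns`` is either the small text syntax or pre-parsed pattern
    triples.  Output columns follow first appearance of each variable.
    """
    if isinstance(patterns, str):
        patterns = parse_query(patterns, prefixes)
    var_order: list[str] = []
    for pat in patterns:
        for kind, val in pat:
            if kind == "var" and val not in var_order:
                var_order.append(val)

    rows: list[dict] = [{}]
    for pat in patterns:
        new_rows = []
        for binding in rows:
            lookup = tuple(
                (binding.get(val) if kind == "var" else val) for kind, val in pat
            )
            for s, p, o in g.triples(lookup):
                cand = dict(binding)
                ok = True
                for (kind, val), term in zip(pat, (s, p, o)):
                    if kind != "var":
                        continue
                    if val in cand and cand[val] != term:
                        ok = False
                        break
                    cand[val] = term
                if ok:
                    new_rows.append(cand)
        rows = new_rows
        if not rows:
            break
    data = [{v: _plain(r.get(v)) for v in var_order} for r in rows]
    df = pd.DataFrame(data, columns=var_order)
    return df.sort_values(var_order).reset_index(drop=True) if len(df) else df


def _plain(term):
    if isinstance(term, Literal):
        return str(term)
    return str(term) if term is not None else None


# ---------------------------------------------------------------------------
# concordance


def ccc(x, y) -> float:
    """Concordance correlation coefficient (population moments):

        CCC = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2)

    Both inputs constant and equal returns 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("ccc needs two equal-length 1-D vectors of length >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return 1.0
    cov = ((x - mx) * (y - my)).mean()
    return float(2.0 * cov / denom)
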