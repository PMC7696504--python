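"""Model I/O: PNML (ISO/IEC 15909-2 core), native JSON, and CSV reports.

The native JSON schema is::

    {"places":      [{"id", "name", "tokens"}, ...],
     "transitions": [{"id", "name", "rate_constant"}, ...],
     "arcs":        [{"from", "to", "weight"}, ...]}

PNML files written here carry the marking in ``initialMarking`` and the
rate constant in a ``toolspecific`` extension; unknown extension elements
from other tools are ignored on read.  Repeated place entries with one id
(logical places, a pure rendering device) collapse to a single node.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from lxml import etree

from .invariants import InvariantSet
from .mct import MCTSet
from .net import Arc, Marking, NetValidationError, PetriNet, incidence_matrix
from .simulate import StochasticRates

__all__ = [
    "read_model",
    "write_model",
    "incidence_frame",
    "invariants_frame",
    "mct_frame",
]

_PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"


class ModelParseError(ValueError):
    """Malformed model file (includes location information when available)."""


def write_model(path: str | Path, net: PetriNet, marking: Marking,
                rates: StochasticRates | None = None, *, format: str | None = None) -> None:
    """Serialise ``(net, marking, rates)`` to PNML or native JSON.

    The format is inferred from the suffix unless given explicitly.
    """
    path = Path(path)
    fmt = (format or ("pnml" if path.suffix.lower() in (".pnml", ".xml") else "json")).lower()
    if fmt == "json":
        doc = {
            "places": [
                {"id": p, "name": net.label(p), "tokens": int(marking.counts[p])}
                for p in net.places
            ],
            "transitions": [
                {"id": t, "name": net.label(t),
                 "rate_constant": (None if rates is None
                                   else rates.rate_constants.get(t, 0.0))}
                for t in net.transitions
            ],
            "arcs": [
                {"from": a.source, "to": a.target, "weight": a.weight}
                for a in net.arcs
            ],
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
    elif fmt == "pnml":
        nsmap = {None: _PNML_NS}
        root = etree.Element("pnml", nsmap=nsmap)
        netel = etree.SubElement(root, "net", id="net0",
                                 type="http://www.pnml.org/version-2009/grammar/ptnet")
        page = etree.SubElement(netel, "page", id="page0")
        for p in net.places:
            pel = etree.SubElement(page, "place", id=p)
            nm = etree.SubElement(etree.SubElement(pel, "name"), "text")
            nm.text = net.label(p)
            mk = etree.SubElement(etree.SubElement(pel, "initialMarking"), "text")
            mk.text = str(int(marking.counts[p]))
        for t in net.transitions:
            tel = etree.SubElement(page, "transition", id=t)
            nm = etree.SubElement(etree.SubElement(tel, "name"), "text")
            nm.text = net.label(t)
            if rates is not None:
                ts = etree.SubElement(tel, "toolspecific", tool="spnkit", version="0.1")
                rt = etree.SubElement(ts, "rate")
                rt.text = repr(float(rates.rate_constants.get(t, 0.0)))
        for i, a in enumerate(net.arcs):
            ael = etree.SubElement(page, "arc", id=f"a{i}", source=a.source, target=a.target)
            if a.weight != 1:
                w = etree.SubElement(etree.SubElement(ael, "inscription"), "text")
                w.text = str(a.weight)
        path.write_bytes(etree.tostring(root, xml_declaration=True,
                                        encoding="UTF-8", pretty_print=True))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_model(path: str | Path, *, format: str | None = None
               ) -> tuple[PetriNet, Marking, StochasticRates | None]:
    """Load a model from PNML or native JSON.

    ``read_model(write_model(x))`` is the identity on (net, marking, rates)
    up to element order.
    """
    path = Path(path)
    fmt = (format or ("pnml" if path.suffix.lower() in (".pnml", ".xml") else "json")).lower()
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise ModelParseError(f"{path}: invalid JSON at line {e.lineno}, column {e.colno}") from e
        places, labels, tokens = [], {}, {}
        for rec in doc["places"]:
            pid = rec["id"]
            if pid in tokens:  # logical duplicate
                continue
            places.append(pid)
            labels[pid] = rec.get("name", pid)
            tokens[pid] = int(rec.get("tokens", 0))
        transitions, rates_map, has_rates = [], {}, False
        for rec in doc["transitions"]:
            tid = rec["id"]
            transitions.append(tid)
            labels[tid] = rec.get("name", tid)
            c = rec.get("rate_constant")
            if c is not None:
                has_rates = True
                rates_map[tid] = float(c)
        arcs = [Arc(r["from"], r["to"], int(r.get("weight", 1))) for r in doc["arcs"]]
    elif fmt == "pnml":
        try:
            tree = etree.parse(str(path))
        except etree.XMLSyntaxError as e:
            raise ModelParseError(f"{path}: {e}") from e

        def local(tag: str) -> str:
            return etree.QName(tag).localname if "}" in tag else tag

        places, labels, tokens = [], {}, {}
        transitions, rates_map, has_rates = [], {}, False
        arcs = []

        def text_of(el, child: str) -> str | None:
            for sub in el.iter():
                if local(sub.tag) == child:
                    for txt in sub.iter():
                        if local(txt.tag) == "text" and txt.text is not None:
                            return txt.text.strip()
            return None

        for el in tree.iter():
            tag = local(el.tag) if isinstance(el.tag, str) else None
            if tag == "place":
                pid = el.get("id")
                if pid in tokens:  # logical place: one node per id
                    continue
                places.append(pid)
                labels[pid] = text_of(el, "name") or pid
                tokens[pid] = int(text_of(el, "initialMarking") or 0)
            elif tag == "transition":
                tid = el.get("id")
                transitions.append(tid)
                labels[tid] = text_of(el, "name") or tid
                for ts in el:
                    if (isinstance(ts.tag, str) and local(ts.tag) == "toolspecific"
                            and ts.get("tool") == "spnkit"):
                        for sub in ts.iter():
                            if (isinstance(sub.tag, str) and local(sub.tag) == "rate"
                                    and sub.text is not None):
                                has_rates = True
                                rates_map[tid] = float(sub.text.strip())
            elif tag == "arc":
                w = text_of(el, "inscription")
                arcs.append(Arc(el.get("source"), el.get("target"), int(w) if w else 1))
    else:
        raise ValueError(f"unknown format {fmt!r}")

    # drop exact duplicate arcs (logical-place renderings); conflicting
    # duplicates are a modelling error
    seen: dict[tuple[str, str], int] = {}
    uniq: list[Arc] = []
    for a in arcs:
        key = (a.source, a.target)
        if key in seen:
            if seen[key] != a.weight:
                raise ModelParseError(f"{path}: conflicting weights for arc {key}")
            continue
        seen[key] = a.weight
        uniq.append(a)
    try:
        net = PetriNet(tuple(places), tuple(transitions), tuple(uniq), labels)
    except NetValidationError as e:
        raise ModelParseError(f"{path}: {e}") from e
    marking = Marking.for_net(net, tokens)
    rates = StochasticRates(
        {t: rates_map.get(t, 0.0) for t in transitions}) if has_rates else None
    return net, marking, rates


# -- tabular reports -------------------------------------------------------

def incidence_frame(net: PetriNet) -> pd.DataFrame:
    """Incidence matrix as a DataFrame (places as rows, transitions as columns)."""
    return pd.DataFrame(incidence_matrix(net), index=list(net.places),
                        columns=list(net.transitions))


def invariants_frame(invs: InvariantSet) -> pd.DataFrame:
    """One row per invariant: coefficients per transition plus support size."""
    df = pd.DataFrame(invs.matrix(), columns=list(invs.transitions))
    df.insert(len(df.columns), "support_size", [len(inv.support) for inv in invs])
    return df


def mct_frame(sets: list[MCTSet]) -> pd.DataFrame:
    """MCT report: m1..mk in output order with sizes and member lists."""
    return pd.DataFrame([
        {"mct_id": f"m{i + 1}", "size": len(s), "is_trivial": s.is_trivial,
         "transitions": ",".join(s.transitions)}
        for i, s in enumerate(sets)
    ])
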