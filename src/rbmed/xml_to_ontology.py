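"""Generic XML → syntactic-ontology conversion.

A syntactic ontology mirrors a data format's structure: every distinct
element tag becomes a class, every attribute a data property, every
parent→child nesting an object property, and every element occurrence an
instance.  Data values (attributes, text content) become data-property
assertions on the element's instance.  This isolates syntactic variability
so the core domain ontology never has to know about any file format.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from lxml import etree

from .instance_graph import InstanceGraph, Literal, UnknownSymbolError

__all__ = ["XmlMappingConvention", "XmlParseError", "derive_schema", "populate", "parse_xml"]


class XmlParseError(ValueError):
    """Malformed XML; message carries the reported line number."""


@dataclass(frozen=True)
class XmlMappingConvention:
    """Naming rules mapping XML structure onto ontology symbols.

    * element tag  -> CamelCase class name (``entry`` -> ``Entry``)
    * attribute    -> data property ``has`` + CamelCase (``id`` -> ``hasId``)
    * child nesting-> object property ``has`` + CamelCase of the child tag
    * text content -> data property ``hasValue``

    ``prefix`` (e.g. ``"up"``) namespaces every generated symbol as
    ``up:Entry`` so syntactic ontologies for different formats stay
    disjoint under graph union.  XML namespaces are stripped to local
    names before naming.
    """

    prefix: str = ""
    text_property: str = "hasValue"

    def qualify(self, name: str) -> str:
        return f"{self.prefix}:{name}" if self.prefix else name

    def class_name(self, tag: str) -> str:
        return self.qualify(_camel(_local(tag)))

    def attr_property(self, attr: str) -> str:
        return self.qualify("has" + _camel(_local(attr)))

    def child_property(self, child_tag: str) -> str:
        return self.qualify("has" + _camel(_local(child_tag)))

    def value_property(self) -> str:
        return self.qualify(self.text_property)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _camel(name: str) -> str:
    parts = name.replace("-", "_").replace(".", "_").split("_")
    return "".join(p[:1].upper() + p[1:] for p in parts if p)


def parse_xml(source) -> etree._Element:
    """Parse a path/file-like/string into an element tree root."""
    try:
        if isinstance(source, (str, bytes)) and b"<" in (
            source.encode() if isinstance(source, str) else source
        )[:200]:
            return etree.fromstring(source.encode() if isinstance(source, str) else source)
        return etree.parse(source).getroot()
    except etree.XMLSyntaxError as exc:
        raise XmlParseError(f"malformed XML: {exc}") from exc


def derive_schema(doc, conv: XmlMappingConvention) -> InstanceGraph:
    """Induce a schema (classes + properties, no instances) from a document.

    Idempotent: re-deriving from the same document yields an identical
    schema; deriving into the same convention from several documents of one
    format accumulates a single shared schema.
    """
    root = doc if isinstance(doc, etree._Element) else parse_xml(doc)
    schema = InstanceGraph()
    extend_schema(root, schema, conv)
    return schema


def extend_schema(root: etree._Element, schema: InstanceGraph, conv: XmlMappingConvention) -> None:
    for el in root.iter():
        if not isinstance(el.tag, str):  # comments / PIs
            continue
        schema.add_class(conv.class_name(el.tag))
        for attr in el.attrib:
            schema.add_property(conv.attr_property(attr), "data")
        if (el.text or "").strip():
            schema.add_property(conv.value_property(), "data")
        for child in el:
            if not isinstance(child.tag, str):
                continue
            schema.add_property(conv.child_property(child.tag), "object")


def populate(
    doc,
    schema: InstanceGraph,
    conv: XmlMappingConvention,
    source_label: str,
    mode: str = "strict",
    id_prefix: Optional[str] = None,
) -> InstanceGraph:
    """Populate ``schema`` with one instance per element occurrence.

    Attribute values and non-empty trimmed text become data-property
    assertions; parent→child links become object-property assertions.
    Instances are created in document order with ids
    ``<source>#<tag><ordinal>``; every instance carries ``source_label``
    as provenance.

    ``mode`` is ``"strict"`` (unknown tag → error) or ``"lenient"``
    (class/property added on the fly).
    """
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    root = doc if isinstance(doc, etree._Element) else parse_xml(doc)
    ns = id_prefix if id_prefix is not None else source_label
    # resume ordinals when several files of one format share a schema
    counters: dict[str, int] = {}
    for iid in schema.instances:
        nsp, _, local = iid.partition("#")
        if nsp == ns:
            tag = local.rstrip("0123456789")
            num = local[len(tag):]
            if num:
                counters[tag] = max(counters.get(tag, 0), int(num))

    def ensure_class(name: str):
        if name not in schema.classes:
            if mode == "strict":
                raise UnknownSymbolError(f"element class {name!r} not in pinned schema")
            schema.add_class(name)

    def ensure_prop(name: str, kind: str):
        if name not in schema.properties:
            if mode == "strict":
                raise UnknownSymbolError(f"property {name!r} not in pinned schema")
            schema.add_property(name, kind)

    def walk(el: etree._Element):
        cls = conv.class_name(el.tag)
        ensure_class(cls)
        tag = _local(el.tag)
        n = counters.get(tag, 0) + 1
        counters[tag] = n
        inst = schema.add_instance(f"{ns}#{tag}{n}", [cls], source=source_label)
        for attr, value in el.attrib.items():
            prop = conv.attr_property(attr)
            ensure_prop(prop, "data")
            schema.assert_value(inst, prop, Literal(value))
        text = (el.text or "").strip()
        if text:
            prop = conv.value_property()
            ensure_prop(prop, "data")
            schema.assert_value(inst, prop, Literal(text))
        for child in el:
            if not isinstance(child.tag, str):
                continue
            child_inst = walk(child)
            prop = conv.child_property(child.tag)
            ensure_prop(prop, "object")
            schema.assert_value(inst, prop, child_inst)
        return inst

    walk(root)
    return schema
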