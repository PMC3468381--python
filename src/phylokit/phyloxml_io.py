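"""phyloXML: annotation-rich tree classes, streaming parser and serializer.

phyloXML is an XML format in which each ``<phylogeny>`` element carries a
nested ``<clade>`` hierarchy that may be annotated with taxonomies, molecular
sequences, protein domain architectures, confidence values, evolutionary
events, typed properties and URIs.  The classes here extend the plain tree
model (:class:`~phylokit.treemodel.Tree` / ``Clade``) so every generic tree
method keeps working on parsed phyloXML documents.

Unrecognized elements and attributes are preserved verbatim in ``extras`` so
third-party phyloXML survives a conversion cycle (byte-preserving modulo
namespace normalization).  Repeated elements keep their document order.

Note on coordinates: ``ProteinDomain.start``/``end`` are **1-based inclusive**
positions, as in the phyloXML specification — not 0-based half-open.
"""

from __future__ import annotations

import copy
import warnings
import xml.etree.ElementTree as ET

from .treemodel import BranchColor, Clade, Tree


class PhyloXMLError(ValueError):
    """Malformed or incomplete phyloXML data."""


class PhyloXMLWarning(UserWarning):
    """Suspicious but tolerated phyloXML content."""


NAMESPACE = "http://www.phyloxml.org"
XSI = "http://www.w3.org/2001/XMLSchema-instance"
SCHEMA_LOCATION = "http://www.phyloxml.org http://www.phyloxml.org/1.10/phyloxml.xsd"


def _local(tag):
    """Local part of a possibly namespace-qualified tag, or None if the tag
    belongs to a foreign namespace."""
    if tag.startswith("{"):
        ns, _, local = tag[1:].partition("}")
        return local if ns == NAMESPACE else None
    return tag


def _text(elem):
    return (elem.text or "").strip() or None


def _as_extra(elem):
    """Deep-copy an unrecognized element, rewriting tags in the phyloXML
    default namespace to their bare local names so that re-serialization
    (with phyloXML as the default namespace) reproduces the original markup
    without artificial prefixes.  Foreign namespaces are kept qualified."""
    extra = copy.deepcopy(elem)
    for node in extra.iter():
        local = _local(node.tag)
        if local is not None:
            node.tag = local
    return extra


def _parse_bool(value, context):
    if value in ("true", "1"):
        return True
    if value in ("false", "0"):
        return False
    raise PhyloXMLError(f"invalid boolean {value!r} in {context}")


def _serialize_bool(value):
    return "true" if value else "false"


# ---------------------------------------------------------------------------
# Annotation element classes

class PhyloElement:
    """Base class for phyloXML annotation elements: value-equality over the
    declared fields and a compact repr."""

    _fields = ()

    def _sub_elements(self):
        return []

    def __eq__(self, other):
        if type(other) is not type(self):
            return NotImplemented
        return all(
            getattr(self, f) == getattr(other, f) for f in self._fields
        )

    def __hash__(self):
        return object.__hash__(self)

    def __repr__(self):
        shown = ", ".join(
            f"{f}={getattr(self, f)!r}"
            for f in self._fields
            if getattr(self, f) not in (None, [], ())
        )
        return f"{type(self).__name__}({shown})"


class Id(PhyloElement):
    """An identifier with an optional provider (e.g. "ncbi_taxonomy")."""

    _fields = ("value", "provider")

    def __init__(self, value, provider=None):
        self.value = value
        self.provider = provider


class Accession(PhyloElement):
    """A sequence accession with its source database (e.g. "UniProtKB")."""

    _fields = ("value", "source")

    def __init__(self, value, source=None):
        self.value = value
        self.source = source


class Confidence(PhyloElement):
    """A support value with a type, e.g. Confidence(95, "bootstrap")."""

    _fields = ("value", "type")

    def __init__(self, value, type="unknown"):
        self.value = value
        self.type = type


class Uri(PhyloElement):
    _fields = ("value", "desc", "type")

    def __init__(self, value, desc=None, type=None):
        self.value = value
        self.desc = desc
        self.type = type


class Property(PhyloElement):
    """A typed, externally-defined annotation (ref/unit/datatype/applies_to)."""

    _fields = ("value", "ref", "unit", "datatype", "applies_to", "id_source")

    def __init__(self, value, ref=None, unit=None, datatype=None,
                 applies_to=None, id_source=None):
        self.value = value
        self.ref = ref
        self.unit = unit
        self.datatype = datatype
        self.applies_to = applies_to
        self.id_source = id_source


class Events(PhyloElement):
    """Counts of evolutionary events at a node (all non-negative)."""

    _fields = ("type", "duplications", "speciations", "losses")

    def __init__(self, type=None, duplications=None, speciations=None,
                 losses=None):
        for label, count in (("duplications", duplications),
                             ("speciations", speciations),
                             ("losses", losses)):
            if count is not None and count < 0:
                raise ValueError(f"{label} count must be non-negative")
        self.type = type
        self.duplications = duplications
        self.speciations = speciations
        self.losses = losses


#: Closed vocabulary of taxonomic ranks defined by the phyloXML schema.
TAXONOMY_RANKS = frozenset((
    "domain", "superkingdom", "kingdom", "subkingdom", "branch", "infrakingdom",
    "superphylum", "phylum", "subphylum", "infraphylum", "microphylum",
    "superdivision", "division", "subdivision", "infradivision",
    "superclass", "class", "subclass", "infraclass", "superlegion", "legion",
    "sublegion", "infralegion", "supercohort", "cohort", "subcohort",
    "infracohort", "superorder", "order", "suborder", "superfamily", "family",
    "subfamily", "supertribe", "tribe", "subtribe", "infratribe", "genus",
    "subgenus", "superspecies", "species", "subspecies", "variety",
    "subvariety", "form", "subform", "cultivar", "unknown", "other",
))


class Taxonomy(PhyloElement):
    """Taxonomic assignment of a clade.

    ``rank`` must come from the schema's closed vocabulary
    (:data:`TAXONOMY_RANKS`).
    """

    _fields = ("id", "code", "scientific_name", "common_names", "rank", "uri")

    def __init__(self, id=None, code=None, scientific_name=None,
                 common_names=None, rank=None, uri=None):
        if rank is not None and rank not in TAXONOMY_RANKS:
            raise ValueError(
                f"invalid taxonomy rank {rank!r}; must be one of the "
                f"phyloXML rank vocabulary"
            )
        self.id = id
        self.code = code
        self.scientific_name = scientific_name
        self.common_names = list(common_names) if common_names else []
        self.rank = rank
        self.uri = uri

    def _sub_elements(self):
        return [e for e in (self.id, self.uri) if e is not None]


class ProteinDomain(PhyloElement):
    """A functional domain within a protein sequence.

    ``start`` and ``end`` are 1-based inclusive coordinates, so a domain
    covering the first ten residues is ``start=1, end=10``.
    """

    _fields = ("start", "end", "confidence", "id", "value")

    def __init__(self, start, end, confidence=None, id=None, value=None):
        if not 1 <= start <= end:
            raise ValueError(
                f"invalid domain coordinates {start}..{end}: must satisfy "
                f"1 <= start <= end (1-based inclusive)"
            )
        self.start = start
        self.end = end
        self.confidence = confidence
        self.id = id
        self.value = value


class DomainArchitecture(PhyloElement):
    """The ordered protein domains of a sequence, with its total length."""

    _fields = ("length", "domains")

    def __init__(self, length=None, domains=None):
        self.length = length
        self.domains = list(domains) if domains else []
        if length is not None:
            for dom in self.domains:
                if dom.end > length:
                    warnings.warn(
                        f"domain {dom.value or dom.id!r} ends at {dom.end}, "
                        f"beyond sequence length {length}",
                        PhyloXMLWarning,
                        stacklevel=2,
                    )

    def _sub_elements(self):
        return list(self.domains)


_ALPHABETS = {
    "dna": set("ACGTUMRWSYKVHDBXN.-?"),
    "rna": set("ACGUMRWSYKVHDBXN.-?"),
    "protein": set("ABCDEFGHIJKLMNOPQRSTUVWXYZ*.-?"),
}


class MolecularSequence(PhyloElement):
    """A molecular sequence attached to a clade.

    ``type`` is one of dna/rna/protein; a sequence text that does not match
    the declared alphabet triggers a warning, not an error.  ``is_aligned``
    marks rows usable by :func:`to_alignment`.
    """

    _fields = ("type", "symbol", "accession", "name", "mol_seq", "is_aligned",
               "domain_architecture", "uri")

    def __init__(self, type=None, symbol=None, accession=None, name=None,
                 mol_seq=None, is_aligned=None, domain_architecture=None,
                 uri=None):
        if type is not None and type not in _ALPHABETS:
            raise ValueError(f"sequence type must be dna, rna or protein, not {type!r}")
        self.type = type
        self.symbol = symbol
        self.accession = accession
        self.name = name
        self.mol_seq = mol_seq
        self.is_aligned = is_aligned
        self.domain_architecture = domain_architecture
        self.uri = uri
        if type and mol_seq:
            stray = set(mol_seq.upper()) - _ALPHABETS[type]
            if stray:
                warnings.warn(
                    f"sequence characters {sorted(stray)} do not match the "
                    f"declared {type} alphabet",
                    PhyloXMLWarning,
                    stacklevel=2,
                )

    def _sub_elements(self):
        subs = [e for e in (self.accession, self.uri, self.domain_architecture)
                if e is not None]
        if self.domain_architecture is not None:
            subs.extend(self.domain_architecture.domains)
        return subs


# ---------------------------------------------------------------------------
# Tree classes

class PhyloClade(Clade):
    """A clade carrying phyloXML annotations.

    Branch color and width cascade to descendants, as in the plain model.
    Unknown child elements/attributes are kept verbatim in ``extras``.
    """

    def __init__(self, branch_length=None, name=None, clades=None,
                 confidence=None, color=None, width=None, confidences=None,
                 taxonomies=None, sequences=None, events=None, properties=None,
                 uris=None, id_source=None, extras=None):
        self.confidences = list(confidences) if confidences else []
        super().__init__(branch_length=branch_length, name=name, clades=clades,
                         confidence=confidence, color=color, width=width)
        self.taxonomies = list(taxonomies) if taxonomies else []
        self.sequences = list(sequences) if sequences else []
        self.events = events
        self.properties = list(properties) if properties else []
        self.uris = list(uris) if uris else []
        self.id_source = id_source
        self.extras = list(extras) if extras else []

    @property
    def confidence(self):
        """Value of the first attached Confidence, or None."""
        if self.confidences:
            return self.confidences[0].value
        return None

    @confidence.setter
    def confidence(self, value):
        if value is None:
            return
        if isinstance(value, Confidence):
            self.confidences.append(value)
        elif self.confidences:
            self.confidences[0].value = value
        else:
            self.confidences.append(Confidence(value))

    def _iter_elements(self):
        yield self
        pending = list(self.taxonomies) + list(self.sequences)
        if self.events is not None:
            pending.append(self.events)
        pending += list(self.confidences) + list(self.properties) + list(self.uris)
        while pending:
            element = pending.pop(0)
            yield element
            pending = element._sub_elements() + pending


class Phylogeny(Tree):
    """A phyloXML phylogeny: a Tree with a required rootedness flag and
    document-level annotations."""

    def __init__(self, root=None, rooted=None, id=None, name=None,
                 description=None, rerootable=None, branch_length_unit=None,
                 type=None, confidences=None, properties=None, extras=None):
        if rooted is None:
            raise PhyloXMLError("a phylogeny requires an explicit 'rooted' flag")
        super().__init__(root=root if root is not None else PhyloClade(),
                         rooted=rooted, id=id, name=name)
        self.description = description
        self.rerootable = rerootable
        self.branch_length_unit = branch_length_unit
        self.type = type
        self.confidences = list(confidences) if confidences else []
        self.properties = list(properties) if properties else []
        self.extras = list(extras) if extras else []

    def to_alignment(self):
        """Rows (name, sequence text) for every clade bearing an aligned
        molecular sequence, in preorder; all rows must have equal length."""
        return to_alignment(self)


# ---------------------------------------------------------------------------
# Parsing

def _parse_id(elem):
    return Id(_text(elem), provider=elem.get("provider"))


def _parse_confidence(elem):
    value = _text(elem)
    return Confidence(float(value) if value is not None else None,
                      type=elem.get("type", "unknown"))


def _parse_uri(elem):
    return Uri(_text(elem), desc=elem.get("desc"), type=elem.get("type"))


def _parse_property(elem):
    return Property(
        _text(elem),
        ref=elem.get("ref"),
        unit=elem.get("unit"),
        datatype=elem.get("datatype"),
        applies_to=elem.get("applies_to"),
        id_source=elem.get("id_source"),
    )


def _parse_events(elem):
    kwargs = {}
    for child in elem:
        tag = _local(child.tag)
        if tag == "type":
            kwargs["type"] = _text(child)
        elif tag in ("duplications", "speciations", "losses"):
            kwargs[tag] = int(_text(child))
    return Events(**kwargs)


def _parse_taxonomy(elem):
    kwargs = {"common_names": []}
    for child in elem:
        tag = _local(child.tag)
        if tag == "id":
            kwargs["id"] = _parse_id(child)
        elif tag == "code":
            kwargs["code"] = _text(child)
        elif tag == "scientific_name":
            kwargs["scientific_name"] = _text(child)
        elif tag == "common_name":
            kwargs["common_names"].append(_text(child))
        elif tag == "rank":
            kwargs["rank"] = _text(child)
        elif tag == "uri":
            kwargs["uri"] = _parse_uri(child)
    return Taxonomy(**kwargs)


def _parse_domain(elem):
    return ProteinDomain(
        start=int(elem.get("from")),
        end=int(elem.get("to")),
        confidence=float(elem.get("confidence")) if elem.get("confidence") else None,
        id=elem.get("id"),
        value=_text(elem),
    )


def _parse_domain_architecture(elem):
    length = elem.get("length")
    domains = [
        _parse_domain(child) for child in elem if _local(child.tag) == "domain"
    ]
    return DomainArchitecture(length=int(length) if length else None,
                              domains=domains)


def _parse_sequence(elem):
    kwargs = {"type": elem.get("type")}
    for child in elem:
        tag = _local(child.tag)
        if tag == "symbol":
            kwargs["symbol"] = _text(child)
        elif tag == "accession":
            kwargs["accession"] = Accession(_text(child), source=child.get("source"))
        elif tag == "name":
            kwargs["name"] = _text(child)
        elif tag == "mol_seq":
            kwargs["mol_seq"] = _text(child)
            aligned = child.get("is_aligned")
            if aligned is not None:
                kwargs["is_aligned"] = _parse_bool(aligned, "mol_seq/@is_aligned")
        elif tag == "domain_architecture":
            kwargs["domain_architecture"] = _parse_domain_architecture(child)
        elif tag == "uri":
            kwargs["uri"] = _parse_uri(child)
    return MolecularSequence(**kwargs)


def _parse_color(elem):
    channels = {}
    for child in elem:
        tag = _local(child.tag)
        if tag in ("red", "green", "blue"):
            channels[tag] = int(_text(child))
    return BranchColor(channels.get("red", 0), channels.get("green", 0),
                       channels.get("blue", 0))


def _parse_clade(elem):
    clade = PhyloClade()
    bl_attr = elem.get("branch_length")
    if bl_attr is not None:
        clade.branch_length = float(bl_attr)
    clade.id_source = elem.get("id_source")
    for child in elem:
        tag = _local(child.tag)
        if tag == "clade":
            clade.clades.append(_parse_clade(child))
        elif tag == "name":
            clade.name = _text(child)
        elif tag == "branch_length":
            clade.branch_length = float(_text(child))
        elif tag == "confidence":
            clade.confidences.append(_parse_confidence(child))
        elif tag == "width":
            clade.width = float(_text(child))
        elif tag == "color":
            clade.color = _parse_color(child)
        elif tag == "taxonomy":
            clade.taxonomies.append(_parse_taxonomy(child))
        elif tag == "sequence":
            clade.sequences.append(_parse_sequence(child))
        elif tag == "events":
            clade.events = _parse_events(child)
        elif tag == "property":
            clade.properties.append(_parse_property(child))
        elif tag == "uri":
            clade.uris.append(_parse_uri(child))
        else:
            clade.extras.append(_as_extra(child))
    return clade


def _parse_phylogeny(elem, index):
    rooted_attr = elem.get("rooted")
    name = None
    for child in elem:
        if _local(child.tag) == "name":
            name = _text(child)
            break
    if rooted_attr is None:
        label = name or f"#{index}"
        raise PhyloXMLError(
            f"phylogeny {label} is missing the required 'rooted' attribute"
        )
    phy = Phylogeny(rooted=_parse_bool(rooted_attr, "phylogeny/@rooted"))
    phy.rerootable = (
        _parse_bool(elem.get("rerootable"), "phylogeny/@rerootable")
        if elem.get("rerootable") is not None else None
    )
    phy.branch_length_unit = elem.get("branch_length_unit")
    phy.type = elem.get("type")
    for child in elem:
        tag = _local(child.tag)
        if tag == "name":
            phy.name = _text(child)
        elif tag == "id":
            phy.id = _parse_id(child)
        elif tag == "description":
            phy.description = _text(child)
        elif tag == "confidence":
            phy.confidences.append(_parse_confidence(child))
        elif tag == "property":
            phy.properties.append(_parse_property(child))
        elif tag == "clade":
            phy.root = _parse_clade(child)
        else:
            phy.extras.append(_as_extra(child))
    return phy


def parse(source):
    """Yield one :class:`Phylogeny` per ``<phylogeny>`` element, streaming.

    Memory use is bounded by the largest single phylogeny regardless of how
    many the document contains: each phylogeny element is detached from the
    document root as soon as it has been converted.
    """
    context = ET.iterparse(source, events=("start", "end"))
    try:
        _, doc_root = next(context)
    except StopIteration:
        return
    index = 0
    for event, elem in context:
        if event == "end" and _local(elem.tag) == "phylogeny":
            index += 1
            yield _parse_phylogeny(elem, index)
            elem.clear()
            try:
                doc_root.remove(elem)
            except ValueError:
                pass


# ---------------------------------------------------------------------------
# Serialization

def _sub(parent, tag, text=None, **attrs):
    elem = ET.SubElement(parent, tag, {k: v for k, v in attrs.items() if v is not None})
    if text is not None:
        elem.text = str(text)
    return elem


def _write_confidence(parent, conf):
    _sub(parent, "confidence",
         text=None if conf.value is None else _fmt_float(conf.value),
         type=conf.type)


def _fmt_float(value):
    if isinstance(value, float) and value == int(value) and abs(value) < 1e16:
        return str(int(value))
    return repr(value) if isinstance(value, float) else str(value)


def _write_property(parent, prop):
    _sub(parent, "property", text=prop.value, ref=prop.ref, unit=prop.unit,
         datatype=prop.datatype, applies_to=prop.applies_to,
         id_source=prop.id_source)


def _write_uri(parent, uri):
    _sub(parent, "uri", text=uri.value, desc=uri.desc, type=uri.type)


def _write_taxonomy(parent, tax):
    elem = ET.SubElement(parent, "taxonomy")
    if tax.id is not None:
        _sub(elem, "id", text=tax.id.value, provider=tax.id.provider)
    if tax.code is not None:
        _sub(elem, "code", text=tax.code)
    if tax.scientific_name is not None:
        _sub(elem, "scientific_name", text=tax.scientific_name)
    for cn in tax.common_names:
        _sub(elem, "common_name", text=cn)
    if tax.rank is not None:
        _sub(elem, "rank", text=tax.rank)
    if tax.uri is not None:
        _write_uri(elem, tax.uri)


def _write_sequence(parent, seq):
    elem = ET.SubElement(parent, "sequence")
    if seq.type is not None:
        elem.set("type", seq.type)
    if seq.symbol is not None:
        _sub(elem, "symbol", text=seq.symbol)
    if seq.accession is not None:
        _sub(elem, "accession", text=seq.accession.value, source=seq.accession.source)
    if seq.name is not None:
        _sub(elem, "name", text=seq.name)
    if seq.mol_seq is not None:
        mol = _sub(elem, "mol_seq", text=seq.mol_seq)
        if seq.is_aligned is not None:
            mol.set("is_aligned", _serialize_bool(seq.is_aligned))
    if seq.uri is not None:
        _write_uri(elem, seq.uri)
    if seq.domain_architecture is not None:
        arch = ET.SubElement(elem, "domain_architecture")
        if seq.domain_architecture.length is not None:
            arch.set("length", str(seq.domain_architecture.length))
        for dom in seq.domain_architecture.domains:
            attrs = {"from": str(dom.start), "to": str(dom.end)}
            if dom.confidence is not None:
                attrs["confidence"] = _fmt_float(dom.confidence)
            if dom.id is not None:
                attrs["id"] = dom.id
            _sub(arch, "domain", text=dom.value, **attrs)


def _write_events(parent, events):
    elem = ET.SubElement(parent, "events")
    if events.type is not None:
        _sub(elem, "type", text=events.type)
    for tag in ("duplications", "speciations", "losses"):
        value = getattr(events, tag)
        if value is not None:
            _sub(elem, tag, text=str(value))


def _write_clade(parent, clade):
    elem = ET.SubElement(parent, "clade")
    if clade.branch_length is not None:
        elem.set("branch_length", _fmt_float(clade.branch_length))
    if getattr(clade, "id_source", None) is not None:
        elem.set("id_source", clade.id_source)
    if clade.name is not None:
        _sub(elem, "name", text=clade.name)
    confidences = getattr(clade, "confidences", None)
    if confidences is None and clade.confidence is not None:
        confidences = [Confidence(clade.confidence)]
    for conf in confidences or []:
        _write_confidence(elem, conf)
    if clade.width is not None:
        _sub(elem, "width", text=_fmt_float(clade.width))
    if clade.color is not None:
        color = ET.SubElement(elem, "color")
        _sub(color, "red", text=str(clade.color.red))
        _sub(color, "green", text=str(clade.color.green))
        _sub(color, "blue", text=str(clade.color.blue))
    for tax in getattr(clade, "taxonomies", []):
        _write_taxonomy(elem, tax)
    for seq in getattr(clade, "sequences", []):
        _write_sequence(elem, seq)
    if getattr(clade, "events", None) is not None:
        _write_events(elem, clade.events)
    for prop in getattr(clade, "properties", []):
        _write_property(elem, prop)
    for uri in getattr(clade, "uris", []):
        _write_uri(elem, uri)
    for extra in getattr(clade, "extras", []):
        elem.append(copy.deepcopy(extra))
    for child in clade.clades:
        _write_clade(elem, child)


def _write_phylogeny(parent, phy):
    elem = ET.SubElement(parent, "phylogeny")
    elem.set("rooted", _serialize_bool(bool(phy.rooted)))
    if getattr(phy, "rerootable", None) is not None:
        elem.set("rerootable", _serialize_bool(phy.rerootable))
    if getattr(phy, "branch_length_unit", None) is not None:
        elem.set("branch_length_unit", phy.branch_length_unit)
    if getattr(phy, "type", None) is not None:
        elem.set("type", phy.type)
    if phy.name is not None:
        _sub(elem, "name", text=phy.name)
    if phy.id is not None:
        if isinstance(phy.id, Id):
            _sub(elem, "id", text=phy.id.value, provider=phy.id.provider)
        else:
            _sub(elem, "id", text=str(phy.id))
    if getattr(phy, "description", None) is not None:
        _sub(elem, "description", text=phy.description)
    for conf in getattr(phy, "confidences", []):
        _write_confidence(elem, conf)
    for prop in getattr(phy, "properties", []):
        _write_property(elem, prop)
    _write_clade(elem, phy.root)
    for extra in getattr(phy, "extras", []):
        elem.append(copy.deepcopy(extra))


def serialize_phyloxml(phylogenies):
    """Serialize phylogenies into a namespace-correct phyloXML document."""
    root = ET.Element("phyloxml", {
        "xmlns": NAMESPACE,
        "xmlns:xsi": XSI,
        "xsi:schemaLocation": SCHEMA_LOCATION,
    })
    count = 0
    for phy in phylogenies:
        if not isinstance(phy, Phylogeny):
            phy = as_phyloxml(phy)
        _write_phylogeny(root, phy)
        count += 1
    ET.indent(root)
    text = ET.tostring(root, encoding="unicode")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + text + "\n", count


def write(trees, handle):
    """Write trees as one phyloXML document; return the number written."""
    text, count = serialize_phyloxml(trees)
    handle.write(text)
    return count


# ---------------------------------------------------------------------------
# Promotion and alignment extraction

def as_phyloxml(tree):
    """Promote a plain tree to its phyloXML equivalent, losslessly.

    Names, branch lengths, colors and widths carry over; a plain confidence
    becomes ``Confidence(value, type="unknown")``.  An existing
    :class:`Phylogeny` is returned unchanged.
    """
    if isinstance(tree, Phylogeny):
        return tree

    def promote(clade):
        if isinstance(clade, PhyloClade):
            return clade
        new = PhyloClade(
            branch_length=clade.branch_length,
            name=clade.name,
            color=clade.color,
            width=clade.width,
        )
        if clade.confidence is not None:
            new.confidences = [Confidence(clade.confidence, type="unknown")]
        new.clades = [promote(child) for child in clade.clades]
        return new

    if isinstance(tree, Clade):
        return Phylogeny(root=promote(tree), rooted=False)
    return Phylogeny(
        root=promote(tree.root),
        rooted=bool(tree.rooted),
        id=tree.id,
        name=tree.name,
    )


def to_alignment(phylogeny):
    """Rows ``(name, sequence_text)`` from the aligned sequences in a tree.

    One row per clade carrying a ``MolecularSequence`` with ``is_aligned``,
    in preorder.  Unequal row lengths are an error (the offending names are
    listed); a tree without aligned sequences yields an empty alignment with
    a warning.
    """
    rows = []
    for clade in phylogeny.find_clades():
        for seq in getattr(clade, "sequences", []):
            if seq.is_aligned and seq.mol_seq:
                label = (clade.name or seq.name
                         or (seq.accession.value if seq.accession else None) or "")
                rows.append((label, seq.mol_seq))
                break
    if not rows:
        warnings.warn("tree contains no aligned sequences; alignment is empty",
                      PhyloXMLWarning, stacklevel=2)
        return []
    width = len(rows[0][1])
    bad = [name for name, seq in rows if len(seq) != width]
    if bad:
        raise PhyloXMLError(
            f"aligned sequences have unequal lengths; offending rows: {bad}"
        )
    return rows
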