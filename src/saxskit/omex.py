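"""COMBINE/OMEX archive packaging for AnIML documents and companion files.

A COMBINE archive is a ZIP container with a mandatory ``manifest.xml`` that
lists every member (including the manifest itself), one of which is marked
as the *master* document — here the AnIML file.  In the dialect written by
this package each content file additionally gets its own ``metadata.rdf``
carrying a minimal Dublin-Core description (creation time, creators, free
text); archives using the more common single-metadata-file convention are
accepted on read.  The ``.zip`` suffix is used by default, but the suffix is
not semantic and ``.omex`` archives are read just the same.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass
from pathlib import Path, PurePosixPath
from typing import Sequence

from lxml import etree
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import DCTERMS

__all__ = [
    "ArchiveManifestEntry",
    "OmexError",
    "FORMAT_URIS",
    "create_archive",
    "read_archive",
]

_MANIFEST_NS = "http://identifiers.org/combine.specifications/omex-manifest"

FORMAT_URIS = {
    "manifest": "http://identifiers.org/combine.specifications/omex-manifest",
    "metadata": "http://identifiers.org/combine.specifications/omex-metadata",
    "animl": "http://purl.org/NET/mediatypes/application/x-animl",
    # PDH has no registered identifier; a stable custom URI is used instead
    "pdh": "http://purl.org/NET/mediatypes/application/x-saxs-pdh",
    "xml": "http://purl.org/NET/mediatypes/application/xml",
    "json": "http://purl.org/NET/mediatypes/application/json",
    "text": "http://purl.org/NET/mediatypes/text/plain",
    "tsv": "http://purl.org/NET/mediatypes/text/tab-separated-values",
}

_SUFFIX_FORMATS = {
    ".animl": "animl",
    ".pdh": "pdh",
    ".xml": "xml",
    ".json": "json",
    ".tsv": "tsv",
    ".txt": "text",
}


class OmexError(ValueError):
    """Raised for malformed or inconsistent COMBINE archives."""


@dataclass(frozen=True)
class ArchiveManifestEntry:
    location: str
    format: str
    master: bool = False


def format_uri_for(path: str | Path) -> str:
    key = _SUFFIX_FORMATS.get(Path(path).suffix.lower(), "text")
    return FORMAT_URIS[key]


def _manifest_xml(entries: Sequence[ArchiveManifestEntry]) -> bytes:
    root = etree.Element("omexManifest", nsmap={None: _MANIFEST_NS})
    for e in entries:
        etree.SubElement(
            root,
            f"{{{_MANIFEST_NS}}}content",
            location=e.location,
            format=e.format,
            master="true" if e.master else "false",
        )
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def _parse_manifest(data: bytes) -> list[ArchiveManifestEntry]:
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise OmexError(f"manifest.xml is not well-formed XML: {exc}")
    entries = []
    for content in root.findall(f"{{{_MANIFEST_NS}}}content") + root.findall(
        "content"
    ):
        entries.append(
            ArchiveManifestEntry(
                location=content.get("location", ""),
                format=content.get("format", ""),
                master=content.get("master", "false").lower() == "true",
            )
        )
    return entries


def _metadata_rdf(
    location: str,
    creators: Sequence[str],
    description: str,
    created: str,
) -> bytes:
    graph = Graph()
    subject = URIRef(f"./{location}")
    for creator in creators:
        graph.add((subject, DCTERMS.creator, Literal(creator)))
    if description:
        graph.add((subject, DCTERMS.description, Literal(description)))
    graph.add((subject, DCTERMS.created, Literal(created)))
    return graph.serialize(format="pretty-xml").encode("utf-8")


def _metadata_location(location: str) -> str:
    # one metadata.rdf per content file, kept alongside it
    p = PurePosixPath(location)
    return str(p.with_name(p.name + ".metadata.rdf"))


def create_archive(
    animl_path: str | Path,
    extra_files: Sequence[str | Path] = (),
    out_path: str | Path = "archive.zip",
    creators: Sequence[str] = ("saxskit",),
    description: str = "",
    created: str = "1970-01-01T00:00:00Z",
) -> Path:
    """Bundle an AnIML master document and companion files into an archive.

    The manifest lists every member including itself; each content file gets
    a per-file metadata.rdf.  ``created`` is an explicit timestamp so archive
    bytes are reproducible.
    """
    animl_path = Path(animl_path)
    if not animl_path.is_file():
        raise FileNotFoundError(animl_path)
    members: list[tuple[str, Path]] = [(animl_path.name, animl_path)]
    for f in extra_files:
        f = Path(f)
        if not f.is_file():
            raise FileNotFoundError(f)
        members.append((f.name, f))
    locations = [loc for loc, _ in members]
    if len(set(locations)) != len(locations):
        dupes = sorted({l for l in locations if locations.count(l) > 1})
        raise OmexError(f"duplicate in-archive locations: {dupes}")

    entries = [
        ArchiveManifestEntry("manifest.xml", FORMAT_URIS["manifest"], False)
    ]
    payload: list[tuple[str, bytes]] = []
    for loc, src in members:
        entries.append(
            ArchiveManifestEntry(loc, format_uri_for(loc), src == animl_path)
        )
        payload.append((loc, src.read_bytes()))
        meta_loc = _metadata_location(loc)
        entries.append(
            ArchiveManifestEntry(meta_loc, FORMAT_URIS["metadata"], False)
        )
        payload.append(
            (meta_loc, _metadata_rdf(loc, creators, description, created))
        )

    out_path = Path(out_path)
    fixed_time = (1980, 1, 1, 0, 0, 0)  # reproducible zip member timestamps
    with zipfile.ZipFile(out_path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(zipfile.ZipInfo("manifest.xml", fixed_time), _manifest_xml(entries))
        for loc, data in payload:
            zf.writestr(zipfile.ZipInfo(loc, fixed_time), data)
    return out_path


def read_archive(
    path: str | Path, strict: bool = True
) -> tuple[list[ArchiveManifestEntry], dict[str, bytes]]:
    """Read a COMBINE archive: returns (manifest entries, member bytes).

    The archive suffix is not semantic (.zip and .omex both accepted).  In
    strict mode the archive must declare exactly one master and the manifest
    must agree with the member list; lenient mode tolerates missing per-file
    metadata and undeclared members (they are still returned).
    """
    path = Path(path)
    if not zipfile.is_zipfile(path):
        raise OmexError(f"{path} is not a ZIP container")
    with zipfile.ZipFile(path) as zf:
        names = set(zf.namelist())
        if "manifest.xml" not in names:
            raise OmexError(f"{path} has no manifest.xml: not a COMBINE archive")
        entries = _parse_manifest(zf.read("manifest.xml"))
        files = {name: zf.read(name) for name in sorted(names)}

    masters = [e for e in entries if e.master]
    if strict and len(masters) != 1:
        raise OmexError(
            f"archive must declare exactly one master document, found "
            f"{len(masters)}"
        )
    declared = {e.location for e in entries}
    undeclared = sorted(n for n in files if n not in declared)
    missing = sorted(
        loc for loc in declared if loc not in files and loc != "."
    )
    if strict and (undeclared or missing):
        raise OmexError(
            f"manifest/member mismatch: undeclared {undeclared}, "
            f"missing {missing}"
        )
    if len(declared) != len(entries):
        raise OmexError("manifest lists a location more than once")
    return entries, files
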