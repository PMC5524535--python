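"""Offline structured-annotation backend.

Structured biological annotation ties a segment to identifiers from
established resources (GO terms, UniProt accessions, taxa) so segmentations
can be searched and integrated across archives. Everything here is offline:
ontologies are local OBO 1.2 flat files and preset term lists are packaged
CSVs, mirroring the term-search and predefined-list workflow an annotation
tool offers, without any web service. Live lookup services are an obvious
extension point behind the same :class:`TermStore` interface.
"""

from __future__ import annotations

import csv
import logging
import re
import warnings
from collections import deque
from dataclasses import dataclass, field
from importlib import resources

from .errors import FormatError, SegffError, ValidationError
from .model import BiologicalAnnotation, Segmentation

log = logging.getLogger(__name__)

_CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.-]*:\S+$")
_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')


def is_curie(s: str) -> bool:
    return bool(_CURIE_RE.match(s or ""))


@dataclass
class Term:
    id: str
    name: str = ""
    namespace: str = ""
    synonyms: list[str] = field(default_factory=list)
    parents: list[str] = field(default_factory=list)  # is_a targets


@dataclass
class TermStore:
    terms: dict[str, Term] = field(default_factory=dict)

    def __len__(self):
        return len(self.terms)

    def __contains__(self, id):
        return id in self.terms

    def get(self, id: str) -> Term:
        if id not in self.terms:
            raise SegffError(f"unknown term {id!r}")
        return self.terms[id]


# ---------------------------------------------------------------------------
# OBO 1.2
# ---------------------------------------------------------------------------

def load_obo(path) -> TermStore:
    """Parse [Term] stanzas from an OBO 1.2 flat file.

    Reads id, name, namespace, synonym (the quoted string) and is_a (the id
    before any '!' comment). Obsolete terms are skipped with a warning;
    dangling is_a targets are logged but kept.
    """
    store = TermStore()
    cur: dict | None = None
    cur_line = 0
    n_stanzas = 0

    def flush():
        nonlocal cur
        if cur is None:
            return
        if "id" not in cur:
            raise FormatError(
                f"{path}: [Term] stanza starting at line {cur_line} has no id")
        if cur.get("obsolete"):
            warnings.warn(f"skipping obsolete term {cur['id']}")
        else:
            t = Term(id=cur["id"], name=cur.get("name", ""),
                     namespace=cur.get("namespace", ""),
                     synonyms=cur.get("synonyms", []),
                     parents=cur.get("parents", []))
            store.terms[t.id] = t
        cur = None

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("["):
                flush()
                if line == "[Term]":
                    cur = {}
                    cur_line = lineno
                    n_stanzas += 1
                continue
            if cur is None or not line or line.startswith("!"):
                continue
            if ":" not in line:
                continue
            key, _, value = line.partition(":")
            key = key.strip()
            value = value.strip()
            if key == "id":
                cur["id"] = value.split("!")[0].strip()
            elif key == "name":
                cur["name"] = value
            elif key == "namespace":
                cur["namespace"] = value
            elif key == "synonym":
                m = _SYNONYM_RE.match(value)
                if m:
                    cur.setdefault("synonyms", []).append(m.group("text"))
            elif key == "is_a":
                cur.setdefault("parents", []).append(
                    value.split("!")[0].strip())
            elif key == "is_obsolete" and value.lower().startswith("true"):
                cur["obsolete"] = True
    flush()
    if n_stanzas == 0:
        warnings.warn(f"{path}: no [Term] stanzas found; empty term store")
    for t in store.terms.values():
        for p in t.parents:
            if p not in store.terms:
                log.warning("term %s: dangling is_a target %s (kept)",
                            t.id, p)
    return store


def save_obo(store: TermStore, path) -> None:
    """Minimal OBO 1.2 writer (the subset load_obo reads); terms sorted by
    id so output is deterministic."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for tid in sorted(store.terms):
            t = store.terms[tid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {t.id}\n")
            if t.name:
                fh.write(f"name: {t.name}\n")
            if t.namespace:
                fh.write(f"namespace: {t.namespace}\n")
            for s in t.synonyms:
                fh.write(f'synonym: "{s}" EXACT []\n')
            for p in t.parents:
                fh.write(f"is_a: {p}\n")


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def search(store: TermStore, query: str, limit: int = 10):
    """Ranked, deterministic term search.

    Tiers: exact name match (4) > exact synonym (3) > name prefix (2) >
    name/synonym substring (1). Within a tier shorter names rank first,
    then lexicographic id. Case-insensitive; no hits gives an empty list.
    """
    if limit < 1:
        raise SegffError("limit must be >= 1")
    q = query.strip().lower()
    if not q:
        return []
    hits = []
    for t in store.terms.values():
        name = t.name.lower()
        syns = [s.lower() for s in t.synonyms]
        if name == q:
            score = 4
        elif q in syns:
            score = 3
        elif name.startswith(q):
            score = 2
        elif q in name or any(q in s for s in syns):
            score = 1
        else:
            continue
        hits.append((t, score))
    hits.sort(key=lambda h: (-h[1], len(h[0].name), h[0].id))
    return hits[:limit]


def ancestors(store: TermStore, id: str) -> list[str]:
    """Transitive is_a closure of ``id`` (excluded), breadth-first,
    deduplicated; terminates on cyclic inputs."""
    start = store.get(id)
    seen = {start.id}
    out: list[str] = []
    queue = deque(start.parents)
    while queue:
        pid = queue.popleft()
        if pid in seen:
            continue
        seen.add(pid)
        out.append(pid)
        if pid in store.terms:
            queue.extend(store.terms[pid].parents)
    return out


# ---------------------------------------------------------------------------
# annotation editing
# ---------------------------------------------------------------------------

def attach_annotation(seg: Segmentation, segment_id: int,
                      annotation: BiologicalAnnotation,
                      replace: bool = False) -> Segmentation:
    """Set a segment's single biological annotation.

    A segment carries at most one annotation; attaching to an already
    annotated segment requires ``replace=True`` and overwrites it.
    """
    s = seg.segment(segment_id)
    if s.biological_annotation is not None and not replace:
        raise ValidationError(f"segment {segment_id} already annotated")
    s.biological_annotation = annotation
    return seg


# ---------------------------------------------------------------------------
# preset term lists
# ---------------------------------------------------------------------------

@dataclass
class PresetList:
    category: str
    rows: list[tuple] = field(default_factory=list)  # (term_id, resource, label)


def read_preset_csv(path_or_file) -> dict[str, PresetList]:
    """Read a preset CSV (header ``category,term_id,resource,label``) into
    per-category lists, preserving row order."""
    def _parse(fh):
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != \
                ["category", "term_id", "resource", "label"]:
            raise FormatError(
                "preset CSV must start with header "
                "'category,term_id,resource,label'")
        out: dict[str, PresetList] = {}
        for row in reader:
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) != 4:
                raise FormatError(f"preset CSV row has {len(row)} fields, "
                                  "expected 4")
            cat, tid, res, label = (c.strip() for c in row)
            out.setdefault(cat, PresetList(cat)).rows.append(
                (tid, res, label))
        return out

    if hasattr(path_or_file, "read"):
        return _parse(path_or_file)
    with open(path_or_file, "r", encoding="utf-8", newline="") as fh:
        return _parse(fh)


def write_preset_csv(presets, path) -> None:
    """Write preset lists back out in the same CSV schema (categories in
    given order, rows preserved)."""
    if isinstance(presets, PresetList):
        presets = [presets]
    elif isinstance(presets, dict):
        presets = list(presets.values())
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["category", "term_id", "resource", "label"])
        for p in presets:
            for tid, res, label in p.rows:
                w.writerow([p.category, tid, res, label])


def _packaged_presets() -> dict[str, PresetList]:
    ref = resources.files("segff").joinpath("data/presets.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return read_preset_csv(fh)


def available_categories() -> list[str]:
    return sorted(_packaged_presets())


def preset_terms(category: str) -> PresetList:
    """Packaged predefined term list for a frequently studied assembly
    category (ribosome, proteasome, chaperonin, ...)."""
    presets = _packaged_presets()
    if category not in presets:
        raise SegffError(
            f"unknown preset category {category!r}; available: "
            + ", ".join(sorted(presets)))
    return presets[category]


def packaged_ontology_path():
    """Path to the packaged toy GO slice used for offline search and tests."""
    return resources.files("segff").joinpath("data/toy_go.obo")
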