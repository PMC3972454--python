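"""Controlled-vocabulary data dictionary with a regex-driven hierarchy.

Every measure (spreadsheet column) gets a dictionary entry carrying a
short axis label and a long description.  On top of the flat term list, a
set of *grouping terms* — each defined by a regular expression — imposes a
browsable hierarchy: expanding a group evaluates its pattern against
candidate labels, so the tree is lazy and only the explored branches cost
anything.  A coverage check classifies every leaf term as uniquely
placed, unmatched, or multi-parent, which is how new columns that follow
an established naming convention (``MRI_``, ``PHX_``, ``GAF_``, ``TBX_``
prefixes and the like) are validated without touching the pattern set.
"""

from __future__ import annotations

import csv
import dataclasses
import re
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

__all__ = [
    "DictionaryTerm",
    "GroupingTerm",
    "DictionaryHierarchy",
    "CoverageReport",
    "DataDictionary",
    "load_dictionary",
    "expand_group",
]


class DictionaryError(ValueError):
    pass


@dataclasses.dataclass
class DictionaryTerm:
    name: str
    axis_label: str
    description: str = ""
    external_links: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.axis_label:
            raise DictionaryError(f"term {self.name!r} has an empty axis label")


@dataclasses.dataclass
class GroupingTerm:
    """A hierarchy node defined by a pattern over candidate labels.

    Patterns are stored without surrounding slashes; a ``/(…)/`` notation
    is stripped on load.  Matching uses unanchored search semantics.
    """

    label: str
    pattern: str
    parent: str | None = None  # label of parent group, or None for root

    def __post_init__(self) -> None:
        self.pattern = _strip_slashes(self.pattern)
        try:
            self._compiled = re.compile(self.pattern)
        except re.error as exc:
            raise DictionaryError(
                f"grouping term {self.label!r}: invalid pattern {self.pattern!r}: {exc}"
            ) from exc

    @property
    def compiled(self) -> re.Pattern:
        return self._compiled


def _strip_slashes(pattern: str) -> str:
    if len(pattern) >= 2 and pattern.startswith("/") and pattern.endswith("/"):
        return pattern[1:-1]
    return pattern


def expand_group(group: GroupingTerm, candidates: Sequence[str]) -> list[str]:
    """Candidates whose label matches the group pattern, in candidate order."""
    return [c for c in candidates if group.compiled.search(c)]


@dataclasses.dataclass
class CoverageReport:
    unmatched_terms: list[str]
    multi_parent_terms: list[tuple[str, list[str]]]
    empty_groups: list[str]
    placed_terms: dict[str, str] = dataclasses.field(default_factory=dict)

    @property
    def n_uniquely_placed(self) -> int:
        return len(self.placed_terms)

    @property
    def complete(self) -> bool:
        return not self.unmatched_terms


class DictionaryHierarchy:
    """Grouping terms forming a lazy, acyclic tree over leaf terms.

    Children of a group are (a) grouping terms declaring it as parent,
    then (b) leaf terms matching its pattern that are not claimed by any
    of its child groups.
    """

    def __init__(self, groups: Iterable[GroupingTerm]):
        self.groups: dict[str, GroupingTerm] = {}
        for g in groups:
            if g.label in self.groups:
                raise DictionaryError(f"duplicate grouping term {g.label!r}")
            self.groups[g.label] = g
        for g in self.groups.values():
            if g.parent is not None and g.parent not in self.groups:
                raise DictionaryError(
                    f"grouping term {g.label!r} names unknown parent {g.parent!r}"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for start in self.groups:
            seen = set()
            cur: str | None = start
            while cur is not None:
                if cur in seen:
                    raise DictionaryError(f"cycle in hierarchy involving {cur!r}")
                seen.add(cur)
                cur = self.groups[cur].parent

    @property
    def roots(self) -> list[GroupingTerm]:
        return [g for g in self.groups.values() if g.parent is None]

    def child_groups(self, label: str) -> list[GroupingTerm]:
        return [g for g in self.groups.values() if g.parent == label]

    def children(self, label: str, leaf_names: Sequence[str]) -> list[str]:
        """Expand one node: child group labels, then unclaimed matching leaves.

        Only this node's pattern and its direct children's patterns are
        evaluated; sibling branches stay untouched (lazy expansion).
        """
        group = self.groups[label]
        subgroups = self.child_groups(label)
        out = [g.label for g in subgroups]
        claimed: set[str] = set()
        for sg in subgroups:
            claimed.update(expand_group(sg, leaf_names))
        out.extend(t for t in expand_group(group, leaf_names) if t not in claimed)
        return out

    def leaf_parents(self, term: str) -> list[str]:
        """Groups under which a leaf is placed (pattern matches, no child claims)."""
        parents = []
        for g in self.groups.values():
            if not g.compiled.search(term):
                continue
            if any(sg.compiled.search(term) for sg in self.child_groups(g.label)):
                continue
            parents.append(g.label)
        return parents


def coverage_check(
    hierarchy: DictionaryHierarchy, terms: Sequence[str] | Sequence[DictionaryTerm]
) -> CoverageReport:
    """Classify every leaf term: uniquely placed, unmatched, or multi-parent."""
    names = [t.name if isinstance(t, DictionaryTerm) else t for t in terms]
    unmatched: list[str] = []
    multi: list[tuple[str, list[str]]] = []
    placed: dict[str, str] = {}
    for name in names:
        parents = hierarchy.leaf_parents(name)
        if not parents:
            unmatched.append(name)
        elif len(parents) == 1:
            placed[name] = parents[0]
        else:
            multi.append((name, parents))
    empty = [
        g.label
        for g in hierarchy.groups.values()
        if not hierarchy.children(g.label, names)
    ]
    return CoverageReport(unmatched, multi, empty, placed)


class DataDictionary:
    """Flat term registry plus the grouping hierarchy."""

    def __init__(self, terms: Iterable[DictionaryTerm], hierarchy: DictionaryHierarchy):
        self.terms: dict[str, DictionaryTerm] = {}
        for t in terms:
            if t.name in self.terms:
                raise DictionaryError(f"duplicate term name {t.name!r}")
            self.terms[t.name] = t
        self.hierarchy = hierarchy

    def __contains__(self, name: str) -> bool:
        return name in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def term_names(self) -> list[str]:
        return list(self.terms)

    def lookup(self, name: str) -> DictionaryTerm:
        if name not in self.terms:
            raise DictionaryError(f"unknown dictionary term {name!r}")
        return self.terms[name]

    def suggest(self, name: str, n: int = 3) -> list[str]:
        """Nearest terms by edit distance, for validation feedback."""
        import difflib

        return difflib.get_close_matches(name, self.term_names, n=n, cutoff=0.6)

    def search(self, query: str) -> list[DictionaryTerm]:
        """Case-insensitive match on name, axis label and description.

        Name hits rank before label/description hits.  An invalid regex is
        retried as a literal substring instead of raising.
        """
        try:
            rx = re.compile(query, re.IGNORECASE)
        except re.error:
            rx = re.compile(re.escape(query), re.IGNORECASE)
        name_hits, other_hits = [], []
        for t in self.terms.values():
            if rx.search(t.name):
                name_hits.append(t)
            elif rx.search(t.axis_label) or rx.search(t.description):
                other_hits.append(t)
        return name_hits + other_hits

    def coverage_check(self) -> CoverageReport:
        return coverage_check(self.hierarchy, self.term_names)

    def export_structured(self) -> str:
        """Term list as HTML5 with machine-readable (RDFa-style) attributes.

        One numbered entry per term; names, labels, descriptions and links
        are carried in ``property`` attributes so a parser can recover them
        exactly.
        """
        html = etree.Element("html")
        body = etree.SubElement(html, "body")
        ol = etree.SubElement(body, "ol", {"class": "data-dictionary"})
        for i, t in enumerate(self.terms.values(), start=1):
            li = etree.SubElement(
                ol, "li", {"typeof": "MeasureTerm", "resource": f"#term-{i}"}
            )
            num = etree.SubElement(li, "span", {"class": "seq"})
            num.text = str(i)
            name = etree.SubElement(li, "span", {"property": "name"})
            name.text = t.name
            label = etree.SubElement(li, "span", {"property": "axisLabel"})
            label.text = t.axis_label
            desc = etree.SubElement(li, "span", {"property": "description"})
            desc.text = t.description
            for link_label, url in t.external_links:
                a = etree.SubElement(li, "a", {"property": "externalLink", "href": url})
                a.text = link_label
        return etree.tostring(
            html, pretty_print=True, doctype="<!DOCTYPE html>", encoding="unicode"
        )

    def tree_text(self) -> str:
        """Indented text rendering of the hierarchy."""
        names = self.term_names
        lines: list[str] = []

        def walk(label: str, depth: int) -> None:
            lines.append("  " * depth + label)
            for child in self.hierarchy.children(label, names):
                if child in self.hierarchy.groups:
                    walk(child, depth + 1)
                else:
                    lines.append("  " * (depth + 1) + child)

        for root in self.hierarchy.roots:
            walk(root.label, 0)
        return "\n".join(lines)


def parse_structured(html_text: str) -> list[tuple[str, str, str]]:
    """Recover (name, axis label, description) triples from the HTML export."""
    root = etree.fromstring(html_text.encode())
    out = []
    for li in root.iter("li"):
        fields = {
            el.get("property"): (el.text or "")
            for el in li
            if el.get("property") in ("name", "axisLabel", "description")
        }
        out.append((fields["name"], fields["axisLabel"], fields["description"]))
    return out


def load_dictionary(
    terms_path: str | Path, patterns_path: str | Path
) -> DataDictionary:
    """Load terms CSV (name,axis_label,description,links) and patterns JSON.

    An invalid regex or a duplicate term name is a hard error; expansion of
    the hierarchy itself stays lazy.
    """
    import json

    terms: list[DictionaryTerm] = []
    with open(terms_path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            links = []
            for chunk in (row.get("links") or "").split(";"):
                chunk = chunk.strip()
                if chunk:
                    links.append((chunk.split("/")[-1] or chunk, chunk))
            terms.append(
                DictionaryTerm(
                    row["name"], row["axis_label"], row.get("description", ""), links
                )
            )
    raw = json.loads(Path(patterns_path).read_text())
    groups = [
        GroupingTerm(d["label"], d["pattern"], d.get("parent")) for d in raw
    ]
    return DataDictionary(terms, DictionaryHierarchy(groups))
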