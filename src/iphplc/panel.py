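"""Antibody panel registry.

An IP-HPLC screen runs one immunoprecipitation column per antibody. The panel
catalog records which antibodies were run, grouped into functional categories
(signaling pathways, inflammation, apoptosis, ...), plus *overlap references*:
antibodies listed parenthetically under a second category because the same
protein is relevant to more than one pathway. An overlap reference is not a
separate measurement — it must resolve, by exact name, to exactly one primary
entry somewhere in the catalog.

The packaged default panel transcribes the study's 218-antibody / 20-category
table (73 overlap references); see ``data/panel218.CHANGELOG.md`` for the
transcription record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import PanelError

HOUSEKEEPING_CATEGORY = "Control housekeeping proteins"

_PANEL_COLUMNS = ("name", "category", "is_overlap", "source_tag", "description")


@dataclass(frozen=True)
class AntibodyEntry:
    """One row of the panel: a primary antibody or an overlap reference."""

    name: str
    category: str
    is_overlap_reference: bool = False
    source_tag: str = ""
    target_description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelError("antibody name must be non-empty")
        if not self.category:
            raise PanelError(f"entry {self.name!r}: category must be non-empty")


@dataclass
class PanelCatalog:
    """An ordered antibody panel with overlap cross-references.

    ``categories`` preserves first-appearance order of the source file, which
    fixes the deterministic antibody ordering used by the reporting plots.
    """

    categories: list[str]
    entries: list[AntibodyEntry]
    housekeeping_category: str = HOUSEKEEPING_CATEGORY

    def __post_init__(self) -> None:
        self._validate()

    # -- queries -----------------------------------------------------------

    def primary_entries(self, category: str | None = None) -> list[AntibodyEntry]:
        return [
            e
            for e in self.entries
            if not e.is_overlap_reference
            and (category is None or e.category == category)
        ]

    def overlap_entries(self, category: str | None = None) -> list[AntibodyEntry]:
        return [
            e
            for e in self.entries
            if e.is_overlap_reference
            and (category is None or e.category == category)
        ]

    def housekeeping_names(self) -> list[str]:
        return [e.name for e in self.primary_entries(self.housekeeping_category)]

    def primary_names(self) -> list[str]:
        """All primary antibody names in panel order (duplicates preserved)."""
        return [e.name for e in self.primary_entries()]

    def resolve_overlap(self, entry: AntibodyEntry) -> AntibodyEntry:
        """Return the unique primary entry an overlap reference points at."""
        matches = [
            e
            for e in self.entries
            if not e.is_overlap_reference and e.name == entry.name
        ]
        if len(matches) != 1:
            raise PanelError(
                f"overlap reference {entry.name!r} in {entry.category!r} "
                f"resolves to {len(matches)} primary entries (expected 1)"
            )
        return matches[0]

    def category_members(self, category: str) -> list[AntibodyEntry]:
        """Primary entries then resolved overlap references, in file order."""
        if category not in self.categories:
            raise PanelError(f"unknown category {category!r}")
        members = self.primary_entries(category)
        members += [self.resolve_overlap(e) for e in self.overlap_entries(category)]
        return members

    def primary_category_of(self, antibody: str) -> str | None:
        for e in self.entries:
            if not e.is_overlap_reference and e.name == antibody:
                return e.category
        return None

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        seen: set[tuple[str, str, bool]] = set()
        primary_by_name: dict[str, int] = {}
        for i, e in enumerate(self.entries):
            key = (e.name, e.category, e.is_overlap_reference)
            if key in seen:
                raise PanelError(f"row {i}: duplicate entry {key}")
            seen.add(key)
            if e.category not in self.categories:
                raise PanelError(f"row {i}: category {e.category!r} not declared")
            if not e.is_overlap_reference:
                primary_by_name[e.name] = primary_by_name.get(e.name, 0) + 1
        for i, e in enumerate(self.entries):
            if e.is_overlap_reference and primary_by_name.get(e.name, 0) != 1:
                raise PanelError(
                    f"row {i}: overlap reference {e.name!r} in {e.category!r} must "
                    f"resolve to exactly one primary entry "
                    f"(found {primary_by_name.get(e.name, 0)})"
                )
        if self.housekeeping_category not in self.categories:
            raise PanelError(
                f"housekeeping category {self.housekeeping_category!r} missing"
            )


def category_counts(catalog: PanelCatalog) -> dict[str, tuple[int, int]]:
    """Per-category (primary count, overlap count), in catalog category order."""
    counts = {c: [0, 0] for c in catalog.categories}
    for e in catalog.entries:
        counts[e.category][1 if e.is_overlap_reference else 0] += 1
    return {c: (p, o) for c, (p, o) in counts.items()}


def _entries_to_catalog(
    raw: Iterable[tuple[int, dict[str, str]]], source: str
) -> PanelCatalog:
    entries: list[AntibodyEntry] = []
    categories: list[str] = []
    for lineno, rec in raw:
        try:
            flag = str(rec.get("is_overlap", "0")).strip().lower()
            if flag not in {"0", "1", "true", "false"}:
                raise PanelError(f"is_overlap must be boolean, got {flag!r}")
            entry = AntibodyEntry(
                name=rec.get("name", "").strip(),
                category=rec.get("category", "").strip(),
                is_overlap_reference=flag in {"1", "true"},
                source_tag=(rec.get("source_tag") or "").strip(),
                target_description=(rec.get("description") or "").strip(),
            )
        except PanelError as exc:
            raise PanelError(f"{source}, row {lineno}: {exc}") from exc
        entries.append(entry)
        if entry.category not in categories:
            categories.append(entry.category)
    if not entries:
        raise PanelError(f"{source}: panel file contains no entries")
    try:
        return PanelCatalog(categories=categories, entries=entries)
    except PanelError as exc:
        raise PanelError(f"{source}: {exc}") from exc


def load_panel(path: str | Path) -> PanelCatalog:
    """Load a panel from TSV (header: name category is_overlap source_tag
    description) or from an equivalent JSON rendering."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        records = json.loads(text)
        if not isinstance(records, list):
            raise PanelError(f"{path}: JSON panel must be a list of objects")
        return _entries_to_catalog(enumerate(records, start=1), str(path))

    lines = [
        (i, ln)
        for i, ln in enumerate(text.splitlines(), start=1)
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise PanelError(f"{path}: empty panel file")
    header = [h.strip() for h in lines[0][1].split("\t")]
    missing = {"name", "category", "is_overlap"} - set(header)
    if missing:
        raise PanelError(f"{path}: header missing columns {sorted(missing)}")

    def rows() -> Iterable[tuple[int, dict[str, str]]]:
        for lineno, ln in lines[1:]:
            fields = ln.split("\t")
            yield lineno, dict(zip(header, fields))

    return _entries_to_catalog(rows(), str(path))


def write_panel(catalog: PanelCatalog, path: str | Path) -> Path:
    """Write a catalog in the TSV (or, by extension, JSON) panel format."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = [
            {
                "name": e.name,
                "category": e.category,
                "is_overlap": "1" if e.is_overlap_reference else "0",
                "source_tag": e.source_tag,
                "description": e.target_description,
            }
            for e in catalog.entries
        ]
        path.write_text(
            json.dumps(payload, ensure_ascii=False, indent=1), encoding="utf-8"
        )
        return path
    out = ["\t".join(_PANEL_COLUMNS)]
    for e in catalog.entries:
        out.append(
            "\t".join(
                [
                    e.name,
                    e.category,
                    "1" if e.is_overlap_reference else "0",
                    e.source_tag,
                    e.target_description,
                ]
            ).rstrip("\t")
        )
    path.write_text("\n".join(out) + "\n", encoding="utf-8")
    return path


def load_default_panel() -> PanelCatalog:
    """The packaged 218-antibody panel."""
    ref = resources.files("iphplc.data").joinpath("panel218.tsv")
    with resources.as_file(ref) as p:
        return load_panel(p)
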