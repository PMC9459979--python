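"""Unified S-haplotype nomenclature for radish.

Several research groups published radish S haplotypes under their own
numbering schemes (Okamoto, Lim, Kim D, and assorted other groups), and the
schemes overlap: one biological haplotype may carry three or four names.
This module loads a cross-reference table of team-specific labels, treats
each table row as a declaration that its labels denote the same haplotype,
and unifies the declarations into non-redundant classes by transitive
closure.  Classes are assigned canonical ``NAU-S<k>`` names; novel
haplotypes discovered downstream extend the numbering monotonically
(``NAU-S53``, ``NAU-S54``, ...).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "Team",
    "AliasRecord",
    "AliasTable",
    "UnifiedHaplotype",
    "Registry",
    "RegistryError",
    "UnknownLabelError",
    "load_alias_table",
    "unify",
    "default_registry",
    "packaged_alias_table_path",
]


class RegistryError(ValueError):
    """Malformed alias table or inconsistent registry operation."""


class UnknownLabelError(KeyError):
    """A (team, label) pair absent from the registry."""


class Team(str, Enum):
    OKAMOTO = "okamoto"
    LIM = "lim"
    KIM_D = "kim_d"
    OTHER = "other"


# Canonical numbering walks teams in this order (see `unify`).
_TEAM_PRIORITY = {Team.OKAMOTO: 0, Team.LIM: 1, Team.KIM_D: 2, Team.OTHER: 3}

_PAREN_RE = re.compile(r"\(([^()]*)\)")


@dataclass(frozen=True)
class AliasRecord:
    """One team-specific haplotype name plus its declared equivalences.

    ``label`` is the normalized primary name; ``synonyms`` are secondary
    names of the *same* team taken from parenthesized tokens in the table
    cell ("S22 (S7)" gives label "S22", synonym "S7").  ``links`` are
    (team, label) pairs of other records declared equivalent by row
    co-membership.
    """

    team: Team
    label: str
    synonyms: frozenset[str] = frozenset()
    links: frozenset[tuple[Team, str]] = frozenset()
    similarity_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.label:
            raise RegistryError("alias label empty after normalization")
        if (self.team, self.label) in self.links:
            raise RegistryError(f"record {self.team.value}:{self.label} links to itself")

    @property
    def key(self) -> tuple[Team, str]:
        return (self.team, self.label)


@dataclass
class AliasTable:
    records: list[AliasRecord] = field(default_factory=list)
    # row number (1-based, data rows) for each record, for error reporting
    row_of: dict[tuple[Team, str], int] = field(default_factory=dict)
    fixture_names: dict[tuple[Team, str], str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class UnifiedHaplotype:
    nau_name: str
    members: frozenset[tuple[Team, str]]
    si_class: str = "unknown"  # class_I | class_II | unknown


def normalize_label(cell: str) -> tuple[str, frozenset[str]]:
    """Split a table cell into (primary label, same-team synonyms).

    Parenthesized tokens are synonyms of the same team, not cross-team
    links: "S22 (S7)" names one Okamoto haplotype under two Okamoto labels.
    """
    synonyms = frozenset(t.strip() for t in _PAREN_RE.findall(cell) if t.strip())
    primary = _PAREN_RE.sub("", cell).strip()
    return primary, synonyms


def _parse_similarity(cell: str) -> Optional[float]:
    cell = cell.strip().rstrip("%")
    if not cell:
        return None
    try:
        value = float(cell)
    except ValueError:
        return None
    if not 0.0 <= value <= 100.0:
        raise RegistryError(f"similarity {value} outside [0, 100]")
    return value


def load_alias_table(path: str | Path) -> AliasTable:
    """Load a TSV cross-reference of team-specific S-haplotype labels.

    Expected columns: ``nau_name`` (optional, fixture validation only),
    one column per team (``okamoto``, ``lim``, ``kim_d``, ``other``), and
    optional similarity annotation columns.  All non-empty team cells in a
    row are declared mutually equivalent.

    Raises
    ------
    RegistryError
        If a row has no non-empty team cell, or the same (team, label)
        appears in two different rows.
    """
    path = Path(path)
    table = AliasTable()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t", restval="")
        if reader.fieldnames is None:
            raise RegistryError(f"{path}: empty file, header row required")
        team_cols = [t for t in Team if t.value in reader.fieldnames]
        if not team_cols:
            raise RegistryError(f"{path}: no team columns found in header")
        for row_no, row in enumerate(reader, start=1):
            entries: list[tuple[Team, str, frozenset[str]]] = []
            for team in team_cols:
                cell = (row.get(team.value) or "").strip()
                if not cell:
                    continue
                primary, synonyms = normalize_label(cell)
                if not primary:
                    raise RegistryError(f"{path}:{row_no}: cell '{cell}' empty after normalization")
                entries.append((team, primary, synonyms))
            if not entries:
                raise RegistryError(f"{path}:{row_no}: row has no non-empty team cell")
            sim = _parse_similarity(row.get("sim_okamoto_lim") or "")
            keys = [(team, label) for team, label, _ in entries]
            for (team, label, synonyms) in entries:
                key = (team, label)
                if key in table.row_of:
                    raise RegistryError(
                        f"{path}: duplicate {team.value}:{label} in rows "
                        f"{table.row_of[key]} and {row_no}"
                    )
                links = frozenset(k for k in keys if k != key)
                table.records.append(
                    AliasRecord(team, label, synonyms, links, similarity_pct=sim)
                )
                table.row_of[key] = row_no
                fixture = (row.get("nau_name") or "").strip()
                if fixture:
                    table.fixture_names[key] = fixture
    return table


def _numeric_key(label: str) -> tuple[int, str]:
    """Ordering key for a label: first embedded integer, then the label."""
    m = re.search(r"\d+", label)
    return (int(m.group()) if m else 0, label)


class _UnionFind:
    def __init__(self, items: Iterable[tuple[Team, str]]) -> None:
        self.parent = {item: item for item in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def unify(table: AliasTable) -> list[UnifiedHaplotype]:
    """Collapse the alias link graph into unified haplotype classes.

    Connected components of the equivalence graph (transitive closure of
    the declared links) become one class each.  Components are numbered
    ``NAU-S1``, ``NAU-S2``, ... deterministically: by the most senior team
    represented (okamoto < lim < kim_d < other), then by the numeric part
    of that team's smallest primary label.  Row order of the input is
    irrelevant.
    """
    uf = _UnionFind(r.key for r in table.records)
    for record in table.records:
        for link in record.links:
            if link in uf.parent:
                uf.union(record.key, link)

    by_record: dict[tuple[Team, str], AliasRecord] = {r.key: r for r in table.records}
    components: dict[tuple[Team, str], list[AliasRecord]] = {}
    for record in table.records:
        components.setdefault(uf.find(record.key), []).append(record)

    def order_key(records: list[AliasRecord]) -> tuple[int, tuple[int, str]]:
        best_team = min((r.team for r in records), key=_TEAM_PRIORITY.__getitem__)
        labels = [r.label for r in records if r.team == best_team]
        return (_TEAM_PRIORITY[best_team], min(_numeric_key(lab) for lab in labels))

    unified: list[UnifiedHaplotype] = []
    for index, records in enumerate(sorted(components.values(), key=order_key), start=1):
        members = set()
        for r in records:
            members.add(r.key)
            members.update((r.team, syn) for syn in r.synonyms)
        unified.append(UnifiedHaplotype(f"NAU-S{index}", frozenset(members)))
    _ = by_record  # membership bookkeeping only
    return unified


_NAU_RE = re.compile(r"^NAU-S0*(\d+)$")


def parse_nau_index(nau_name: str) -> int:
    m = _NAU_RE.match(nau_name)
    if not m:
        raise RegistryError(f"not a NAU-S name: {nau_name!r}")
    return int(m.group(1))


class Registry:
    """Serves NAU-S names: alias lookup, reverse lookup, novel registration."""

    def __init__(self, haplotypes: Iterable[UnifiedHaplotype] = ()) -> None:
        self.haplotypes: dict[str, UnifiedHaplotype] = {}
        self._member_index: dict[tuple[Team, str], str] = {}
        self._novel: dict[str, str] = {}  # query_id -> nau_name
        for hap in haplotypes:
            self.add(hap)

    def add(self, hap: UnifiedHaplotype) -> None:
        if hap.nau_name in self.haplotypes:
            raise RegistryError(f"duplicate name {hap.nau_name}")
        for member in hap.members:
            if member in self._member_index:
                raise RegistryError(
                    f"{member[0].value}:{member[1]} already in "
                    f"{self._member_index[member]}"
                )
        self.haplotypes[hap.nau_name] = hap
        for member in hap.members:
            self._member_index[member] = hap.nau_name

    def __len__(self) -> int:
        return len(self.haplotypes)

    def lookup(self, team: Team | str, label: str) -> str:
        """NAU-S name carrying (team, label); UnknownLabelError if absent."""
        team = Team(team)
        try:
            return self._member_index[(team, label)]
        except KeyError:
            raise UnknownLabelError(f"{team.value}:{label} not in registry") from None

    def members(self, nau_name: str) -> frozenset[tuple[Team, str]]:
        try:
            return self.haplotypes[nau_name].members
        except KeyError:
            raise UnknownLabelError(f"{nau_name} not in registry") from None

    def si_class(self, nau_name: str) -> str:
        return self.haplotypes[nau_name].si_class

    def set_si_class(self, nau_name: str, si_class: str) -> None:
        if si_class not in ("class_I", "class_II", "unknown"):
            raise RegistryError(f"invalid si_class {si_class!r}")
        self.haplotypes[nau_name].si_class = si_class

    def register_novel(self, query_id: str) -> str:
        """Assign the next free NAU-S number to a novel haplotype.

        Idempotent per query id: re-registering returns the name assigned
        the first time.
        """
        if query_id in self._novel:
            return self._novel[query_id]
        next_index = max(
            (parse_nau_index(name) for name in self.haplotypes), default=0
        ) + 1
        name = f"NAU-S{next_index}"
        self.add(UnifiedHaplotype(name, frozenset()))
        self._novel[query_id] = name
        return name

    # -- serialization -------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["nau_name", "team", "label"])
            for name in sorted(self.haplotypes, key=parse_nau_index):
                for team, label in sorted(self.haplotypes[name].members):
                    writer.writerow([name, team.value, label])

    def to_json(self, path: str | Path) -> None:
        payload = {
            name: {
                "members": sorted([t.value, lab] for t, lab in hap.members),
                "si_class": hap.si_class,
            }
            for name, hap in sorted(
                self.haplotypes.items(), key=lambda kv: parse_nau_index(kv[0])
            )
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def packaged_alias_table_path() -> Path:
    return Path(__file__).parent / "data" / "alias_table.tsv"


def default_registry() -> Registry:
    """Registry built from the packaged radish alias cross-reference."""
    return Registry(unify(load_alias_table(packaged_alias_table_path())))
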