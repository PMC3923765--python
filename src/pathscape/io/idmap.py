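"""Offline identifier-mapping tables (two-column TSV, possibly many-to-many)."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import FormatError


@dataclass
class IdMappingTable:
    """Rows of (source id, target id); a source may map to several targets."""

    rows: list[tuple[str, str]] = field(default_factory=list)
    _index: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for s, t in self.rows:
            if not s or not t:
                raise FormatError("empty identifier in mapping table")
            self._index.setdefault(s, []).append(t)

    def map(self, source_id: str) -> list[str]:
        return self._index.get(source_id, [])

    def map_one(self, source_id: str) -> str:
        """First mapped target, or the source itself when unmapped."""
        targets = self.map(source_id)
        return targets[0] if targets else source_id

    def translate_set(self, ids: frozenset[str]) -> frozenset[str]:
        """Union of originals and all their mapped targets."""
        out = set(ids)
        for i in ids:
            out.update(self.map(i))
        return frozenset(out)


def read_id_mapping(text: str) -> IdMappingTable:
    rows = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"mapping table line {ln}: expected 2 tab-separated columns")
        rows.append((parts[0].strip(), parts[1].strip()))
    return IdMappingTable(rows)
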