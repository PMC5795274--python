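"""GMT and TSV readers/writers shared by all pipeline stages.

The GMT dialect is the MSigDB one: tab-separated, UTF-8, no quoting; one
gene set per line as ``name<TAB>description<TAB>member1<TAB>member2...``.
The description field is preserved verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("tfannot")

__all__ = [
    "GeneSetCollection",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "read_gene_table",
    "write_gene_table",
]


class GmtParseError(ValueError):
    """Raised when a GMT line cannot be parsed; message carries the line number."""


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (one annotation source, or a compendium).

    ``source_type`` distinguishes manually curated sources (OMIM-like) from
    machine annotation sources (GWAS-like); it drives the gene-universe policy
    during enrichment and is ``None`` for collections where the distinction
    does not apply (e.g. a TF->TG compendium).
    """

    name: str
    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source_type: str | None = None  # "curated" | "machine" | None

    def __post_init__(self) -> None:
        for set_name in self.sets:
            self.descriptions.setdefault(set_name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, set_name: str) -> frozenset[str]:
        return self.sets[set_name]

    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return frozenset(out)


def read_gmt(path: str | Path, name: str | None = None,
             source_type: str | None = None) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    Lines with fewer than three tab-separated fields raise
    :class:`GmtParseError` with the 1-based line number. Duplicate members
    within a line are deduplicated with a logged warning. Line order is
    preserved (dicts are insertion-ordered).
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_name, description, *members = fields
            members = [m for m in members if m]
            uniq = frozenset(members)
            if len(uniq) < len(members):
                logger.warning(
                    "%s:%d: %d duplicate member(s) in set %r collapsed",
                    path, lineno, len(members) - len(uniq), set_name,
                )
            sets[set_name] = uniq
            descriptions[set_name] = description
    return GeneSetCollection(
        name=name or path.stem,
        sets=sets,
        descriptions=descriptions,
        source_type=source_type,
    )


def write_gmt(collection: GeneSetCollection | Mapping[str, Iterable[str]],
              path: str | Path) -> None:
    """Write gene sets as GMT. Members are sorted for reproducible output."""
    if isinstance(collection, GeneSetCollection):
        sets = collection.sets
        descriptions = collection.descriptions
    else:
        sets = {k: frozenset(v) for k, v in collection.items()}
        descriptions = {k: "" for k in sets}
    with open(path, "w", encoding="utf-8") as fh:
        for set_name, members in sets.items():
            fields = [set_name, descriptions.get(set_name, "")]
            fields.extend(sorted(members))
            fh.write("\t".join(fields) + "\n")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read the gene metadata table (gene_id, is_coding, per-source flags)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    bool_cols = [c for c in df.columns if c == "is_coding" or c.startswith("in_")]
    for c in bool_cols:
        df[c] = df[c].astype(bool)
    return df


def write_gene_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
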