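"""Data model and summary statistics for the TF -> target-gene compendium.

A compendium is a directed bipartite-ish edge set from transcription factors
to target genes (TFs are themselves genes, so TF->TF edges and self-loops are
legal). Edges are unweighted after FDR filtering; an edge may carry several
evidence labels when it was observed in more than one source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import GeneSetCollection, read_gmt, write_gmt

EVIDENCE_LABELS = ("low_throughput", "encode", "other_high_throughput")
LOW = "low_throughput"
HIGH = ("encode", "other_high_throughput")

__all__ = [
    "Compendium",
    "merge_sources",
    "degree_statistics",
    "master_regulators",
    "read_edge_list",
]


class EdgeParseError(ValueError):
    pass


@dataclass
class Compendium:
    """Directed TF->TG edge set with per-edge evidence labels.

    ``edges`` maps (tf_id, tg_id) to the set of evidence labels supporting
    the relationship. Rosters are projections of the edge set.
    """

    edges: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(tf for tf, _ in self.edges)

    @property
    def tgs(self) -> frozenset[str]:
        return frozenset(tg for _, tg in self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def targets_of(self, tf: str) -> frozenset[str]:
        return frozenset(tg for (t, tg) in self.edges if t == tf)

    def target_map(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for tf, tg in self.edges:
            out.setdefault(tf, set()).add(tg)
        return {tf: frozenset(s) for tf, s in out.items()}

    def regulator_map(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for tf, tg in self.edges:
            out.setdefault(tg, set()).add(tf)
        return {tg: frozenset(s) for tg, s in out.items()}

    def add_edge(self, tf: str, tg: str, evidence: str) -> None:
        if not tf or not tg:
            raise EdgeParseError(f"edge with empty id: ({tf!r}, {tg!r})")
        self.edges.setdefault((tf, tg), set()).add(evidence)

    # -- GMT serialization: one line per TF (tf_id, description, TGs) -------

    def to_gmt(self, path: str | Path) -> None:
        write_gmt(self.to_collection(), path)

    def to_collection(self) -> GeneSetCollection:
        return GeneSetCollection(
            name="compendium",
            sets={tf: tgs for tf, tgs in sorted(self.target_map().items())},
        )

    @classmethod
    def from_gmt(cls, path: str | Path,
                 evidence: str = "other_high_throughput") -> "Compendium":
        coll = read_gmt(path)
        return cls.from_collection(coll, evidence=evidence)

    @classmethod
    def from_collection(cls, coll: GeneSetCollection | Mapping[str, Iterable[str]],
                        evidence: str = "other_high_throughput") -> "Compendium":
        sets = coll.sets if isinstance(coll, GeneSetCollection) else coll
        comp = cls()
        for tf, tgs in sets.items():
            for tg in tgs:
                comp.add_edge(tf, tg, evidence)
        return comp


def read_edge_list(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a TSV edge list (tf, tg, evidence); header optional.

    Malformed rows (missing ids) raise :class:`EdgeParseError` with the line
    number.
    """
    edges: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] in ("tf", "tf_id"):
                continue
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise EdgeParseError(f"{path}:{lineno}: malformed edge {line!r}")
            evidence = fields[2] if len(fields) > 2 and fields[2] else "other_high_throughput"
            edges.append((fields[0], fields[1], evidence))
    return edges


def merge_sources(edge_lists: Sequence[Iterable[tuple[str, str, str]]]) -> Compendium:
    """Union of several (tf, tg, evidence) edge lists with deduplication.

    Duplicate (tf, tg) pairs collapse to a single edge carrying the union of
    evidence labels — the compendium counts unique regulatory relationships.
    """
    comp = Compendium()
    for edges in edge_lists:
        for tf, tg, evidence in edges:
            comp.add_edge(tf, tg, evidence)
    return comp


def evidence_partition(comp: Compendium) -> dict[str, int]:
    """Count TFs supported only by low-throughput, only high-throughput, or both."""
    only_low = only_high = both = 0
    for tf, tgs in comp.target_map().items():
        labels: set[str] = set()
        for tg in tgs:
            labels |= comp.edges[(tf, tg)]
        has_low = LOW in labels
        has_high = bool(labels & set(HIGH))
        if has_low and has_high:
            both += 1
        elif has_low:
            only_low += 1
        else:
            only_high += 1
    return {"only_low": only_low, "only_high": only_high, "both": both}


def degree_statistics(comp: Compendium) -> dict[str, float]:
    """Degree summary of the compendium.

    Returns the mean number of regulators per target gene (|edges| / |TGs|),
    the mean number of TGs per TF (|edges| / |TFs|), and the fractions of TGs
    with >= 5 regulators and with exactly one regulator.
    """
    if comp.n_edges == 0:
        raise ValueError("degree_statistics: empty compendium")
    reg_map = comp.regulator_map()
    n_tgs = len(reg_map)
    n_tfs = len(comp.tfs)
    in_degrees = [len(v) for v in reg_map.values()]
    return {
        "n_edges": float(comp.n_edges),
        "n_tfs": float(n_tfs),
        "n_tgs": float(n_tgs),
        "mean_regulators_per_gene": comp.n_edges / n_tgs,
        "mean_targets_per_tf": comp.n_edges / n_tfs,
        "frac_tgs_ge5_regulators": sum(d >= 5 for d in in_degrees) / n_tgs,
        "frac_tgs_single_regulator": sum(d == 1 for d in in_degrees) / n_tgs,
    }


def master_regulators(comp: Compendium) -> dict[str, bool]:
    """TFs with no incoming edge from any *other* TF in the compendium.

    Self-loops do not disqualify a master regulator; they are flagged in the
    returned mapping (master TF -> self_regulated flag).
    """
    tfs = comp.tfs
    masters: dict[str, bool] = {}
    for tf in sorted(tfs):
        incoming = {reg for (reg, tg) in comp.edges if tg == tf and reg in tfs}
        if incoming - {tf}:
            continue
        masters[tf] = (tf, tf) in comp.edges
    return masters
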