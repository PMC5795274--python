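"""Target-function detection: universe-conditioned gene-set enrichment.

A 'target function' of a TF is a functional term statistically over- (or
under-) represented among the TF's target genes. Every 2x2 test is
conditioned on an explicit gene universe — the allowed set of genes that
restricts both the TG set and the term's member set — because the universe
choice changes both the magnitude and the direction of the association: an
overly large universe inflates apparent enrichment, an overly restrictive
one inflates apparent depletion.

Universe policy: manually curated sources (OMIM-like, PharmGKB-like, ...)
are tested against the 'literature rich' universe (coding genes carrying at
least one curated annotation); machine annotation sources (GWAS-like) are
tested against all coding genes. Multiple-testing correction is
Benjamini-Hochberg, applied within each annotation source separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .compendium import Compendium
from .io import GeneSetCollection

__all__ = [
    "GeneUniverse",
    "ContingencyTable",
    "build_universe",
    "build_contingency",
    "fisher_test",
    "g_test",
    "phi_coefficient",
    "odds_ratio",
    "log2_odds_ratio",
    "bh_fdr",
    "annotate_tfs",
    "DEFAULT_UNIVERSE_POLICY",
    "roc_auc",
]

DEFAULT_UNIVERSE_POLICY: dict[str, str] = {"curated": "literature_rich",
                                           "machine": "coding"}


class ZeroMarginError(ValueError):
    pass


class ContingencyTable(NamedTuple):
    """2x2 counts restricted to the universe.

    n11 = TG and term member; n10 = TG, not member; n01 = member, not TG;
    n00 = neither. The four cells sum to the universe size.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n10], [self.n01, self.n00]], dtype=float)


@dataclass(frozen=True)
class GeneUniverse:
    name: str  # "coding" | "literature_rich" | "custom"
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"universe {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


def build_universe(genes: pd.DataFrame, kind: str,
                   curated_sources: Iterable[str] | None = None) -> GeneUniverse:
    """Build the coding or literature-rich universe from the gene table.

    ``coding``: all coding genes. ``literature_rich``: coding genes with at
    least one curated-source membership; annotated non-coding genes are
    purged. ``curated_sources`` names the gene-table flag columns (without
    the ``in_`` prefix) counted as curated; default: every ``in_*`` column.
    """
    coding = genes.loc[genes["is_coding"], "gene_id"]
    if kind == "coding":
        return GeneUniverse("coding", frozenset(coding))
    if kind == "literature_rich":
        if curated_sources is None:
            flag_cols = [c for c in genes.columns if c.startswith("in_")]
        else:
            flag_cols = [f"in_{s}" for s in curated_sources]
        if not flag_cols:
            raise ValueError("no annotation flag columns for literature_rich")
        annotated = genes[flag_cols].any(axis=1)
        members = genes.loc[annotated & genes["is_coding"], "gene_id"]
        return GeneUniverse("literature_rich", frozenset(members))
    raise ValueError(f"unknown universe kind {kind!r}")


def build_contingency(tg_set: Iterable[str], term_set: Iterable[str],
                      universe: GeneUniverse | Iterable[str]) -> ContingencyTable:
    """Cross-tabulate TG membership against term membership over the universe."""
    uni = universe.members if isinstance(universe, GeneUniverse) else frozenset(universe)
    tg = frozenset(tg_set) & uni
    term = frozenset(term_set) & uni
    n11 = len(tg & term)
    n10 = len(tg) - n11
    n01 = len(term) - n11
    n00 = len(uni) - n11 - n10 - n01
    return ContingencyTable(n11, n10, n01, n00)


def fisher_test(table: ContingencyTable, alternative: str = "greater") -> float:
    """Fisher's exact test p-value; 'greater' tests enrichment (OR > 1)."""
    if alternative not in ("greater", "two-sided", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(stats.fisher_exact(table.as_array(), alternative=alternative)[1])


def g_test(table: ContingencyTable) -> tuple[float, float]:
    """Likelihood-ratio (G) test of independence for the 2x2 table.

    G = 2 * sum O * ln(O/E), expected counts from the margins, p from
    chi-square with one degree of freedom. Zero margins make the expected
    counts zero and the test undefined.
    """
    obs = table.as_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ZeroMarginError("g_test: zero margin, expected counts undefined")
    expected = np.outer(row, col) / obs.sum()
    mask = obs > 0  # lim O->0 of O*ln(O/E) is 0
    g = 2.0 * float((obs[mask] * np.log(obs[mask] / expected[mask])).sum())
    return g, float(stats.chi2.sf(g, df=1))


def phi_coefficient(table: ContingencyTable) -> float:
    """Pearson's phi: (n11*n00 - n10*n01) / sqrt of the four margin products.

    Equals the Pearson correlation of the two 0/1 indicator vectors; its
    sign gives the direction of the association.
    """
    n11, n10, n01, n00 = table
    denom = (
        (n10 + n11) * (n00 + n10) * (n01 + n11) * (n00 + n01)
    )
    if denom == 0:
        raise ZeroMarginError("phi undefined: zero margin")
    return (n11 * n00 - n10 * n01) / math.sqrt(denom)


def odds_ratio(table: ContingencyTable) -> float:
    """Sample odds ratio n11*n00 / (n10*n01); inf/nan on zero cells."""
    n11, n10, n01, n00 = table
    if n10 * n01 == 0:
        return math.inf if n11 * n00 > 0 else math.nan
    return (n11 * n00) / (n10 * n01)


def log2_odds_ratio(table: ContingencyTable) -> float:
    """log2(OR); a Haldane-Anscombe 0.5 pseudo-count is added to all four
    cells only when any cell is zero, keeping the value finite."""
    n11, n10, n01, n00 = table
    if min(table) == 0:
        n11, n10, n01, n00 = (c + 0.5 for c in table)
    return math.log2((n11 * n00) / (n10 * n01))


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j)*m/j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def annotate_tfs(
    comp: Compendium,
    collections: Sequence[GeneSetCollection],
    universes: Mapping[str, GeneUniverse],
    universe_policy: Mapping[str, str] = DEFAULT_UNIVERSE_POLICY,
    fdr: float = 0.05,
    q_on: str = "two_sided",
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Test every TF x term pair for association over the policy universe.

    ``universes`` maps universe kind -> :class:`GeneUniverse`;
    ``universe_policy`` maps source type (curated/machine) -> universe kind.
    One record is emitted per TF x term with a term-universe intersection of
    at least ``min_term_size`` genes (smaller terms support only vacuous
    tests). Both one-tailed (enrichment) and two-tailed Fisher p-values are
    reported, plus the G-test; ``q_on`` in {"two_sided", "greater", "g"}
    selects which p-value drives the per-source BH q-values. Direction comes
    from the sign of phi.
    """
    if q_on not in ("two_sided", "greater", "g"):
        raise ValueError(f"unknown q_on {q_on!r}")
    target_map = comp.target_map()
    rows: list[dict] = []
    for coll in collections:
        if coll.source_type not in universe_policy:
            raise ValueError(
                f"source type {coll.source_type!r} missing from universe policy"
            )
        universe = universes[universe_policy[coll.source_type]]
        uni = universe.members
        terms = {
            name: members & uni
            for name, members in coll.sets.items()
        }
        terms = {n: m for n, m in terms.items() if len(m) >= min_term_size}
        for tf in sorted(target_map):
            tg = target_map[tf] & uni
            for term_name, term_members in sorted(terms.items()):
                table = ContingencyTable(
                    n11=len(tg & term_members),
                    n10=len(tg) - len(tg & term_members),
                    n01=len(term_members) - len(tg & term_members),
                    n00=len(uni) - len(tg | term_members),
                )
                try:
                    phi = phi_coefficient(table)
                except ZeroMarginError:
                    phi = math.nan
                try:
                    g, p_g = g_test(table)
                except ZeroMarginError:
                    g, p_g = math.nan, math.nan
                rows.append(
                    {
                        "tf_id": tf,
                        "term_id": term_name,
                        "source": coll.name,
                        "universe": universe.name,
                        "n11": table.n11,
                        "n10": table.n10,
                        "n01": table.n01,
                        "n00": table.n00,
                        "odds_ratio": odds_ratio(table),
                        "log2_odds_ratio": log2_odds_ratio(table),
                        "phi": phi,
                        "p_greater": fisher_test(table, "greater"),
                        "p_two_sided": fisher_test(table, "two-sided"),
                        "g_statistic": g,
                        "p_gtest": p_g,
                    }
                )
    records = pd.DataFrame(rows)
    if records.empty:
        records["q_value"] = []
        records["direction"] = []
        records["significant"] = []
        return records

    p_col = {"two_sided": "p_two_sided", "greater": "p_greater", "g": "p_gtest"}[q_on]
    records["q_value"] = np.nan
    for _, idx in records.groupby("source").groups.items():
        p = records.loc[idx, p_col].to_numpy()
        ok = ~np.isnan(p)
        q = np.full(p.shape, np.nan)
        if ok.any():
            q[ok] = bh_fdr(p[ok])
        records.loc[idx, "q_value"] = q
    records["direction"] = np.where(records["phi"] > 0, "positive", "negative")
    records["significant"] = records["q_value"] <= fdr
    return records


def roc_auc(labels: Sequence[bool], p_values: Sequence[float]) -> float:
    """AUC for ranking by association p-value (smaller p = stronger prediction)."""
    labels = np.asarray(labels, dtype=bool)
    p = np.asarray(p_values, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("roc_auc needs both positive and negative labels")
    return float(roc_auc_score(labels, -p))
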