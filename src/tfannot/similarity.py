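"""Pairwise sharing networks: TF-TF target genes and target functions,
TF-TF known functions, function-function member genes, and the discordance
analysis contrasting target-function similarity with target-gene similarity.

Two TFs are 'neighbors' when their TG sets overlap more than expected by
chance in the universe (one-tailed Fisher, BH FDR across all pairs). Two TFs
can share target functions without sharing target genes — the discordance
analysis asks whether such pairs nevertheless share known functions more
often than other pairs, stratified by TG-sharing level (odds ratio of TG
sharing < 1 is 'low', >= 1 'high').
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .compendium import Compendium
from .enrichment import (
    ContingencyTable,
    GeneUniverse,
    ZeroMarginError,
    bh_fdr,
    build_contingency,
    fisher_test,
    odds_ratio,
    phi_coefficient,
)
from .io import GeneSetCollection

__all__ = [
    "pair_sharing",
    "pairwise_sharing_table",
    "tf_pair_table",
    "discordance_analysis",
    "discordance_stratum",
    "function_regulator_sharing",
    "overlap_odds_ratio",
]


def pair_sharing(set_a: Iterable[str], set_b: Iterable[str],
                 universe: GeneUniverse | Iterable[str]) -> dict:
    """2x2 sharing statistics for one unordered pair of sets over a universe.

    Returns the contingency counts, phi (NaN when a margin is zero; the
    p-value is still defined), odds ratio, and one-tailed (enrichment) and
    two-tailed Fisher p-values. Symmetric in (a, b).
    """
    table = build_contingency(set_a, set_b, universe)
    try:
        phi = phi_coefficient(table)
    except ZeroMarginError:
        phi = math.nan
    return {
        "n_shared": table.n11,
        "n_only_a": table.n10,
        "n_only_b": table.n01,
        "n_neither": table.n00,
        "phi": phi,
        "odds_ratio": odds_ratio(table),
        "p_greater": fisher_test(table, "greater"),
        "p_two_sided": fisher_test(table, "two-sided"),
    }


def pairwise_sharing_table(sets: Mapping[str, frozenset[str]],
                           universe: GeneUniverse | Iterable[str],
                           fdr: float = 0.01) -> pd.DataFrame:
    """All unordered pairs of entities with sharing stats and BH q-values.

    Significance (q <= fdr) is based on the one-tailed enrichment p-value.
    """
    uni = universe if isinstance(universe, GeneUniverse) else \
        GeneUniverse("custom", frozenset(universe))
    names = sorted(sets)
    rows = []
    for a, b in itertools.combinations(names, 2):
        rec = pair_sharing(sets[a], sets[b], uni)
        rec["entity_a"] = a
        rec["entity_b"] = b
        rows.append(rec)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q_value"] = bh_fdr(df["p_greater"].to_numpy())
    df["significant_sharing"] = df["q_value"] <= fdr
    front = ["entity_a", "entity_b"]
    return df[front + [c for c in df.columns if c not in front]]


def tf_pair_table(
    comp: Compendium,
    universe: GeneUniverse,
    associations: pd.DataFrame,
    known_function_sets: Mapping[str, frozenset[str]] | None = None,
    tg_fdr: float = 0.01,
    target_fun_fdr: float = 0.05,
    known_fun_fdr: float = 0.01,
) -> pd.DataFrame:
    """Per-TF-pair record combining TG, target-function and known-function
    sharing, with the flags the discordance analysis consumes.

    ``associations`` is the annotate_tfs output; a TF's target-function set
    is its significant positively-associated terms, and sharing between two
    TFs is tested by Fisher over the space of all tested terms. Known
    functions (term sets annotating the TF gene itself) are optional.
    """
    tg_sets = comp.target_map()
    tg = pairwise_sharing_table(tg_sets, universe, fdr=tg_fdr)
    tg = tg.rename(columns={c: f"{c}_tg" for c in tg.columns
                            if c not in ("entity_a", "entity_b")})
    tg["significant_tg_sharing"] = tg["q_value_tg"] <= tg_fdr
    tg["low_tg_sharing"] = tg["odds_ratio_tg"] < 1  # ties at OR=1 are 'high'

    sig = associations[associations["significant"]
                       & (associations["direction"] == "positive")]
    target_fun_sets = {
        tf: frozenset(g["source"] + ":" + g["term_id"]
                      if not g["term_id"].startswith(g["source"]) else g["term_id"]
                      for _, g in grp.iterrows())
        for tf, grp in sig.groupby("tf_id")
    }
    term_space = frozenset(
        row["source"] + ":" + row["term_id"]
        if not row["term_id"].startswith(row["source"]) else row["term_id"]
        for _, row in associations.drop_duplicates(["source", "term_id"]).iterrows()
    )
    all_tfs = sorted(tg_sets)
    fun_sets = {tf: target_fun_sets.get(tf, frozenset()) for tf in all_tfs}
    fun = pairwise_sharing_table(fun_sets, term_space, fdr=target_fun_fdr)
    fun = fun.rename(columns={c: f"{c}_target_fun" for c in fun.columns
                              if c not in ("entity_a", "entity_b")})
    fun["significant_target_function_sharing"] = (
        fun["q_value_target_fun"] <= target_fun_fdr
    )
    fun["n_shared_target_functions"] = fun["n_shared_target_fun"]

    out = tg.merge(fun, on=["entity_a", "entity_b"])

    if known_function_sets is not None:
        term_universe = frozenset().union(*known_function_sets.values()) \
            if known_function_sets else frozenset()
        known = {tf: known_function_sets.get(tf, frozenset()) for tf in all_tfs}
        if term_universe:
            kf = pairwise_sharing_table(known, term_universe, fdr=known_fun_fdr)
            kf = kf.rename(columns={c: f"{c}_known_fun" for c in kf.columns
                                    if c not in ("entity_a", "entity_b")})
            kf["significant_known_function_sharing"] = (
                kf["q_value_known_fun"] <= known_fun_fdr
            )
            out = out.merge(kf, on=["entity_a", "entity_b"])
    return out


def discordance_stratum(n_sig_pairs: int, k_sig_supported: int,
                        n_other_pairs: int, k_other_supported: int) -> dict:
    """One stratum of the discordance table: do pairs with significant
    target-function sharing carry known-function support more often than
    the other pairs in the same TG-sharing stratum?

    Inputs are the stratum counts (pairs with significant target-function
    sharing, how many of those are supported; other pairs, how many
    supported); output has the two percentages, the odds ratio and the
    Fisher p-value.
    """
    table = ContingencyTable(
        n11=k_sig_supported,
        n10=n_sig_pairs - k_sig_supported,
        n01=k_other_supported,
        n00=n_other_pairs - k_other_supported,
    )
    if min(table) < 0:
        raise ValueError("inconsistent stratum counts")
    return {
        "n_sig_pairs": n_sig_pairs,
        "k_sig_supported": k_sig_supported,
        "pct_sig_supported": 100.0 * k_sig_supported / n_sig_pairs
        if n_sig_pairs else math.nan,
        "n_other_pairs": n_other_pairs,
        "k_other_supported": k_other_supported,
        "pct_other_supported": 100.0 * k_other_supported / n_other_pairs
        if n_other_pairs else math.nan,
        "odds_ratio": odds_ratio(table),
        "p_value": fisher_test(table, "greater"),
    }


def discordance_analysis(pair_records: pd.DataFrame) -> pd.DataFrame:
    """Stratify TF pairs by TG-sharing level and test, within each stratum,
    whether significant target-function sharing predicts significant
    known-function sharing.

    Needs the flags ``significant_target_function_sharing``,
    ``low_tg_sharing`` and ``significant_known_function_sharing`` (from
    :func:`tf_pair_table` with known function sets). Empty strata are
    skipped with a notice row.
    """
    required = ["significant_target_function_sharing", "low_tg_sharing",
                "significant_known_function_sharing"]
    for col in required:
        if col not in pair_records.columns:
            raise ValueError(f"pair records missing flag column {col!r}")
    rows = []
    for stratum, low in (("low_tg_sharing", True), ("high_tg_sharing", False)):
        sub = pair_records[pair_records["low_tg_sharing"] == low]
        sig = sub[sub["significant_target_function_sharing"]]
        other = sub[~sub["significant_target_function_sharing"]]
        if len(sig) == 0 or len(other) == 0:
            rows.append({"stratum": stratum, "note": "empty stratum, test skipped",
                         "n_sig_pairs": len(sig), "n_other_pairs": len(other)})
            continue
        rec = discordance_stratum(
            len(sig), int(sig["significant_known_function_sharing"].sum()),
            len(other), int(other["significant_known_function_sharing"].sum()),
        )
        rec["stratum"] = stratum
        rows.append(rec)
    return pd.DataFrame(rows)


def function_regulator_sharing(
    associations: pd.DataFrame,
    collections: Sequence[GeneSetCollection],
    universe: GeneUniverse,
) -> pd.DataFrame:
    """Function-pair table: shared regulators vs shared member genes.

    Terms with at least one significant positive regulator are paired; for
    each pair the table reports the regulator sets, whether they are
    identical, the member-gene-overlap odds ratio and phi over the universe,
    and the flag for pairs linked by identical regulators despite
    lower-than-expected gene overlap (OR < 1) — functions connected through
    regulation rather than through shared genes.
    """
    members = {
        f"{coll.name}:{t}" if not t.startswith(coll.name) else t: s
        for coll in collections for t, s in coll.sets.items()
    }
    sig = associations[associations["significant"]
                       & (associations["direction"] == "positive")]
    regulators: dict[str, frozenset[str]] = {}
    for (source, term), grp in sig.groupby(["source", "term_id"]):
        key = f"{source}:{term}" if not term.startswith(source) else term
        regulators[key] = frozenset(grp["tf_id"])
    rows = []
    for a, b in itertools.combinations(sorted(regulators), 2):
        shared = regulators[a] & regulators[b]
        if not shared:
            continue
        gene_rec = pair_sharing(members[a], members[b], universe)
        identical = regulators[a] == regulators[b]
        rows.append(
            {
                "function_a": a,
                "function_b": b,
                "n_regulators_a": len(regulators[a]),
                "n_regulators_b": len(regulators[b]),
                "n_shared_regulators": len(shared),
                "identical_regulators": identical,
                "gene_overlap_or": gene_rec["odds_ratio"],
                "gene_overlap_phi": gene_rec["phi"],
                "n_shared_genes": gene_rec["n_shared"],
                "linked_without_shared_genes": identical
                and (gene_rec["odds_ratio"] < 1),
            }
        )
    return pd.DataFrame(rows)


def overlap_odds_ratio(n_total_pairs: int, n_flag_a: int, n_flag_b: int,
                       n_both: int, pseudo_count: float = 0.0) -> float:
    """Odds ratio of two flags over a pair population, from marginal counts.

    The implied 2x2 is (n_both, n_a - n_both, n_b - n_both,
    n_total - n_a - n_b + n_both). A 0.5 pseudo-count variant keeps the OR
    finite when a cell is empty.
    """
    cells = (
        n_both,
        n_flag_a - n_both,
        n_flag_b - n_both,
        n_total_pairs - n_flag_a - n_flag_b + n_both,
    )
    if min(cells) < 0:
        raise ValueError(f"implied contingency cell negative: {cells}")
    a, b, c, d = (x + pseudo_count for x in cells)
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)
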