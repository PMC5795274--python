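"""Uniqueness-weighted effective numbers and the pleiotropy analysis.

Raw counts (number of regulators of a gene, number of target functions of a
TF) double-count redundant entities: two TFs that bind nearly the same
genes, or two terms with nearly the same members, are not two independent
pieces of information. Each entity t is therefore weighted by its
uniqueness, u_t = 1 / sum_{t'} phi_{tt'}^2, where phi is the pairwise
association (phi_tt = 1, so u_t is in (0, 1]; a block of k perfectly
correlated entities gets u = 1/k each). Diversity pi is the sum of u over
an entity's members — the effective, non-redundant count: k perfect copies
of one regulator contribute pi = 1 together.

The pleiotropy analysis regresses a TF's function diversity on its
regulator diversity with the number of TGs as covariate (a proxy for data
volume / research attention), reporting the Wald t and p for the predictor
plus a Spearman rank-correlation variant; PageRank over the TF->TF network
serves as a hierarchical-position control.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .compendium import Compendium
from .enrichment import GeneUniverse, ZeroMarginError, build_contingency, phi_coefficient
from .io import GeneSetCollection

__all__ = [
    "phi_matrix",
    "tf_phi_matrix",
    "uniqueness",
    "diversity",
    "diversity_profiles",
    "pleiotropy_association",
    "pagerank",
]


def phi_matrix(sets: Mapping[str, frozenset[str]],
               universe: GeneUniverse | Iterable[str]) -> pd.DataFrame:
    """Symmetric pairwise phi of set-membership indicators over a universe.

    The diagonal is 1 by definition; pairs whose 2x2 has a zero margin get
    phi 0 (no usable association information).
    """
    names = sorted(sets)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        table = build_contingency(sets[a], sets[b], universe)
        try:
            v = phi_coefficient(table)
        except ZeroMarginError:
            v = 0.0
        mat.loc[a, b] = v
        mat.loc[b, a] = v
    return mat


def tf_phi_matrix(comp: Compendium, universe: GeneUniverse) -> pd.DataFrame:
    """TF-TF phi matrix of target-gene sharing over the universe."""
    return phi_matrix(comp.target_map(), universe)


def uniqueness(phi: pd.DataFrame) -> pd.Series:
    """u_t = 1 / sum_{t'} phi_{tt'}^2, with NaN entries treated as 0.

    Requires a symmetric matrix with unit diagonal (each entity is perfectly
    associated with itself), which guarantees u_t in (0, 1].
    """
    values = phi.to_numpy(dtype=float)
    if not np.allclose(np.diag(values), 1.0, atol=1e-9):
        raise ValueError("phi matrix must have unit diagonal")
    clean = np.nan_to_num(values, nan=0.0)
    if not np.allclose(clean, clean.T, atol=1e-9):
        raise ValueError("phi matrix must be symmetric")
    denom = (clean**2).sum(axis=1)
    return pd.Series(1.0 / denom, index=phi.index, name="uniqueness")


def diversity(memberships: Mapping[str, Iterable[str]],
              uniq: pd.Series) -> pd.Series:
    """pi per entity: the sum of uniqueness over its members."""
    out = {}
    for entity, members in memberships.items():
        members = sorted(members)  # fixed summation order => reproducible floats
        unknown = [m for m in members if m not in uniq.index]
        if unknown:
            raise KeyError(f"unknown entities in membership: {unknown[:5]}")
        out[entity] = float(uniq.loc[members].sum()) if members else 0.0
    return pd.Series(out, name="diversity")


def diversity_profiles(
    comp: Compendium,
    associations: pd.DataFrame,
    collections: Sequence[GeneSetCollection],
    universes: Mapping[str, GeneUniverse],
    universe_policy: Mapping[str, str],
) -> pd.DataFrame:
    """Per-TF profile of raw and effective counts (Table-style output).

    Columns: n_tg; n_reg / pi_reg (upstream regulators within the TF roster,
    weighted by TG-sharing uniqueness); per-source and total n_target_fun /
    pi_target_fun (significant positive associations, weighted by
    member-gene-sharing uniqueness of the terms, computed within each
    source); n_known_fun / pi_known_fun (terms annotating the TF gene
    itself). Total diversity is the sum of per-source pi.
    """
    tfs = sorted(comp.tfs)
    target_map = comp.target_map()
    reg_map = comp.regulator_map()

    # regulator uniqueness from TG-sharing phi over the pooled universe
    pool = frozenset().union(*(u.members for u in universes.values()))
    u_tf = uniqueness(tf_phi_matrix(comp, GeneUniverse("pool", pool)))

    sig = associations[associations["significant"]
                       & (associations["direction"] == "positive")]

    rows = []
    per_source_uniq: dict[str, pd.Series] = {}
    for coll in collections:
        uni = universes[universe_policy[coll.source_type]]
        keyed = {
            (t if t.startswith(coll.name) else f"{coll.name}:{t}"): s
            for t, s in coll.sets.items()
        }
        per_source_uniq[coll.name] = uniqueness(phi_matrix(keyed, uni))

    for tf in tfs:
        row: dict[str, float | str] = {"tf_id": tf, "n_tg": len(target_map[tf])}
        regulators = sorted(r for r in reg_map.get(tf, frozenset()) if r != tf)
        row["n_reg"] = len(regulators)
        row["pi_reg"] = float(u_tf.loc[regulators].sum()) if regulators else 0.0
        total_n = 0
        total_pi = 0.0
        for coll in collections:
            sub = sig[(sig["tf_id"] == tf) & (sig["source"] == coll.name)]
            terms = [
                t if t.startswith(coll.name) else f"{coll.name}:{t}"
                for t in sub["term_id"]
            ]
            uq = per_source_uniq[coll.name]
            pi = float(uq.loc[terms].sum()) if terms else 0.0
            row[f"n_target_fun_{coll.name}"] = len(terms)
            row[f"pi_target_fun_{coll.name}"] = pi
            total_n += len(terms)
            total_pi += pi
        row["n_target_fun"] = total_n
        row["pi_target_fun"] = total_pi

        known_n = 0
        known_pi = 0.0
        for coll in collections:
            uq = per_source_uniq[coll.name]
            terms = [
                t if t.startswith(coll.name) else f"{coll.name}:{t}"
                for t, members in coll.sets.items()
                if tf in members
            ]
            known_n += len(terms)
            known_pi += float(uq.loc[terms].sum()) if terms else 0.0
        row["n_known_fun"] = known_n
        row["pi_known_fun"] = known_pi
        rows.append(row)
    return pd.DataFrame(rows).set_index("tf_id")


def pleiotropy_association(
    profiles: pd.DataFrame,
    response: str,
    predictor: str,
    covariates: Sequence[str] = (),
) -> dict:
    """OLS of response on predictor (+ covariates) with Wald inference.

    Returns the predictor's coefficient, Wald t and two-sided p, plus the
    (covariate-free) Spearman rank correlation as a robustness companion.
    A rank-deficient design raises, naming the collinear column.
    """
    cols = [predictor, *covariates]
    if len(profiles) < 10:
        raise ValueError("need >= 10 observations")
    X = profiles[cols].to_numpy(dtype=float)
    y = profiles[response].to_numpy(dtype=float)
    if np.ptp(X[:, 0]) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        for j, name in enumerate(cols):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(design):
                raise ValueError(f"collinear design: column {name!r} is redundant")
        raise ValueError("collinear design")
    fit = sm.OLS(y, design).fit()
    rho, rho_p = stats.spearmanr(profiles[predictor], profiles[response])
    return {
        "coef": float(fit.params[1]),
        "wald_t": float(fit.tvalues[1]),
        "p_value": float(fit.pvalues[1]),
        "n": int(fit.nobs),
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
    }


def pagerank(tf_network: nx.DiGraph, damping: float = 0.85) -> pd.Series:
    """Standard PageRank with uniform teleport on the TF->TF network.

    Scores sum to one. The graph may include self-loops (self-regulating
    TFs); dangling nodes redistribute uniformly, as usual.
    """
    if tf_network.number_of_nodes() == 0:
        raise ValueError("pagerank: empty graph")
    # tight convergence: the default 1e-6 tolerance leaves visible residuals
    scores = nx.pagerank(tf_network, alpha=damping, tol=1e-13, max_iter=10_000)
    return pd.Series(scores, name="pagerank").sort_index()
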