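"""Synthetic gene spaces, annotation sources, compendia and binding signals.

The generator plants a known regulatory structure — a set of true TF-term
links — and emits every input the downstream stages consume: a gene metadata
table, GMT annotation collections emulating six sources (OMIM, GWAS,
PharmGKB, Reactome, GO-BP, GO-MF), a TF->TG compendium whose target sets are
enriched in the member genes of planted terms, and TSS-anchored binding
signal matrices with Gaussian peaks over true targets.

Target-gene membership is sampled per gene as an independent Bernoulli:
probability ``target_rate_in_term`` if the gene belongs to a term planted for
the TF, ``background_rate`` otherwise. Setting the two rates equal produces
structure-free data (the planted truth carries no signal), which downstream
null-model tests rely on.

All randomness flows from one seed, expanded into fixed per-component
substreams so adding a generator does not perturb existing outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneSetCollection
from .compendium import Compendium
from .target_calling import BindingProfileMatrix

__all__ = [
    "SourceSpec",
    "BindingParams",
    "SimulationConfig",
    "default_config",
    "generate_gene_space",
    "sample_planted_links",
    "generate_compendium",
    "generate_binding_signals",
]

# Fixed substream keys: each component draws from default_rng([seed, key]).
_STREAMS = {"gene_space": 11, "links": 23, "compendium": 37, "binding": 53}


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SourceSpec:
    """One annotation source: curated sources annotate only coding genes."""

    name: str
    source_type: str  # "curated" | "machine"
    n_terms: int
    term_size_range: tuple[int, int]


@dataclass(frozen=True)
class BindingParams:
    """Shape of the simulated TSS-anchored binding signal.

    ``peak_height``/``peak_sd_bp`` describe the Gaussian bump added over true
    targets; ``noise_sd`` is the scale of the zero-mean background noise
    (intensities are clipped at zero, as coverage is non-negative).
    """

    window_bp: int = 6000
    bin_bp: int = 100
    peak_height: float = 5.0
    peak_sd_bp: float = 300.0
    noise_sd: float = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 3000
    frac_coding: float = 0.85
    n_tfs: int = 30
    sources: tuple[SourceSpec, ...] = ()
    n_planted_links: int = 30
    target_rate_in_term: float = 0.6
    background_rate: float = 0.02
    binding: BindingParams = field(default_factory=BindingParams)

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_tfs <= 0:
            raise InvalidConfigError("n_genes and n_tfs must be positive")
        if not 0.0 <= self.frac_coding <= 1.0:
            raise InvalidConfigError("frac_coding must be in [0, 1]")
        ok = (0.0 <= self.background_rate <= self.target_rate_in_term <= 1.0)
        if not ok:
            raise InvalidConfigError(
                "need 0 <= background_rate <= target_rate_in_term <= 1"
            )
        if self.binding.window_bp % self.binding.bin_bp != 0:
            raise InvalidConfigError("window_bp must be divisible by bin_bp")
        for src in self.sources:
            lo, hi = src.term_size_range
            if lo < 1 or hi < lo:
                raise InvalidConfigError(f"bad term_size_range for {src.name}")
            if hi > self.n_genes:
                raise InvalidConfigError(
                    f"term_size_range for {src.name} exceeds n_genes"
                )

    def rng(self, component: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[component]])


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default synthetic scenario: six annotation sources emulating
    OMIM / GWAS / PharmGKB / Reactome / GO-BP / GO-MF, 3,000 genes, 30 TFs,
    30 planted TF-term links with a strong in-term targeting rate (0.6)
    over a 2% background."""
    sources = (
        SourceSpec("omim", "curated", 12, (10, 40)),
        SourceSpec("gwas", "machine", 12, (10, 40)),
        SourceSpec("pharmgkb", "curated", 12, (10, 40)),
        SourceSpec("reactome", "curated", 15, (10, 40)),
        SourceSpec("go_bp", "curated", 20, (10, 40)),
        SourceSpec("go_mf", "curated", 12, (10, 40)),
    )
    params = dict(seed=seed, sources=sources)
    params.update(overrides)
    return SimulationConfig(**params)


def generate_gene_space(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[GeneSetCollection]]:
    """Generate the gene table and one annotation collection per source.

    Gene ids are synthetic tokens ("G000001", ...). The first ceil(frac_coding
    * n_genes) genes are coding. Curated sources draw term members from coding
    genes only; machine sources draw from all genes (so annotated non-coding
    genes exist and exercise the universe purge rule). Membership flags in the
    gene table agree with the emitted sets by construction.
    """
    rng = config.rng("gene_space")
    n = config.n_genes
    gene_ids = np.array([f"G{i:06d}" for i in range(1, n + 1)])
    n_coding = int(round(config.frac_coding * n))
    is_coding = np.zeros(n, dtype=bool)
    is_coding[:n_coding] = True

    collections: list[GeneSetCollection] = []
    flags: dict[str, np.ndarray] = {}
    for src in config.sources:
        pool = np.flatnonzero(is_coding) if src.source_type == "curated" else np.arange(n)
        if len(pool) == 0:
            raise InvalidConfigError(f"source {src.name}: empty gene pool")
        lo, hi = src.term_size_range
        if hi > len(pool):
            raise InvalidConfigError(
                f"source {src.name}: term_size_range exceeds available pool"
            )
        sets: dict[str, frozenset[str]] = {}
        member_mask = np.zeros(n, dtype=bool)
        for t in range(src.n_terms):
            size = int(rng.integers(lo, hi + 1))
            members = rng.choice(pool, size=size, replace=False)
            member_mask[members] = True
            sets[f"{src.name}:T{t + 1:03d}"] = frozenset(gene_ids[members])
        collections.append(
            GeneSetCollection(name=src.name, sets=sets, source_type=src.source_type)
        )
        flags[f"in_{src.name}"] = member_mask

    table = pd.DataFrame({"gene_id": gene_ids, "is_coding": is_coding, **flags})
    return table, collections


def sample_planted_links(
    config: SimulationConfig, collections: Sequence[GeneSetCollection]
) -> pd.DataFrame:
    """Sample n_planted_links unique (tf_id, source, term_id) true links.

    TFs are the first n_tfs (coding) genes of the gene space, so TF->TF
    regulation and self-loops can occur naturally downstream.
    """
    rng = config.rng("links")
    tf_ids = [f"G{i:06d}" for i in range(1, config.n_tfs + 1)]
    terms = [
        (coll.name, term) for coll in collections for term in coll.sets
    ]
    if config.n_planted_links > 0 and not terms:
        raise InvalidConfigError("planted links requested but no terms exist")
    pairs: set[tuple[str, str, str]] = set()
    while len(pairs) < config.n_planted_links:
        tf = tf_ids[int(rng.integers(len(tf_ids)))]
        source, term = terms[int(rng.integers(len(terms)))]
        pairs.add((tf, source, term))
    df = pd.DataFrame(sorted(pairs), columns=["tf_id", "source", "term_id"])
    return df


def generate_compendium(
    config: SimulationConfig,
    genes: pd.DataFrame,
    collections: Sequence[GeneSetCollection],
    planted_links: pd.DataFrame,
) -> tuple[Compendium, pd.DataFrame]:
    """Draw the TF->TG compendium around the planted links.

    For each TF, every gene is an independent Bernoulli draw: probability
    ``target_rate_in_term`` if the gene belongs to any term planted for that
    TF, else ``background_rate``. Returns the compendium and the planted
    truth table (a copy of ``planted_links``).
    """
    by_coll = {coll.name: coll for coll in collections}
    for _, row in planted_links.iterrows():
        if row.source not in by_coll or row.term_id not in by_coll[row.source].sets:
            raise InvalidConfigError(
                f"planted link references unknown term {row.source}:{row.term_id}"
            )
    rng = config.rng("compendium")
    gene_ids = genes["gene_id"].to_numpy()
    index = {g: i for i, g in enumerate(gene_ids)}
    tf_ids = [f"G{i:06d}" for i in range(1, config.n_tfs + 1)]

    comp = Compendium()
    for tf in tf_ids:
        p = np.full(len(gene_ids), config.background_rate)
        rows = planted_links[planted_links["tf_id"] == tf]
        for _, row in rows.iterrows():
            for g in by_coll[row.source].sets[row.term_id]:
                p[index[g]] = config.target_rate_in_term
        hits = rng.random(len(gene_ids)) < p
        for g in gene_ids[hits]:
            comp.add_edge(tf, g, "other_high_throughput")
    return comp, planted_links.copy()


def generate_binding_signals(
    config: SimulationConfig,
    tf_id: str,
    true_targets: set[str] | frozenset[str],
    gene_ids: Sequence[str],
    window_bp: int | None = None,
) -> BindingProfileMatrix:
    """Simulate the genes x bins binding-intensity matrix for one TF.

    True targets get a Gaussian peak centred on the TSS bin plus noise;
    non-targets get noise only; everything is clipped at zero.
    """
    if len(gene_ids) == 0:
        raise ValueError("generate_binding_signals: empty gene list")
    b = config.binding
    window_bp = window_bp or b.window_bp
    n_bins = window_bp // b.bin_bp
    if n_bins < 4:
        raise InvalidConfigError("window_bp/bin_bp must yield >= 4 bins")

    # hash the tf id into the substream so each TF draws independent noise
    # (crc32: stable across processes, unlike builtin str hash)
    tf_key = zlib.crc32(tf_id.encode()) % (2**31)
    rng = np.random.default_rng([config.seed, _STREAMS["binding"], tf_key])

    # bin centres in bp relative to the TSS (window centred on the TSS)
    centers = (np.arange(n_bins) + 0.5) * b.bin_bp - window_bp / 2
    peak = b.peak_height * np.exp(-(centers**2) / (2 * b.peak_sd_bp**2))

    signal = rng.normal(0.0, b.noise_sd, size=(len(gene_ids), n_bins)) if b.noise_sd > 0 \
        else np.zeros((len(gene_ids), n_bins))
    target_rows = np.array([g in true_targets for g in gene_ids])
    signal[target_rows] += peak
    np.clip(signal, 0.0, None, out=signal)
    return BindingProfileMatrix(
        tf_id=tf_id,
        gene_ids=list(gene_ids),
        signal=signal,
        window_bp=window_bp,
        bin_bp=b.bin_bp,
    )
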