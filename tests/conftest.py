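"""Shared fixtures: the default synthetic scenario and a structure-free twin.

Session-scoped because the scenario (3,000 genes, 30 TFs, six annotation
sources, 30 planted TF-term links) is the unit many tests exercise jointly.
"""

from __future__ import annotations

import pytest

from tfannot.enrichment import build_universe
from tfannot.simulate import (
    default_config,
    generate_compendium,
    generate_gene_space,
    sample_planted_links,
)


def make_scenario(seed: int = 1, **overrides):
    """Build (config, genes, collections, planted links, compendium, universes)."""
    cfg = default_config(seed=seed, **overrides)
    genes, collections = generate_gene_space(cfg)
    links = sample_planted_links(cfg, collections)
    comp, truth = generate_compendium(cfg, genes, collections, links)
    universes = {
        "coding": build_universe(genes, "coding"),
        "literature_rich": build_universe(
            genes, "literature_rich",
            curated_sources=[c.name for c in collections
                             if c.source_type == "curated"],
        ),
    }
    return {
        "config": cfg,
        "genes": genes,
        "collections": collections,
        "links": links,
        "compendium": comp,
        "truth": truth,
        "universes": universes,
    }


@pytest.fixture(scope="session")
def planted_scenario():
    """Default scenario with strong planted structure (seed 1)."""
    return make_scenario(seed=1)


@pytest.fixture(scope="session")
def null_scenario():
    """Structure-free twin: target rate equals background rate, so the
    planted truth carries no signal."""
    return make_scenario(seed=1, background_rate=0.02, target_rate_in_term=0.02)


@pytest.fixture(scope="session")
def planted_associations(planted_scenario):
    from tfannot.enrichment import DEFAULT_UNIVERSE_POLICY, annotate_tfs

    s = planted_scenario
    return annotate_tfs(s["compendium"], s["collections"], s["universes"],
                        DEFAULT_UNIVERSE_POLICY, fdr=0.05)
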