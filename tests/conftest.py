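"""Shared fixtures: the default synthetic panel and derived analysis products.

Heavy objects (the panel, its cluster graph) are session-scoped so the
all-vs-all alignment work happens once per test run.
"""

from __future__ import annotations

import pytest

from flagdiv import clustering
from flagdiv.sequence_model import deduplicate
from flagdiv.synthetic_data import PanelConfig, generate_panel

PANEL_SEED = 1


@pytest.fixture(scope="session")
def panel():
    """Default synthetic panel (the study conditions), seed fixed."""
    return generate_panel(PanelConfig(rng_seed=PANEL_SEED))


@pytest.fixture(scope="session")
def flagellin_uniques(panel):
    """Unique set of the true flagellin (bacterial + archaeal) records."""
    keep = set(panel.truth[panel.truth.category.isin(
        ["flagellin", "archaeal"])].record_id)
    return deduplicate([r for r in panel.proteins if r.id in keep])


@pytest.fixture(scope="session")
def panel_clusters(panel, flagellin_uniques):
    clusters = clustering.greedy_cluster(flagellin_uniques)
    lineage = dict(zip(panel.truth.record_id, panel.truth.lineage))
    phylum = dict(zip(panel.truth.record_id, panel.truth.phylum))
    phylum_by_key = {seq: phylum[ids[0]]
                     for seq, ids in flagellin_uniques.members.items()}
    clustering.attach_phyla(clusters, phylum_by_key)
    return clusters


@pytest.fixture(scope="session")
def panel_forest(panel_clusters):
    graph = clustering.build_cluster_graph(panel_clusters)
    return clustering.minimum_spanning_forest(graph)


@pytest.fixture(scope="session")
def small_panel():
    """Low-divergence panel for fast curation-recovery checks."""
    return generate_panel(PanelConfig(
        rng_seed=7, n_phyla=2, forms_per_species=4,
        phylum_divergence=0.04, species_divergence=0.01,
        n_flgl_decoys=4, n_random_decoys=4, n_archaeal_species=1,
        n_hgt_species=0, multiplicity_choices=(1, 2),
    ))
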