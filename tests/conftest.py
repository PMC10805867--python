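import numpy as np
import pytest

import tmbsim as t


@pytest.fixture(scope="session")
def small_cohort():
    """A small but non-trivial cohort shared across read-only tests."""
    cfg = t.CohortConfig(n_samples=200, n_genes=500, seed=11)
    genome = t.generate_genome(cfg)
    samples, mutations = t.generate_cohort(genome, cfg)
    return cfg, genome, samples, mutations


@pytest.fixture(scope="session")
def exome_panel(small_cohort):
    _, genome, _, _ = small_cohort
    return t.panel_from_genes("exome", [g.gene_symbol for g in genome], genome)


def make_record(**kwargs):
    defaults = dict(
        sample_id="S1",
        gene_symbol="GENE1",
        chromosome="chr1",
        position=100,
        ref_allele="A",
        alt_allele="T",
        variant_classification="Missense_Mutation",
        vaf=0.25,
        t_depth=100,
        t_alt_count=25,
        is_hotspot=False,
    )
    defaults.update(kwargs)
    return t.MutationRecord(**defaults)
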