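"""Shared fixtures: one default synthetic world reused across the suite.

The default world is the reference study condition: 500 genes, 10%
essential, three auxotrophy genes each for his/met/ser with a -4 defect,
~20 insertion strains per gene and 50 reads/strain, two replicates of a
defined / single-supplement / rich compendium.  Two gaps are planted: the
phosphoribosyl-ATP diphosphatase step is hidden from every resource
(a genuine gap) and the ATP phosphoribosyltransferase step from the
baseline only (a clear candidate).
"""

import pytest

from auxofill import classify as cl
from auxofill import essentials as es
from auxofill import fitness as fm
from auxofill import gaps as gp
from auxofill import simulate as sim

ALL_RESOURCES = ["baseline", "res1", "res2", "res3"]
#: reactions held by planted his-auxotrophy genes (first three non-transaminase
#: steps of the his pathway, in step order)
HIS_ROLE_REACTIONS = ["ATP-PRTRANS", "PRATP-PPASE", "PRAMP-CH"]


@pytest.fixture(scope="session")
def world():
    return sim.simulate_world(
        seed=1,
        drop_spec=[
            ("PRAMP-CH", ALL_RESOURCES),   # genuine gap, fillable by rescue
            ("ATP-PRTRANS", ["baseline"]),  # gap with a clear candidate
        ],
    )


@pytest.fixture(scope="session")
def pool_assigned(world):
    return fm.assign_genes(world.pool, world.genes)


@pytest.fixture(scope="session")
def fit(world, pool_assigned):
    return fm.fitness_pipeline(pool_assigned, world.counts, world.experiments,
                               world.genes)


@pytest.fixture(scope="session")
def insertion_stats(world):
    return es.gene_insertion_stats(world.pool, world.genes, world.genome)


@pytest.fixture(scope="session")
def essential_calls(world, insertion_stats):
    return es.call_essential(insertion_stats, genome=world.genome, pool=world.pool)


@pytest.fixture(scope="session")
def classified_gaps(world, fit, essential_calls):
    essentials = set(essential_calls.index[essential_calls["called"]])
    _, gap_list = gp.predict_status(world.pathway_db, world.annotations,
                                    world.baseline_resource)
    for gap in gap_list:
        gp.clear_candidates(gap, world.annotations, world.resources)
        gp.flag_special(gap, pathway_db=world.pathway_db)
    calls = cl.phenotype_calls(fit, world.experiments, essentials)
    return cl.classify_all(gap_list, calls, fit, world.experiments,
                           world.annotations, world.pathway_db)
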