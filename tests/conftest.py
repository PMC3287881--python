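import numpy as np
import pytest

from raremix import CohortGenotypes, GeneMap, StudyDesign, simulate_cohort


@pytest.fixture
def toy_cohort():
    """4 individuals x 5 hand-written variants (one per MAF regime)."""
    dosage = np.array(
        [
            # v_rare1 v_rare2 v_comm1 v_comm2 v_mono
            [0, 1, 1, 2, 0],
            [1, 0, 0, 1, 0],
            [2, 0, 1, 0, 0],
            [0, 0, 2, 1, 0],
        ],
        dtype=np.int8,
    )
    cohort = CohortGenotypes(
        ["s1", "s2", "s3", "s4"],
        ["v_rare1", "v_rare2", "v_comm1", "v_comm2", "v_mono"],
        dosage,
    )
    gene_map = GeneMap({
        "GENE_A": ["v_rare1", "v_rare2", "v_comm1"],
        "GENE_B": ["v_comm2", "v_mono"],
    })
    return cohort, gene_map


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated cohort shared by read-only tests."""
    design = StudyDesign(n_individuals=300, n_genes_per_group=(30, 15, 5), seed=42)
    cohort, gene_map, ancestry = simulate_cohort(design)
    return design, cohort, gene_map, ancestry
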