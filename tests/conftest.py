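import pytest

import baitcall as bc
from baitcall.synthetic import default_domain_truth

APMS_SEED = 1
RNASEQ_SEED = 1


@pytest.fixture(scope="session")
def apms_sim():
    """Seeded AP-MS simulation: 200 proteins, 20 planted interactors of every
    bait construct, enrichment 8, the study's 5-control/4-WT run layout."""
    design = bc.default_design(n_proteins=200)
    truth = bc.default_apms_truth(design, seed=APMS_SEED)
    matrix, truth_table = bc.simulate_apms(design, truth)
    return design, truth, matrix, truth_table


@pytest.fixture(scope="session")
def domain_sim():
    """Seeded simulation with one selective-reduced (dRRM1) and one
    selective-enhanced (dRRM2) prey planted among 20 interactors."""
    design = bc.default_design(n_proteins=200)
    truth, reduced_idx, enhanced_idx = default_domain_truth(design, seed=APMS_SEED)
    matrix, truth_table = bc.simulate_apms(design, truth)
    return design, truth, matrix, truth_table, reduced_idx, enhanced_idx


@pytest.fixture(scope="session")
def rnaseq_sim():
    """Seeded four-condition RNA-seq simulation with planted tag-responsive
    and bait-specific genes and a 30x exon-sharing transgene."""
    truth = bc.default_rnaseq_truth(seed=RNASEQ_SEED)
    gene_table, exon_table, truth_table = bc.simulate_rnaseq(
        truth, bc.default_groups()
    )
    return truth, gene_table, exon_table, truth_table


@pytest.fixture(scope="session")
def wt_calls(apms_sim):
    """Full WT calling pass on the seeded AP-MS simulation."""
    _, _, matrix, truth_table = apms_sim
    bait = matrix.protein_ids[0]
    table = bc.enrichment_table(matrix, "WT").drop(index=bait)
    bg = bc.fit_background(matrix)
    scores = bc.score_construct(matrix, "WT", bg, exclude=[bait])
    calls = bc.call_interactors(table, scores, bc.CallCriteria())
    return table, bg, scores, calls
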