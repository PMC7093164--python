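import numpy as np
import pytest

from genecoord.io import AnalysisConfig, ExpressionMatrix, SampleDesign
from genecoord.simulate import SimulationConfig, combine_groups, simulate_dataset


def make_matrix(values, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"G{i+1}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j+1}" for j in range(values.shape[1])]
    return ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids,
                            values=values)


def make_design(n_ref: int, n_cond: int, ref="NOR", cond="FRA") -> SampleDesign:
    assignments = {f"S{j+1}": ref for j in range(n_ref)}
    assignments.update({f"S{n_ref+j+1}": cond for j in range(n_cond)})
    return SampleDesign(assignments=assignments, reference_label=ref,
                        condition_label=cond)


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_sim():
    """A small two-group dataset with 4 planted modules and 4 rewired seeds."""
    cfg = SimulationConfig(
        n_genes=300, n_samples_ref=25, n_samples_cond=25, n_modules=4,
        module_size=40, n_seed_genes=20, n_rewired=4, rng_seed=2024,
    )
    matrix_ref, matrix_cond, truth = simulate_dataset(cfg)
    combined, design = combine_groups(matrix_ref, matrix_cond)
    return cfg, combined, design, truth
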