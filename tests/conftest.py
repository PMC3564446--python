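import pytest

from thiolox import clustering, io, quant, synthetic


@pytest.fixture(scope="session")
def reference_matrices():
    """Bundled 29-peptide aging-oxidation dataset (standard, CR)."""
    return io.load_reference_trajectories()


@pytest.fixture(scope="session")
def reference_assignments(reference_matrices):
    mstd, mcr = reference_matrices
    return {
        "standard": clustering.classify_matrix(mstd),
        "caloric_restriction": clustering.classify_matrix(mcr),
    }


@pytest.fixture(scope="session")
def noisy_standard_set():
    """300 archetype trajectories, noise SD 5, 4 replicates, seed 1."""
    cfg = synthetic.SimConfig(n_peptides=300, seed=1, noise_sd=5.0)
    replicates, truth = synthetic.gen_trajectories(cfg)
    matrix = quant.combine_replicate_matrices(replicates)
    return replicates, matrix, truth


@pytest.fixture(scope="session")
def metabolite_series():
    return {
        cond: synthetic.gen_metabolites(cond, seed=11)
        for cond in ("standard", "caloric_restriction", "water")
    }
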