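import numpy as np
import pandas as pd
import pytest

from wheatstress import (
    ExpressionMatrix,
    SimulationConfig,
    generate_expression,
    generate_hit_table,
    generate_vcf,
)


@pytest.fixture(scope="session")
def study():
    """Mid-size synthetic study with planted DEGs, triplets and a pattern."""
    config = SimulationConfig(
        n_genes=400,
        deg_fraction=0.1,
        n_triplets=12,
        noise_cv=0.05,
        consistent_fraction=0.5,
        n_pattern_genes=5,
        seed=11,
    )
    expr, truth = generate_expression(config)
    return config, expr, truth


@pytest.fixture(scope="session")
def noiseless_study():
    """Zero-noise study: planted effects are realized exactly."""
    config = SimulationConfig(
        n_genes=300,
        deg_fraction=0.1,
        noise_cv=0.0,
        fc_range=(5.5, 8.0),
        consistent_fraction=1.0,
        n_pattern_genes=10,
        seed=5,
    )
    expr, truth = generate_expression(config)
    return config, expr, truth


@pytest.fixture(scope="session")
def hit_table(study):
    config, _, truth = study
    return generate_hit_table(config, truth)


@pytest.fixture(scope="session")
def vcf_study(tmp_path_factory):
    config = SimulationConfig(n_genes=10, n_snps=1000, seed=23)
    path = tmp_path_factory.mktemp("vcf") / "variants.vcf"
    truth = generate_vcf(config, path)
    return config, path, truth


@pytest.fixture
def tiny_matrix():
    """Hand-built 3-gene, 2-condition matrix (2 varieties x 2 reps)."""
    libraries = ["A_control_R1", "A_control_R2", "A_stress_R1", "A_stress_R2"]
    values = pd.DataFrame(
        np.array(
            [
                [10.0, 10.0, 40.0, 40.0],
                [5.0, 5.0, 5.0, 5.0],
                [8.0, 8.0, 2.0, 2.0],
            ]
        ),
        index=["g1", "g2", "g3"],
        columns=libraries,
    )
    design = pd.DataFrame(
        {
            "variety": ["A", "A", "A", "A"],
            "treatment": ["control", "control", "stress", "stress"],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(libraries, name="library"),
    )
    return ExpressionMatrix(values=values, design=design, normalized=True)
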