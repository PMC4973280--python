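import numpy as np
import pandas as pd
import pytest

from thermoarray import (
    ArchitectureConfig,
    ExpressionMatrix,
    ctmax_group_means,
    generate_architecture,
    generate_design,
    simulate_ctmax,
    simulate_expression,
)

#: scaled-down architecture keeping the default module proportions
SMALL_ARCH = ArchitectureConfig(
    n_genes=2000,
    mean_temp_module_size=600,
    ramping_module_size=300,
    fluctuation_module_size=30,
    chaperone_size=10,
    phototransduction_size=10,
)


def two_group_matrix(group_a: np.ndarray, group_b: np.ndarray) -> ExpressionMatrix:
    """Build an ExpressionMatrix with one two-level factor ``group``.

    ``group_a`` and ``group_b`` are genes x replicates arrays.
    """
    group_a = np.atleast_2d(group_a)
    group_b = np.atleast_2d(group_b)
    n_genes = group_a.shape[0]
    ids_a = [f"a{j}" for j in range(group_a.shape[1])]
    ids_b = [f"b{j}" for j in range(group_b.shape[1])]
    values = pd.DataFrame(
        np.hstack([group_a, group_b]),
        index=[f"g{i}" for i in range(n_genes)],
        columns=ids_a + ids_b,
    )
    ann = pd.DataFrame(
        {"group": ["A"] * len(ids_a) + ["B"] * len(ids_b)}, index=values.columns
    )
    return ExpressionMatrix(values, ann)


@pytest.fixture(scope="session")
def small_experiment():
    """One simulated experiment at reduced scale: design, architecture,
    CTmax table, group means and expression matrix."""
    design = generate_design(3)
    arch = generate_architecture(SMALL_ARCH, seed=11)
    ctmax = simulate_ctmax(seed=12)
    group_means = ctmax_group_means(ctmax)
    matrix = simulate_expression(design, arch, seed=13, group_ctmax=group_means)
    return {
        "design": design,
        "architecture": arch,
        "ctmax": ctmax,
        "group_means": group_means,
        "matrix": matrix,
    }
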