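import numpy as np
import pytest

from aspdhg import (
    Block,
    L2Squared,
    MatrixMap,
    SaddleProblem,
    Zero,
    estimate_norm,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_ls_problem(rng, n_blocks=2, rows_per_block=6, n_vars=4):
    """Small random least-squares saddle problem (g = 0, quadratic blocks)."""
    blocks = []
    for _ in range(n_blocks):
        M = MatrixMap(rng.standard_normal((rows_per_block, n_vars)))
        b = rng.standard_normal(rows_per_block)
        blocks.append(
            Block(
                op=M,
                conj_prox=L2Squared(b).conj_prox,
                p=1.0 / n_blocks,
                L=float(estimate_norm(M)),
                b=b,
            )
        )
    return SaddleProblem(g=Zero(), blocks=blocks, domain_shape=(n_vars,))


@pytest.fixture
def ls_problem(rng):
    return random_ls_problem(rng)
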