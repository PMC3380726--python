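import numpy as np
import pytest
from hypothesis import settings
from scipy import sparse

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from phenomod.bipartite import BipartiteMatrix
from phenomod.io import CogNetwork, canonical_pair
from phenomod.pipeline import RunConfig, run_pipeline
from phenomod.synth import SynthSpec, generate_panel


def matrix_from_dense(rows, organisms=None, cog_pairs=None) -> BipartiteMatrix:
    """Build a BipartiteMatrix straight from a dense 0/1 array (tests only)."""
    arr = np.asarray(rows, dtype=np.int8)
    n, m = arr.shape
    organisms = organisms or [f"org{i}" for i in range(n)]
    cog_pairs = cog_pairs or [(f"C{j:02d}", f"D{j:02d}") for j in range(m)]
    return BipartiteMatrix(
        organisms=list(organisms),
        cog_pairs=list(cog_pairs),
        cells=sparse.csr_matrix(arr),
    )


def random_cog_network(rng, organism_id, cogs, n_edges) -> CogNetwork:
    edges = set()
    while len(edges) < n_edges:
        u, v = rng.choice(cogs, size=2, replace=False)
        edges.add(canonical_pair(str(u), str(v)))
    return CogNetwork(organism_id=organism_id, edges=frozenset(edges))


@pytest.fixture(scope="session")
def benchmark_panel(tmp_path_factory):
    """The default synthetic panel (bg prob 0.02, one planted module)."""
    d = tmp_path_factory.mktemp("panel")
    return generate_panel(SynthSpec(seed=1), d)


@pytest.fixture(scope="session")
def benchmark_run(benchmark_panel, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    config = RunConfig(
        manifest=benchmark_panel.manifest,
        mapping=benchmark_panel.mapping,
        out_dir=out,
        seed=1,
    )
    return run_pipeline(config)
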