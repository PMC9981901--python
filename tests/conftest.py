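import pytest

from mogat import (
    HyperParams,
    MolecularGraph,
    SplitSpec,
    SyntheticSpec,
    evaluate,
    fixture_graphs,
    generate_dataset,
    init_params,
    split_dataset,
    train,
)

#: Benchmark study conditions: 600 molecules, 3-12 heavy atoms over
#: C/N/O/S, per-element group contributions, noise sd 0.3 logS units.
BENCHMARK_SPEC = SyntheticSpec(n_molecules=600, seed=0)
#: Training length for the benchmark; convergence plateaus well before this.
BENCHMARK_EPOCHS = 30
BENCHMARK_BATCH = 128
N_BENCHMARK_SEEDS = 3


@pytest.fixture(scope="session")
def fixtures():
    return fixture_graphs()


@pytest.fixture
def small_hyper():
    return HyperParams(d_g=8, kappa=2, tau=2, dropout_rate=0.0, seed=1)


@pytest.fixture
def small_params(small_hyper):
    return init_params(small_hyper)


@pytest.fixture(scope="session")
def benchmark_dataset():
    return generate_dataset(BENCHMARK_SPEC)


@pytest.fixture(scope="session")
def trained_models(benchmark_dataset):
    """Models trained on the group-contribution benchmark, one per seed.

    Each entry re-splits the dataset with its own seed, trains with the
    reference-optimum hyperparameters, and evaluates on the held-out
    test fold.
    """
    graphs = benchmark_dataset.graphs()
    results = []
    for rep in range(N_BENCHMARK_SEEDS):
        tr, va, te = split_dataset(len(graphs), SplitSpec(n_repeats=1, seed=rep))
        hyper = HyperParams(epochs=BENCHMARK_EPOCHS, seed=rep)
        res = train([graphs[i] for i in tr], [graphs[i] for i in va],
                    hyper, batch_size=BENCHMARK_BATCH)
        ev = evaluate(res.params, hyper, [graphs[i] for i in te])
        results.append({
            "params": res.params,
            "hyper": hyper,
            "eval": ev,
            "test_graphs": [graphs[i] for i in te],
        })
    return results


def permute_graph(graph: MolecularGraph, perm) -> MolecularGraph:
    """Reindex a molecular graph's atoms by ``perm`` (new_index = position
    of old index in perm)."""
    perm = list(perm)
    inv = {old: new for new, old in enumerate(perm)}
    atoms = [graph.atoms[old] for old in perm]
    bonds = [(inv[i], inv[j], bf) for i, j, bf in graph.bonds]
    return MolecularGraph(atoms=atoms, bonds=bonds, smiles=graph.smiles,
                          target=graph.target)
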