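import numpy as np
import pandas as pd
import pytest

from socivis.connectome import ConnectivityTable


def random_typed_table(seed, n_types=20, n_edges=300, state="S",
                       sensory=("V1", "V2", "V3"), max_weight=400,
                       untyped_frac=0.1, body_offset=0):
    """A random typed connectivity table for oracle comparisons.

    One neuron per type keeps the type level and the neuron level identical;
    a few untyped bodies exercise the denominator convention. The state type
    is cholinergic, other types get random transmitters.
    """
    rng = np.random.default_rng(seed)
    names = [state, *sensory] + [f"T{i:02d}" for i in range(n_types - 1 - len(sensory))]
    nts = {state: "ACh"}
    for i, t in enumerate(names):
        if t not in nts:
            nts[t] = ["ACh", "GABA", "Glu", "unknown"][rng.integers(0, 4)]
    body = {t: body_offset + 1000 + i for i, t in enumerate(names)}
    n_untyped = max(1, int(untyped_frac * n_types))
    untyped_ids = [body_offset + 5000 + i for i in range(n_untyped)]

    rows = []
    for _ in range(n_edges):
        pre, post = rng.choice(names, 2, replace=False)
        rows.append((body[pre], body[post], ["R1", "R2"][rng.integers(0, 2)],
                     int(rng.integers(1, max_weight))))
    for u in untyped_ids:
        post = names[rng.integers(0, len(names))]
        rows.append((u, body[post], "R1", int(rng.integers(1, max_weight))))
    edges = pd.DataFrame(rows, columns=["bodyId_pre", "bodyId_post", "roi", "weight"])
    neurons = pd.DataFrame(
        [(body[t], t, "right", nts[t]) for t in names]
        + [(u, None, None, None) for u in untyped_ids],
        columns=["bodyId", "type", "hemisphere", "nt"])
    return ConnectivityTable(edges=edges, neurons=neurons, dataset_tag=f"rand{seed}")


@pytest.fixture
def small_table():
    """Tiny hand-written table: A,B excitatory onto X, one untyped input."""
    edges = pd.DataFrame({
        "bodyId_pre": [1, 2, 9, 1],
        "bodyId_post": [3, 3, 3, 4],
        "roi": ["R1", "R1", "R1", "R2"],
        "weight": [30, 70, 50, 10],
    })
    neurons = pd.DataFrame({
        "bodyId": [1, 2, 3, 4, 9],
        "type": ["A", "B", "X", "Y", None],
        "hemisphere": ["right"] * 5,
        "nt": ["ACh", "ACh", "ACh", "GABA", None],
    })
    return ConnectivityTable(edges=edges, neurons=neurons, dataset_tag="toy")
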