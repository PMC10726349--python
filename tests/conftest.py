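"""Shared fixtures: small ion libraries, featurized graphs, oracles."""

from __future__ import annotations

import re

import numpy as np
import pytest

import iongraph as ig

# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

_ELEMENT_TOKEN = re.compile(
    r"Cl|Br|Si|Se|[BCNOPSFI]|\[[^\]]*\]|[bcnops]")
_BRACKET_CHARGE = re.compile(r"\[([^\]]*)\]")


def smiles_net_charge(smiles: str) -> int:
    """Net formal charge read straight off the SMILES text brackets."""
    total = 0
    for body in _BRACKET_CHARGE.findall(smiles):
        for sign, digits in re.findall(r"([+-])(\d*)", body):
            magnitude = int(digits) if digits else 1
            total += magnitude if sign == "+" else -magnitude
    return total


def smiles_heavy_atoms(smiles: str) -> int:
    """Heavy-atom count from a token scan of the SMILES text."""
    count = 0
    for token in _ELEMENT_TOKEN.findall(smiles):
        if token.startswith("["):
            symbol = re.match(r"\[\d*([A-Za-z][a-z]?)", token).group(1)
            if symbol.upper() != "H":
                count += 1
        else:
            count += 1
    return count


def dense_gcn_forward(node_features, edge_index, edge_weights, W):
    """Brute-force dense evaluation of the normalized graph convolution:
    x'_v = Σ_{w∈N(v)∪{v}} (e_wv / √(d_v d_w)) W x_w, degrees from |e|."""
    x = np.asarray(node_features, dtype=float)
    n = x.shape[0]
    adj = np.zeros((n, n))
    for (src, dst), w in zip(edge_index, edge_weights):
        adj[dst, src] = w
    adj = adj + np.eye(n)
    deg = np.abs(adj).sum(axis=1)
    out = np.zeros((n, W.shape[1]))
    xw = x @ W
    for v in range(n):
        for u in range(n):
            if adj[v, u] != 0.0:
                out[v] += adj[v, u] / np.sqrt(deg[v] * deg[u]) * xw[u]
    return out


def brute_quartile(values, q):
    """Linear-interpolation quantile computed by hand."""
    data = sorted(values)
    pos = (len(data) - 1) * q
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return data[lo] + (data[hi] - data[lo]) * (pos - lo)


def brute_outlier_mask(values, method, threshold):
    values = list(map(float, values))
    n = len(values)
    if method == "zscore":
        mean = sum(values) / n
        sd = (sum((v - mean) ** 2 for v in values) / n) ** 0.5
        if sd == 0:
            return [False] * n
        return [abs(v - mean) / sd > threshold for v in values]
    if method == "iqr":
        q1 = brute_quartile(values, 0.25)
        q3 = brute_quartile(values, 0.75)
        iqr = q3 - q1
        return [v < q1 - threshold * iqr or v > q3 + threshold * iqr
                for v in values]
    med = brute_quartile(values, 0.5)
    mad = brute_quartile([abs(v - med) for v in values], 0.5)
    if mad == 0:
        return [False] * n
    return [abs(v - med) > threshold * mad for v in values]


def random_small_graph(rng, max_nodes=6, d_in=3):
    """A random weighted undirected graph in MolecularGraph edge layout."""
    n = int(rng.integers(1, max_nodes + 1))
    x = rng.normal(size=(n, d_in))
    src, dst, w = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                weight = float(rng.choice([1.0, 1.5, 2.0, 3.0, -1.0]))
                src += [i, j]
                dst += [j, i]
                w += [weight, weight]
    edge_index = (np.array(list(zip(src, dst)), dtype=int).reshape(-1, 2))
    return x, edge_index, np.array(w)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def emim_cl():
    return ig.parse_ion_pair("CC[n+]1ccn(C)c1", "[Cl-]", "emim-Cl")


@pytest.fixture(scope="session")
def ion_library():
    return ig.generate_ion_library(4, 3, seed=7)


@pytest.fixture(scope="session")
def library_graphs_a(ion_library):
    """Scenario-A graphs (formal charges, ionic bond) for the library."""
    feat = ig.GraphFeaturizer(scenario="a", charge_scheme="formal",
                              ionic_bond=True)
    return ig.featurize_pairs(ion_library, feat)


@pytest.fixture(scope="session")
def tiny_task():
    """A small noiseless synthetic regression task with graphs and split."""
    spec = ig.SyntheticSpec(n_cations=6, n_anions=4, noise_sd=0.0,
                            temps=tuple(288.15 + 15 * k for k in range(4)),
                            seed=3)
    pairs = ig.generate_ion_library(spec.n_cations, spec.n_anions,
                                    spec.seed)
    ds = ig.synthesize_dataset(pairs, spec)
    feat = ig.GraphFeaturizer(scenario="a", charge_scheme="formal",
                              ionic_bond=True)
    graphs = ig.featurize_dataset(ds, feat)
    test_ils = ig.select_test_ils(ds, 0.10, seed=0)
    split = ig.assign_splits(ds, test_ils, mode="random", seed=0)
    return {"spec": spec, "pairs": pairs, "ds": ds, "graphs": graphs,
            "split": split, "test_ils": test_ils}


@pytest.fixture
def small_model_config():
    return ig.ModelConfig(conv_widths=(8, 16, 16, 8), head_widths=(16, 8))
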