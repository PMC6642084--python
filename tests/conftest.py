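import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import skewscan as sk

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def balanced_newick(n: int, prefix: str = "t") -> tuple[str, list[str]]:
    """Newick string for a fully balanced binary tree with n leaves."""
    labels = [f"{prefix}{i + 1}" for i in range(n)]

    def build(block):
        if len(block) == 1:
            return block[0]
        mid = len(block) // 2
        return f"({build(block[:mid])},{build(block[mid:])})"

    return build(labels) + ";", labels


@pytest.fixture
def balanced32():
    newick, labels = balanced_newick(32)
    return sk.parse_newick(newick), labels


@pytest.fixture
def planted_loss_matrix(balanced32):
    """One gene absent exactly in the first 8-leaf clade of a balanced
    32-leaf tree, present everywhere else (no dropout)."""
    tree, labels = balanced32
    calls = pd.DataFrame({"g1": [0] * 8 + [1] * 24}, index=labels)
    return tree, sk.PresenceMatrix(calls)


def counts_matrix(per_clade: dict[str, tuple[int, int]], hmm: str = "h1"):
    """PresenceMatrix + CladeMap realizing given (positives, size) per clade."""
    samples, labels, calls = [], {}, []
    for clade, (k, n) in per_clade.items():
        for i in range(n):
            name = f"{clade}_{i}"
            samples.append(name)
            labels[name] = clade
            calls.append(1 if i < k else 0)
    matrix = sk.PresenceMatrix(pd.DataFrame({hmm: calls}, index=samples))
    clades = sk.CladeMap.from_mapping(labels, order=tuple(per_clade))
    return matrix, clades


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
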