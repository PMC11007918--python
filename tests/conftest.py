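import numpy as np
import pytest

from koassign.records import SequenceRecord
from koassign.synthetic import FixtureConfig, make_embedding_clusters


@pytest.fixture
def two_gaussian_fixture():
    """Linearly separable embedding clusters: n=400, class separation 10 sigma."""
    rng = np.random.default_rng(7)
    n, dim, separation = 400, 64, 10.0
    shift = separation / np.sqrt(dim)  # ||mean difference|| = 10, sigma = 1
    X = np.vstack([
        rng.standard_normal((n // 2, dim)),
        rng.standard_normal((n // 2, dim)) + shift,
    ])
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    perm = rng.permutation(n)
    return X[perm], y[perm]


@pytest.fixture(scope="session")
def cluster_fixture():
    """Reference/query embedding clusters with separation / sigma = 20."""
    cfg = FixtureConfig(
        n_ko_families=20,
        members_per_family=5,
        n_nonko=30,
        embed_dim=64,
        cluster_sigma=0.5,
        centroid_separation=10.0,
        seed=11,
    )
    refs, ref_ann, queries, query_truth = make_embedding_clusters(cfg)
    return cfg, refs, ref_ann, queries, query_truth


def make_records(lengths, prefix="r", annotations=None):
    """Records of given lengths with deterministic sequence content."""
    rng = np.random.default_rng(sum(lengths) + len(lengths))
    out = []
    for i, length in enumerate(lengths):
        seq = "".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length)
        )
        ann = annotations[i] if annotations else frozenset()
        out.append(SequenceRecord(f"{prefix}{i}", seq, ann))
    return out
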