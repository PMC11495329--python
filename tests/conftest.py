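import numpy as np
import networkx as nx
import pytest

from bicascade import ActivityLog, ThresholdProfile, uniform_weights
from bicascade.network_io import SocialNetwork


def star_network(n_followees: int = 5, focal: str = "A"):
    """Focal user following ``n_followees`` accounts (the bubble-diagram
    geometry: each followee carries weight 1/n)."""
    g = nx.DiGraph()
    for k in range(1, n_followees + 1):
        g.add_edge(focal, f"n{k}")
    return uniform_weights(SocialNetwork(g))


def random_instance(rng, max_users=20, max_steps=30):
    """Small random weighted network + thresholds + seed activity."""
    n = int(rng.integers(3, max_users + 1))
    T = int(rng.integers(3, max_steps + 1))
    p = rng.uniform(0.1, 0.5)
    g = nx.DiGraph()
    users = [f"u{k}" for k in range(n)]
    g.add_nodes_from(users)
    for i in users:
        for j in users:
            if i != j and rng.random() < p:
                g.add_edge(i, j)
    wnet = uniform_weights(SocialNetwork(g))
    order = wnet.user_order
    theta = rng.uniform(0, 1, size=n)
    profile_linear = ThresholdProfile(order, theta, np.ones(n))
    init = (rng.random((n, 1)) < 0.3).astype(np.uint8)
    init_log = ActivityLog(order, init)
    return wnet, profile_linear, init_log, T


@pytest.fixture
def fig2_setup():
    """Fig.-2-style scenario: 5 followees activating one per step; the focal
    user's band is (0.3, 0.7)."""
    wnet = star_network(5)
    users = wnet.user_order
    idx = {u: k for k, u in enumerate(users)}
    mat = np.zeros((len(users), 6), dtype=np.uint8)
    for t, cnt in zip([1, 2, 3, 4], [1, 2, 3, 4]):
        for k in range(1, cnt + 1):
            mat[idx[f"n{k}"], t] = 1
    log = ActivityLog(users, mat)
    bands = {u: (0.0, 1.0) for u in users}
    bands["A"] = (0.3, 0.7)
    return wnet, log, ThresholdProfile.from_dict(bands), idx
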