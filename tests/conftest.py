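import numpy as np
import pytest

from pleiosim.network import (
    DETECTOR,
    EFFECTOR,
    Node,
    RegulatoryNetwork,
    SIGNALING,
)


def make_net(edges, n_signaling=3, pleiotropy=None, lineage_id=None):
    """Hand-build a small network: nodes D, S1..Sk, E with the given
    {(src, dst): weight} edge map."""
    nodes = (
        [Node("D", DETECTOR)]
        + [Node(f"S{i + 1}", SIGNALING) for i in range(n_signaling)]
        + [Node("E", EFFECTOR)]
    )
    return RegulatoryNetwork(nodes, edges, pleiotropy, lineage_id)


def naive_step(net, active, use_coef):
    """Independent double-loop evaluation of the update rule, used as the
    dynamics oracle: ``active`` maps node id -> active fraction."""
    out = {}
    for node in net.nodes:
        i = node.id
        gain = 0.0
        loss = 0.0
        n_out = 0
        for (src, dst), w in net.edges.items():
            if dst == i and w >= 0:
                gain += w * active[src]
            if dst == i and w < 0:
                loss += (-w) * active[src]
            if src == i:
                n_out += 1
        new = (
            active[i]
            + (1.0 - active[i]) * gain
            - active[i] * loss
            - use_coef * n_out
        )
        out[i] = min(1.0, max(0.0, new))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
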