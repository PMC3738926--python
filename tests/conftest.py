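import numpy as np
import pytest

from lcnmorph.core import AXON, SOMA, MorphNode, Reconstruction
from lcnmorph.synthetic import SyntheticSpec, generate_lcn


@pytest.fixture(scope="session")
def default_lcn():
    """One default-preset synthetic LCN with its ground truth (seed 0)."""
    return generate_lcn(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def lcn_cohort():
    """Ten default-preset synthetic LCNs, seeds 0-9."""
    return [generate_lcn(SyntheticSpec(seed=s)) for s in range(10)]


def make_swc(tmp_path, text, name="cell.swc"):
    path = tmp_path / name
    path.write_text(text)
    return path


THREE_NODE_SWC = """\
1 1 0.0 0.0 0.0 5.0 -1
2 2 10.0 0.0 0.0 0.5 1
3 3 0.0 10.0 0.0 1.0 1
"""


def random_axon_tree(rng: np.random.Generator, n_nodes: int) -> Reconstruction:
    """A random rooted axon tree under a point soma (for oracle tests)."""
    nodes = [MorphNode(node_id=1, parent_id=None, x=0.0, y=0.0, z=0.0, diameter=8.0, label=SOMA)]
    nodes.append(
        MorphNode(node_id=2, parent_id=1, x=0.0, y=0.0, z=0.0, diameter=1.0, label=AXON)
    )
    for i in range(3, n_nodes + 2):
        parent = int(rng.integers(2, i))
        p = nodes[parent - 1]
        pos = np.array([p.x, p.y, p.z]) + rng.normal(scale=20.0, size=3)
        nodes.append(
            MorphNode(
                node_id=i,
                parent_id=parent,
                x=float(pos[0]),
                y=float(pos[1]),
                z=float(pos[2]),
                diameter=float(rng.uniform(0.2, 1.2)),
                label=AXON,
            )
        )
    return Reconstruction(neuron_id="random-tree", nodes=nodes)
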