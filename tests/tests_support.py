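"""Small helpers shared across test modules."""
import numpy as np

from nacage import NodeModel


def random_connected_nodes(rng, n=60, cutoff=12.0, box=25.0):
    """Random nodes resampled until the cutoff graph is connected."""
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial.distance import squareform, pdist
    for _ in range(100):
        pos = rng.uniform(0, box, (n, 3))
        adj = squareform(pdist(pos)) <= cutoff
        np.fill_diagonal(adj, False)
        if connected_components(adj, directed=False)[0] == 1:
            meta = [("A", i + 1, "P", None) for i in range(n)]
            return NodeModel(level=1, positions=pos, node_meta=meta)
    raise RuntimeError("could not sample a connected configuration")
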