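"""Independent transport-cost oracle for the EMD tests.

Solves the same transportation problem as the package's LP route, but as an
integer min-cost flow via networkx's network simplex, with masses and costs
scaled to 10^12 so the solve is exact for the rounded problem.
"""

import numpy as np
import networkx as nx


def emd_network_simplex(P, Q, scale=None):
    coords, p = P.flat()
    _, q = Q.flat()
    if scale is not None:
        coords = coords / np.asarray(scale, dtype=float)
    MASS, COST = 10 ** 12, 10 ** 12
    pi = np.round(p * MASS).astype(np.int64)
    qi = np.round(q * MASS).astype(np.int64)
    pi[np.argmax(pi)] += MASS - pi.sum()
    qi[np.argmax(qi)] += MASS - qi.sum()
    g = nx.DiGraph()
    for i in np.flatnonzero(pi):
        g.add_node(("p", i), demand=-int(pi[i]))
    for j in np.flatnonzero(qi):
        g.add_node(("q", j), demand=int(qi[j]))
    for i in np.flatnonzero(pi):
        for j in np.flatnonzero(qi):
            c = np.linalg.norm(coords[i] - coords[j])
            g.add_edge(("p", i), ("q", j), weight=int(round(c * COST)))
    cost, _ = nx.network_simplex(g)
    return cost / (MASS * COST)
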