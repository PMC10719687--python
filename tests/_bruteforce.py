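"""Brute-force all-pairs shortest-path oracle (independent of networkx).

Enumerates every simple path between each node pair, so it is only usable
on tiny graphs (<= ~7 nodes); used to validate the path-based centrality
implementations.
"""

import itertools
import math


def brute_force_centralities(nodes, lengths, tol=1e-12):
    """Betweenness (fractional credit over tied shortest paths, interior
    nodes only, unordered pairs) and closeness (reachable-mean inverse).

    ``lengths`` maps frozenset({u, v}) -> positive path length.
    """
    betweenness = {v: 0.0 for v in nodes}
    dist = {v: {} for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        best = math.inf
        best_paths = []
        others = [v for v in nodes if v not in (s, t)]
        for r in range(len(others) + 1):
            for mid in itertools.permutations(others, r):
                path = (s,) + mid + (t,)
                d = 0.0
                ok = True
                for u, v in zip(path, path[1:]):
                    e = lengths.get(frozenset((u, v)))
                    if e is None:
                        ok = False
                        break
                    d += e
                if not ok:
                    continue
                if d < best - tol:
                    best, best_paths = d, [path]
                elif abs(d - best) <= tol:
                    best_paths.append(path)
        if best < math.inf:
            dist[s][t] = dist[t][s] = best
            for v in others:
                cnt = sum(1 for p in best_paths if v in p[1:-1])
                betweenness[v] += cnt / len(best_paths)
    closeness = {}
    for v in nodes:
        ds = dist[v]
        closeness[v] = len(ds) / sum(ds.values()) if ds else 0.0
    return betweenness, closeness


def random_weighted_network(rng, max_nodes=7):
    """A random Network with continuous weights (ties almost surely absent)."""
    from bridgenet.mgm import Network
    from bridgenet.variables import CONTINUOUS, VariableSpec

    n = int(rng.integers(3, max_nodes + 1))
    specs = [VariableSpec(f"v{i}", CONTINUOUS, 0, "g", i) for i in range(n)]
    net = Network(nodes=specs)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.55:
                net.add_edge(f"v{i}", f"v{j}", float(rng.uniform(0.1, 1.0)), "+")
    return net
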