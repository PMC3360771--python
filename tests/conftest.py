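"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
import pytest


@pytest.fixture(scope="session")
def klap_bruteforce():
    """Exhaustive k-cardinality assignment oracle for small cost matrices."""
    perm_cache: dict = {}

    def solve(costs: np.ndarray, k: int) -> float:
        costs = np.asarray(costs, dtype=float)
        m, n = costs.shape
        key = (n, k)
        if key not in perm_cache:
            perm_cache[key] = np.array(list(permutations(range(n), k)), dtype=int)
        perms = perm_cache[key]
        idx = np.arange(k)
        best = np.inf
        for rows in combinations(range(m), k):
            sub = costs[list(rows)]
            best = min(best, float(sub[idx, perms].sum(axis=1).min()))
        return best

    return solve


@pytest.fixture(scope="session")
def longest_chain_bruteforce():
    """Maximum subset of pairs strictly increasing in both coordinates.

    Independent of the dynamic program under test: the problem is recast
    as maximum clique on the comparability graph (two pairs are compatible
    iff they increase together) and solved by networkx's exact
    branch-and-bound clique solver.
    """
    import networkx as nx

    def solve(pairs) -> int:
        pairs = list(pairs)
        graph = nx.Graph()
        graph.add_nodes_from(range(len(pairs)))
        for a in range(len(pairs)):
            ia, ja = pairs[a]
            for b in range(a + 1, len(pairs)):
                ib, jb = pairs[b]
                if (ia - ib) * (ja - jb) > 0:
                    graph.add_edge(a, b)
        clique, _ = nx.max_weight_clique(graph, weight=None)
        return len(clique)

    return solve


def rotation_angle_deg(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic angle (degrees) between two rotation matrices."""
    cos = (np.trace(r1 @ r2.T) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


@pytest.fixture(scope="session")
def rotation_error_deg():
    return rotation_angle_deg


# --- tiny PDB fixture texts ----------------------------------------------

PDB_THREE_RESIDUES = """\
ATOM      1  N   ALA A   1      10.000   5.000   1.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.104   6.134   1.711  1.00  0.00           C
ATOM      3  CA  GLY A   2      13.200   8.000   2.500  1.00  0.00           C
ATOM      4  CB  GLY A   2      13.900   8.400   3.100  1.00  0.00           C
ATOM      5  CA  SER A   3      15.800  10.200   3.900  1.00  0.00           C
HETATM    6  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
END
"""

PDB_ALTLOC = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA AGLY A   2       4.000   5.000   6.000  0.40  0.00           C
ATOM      3  CA BGLY A   2       4.500   5.500   6.500  0.60  0.00           C
ATOM      4  CA  SER A   3       8.000   9.000  10.000  1.00  0.00           C
END
"""

PDB_TWO_CHAINS = """\
ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       4.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       8.600   0.000   0.000  1.00  0.00           C
ATOM      4  CA  ALA A   4      12.400   0.000   0.000  1.00  0.00           C
ATOM      5  CA  ALA A   5      16.200   0.000   0.000  1.00  0.00           C
ATOM      6  CA  GLY B  10       0.000   1.000   0.000  1.00  0.00           C
ATOM      7  CA  GLY B  11       0.000   4.800   0.000  1.00  0.00           C
ATOM      8  CA  GLY B  12       0.000   8.600   0.000  1.00  0.00           C
ATOM      9  CA  GLY B  13       0.000  12.400   0.000  1.00  0.00           C
END
"""

PDB_TWO_MODELS = """\
MODEL        1
ATOM      1  CA  ALA A   1       1.000   1.000   1.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       4.800   1.000   1.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       9.000   9.000   9.000  1.00  0.00           C
ATOM      2  CA  ALA A   2      12.800   9.000   9.000  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def pdb_file(tmp_path):
    """Write PDB text to a temp file and return its path."""

    def write(text, name="fixture.pdb"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return write
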