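"""Largest sequential sub-alignment of a non-sequential alignment.

The one-to-one matching returned by the k-cardinality assignment carries no
ordering constraint. The largest sequential alignment contained in it — the
maximum-cardinality subset of pairs strictly increasing in both chains — is
found by dynamic programming: for each aligned residue i of A (in chain
order) compute len[i], the length of the longest sequential sub-alignment
terminating at i, together with a back-pointer prev[i] to the preceding
aligned residue; backtracking from the maximal len yields the alignment.
Quadratic in the number of aligned pairs, which is immaterial at protein
scale.
"""

from __future__ import annotations

from .assignment import Alignment

__all__ = ["extract_sequential"]


def extract_sequential(alignment: Alignment) -> Alignment:
    """Maximum subset of pairs strictly increasing in both i and pi(i).

    Ties among equal-length predecessors are broken toward the smallest
    predecessor index so the output is deterministic; the optimal
    cardinality is unaffected. An empty alignment maps to an empty
    alignment.
    """
    pairs = sorted(alignment.pairs)  # ascending in i; j = pi(i) one-to-one
    n = len(pairs)
    if n == 0:
        return Alignment(())

    length = [1] * n
    prev = [-1] * n
    for a in range(n):
        for b in range(a):
            if pairs[b][1] < pairs[a][1] and length[b] + 1 > length[a]:
                length[a] = length[b] + 1
                prev[a] = b  # first (smallest) b attaining the max wins
    end = max(range(n), key=lambda idx: (length[idx], -idx))

    chosen = []
    while end != -1:
        chosen.append(pairs[end])
        end = prev[end]
    return Alignment(tuple(reversed(chosen)))
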