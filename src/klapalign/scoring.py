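"""Length-normalized similarity scores: SAS, SI, fragment length N_f, SAS_f.

SAS = 100 * RMSD / N_match        (Subbiah-style structure alignment score)
SI  = RMSD * min(L_A, L_B) / N_match   (Kleywegt & Jones similarity index)

Non-sequential alignments have no well-defined "length of alignment", so the
total fragment length N_f stands in for it: the sum of lengths of aligned
runs that are consecutive in both proteins with the same offset
((i, j), (i+1, j+1), ...), counting only runs of five or more residues.

SAS_f = 100 * RMSD / N_f, which reduces to SAS for a fully sequential
alignment made of such fragments. Lower is better; 4 A is the conventional
similar/dissimilar cutoff. A one-to-one matching scattered into runs all
shorter than five residues has N_f = 0: it is flagged disordered and SAS_f
is reported as +inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .assignment import Alignment

__all__ = ["ScoreReport", "fragment_decomposition", "compute_scores", "MIN_FRAGMENT"]

MIN_FRAGMENT = 5  # residues; shorter runs do not count toward N_f


@dataclass(frozen=True)
class ScoreReport:
    """Similarity scores of one alignment (all distances in Angstrom)."""

    rmsd: float
    n_match: int
    n_f: int
    sas: float
    si: float
    sas_f: float  # +inf when n_f == 0 (disordered alignment)
    fragments: tuple  # of (start_i, start_j, length), runs >= MIN_FRAGMENT

    @property
    def disordered(self) -> bool:
        return self.n_f == 0

    def to_dict(self) -> dict:
        return {
            "rmsd": self.rmsd,
            "n_match": self.n_match,
            "n_f": self.n_f,
            "sas": self.sas,
            "si": self.si,
            "sas_f": self.sas_f,
            "disordered": self.disordered,
            "fragments": [list(f) for f in self.fragments],
        }


def fragment_decomposition(alignment: Alignment):
    """Maximal co-directional runs of an alignment and the total length N_f.

    A run is a maximal set of pairs (i, j), (i+1, j+1), ... consecutive in
    both proteins. Returns ``(fragments, n_f)`` where ``fragments`` lists
    runs of length >= 5 as ``(start_i, start_j, length)`` and ``n_f`` is the
    sum of their lengths. Shorter runs contribute nothing.
    """
    mapping = alignment.mapping()
    fragments = []
    for i, j in sorted(mapping.items()):
        if mapping.get(i - 1) == j - 1:
            continue  # not a run start
        length = 1
        while mapping.get(i + length) == j + length:
            length += 1
        if length >= MIN_FRAGMENT:
            fragments.append((i, j, length))
    n_f = sum(f[2] for f in fragments)
    return tuple(fragments), n_f


def compute_scores(rmsd: float, alignment: Alignment, length_a: int, length_b: int) -> ScoreReport:
    """Score an alignment of proteins with ``length_a`` and ``length_b`` residues."""
    if rmsd < 0 or not math.isfinite(rmsd):
        raise ValueError("rmsd must be finite and nonnegative")
    n_match = alignment.k
    if n_match == 0:
        raise ValueError("cannot score an empty alignment")
    fragments, n_f = fragment_decomposition(alignment)
    sas = 100.0 * rmsd / n_match
    si = rmsd * min(length_a, length_b) / n_match
    sas_f = 100.0 * rmsd / n_f if n_f > 0 else math.inf
    return ScoreReport(
        rmsd=float(rmsd),
        n_match=n_match,
        n_f=n_f,
        sas=sas,
        si=si,
        sas_f=sas_f,
        fragments=fragments,
    )
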