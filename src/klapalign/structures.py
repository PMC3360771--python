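"""Calpha-only structure I/O: PDB reading/writing and alignment tables.

Only ATOM records are used (HETATM ignored): the alignment operates on the
protein backbone, represented by one Calpha per residue. For alternate
locations the first listed altLoc is kept; multi-model (NMR) files
contribute only their first MODEL. Residues lacking a Calpha are skipped.

Alignment indices throughout the library are 1-based positions along the
parsed chain; author residue numbers plus insertion codes are carried in
``residue_ids`` so that reports remain unambiguous.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .assignment import Alignment
from .geometry import RigidTransform, apply_transform

__all__ = [
    "ProteinStructure",
    "read_ca_chain",
    "write_transformed_pdb",
    "write_alignment_tsv",
    "read_alignment_tsv",
]


@dataclass(frozen=True)
class ProteinStructure:
    """Ordered Calpha trace of one chain.

    ``residue_ids`` is an ordered tuple of ``(author sequence number,
    insertion code)``; ``coords`` is an (L, 3) float array in Angstrom.
    ``resnames`` (optional, parallel to residues) keeps 3-letter residue
    names for PDB output; absent entries are written as UNK.
    """

    name: str
    chain: str
    residue_ids: tuple
    coords: np.ndarray
    resnames: tuple = field(default=())

    def __post_init__(self) -> None:
        coords = np.array(self.coords, dtype=float).reshape(-1, 3)
        rids = tuple((int(num), str(icode)) for num, icode in self.residue_ids)
        if len(rids) < 1 or len(rids) != len(coords):
            raise ValueError("residue_ids and coords must have equal length >= 1")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        resnames = tuple(self.resnames) if self.resnames else tuple("UNK" for _ in rids)
        if len(resnames) != len(rids):
            raise ValueError("resnames must parallel residue_ids")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residue_ids", rids)
        object.__setattr__(self, "resnames", resnames)

    @property
    def length(self) -> int:
        return len(self.residue_ids)

    def residue_label(self, index: int) -> str:
        """Author residue number (+ insertion code) for a 1-based position."""
        num, icode = self.residue_ids[index - 1]
        return f"{num}{icode.strip()}"

    def subset(self, positions) -> "ProteinStructure":
        """New structure restricted to the given 1-based positions (in order)."""
        idx = [int(p) - 1 for p in positions]
        if not idx:
            raise ValueError("subset must keep at least one residue")
        return ProteinStructure(
            name=self.name,
            chain=self.chain,
            residue_ids=tuple(self.residue_ids[i] for i in idx),
            coords=self.coords[idx],
            resnames=tuple(self.resnames[i] for i in idx),
        )


def read_ca_chain(path, chain: str, name: str | None = None) -> ProteinStructure:
    """Parse one chain of a PDB file into a Calpha-only structure.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` if
    the chain is absent or contributes no Calpha atoms.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = next(parser.get_structure("s", str(path)).get_models())  # first MODEL only
    if chain not in [c.id for c in model]:
        raise ValueError(f"chain {chain!r} not found in {path}")

    residue_ids, resnames, coords = [], [], []
    for residue in model[chain]:
        if residue.id[0] != " ":  # HETATM / water
            continue
        if "CA" not in residue:
            continue  # residues lacking a Calpha are skipped
        atom = residue["CA"]
        if atom.is_disordered():
            atom = atom.disordered_get_list()[0]  # first listed altLoc
        residue_ids.append((residue.id[1], residue.id[2]))
        resnames.append(residue.get_resname())
        coords.append(atom.get_coord())

    if not coords:
        raise ValueError(f"chain {chain!r} of {path} contains no Calpha atoms")
    label = name if name is not None else str(path)
    return ProteinStructure(label, chain, tuple(residue_ids), np.array(coords, float), tuple(resnames))


def write_transformed_pdb(structure: ProteinStructure, transform: RigidTransform, path) -> None:
    """Write the structure's Calpha trace, moved by ``transform``, as PDB."""
    moved = apply_transform(transform, structure.coords)
    lines = []
    for serial, ((num, icode), resname, xyz) in enumerate(
        zip(structure.residue_ids, structure.resnames, moved), start=1
    ):
        lines.append(
            f"ATOM  {serial:5d}  CA  {resname:>3.3s} {structure.chain:1.1s}"
            f"{num:4d}{(icode or ' '):1.1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          " + " C"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_TSV_COLUMNS = "index_A\tresid_A\tindex_B\tresid_B\tdistance_A"


def write_alignment_tsv(
    path,
    alignment: Alignment,
    *,
    rmsd: float,
    transform: RigidTransform,
    structure_a: ProteinStructure | None = None,
    structure_b: ProteinStructure | None = None,
    n_f: int | None = None,
    sas_f: float | None = None,
    distances=None,
) -> None:
    """Write an alignment as TSV with header metadata lines.

    Per-pair distances are computed from the structures under ``transform``
    when both are given; otherwise a precomputed ``distances`` sequence
    (parallel to ``alignment.pairs``) may be supplied.
    """
    pairs = alignment.sorted_by_a()
    if structure_a is not None and structure_b is not None:
        moved = apply_transform(transform, structure_a.coords)
        dist_of = {
            (i, j): float(np.linalg.norm(moved[i - 1] - structure_b.coords[j - 1]))
            for i, j in pairs
        }
    elif distances is not None:
        dist_of = dict(zip(alignment.pairs, [float(d) for d in distances]))
    else:
        dist_of = {p: float("nan") for p in pairs}

    def label(structure, idx):
        return structure.residue_label(idx) if structure is not None else str(idx)

    header = [
        f"# rmsd\t{rmsd:.6f}",
        f"# k\t{alignment.k}",
        f"# transform_t\t{transform.t[0]:.9g}\t{transform.t[1]:.9g}\t{transform.t[2]:.9g}",
        f"# transform_theta\t{transform.theta[0]:.9g}\t{transform.theta[1]:.9g}\t{transform.theta[2]:.9g}",
    ]
    if n_f is not None:
        header.append(f"# n_f\t{n_f}")
    if sas_f is not None:
        header.append(f"# sas_f\t{'inf' if not np.isfinite(sas_f) else f'{sas_f:.6f}'}")
    rows = [
        f"{i}\t{label(structure_a, i)}\t{j}\t{label(structure_b, j)}\t{dist_of[(i, j)]:.4f}"
        for i, j in pairs
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header + [_TSV_COLUMNS] + rows) + "\n")


def read_alignment_tsv(path) -> dict:
    """Read an alignment TSV back into its parts.

    Returns a dict with keys ``alignment`` (Alignment), ``rmsd`` (float or
    None), ``transform`` (RigidTransform or None) and ``distances`` (list of
    floats parallel to the alignment pairs). Raises ``ValueError`` on
    malformed input.
    """
    meta: dict = {}
    pairs, distances = [], []
    try:
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        body_seen = False
        for line in lines:
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                meta[parts[0]] = parts[1:]
                continue
            if not body_seen:
                if line.split("\t")[:2] != ["index_A", "resid_A"]:
                    raise ValueError("missing column header")
                body_seen = True
                continue
            fields = line.split("\t")
            pairs.append((int(fields[0]), int(fields[2])))
            distances.append(float(fields[4]))
        if not body_seen:
            raise ValueError("no column header found")
        alignment = Alignment(tuple(pairs))
        rmsd = float(meta["rmsd"][0]) if "rmsd" in meta else None
        transform = None
        if "transform_t" in meta and "transform_theta" in meta:
            transform = RigidTransform(
                np.array([float(v) for v in meta["transform_t"]]),
                np.array([float(v) for v in meta["transform_theta"]]),
            )
    except (OSError, ValueError):
        raise
    except Exception as exc:  # index errors, parse errors -> uniform failure mode
        raise ValueError(f"malformed alignment TSV {path}: {exc}") from exc
    return {"alignment": alignment, "rmsd": rmsd, "transform": transform, "distances": distances}


def write_score_json(path, payload: dict) -> None:
    """Dump a score report dict as JSON (non-finite numbers become null)."""
    def _clean(obj):
        if isinstance(obj, float) and not np.isfinite(obj):
            return None
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        json.dump(_clean(payload), fh, indent=2)
        fh.write("\n")
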