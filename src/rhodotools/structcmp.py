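"""Cα superposition and RMSD between rhodopsin structures.

Residues of the two chains are paired by global sequence alignment, the
optimal rigid transform is found by the Kabsch (SVD) algorithm, and the
root-mean-square deviation of the paired Cα atoms is reported. An
optional iterative trimming step discards the worst-fitting pairs, which
mimics the core-selection behaviour of common superposition tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .opsinseq import align_to_reference

__all__ = [
    "StructureModel",
    "read_structure",
    "write_structure",
    "kabsch_superpose",
    "align_and_rmsd",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class StructureModel:
    """Cα-only model of one chain: residue numbers, amino acids, coordinates (Å)."""

    chain: str
    residue_ids: list[int]
    residues: str                # one-letter sequence, X for non-standard
    coords: np.ndarray           # (n, 3) Cα coordinates
    source: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.residue_ids), 3):
            raise ValueError("coords must be (n_residues, 3)")
        if len(self.residues) != len(self.residue_ids):
            raise ValueError("sequence length must match residue count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if list(self.residue_ids) != sorted(set(self.residue_ids)):
            raise ValueError("residue ids must be strictly increasing")


def read_structure(path: str | Path, chain: str | None = None) -> StructureModel:
    """Read the Cα trace of one chain from a PDB file.

    When ``chain`` is None the first polymer chain is used. Alternate
    locations resolve to the highest occupancy, ties to altloc 'A'.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    target = None
    for ch in model:
        if chain is None or ch.name == chain:
            target = ch
            break
    if target is None:
        raise ValueError(f"chain {chain!r} not found in {path}")

    ids, seq, xyz = [], [], []
    for res in target:
        best = None
        for atom in res:
            if atom.name != "CA":
                continue
            if best is None or (atom.occ, -ord(atom.altloc or "A")) > (
                best.occ, -ord(best.altloc or "A")
            ):
                best = atom
        if best is None:
            continue
        ids.append(res.seqid.num)
        seq.append(_THREE_TO_ONE.get(res.name, "X"))
        xyz.append([best.pos.x, best.pos.y, best.pos.z])
    if not xyz:
        raise ValueError(f"no Cα atoms in chain {target.name} of {path}")
    return StructureModel(
        chain=target.name,
        residue_ids=ids,
        residues="".join(seq),
        coords=np.array(xyz),
        source=str(path),
    )


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a Cα-only model as a PDB file (coordinates to 3 decimals)."""
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items()}
    with open(path, "w") as fh:
        for n, (rid, aa, xyz) in enumerate(
            zip(model.residue_ids, model.residues, model.coords), start=1
        ):
            res3 = one_to_three.get(aa, "UNK")
            fh.write(
                f"ATOM  {n:5d}  CA  {res3} {model.chain[:1]}{rid:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired point sets (Kabsch, SVD).

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords_b @ rotation.T + translation`` best fits ``coords_a`` in the
    least-squares sense. The rotation is proper (det = +1); reflections
    are excluded by the usual sign correction on the smallest singular
    vector.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("need two equally sized (n, 3) arrays")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = B0.T @ A0
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    resid = A - (B @ R.T + t)
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return R, t, rmsd


def align_and_rmsd(
    struct_a: StructureModel,
    struct_b: StructureModel,
    trim_fraction: float = 0.0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> dict:
    """Sequence-alignment-guided Cα RMSD between two chains.

    Residues are paired by global alignment of the one-letter sequences;
    all matched pairs enter a Kabsch fit. With ``trim_fraction`` > 0 the
    worst-fitting pairs are removed one at a time, re-fitting after each
    removal, until that fraction of the initial pairs is gone.

    Returns a dict with ``n_pairs``, ``rmsd``, ``rotation``,
    ``translation``, and the retained index pairs.
    """
    if not (0.0 <= trim_fraction < 1.0):
        raise ValueError("trim_fraction must be in [0, 1)")
    mapping, _ = align_to_reference(
        struct_b.residues, struct_a.residues, gap_open=gap_open, gap_extend=gap_extend
    )
    pairs = [(p - 1, q - 1) for p, q in mapping.items() if q is not None]
    pairs.sort()
    if len(pairs) < 3:
        raise ValueError("fewer than 3 aligned residue pairs")
    ia = np.array([p for p, _ in pairs])
    ib = np.array([q for _, q in pairs])
    n_remove = int(np.floor(trim_fraction * len(pairs)))
    keep = np.ones(len(pairs), dtype=bool)
    R, t, rmsd = kabsch_superpose(struct_a.coords[ia], struct_b.coords[ib])
    for _ in range(n_remove):
        if keep.sum() <= 3:
            break
        resid = struct_a.coords[ia] - (struct_b.coords[ib] @ R.T + t)
        dist = np.sum(resid**2, axis=1)
        dist[~keep] = -1.0
        keep[np.argmax(dist)] = False
        R, t, rmsd = kabsch_superpose(
            struct_a.coords[ia[keep]], struct_b.coords[ib[keep]]
        )
    return {
        "n_pairs": int(keep.sum()),
        "rmsd": rmsd,
        "rotation": R,
        "translation": t,
        "pairs": list(zip(ia[keep].tolist(), ib[keep].tolist())),
    }
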