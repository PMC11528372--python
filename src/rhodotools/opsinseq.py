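"""Opsin sequence analysis: reference-position mapping and motif classification.

Microbial rhodopsin function tracks a small set of residues expressed in
bacteriorhodopsin (BR) numbering: the proton acceptor Asp85, the Thr89
position, the proton donor Asp96 (together the three-letter transport
motif), the proton-release pair Glu194/Glu204, the counterion Asp212, and
the Schiff-base lysine Lys216. This module maps query sequences onto a
bundled reference by global alignment, extracts those positions, derives
the motif (e.g. DTD, DTS, NDQ, NTQ) and the corresponding transported-ion
prediction, and checks whether a stable retinal Schiff base can form
(lysine at the 216-equivalent plus carboxylates at 85 and 212).

Numbering convention: positions are counted from the first residue of the
bundled reference template, 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "OpsinRecord",
    "KEY_POSITIONS",
    "DEFAULT_MOTIF_RULES",
    "load_reference",
    "load_motif_rules",
    "align_to_reference",
    "extract_key_residues",
    "classify_motif",
    "check_schiff_base",
    "screen_fasta",
]

#: BR-numbering positions extracted for every query (functional residue set)
KEY_POSITIONS = (85, 89, 96, 194, 204, 212, 216)

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class OpsinRecord:
    """One classified opsin sequence."""

    id: str
    sequence: str
    key_residues: dict[int, tuple[int | None, str]] = field(default_factory=dict)
    motif: str = ""
    schiff_base_ok: bool = False
    predicted_function: str = "unclassified"


def _data_path(name: str) -> Path:
    return Path(str(resources.files("rhodotools").joinpath("data", name)))


def load_reference() -> tuple[str, str]:
    """Return (id, sequence) of the bundled reference opsin template.

    The template is a synthetic BR-like sequence (see its FASTA header):
    a constructed seven-helix opsin scaffold carrying the canonical
    functional residues at the canonical BR positions, used purely as a
    numbering reference.
    """
    rec = next(SeqIO.parse(_data_path("reference_opsin_synthetic.fasta"), "fasta"))
    return rec.id, str(rec.seq)


def load_motif_rules(path: str | Path | None = None) -> dict[str, str]:
    """Motif→function rule table from YAML; bundled defaults when no path."""
    p = Path(path) if path is not None else _data_path("motif_rules.yaml")
    with open(p) as fh:
        rules = yaml.safe_load(fh)
    if not isinstance(rules, dict):
        raise ValueError("motif rule table must be a mapping motif -> function")
    return {str(k).upper(): str(v) for k, v in rules.items()}


DEFAULT_MOTIF_RULES = {
    "DTD": "outward H+ pump",
    "DTE": "outward H+ pump",
    "DTS": "outward H+ pump",   # Ser at the donor site, still a proton pump
    "NDQ": "Na+ pump",
    "NTQ": "Cl- pump",
    "TSA": "Cl- pump",          # halorhodopsin-like
    "TSD": "Cl- pump",
}


def _validate_seq(seq: str, name: str) -> str:
    s = seq.strip().upper()
    if not s:
        raise ValueError(f"{name} sequence is empty")
    bad = set(s) - _AA
    if bad:
        raise ValueError(f"{name} sequence has invalid residues: {sorted(bad)}")
    return s


def align_to_reference(
    query: str,
    reference: str | None = None,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[dict[int, int | None], float]:
    """Global affine-gap alignment of query onto the reference numbering.

    Needleman–Wunsch/Gotoh with end gaps penalized. A gap of length L
    costs ``gap_open + (L-1)*gap_extend``. Returns ``(mapping, score)``
    where ``mapping`` sends each 1-based reference position to the 1-based
    query position aligned to it, or None at a gap. Traceback ties prefer
    substitution over a gap in the query over a gap in the reference, so
    the reported alignment is deterministic.
    """
    if reference is None:
        _, reference = load_reference()
    a = _validate_seq(reference, "reference")  # rows
    b = _validate_seq(query, "query")          # columns
    sub = substitution_matrices.load(matrix)
    alpha = {c: i for i, c in enumerate(sub.alphabet)}
    smat = np.asarray(sub)
    ai = np.array([alpha.get(c, alpha.get("X", 0)) for c in a])
    bi = np.array([alpha.get(c, alpha.get("X", 0)) for c in b])
    n, m = len(a), len(b)
    NEG = -1e18
    go, ge = -float(gap_open), -float(gap_extend)

    # state matrices: M substitution, U gap in query (consumes reference),
    # L gap in reference (consumes query)
    M = np.full((n + 1, m + 1), NEG)
    U = np.full((n + 1, m + 1), NEG)
    L = np.full((n + 1, m + 1), NEG)
    # pointers: for M, 0=from M,1=from U,2=from L (diagonal step);
    # for U/L, 0=open (from M), 1=extend
    ptrM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrU = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrL = np.zeros((n + 1, m + 1), dtype=np.uint8)

    M[0, 0] = 0.0
    for j in range(1, m + 1):
        L[0, j] = go + (j - 1) * ge
        ptrL[0, j] = 0 if j == 1 else 1
    for i in range(1, n + 1):
        U[i, 0] = go + (i - 1) * ge
        ptrU[i, 0] = 0 if i == 1 else 1

    for i in range(1, n + 1):
        s_row = smat[ai[i - 1], bi]  # substitution scores vs whole query
        # U row: gap in query, vertical moves (depends on row i-1 only)
        open_u = M[i - 1, :] + go
        ext_u = U[i - 1, :] + ge
        U[i, :] = np.maximum(open_u, ext_u)
        ptrU[i, :] = np.where(open_u >= ext_u, 0, 1)
        # M row: diagonal from row i-1 (prefer M, then U, then L on ties)
        prevM, prevU, prevL = M[i - 1, :-1], U[i - 1, :-1], L[i - 1, :-1]
        diag = np.maximum(np.maximum(prevM, prevU), prevL)
        M[i, 1:] = diag + s_row
        ptrM[i, 1:] = np.where(prevM >= diag, 0, np.where(prevU >= diag, 1, 2))
        M[i, 0] = NEG
        # L row: gap in reference, horizontal. The recurrence
        # L[i,j] = max(M[i,j-1]+go, L[i,j-1]+ge) unrolls to a cumulative
        # max over openings k<j of M[i,k] + go + (j-1-k)*ge.
        src = M[i, :-1] + go
        jj = np.arange(m)
        L[i, 1:] = np.maximum.accumulate(src - jj * ge) + jj * ge
        ptrL[i, 1:] = np.where(src >= L[i, :-1] + ge, 0, 1)

    ends = np.array([M[n, m], U[n, m], L[n, m]])
    state = int(np.argmax(ends))  # prefers M on ties
    score = float(ends[state])

    mapping: dict[int, int | None] = {}
    i, j = n, m
    states = "MUL"
    while i > 0 or j > 0:
        st = states[state]
        if st == "M":
            mapping[i] = j
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif st == "U":
            mapping[i] = None
            state = 0 if ptrU[i, j] == 0 else 1
            i -= 1
        else:
            state = 0 if ptrL[i, j] == 0 else 2
            j -= 1
    return mapping, score


def extract_key_residues(
    query: str,
    mapping: dict[int, int | None],
    positions: tuple[int, ...] = KEY_POSITIONS,
) -> dict[int, tuple[int | None, str]]:
    """Residues of ``query`` at the reference-numbered ``positions``.

    Returns reference position → (query position 1-based or None, residue
    or '-') for each requested position.
    """
    out: dict[int, tuple[int | None, str]] = {}
    for p in positions:
        q = mapping.get(p)
        if q is None:
            out[p] = (None, "-")
        else:
            out[p] = (q, query[q - 1].upper())
    return out


def classify_motif(
    key_residues: dict[int, tuple[int | None, str]],
    rules: dict[str, str] | None = None,
) -> tuple[str, str]:
    """Transport motif (residues at 85/89/96) and its function prediction."""
    if rules is None:
        rules = DEFAULT_MOTIF_RULES
    try:
        motif = "".join(key_residues[p][1] for p in (85, 89, 96))
    except KeyError as e:
        raise ValueError(f"key residue at reference position {e} missing") from e
    if "-" in motif:
        return motif, "unclassified"
    return motif, rules.get(motif.upper(), "unclassified")


def check_schiff_base(key_residues: dict[int, tuple[int | None, str]]) -> bool:
    """True iff a stable retinal Schiff base can plausibly form.

    Requires the Schiff-base lysine at the 216-equivalent and carboxylate
    counterions (Asp or Glu) at both the 85- and 212-equivalents.
    """
    r216 = key_residues.get(216, (None, "-"))[1]
    r85 = key_residues.get(85, (None, "-"))[1]
    r212 = key_residues.get(212, (None, "-"))[1]
    return r216 == "K" and r85 in ("D", "E") and r212 in ("D", "E")


def analyze_sequence(
    seq_id: str,
    sequence: str,
    reference: str | None = None,
    rules: dict[str, str] | None = None,
) -> OpsinRecord:
    """Full per-sequence analysis: align, extract, classify."""
    mapping, _ = align_to_reference(sequence, reference)
    seq = sequence.strip().upper()
    key = extract_key_residues(seq, mapping)
    motif, func = classify_motif(key, rules)
    return OpsinRecord(
        id=seq_id,
        sequence=seq,
        key_residues=key,
        motif=motif,
        schiff_base_ok=check_schiff_base(key),
        predicted_function=func,
    )


def screen_fasta(
    path: str | Path,
    reference: str | None = None,
    rules: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Classify every sequence of a FASTA file into a summary table.

    One row per record: id, motif, predicted function, Schiff-base
    viability, and the (query position, residue) pair for each reference
    position. Records that fail to parse are kept as rows flagged in the
    ``error`` column; an unreadable or empty file raises.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise IOError(f"no FASTA records found in {path}")
    rows = []
    for rec in records:
        row: dict = {"id": rec.id, "error": ""}
        try:
            r = analyze_sequence(rec.id, str(rec.seq), reference, rules)
            row.update(
                motif=r.motif,
                function=r.predicted_function,
                schiff_base=r.schiff_base_ok,
            )
            for p in KEY_POSITIONS:
                q, aa = r.key_residues[p]
                row[f"pos{p}"] = q
                row[f"res{p}"] = aa
        except (ValueError, KeyError) as e:
            row.update(motif="", function="unclassified", schiff_base=False, error=str(e))
        rows.append(row)
    return pd.DataFrame(rows)
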