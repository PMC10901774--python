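"""Geometric side of the mirror principle: reflect models, classify helices.

Reflection through the yz-plane (x -> -x) is the canonical mirror here; any
other reflection differs only by a proper rotation, and fixing one keeps
outputs reproducible.  Helix handedness is read from C-alpha virtual
torsions — the dihedral over four consecutive alpha carbons — which is
robust to missing side-chain and backbone atoms.  An ideal right-handed
alpha-helix has a virtual torsion near +50 degrees; its mirror image has the
sign flipped, so D-peptide helices classify as left-handed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

RIGHT_WINDOW = (30.0, 70.0)   # degrees; left window is the mirror image
MIN_CA_SPACING = 2.0          # Angstrom
MAX_CA_SPACING = 4.5


@dataclass
class BackboneTrace:
    """Ordered C-alpha coordinates of one chain."""

    coords: np.ndarray          # (n, 3) Angstrom
    residue_ids: list[str]      # auth seq id + insertion code, in order
    chain: str

    def __len__(self) -> int:
        return len(self.coords)


def read_ca_trace(path: str | Path, chain: str) -> BackboneTrace:
    """C-alpha trace of a chain from a PDB or mmCIF file.

    Altloc A (or blank) is preferred; one record per residue; insertion
    codes are preserved in the ordering the file gives.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    names = [ch.name for ch in model]
    if chain not in names:
        raise ValueError(f"chain {chain!r} not found; available: {names}")
    coords = []
    rids = []
    for res in model[chain]:
        ca = None
        for atom in res:
            if atom.name == "CA" and atom.altloc in ("", "A", "\x00"):
                ca = atom
                break
        if ca is not None:
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            icode = res.seqid.icode.strip()
            rids.append(f"{res.seqid.num}{icode}")
    if not coords:
        raise ValueError(f"chain {chain!r} has no alpha-carbon atoms")
    return BackboneTrace(np.asarray(coords, dtype=float), rids, chain)


def mirror_coords(coords: np.ndarray) -> np.ndarray:
    """Reflect coordinates through the yz-plane (x -> -x).

    An involution and an isometry: applying twice restores the input
    exactly, and all pairwise distances are preserved; the signed volume of
    any point tetrad flips sign.
    """
    out = np.array(coords, dtype=float, copy=True)
    out[..., 0] = -out[..., 0]
    return out


def mirror_structure(path: str | Path, out_path: str | Path) -> None:
    """Write a mirrored copy (x -> -x) of a PDB/mmCIF coordinate file.

    Residue names and chirality labels are left untouched; the output
    carries a header remark marking the model as mirrored.
    """
    st = gemmi.read_structure(str(path))
    for model in st:
        for ch in model:
            for res in ch:
                for atom in res:
                    atom.pos = gemmi.Position(-atom.pos.x, atom.pos.y, atom.pos.z)
    out_path = Path(out_path)
    st.raw_remarks = ["REMARK 999 MIRRORED MODEL: REFLECTED THROUGH X -> -X"]
    if out_path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(out_path))
    else:
        st.write_pdb(str(out_path))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
             ) -> float:
    """Signed dihedral angle in degrees; NaN when degenerate (collinear)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    b1n = np.linalg.norm(b1)
    if n1n < 1e-10 or n2n < 1e-10 or b1n < 1e-10:
        return float("nan")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1 / b1n))
    return float(np.degrees(np.arctan2(y, x)))


def virtual_torsions(coords: np.ndarray) -> np.ndarray:
    """Dihedrals over consecutive C-alpha quadruples (degrees)."""
    coords = np.asarray(coords, float)
    if len(coords) < 4:
        raise ValueError("at least 4 alpha carbons are required")
    return np.array([
        dihedral(coords[i], coords[i + 1], coords[i + 2], coords[i + 3])
        for i in range(len(coords) - 3)
    ])


def helix_handedness(trace: BackboneTrace | np.ndarray
                     ) -> tuple[str, float]:
    """Classify a C-alpha trace as a right- or left-handed helix.

    Returns (handedness, median virtual torsion in degrees); handedness is
    "right" for a median in [+30, +70], "left" for [-70, -30], else "none".
    Traces with non-physical consecutive spacing (outside 2.0-4.5 A) or
    all-degenerate torsions are "none".
    """
    coords = trace.coords if isinstance(trace, BackboneTrace) else np.asarray(trace)
    if len(coords) < 4:
        raise ValueError("at least 4 residues are required")
    gaps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    if ((gaps < MIN_CA_SPACING) | (gaps > MAX_CA_SPACING)).any():
        return "none", float("nan")
    torsions = virtual_torsions(coords)
    torsions = torsions[~np.isnan(torsions)]
    if len(torsions) == 0:
        return "none", float("nan")
    med = float(np.median(torsions))
    lo, hi = RIGHT_WINDOW
    if lo <= med <= hi:
        return "right", med
    if -hi <= med <= -lo:
        return "left", med
    return "none", med


def ideal_helix(n_residues: int, radius: float = 2.3, rise: float = 1.5,
                twist_deg: float = 100.0, handedness: str = "right"
                ) -> np.ndarray:
    """C-alpha coordinates of a parametric alpha-helix (Angstrom).

    Defaults match the ideal alpha-helix: 2.3 A radius, 1.5 A rise and 100
    degrees of twist per residue.  ``handedness='left'`` mirrors the turn
    direction.
    """
    sign = 1.0 if handedness == "right" else -1.0
    t = np.arange(n_residues) * np.radians(twist_deg) * sign
    return np.column_stack([
        radius * np.cos(t), radius * np.sin(t),
        np.arange(n_residues) * rise,
    ])


def write_ca_pdb(coords: np.ndarray, path: str | Path, chain: str = "A") -> None:
    """Write a C-alpha-only poly-alanine PDB for a coordinate trace."""
    st = gemmi.Structure()
    st.name = "trace"
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)
    for i, (x, y, z) in enumerate(np.asarray(coords, float), start=1):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = 1.0
        atom.b_iso = 20.0
        res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.write_pdb(str(path))
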