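"""L -> D peptide conversion for synthesis candidates.

A D-peptide binding an L-protein is, by symmetry, the mirror image of the
screened L-peptide binding the D-protein, so candidate generation is a pure
chirality inversion: same residue order (never retro-inverso), every residue
flipped L -> D.  Rendering follows the field's convention: upper-case for
L-residues, lower-case for D-residues, with norleucine written as the token
``[nle]`` (methionine's oxidation-resistant isostere, offered as an optional
substitution for synthesis).  Glycine is achiral but is rendered lower-case
inside a D-sequence for string consistency.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

NLE = "nle"
_TOKEN_RE = re.compile(r"\[([a-z]+)\]|([A-Za-z])")
_AA_UPPER = set("ACDEFGHIKLMNPQRSTVWY")


class ChiralityError(ValueError):
    pass


@dataclass(frozen=True)
class Residue:
    code: str          # one-letter upper-case code, or "nle"
    chirality: str     # "L", "D", or "achiral" (glycine)

    def __post_init__(self) -> None:
        if self.code != NLE and self.code not in _AA_UPPER:
            raise ChiralityError(f"unknown residue code {self.code!r}")
        if self.chirality not in ("L", "D", "achiral"):
            raise ChiralityError(f"bad chirality {self.chirality!r}")


@dataclass(frozen=True)
class ChiralPeptide:
    residues: tuple[Residue, ...]
    label: str = ""
    staple_positions: tuple[int, int] | None = None

    def render(self) -> str:
        """Lower-case for D, upper-case for L, ``[nle]`` for norleucine."""
        out = []
        for r in self.residues:
            if r.code == NLE:
                out.append(f"[{NLE}]")
            elif r.chirality == "L":
                out.append(r.code)
            else:  # D or achiral-in-D-context
                out.append(r.code.lower())
        return "".join(out)

    def __len__(self) -> int:
        return len(self.residues)


def parse(rendered: str, label: str = "",
          staple_positions: tuple[int, int] | None = None) -> ChiralPeptide:
    """Inverse of :meth:`ChiralPeptide.render`."""
    residues = []
    pos = 0
    for m in _TOKEN_RE.finditer(rendered):
        if m.start() != pos:
            raise ChiralityError(f"unparsable sequence at offset {pos}")
        pos = m.end()
        if m.group(1) is not None:
            if m.group(1) != NLE:
                raise ChiralityError(f"unknown token [{m.group(1)}]")
            residues.append(Residue(NLE, "D"))
        else:
            ch = m.group(2)
            if ch == "G" or ch == "g":
                residues.append(Residue("G", "achiral"))
            elif ch.isupper():
                residues.append(Residue(ch, "L"))
            else:
                residues.append(Residue(ch.upper(), "D"))
    if pos != len(rendered):
        raise ChiralityError(f"unparsable sequence at offset {pos}")
    return ChiralPeptide(tuple(residues), label, staple_positions)


def to_d(peptide: str, substitute_met_nle: bool = False, label: str = "",
         staple_positions: tuple[int, int] | None = None) -> ChiralPeptide:
    """Mirror an L-peptide into its D-enantiomer.

    Residue order is preserved; chirality flips per residue.  With
    ``substitute_met_nle`` every methionine becomes D-norleucine.
    """
    residues = []
    for aa in peptide:
        if aa not in _AA_UPPER:
            raise ChiralityError(f"unknown residue letter {aa!r}")
        if substitute_met_nle and aa == "M":
            residues.append(Residue(NLE, "D"))
        elif aa == "G":
            residues.append(Residue("G", "achiral"))
        else:
            residues.append(Residue(aa, "D"))
    return ChiralPeptide(tuple(residues), label, staple_positions)


def to_l(peptide: ChiralPeptide) -> str:
    """Recover the L-sequence from a D-peptide.

    Fails on substituted tokens: norleucine has no unique L-precursor once
    the methionine identity is lost.
    """
    out = []
    for i, r in enumerate(peptide.residues, start=1):
        if r.code == NLE:
            raise ChiralityError(
                f"residue {i} is {NLE}; the substitution is not invertible"
            )
        out.append(r.code)
    return "".join(out)


def synthesis_report(family_set, substitute_met_nle: bool = True,
                     include_top_member: bool = True,
                     staple_positions: tuple[int, int] | None = None
                     ) -> pd.DataFrame:
    """D-candidate table: per family, the consensus (and optionally the
    top-Hit-Strength member) rendered as D-peptides with substitution notes.

    ``staple_positions`` is the design's staple metadata, carried through
    verbatim for the synthesis chemist.
    """
    fams = family_set.proper_families or family_set.families
    if not fams:
        raise ValueError("no families to report")
    rows = []

    def add(fam, role: str, seq: str, hs: float | None) -> None:
        cand = to_d(seq, substitute_met_nle, label=f"{fam.family_id}.{role}",
                    staple_positions=staple_positions)
        notes = []
        if substitute_met_nle and "M" in seq:
            sub_pos = [str(i) for i, aa in enumerate(seq, start=1) if aa == "M"]
            notes.append(f"Met->Nle at position(s) {','.join(sub_pos)}")
        if cand.staple_positions:
            notes.append(f"staple at {cand.staple_positions}")
        rows.append({
            "family_id": fam.family_id,
            "role": role,
            "l_sequence": seq,
            "d_candidate": cand.render(),
            "hit_strength": hs,
            "notes": "; ".join(notes),
        })

    for fam in fams:
        add(fam, "consensus", fam.consensus, None)
        if include_top_member and fam.members:
            best = max(
                range(len(fam.members)),
                key=lambda i: (fam.member_hs[i]
                               if fam.member_hs[i] == fam.member_hs[i] else -1),
            )
            if fam.members[best] != fam.consensus:
                add(fam, "top_member", fam.members[best], fam.member_hs[best])
    return pd.DataFrame(
        rows, columns=["family_id", "role", "l_sequence", "d_candidate",
                       "hit_strength", "notes"]
    )


def write_candidates(report: pd.DataFrame, outdir: str | Path) -> None:
    """Candidates TSV plus a FASTA-like file with a chirality tag line."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_csv(outdir / "d_candidates.tsv", sep="\t", index=False,
                  float_format="%.6g")
    with open(outdir / "d_candidates.txt", "w") as fh:
        for _, row in report.iterrows():
            fh.write(f">{row['family_id']}.{row['role']} chirality=D\n")
            fh.write(f"{row['d_candidate']}\n")
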