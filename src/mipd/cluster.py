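"""Binder-family clustering, consensus calling, and logo matrices.

Hits share a common length by design, so peptides are compared
position-by-position over the variable positions only.  The default
dissimilarity rescales BLOSUM62 log-odds similarities into [0, 1] per
residue pair: sim(x, y) = (S(x,y) - Smin) / (min(S(x,x), S(y,y)) - Smin),
clipped to [0, 1], so identical residues always score 1 (d(a, a) = 0) and
the least-similar residue pair in the matrix scores 0.  This dissimilarity
satisfies identity, symmetry and boundedness but is not guaranteed to obey
the triangle inequality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .library_design import LibraryDesign


@dataclass(frozen=True)
class ClusterParams:
    metric: str = "blosum62"      # or "hamming"
    linkage_method: str = "average"
    cut_height: float = 0.5
    min_family_size: int = 3


@lru_cache(maxsize=1)
def _blosum62_pair_distance() -> dict[tuple[str, str], float]:
    """Per-residue-pair dissimilarity in [0, 1] from BLOSUM62."""
    mat = substitution_matrices.load("BLOSUM62")
    letters = [a for a in mat.alphabet if a in set("ACDEFGHIKLMNPQRSTVWY")]
    smin = min(mat[a, b] for a in letters for b in letters)
    table: dict[tuple[str, str], float] = {}
    for a in letters:
        for b in letters:
            top = min(mat[a, a], mat[b, b])
            sim = (mat[a, b] - smin) / (top - smin)
            table[(a, b)] = 1.0 - min(1.0, max(0.0, sim))
    return table


def pair_distance(a: str, b: str) -> float:
    """Rescaled BLOSUM62 dissimilarity between two residues."""
    return _blosum62_pair_distance()[(a, b)]


def distance_matrix(peptides: list[str], design: LibraryDesign,
                    metric: str = "blosum62") -> np.ndarray:
    """Pairwise peptide dissimilarities in [0, 1], square symmetric.

    d(a, b) averages the per-position residue dissimilarity over the
    design's variable positions; fixed positions are identical by
    construction and carry no signal.
    """
    lengths = {len(p) for p in peptides}
    if len(lengths) > 1:
        raise ValueError(f"peptides have mixed lengths: {sorted(lengths)}")
    var_idx = design.variable_indices
    if not var_idx:
        return np.zeros((len(peptides), len(peptides)))
    if metric == "hamming":
        def pos_d(x: str, y: str) -> float:
            return 0.0 if x == y else 1.0
    elif metric == "blosum62":
        table = _blosum62_pair_distance()

        def pos_d(x: str, y: str) -> float:
            return table[(x, y)]
    else:
        raise ValueError(f"unknown metric {metric!r}")

    n = len(peptides)
    d = np.zeros((n, n))
    cols = [[p[i] for p in peptides] for i in var_idx]
    inv_l = 1.0 / len(var_idx)
    for i in range(n):
        for j in range(i + 1, n):
            acc = 0.0
            for col in cols:
                acc += pos_d(col[i], col[j])
            d[i, j] = d[j, i] = acc * inv_l
    return d


@dataclass
class Family:
    family_id: str
    members: list[str]
    member_hs: list[float]
    consensus: str
    logo: pd.DataFrame            # rows: alphabet letters, cols: 1-based positions
    fixed_mask: list[bool]
    information_content: list[float]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class FamilySet:
    families: list[Family]
    params: ClusterParams

    def __len__(self) -> int:
        return len(self.families)

    @property
    def proper_families(self) -> list[Family]:
        """Families that met the minimum size (excludes singleton fallout)."""
        return [f for f in self.families if not f.family_id.startswith("S")]

    def assignments(self) -> pd.Series:
        rows = {}
        for fam in self.families:
            for pep in fam.members:
                rows[pep] = fam.family_id
        return pd.Series(rows, name="family_id").sort_index()


def consensus_and_logo(members: list[str], design: LibraryDesign,
                       weights: list[float] | None = None
                       ) -> tuple[str, pd.DataFrame, list[float]]:
    """Per-position residue frequencies, modal consensus, and information
    content.

    Ties in the modal residue break by design-alphabet order.  Information
    content at position j is log2 |alphabet_j| + sum_r p_jr log2 p_jr with
    0 log 0 = 0, where alphabet_j is that position's allowed set (a fixed
    position has |alphabet_j| = 1, hence IC 0).
    """
    if not members:
        raise ValueError("empty family")
    letters = list(design.alphabet.letters)
    L = design.length
    w = np.ones(len(members)) if weights is None else np.asarray(weights, float)
    if w.sum() <= 0:
        w = np.ones(len(members))
    freq = np.zeros((len(letters), L))
    lut = {a: i for i, a in enumerate(letters)}
    for pep, wt in zip(members, w):
        for j, aa in enumerate(pep):
            freq[lut[aa], j] += wt
    freq /= freq.sum(axis=0, keepdims=True)
    logo = pd.DataFrame(freq, index=letters, columns=range(1, L + 1))

    consensus = "".join(
        letters[int(np.argmax(freq[:, j]))] for j in range(L)
    )
    ic = []
    for j in range(L):
        k = len(design.allowed_at(j))
        p = freq[:, j]
        p = p[p > 0]
        ic.append(float(math.log2(k) + (p * np.log2(p)).sum()) if k > 1 else 0.0)
    return consensus, logo, ic


def hierarchical_cluster(peptides: list[str], design: LibraryDesign,
                         hs: dict[str, float] | pd.Series | None = None,
                         params: ClusterParams | None = None,
                         logo_weights: dict[str, float] | None = None
                         ) -> FamilySet:
    """Group hit peptides into binder families by agglomerative clustering.

    The tree is cut at ``cut_height``; flat clusters smaller than
    ``min_family_size`` are demoted to singletons.  Peptides are sorted
    before clustering so the partition is invariant to input order.  Family
    ids are F1, F2, ... by decreasing size (ties by consensus), singletons
    S1, S2, ... by peptide order.
    """
    params = params or ClusterParams()
    if not peptides:
        raise ValueError("empty hit set")
    peptides = sorted(set(peptides))
    hs = dict(hs) if hs is not None else {}

    if len(peptides) == 1:
        labels = np.array([1])
    else:
        d = distance_matrix(peptides, design, params.metric)
        z = linkage(squareform(d, checks=False), method=params.linkage_method)
        labels = fcluster(z, t=params.cut_height, criterion="distance")

    groups: dict[int, list[str]] = {}
    for pep, lab in zip(peptides, labels):
        groups.setdefault(int(lab), []).append(pep)

    proper = [m for m in groups.values() if len(m) >= params.min_family_size]
    single = sorted(
        pep for m in groups.values() if len(m) < params.min_family_size
        for pep in m
    )

    def build(fid: str, members: list[str]) -> Family:
        members = sorted(members)
        wts = ([logo_weights.get(p, 0.0) for p in members]
               if logo_weights else None)
        consensus, logo, ic = consensus_and_logo(members, design, wts)
        return Family(
            family_id=fid,
            members=members,
            member_hs=[float(hs.get(p, float("nan"))) for p in members],
            consensus=consensus,
            logo=logo,
            fixed_mask=list(design.fixed_mask),
            information_content=ic,
        )

    drafts = [build("tmp", m) for m in proper]
    drafts.sort(key=lambda f: (-f.size, f.consensus))
    families = []
    for i, fam in enumerate(drafts, start=1):
        fam.family_id = f"F{i}"
        families.append(fam)
    for i, pep in enumerate(single, start=1):
        families.append(build(f"S{i}", [pep]))
    return FamilySet(families, params)


def write_families(fams: FamilySet, outdir: str | Path) -> None:
    """Families TSV, consensus FASTA, and one logo-matrix TSV per family."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for fam in fams.families:
        for pep, h in zip(fam.members, fam.member_hs):
            rows.append({"peptide": pep, "family_id": fam.family_id,
                         "hit_strength": h})
    pd.DataFrame(rows, columns=["peptide", "family_id", "hit_strength"]).to_csv(
        outdir / "families.tsv", sep="\t", index=False, float_format="%.6g"
    )
    with open(outdir / "consensus.fasta", "w") as fh:
        for fam in fams.families:
            fh.write(f">{fam.family_id} n={fam.size}\n{fam.consensus}\n")
    for fam in fams.families:
        logo = fam.logo.copy()
        logo.loc["fixed_position"] = [int(m) for m in fam.fixed_mask]
        logo.to_csv(outdir / f"logo_{fam.family_id}.tsv", sep="\t",
                    index_label="residue", float_format="%.6g")
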