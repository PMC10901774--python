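"""Stapled-peptide library design: alphabet, codon encoding, membership rules.

A trimer-phosphoramidite library assigns exactly one DNA codon to each
allowed residue, so membership in the library ("matched the design") is a
purely positional test: correct length, fixed positions exact, variable
positions drawn from their allowed subsets.  The spike-in reference used for
cross-well normalization is deliberately *not* a design member.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import yaml
from Bio.Seq import Seq

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
_DNA = set("ACGT")


class DesignError(ValueError):
    """Raised when a library design violates its invariants."""


@dataclass(frozen=True)
class AminoAlphabet:
    """Ordered residue alphabet with its one-codon-per-residue trimer map."""

    letters: str
    codon_map: dict[str, str]

    def __post_init__(self) -> None:
        letters = list(self.letters)
        if len(set(letters)) != len(letters):
            raise DesignError("alphabet letters must be unique")
        bad = set(letters) - CANONICAL_AA
        if bad:
            raise DesignError(f"non-canonical residue letters: {sorted(bad)}")
        if set(self.codon_map) != set(letters):
            raise DesignError("codon_map keys must equal the alphabet letters")
        for aa, codon in self.codon_map.items():
            if len(codon) != 3 or set(codon) - _DNA:
                raise DesignError(f"codon for {aa} is not a DNA trimer: {codon!r}")
            translated = str(Seq(codon).translate())
            if translated != aa:
                raise DesignError(
                    f"codon {codon} translates to {translated!r}, not {aa!r}"
                )
        codons = list(self.codon_map.values())
        if len(set(codons)) != len(codons):
            raise DesignError("codons must be pairwise distinct")

    def __contains__(self, letter: str) -> bool:
        return letter in self.codon_map

    def __len__(self) -> int:
        return len(self.letters)


@dataclass(frozen=True)
class Fixed:
    residue: str


@dataclass(frozen=True)
class Variable:
    allowed: str  # subset of the design alphabet, in alphabet order


Position = Union[Fixed, Variable]


@dataclass(frozen=True)
class LibraryDesign:
    """Positional scaffold plus flanking DNA and the spike-in reference.

    Peptide positions are 1-based in reports; staple positions are inert
    metadata (no chemistry is modeled).
    """

    name: str
    alphabet: AminoAlphabet
    positions: tuple[Position, ...]
    flank5: str
    flank3: str
    spike_in_dna: str
    spike_in_label: str = "SPIKE"
    staple_positions: tuple[int, int] | None = None
    _allowed_sets: tuple[frozenset[str], ...] = field(
        init=False, repr=False, compare=False, default=()
    )

    def __post_init__(self) -> None:
        if not self.positions:
            raise DesignError("design must have at least one position")
        for i, pos in enumerate(self.positions, start=1):
            if isinstance(pos, Fixed):
                if pos.residue not in self.alphabet:
                    raise DesignError(
                        f"fixed residue {pos.residue!r} at position {i} "
                        "is outside the design alphabet"
                    )
            elif isinstance(pos, Variable):
                if not pos.allowed:
                    raise DesignError(f"variable position {i} has an empty allowed set")
                bad = set(pos.allowed) - set(self.alphabet.letters)
                if bad:
                    raise DesignError(
                        f"variable position {i} allows residues outside "
                        f"the alphabet: {sorted(bad)}"
                    )
            else:  # pragma: no cover - type guard
                raise DesignError(f"position {i} is neither Fixed nor Variable")
        for flank, label in ((self.flank5, "flank5"), (self.flank3, "flank3")):
            if not flank or set(flank) - _DNA:
                raise DesignError(f"{label} must be a non-empty DNA string")
        if self.flank5 in self.flank3 or self.flank3 in self.flank5:
            raise DesignError("flank5 and flank3 must not contain each other")
        object.__setattr__(
            self,
            "_allowed_sets",
            tuple(
                frozenset(p.residue) if isinstance(p, Fixed) else frozenset(p.allowed)
                for p in self.positions
            ),
        )
        if set(self.spike_in_dna) - _DNA:
            raise DesignError("spike_in_dna must be a DNA string")
        if len(self.spike_in_dna) == self.insert_length:
            spike_pep = str(Seq(self.spike_in_dna).translate())
            if "*" not in spike_pep and matches_design(spike_pep, self):
                raise DesignError(
                    "spike-in insert translates to a design member; the "
                    "spike-in must not be a library member"
                )
        if self.staple_positions is not None:
            a, b = self.staple_positions
            if not (1 <= a <= len(self.positions) and 1 <= b <= len(self.positions)):
                raise DesignError("staple positions out of range")

    @property
    def length(self) -> int:
        """Number of peptide positions."""
        return len(self.positions)

    @property
    def insert_length(self) -> int:
        """DNA insert length: three bases per peptide position."""
        return 3 * len(self.positions)

    @property
    def variable_indices(self) -> tuple[int, ...]:
        """0-based indices of variable positions."""
        return tuple(
            i for i, p in enumerate(self.positions) if isinstance(p, Variable)
        )

    @property
    def fixed_mask(self) -> tuple[bool, ...]:
        """Per-position flag, True where the residue is fixed."""
        return tuple(isinstance(p, Fixed) for p in self.positions)

    def allowed_at(self, index: int) -> frozenset[str]:
        """Allowed residues at a 0-based position."""
        return self._allowed_sets[index]


def load_design(source: str | Path | dict) -> LibraryDesign:
    """Load and validate a library design from a YAML document or path.

    The document supplies ``name``, ``alphabet``, ``codon_map``, ``positions``
    (list of ``{fixed: X}`` or ``{variable: [..] | "all"}``), ``flank5``,
    ``flank3``, optional ``staple_positions``, ``spike_in_dna`` and
    ``spike_in_label``.
    """
    if isinstance(source, dict):
        doc = source
    else:
        text = Path(source).read_text()
        doc = yaml.safe_load(text)
    required = {"name", "alphabet", "codon_map", "positions", "flank5", "flank3",
                "spike_in_dna"}
    missing = required - set(doc)
    if missing:
        raise DesignError(f"design config missing fields: {sorted(missing)}")

    alphabet = AminoAlphabet(
        letters=str(doc["alphabet"]),
        codon_map={str(k): str(v).upper() for k, v in doc["codon_map"].items()},
    )
    positions: list[Position] = []
    for i, entry in enumerate(doc["positions"], start=1):
        if not isinstance(entry, dict) or len(entry) != 1:
            raise DesignError(f"position {i}: expected one of 'fixed'/'variable'")
        (kind, value), = entry.items()
        if kind == "fixed":
            positions.append(Fixed(str(value)))
        elif kind == "variable":
            if value == "all":
                positions.append(Variable(alphabet.letters))
            else:
                allowed = "".join(
                    a for a in alphabet.letters if a in set(map(str, value))
                )
                positions.append(Variable(allowed))
        else:
            raise DesignError(f"position {i}: unknown kind {kind!r}")

    staple = doc.get("staple_positions")
    return LibraryDesign(
        name=str(doc["name"]),
        alphabet=alphabet,
        positions=tuple(positions),
        flank5=str(doc["flank5"]).upper(),
        flank3=str(doc["flank3"]).upper(),
        spike_in_dna=str(doc["spike_in_dna"]).upper(),
        spike_in_label=str(doc.get("spike_in_label", "SPIKE")),
        staple_positions=tuple(staple) if staple else None,
    )


def default_design() -> LibraryDesign:
    """The package's default 12-position stapled-helix fixture design."""
    with resources.files("mipd.data").joinpath("default_design.yaml").open() as fh:
        return load_design(yaml.safe_load(fh))


def theoretical_diversity(design: LibraryDesign) -> int:
    """Design-space size: product of allowed-set sizes over variable positions."""
    n = 1
    for pos in design.positions:
        if isinstance(pos, Variable):
            n *= len(pos.allowed)
    return n


def matches_design(peptide: str, design: LibraryDesign) -> bool:
    """True iff ``peptide`` is a member of the library design.

    Never raises: wrong length, a wrong fixed residue, or a residue outside a
    variable position's allowed set all return False.
    """
    if len(peptide) != design.length:
        return False
    return all(
        aa in allowed for aa, allowed in zip(peptide, design._allowed_sets)
    )


def encode_peptide(peptide: str, design: LibraryDesign) -> str:
    """DNA insert encoding a design member via the trimer codon map."""
    if not matches_design(peptide, design):
        raise DesignError(f"peptide {peptide!r} does not match the design")
    return "".join(design.alphabet.codon_map[aa] for aa in peptide)


def iter_members(design: LibraryDesign) -> Iterator[str]:
    """Enumerate all design members in alphabet order (small designs only)."""
    pools: list[Sequence[str]] = [
        pos.residue if isinstance(pos, Fixed) else pos.allowed
        for pos in design.positions
    ]
    for combo in itertools.product(*pools):
        yield "".join(combo)


def members_to_fasta(peptides: Iterable[str], path: str | Path) -> None:
    """Write design members as a peptide FASTA."""
    with open(path, "w") as fh:
        for i, pep in enumerate(peptides, start=1):
            fh.write(f">member_{i}\n{pep}\n")


def members_to_dna_fasta(
    peptides: Iterable[str], design: LibraryDesign, path: str | Path
) -> None:
    """Write design members as DNA inserts with flanks, FASTA format."""
    with open(path, "w") as fh:
        for i, pep in enumerate(peptides, start=1):
            dna = design.flank5 + encode_peptide(pep, design) + design.flank3
            fh.write(f">member_{i} {pep}\n{dna}\n")
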