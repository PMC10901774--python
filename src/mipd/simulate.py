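"""Seeded synthetic phage-display screens.

Emulates the statistical structure the downstream analysis assumes: a
log-normal background of library members, planted binder families whose
enrichment follows single-site Langmuir occupancy theta = C/(C+Kd), a
spike-in reference at a known expected read fraction, and per-well FASTQ
output with optional sequencing noise.  Selection is a single round (the
screen format reads out bead-bound phage directly), so a binder's expected
weight in a well at bait concentration C is a_s * (1 + beta * theta).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .library_design import (
    LibraryDesign,
    Variable,
    encode_peptide,
    matches_design,
    theoretical_diversity,
)

_RC = str.maketrans("ACGT", "TGCA")
Q37 = "F"  # phred 37 in Sanger encoding
Q2 = "#"


@dataclass(frozen=True)
class BinderFamily:
    """A planted binder family: consensus, affinity, and diversification."""

    family_id: str
    consensus: str
    kd_nM: float
    n_members: int = 20
    substitution_rate: float = 0.1
    abundance_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kd_nM <= 0:
            raise ValueError("kd_nM must be positive")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")


@dataclass(frozen=True)
class Well:
    sample_id: str
    role: str  # "blank" or "bait"
    concentration_nM: float
    replicate: int
    reads: int


@dataclass(frozen=True)
class ScreenLayout:
    wells: tuple[Well, ...]
    spike_in_fraction: float = 0.05

    def __post_init__(self) -> None:
        roles = {w.role for w in self.wells}
        if not roles <= {"blank", "bait"}:
            raise ValueError(f"unknown well roles: {roles - {'blank', 'bait'}}")
        if not any(w.role == "blank" for w in self.wells):
            raise ValueError("layout needs at least one blank well")
        if not 0 < self.spike_in_fraction < 0.5:
            raise ValueError("spike_in_fraction must be in (0, 0.5)")
        for w in self.wells:
            if w.role == "blank" and w.concentration_nM != 0:
                raise ValueError("blank wells must have zero concentration")
            if w.role == "bait" and w.concentration_nM <= 0:
                raise ValueError("bait wells must have positive concentration")

    @property
    def highest_concentration_nM(self) -> float:
        return max((w.concentration_nM for w in self.wells if w.role == "bait"),
                   default=0.0)

    @property
    def concentration_levels(self) -> tuple[float, ...]:
        """Distinct concentrations, blank (0) included, ascending."""
        return tuple(sorted({w.concentration_nM for w in self.wells}))


@dataclass(frozen=True)
class EnrichmentModel:
    """Capture gain and sequencing-noise knobs for the simulator."""

    beta: float = 50.0
    epsilon: float = 0.0
    rc_fraction: float = 0.0
    low_quality_tail_fraction: float = 0.0
    low_quality_tail_length: int = 8

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0 <= self.epsilon < 0.25:
            raise ValueError("epsilon must be in [0, 0.25)")


def occupancy(concentration_nM: float, kd_nM: float) -> float:
    """Single-site equilibrium occupancy C / (C + Kd)."""
    if concentration_nM <= 0:
        return 0.0
    return concentration_nM / (concentration_nM + kd_nM)


def default_layout(
    reads_per_well: int = 20_000,
    concentrations_nM: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0),
    n_replicates: int = 2,
    n_blanks: int = 2,
    spike_in_fraction: float = 0.05,
) -> ScreenLayout:
    """Blank wells plus a concentration series with replicates."""
    wells = [
        Well(f"blank_r{r}", "blank", 0.0, r, reads_per_well)
        for r in range(1, n_blanks + 1)
    ]
    for c in concentrations_nM:
        for r in range(1, n_replicates + 1):
            wells.append(Well(f"c{c:g}nM_r{r}", "bait", c, r, reads_per_well))
    return ScreenLayout(tuple(wells), spike_in_fraction)


def mdm2_like_families() -> tuple[BinderFamily, ...]:
    """Three planted families with N-terminal tryptophan anchors.

    Consensus sequences carry the anchor tryptophan (position 2 in C1,
    position 1 in C2/C3) and are mutually well separated under the default
    clustering distance, so planted families are resolvable by construction.
    Dissociation constants span the default concentration series.
    """
    return (
        BinderFamily("MDM2.C1", "HWFSDWDVDRSL", kd_nM=5.0),
        BinderFamily("MDM2.C2", "WNNSFDWSTQSN", kd_nM=50.0),
        BinderFamily("MDM2.C3", "WVESQFRLLISQ", kd_nM=500.0),
    )


def chip_like_families() -> tuple[BinderFamily, ...]:
    """Three planted families with terminal carboxylate residues.

    Consensus sequences carry the terminal aspartate/glutamate anchors
    (D1 in C1, D1/E2 in C2, D12 in C3) and are mutually well separated
    under the default clustering distance.
    """
    return (
        BinderFamily("CHIP.C1", "DLYSINDLDDST", kd_nM=5.0),
        BinderFamily("CHIP.C2", "DEASAWYEWVSY", kd_nM=50.0),
        BinderFamily("CHIP.C3", "LTDSAADWIISD", kd_nM=500.0),
    )


def _random_member(design: LibraryDesign, rng: np.random.Generator) -> str:
    out = []
    for pos in design.positions:
        if isinstance(pos, Variable):
            out.append(pos.allowed[rng.integers(len(pos.allowed))])
        else:
            out.append(pos.residue)
    return "".join(out)


def sample_background(
    design: LibraryDesign,
    n_sequences: int,
    lognormal_mu: float = 0.0,
    lognormal_sigma: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> dict[str, float]:
    """Draw distinct design members with log-normal relative abundances.

    Abundances are normalized to sum to 1.  ``sigma=0`` degenerates to a
    uniform population.
    """
    rng = np.random.default_rng(rng)
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if n_sequences > theoretical_diversity(design):
        raise ValueError("n_sequences exceeds the design's theoretical diversity")
    members: set[str] = set()
    while len(members) < n_sequences:
        members.add(_random_member(design, rng))
    ordered = sorted(members)
    weights = np.exp(rng.normal(lognormal_mu, lognormal_sigma, size=n_sequences))
    weights /= weights.sum()
    return dict(zip(ordered, weights))


def _mutate(
    consensus: str,
    design: LibraryDesign,
    rate: float,
    rng: np.random.Generator,
) -> str:
    """Substitute variable positions of a consensus at the given rate."""
    out = list(consensus)
    for i in design.variable_indices:
        if rate > 0 and rng.random() < rate:
            allowed = design.positions[i].allowed
            alternatives = [a for a in allowed if a != consensus[i]]
            if alternatives:
                out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def plant_families(
    population: dict[str, float],
    families: tuple[BinderFamily, ...] | list[BinderFamily],
    design: LibraryDesign,
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Add binder-family members to a background population.

    Each family contributes ``n_members`` sequences derived from its consensus
    by substituting variable positions at ``substitution_rate`` (fixed
    positions are never touched, so members remain design members).  A planted
    member's pre-normalization abundance is ``abundance_scale`` times the mean
    background abundance; duplicate draws accumulate.  Returns the
    renormalized population and a truth table (peptide, family_id, kd_nM).
    """
    rng = np.random.default_rng(rng)
    for fam in families:
        if not matches_design(fam.consensus, design):
            raise ValueError(
                f"family {fam.family_id} consensus {fam.consensus!r} "
                "does not match the design"
            )
    mean_bg = float(np.mean(list(population.values())))
    pop = dict(population)
    truth_rows: list[dict] = []
    assigned: dict[str, str] = {}
    for fam in families:
        for _ in range(fam.n_members):
            member = _mutate(fam.consensus, design, fam.substitution_rate, rng)
            pop[member] = pop.get(member, 0.0) + fam.abundance_scale * mean_bg
            if member not in assigned:
                assigned[member] = fam.family_id
                truth_rows.append(
                    {"peptide": member, "family_id": fam.family_id,
                     "kd_nM": fam.kd_nM}
                )
    total = sum(pop.values())
    pop = {p: a / total for p, a in sorted(pop.items())}
    truth = pd.DataFrame(truth_rows, columns=["peptide", "family_id", "kd_nM"])
    truth = truth.sort_values("peptide").reset_index(drop=True)
    return pop, truth


def _apply_errors(read: str, epsilon: float, rng: np.random.Generator) -> str:
    if epsilon <= 0:
        return read
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < epsilon
    if not hit.any():
        return read
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    idx = np.where(hit)[0]
    for i in idx:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


@dataclass
class SimulatedScreen:
    """Paths and ground truth for one simulated screen."""

    outdir: Path
    sample_sheet: Path
    truth_table: Path
    manifest: Path
    fastq_paths: dict[str, Path]
    drawn_counts: pd.DataFrame  # peptide x sample, the exact multinomial draws
    drawn_spike: pd.Series


def simulate_screen(
    population: dict[str, float],
    truth: pd.DataFrame,
    layout: ScreenLayout,
    model: EnrichmentModel,
    design: LibraryDesign,
    outdir: str | Path,
    seed: int | np.random.Generator,
    gzip_fastq: bool = False,
) -> SimulatedScreen:
    """Draw per-well reads and write FASTQ, sample sheet, truth, manifest.

    Reads in a well are one multinomial draw over background members
    (weight a_s), planted binders (weight a_s * (1 + beta * theta)), and the
    spike-in, whose weight is set so its expected read fraction equals the
    layout's ``spike_in_fraction``.  Each read is flank5 + insert + flank3
    with substitution errors at rate epsilon and constant Q37 qualities.
    Fixed seed implies byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if any(w.reads <= 0 for w in layout.wells):
        raise ValueError("every well must request at least one read")

    peptides = sorted(population)
    abund = np.array([population[p] for p in peptides])
    kd = np.full(len(peptides), np.nan)
    if len(truth):
        kd_map = dict(zip(truth["peptide"], truth["kd_nM"]))
        for i, p in enumerate(peptides):
            if p in kd_map:
                kd[i] = kd_map[p]
    planted = ~np.isnan(kd)

    inserts = {p: encode_peptide(p, design) for p in peptides}
    f = layout.spike_in_fraction
    q_good = Q37
    counts = pd.DataFrame(
        0, index=peptides, columns=[w.sample_id for w in layout.wells], dtype=int
    )
    spike_counts = pd.Series(0, index=counts.columns, dtype=int)
    fastq_paths: dict[str, Path] = {}
    sheet_rows = []

    for well in layout.wells:
        w = abund.copy()
        if model.beta > 0 and planted.any() and well.concentration_nM > 0:
            theta = well.concentration_nM / (well.concentration_nM + kd[planted])
            w[planted] = w[planted] * (1.0 + model.beta * theta)
        spike_w = f / (1.0 - f) * w.sum()
        probs = np.concatenate([w, [spike_w]])
        probs /= probs.sum()
        draw = rng.multinomial(well.reads, probs)
        counts[well.sample_id] = draw[:-1]
        spike_counts[well.sample_id] = draw[-1]

        records: list[tuple[str, str]] = []
        for p, c in zip(peptides, draw[:-1]):
            if c:
                dna = design.flank5 + inserts[p] + design.flank3
                records.extend((p, dna) for _ in range(c))
        spike_dna = design.flank5 + design.spike_in_dna + design.flank3
        records.extend(("spike", spike_dna) for _ in range(draw[-1]))
        order = rng.permutation(len(records))

        suffix = ".fastq.gz" if gzip_fastq else ".fastq"
        path = outdir / f"{well.sample_id}{suffix}"
        opener = gzip.open if gzip_fastq else open
        with opener(path, "wt") as fh:
            for n, ridx in enumerate(order):
                _, dna = records[ridx]
                read = _apply_errors(dna, model.epsilon, rng)
                qual = q_good * len(read)
                if (model.rc_fraction > 0
                        and rng.random() < model.rc_fraction):
                    read = read.translate(_RC)[::-1]
                if (model.low_quality_tail_fraction > 0
                        and rng.random() < model.low_quality_tail_fraction):
                    tail = "".join(
                        "ACGT"[rng.integers(4)]
                        for _ in range(model.low_quality_tail_length)
                    )
                    read += tail
                    qual += Q2 * model.low_quality_tail_length
                fh.write(f"@{well.sample_id}:{n}\n{read}\n+\n{qual}\n")
        fastq_paths[well.sample_id] = path
        sheet_rows.append(
            {"sample_id": well.sample_id, "role": well.role,
             "concentration_nM": well.concentration_nM,
             "replicate": well.replicate, "fastq": path.name}
        )

    sheet = outdir / "samples.csv"
    pd.DataFrame(sheet_rows).to_csv(sheet, index=False)

    truth_path = outdir / "truth.tsv"
    truth_out = truth.copy()
    if len(truth_out) == 0:
        truth_out = pd.DataFrame(columns=["peptide", "family_id", "kd_nM"])
    truth_out["is_spike"] = 0
    spike_row = pd.DataFrame(
        [{"peptide": design.spike_in_label, "family_id": "", "kd_nM": "",
          "is_spike": 1}]
    )
    pd.concat([truth_out, spike_row], ignore_index=True).to_csv(
        truth_path, sep="\t", index=False
    )

    manifest_path = outdir / "manifest.json"
    manifest = {
        "design": design.name,
        "seed": int(seed) if isinstance(seed, (int, np.integer)) else None,
        "model": asdict(model),
        "layout": {
            "spike_in_fraction": layout.spike_in_fraction,
            "wells": [asdict(w) for w in layout.wells],
        },
        "n_population": len(peptides),
        "n_planted": int(planted.sum()),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return SimulatedScreen(
        outdir=outdir,
        sample_sheet=sheet,
        truth_table=truth_path,
        manifest=manifest_path,
        fastq_paths=fastq_paths,
        drawn_counts=counts,
        drawn_spike=spike_counts,
    )
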