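"""Read decoding: quality trim, flank location, translation, design gate.

Every read ends up in exactly one bucket — a design-member peptide count,
the spike-in count, or a rejection reason — so per sample
``assigned + spike + rejected == total`` always holds.  Rejections are data,
never exceptions.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library_design import LibraryDesign, matches_design

REJECT_REASONS = (
    "low_quality",
    "flank_not_found",
    "length_mismatch",
    "stop_codon",
    "not_in_design",
)

_RC = str.maketrans("ACGTN", "TGCAN")


@dataclass
class DecodeParams:
    q_threshold: int = 20
    max_flank_mismatches: int = 1
    quality_offset: int = 33


@dataclass
class CountMatrix:
    """Peptide x sample raw counts with spike-in counts and a rejection ledger."""

    counts: pd.DataFrame        # rows: peptides (lexicographic), cols: samples
    spike_counts: pd.Series     # per sample
    rejected: pd.DataFrame      # rows: REJECT_REASONS, cols: samples
    total_reads: pd.Series      # per sample
    spike_in_label: str = "SPIKE"

    def conservation_ok(self) -> bool:
        """assigned + spike + rejected == total, per sample."""
        lhs = self.counts.sum(axis=0) + self.spike_counts + self.rejected.sum(axis=0)
        return bool((lhs == self.total_reads).all())

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, counts_path: str | Path, rejected_path: str | Path | None = None
               ) -> None:
        out = self.counts.copy()
        out.loc[self.spike_in_label] = self.spike_counts
        out.to_csv(counts_path, sep="\t", index_label="peptide")
        if rejected_path is not None:
            ledger = self.rejected.copy()
            ledger.loc["total_reads"] = self.total_reads
            ledger.to_csv(rejected_path, sep="\t", index_label="reason")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, spike_in_label: str = "SPIKE",
                 rejected_path: str | Path | None = None) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col="peptide")
        if spike_in_label not in df.index:
            raise ValueError(f"counts file has no spike-in row {spike_in_label!r}")
        spike = df.loc[spike_in_label].astype(int)
        counts = df.drop(index=spike_in_label).astype(int)
        counts = counts.sort_index()
        if rejected_path is not None:
            ledger = pd.read_csv(rejected_path, sep="\t", index_col="reason")
            total = ledger.loc["total_reads"].astype(int)
            rejected = ledger.drop(index="total_reads").astype(int)
        else:
            rejected = pd.DataFrame(0, index=list(REJECT_REASONS),
                                    columns=counts.columns)
            total = counts.sum(axis=0) + spike
        return cls(counts, spike, rejected, total, spike_in_label)


def trim_read(seq: str, qual: str, q_threshold: int, min_length: int,
              quality_offset: int = 33) -> tuple[str, str] | None:
    """Trim 3' bases whose quality is below threshold; None if too short."""
    cut = len(seq)
    floor = chr(q_threshold + quality_offset)
    while cut > 0 and qual[cut - 1] < floor:
        cut -= 1
    if cut < min_length:
        return None
    return seq[:cut], qual[:cut]


def find_approx(haystack: str, needle: str, max_mismatches: int,
                start: int = 0) -> int:
    """Leftmost occurrence of needle with <= max_mismatches substitutions."""
    exact = haystack.find(needle, start)
    if exact != -1 or max_mismatches == 0:
        return exact
    n = len(needle)
    for i in range(start, len(haystack) - n + 1):
        mm = 0
        window = haystack[i:i + n]
        for a, b in zip(window, needle):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            return i
    return -1


def _extract_oriented(seq: str, design: LibraryDesign, max_mm: int
                      ) -> tuple[str | None, str | None]:
    i = find_approx(seq, design.flank5, max_mm)
    if i == -1:
        return None, "flank_not_found"
    insert_start = i + len(design.flank5)
    j = find_approx(seq, design.flank3, max_mm, start=insert_start)
    if j == -1:
        return None, "flank_not_found"
    insert = seq[insert_start:j]
    if len(insert) != design.insert_length:
        return None, "length_mismatch"
    return insert, None


def extract_insert(seq: str, design: LibraryDesign, max_flank_mismatches: int = 1
                   ) -> tuple[str | None, str | None]:
    """Locate both flanks (forward, then reverse complement) and cut the insert.

    Returns (insert, None) on success or (None, reason).  When both
    orientations would match, the forward hit wins.
    """
    insert, reason = _extract_oriented(seq, design, max_flank_mismatches)
    if insert is not None:
        return insert, None
    rc = seq.translate(_RC)[::-1]
    insert_rc, reason_rc = _extract_oriented(rc, design, max_flank_mismatches)
    if insert_rc is not None:
        return insert_rc, None
    # report the more informative of the two failure reasons
    if "length_mismatch" in (reason, reason_rc):
        return None, "length_mismatch"
    return None, "flank_not_found"


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def classify_insert(insert: str, design: LibraryDesign
                    ) -> tuple[str, str | None]:
    """Classify a DNA insert as ('spike', None), ('peptide', pep) or
    ('reject', reason).

    The spike-in is recognized at the DNA level (exact, then <=1 mismatch)
    before translation and the design gate.
    """
    if insert == design.spike_in_dna or (
        len(insert) == len(design.spike_in_dna)
        and _hamming(insert, design.spike_in_dna) <= 1
    ):
        return "spike", None
    peptide = str(Seq(insert).translate())
    if "*" in peptide:
        return "reject", "stop_codon"
    if not matches_design(peptide, design):
        return "reject", "not_in_design"
    return "peptide", peptide


def translate_insert(insert: str, design: LibraryDesign
                     ) -> tuple[str | None, str | None]:
    """Translate an insert and apply the design gate.

    Returns (peptide, None), (spike_in_label, None) for the spike-in, or
    (None, reason).
    """
    kind, value = classify_insert(insert, design)
    if kind == "spike":
        return design.spike_in_label, None
    if kind == "reject":
        return None, value
    return value, None


def _open_fastq(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def decode_well(path: str | Path, design: LibraryDesign,
                params: DecodeParams | None = None,
                _cache: dict | None = None
                ) -> tuple[dict[str, int], int, dict[str, int], int]:
    """Decode one FASTQ file.

    Returns (peptide counts, spike count, rejection counts, total reads).
    """
    params = params or DecodeParams()
    cache = _cache if _cache is not None else {}
    min_len = len(design.flank5) + len(design.flank3) + design.insert_length
    counts: dict[str, int] = {}
    rejected = dict.fromkeys(REJECT_REASONS, 0)
    spike = 0
    total = 0
    with _open_fastq(Path(path)) as fh:
        for _, seq, qual in FastqGeneralIterator(fh):
            total += 1
            trimmed = trim_read(seq, qual, params.q_threshold, min_len,
                                params.quality_offset)
            if trimmed is None:
                rejected["low_quality"] += 1
                continue
            seq_t = trimmed[0]
            insert, reason = extract_insert(seq_t, design,
                                            params.max_flank_mismatches)
            if insert is None:
                rejected[reason] += 1
                continue
            verdict = cache.get(insert)
            if verdict is None:
                verdict = classify_insert(insert, design)
                cache[insert] = verdict
            kind, value = verdict
            if kind == "spike":
                spike += 1
            elif kind == "reject":
                rejected[value] += 1
            else:
                counts[value] = counts.get(value, 0) + 1
    return counts, spike, rejected, total


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet CSV with columns sample_id, role, concentration_nM,
    replicate, fastq; indexed by sample_id, fastq paths resolved relative to
    the sheet's directory."""
    path = Path(path)
    sheet = pd.read_csv(path)
    required = {"sample_id", "role", "concentration_nM", "replicate", "fastq"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    sheet = sheet.set_index("sample_id")
    sheet["fastq"] = [
        str(p) if Path(p).is_absolute() else str(path.parent / p)
        for p in sheet["fastq"]
    ]
    return sheet


def tally(sample_sheet: pd.DataFrame | str | Path, design: LibraryDesign,
          params: DecodeParams | None = None) -> CountMatrix:
    """Decode every well of a screen into a CountMatrix.

    Peptide rows are sorted lexicographically for determinism; the
    conservation invariant (assigned + spike + rejected = total) holds per
    sample by construction.
    """
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = read_sample_sheet(sample_sheet)
    params = params or DecodeParams()
    cache: dict = {}
    per_sample: dict[str, dict[str, int]] = {}
    spike = {}
    rejected = {}
    total = {}
    for sample_id, row in sample_sheet.iterrows():
        fq = Path(row["fastq"])
        if not fq.exists():
            raise FileNotFoundError(f"FASTQ for sample {sample_id!r}: {fq}")
        c, s, r, t = decode_well(fq, design, params, _cache=cache)
        per_sample[sample_id] = c
        spike[sample_id] = s
        rejected[sample_id] = r
        total[sample_id] = t
    peptides = sorted(set().union(*per_sample.values())) if per_sample else []
    samples = list(sample_sheet.index)
    counts = pd.DataFrame(
        {s: [per_sample[s].get(p, 0) for p in peptides] for s in samples},
        index=peptides, dtype=int,
    )
    return CountMatrix(
        counts=counts,
        spike_counts=pd.Series(spike, dtype=int)[samples],
        rejected=pd.DataFrame(rejected)[samples].reindex(list(REJECT_REASONS)),
        total_reads=pd.Series(total, dtype=int)[samples],
        spike_in_label=design.spike_in_label,
    )
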