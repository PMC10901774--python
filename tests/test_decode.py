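"""Decoder: trimming, flank extraction, translation, tallying, conservation."""

import numpy as np
import pandas as pd
import pytest

from mipd.decode import (
    CountMatrix,
    DecodeParams,
    classify_insert,
    decode_well,
    extract_insert,
    read_sample_sheet,
    tally,
    translate_insert,
    trim_read,
)
from mipd.library_design import encode_peptide, load_design
from mipd.simulate import _random_member

_RC = str.maketrans("ACGT", "TGCA")

# independent standard-genetic-code oracle (DNA codon -> amino acid)
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AAS[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def _read_for(peptide, design):
    return design.flank5 + encode_peptide(peptide, design) + design.flank3


class TestTrim:
    def test_high_quality_read_unchanged(self):
        out = trim_read("ACGTACGT", "F" * 8, q_threshold=20, min_length=4)
        assert out == ("ACGTACGT", "F" * 8)

    def test_all_low_quality_rejected(self):
        assert trim_read("ACGTACGT", "#" * 8, 20, 4) is None

    def test_exact_low_quality_tail_removed(self):
        # direct-scan oracle: exactly the last 5 bases sit below threshold
        seq, qual = "ACGTACGTAC", "FFFFF#####"
        out = trim_read(seq, qual, 20, 4)
        assert out == ("ACGTA", "FFFFF")

    def test_trimmed_below_decodable_length_rejected(self):
        assert trim_read("ACGTACGTAC", "FFFFF#####", 20, 6) is None


class TestExtract:
    def test_constructed_read_recovers_insert(self, design, rng):
        p = _random_member(design, rng)
        read = _read_for(p, design)
        insert, reason = extract_insert(read, design)
        assert reason is None
        assert insert == encode_peptide(p, design)

    def test_reverse_complement_recovers_same_insert(self, design, rng):
        p = _random_member(design, rng)
        read = _read_for(p, design)
        rc = read.translate(_RC)[::-1]
        assert extract_insert(rc, design) == extract_insert(read, design)

    def test_too_many_flank_mismatches_rejected(self, design, rng):
        p = _random_member(design, rng)
        read = _read_for(p, design)
        broken = list(read)
        for i in range(2):  # max_flank_mismatches=1, inject 2
            broken[i] = "A" if broken[i] != "A" else "C"
        insert, reason = extract_insert("".join(broken), design,
                                        max_flank_mismatches=1)
        assert insert is None and reason == "flank_not_found"

    def test_wrong_insert_length_rejected(self, design, rng):
        p = _random_member(design, rng)
        dna = encode_peptide(p, design)
        read = design.flank5 + dna[:-3] + design.flank3
        insert, reason = extract_insert(read, design)
        assert insert is None and reason == "length_mismatch"


class TestTranslate:
    def test_single_codon_design(self):
        d = load_design({
            "name": "one", "alphabet": "W", "codon_map": {"W": "TGG"},
            "positions": [{"variable": "all"}],
            "flank5": "ACGT", "flank3": "TTGG", "spike_in_dna": "AAA",
        })
        assert translate_insert("TGG", d) == ("W", None)

    def test_stop_codon_rejected(self, design):
        insert = "TAA" + "GCT" * (design.length - 1)
        assert translate_insert(insert, design) == (None, "stop_codon")

    def test_wrong_fixed_position_rejected(self, design, rng):
        p = list(_random_member(design, rng))
        fixed_idx = design.fixed_mask.index(True)
        insert = encode_peptide("".join(p), design)
        # overwrite the fixed position's codon with Trp's
        insert = (insert[:3 * fixed_idx] + "TGG" + insert[3 * fixed_idx + 3:])
        assert translate_insert(insert, design) == (None, "not_in_design")

    def test_spike_in_diverted(self, design):
        assert translate_insert(design.spike_in_dna, design) == (
            design.spike_in_label, None)
        # one mismatch still recognized as spike
        near = "C" + design.spike_in_dna[1:]
        assert classify_insert(near, design)[0] == "spike"

    def test_translation_matches_codon_table_oracle(self, design, rng):
        bases = "ACGT"
        L = design.insert_length
        for _ in range(1000):
            insert = "".join(bases[i] for i in rng.integers(0, 4, L))
            expected = "".join(CODON_TABLE[insert[i:i + 3]]
                               for i in range(0, L, 3))
            kind, value = classify_insert(insert, design)
            if kind == "spike":
                continue
            if "*" in expected:
                assert (kind, value) == ("reject", "stop_codon")
            elif kind == "peptide":
                assert value == expected
            else:
                assert value == "not_in_design"


class TestTally:
    def test_round_trip_reproduces_simulator_draws_exactly(self, small_screen):
        screen, sheet, counts = small_screen
        drawn = screen.drawn_counts
        drawn_nonzero = drawn.loc[(drawn != 0).any(axis=1)].sort_index()
        pd.testing.assert_frame_equal(counts.counts, drawn_nonzero,
                                      check_names=False)
        assert (counts.spike_counts == screen.drawn_spike).all()
        assert counts.rejected.to_numpy().sum() == 0

    def test_conservation_with_noise(self, noisy_screen):
        _, _, counts = noisy_screen
        assert counts.conservation_ok()
        # noise must actually exercise the rejection paths
        assert counts.rejected.to_numpy().sum() > 0

    def test_duplicate_reads_tally_to_one_row(self, design, tmp_path, rng):
        p = _random_member(design, rng)
        read = _read_for(p, design)
        fq = tmp_path / "w.fastq"
        fq.write_text("".join(f"@r{i}\n{read}\n+\n{'F' * len(read)}\n"
                              for i in range(7)))
        counts, spike, rejected, total = decode_well(fq, design)
        assert counts == {p: 7} and total == 7 and spike == 0

    def test_empty_well_gives_zero_column(self, design, tmp_path):
        (tmp_path / "empty.fastq").write_text("")
        pd.DataFrame([
            {"sample_id": "w0", "role": "blank", "concentration_nM": 0.0,
             "replicate": 1, "fastq": "empty.fastq"},
        ]).to_csv(tmp_path / "samples.csv", index=False)
        sheet = read_sample_sheet(tmp_path / "samples.csv")
        cm = tally(sheet, design)
        assert cm.total_reads["w0"] == 0
        assert cm.counts.shape[0] == 0
        assert cm.conservation_ok()

    def test_count_matrix_tsv_round_trip(self, small_screen, tmp_path):
        _, _, counts = small_screen
        counts.to_tsv(tmp_path / "c.tsv", tmp_path / "r.tsv")
        back = CountMatrix.from_tsv(tmp_path / "c.tsv",
                                    rejected_path=tmp_path / "r.tsv")
        pd.testing.assert_frame_equal(back.counts, counts.counts,
                                      check_names=False)
        assert (back.spike_counts == counts.spike_counts).all()
        assert back.conservation_ok()

    def test_missing_fastq_raises(self, design, tmp_path):
        pd.DataFrame([
            {"sample_id": "w0", "role": "blank", "concentration_nM": 0.0,
             "replicate": 1, "fastq": "nope.fastq"},
        ]).to_csv(tmp_path / "samples.csv", index=False)
        with pytest.raises(FileNotFoundError):
            tally(read_sample_sheet(tmp_path / "samples.csv"), design)
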