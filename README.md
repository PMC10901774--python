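# mipd — mirror-image phage display screen analysis

`mipd` turns raw NGS reads from a mirror-image phage display (MIPD) screen of
a stapled α-helical peptide library into ranked, clustered binder families
and mirrored D-peptide synthesis candidates. It is written for groups running
(or simulating) bead-based phage screens against chemically synthesized
D-proteins, where by symmetry every L-peptide hit against the D-target
defines a D-peptide binder to the natural L-protein.

## What it computes

Reads from each screening well (blank wells with beads only, and bait wells
across a concentration series) are quality-trimmed, their constant flanking
DNA located, and the trimer-encoded insert translated and gated against the
library design — a scaffold of fixed and variable positions over a 16-letter
alphabet (the 20 canonical residues without Cys, Lys, Pro and Gly). Counts
for each unique peptide are tallied, and a known non-library spike-in
sequence added to every well provides cross-well normalization.

For a peptide *s*, the **Hit Strength** is the fold change

HS(*s*) = mean over top-concentration replicates of *n*(*s*) / mean over
blank replicates of *n*′(*s*),

where *n*(*s*) = count(*s*) / count(spike-in) per well, and in the blanks a
raw count of 0 is replaced by 0.5 before dividing, so HS is always finite.
A **dose-response gate** (Spearman rank correlation ρ of per-concentration
mean normalized counts against concentration, ρ ≥ 0.8 by default) and a
minimum read depth complete the hit call. Hits are grouped into **binder
families** by average-linkage hierarchical clustering of a per-position
BLOSUM62-derived dissimilarity over the variable positions, and each family
is summarized by a consensus, a per-position frequency (logo) matrix and
information content. Finally, family representatives are **mirrored** into
D-peptide candidates (rendered lower-case, optional Met → Nle substitution
for synthesis), and small structural utilities reflect coordinate models
(x → −x) and classify helix handedness from Cα virtual torsions.

A seeded synthetic-screen generator produces FASTQ wells with a log-normal
background, planted binder families enriched by Langmuir occupancy
θ = C / (C + K_D), and a spike-in at known expected fraction, so the whole
pipeline is testable against planted ground truth.

## Worked example

Simulate a default-scale screen (5,000 background members, three planted
Trp-anchor families of 20 members at K_D = 5, 50 and 500 nM, 2 blank wells
plus 4 concentrations × 2 replicates at 20,000 reads per well) and run the
full pipeline:

```python
from mipd.pipeline import run_all
out = run_all({"simulation": {"preset": "mdm2_like"}}, "run1", seed=1)
```

or, from the shell, `mipd run-all --config run.yaml --outdir run1 --seed 1`.
With seed 1 this prints 46 hits clustered into exactly 3 families
(`manifest.json`), with consensus sequences recovering the planted ones:

```
>F1 n=17
WNNSFDWSTQSN
>F2 n=16
HWFSDWDVDRSL
>F3 n=13
WVESQFRLLISQ
```

The strongest hit, `WNTSFLWSTQSN`, has Hit Strength 90.7 (its normalized
abundance at 1000 nM bait is ~91× its blank level) with a perfect
dose-response (ρ = 1.0). `d_candidates.tsv` lists the mirrored synthesis
candidates, e.g. consensus `WNNSFDWSTQSN` → `wnnsfdwstqsn` (lower-case = 
D-residues, staple positions 4/11 carried as metadata).

Structural side:

```bash
mipd handedness --structure helix.pdb --chain A
# helix.pdb chain A: right (median virtual torsion +50.0 deg, 12 CA)
mipd mirror-structure --in helix.pdb --out helix_mirror.pdb
# mirrored model classifies left at -50.0 deg
```

## Layout

- `mipd.library_design` — design loading/validation, membership and codon
  encoding
- `mipd.simulate` — seeded synthetic screens with planted families
- `mipd.decode` — FASTQ → peptide × sample count matrix with a rejection
  ledger
- `mipd.hitcall` — spike-in normalization, Hit Strength, dose-response gate
- `mipd.cluster` — family clustering, consensus, logo matrices
- `mipd.mirror` — L → D conversion and synthesis reports
- `mipd.chirality` — structure reflection and helix handedness
- `mipd.pipeline` / `mipd.cli` — orchestration and the `mipd` command

See `docs/methods.md` for the model, parameter defaults and limitations.
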