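# Methods

## Screen model and what the pipeline assumes

A mirror-image phage display screen reads out, per well, the phage particles
remaining bound to bead-immobilized D-protein bait after washing. `mipd`
models one selection round: there is no amplification or re-panning between
rounds, so a sequence's read count in a well reflects its pre-selection
abundance modulated by capture. Wells are either *blanks* (beads, zero bait)
or *bait wells* at known concentrations C, with replicates. A spike-in — a
sequence deliberately outside the library design — is added to every well at
denaturation and provides the only cross-well scale anchor: all abundances
are expressed as reads per spike-in read, which removes per-well depth and
recovery differences.

## Library design and decoding

The library is a trimer-codon design: each allowed residue has exactly one
DNA codon, the insert is bounded by constant flanks, and membership is a
positional test (fixed positions exact, variable positions within their
allowed sets). The default fixture design is a synthetic 12-position
stapled-helix scaffold — 16-letter alphabet (canonical 20 minus C/K/P/G),
fixed Ser at positions 4 and 11 recorded together with the staple pair
(4, 11) as inert metadata — declared in `src/mipd/data/default_design.yaml`,
not hard-coded.

Decoding is deterministic and total: every read lands in exactly one bucket
(peptide count, spike-in count, or one of five rejection reasons), so
`assigned + spike + rejected = total` holds per sample by construction.
Choices:

- **Quality trimming**: 3′ running trim at Q20 (Sanger offset 33); a read
  trimmed below flank5+insert+flank3 length is rejected `low_quality`.
  Simple and order-independent.
- **Flank location**: substitution-only Hamming match, ≤1 mismatch per
  flank by default, forward strand first then reverse complement; when both
  orientations would match, forward wins. No indel alignment — a frameshift
  in a trimer insert is unrecoverable anyway.
- **Spike-in** is recognized at the DNA level (exact insert, then ≤1
  mismatch) *before* translation and the design gate, so sequencing errors
  in the spike-in do not leak into the peptide matrix.
- **Translation** uses the standard genetic code; any stop codon rejects the
  read (`stop_codon`), then the membership gate rejects non-members
  (`not_in_design`).

## Hit Strength and the dose-response gate

With n(s, w) = count(s, w) / spike(w):

- HS(s) = mean over top-concentration replicates of n(s, ·) divided by the
  mean over blank replicates of n′(s, ·), where n′ substitutes a raw blank
  count of 0 by **0.5 before normalization** (a count, not a normalized
  value; each blank replicate is pseudocounted individually, then averaged).
  The pseudocount applies only in blanks; a zero at the top concentration
  legitimately gives HS = 0. The spike-in's own HS is exactly 1 in any
  screen — a useful analytic invariant, tested as such.
- Dose response: per concentration level (blank = 0 included), normalized
  counts are averaged across replicates; the statistic is the Spearman rank
  correlation of level means against concentration, ties mid-ranked, defined
  as 0 when all level means are equal. Default pass threshold ρ ≥ 0.8. With
  fewer than three levels the gate is not evaluable and degrades to
  HS-only with a logged warning.
- A hit requires HS ≥ 5, a dose-response pass, and ≥5 raw reads in the best
  top-concentration replicate. All three thresholds are configuration, not
  constants.

## Clustering and logos

Hits share one length by design, so distances are positional and
alignment-free, averaged over **variable positions only** (fixed positions
carry no signal). Per residue pair, BLOSUM62 log-odds are affinely rescaled
into a [0, 1] similarity using the pair's own diagonal,
sim(x, y) = (S(x, y) − S_min) / (min(S(x, x), S(y, y)) − S_min) clipped to
[0, 1], and d = 1 − sim. This guarantees d(a, a) = 0 exactly and d = 1 for
globally minimum-similarity pairs; it satisfies identity, symmetry and
boundedness but not necessarily the triangle inequality. Hamming distance is
available as an alternative.

Families come from average-linkage agglomerative clustering cut at height
0.5; clusters under 3 members are reported as singletons. Peptides are
sorted before clustering, making the partition invariant to input order.
Per family: consensus = per-position modal residue (ties broken by design
alphabet order), logo = per-position frequency matrix over the alphabet
(columns sum to 1), and information content
IC_j = log2 |A_j| + Σ_r p_jr log2 p_jr with |A_j| the position's allowed-set
size (so fixed positions score 0 and a one-hot variable column scores
log2 16 = 4 bits). Logos can optionally be weighted by top-concentration
normalized abundance (off by default). Logo output is matrix-form TSV
(PSPM-compatible); image rendering is deliberately out of the contract.

## Mirroring

D-candidate generation is chirality inversion at fixed sequence order —
*not* retro-inverso. Rendering: upper-case L, lower-case D, glycine achiral
but rendered lower-case in D-context, norleucine as the bracketed token
`[nle]` so that rendering parses back unambiguously (the bare letters n, l,
e are themselves D-residue codes). The Met → Nle substitution (on by
default in synthesis reports, to avoid methionine side-chain oxidation) is
not invertible; `to_l` refuses it with the offending position. Without
substitution, `to_l(to_d(p)) = p` for every design member.

## Structural utilities

Reflection is fixed as x → −x (any mirror differs from it only by a proper
rotation); it is an exact involution and an isometry, and flips the sign of
every signed volume. Handedness is classified from Cα virtual torsions
(dihedral over four consecutive Cα), which needs no side chains or full
backbone: the median torsion of an ideal α-helix (2.3 Å radius, 1.5 Å rise,
100°/residue) is ≈ +50°, so the windows are [+30°, +70°] → right,
[−70°, −30°] → left, else none — symmetric about zero, hence
handedness(mirror(T)) is always the opposite of handedness(T). Traces with
non-physical consecutive Cα spacing (outside 2.0–4.5 Å) or degenerate
(collinear) torsions classify as none. Mirrored structure files keep their
residue names and chirality labels untouched and carry a header remark
marking the model as mirrored.

## Synthetic screens

The generator emulates the statistical structure the analysis relies on:

- Background: n distinct design members with log-normal relative abundances
  (default n = 5,000, σ = 1) — heavy-tailed, as phage libraries are after
  amplification.
- Planted families: members derived from a consensus by substituting
  variable positions at rate 0.1; pre-selection abundance =
  abundance_scale × mean background abundance. Preset consensus triples
  carry the motif flavor of real screens (N-terminal Trp anchors;
  terminal carboxylates) and are chosen mutually distant (min pairwise
  distance 0.69) so the planted partition is resolvable by construction —
  the planting precondition, not a tuned quantity.
- Enrichment: a binder's well weight is a·(1 + β·θ) with θ = C/(C + K_D)
  (θ = 0 in blanks); β = 50 by default. Preset K_D values 5/50/500 nM span
  the default 1–1000 nM concentration series.
- Spike-in joins the same multinomial draw with weight set for a 5%
  expected read fraction, keeping its count noise realistic.
- Reads are flank5+insert+flank3 at constant Q37, with optional per-base
  substitution errors (ε), reverse-complemented fraction, and low-quality
  tail injection to exercise trimming. One RNG stream per run; identical
  seeds give byte-identical outputs.
- Default layout: 2 blanks + 4 concentrations × 2 replicates at 20,000
  reads/well.

What the generator does **not** model: PCR/polymerase bias, indels,
paired-end structure, multi-round panning dynamics, or well-to-well
contamination. Passing tests therefore demonstrate correctness of the
decoding/statistics pipeline under the stated noise model, not performance
on arbitrary real screens.

## Numerical and scale choices

- Test fixtures run scaled-down screens (hundreds of background members,
  2,000–6,000 reads/well) that preserve the planted-to-background ratio
  (~1.5%) of the default conditions, because competition for a fixed read
  budget is ratio-driven: when planted binders are a large pool fraction,
  every sequence's normalized share shrinks at high bait concentration.
- A real consequence of the dose gate worth knowing: binders already
  saturated across the top of the concentration series (K_D far below
  C_max) have flat level means there and can fail ρ ≥ 0.8 at shallow read
  depth even though they are genuine. At default depth this affects only a
  minority of the tightest family's members and never the family count.
- Under the null (β = 0) a small number of low-abundance background
  sequences (well under 1%) reach HS ≥ 5 by chance — zero blank counts meet
  a lucky handful of top-concentration reads. They surface as singletons,
  never as families.
- Seeds: a single top-level seed fans out to per-stage child seeds through
  `numpy.random.SeedSequence`, all below 2^31; stages rerun in isolation
  with their recorded child seed reproduce their outputs.
- Determinism: peptide rows sorted lexicographically everywhere; family ids
  ordered by size then consensus; all floats written at %.6g.

## Known limitations

- Hit thresholds (HS ≥ 5, ρ ≥ 0.8, ≥5 reads) are pragmatic defaults, not
  calibrated error rates; no FDR control is attempted because no replicate
  null model is defined for a single-round screen.
- K_D is not estimable from this readout beyond rank information; the
  dose-response statistic is ordinal by design.
- The distance metric ignores position couplings (e.g. staple-face
  geometry); families are sequence families, not binding-mode families —
  real screens show that one family can contain reversed-direction binders.
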