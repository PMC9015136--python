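# Methods

This note records the models implemented in `idpseq`, the numerical and
design choices behind them, and what the synthetic-sequence generator does
and does not emulate.

## Charge model

Per-residue fractional charge follows the Henderson–Hasselbalch equation.
Group polarity is fixed by chemistry and not configurable: D, E, C, Y side
chains and the free C-terminus are acids (`q = −1/(1+10^(pKa−pH))`,
in [−1, 0]); H, K, R side chains and the free N-terminus are bases
(`q = +1/(1+10^(pH−pKa))`, in [0, +1]). All other residues contribute
exactly zero. Histidine is treated as an ordinary base with its set's pKa —
no special casing — which gives it a small positive charge near neutral pH.
At pH = pKa every group is exactly half-ionized (|q| = 0.5), and since
raising pH deprotonates every group, the signed charge of each ionizable
residue is monotonically non-increasing in pH; both identities are asserted
by the test suite.

The default pKa set is **IPC_protein** (side chains: C 7.555, D 3.872,
E 4.412, H 5.637, K 9.052, R 11.84, Y 10.85; N-terminus 9.094, C-terminus
2.869), a set optimized for whole folded proteins. Nine classical
compilations (EMBOSS, Lehninger, Bjellqvist, Dawson, Murray, Rodwell,
Sillero, Solomon, Stryer) are built in under their usual names, and
arbitrary sets load from `residue<TAB>pKa` text with `NTERM`/`CTERM` rows.
All pKa values must lie in (0, 14).

**Termini.** Whole-sequence `net_charge` includes the two free-terminus
groups by default (`include_termini=False` to drop them). Sliding-window
local charge always excludes termini: the residues inside a window are not
free ends, and including them would step the profile at both edges. The
mean net charge per residue divides by the number of (unmasked) residues.

## Hydropathy

Raw Kyte–Doolittle values are embedded (the canonical 20-value table,
range −4.5 for Arg to +4.5 for Ile). The default scale rescales them
linearly, `(raw + 4.5)/9`, which is the unique affine map sending Arg to
exactly 0.0 and Ile to exactly 1.0. Values are carried at full precision
everywhere; any rounding (e.g. three decimals) happens only at display
time. Alternative scales can be loaded from text files but must cover all
20 residues with values in [0, 1].

## Charge–hydropathy classification

A sequence is summarized by the point (⟨H⟩, ⟨q⟩) = (mean scaled hydropathy,
mean net charge per residue) and labelled by two rules, applied in order:

1. **Insolubility override**: ⟨H⟩ ≥ 0.7 → `insoluble`.
2. **Boundary**: `|⟨q⟩| > 2.785·⟨H⟩ − 1.151` → `extended` (natively
   disordered); otherwise `collapsed`.

Exact equality with the boundary is assigned `collapsed` (extended requires
a strict inequality); the boundary is a measure-zero set, so the tie-break
only matters for constructed inputs. The label is symmetric in the sign of
the charge by construction. At ⟨H⟩ = 0 the boundary is negative, so any
charge — including zero — classifies as extended; this is the correct
limiting behavior of the linear boundary, not an edge case.

## FoldIndex

For every full window of width `w` (default 51, any odd number) the score

    score = 2.785·⟨H⟩_w − |⟨q⟩_w| − 1.151

is reported at the window's center position. Windows use the same
full-window-only semantics as the local profiles (centers `w//2+1` to
`L−w//2`, 1-based), window charge never includes terminal groups, and the
score is algebraically identical to evaluating the charge–hydropathy
boundary on the window's own coordinates. `score < 0` predicts disorder,
`score > 0` order. A score of exactly 0 is called ordered — a deterministic
total rule is needed and the boundary set has measure zero — and the
position is flagged in `boundary_positions`. Maximal runs of identical
calls over consecutive reported positions become `(start, end, call)`
regions; a gap in reported positions (from masking) closes the run, so
regions never span unreported residues.

**Short sequences.** When the sequence is shorter than the window, the
whole sequence is used as a single window reported at the central position,
and the result is flagged `whole_sequence_window`. Edge positions are never
given shrunk-window scores: every reported value is a true `w`-residue (or
whole-chain) mean.

## Structural tendency and composition

The default scheme is the published three-way partition
(disorder-promoting P,E,S,Q,K,A,G; order-promoting M,N,V,H,L,F,Y,I,W,C;
neutral D,T,R). Any user scheme is accepted provided the three sets are
pairwise disjoint and cover the 20-letter alphabet exactly, which makes
classification total and unambiguous by construction. Compositional
summaries report counts, fractions and class fractions (each summing to 1
over unmasked residues). Enrichment, `(fraction − reference)/reference`, is
computed only when the caller supplies a reference composition: no
reference is shipped as authoritative because published disordered-protein
reference compositions vary; a uniform 5% reference is available as an
explicit choice.

## Sequence maps

The layout contract is purely arithmetic: cells are placed row-major,
left-to-right then top-to-bottom, with
`position = (row−1)·n_columns + column`, covering positions 1..L exactly
once (the last row may be partial). Values — discrete labels or real
numbers — pass through untouched, so flattening the cells in (row, column)
order reproduces the input exactly. Annotations are 1-based inclusive
ranges validated against the sequence length. Rendering (matplotlib) is a
thin adapter over this layout; the layout, not the image, is tested.

## Substitution matrices

The reader accepts NCBI/EMBOSS-style whitespace-delimited square matrices
('#' comments, a header row of codes, labelled rows) and validates
squareness, header/row agreement and symmetry, naming the offending pair on
failure. No matrix values are bundled: BLOSUM/PAM files and the IDP-derived
EDSSMat/Disorder/DUNMat families all parse from their distributed text
forms. `score_aligned_pair` scores pre-aligned sequences: matrix scores
over residue–residue columns plus affine gap penalties, where each maximal
gap run in either sequence costs `gap_open + (len−1)·gap_extend`. Penalty
arguments are signed (typically negative). Alignment search is out of
scope.

## Unknown residues

The strict policy (default) rejects any character outside the 20-letter
alphabet, naming the character and position — silently averaging over
unknowns would bias classification. The mask policy replaces the
ambiguity/rare codes B, J, O, U, X, Z with a sentinel, warns, and excludes
masked positions from every mean; windows covering a masked position are
dropped from profiles rather than reported from partial data.

## Synthetic sequences

`generate_fixture(kind, length, seed)` draws sequences with exactly
controlled composition: target fractions are converted to integer counts by
largest-remainder apportionment and the residue multiset is shuffled with a
seeded generator. Guarantees therefore hold deterministically, not in
expectation — an `acidic` sequence (60% D/E, remainder non-ionizable)
always has negative net charge at pH 7; `disorder-rich` (80% mass on the
disorder-promoting set) always meets its composition bound. Kinds:
disorder-rich, order-rich (80% on the respective tendency set, remainder
spread uniformly over the other residues), acidic, basic (60% on E/D or
K/R, remainder over G,S,T,A,N,Q,P), and mixed (uniform).

These fixtures emulate composition bias only. Real disordered regions also
carry positional structure — charge patterning, tandem repeats, motifs,
low-complexity runs — that uniform shuffling destroys, so passing tests
demonstrate correctness of the computations and the direction of
composition-driven effects, not predictive accuracy on natural proteins.
The bundled α-synuclein example provides one natural-sequence anchor:
collapsed overall, extended for residues 104–140, with FoldIndex placing
the disordered region at the C-terminal window centers (98–115).

## Problem sizes and determinism

Test and acceptance runs use sequences of length 9–500, 50–200 random
sequences per oracle-equivalence check, and 50 seed pairs for the
composition-separation check; the classifier grid sweep uses a 201×101
point lattice over [0,1]×[−1,1]. All randomness flows from explicit integer
seeds (property tests run derandomized), so every reported number is
reproducible bit-for-bit. Windowed means use vectorized sliding windows and
are checked against naive Python loops to < 10⁻¹² absolute deviation.

## Known limitations

- Charge ignores post-translational modifications, bound ions and local
  electrostatic context; pKa sets assume independent, context-free groups.
- The charge–hydropathy boundary and FoldIndex coefficients are fixed
  empirical constants; no uncertainty is propagated.
- Web-service disorder predictors (IUPred2A/ANCHOR2/redox) are deliberately
  excluded; the optional UniProt fetch requires explicitly enabled network
  access and is not exercised by the offline test surface.
- The published worked-example value for mouse GCNA (mean scaled hydropathy
  0.348, UniProt A0A1D9BZF0) is asserted by a test that loads a locally
  cached copy of the sequence or fetches it from UniProt; without network
  access or a cached `data/A0A1D9BZF0.fasta` that test cannot run to a
  pass.
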