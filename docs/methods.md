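# Methods

## Array design and coordinate arithmetic

A protein antigen of length `L` is elongated with the neutral linker
`GSGSGSG` (7 residues) at both termini and decomposed into overlapping
15-mer peptides at step 1 (14-residue overlap). The elongated sequence has
length `L + 14`, so tiling yields exactly `L` peptides per protein, indexed
consecutively from 1. Tile `i` occupies elongated positions `i … i + 14`;
protein residue `r` sits at elongated position `r + 7`, so the
linker-clipped protein span of tile `i` is

```
start = max(1, i − 7),   end = min(L, i + 7)
```

— every interior tile (`8 ≤ i ≤ L − 7`) is centred on residue `i`. All
protein coordinates are 1-based inclusive throughout the package; the
annotation TSV format is likewise 1-based inclusive (deliberately *not* BED's
0-based half-open convention, which is documented on the reader).

One published reactivity-table row (index 55 with a printed span starting at
28) contradicts this otherwise-universal centring rule, which 60+ other rows
obey; we treat that row as a typo in the source table and implement the
consistent rule.

Identical 15-mers arising from homologous proteins are printed once: the
library deduplicates sequences across all proteins on the array, and a
shared spot's intensity is attributed to every origin `(protein, index)`.
Each distinct peptide is printed in duplicate, so a library of `D` distinct
peptides occupies `2·D` spots (471 → 942 for three 157-residue antigens).
Tiling into synthesizable peptides requires standard residues, so ambiguity
codes (X, B, Z) are rejected at FASTA parse time.

## Quantification

Net spot signal is median foreground minus median local background.
Negative net signals are retained — the downstream statistics are
location-scale based, and flooring at zero would distort the empirical
distribution. Duplicate spots are averaged after background subtraction,
with no outlier rejection between duplicates. Spots flagged bad/absent
(`Flags < 0` in the GPR dialect) are dropped with a logged count; a peptide
whose spots are all dropped is excluded from normalisation (not imputed) and
reported as missing.

## Reactivity statistics

Per sample, intensities are standardised over **all** distinct peptides on
the array jointly (not per protein):

```
Z_p = (x_p − mean(x)) / SD(x)
```

Sample standard deviations (n − 1 denominator) are used everywhere; the
population-SD alternative is a one-argument change (`ddof`). Peptides with
`Z > 2` (strict inequality; boundary values are negative) are called
reactive.

Group-vs-control comparisons use the Z-ratio: per-peptide difference of the
two samples' Z-scores divided by the sample SD of **all** those differences
(computed per comparison over the shared peptide set). `Zratio > 1.96` —
the two-sided standard-normal critical value at p = 0.05 — is declared
significant. The default rule is one-sided (greater), matching an analysis
focused on peptides *more* reactive in immunized than control serum; a
two-sided option (`|Zratio| > 1.96`) exists for calibration work. With one
pooled-serum array per group, the "average of observed Z-scores" entering
the difference is that single duplicate-averaged value. No multiple-testing
correction is applied; the number of tests is stored on each comparison so
users can post-correct.

Peptides whose **control** Z-score exceeds the reactive threshold are
flagged as nonspecific (control-reactive). They are flagged, never deleted:
reports include them (the reactivity table shows control-column marks), but
candidate protective regions exclude them by default.

## Epitope regions

A region is a maximal run of consecutive reactive peptide indices on one
protein for one group; inter-run gaps up to `max_gap` (default 0) may be
bridged to tolerate single-peptide dropouts. The region span is the full
15-mer footprint — start of the first peptide to end of the last — matching
how printed reactivity tables report spans. Control-flagged peptides break
runs by default and mark adjacent regions as `control_contaminated`; an
option keeps them inside runs instead.

The pipeline applies two further criteria to **candidate** regions, both
configurable:

* `require_significant` (default on): region peptides must also have
  `Zratio > 1.96` vs the control, the comparison the analysis is focused on.
* `min_region_peptides = 2`: with step-1 tiling, a genuine linear epitope is
  necessarily covered by several adjacent peptides (any epitope of at least
  `min_overlap = 8` residues makes ≥ 8 consecutive peptides respond), so
  isolated single-peptide hits are treated as noise for region calling while
  remaining visible in the reactivity table.

Without these, the right-skewed fluorescence background (see below) leaves
roughly 1–5% isolated heavy-tail hits per group that would each become a
spurious one-peptide region. Near a threshold the converse also happens:
borderline peptides inside a true epitope can fall just short, splitting one
epitope into adjacent region fragments; the fragments still lie inside the
true peptide run.

## Alignment projection and annotation overlap

Cross-species coordinate transfer consumes a user-supplied equal-length
gapped FASTA alignment (e.g. Clustal Omega output); the package never
computes alignments. A span is projected by mapping its residues to
alignment columns on the source sequence and taking the residues of the
target sequence within that column window — gap-only edges shrink inward,
and a span falling entirely in a deletion projects to nothing. Projection is
monotone: sub-spans project to sub-spans.

Annotations (protective chimera peptides, interaction domains) are intervals
on a named reference, optionally carrying a literal sequence which can be
located by exact substring match on its own reference; transfer to other
proteins goes through the alignment. Overlap reports use closed-interval
intersection and give the overlap length plus fractions of the region and of
the annotation.

## Synthetic experiments

The generator emulates the data-generating process the analysis assumes:

| parameter | default | meaning |
| --- | --- | --- |
| `proteins` | 3 × 157 residues | antigens; 471 tiles before dedup |
| `groups` | 2 immunized + `control` | one pooled-serum array per group |
| `background_mu`, `background_sigma` | log 500, 0.4 | log-normal background fluorescence (a.u.), right-skewed like raw array data |
| planted effect size | 8 | additive shift in background-SD units, so effect size maps onto the expected Z-scale |
| `duplicate_cv` | 0.1 | CV of mean-one multiplicative noise between duplicate spots |
| `bg_fraction` | 0.05 | constant local-background column, as a fraction of exp(μ) |
| `min_overlap` | 8 | residues of span∩epitope for a peptide to respond (a majority of a 15-mer; linear epitope cores are 5–8 residues) |
| `control_effect_size` | 8 | effect applied to the control group's nonspecific intervals |

A deduplicated spot responds when *any* of its origins overlaps a planted
epitope of the scanned group by ≥ `min_overlap`; the control group carries
signal only on its nonspecific intervals. Zero effect sizes are allowed and
constitute the null model used for calibration. All randomness derives from
one integer seed through independent per-purpose streams, so identical
configurations yield byte-identical FASTA/GAL/GPR/truth files regardless of
call order.

What the generator does **not** emulate: spatial artefacts and print-tip
effects, saturation, isotype structure, titer kinetics, and sequence-driven
cross-reactivity (nonspecific binding is planted by interval, not predicted
from sequence). Passing recovery tests therefore demonstrate the pipeline's
statistical behaviour under its own assumptions, not robustness to those
real-data artefacts.

Recovery scoring: a planted epitope counts as recovered when a called region
of the same protein and group overlaps it by ≥ `min_overlap` residues; a
region is a true positive by the same rule. Precision is over regions,
recall over epitopes, F1 their harmonic mean (no regions and no epitopes
scores precision 1). Under the defaults the two-sided null significance
rate is ≈ 0.05 and F1 rises monotonically with effect size, reaching 1.0 at
effect size 8.

## Numerical and degenerate-input conventions

* Z-scoring requires ≥ 3 peptides and positive SD; constant vectors raise a
  "degenerate intensity distribution" error, identical profiles raise on the
  Z-ratio's zero SD.
* Both thresholds use strict inequalities; `Z = 2` and `Zratio = 1.96` are
  non-significant.
* Z-profiles satisfy mean 0 / SD 1 to 1e−9; the vectorised Z-ratio matches
  an explicit-loop computation to 1e−12.
* Report files are UTF-8, tab-separated, LF-terminated, with fixed float
  formats, so re-runs are byte-identical.
* CLI exit codes: 0 ok, 1 validation error, 2 runtime error.

## Known limitations

Only linear epitopes are addressable with tiled peptides; conformational
epitopes, secondary-structure effects, and isotype-specific responses are
out of scope. The GPR/GAL support is a minimal dialect (the columns named
above), not a full GenePix parser. Alignment projection assumes the supplied
alignment is trustworthy; no realignment or quality control is attempted.
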