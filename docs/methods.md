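# Methods

This note records the models, numerical conventions and design choices
behind depsitools, and what the simulators do and do not emulate.

## Exact-mass conventions

Monoisotopic atomic masses ship as a versioned TSV
(`data/atomic_masses.tsv`, NIST/CODATA values, ≥ 6 decimals). Protonated
adducts use the proton mass 1.00727646 Da — the electron mass is thereby
accounted for — so [M+H]⁺ = M + 1.00727646 and
[M+2H]²⁺ = (M + 2·1.00727646)/2. The ppm sign convention is
(observed − theoretical)/theoretical × 10⁶. Only protonated charge
carriers are supported; sodiated/potassiated species and isotope
patterns are out of scope.

Published adduct masses for this compound class are commonly rounded
from slightly different mass tables; agreement should be expected to the
printed precision (10⁻⁴ for four-decimal m/z values, ~0.05 ppm on
deviations), not to machine precision.

RDBE is C − H/2 + N/2 + 1 with halogens counted as H-like and divalent
elements ignored; it is half-integer for odd-electron species.

## Peptide model and ion ladders

A cyclic lipodepsipeptide is handled in its ring-opened form
(`LinearLipopeptide`): an ordered residue list whose position 1 carries
the N-terminal fatty-acyl chain. Residues are in-chain formulas (monomer
minus water); acyl chains are defined by their free β-hydroxy acid, and
the acyl increment (acid − H₂O) is always derived, never stored. The
cyclic parent's neutral mass is the acyl increment plus the residue
masses; the linearized (hydrolyzed) form carries one extra water. The
ring is always opened at the macrolactone ester bond (acyl β-hydroxyl ↔
C-terminal carbonyl), which is the opening consistent with the observed
contiguous b-ion ladders; alternative openings are not enumerated.

Ion series: b_n = Σ residues 1..n + acyl increment + proton;
y_n = Σ last n residues + H₂O + proton; doubly charged variants are
(m/z₁ + proton)/2. Neutral losses:

* b° = b − 18.010565 (water). Emitted for *all* b ions — water loss is
  not restricted to hydroxylated residues, since high-energy CID shows
  it broadly.
* b\* = b − 43.005814 (isocyanic acid, HNCO), emitted only when the
  fragment contains a ureido-flagged residue (citrulline). This is the
  citrulline-diagnostic loss.
* b# = b − acyl increment. The exact neutral composition of the
  acyl-chain loss is not experimentally settled; defining it as the acyl
  increment (fatty acid − H₂O) is this package's convention.

a-ions, internal and immonium ions are not generated. Annotation matches
each theoretical ion to the nearest peak in ppm within tolerance
(default 10 ppm, HR-QTOF scale); ties go to the lower-m/z peak; one peak
may satisfy several ions but each ion matches at most one peak. Ladder
coverage is the fraction of the N−1 backbone bonds supported by at least
one matched b_i or y_{N−i} ion of any loss/charge state. Candidate
ranking scores matched-ion count with ladder coverage as a sub-integer
tiebreak; remaining ties keep input order.

Congener-shift inference matches the precursor neutral-mass delta
against combinations of at most two elementary events (+O on a residue,
±CH₂ on the acyl chain, ±0.01 Da) and re-annotates the query spectrum
under every compatible placement; the best-supported placement wins. An
oxygen *loss* relative to the chosen reference cannot be placed on the
scaffold and is reported without localization; deltas matching no
hypothesis yield an "unassigned" report rather than an error.

## Molecular networking

Parameters default to the classic networking workflow: fragment ions
within ±17 Da of the precursor removed; a peak kept only if it is among
the 6 most intense within ±50 Da of itself (evaluated against the
original peak set, so filtering is order-independent); 0.02 Da fragment
and precursor tolerances; edges require cosine > 0.7, ≥ 6 matched peaks
and mutual top-10 rank; connected components above 100 members lose
their lowest-cosine edges until the bound holds (ties broken by node
ids, making pruning deterministic).

The modified cosine square-root-transforms and L2-normalizes
intensities, admits peak pairs at fragment delta 0 or at the *parent*
(singly-protonated-equivalent) mass difference — for multiply charged
precursors the raw precursor m/z difference understates the ladder
shift — and then finds the one-to-one pairing maximizing the summed
intensity products *exactly* via linear-sum assignment. An exact
assignment rather than the common greedy heuristic costs little at
centroided-spectrum sizes and makes the score provably equal to the
exhaustive optimum; spectra are scored in a canonical orientation so
cosine(a,b) and cosine(b,a) are bit-identical. "More than 6 matched
peaks" follows the platform's minimum-matched-peaks semantics
(matched ≥ 6); the strict reading is available via
`matched_peaks_rule="strict"`. The intensity transform and the pruning
tie rule are not fixed by the workflow's public description; both
choices here are documented defaults, not claims.

## Gene-cluster evolution analysis

Domain annotations use a closed vocabulary (C_Starter, C, A, T, E, TE,
other) with 0-based half-open nucleotide spans in memory and 1-based
inclusive coordinates in every file. A module spans from the start of
its C (or C_Starter) domain to the end of its T (or E) domain, and
inter-module linkers belong to the *downstream* module, so a breakpoint
in an A-T linker is attributed to the module whose A domain precedes it.
Module count equals the A-domain count. C_Starter harvesting keeps
clusters encoding more than 5 A domains — the scale at which a
lipopeptide-class NRPS is plausible.

Global alignment is Needleman–Wunsch with affine gaps (match +1,
mismatch −1, gap open −5, gap extend −1, a gap of length L scoring
open + (L−1)·extend). Among co-optimal alignments the aligner's first
deterministic traceback is reported; only the optimum score is
contract-relevant and is verified against exhaustive enumeration in the
tests. Percent identity counts identical columns over all aligned
columns, with gap-containing columns in the denominator by default
(conservative); a flag excludes them.

Sliding-window π (default width 300 nt, step 150 nt) is the mean
per-site difference over columns free of gaps in every sequence,
averaged over all sequence pairs for an MSA; gap columns are excluded
from numerator and denominator. Windows advance until the alignment end;
midpoints are reported in alignment coordinates. Both pairwise and MSA
modes exist because windowed-diversity tools accept either.

Dot plots are exact word matches (default word 25 nt, at which random
hits are negligible at cluster scale), stored sparsely. Deletion
detection chains the word matches into the longest collinear diagonal
(patience LIS), then reports the largest gap where the reference
coordinate jumps further than the query coordinate (≥ 200 nt by
default): the deleted reference span, the query junction, the modules
whose A domains fall in the span, and the inter-domain linker containing
the junction. Gaps at sequence ends are flagged as truncations, not
internal deletions. Chance single-base matches blur breakpoints by a few
nucleotides, so containment checks carry word-size slop.

Duplication detection aligns every non-overlapping pair of module
windows (single modules and tandem di-module blocks, linkers included)
and reports pairs at or above the identity threshold (default 90 %). A
unit-cost edit-distance screen (edlib) skips pairs more than 10 identity
points below threshold; reported identities always come from the full
affine-gap alignment.

Trees are neighbor-joining on p-distances (gap pairs excluded), with
negative branch lengths clamped to zero and optional support from seeded
bootstrap resampling of alignment columns. NJ reproduces additive
distance matrices exactly, which the tests verify up to six taxa.
Maximum-likelihood search is deliberately out of scope.

## Simulators

The spectrum simulator draws the theoretical ladder and corrupts it with
configurable peak dropout, Gaussian m/z jitter (ppm), and uniform-m/z
noise peaks with exponentially distributed intensities. Base peak
intensities are uniform in [200, 1000]; doubly charged fragments are
scaled by 0.25 and neutral-loss satellites by 0.5, reflecting the
observed predominance of singly charged backbone ions in QTOF spectra of
this compound class. Precursors default to the cyclic parent's [M+2H]²⁺.
With zero corruption the simulator is the exact inverse of annotation.
Not emulated: isotope envelopes, chromatography, detector saturation,
chimeric spectra — so passing round trips demonstrate bookkeeping
correctness, not robustness to every real-data artifact.

The congener-series generator applies elementary events to a scaffold;
the bundled six-member preset derives all printed congener formulas of
the flagship family from the des-hydroxy scaffold (Trp7, C17 acyl) via
{+O at 7, +O at 9, −CH₂ on acyl}.

The cluster-family simulator builds an ancestral NRPS (default 10
modules of ~3.1 kb — C 1300, A 1500, T 220 nt with 60 nt linkers — E
domains +1.3 kb, values are configuration, not claims), then derives
each member by (1) background per-site substitution (default 5 %,
uniform over the three alternative bases, no indels) and (2) its planted
events in order. Background precedes events so that a planted
duplication's copy-vs-source identity equals the configured identity
*exactly* (an exact count of sites is substituted); applying background
afterwards would dilute the planted identity by roughly twice the
background rate. Event module indices refer to the member's state at the
moment the event applies; referencing a module that no longer exists
raises. Deletions recombine A-T linker offsets of the flanking modules,
matching how module loss is inferred from real clusters. Not emulated:
codon structure, selection, horizontal transfer of whole clusters,
assembly artifacts.

## Problem sizes

Default test and acceptance runs use: 12-residue peptides (~110
theoretical ions), 6-member congener families plus 20 decoy spectra,
100-replicate shift-recovery batches at 5 ppm jitter, 1000-spectrum
symmetry sweeps, and 10–12-module clusters (34–42 kb) with 20-seed
recombination/deletion batches. These sizes exercise every code path
while keeping a full run in tens of seconds; all are configuration
parameters, and larger runs only cost time.
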