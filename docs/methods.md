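# Methods

## Scope and model

`spscore` scores single missense substitutions by their *local* structural
consequences in a solved protein model.  It deliberately models nothing
global: no allosteric propagation, no backbone motion, no molecular
dynamics, no heterozygous mixing.  The claim the score supports is
correspondingly narrow — a high score flags a substitution whose side
chain cannot be accommodated locally (size, chemistry, sterics) or that
touches positions already known to harbor pathogenic substitutions; a low
score is *uninformative*, never evidence of benignity.

## The five components

**A — size.**  Median over the configured size tables of
|v(mut) − v(wt)| / maxᵢⱼ|vᵢ − vⱼ|.  Shipped defaults: Zamyatnin residue
volumes (Å³) and Tien et al. theoretical maximum accessible surface areas
(Å²).  The per-table normalization constant is the maximum pairwise
difference *within that table*, computed at load time, so each table's
contribution spans exactly [0, 1] and at least one substitution attains 1.
Normalization happens per table, before the median.

**B — hydrophobicity.**  The same construction over four scales
(Kyte–Doolittle, Hopp–Woods, Eisenberg consensus, Janin).  Because only
absolute differences are used, a scale's sign convention (hydrophobicity
vs hydrophilicity) is irrelevant.  The median of an even number of values
is the mean of the two central values.  Both A and B accept user tables
(two-column TSV) — scoring pipelines built on other published scale sets
reproduce their own numbers through this override path.

**C — charge.**  Formal charges at pH 7.4: D, E = −1; K, R = +1; others 0;
score = |Δq| / 2.  Histidine is neutral by default with a configuration
switch to treat it as +1; no other protonation modeling is attempted.

**D — steric clashes.**  The mutant side chain is built on the wild-type
backbone (N, CA, C, O and CB inherited; CB reconstructed from the backbone
at glycine sites) from ideal internal coordinates at every chi-angle set
in the rotamer library.  A clash is a van der Waals overlap

    r_a + r_b − d − allowance ≥ 0.6 Å

with a 0.4 Å hydrogen-bond allowance subtracted for polar (N/O/S) atom
pairs — the established interactive-modeling defaults; both numbers are
configuration keys.  Element radii: C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20, P 1.80 Å (overridable).  Clashing rotamers are given one chance to
escape: deterministic coordinate descent over the chi angles of the mutant
side chain *and of every clashing neighbor's side chain* (backbone fixed),
minimizing total squared positive overlap, with a 30°/10°/5° step schedule
and at most 200 objective evaluations.  This torsion-space relaxation is a
deterministic, dependency-free replacement for a Cartesian force-field
minimization; it preserves the contract that matters (does the clash
persist or disappear?) without importing a force field.  Each rotamer then
contributes 0 (never clashed), `w_relieved` = 0.5 (clash removed) or 1
(clash persists), averaged under library probabilities renormalized to sum
to one over the full library — no probability filter, since every
physically plausible rotamer informs severity.

**E — pathogenic-hotspot contacts.**  For each rotamer with library
probability strictly greater than 10 %, the residues in *direct contact*
with its side-chain atoms are enumerated: any atom pair with overlap
≥ −0.4 Å (near-touching; no H-bond allowance) makes the residue a contact,
counted once.  E = Σ p · (pathogenic contacts / total contacts), with raw
(unrenormalized) probabilities, so E ≤ Σp ≤ 1.  A contact is "pathogenic"
at position level — any known ACMG class 4/5 substitution at that position
puts it in the registry — because a hotspot residue with several
pathogenic substitutions should count once.  The registry is a TSV
(position [, wt, mut, class]); position-only rows are accepted.

## Aggregation and the decision rule

x = (ΣA..E / 3.3)·16, SPS = 1 + ⌊x + ½⌋/4, i.e. linear rescaling of
[0, 3.3] onto [1, 5] rounded to the nearest 0.25 (half-up).  3.3 is the
maximum cumulative sum observed across the full hERG variant set and is a
configuration key (`scale_max_sum`) for other channels; sums above it clamp
to 5 with a warning.  The binary call is **high risk** iff SPS ≥ 3.25,
equivalently raw sum ≥ 8.5·3.3/16 ≈ 1.7531.  For pore-domain variants an
advisory `pore_call` at SPS ≥ 2.5 is reported in a separate column — the
pore is empirically more sensitive — but it never changes the primary
call.

Positions inside the unresolved-region map are scored with D = E = 0
through the same equation (A–C mode).  The hERG map (six intervals,
domain boundaries for N-tail/PAS/N-linker/VSD/pore/C-linker/CNBHD/C-tail)
ships as editable YAML; domain boundaries drive annotation and calibration
strata only.  Structure residue numbering is taken as authored, with an
optional per-chain offset to protein numbering; the wild-type residue in
the structure is checked against the variant's stated wild type and a
mismatch is a hard error, never a silent rescore.  In multimeric channels
the mutation is modeled on one chain (default: the first), while the
clash/contact environment includes all chains, so inter-subunit interfaces
are visible.

## Rotamer library

The embedded library is a minimal backbone-independent table: canonical
gauche−/trans/gauche+ chi wells with approximate penultimate-style
frequencies, probabilities per residue summing to ≤ 1 (rare rotamers
dropped).  It is sufficient for the steric *contract* (which rotamers
exist, how likely they are, whether they fit) but it is not a
backbone-dependent library: per-variant rotamer probabilities from such a
library (and hence exact D and E values published for specific hERG
variants) are reproduced only when the corresponding library file is
supplied (TSV: residue, chi1..chi4, probability).  Proline's ring is
reduced to a chi1-like pucker parameter; side-chain construction covers
heavy atoms only, with hydrogens treated implicitly through the H-bond
allowance.

## Calibration

`calibrate` tallies ACMG classes 1–5 per SPS bin (17-bin grid) for a
stratum — all variants, non-structured positions, structured positions,
or the pore — and reports the pathogenic fraction (class 4 + 5)/total per
bin.  Invalid or missing labels are counted and excluded;
conflicting-interpretation labels should be mapped to class 3 upstream.
`saturation_fit` fits f(s) = a + b·min(s, c), b ≥ 0 — a monotone ramp with
a single breakpoint — by weighted least squares (bin totals as weights)
with the breakpoint scanned over the grid.  The breakpoint c is the
*saturation onset* of pathogenic enrichment; the bin with the largest
jump in fraction is reported as the *rupture point*.  The family is a
declared choice (recorded in the output): the breakpoint form makes
"saturation" directly readable, at the cost of assuming a single regime
change.  Constant fractions are flagged degenerate (no fit); a breakpoint
landing on the top occupied bin is flagged poor-fit (no plateau
observed).  `concordance` cross-tabulates the binary call against an
external predictor's categorical calls after an exact join on variant
identity; duplicates are rejected by name and unmatched variants listed.

## Synthetic fixtures: what they do and do not show

The fixture generators build ideal-geometry models — alpha helices
(φ −57°, ψ −47°), extended strands, a *cavity* (a designated site caged by
backbone-only glycine shells so every rotamer of the designated mutant
clashes irremediably), a *relief* arrangement (two facing residues where
the planted clash provably disappears after a neighbor chi turn), and
random atom gases for neighbor-search oracles.  Planted features are
verified at generation time with the package's own detectors plus an
exhaustive 30° chi-grid search; an infeasible request raises rather than
producing a silently wrong fixture.  Same seed and spec give byte-identical
files.

These fixtures exercise every code path (parsing, placement, clash
detection and relief, contacts, scoring, calibration) against independent
oracles, and the study-scale constants (1159-residue position range,
unresolved intervals, grid, thresholds) are the real ones.  What passing
tests do *not* show: agreement with scores computed on the experimental
cryo-EM model with a backbone-dependent rotamer library, which requires
those external inputs; fixtures are alanine/glycine-background idealized
models without the packing heterogeneity, missing atoms, or alternate
conformations of real structures (alternate locations in real files are
collapsed to the highest-occupancy conformer).

## Numerical and procedural choices

- Rounding ⌊x + ½⌋ is round-half-up; ties round toward the higher bin.
- Rotamer ordering is by descending probability with the chi tuple as a
  deterministic tie-break; identical inputs give bit-identical outputs.
- Relief objective uses *all* positive overlaps (not only those above the
  clash cutoff) so descent has a gradient near the boundary; the
  relieved/persists verdict is then taken under the unchanged clash
  criterion, including clashes the moved neighbors may have created.
- Neighbor side chains are rebuilt from their measured chi angles on the
  ideal-geometry templates when they move; atoms whose names are not in
  the template (e.g. OXT) stay fixed.
- Batch scoring preserves input order and row count; invalid rows carry
  their error message in an `error` column.
- Acceptance and test problem sizes: fixtures of 9–50 residues, 100-seed
  oracle sweeps, 380 ordered residue pairs — chosen so the whole suite
  runs in seconds while still enumerating every substitution and every
  library rotamer exhaustively.

## Known limitations

Local-only scoring (no allostery, no backbone relaxation); heavy-atom
side chains with implicit hydrogens; a backbone-independent default
rotamer library; formal integer charges (no pKa shifts); the hotspot
registry is an input, not mined automatically; the pore-specific
threshold is advisory; and the calibration fit assumes a single monotone
regime change.  The binary call is asymmetric by design: high risk is
actionable, uncertain risk is not a benign call.
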