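# spscore

Structure-based pathogenicity scoring of ion-channel missense variants,
with the cardiac hERG potassium channel (*KCNH2*, isoform 1a, 1159
residues) as the reference target.

Most newly reported *KCNH2* missense variants are clinically "variants of
uncertain significance": the five-tier ACMG classification cannot place
them without functional data that few laboratories can produce at scale.
`spscore` implements a fast structural pre-screen: from a variant's local
consequences in the solved channel structure it computes a **structural
pathogenicity score (SPS)** on the familiar 1–5 scale and makes a binary
call — *high pathogenic risk* (SPS ≥ 3.25) or *uncertain risk*.  A low
score is never interpreted as "benign".

## The score

Five components, each normalized to [0, 1]:

| score | measures | needs 3D structure |
|-------|----------|--------------------|
| A | residue size change — median over volume and surface-area tables of \|v(mut) − v(wt)\| / max-pair-difference | no |
| B | hydrophobicity change — same normalized difference, median over four scales | no |
| C | formal-charge change — \|q(mut) − q(wt)\| / 2 ∈ {0, 0.5, 1} | no |
| D | steric clashes — mutant side chain grafted at every library rotamer; each rotamer contributes 0 (no clash), 0.5 (clash relieved by torsion-space relaxation) or 1 (clash persists), averaged under renormalized rotamer probabilities | yes |
| E | pathogenic-hotspot contacts — Σ over rotamers with probability > 10 % of p·(pathogenic contacts / total contacts), against a registry of positions with known ACMG class 4/5 substitutions | yes |

The raw sum *s* = A+B+C+D+E is rescaled onto a 0.25-step grid:

    x = (s / 3.3) · 16        y = 1 + ⌊x + ½⌋ / 4

so *s* = 0 → SPS 1 and *s* = 3.3 (the maximum observed over the full hERG
variant set) → SPS 5.  Positions inside the regions with no experimental
coordinates (hERG: 132–398, 433–448, 511–519, 578–582, 598–602, 864–1159)
are scored with D = E = 0 ("A–C mode").

Any other channel can be scored by swapping the structure file, the
unresolved-region map, the hotspot registry and, if needed, the scale
maximum.

## Worked example

```python
from spscore import score_variant

bd = score_variant("p.Gly903Arg")
print(bd.A, bd.B, bd.C, bd.raw_sum, bd.sps, bd.mode, bd.risk)
```

prints (default tables):

```
0.8074  0.5492  0.5  1.8566  3.25  A-C  high
```

Position 903 lies in the unresolved C-terminal region, so only the
structure-independent scores apply: a glycine→arginine swap maximizes the
size change (0.81), strongly changes hydrophobicity (0.55) and adds a
charge (0.5).  The raw sum 1.857 scales to SPS 3.25 — exactly the
high-risk threshold, which is why glycine↔arginine substitutions dominate
the structure-free screen.  By contrast `E698K` (charge inversion, C = 1
but small size/hydrophobicity change) reaches only SPS 2.5, and `A561V`
SPS 1.5: both are called *uncertain*.

The same interface runs against a structure for the full A–E mode:

```sh
sps score --structure channel.pdb --variants variants.tsv \
          --registry hotspots.tsv --out scored.tsv --details reports/
sps calibrate --scored scored.tsv --stratum structured --out calib.tsv
sps compare   --scored scored.tsv --external alphamissense.tsv --out concordance.tsv
sps fixture   --kind structure --geometry helix --n 20 --out helix.pdb
```

`sps calibrate` tallies ACMG classes per SPS bin, reports the pathogenic
fraction per bin, and fits a monotone ramp-then-plateau curve whose
breakpoint is the saturation onset of pathogenic enrichment; `sps compare`
cross-tabulates the binary call against an external predictor
(e.g. 215 of 260 high-risk calls shared → 82.7 % concordance).

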