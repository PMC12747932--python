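# wins7

Structural analysis of the WDR5 WIN/S7 pocket switch, and single-site ITC
binding thermodynamics, for the WDR5–Kif2A system.

WDR5 is a WD40 β-propeller scaffold whose central channel (the WIN site)
binds peptides carrying a conserved arginine ("WIN motif", arginine at
position 0). Adjacent to the channel lies a cryptic hydrophobic subsite — the
S7 pocket, walled by Phe133, Phe149, Pro173 and Tyr191 — that opens when the
Tyr191 side chain rotates away and closes when it swings back. The kinesin
Kif2A (residues 114–122, arginine 117 at position 0, serine 121 at +4) is a
physiological WDR5 ligand that induces this opening; dual WIN+S7 binders are
an active drug-design axis. This package provides the quantitative toolkit
for that analysis:

- **Coordinate model and I/O** for PDB/mmCIF (author numbering canonical,
  waters first-class, altloc resolution by occupancy).
- **Kabsch superposition** with residue matching by author number or sequence
  alignment; the Cα propeller frame (residues 31–334) is the common frame for
  all comparisons.
- **Ring-rotation metric**: the Tyr191 switch observable, measured as the
  angle between least-squares ring planes after superposition, folded to
  [0°, 90°]; χ1/χ2 deltas reported alongside.
- **Interface fingerprints**: hydrogen bonds, salt bridges, cation-π,
  van der Waals contacts and water-mediated bridges under heavy-atom
  geometric criteria, including the ordered-water census of the WIN–S7
  region.
- **S7 openness**: probe-accessible cavity volume on a site-anchored grid
  with a burial ray test, classified open/closed against a midpoint-calibrated
  threshold.
- **ITC**: the 1:1 Wiseman isotherm as a forward model, a
  statsmodels-style `SingleSiteModel(...).fit()` returning N, K_D, ΔH with
  standard errors, and the decomposition ΔG = RT ln K_D, −TΔS = ΔG − ΔH at
  20 °C.
- **Synthetic generators** for every input class (rotated tyrosine pairs,
  constructed contact geometries, rigid copies with noise, hollow shells,
  a tyrosine-gated cavity, thermograms), so the full pipeline is testable
  offline with known ground truth.

## Worked example

Fit a simulated wild-type titration (0.05 mM WDR5 in a 200 µL cell, ~1 mM
peptide, 1 µL + 19 × 2 µL injections, 20 °C) and decompose the energetics:

```python
from wins7 import SingleSiteModel, TitrationSetup, simulate_thermogram

setup = TitrationSetup()                     # the conditions above
tg = simulate_thermogram(setup, n=0.91, k_d=0.78e-6, dh=-15.7)
fit = SingleSiteModel(tg, setup).fit()
print(fit.summary())
```

```
Single-site ITC fit
----------------------------------------------
N (sites)                    0.910
K_D (uM)                     0.780
dH (kcal/mol)               -15.70
dG (kcal/mol)                -8.19
-TdS (kcal/mol)               7.51
c value                       58.3
converged                     True
```

The fit recovers the generating parameters exactly on noise-free data; the
derived ΔG = −8.19 kcal/mol splits into a large favourable enthalpy
(−15.7 kcal/mol) opposed by an entropic penalty (−TΔS = +7.51 kcal/mol) — the
signature of an enthalpy-driven, conformation-ordering interaction. The
internal-consistency check over the published table of WDR5–Kif2A variant
fits:

```sh
$ wins7 itc-check
WDR5 + Kif2A(114-122)              -TdS   7.51 (published  7.48, dev 0.027)
WDR5 + Kif2A(114-120)              -TdS   2.26 (published  2.26, dev 0.001)
WDR5 + Kif2A(114-122) S121G        -TdS   3.32 (published  3.29, dev 0.027)
WDR5 + Kif2A(114-122) S121A        -TdS   5.40 (published  5.36, dev 0.040)
WDR5(Y191F) + Kif2A(114-122)       -TdS   0.93 (published  0.92, dev 0.008)
OK: max deviation 0.040 kcal/mol
```

Measure a ring rotation between two structures (here a synthetic pair with a
known 25° rotation; with local copies of deposited entries the same command
compares, e.g., the Kif2A-bound and arginine-bound structures):

```sh
$ wins7 make-fixtures fx --seed 0
$ wins7 rotation fx/tyrosine_ref.pdb fx/tyrosine_rot25.pdb --range 1:10
ring_plane_angle        25.00
```

Other subcommands: `superpose`, `fingerprint`, `pocket`, `itc-fit`,
`report`. Deposited coordinate files are consumed from local paths only;
nothing is fetched over the network.

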