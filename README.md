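# boddkit

A small crystallographic refinement toolkit that layers Gaussian
**bond-oriented deformation density** onto the independent atom model (IAM).
Two card types extend a conventional spherical-atom structure model:

- `BEDE atom1 atom2 r A B1 B2` — adds a Gaussian of amplitude `+A` (spread
  `B1`) on the bond at distance `r` from `atom1`, and subtracts the same
  amplitude (spread `B2`) at `atom1`, keeping the electron count balanced.
- `LONE m atom A B1 B2 r [angle]` — places lone-pair lobes by geometry code
  `m` (1, 2, 3, 6, 7, 9, 12, 15), with a compensating negative Gaussian at
  the atom (`-2A` for m=2, `-6A` for the twelve half-occupied lobes of m=12,
  …). The angle applies only to m = 2, 3, 7, 9.

Lobe spreads are coupled to the host atom's displacement parameter (the `B`
values multiply the isotropic Debye–Waller exponent `8π²·U_eq`; an additive
coupling is available behind a config switch). Card parameters stay fixed
during refinement; only three global scale factors `k_A`, `k_B1`, `k_B2`
(plus coordinates, ADPs and the overall scale) refine against Fo².

The package covers:

- `boddkit.shelx_io` — SHELX-style INS/RES and HKLF-4 reflection I/O,
  round-trip safe, plus an external card-file dialect and FCF output.
- `boddkit.scattering` — four-Gaussian IAM form factors, deformation form
  factors, Debye–Waller factors, complex structure factors over symmetry.
- `boddkit.geometry_typing` — covalent-radius connectivity, lobe geometry
  for every `m` code, two-shell colored environment graphs, canonical graph
  hashing, and automatic card assignment from an archetype database (exact
  hash match → templates; miss → nearest same-element record, flagged;
  heavy atoms without records stay IAM-only).
- `boddkit.refine` — damped Gauss–Newton least squares on Fo² (analytic
  Jacobian for xyz/U/scale, finite differences for the three global
  asphericity scales), riding hydrogens with a default bond elongation of
  1.14 in deformation mode, and a seeded differential-evolution fitter for
  archetype card parameters against reference intensities.
- `boddkit.metrics_maps` — R1/wR2/GooF, fold-based cross-validated
  R_complete, the bias statistic `b`, ADP mean-difference statistics, and
  difference / deformation density maps (CCP4 + text output).
- `boddkit.synthetic` — deterministic P1 toy fixtures, simulated intensity
  data, and a brute-force grid-density + FFT oracle that validates the
  analytic structure-factor path to <0.5% relative.

## CLI

```sh
boddkit simulate --fixture carbonyl_p1 --seed 3 --noise 0.02 --out work/
boddkit assign   --ins work/carbonyl_p1.ins --db work/carbonyl_p1.db \
                 --out cards.txt --report report.json
boddkit refine   --ins work/carbonyl_p1.ins --hkl work/carbonyl_p1.hkl \
                 --mode iam  --out-dir work/run
boddkit refine   --ins work/carbonyl_p1.ins --hkl work/carbonyl_p1.hkl \
                 --mode bodd --out-dir work/run
boddkit metrics  --pair work/run/carbonyl_p1_iam.res work/run/carbonyl_p1_bodd.res \
                 --hkl work/carbonyl_p1.hkl --rcomplete-k 4 --out work/metrics
boddkit maps     --ins work/run/carbonyl_p1_bodd.res --hkl work/carbonyl_p1.hkl \
                 --spacing 0.1 --out-dir work/maps
```

`--mode iam` ignores any deformation cards (with a notice) and reproduces
the conventional refinement bit-for-bit; identical seeds give byte-identical
outputs.

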