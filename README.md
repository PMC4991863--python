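# isopka

Isodesmic-reaction pKa prediction from decomposed semiempirical quantum
chemistry energies, with the benchmark statistics used to evaluate such
predictions.

## The problem and the method

Empirical pKa predictors are fast but fail silently on chemotypes missing
from their training databases — amines in particular. Electronic-structure
methods avoid that failure mode, but absolute deprotonation free energies
from fast semiempirical methods (PM6, PM6-D3H+) are far too inaccurate on
their own. The fix is an *isodesmic* (proton-exchange) reaction against a
structurally matched reference molecule of known experimental pKa:

    BH⁺ + B_ref  ⇌  B + B_ref H⁺

Because bond types are conserved, most of the systematic error cancels.
The prediction is

    pKa = pKa_ref + ΔG° / (RT ln 10)

where ΔG° is the reaction free-energy change and each species' standard
free energy is assembled as

    G°(X) = ΔH_f(X) + [G°_RRHO(X)] + ΔG°_solv(X)

from the semiempirical heat of formation, an optional rigid-rotor /
harmonic-oscillator (RRHO) free-energy correction, and a continuum
solvation free energy (SMD or COSMO). Method labels carry a trailing `*`
when the RRHO term is dropped (e.g. `PM6/COSMO*`). Per molecule and
protonation form, the lowest-G° conformer is used; structures that retain
imaginary vibrational modes at the tightest geometry-convergence tier are
discarded.

The package covers the full workflow around the (externally computed) QM
energies:

- **`isopka.thermo`** — energy records, free-energy assembly, conformer
  selection, imaginary-frequency exclusion;
- **`isopka.isodesmic`** — the isodesmic engine, the reference-molecule
  library (pyridine 5.2, ethanol 15.9, acetic acid 4.8, diethylamine 11.1,
  triethylamine 10.7, …), class corrections (+2 pH units for tertiary
  amines) and optional linear recalibration;
- **`isopka.sites`** — RDKit-based ionizable-site classification and
  enumeration of the manual start states a conformer search misses
  (C–NH2/C–OH torsions, nitrogen inversion);
- **`isopka.qmio`** — the canonical energy-table CSV plus marker-based
  MOPAC/GAMESS output parsers and a fixture generator;
- **`isopka.evalstats`** — MAD, Max AD, Modified Thompson τ outlier
  rejection, OLS regression diagnostics, and the packaged amine benchmark;
- **`isopka.cli`** — the `isopka` command (`predict`, `benchmark`,
  `enumerate`, `parse`, `fit`).

QM engine execution and 3D conformer embedding are out of scope: the
package consumes energies, it does not compute them.

## Worked example

Given an energy table `energies.csv` holding both protonation forms of the
pyridine reference and a 2-methylpyridine target (two acid-form conformers):

```csv
molecule_id,state,conformer_id,method,solvent_model,units,delta_hf,g_rrho,dg_solv,n_imaginary,convergence_tier
Pyridine,acid,c01,PM6,COSMO,kcal/mol,38.9,,-58.4,0,default_5e-4
Pyridine,base,c01,PM6,COSMO,kcal/mol,32.1,,-5.3,0,default_5e-4
2-methylpyridine,acid,c01,PM6,COSMO,kcal/mol,29.5,,-57.1,0,default_5e-4
2-methylpyridine,acid,c02,PM6,COSMO,kcal/mol,29.9,,-57.6,0,default_5e-4
2-methylpyridine,base,c01,PM6,COSMO,kcal/mol,24.7,,-5.0,0,default_5e-4
```

```text
$ isopka predict --energies energies.csv --site-class pyridine --no-rrho
     molecule_id      model reference  delta_g_kcal_mol  correction      pka  pka_display
2-methylpyridine PM6/COSMO*  Pyridine               1.1         0.0 6.006306          6.0
```

The acid-form conformer `c02` wins selection (G° = −27.7 vs −27.6
kcal/mol); the proton-exchange reaction against pyridine costs
ΔG° = +1.1 kcal/mol, and with RT ln 10 = 1.3642 kcal/mol at 298.15 K that
shifts the anchor pKa of 5.2 up by 0.8 units to a predicted pKa of 6.0 —
2-methylpyridine is the weaker acid (stronger base), as expected from the
electron-donating methyl group.

The packaged amine benchmark reproduces the published summary statistics:

```text
$ isopka benchmark --correction tertiary=+2 --exclude Diisopropylmethylamine --method 'PM6-D3H+/SMD*'
...
tertiary_amine (n=5, offset=+2.0)
  method               MAD  Max AD
  PM6-D3H+/SMD*        0.7     1.2
```

and `isopka enumerate CCNCC` lists the two nitrogen-inversion start states
required for deprotonated diethylamine.

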