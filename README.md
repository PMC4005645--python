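# rsmbind

Predicting how tightly CsrA/RsmE-family proteins bind GGA motifs from RNA
sequence and secondary-structure context, plus the binding-thermodynamics
toolkit around it.

## The problem

Csr/Rsm post-transcriptional regulation in bacteria runs on a single,
deceptively simple element: a GGA trinucleotide. The homodimeric CsrA/RsmE
protein binds exposed GGA motifs — ideally presented as an A(N)GGAX
hexanucleotide hairpin loop sitting directly on a stem — and thereby blocks
ribosome-binding sites (RBS) on mRNAs, while decoy small RNAs (RsmZ, RsmX,
RsmY) carrying many GGA motifs titrate the protein away and de-repress
translation. The same protein binds different GGA contexts with dissociation
constants spanning five orders of magnitude, from ~10 nM (canonical hexaloop
on a stem) to ~3 mM (GGA buried inside a helix), and that span is exactly
what lets one protein fine-tune a whole regulon.

`rsmbind` implements that context-to-affinity framework and the measurements
behind it, for RNA biologists and biophysicists who want to:

- **scan** an RNA (sequence + dot-bracket structure) for GGA motifs and
  predict an affinity tier for each from its structural context;
- **fit** isothermal titration calorimetry (ITC) thermograms with one-site or
  sequential two-site binding models, P + L ⇌ PL (K_d1) and PL + L ⇌ PL₂
  (K_d2), including the ΔG = RT·ln K_d and TΔS = ΔH − ΔG decomposition;
- **estimate** K_d directly from slow-exchange NMR free/bound peak integrals:
  with bound fraction f = I_bound/(I_free+I_bound) and complex concentration
  c = f·min(P_tot, R_tot), K_d = (P_tot − c)(R_tot − c)/c;
- **model** equilibrium sequestration: protein sites S partitioned among
  competing motif pools by S + Σⱼ Mⱼ·S/(K_dⱼ + S) = S_tot, giving per-site
  occupancies, translation de-repression curves and mutant rankings.

Affinity tiers map structural context to calibrated K_d ranges:

| context of the GGA | tier | K_d range |
|---|---|---|
| A(N)GGAX hexaloop on a stem; purine pentaloop ARGGA | HIGH | 5 nM – 0.5 µM |
| pentaloop without N; expanded loop; single-stranded | INTERMEDIATE | 0.5 – 10 µM |
| degraded loop geometries | INTERMEDIATE_LOW | 10 – 100 µM |
| GGA partially base-paired | LOW | 0.1 – 1 mM |
| GGA fully base-paired | VERY_LOW | 1 – 10 mM |

## Worked example

```python
import rsmbind as rb

# a synthetic hairpin with an ACGGAU hexaloop on a 4-pair stem
mol, span = rb.make_rna_with_motif(rb.PRESET_SPECS["sl2_like"], seed=3)
print(rb.to_vienna([mol]))
# >sl2_like_hexaloop_on_stem
# AUUCGGUCACGGAUGACCAAAC
# ....((((......))))....

report = rb.scan(mol)
print(report.tier_counts)
# {'HIGH': 1, 'INTERMEDIATE': 0, 'INTERMEDIATE_LOW': 0, 'LOW': 0, 'VERY_LOW': 0}
```

The scan finds one GGA (positions 11–13, 1-based), recognises the canonical
hexaloop (N=C, X=U, C-G closing pair) and assigns tier HIGH, i.e. a
predicted K_d between 5 nM and 0.5 µM.

Fitting a simulated noisy two-site thermogram (35 × 8 µl injections of
300 µM RNA into 1.4 ml of 10 µM protein dimer, 1% heat noise, generated
from the 16 nM / 185 nM reference parameters):

```python
exp = rb.make_itc(rb.sl2_reference_params(), rb.ItcDesign(), seed=11)
res = rb.fit_itc(exp, model="two_site")
print(res.summary())
# ITC two_site fit (converged)
#   T = 298.0 K, 35 injections, RSS = 4.873e-11 J^2
#   Kd1 = 1.255e-08 M (se 2.5e-09)
#   dH1 = -59.35 kJ/mol, dG1 = -45.08 kJ/mol, TdS1 = -14.27 kJ/mol
#   Kd2 = 1.758e-07 M (se 1.2e-08)
#   dH2 = -44.93 kJ/mol, dG2 = -38.54 kJ/mol, TdS2 = -6.40 kJ/mol
#   n = 1.000, q_dil = -4.150e-07 J
```

The fitted macroscopic constants (12.6 nM, 176 nM) recover the generating
values within this replicate's noise, and the decomposition shows
enthalpy-driven binding with an entropic penalty at both sites.

The same operations are available from the shell:

```sh
rsmbind simulate sl2_like --seed 3 --out hexa.vienna
rsmbind scan hexa.vienna --tsv motifs.tsv
rsmbind fit-itc thermogram.csv --model two_site --cell-conc 10e-6 --syringe-conc 300e-6
rsmbind nmr-kd integrals.csv --p-tot 5.4e-4 --r-tot 5.4e-4
rsmbind compete scenario.json
```

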