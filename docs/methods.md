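# Methods

## Scope and representation

`rsmbind` works on RNA secondary structure as *input*: each molecule is a
sequence over {A,C,G,U} (T is normalised to U, case folded) plus a
pseudoknot-free dot-bracket string of equal length. Internally coordinates
are 0-based half-open; every user-facing table and label is 1-based
inclusive (`GGA_39-41` style). No folding is performed; the CLI's `--fold`
hook is present in the interface but deliberately raises, so results never
depend on a structure predictor's choices.

A *hairpin loop* is a maximal unpaired run of at least 3 nucleotides whose
two flanking positions pair with each other. Stem length counts strictly
contiguous stacked pairs below the closing pair, with no bulge tolerance —
the simplest definition that is unambiguous to test. Unpaired runs closed by
two different helices (internal loops, bulges) and loops on a single lone
pair are treated as single-stranded context: the framework distinguishes
only loop / single-stranded / buried presentations.

## The context framework

Every GGA occurrence is classified into exactly one context class, pairing
first, geometry second:

1. all three bases paired → `FULLY_PAIRED`; one or two paired →
   `PARTIALLY_PAIRED`;
2. otherwise, if the GGA lies in a hairpin loop on a stem of ≥ 2 contiguous
   pairs ("on top of a stem"):
   - 6-nt loop reading A N G G A X with no spare nucleotides →
     `HEXALOOP_ON_STEM`;
   - 5-nt loop A R G G A with purine R → `PURINE_PENTALOOP`;
   - 5-nt loop A G G A X (N missing) → `PENTALOOP_NO_N`;
   - loop with ≥ 1 nucleotide between the A(N)GGAX window and the stem →
     `EXPANDED_LOOP`, with the insertion count recorded;
3. everything else → `SINGLE_STRANDED`.

The upstream anchor A is searched at offset −1 (AGGA) and −2 with one
intervening N (ANGGA). When both readings exist (e.g. the loop AAGGAU), the
register whose window best matches the loop geometry wins, ranked by class
canonicality (hexaloop > purine pentaloop > pentaloop-no-N > expanded >
single-stranded), then by fewer inserted nucleotides. This makes
classification deterministic without a tunable parameter. GGA cannot overlap
itself, so each occurrence is one motif.

Two geometric edge cases fit none of the named classes: a pentaloop
A(N)GGA with pyrimidine N, and an in-loop GGA with neither anchor nor
insertions. Both fall to `SINGLE_STRANDED` with an `atypical_loop` flag —
a conservative middle-tier call for a motif that is certainly exposed but
not in a measured geometry. A hairpin whose stem is a single pair is
likewise "not on a stem" and classifies single-stranded.

### Tier assignment

Base mapping: hexaloop-on-stem and purine pentaloop → HIGH; pentaloop-no-N,
expanded loop and single-stranded → INTERMEDIATE; partially paired → LOW;
fully paired → VERY_LOW. A missing anchor A demotes one tier (the anchor
adenine contributes conserved hydrogen bonds to the protein backbone). An
expanded loop with more than 4 insertions is demoted to INTERMEDIATE_LOW and
flagged as extrapolated — no construct with that geometry has been measured.
A single-stranded motif without N stays INTERMEDIATE (the arginine-stacking
/ 2′-OH binding mode compensates) but is flagged. The closing-pair identity
is recorded as a feature and does not move the tier: the recognition is by
side-chains that adapt to any closing pair.

The numeric tier bounds (5 nM–0.5 µM / 0.5–10 µM / 10–100 µM / 0.1–1 mM /
1–10 mM) are calibration choices: the measured reference affinities give
groupings and exemplar values, not boundaries, and these bounds contain
every packaged reference value while keeping tiers disjoint. They are
overridable per scan. Tier-only motifs get a point K_d as the geometric mean
of their tier bounds when an equilibrium calculation needs a number.

The packaged reference table spans 16 nM–185 nM (tightest hairpin,
two-site), 1.5–3.5 µM (pentaloops, expanded loop, single strand), 300 µM
(partially buried) and 2.7 mM (fully buried) — a ≥ 5-decade span, which the
acceptance suite asserts.

## ITC forward model and fitting

Species for the two-site model are P, PL, PL₂ with *macroscopic* sequential
constants K_d1, K_d2 — the convention in which two-site homodimer fits are
reported — and no statistical-factor conversion to microscopic constants.
Free ligand is the unique root of the mass balance
L + bound(L) = L_tot on [0, L_tot], solved with Brent's method to 1e-15
relative; tests cross-check against long bisection.

Injections use a perfusion (displaced-volume) bookkeeping: injecting volume
v dilutes existing cell totals by d = V₀/(V₀+v) and adds syringe ligand at
c_syr·(1−d), with all concentrations referenced to the active volume
V₀ = 1.4 ml. The heat of injection i is

    q_i = V₀ · (H_i − d·H_{i−1}) + q_dil,

where H is the volumetric enthalpy [PL]·ΔH₁ + [PL₂]·(ΔH₁+ΔH₂). The d·H_{i−1}
term accounts for the complex displaced out of the active volume. Two
numerical facts about this convention are pinned in tests: (a) the
single-injection heat agrees with a brute-force bisection equilibrium at the
same totals to ≪ 0.1%; (b) a 10⁴-micro-step mixing path agrees up to the
discretisation bound v/(2V₀) ≈ 0.3% for 8 µl — a discrete ladder and its
continuous limit genuinely differ at that order, for any bookkeeping.

Fitting minimises squared heat residuals over [log₁₀K_d1, (log₁₀K_d2), ΔH₁,
(ΔH₂), q_dil] with scipy's trust-region-reflective least squares (gtol
1e-10, xtol 1e-12), 8 multi-starts on a log-spaced K_d grid with seeded
jitter, and box bounds (K_d in 1 pM–1 M, |ΔH| ≤ 1 MJ/mol) that keep wild
starts finite. Stoichiometry n multiplies the cell protein concentration
(active-fraction correction) and is fixed at 1 unless freed. Standard
errors come from the Gauss–Newton covariance s²(JᵀJ)⁻¹, delta-method
transformed from log₁₀K_d to K_d. ΔG = RT·ln K_d and TΔS = ΔH − ΔG are
reported at the experiment temperature (default 298 K, R = 8.314 J/mol/K).
Noise-free self-consistency is < 0.1% for all parameters and models.

## Slow-exchange NMR estimator

In slow exchange the free and bound species give separate resonances, so
each resonance pair yields the bound fraction directly. The estimator uses
the exact quadratic mass balance; the general unequal-totals form is
implemented even though the reference titrations used equal 0.54 mM totals.
Aggregation across resonance pairs is an unweighted mean ± sample standard
deviation; a single pair reports sd = 0 with an explicit flag. Bound
fractions of exactly 0 or 1 raise (infinite/zero K_d — outside the
quantifiable range). The forward inverse (`bound_fraction_forward`) takes
the physically admissible root of the same quadratic; the round trip is
identity to 1e-9 relative across K_d from 1 nM to 10 mM.

## Sequestration model

Independent-site approximation: each motif is an independent ligand pool for
protein sites, a dimer contributes two identical sites, and no avidity /
bridging term is modelled for one dimer spanning two motifs — the observed
"both tight sites fill first" behaviour emerges from per-site affinities
alone, which is as far as per-motif K_d values can carry a quantitative
model. The site balance is strictly monotone in S, so Brent's method on
(0, S_tot) gives the unique solution; mass balance at the solution is
< 1e-9 relative (property-tested against a damped fixed-point oracle).

Translation activity is 1 − θ_RBS, normalised to the grid maximum when a
curve is reported — matching how reporter assays are normalised to full
de-repression — and raw when ranking knockouts. Scenario presets use 100 nM
protein dimer (cell-free assay conditions); the 6–17 µM cellular
concentration range is available as a named alternative. Knockout of a site
removes its pool (equivalent to K_d → ∞).

## Synthetic data

The generators are pure functions of (spec, seed) and emit the same formats
the pipeline consumes.

- **Planted-motif RNAs** mirror the measured construct geometry: hairpins
  whose loop is closed by C-G with U-A beneath, random stems at 60% GC,
  non-motif loop/flank bases drawn from {A,C,U} so no spurious GGA arises
  from single substitutions; whole constructs are resampled (bounded) until
  the planted GGA is the only one. Partial burial is planted as the stem's
  top two 5′ pairs being G-C/G-C with the A as first loop base; full burial
  as GGA/UCC mid-helix. These emulate isolated structural contexts — they do
  not emulate full-length sRNA architecture, co-transcriptional folding or
  alternative structures, so perfect classifier recovery on them shows the
  rules are implemented as stated, not that real structures are always
  correctly annotated by a single MFE-style input structure.
- **ITC thermograms** add additive Gaussian noise (instrument-like) to the
  forward isotherm; the default level is 1% of full scale. The SL2-like
  design is 35 × 8 µl of 300 µM RNA into 1.4 ml of 10 µM dimer at 298 K,
  inside the stated instrument ranges (30–40 injections of 4–10 µl, syringe
  100–600 µM, cell 5–30 µM dimer). The reference enthalpies ΔH₁ = −60,
  ΔH₂ = −45 kJ/mol are typical exothermic protein–RNA values, chosen once;
  the recovery study's target quantities are the K_d medians only.
- **NMR integral pairs** scale (1−f, f) by per-peak multiplicative lognormal
  noise (peak-integration-like); zero noise reproduces f exactly.

## Problem sizes

The recovery study uses 50 replicate thermograms (medians of 50 fits); the
classifier recovery suite uses 500 molecules per context class; property
tests run 200 randomized sequestration systems. These sizes give stable
medians and exhaust the generators' discrete geometry choices.

## Known limitations

- Tier boundaries between measured exemplars are interpolations; a motif
  near a boundary can legitimately sit in the neighbouring tier.
- No kinetics: the slow-exchange observation constrains k_off but the model
  is equilibrium-only.
- No cooperative or bridging binding terms; competition is purely through
  free-site depletion.
- The ITC model takes integrated, baseline-corrected heats; raw power traces
  are out of scope.
- Reverse-complement scanning is deliberately absent (single-stranded RNA).
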