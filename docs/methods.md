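# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations behind `fgphase`. Everything stated here is
computed by the package itself (and exercised by the test suite or
`scripts/acceptance.py`); nothing is asserted that the code does not
reproduce.

## FG motif taxonomy and precedence

An FG dipeptide is any F immediately followed by G. Since FG is a
distinct 2-mer, occurrences cannot overlap; `FGFG` contains two. Each
dipeptide is assigned to exactly one motif class by the residues around
it, with longer, more specific context taking precedence:

| rank | class    | rule (around the FG)            | masked span |
|------|----------|---------------------------------|-------------|
| 0    | GFGQ     | preceded by G and followed by Q | 4 residues  |
| 1    | GLFG     | preceded by GL                  | 4           |
| 2    | SLFG     | preceded by SL                  | 4           |
| 3    | PAFG     | preceded by PA                  | 4           |
| 4    | PFG      | preceded by P                   | 3           |
| 5    | (G/A)FG  | preceded by G or A              | 3           |
| 6    | (S/T)FG  | preceded by S or T              | 3           |
| 7    | other FG | anything else (catch-all)       | 2           |

The precedence order is a design decision forced by two constraints:
the classes must partition the total FG count (so per-class densities
sum to the overall density), and a GFGQ-dominated domain must not
simultaneously register its motifs as (G/A)FG. Context more specific
than one preceding residue therefore wins. An FG at the very start of a
sequence has no context and falls into the catch-all class.

Motif counting always runs on the full domain **including** any GLEBS
interval. This is deliberate: published motif counts and lengths
reproduce the published overall densities (e.g. 47 motifs / 737
residues → 6.4 per 100 aa) only with the GLEBS included in the
denominator. Composition statistics, by contrast, exclude the GLEBS,
and spacer composition additionally excludes each motif's full matched
span (the span widths above). Because the source tables do not state
the masked span width, `composition_profile` accepts
`full_context_spacers=False` to mask only the bare dipeptide.

Domain delimitation runs from the translation start up to and including
the G of the last FG dipeptide; cohort statistics by default keep only
domains of 400–1000 residues. Cohort dispersions are reported as both
the median absolute deviation and the population standard deviation,
because published "median ± x" figures do not specify the estimator;
the package never claims to reproduce a specific "±" value.

Sequences are upper-cased on ingest. 'X' is tolerated but excluded from
composition and hydrophobicity denominators and rejected by the
molecular-weight calculation (which uses average isotopic residue
masses plus one water, via Biopython). All residue intervals are
1-based and inclusive.

## Charge–hydropathy coordinates

The charged fraction counts D, E, K and R over the (GLEBS-excluded)
sequence length. Hydrophobicity uses the octanol/water partitioning
scale of N-α-acetyl amino-acid amides rescaled linearly to [0, 1]
(R = 0 … W = 1); the twenty values are hard-coded and tested against
their printed form. This scale is chosen over structure-derived scales
because it is not biased by globular protein statistics. Heat-map
binning uses half-open bins with the last bin closed, so points at
exactly 1.0 are counted.

## Concentration estimators

Internally concentrations are molar (mol/L) and mass concentrations
g/L (numerically mg/ml); report layers convert to nM/µM/mM and µg/ml
as appropriate.

- **Pore geometry.** The default geometry is a 80 nm × 40 nm channel
  with FG domains reaching 70 nm into nuclear and cytoplasmic space and
  48 domain copies per pore. The accepted accessible volume,
  1.5 × 10⁻¹⁸ L, is used verbatim as the default; the naive cylinder on
  those dimensions gives only 2.76 × 10⁻¹⁹ L, so the cylinder model is
  exposed as an advisory alternative, not the default — the FG cloud
  evidently extends laterally beyond the channel bore, and the exact
  geometry behind the accepted figure is not specified.
- **Ratiometric intra-particle concentration.** The calibration fit is
  a least-squares line through the origin (a dilution series of one
  fluorophore with background subtracted upstream has no intercept).
  The labelled tracer fraction is taken relative to the unlabelled pool
  by default (14 nM in 10 µM → 1/714); the total-pool convention
  (1/715) is available via a flag.
- **Critical concentration.** Where particles coexist with monomers,
  the soluble concentration estimates the saturation point; the
  estimator averages those points and also reports the coarse bracket
  (highest fully-soluble total, lowest particle-forming total). The
  particle-detection threshold `rel_tol` decides when a point counts as
  phase-separated; for noisy data it should sit at a few standard
  deviations of the relative measurement noise, otherwise fully-soluble
  points leak into the average and bias it downward.
- **Traversal time.** The default convention is L²/(2D), the 1-D mean
  first-passage time to an absorbing far boundary; with L = 40 nm and
  D = 0.1 µm²/s this gives 8 ms. L²/(6D) and L²/D are selectable.

## Partition–diffusion solver

Geometry is a sphere of radius *a* (particle) inside a concentric
sphere of radius *b* (buffer bath), with zero flux at r = 0 and r = b.
The interface follows a radiation-type law J = α κ₀ (c_out − c_in/K):
α is the capture probability of a colliding complex and κ₀ a collision
velocity scale. κ₀ defaults to 10³ · D_buffer / a, which places α = 1
deep in the transport-limited regime where the interface behaves as the
local-equilibrium jump c_in = K c_out; this is one consistent reading
of a scalar "capture efficiency", and the sensitivity analysis
(capture efficiency non-limiting) is robust to the exact value.

Discretisation is conservative finite-volume on a radial grid whose
particle surface coincides with a cell face (default 60 cells inside,
100 outside). Fluxes between cell centres use series resistances; the
interface face adds the 1/(α κ₀) resistance and the K-scaled
inner-half-cell resistance, so the discrete flux is
G · (c_out − c_in/K). Time stepping is backward Euler with a geometric
ramp (small steps through the initial interfacial transient, growing to
t_end/400), which is unconditionally stable and conserves total mass to
the accuracy of the direct tridiagonal solve (observed drift ≲ 10⁻¹⁰
relative). Runs are deterministic. At the reference parameters, halving
the step cap and doubling both grids changes the 180-s metrics by far
less than 1%.

Verification uses three independent oracles: (i) the closed-form
finite-bath equilibrium c_out,∞ = c₀ V_b/(V_b + K V_p); (ii) the
classical eigenfunction series for diffusion into a sphere with fixed
surface concentration (matched to <1% with K = 1, fast buffer and a
deep bath); (iii) a two-compartment ODE for the surface-limited,
well-mixed-particle FRAP regime, whose exact time constant
τ = [(3ακ₀/a)(1/K + V_p/V_b)]⁻¹ the fitted exponential reproduces to
2%.

The bath radius defaults to 5 a. This keeps the domain small and the
equilibrium intra/extra *ratio* exactly K, but note that with K = 220
the bath is substantially depleted at equilibrium (V_b/V_p = 124, so
c_out falls to V_b/(V_b + K V_p) ≈ 36% of c₀). Absolute equilibrium
levels therefore depend on b, and experiments with an effectively
infinite buffer reservoir should be modelled with a larger bath; the
FRAP scenario below does exactly that.

**FRAP.** Full-particle bleach only: the particle starts dark, the bath
at c₀, and recovery (mean intra signal normalised to the pre-bleach
level K c₀) is fitted with A(1 − e^(−t/τ)). Hemispheric bleaches are
not spherically symmetric and are out of scope. The headline FRAP
scenario uses a 10 µm particle (radius 5 µm, the size of the in-vivo
assembled FG bodies probed this way) in a deep bath (b = 100 µm,
bath depletion ~18%) at the reference transport parameters, giving
τ ≈ 49 s — the same order as the measured ≈100 s, which is all the
comparison supports, since the real particle geometry, probe position
and reservoir are not fully specified. Rescaling by (L/a)² to a 40-nm
barrier gives ~3 ms, i.e. "a few milliseconds".

**Sensitivity.** One-at-a-time factors (default: halve/double D_buffer,
K, D_particle; α over 0.1–1) on the mean intra-particle concentration
at 180 s. The baseline row re-runs the unmodified parameters through
the identical deterministic path, so it is bitwise equal to a direct
simulation.

## Synthetic-data generators

The generators define the study conditions for all round-trip tests;
they emulate the *structure* of the real inputs, not their full
realism.

- **Sequences.** Domains are assembled by alternating sampled spacers
  and sampled motifs. Length ~ Normal(549, 87) clipped to [400, 1000]
  and FG density 8.0 per 100 aa by default — the conserved cohort
  medians (one motif per 12.5 residues, ~43–44 motifs per domain).
  The default motif mixture is GLFG/SLFG-dominated (fungal-flavoured);
  the default spacer composition is dominated by T, S, G, A, N, Q and P
  with ~2.5% charged residues and no F (so spacers cannot spawn
  spurious FG dipeptides). Junction guards resample the few flanking
  letters that could re-classify a planted motif (a spacer P before
  AFG, a Q after GFG), and every generated record is verified against
  the classifier, so the ground-truth ledger is exact by construction.
  Optional GLEBS-like inserts use a markedly charged composition.
  What these sequences do **not** emulate: positional autocorrelation,
  real spacer-length distributions, NQ-rich blocks, or inter-species
  covariation — so passing round-trip tests demonstrates estimator
  correctness, not biological realism.
- **Clouds.** Charge/hydropathy points are clipped Normals with cohort
  defaults: IDP-like 28 ± 7% charged, globular-like 24 ± 3%, FG-like
  2.5 ± 0.4% (hydrophobicity centres 0.40/0.47/0.46, chosen so FG-like
  ≈ globular ≫ IDP-like in hydrophobicity while the charge ordering is
  FG < globular < IDP). Real clouds are empirical databases; only these
  summary statistics are reproduced.
- **Calibration / titration.** Linear signal model with relative
  Gaussian noise; soluble = min(total, c_crit) with relative noise,
  clipped to [0, total]. Zero-noise inversion is exact by construction
  and tested as such.

Seeding: one root seed per run; the acceptance script derives
independent child streams per stage from the root seed.

## Problem sizes

Defaults are sized so the full test suite runs in seconds on one CPU:
simulations use ~160 radial cells and a few hundred implicit steps,
Monte-Carlo recoveries use 100 replicates, the classifier oracle runs
on 10,000 random sequences, and synthetic cohorts use 100–300 domains.
All sizes are parameters and can be raised for production analyses.

## Known limitations

- The motif taxonomy is Nup98-centric; FxFG-type motifs common in other
  FG nucleoporins all land in (S/T)FG or the catch-all class.
- GLEBS intervals must be supplied (header token, map file or config);
  alignment-based GLEBS detection is out of scope.
- The solver is strictly spherically symmetric: no hemispheric
  bleaches, no multi-species competition, no NTR–FG binding kinetics
  inside the phase (partitioning is collapsed into K).
- The cylinder model for the pore's accessible volume underestimates
  the accepted figure and is advisory only.
- Published critical-concentration triples for two of the ten reference
  domains (CeNup98, AtNup98B) are not mutually consistent at their
  printed rounding; the consistency tests hold them to a loose
  factor-of-2 check and the rest to the printed 1–2 significant-figure
  rounding.
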