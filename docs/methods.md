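# Methods

## The problem

HP1 proteins dimerize, bind H3K9me2/3-marked nucleosomes through their
chromodomain (CD), and bridge nucleosomes through chromoshadow-domain
(CSD) dimerization. Intervals co-enriched for HP1 and H3K9me3 *outside*
constitutive heterochromatin — heterochromatin-like domains (≥ 100 kb) and
complexes (10–100 kb) — behave like the minority blocks of a block
copolymer: HP1 bridging compacts them and drives micro-phase separation
from flanking euchromatin. This package implements (1) the genomic census
of such intervals from binned fold-enrichment tracks and (2) the
thermodynamic bookkeeping that assigns them a Flory–Huggins χ and a
segregation product χN.

## Genomic survey

**Tracks and coordinates.** All coordinates are 0-based half-open. Tracks
are fixed-width bins (window 5 kb for mammal/fly-scale genomes, 200 bp for
yeast-scale; both are presets, any width is accepted); bin *i* covers
`[i·w, min((i+1)·w, L))` and the final bin of a chromosome may be partial.
bedGraph records are averaged into bins weighted by overlap length;
uncovered positions count as 0 enrichment (fold-enrichment tracks are
dense — absence means no enrichment, not missing data). Signal mass
(value × covered length) is conserved by the binning.

**Mask membership.** A bin is inside an interval set iff its midpoint is.
This is the rule for the constitutive-heterochromatin mask in the
correlation survey and for assigning bins to intervals in the simulator
and the caller. It is order-independent and unambiguous at bin resolution;
any rule based on partial overlap would need an arbitrary threshold.

**Correlation.** Pearson's r over the retained bins (the survey is defined
in terms of Pearson). Bins where both tracks are zero are retained —
co-absence is informative. Values are correlated untransformed by default
(`log2` flag available). Correlations within 10⁻¹² of ±1 are snapped to
exactly ±1 so the degenerate perfect cases (self-correlation, affine
negation) return mathematically exact values; this is a presentation
choice, not a statistical one. Fewer than 3 retained bins is an error.

**Caller.** Per track, maximal runs of bins ≥ τ become bp intervals; runs
separated by ≤ merge_gap merge (default one bin width — the smallest gap
distinguishable at track resolution). HP1 isoforms are combined by union
(a call needs at least one isoform; intersection-of-all is a flag), then
intersected with the H3K9me3 set. Under the outside-heterochromatin mode a
call is dropped when ≥ 50% of its length overlaps the mask (midpoint and
any-overlap policies are selectable). Survivors ≥ 10 kb are classified
half-open: [10 kb, 100 kb) complex, [100 kb, 1 Mb) domain, ≥ 1 Mb large
domain — half-openness resolves the touching published bounds
deterministically. τ defaults to 2.0-fold; there is no canonical published
value, so it is exposed and recorded in outputs. Raising τ never increases
called bp; raising merge_gap never increases call count; outside-mask
counts never exceed whole-genome counts (all property-tested).

## Synthetic data

The generator emulates the statistical structure of a multi-mark
ChIP-seq co-localization study:

- **Planted truth**: non-overlapping labelled intervals with sizes uniform
  per class — large domains 1–4 Mb, domains 0.1–1 Mb, complexes
  10–100 kb (half-open, so a planted label always matches the caller's
  classification). Placement is largest-first into uniformly chosen free
  gaps with a minimum separation (default 50 kb, comfortably above the
  default merge gap); boundaries are snapped to the bin grid in the bundle
  constructor so that planted truth is exactly observable at track
  resolution.
- **Tracks**: background 1.0 (no enrichment over input) outside planted
  territory; 8.0-fold mean enrichment inside (a typical strong
  HP1/H3K9me3 ChIP enrichment). With probability `coloc` (default 0.8) an
  interval carries all marks, else exactly one — co-localization is an
  interval-level property, matching the caller's interval-intersection
  logic. Multiplicative log-normal noise with unit mean and CV 0.3
  (default) keeps tracks non-negative, as befits a ratio quantity.
- **Mask structure**: inside the constitutive-heterochromatin mask every
  mark is enriched and multiplied by *one shared* log-normal spatial field
  (CV 2.0). Real pericentric territories have strong repeat-driven
  coverage structure seen alike by every heterochromatin mark; it is what
  drives within-heterochromatin correlations toward unity. A flat plateau
  would have no signal variance and within-mask correlation would be
  noise-dominated — the opposite of what is observed. The field's CV is
  chosen so that the shared structure dominates the per-mark noise.

Determinism: one `SeedSequence` per bundle spawns a stream for mark
assignment plus one per chromosome for noise and for the mask field, so
identical parameters give bit-identical bundles.

**What the simulator does not emulate** (and hence what passing tests do
not show about real data): read-level sampling noise, fragment-length and
GC effects, input-normalization artifacts, replicate structure,
mappability gaps, and any correlation between interval placement and
genomic features. Recovery of planted truth shows the pipeline's logic is
correct at track resolution, not that a particular published census is
reproduced; reproducing published counts would require the original
processed tracks and their (unstated) upstream peak-calling.

## Clutch thermodynamics

The unit of incompatibility is the oligo-nucleosomal clutch (2–10
nucleosomes, modelled at six), not the nucleosome. For a
heterochromatin-like clutch (HC) vs a euchromatic clutch:

χ_HC = (H_CD + H_CSD − H_COMP − m·H_TL)/T + S_COMP

- `H_CD`: CD–H3K9me3 binding summed over bridges in the clutch;
- `H_CSD`: CSD–CSD dimerization summed over bridging dimers;
- `H_COMP`: compaction potential energy (linker elasticity + steric
  exclusion);
- `H_TL`: terminal-linker elastic energy at the junction with euchromatin;
  m = 2 for a domain/complex flanked on both sides;
- `S_COMP`: excess entropy given up on compaction.

**Units**: H-terms are energy/k_B (kelvin), S_COMP is in k_B, T in kelvin
— χ is then dimensionless and the 1/T scaling is literal. **Signs**:
favorable binding terms are entered as positive magnitudes (they carry a
plus sign in χ); whether S_COMP is negative "by construction" is left to
the caller, as the framework itself does not fix it. With every term zero
(no HP1) χ_HC = 0: the marked clutch is thermodynamically equivalent to a
euchromatic one. The terminal linker opposes separation, so severing it
(chromatin fragmentation) can only increase χ_HC. No magnitudes are
asserted for any term: the module computes χ from user-supplied values.

The classical monomer-level routes are provided for comparison: the
mean-field lattice form, the dispersive form (3/8 coefficient, shared-I
approximation with a warning beyond 10% mismatch), and the empirical
α/T + β form. Note that substituting the pairwise dispersive energies into
the lattice form with I_i = I_j and V = r³ yields coefficient 3/16, not
the 3/8 of the dispersive χ formula as printed; the difference hinges on a
contact-counting convention that the source derivation does not spell
out. The formula is implemented exactly as printed and the tension is
documented here rather than resolved.

An optional HP1–HP1 cooperative term can be added by callers as an extra
positive contribution to `H_CSD`; no dedicated term is implemented.

## Order–disorder transition and profiles

The RPA structure factor of a diblock diverges when χN reaches
min_x F(x, f)/2, with x = q²R_g² and

F = g(1,x) / [g(f,x)·g(1−f,x) − ¼(g(1,x) − g(f,x) − g(1−f,x))²],
g(f,x) = 2(fx + e^(−fx) − 1)/x².

At f = ½ the minimum is χN_s = 10.495 ("around 10.5"). Numerics: g uses a
3-term series for f·x < 10⁻⁴ (cancellation guard; the seam is tested
against the exact branch), the minimization is a 1024-point log-spaced
grid scan (the quotient diverges as x → 0) followed by Brent refinement to
10⁻⁸, and an edge-of-grid minimum is an error rather than a silent answer.
Chromatin caveats are parameterized, not modelled: semi-flexible
(worm-like) chains have their own thresholds, so every consumer takes
`chiN_ODT` as an input with the flexible-chain RPA value as default.

Regimes: χN < ODT disordered; ODT ≤ χN < 5·ODT weak/"wavy" (liquid-like
interfaces); ≥ 5·ODT strong/"sharp". The factor 5 is a package choice —
the distinction is qualitative (χN ≫ ODT) — and is exposed everywhere.

Profiles ϕ_A(r_⊥), lamellar period 2π/q* with q* = √(x*)/R_g, R_g = b√(N/6),
repeat length b = 1 by default:

- **weak**: ϕ_A = f + A·cos(q*r), A = min(f, 1−f)·√(1 − ODT/χN). The
  amplitude law is phenomenological — theory fixes only the scaling near
  the threshold — chosen for continuity at the ODT (A → 0), saturation
  well above it, and hard bounds 0 ≤ ϕ_A ≤ 1.
- **strong**: square wave with A-block fraction f per period, each
  interface smoothed by ½[1 + tanh(2(r − r_edge)/w)] with the standard
  strong-segregation (Helfand-form) width w = 2b/√(6χ); neighbouring
  periods' tails are included so the window edges are correct and the
  spatial mean equals f over whole periods (tested to 10⁻³).

Profile sharpness (max |dϕ_A/dr|) increases monotonically in χN across the
weak → strong handover, reproducing the wavy-to-sharp progression.

## Loop-extrusion mixing

Extrusion of a domain/complex through cohesin converts ATP hydrolysis into
heat via friction with the nucleoplasm, disrupting HP1 bridging. The model
is deliberately minimal: an activity E ≥ 0 subtracts from the segregation
product, χN_eff = χN − E, and a call remains separated iff χN_eff ≥ ODT.
Any monotone alternative can be plugged in via the `effective_chiN` hook.
Consequences, all tested: the mixed set grows monotonically with E; at
fixed χ, small-N complexes mix before large-N domains; E = 0 reconstitutes
every call above threshold (cohesin-loss regime), moderate E mixes only
small complexes (wild type), large E mixes everything (unrestrained
extrusion regime).

## Problem sizes

The shipped analysis and the test suite run on synthetic genomes of
2 × 20 Mb at 5 kb bins with ~14 planted intervals per bundle, and on
randomized parameter grids of 10²–10³ points for the monotonicity
properties — sizes at which every check runs in seconds while exercising
all code paths, including multi-chromosome bookkeeping and partial final
bins.

## Known limitations

- The census is qualitative with respect to any published table: peak
  definitions, input normalization and masks of the original datasets are
  not recoverable from the package's inputs.
- Eq-level χ values are only as good as the supplied clutch energies; the
  package fits nothing to calorimetric or imaging data.
- The RPA spinodal is a mean-field result for flexible chains; fluctuation
  corrections and semi-flexibility shift real thresholds.
- The full phase diagram (cylinders, spheres, gyroid) is out of scope; only
  the lamellar spinodal and 1-D profiles are computed.
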