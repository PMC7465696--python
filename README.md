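# hetchrom

Tools for surveying **heterochromatin-like domains and complexes** —
genomic intervals outside constitutive heterochromatin that are co-enriched
for an HP1 isoform and H3K9me3 — and for reasoning about their
**micro-phase separation** from euchromatin with block-copolymer
thermodynamics in which the repeat unit is the oligo-nucleosomal *clutch*.

It is aimed at chromatin biologists and biophysicists who want to (a) run a
domain/complex census on binned ChIP-seq fold-enrichment tracks, and (b)
put numbers on the tendency of such intervals to demix, via the
Flory–Huggins parameter χ and the segregation product χN.

## What it computes

**Genomics half.** From bedGraph fold-enrichment tracks binned at a fixed
window (5 kb for mammals/fly, 200 bp for fission yeast):

- windowed Pearson correlation of each HP1 isoform with H3K9me3, genome
  wide, outside a constitutive-heterochromatin mask, or restricted to it;
- domain/complex calls: runs of bins ≥ τ-fold enrichment per track, HP1
  isoforms combined by union, intersected with H3K9me3, classified by
  length into complexes [10 kb, 100 kb), domains [100 kb, 1 Mb) and large
  domains (≥ 1 Mb), with census tables per region mode.

A fully seeded synthetic-data generator plants ground-truth intervals and a
heterochromatin mask, so the whole pipeline is testable without downloads.

**Polymer half.** For an A/B diblock with composition *f*, repeat count
*N* and incompatibility χ:

- χ from mean-field lattice contacts, χ_AB = (z/k_BT)[ε_AB − ½(ε_AA+ε_BB)];
  from dispersive interactions, χ = (3/8)(I/k_BT)(z/V²)(α_A−α_B)²; or
  empirically, χ = α/T + β;
- the clutch-level χ for a heterochromatin-like clutch against a
  euchromatic clutch,
  χ_HC = (H_CD + H_CSD − H_COMP − m·H_TL)/T + S_COMP, with m = 2 when the
  domain/complex is flanked by euchromatin on both sides;
- the RPA spinodal χN_s(f) = min_x F(x, f)/2 (≈ 10.5 at f = ½ — the
  order–disorder threshold of a flexible symmetric diblock), lamellar
  composition profiles ϕ_A(r_⊥) in the weak ("wavy") and strong ("sharp")
  segregation regimes, and a loop-extrusion mixing model in which extrusion
  activity E reduces the effective segregation product (χN − E), so small
  complexes mix with euchromatin before large domains do.

All genomic coordinates are 0-based half-open (BED/bedGraph native);
there is no strand handling anywhere.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
40 Mb genome; each step prints what it found and writes tables under
`results/`.

```sh
python analysis/01_simulate_tracks.py
python analysis/02_coloc_survey.py
python analysis/03_call_domains.py
python analysis/04_clutch_chi.py
python analysis/05_odt_profiles.py
```

Step 02 prints the survey table; for the default bundle (80%
co-localization, 30% noise):

```
mark  region_mode     r  n_bins  window
HP1a whole_genome 0.908    8000    5000
HP1a exclude_mask 0.839    7338    5000
HP1a    mask_only 0.905     662    5000
...
```

Correlation is strongest inside constitutive heterochromatin, and the
whole-genome value always dominates the outside-mask value — including
heterochromatin can only strengthen the correlation. Step 03's census
recovers the planted composition outside the mask, and step 05 prints the
spinodal curve with its minimum at the symmetric composition:

```
χN_s(0.5) = 10.4949  (rounds to 10.5)
χN =  11.0: weak_wavy    max |dphi/dr| = 0.093
χN = 100.0: strong_sharp max |dphi/dr| = 2.233
```

i.e. just above the threshold the lamellar interfaces are shallow and wavy
(liquid-like), far above it they are sharp and discrete.

The same operations are available as a CLI (`hetchrom simulate|coloc|call|
chi|mixing|odt|profile`); see `hetchrom --help`.

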