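# hylquant

Quantitative analysis of **hydroxylysine (Hyl)** modification in recombinant
antibodies produced by CHO cell culture, and of the process factors that
drive it.

Lysine hydroxylation by procollagen-lysine 2-oxoglutarate 5-dioxygenases
(PLOD1/2/3) appears in peptide maps as a +15.9949 Da ("Oxidation") shift on
lysine. In T-cell bispecific antibodies it concentrates at a hot-spot
Xaa-Lys-Gly motif (the C-terminal K of the tryptic peptide `LTVLSSASTK`,
K350 in heavy-chain numbering). The modification blocks tryptic cleavage,
so the modified material is strongly enriched in the miscleaved species —
quantifying the correctly cleaved peptide alone grossly underestimates site
occupancy. This package implements the complete computational chain from
peptide-level evidence to process-level interpretation, plus seeded
synthetic-data generators with recorded ground truth for every input.

## What it computes

**Peptide map machinery** (`hylquant.peptide_core`) — fully specific tryptic
digestion (K/R, not before P) with modification-aware blocked-site handling,
monoisotopic peptide and singly charged b/y fragment masses, ppm deviations,
XKG/XKA/XKS consensus-motif scanning, and empirical −2..+2 flanking-residue
probability matrices.

**Relative quantification** (`hylquant.quant`) — the missed-cleavage-aware
pooled-area estimator for a lysine locus,

```
frac_modified = (Kox_0mc + Kox_1mc) / (K_0mc + K_1mc + Kox_0mc + Kox_1mc)
```

over XIC areas of the four informative species, locus reports with
species rows and sums, wild-type-vs-knockout percentage reductions, and the
miscleavage-enrichment diagnostic.

**Culture kinetics** (`hylquant.kinetics`) — trapezoidal IVCD, cell-specific
rates `q_i = ΔC_i/Δt_i / X̄_i` (qP in pg/cell/day, qS_Iron in fmol/cell/day,
negative = consumption), per-cell iron availability, and the product
mass-balance deconvolution `F_n·P_n = F_{n−1}·P_{n−1} + ΔP_n·g_n` that turns
the *cumulative* modified fraction F of harvested product into the
*newly-formed* fraction g per interval — exactly, or through a parametric
sigmoid / two-logistic (dip-and-recovery) fit.

**Response models** (`hylquant.response`) — per-peptide max normalization
and non-linear least-squares fitting of the fixed-top Emax dose-response
`y(C) = b + (1−b)·C/(EC50+C)` with a parametric-bootstrap 95% CI for the
iron titration, and additive OLS attribution of Hyl reduction to PLOD1/2/3
knockouts with contribution shares.

**Synthetic data** (`hylquant.simulate`) — seeded generators for evidence
tables, fed-batch trajectories (including a day-6 dip in g(t)), titration
and knockout panels; at zero noise each generator composed with the matching
estimator is the identity.

## Worked example

```sh
python analysis/01_simulate_inputs.py   # seeded inputs under results/synthetic/
python analysis/03_quantify_hyl.py
```

prints

```
K350 wild type: 12.7% (cleaved 4.9% + miscleaved 7.8%)
K350 PLOD1-3 KO: 0.9%
knockout reduction at K350: 93%
modified fraction within miscleaved species: 69% vs within correctly cleaved: 6% ...
```

i.e. roughly an eighth of the hot-spot lysines carry the hydroxyl in the
wild type, two thirds of that signal sits in the miscleaved species, and the
triple PLOD knockout removes 93% of it. The remaining drivers compute the
culture kinetics (IVCD ≈ 1.1×10⁸ cell·day/mL, qP ≈ 25 pg/cell/day, qS_Iron ≈
−0.4 fmol/cell/day), recover the mid-process dip in newly-formed Hyl near
day 6, fit the iron EC50 (≈4 µM, below 10 µM), and attribute about half of
the total reduction to PLOD3.

The same stages are scriptable through the CLI:

```sh
hylquant simulate --seed 5 --out syn
hylquant quant syn/evidence.csv
hylquant dose-response syn/dose_response.csv
hylquant run --config pipeline.yaml
```

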