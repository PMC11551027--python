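# Methods

## Digestion and mass bookkeeping

Trypsin is modelled as fully specific: cleavage C-terminal to K or R unless
the next residue is proline. Peptides with 0..`max_missed_cleavages` missed
cleavages are emitted as all contiguous joins of consecutive zero-miscleavage
peptides; the missed-cleavage count of a species is defined on the
*unmodified* sequence (internal K/R-not-before-P sites strictly before the
C-terminus). Hydroxylation of a lysine suppresses its tryptic cleavage, so a
modified K at a cleavage site is additionally treated as a candidate blocked
site: the species spanning it is emitted even when the miscleavage budget is
0. The count still reports it as one missed cleavage — that is how search
engines label the long Hyl species, and it keeps counting independent of
modification state.

Chains may contain `X` placeholder residues (unresolved CDR stretches). `X`
is digestible (never a cleavage site, treated as non-proline for the
exception) but peptides containing `X` have no defined mass; mass operations
reject them rather than guessing.

Masses are standard monoisotopic residue masses (≥5 decimal places), water
18.010565 Da, proton 1.007276 Da, oxygen 15.994915 Da. The hydroxylysine
residue mass is K + O = 128.09496 + 15.99491 = 144.08988 Da; the printed
forms 15.9949 and 15.9950 are the same delta at different rounding.
Fragment ions are singly protonated b/y series; y_n sums the last n residue
masses (plus any modification deltas) + water + proton. The y series is
emitted through y_n (= M+H); b_n (the full peptide) is conventionally not
reported.

Motif scanning treats each template as Xaa-Lys-Zaa: any residue, K, then the
+1 residue class (G for the canonical collagen consensus; A and S for the
alternative acceptor motifs). A chain `X` at +1 never matches — unknown is
not evidence. The flanking-residue matrix at offsets −2..+2 uses plain
empirical frequencies without pseudocounts; windows truncated by chain
termini renormalize over the residues actually observed at that offset, so
no flank is fabricated.

## Pooled-area quantification

For one modifiable lysine locus the estimator pools XIC areas of four
species — modified/unmodified crossed with correctly cleaved / miscleaved —
and reports

    frac_modified = (Kox0 + Kox1) / (K0 + K1 + Kox0 + Kox1).

Per-species fractions share the same denominator, so they sum exactly to the
locus total. Properties relied on elsewhere: the estimate is invariant to
global rescaling of areas, and it is algebraically exact on noiseless
synthetic evidence for any (f, p_mc, p_block) because numerator and
denominator both reduce to multiples of the locus abundance.

Records with more than one missed cleavage are folded into the miscleaved
term by default with a logged warning (the searches behind such tables allow
one missed cleavage, so the 1-mc term denotes "not correctly cleaved"); a
strict mode drops them. Evidence covering the locus but with the
modification localized to a *different* residue is excluded from the pools
entirely — it carries no information about this site's occupancy. One known
ambiguity: when two modifiable lysines are adjacent loci (the miscleaved
species of one ends at the other), the unmodified miscleaved species
genuinely covers both, and its area enters both denominators. Reports
format percentages at one decimal place; values detected but below the
quantification floor (default 0.1%) print as `<0.1`. Knockout reductions
`(f_wt − f_ko)/f_wt × 100` are reported rounded to the nearest integer and
may be negative (a knockout can raise the level).

## Culture kinetics

Sampling uses fixed units: time in days, viable cell density (VCD) in
cells/mL, product in mg/L, iron in µM. IVCD is the trapezoidal cumulative
integral of VCD (cell·day/mL, zero at the first sample). Cell-specific
rates divide the per-interval concentration slope by the interval-mean VCD;
the interval mean is chosen to be consistent with the trapezoid, which makes
the discrete forms agree with the continuous balance dC/dt = q·X to second
order in the sampling step. Both conversions share one factor:
(mg/L/day)/(cells/mL) = 10⁶ pg/cell/day and (µM/day)/(cells/mL) =
10⁶ fmol/cell/day; iron per cell is µM/(cells/mL) × 10⁶ = fmol/cell.
Positive rates are production, negative consumption.

## Cumulative-to-newly-formed deconvolution

The measured modified fraction F_n of harvested product is a ΔP-weighted
average over everything synthesized so far, while the biology acts on the
product made now. With the product pool starting at P₀ (default 0 at day 0;
a carried-over pool can be supplied as P₀/F₀):

    F_n · P_n = F_{n−1} · P_{n−1} + ΔP_n · g_n

Exact inversion solves for g_n per interval; intervals with ΔP ≤ ε (default
1 mg/L, below assay resolution) carry no information and are reported
missing. Every F_n is a convex combination of {F₀, g₁..g_n}, and inversion
composed with the forward model is the identity to machine precision.

The parametric route fits g(t) — a single logistic (g_start, g_end, t_mid,
slope) or a two-logistic down-step/up-step family for the mid-process
dip-and-recovery shape — by least squares on the cumulative scale, with g
evaluated at interval midpoints and parameters bounded to keep g in [0, 1]
and transitions inside the sampled horizon. A near-flat fit (|g_start −
g_end| < 10⁻⁴) is flagged: the transition time and slope are then
unidentifiable, as they should be.

## Iron dose-response

Observed cumulative Hyl levels per iron concentration are normalized per
peptide by the maximum per-concentration mean, then fitted with the
fixed-top Emax model y(C) = b + (1−b)·C/(EC50+C) by bounded non-linear
least squares. The baseline b is free because cultures at 0 µM *added* iron
still carry residual iron from the inoculum; the Hill slope is fixed at 1
(no cooperativity assumed for a cofactor titration; a free-slope variant
sits behind a flag). The 95% CI for EC50 is a parametric residual bootstrap
(default 1000 seeded resamples) with the residual scale drawn per replicate
from its chi-square distribution so variance uncertainty is carried into
the interval; bootstrap refits use an equivalent profiled 1-D solver (the
baseline enters linearly, so it has a closed form per candidate EC50),
vectorized over replicates.

A deliberate consequence of this exact procedure: when the top tested
concentration does not fully saturate the curve (60 µM at EC50 6 is ~92% of
the asymptote), normalization pegs that point at 1 while the fixed-top model
predicts less, so the fitted EC50 lands below the generating value even at
zero noise (≈4 µM vs 6). The bias is deterministic and conservative with
respect to the "EC50 below 10 µM" conclusion; on data already on the
model's own scale the fit is exact, which is how the round-trip tests are
phrased.

## Knockout attribution

Observed Hyl levels across knockout combinations are fitted by ordinary
least squares on an additive model: level ~ 1 + ko1 + ko2 + ko3, accepting
binary indicators or continuous KO scores. Each negative coefficient is a
reduction attributable to that isoenzyme; shares normalize the reductions
to 100%. Positive coefficients (a knockout apparently raising the level)
are excluded from the shares and flagged, not silently clipped; a
rank-deficient design raises an error naming the confounded columns.

## Synthetic data: what it emulates, and what it does not

The generators emulate the *designs* of the real experiments at realistic
magnitudes, with ground truth recorded alongside:

- **Evidence**: per locus, the modified pool f·T splits between miscleaved
  (blocked, probability p_block) and cleaved species, the unmodified pool by
  the baseline miscleavage probability p_mc; log-normal area noise.
  Defaults: hot-spot fraction 0.12, p_mc 0.05, p_block 0.6 (≈40/60
  cleaved/miscleaved split of the modified signal).
- **Culture**: logistic VCD growth 2×10⁶ → 2×10⁷ cells/mL at 0.5/day —
  typical CHO fed-batch magnitudes, and a growth curvature at which the
  daily-sampling discretization error of rate recovery stays within 2% —
  constant qP 25 pg/cell/day, qS_Iron −0.4 fmol/cell/day from 60 µM initial
  iron (declining to ~16 µM; full depletion clips at zero with a warning),
  11 daily samples, and a two-logistic g(t) dipping from 0.10 to ~0.02
  around day 6 with recovery to 0.08. Observed concentrations are clipped
  at zero (assays report no negative values).
- **Panels**: Emax titration truth EC50 6 µM, baseline 0.15, concentrations
  0–60 µM, 3 replicates, Gaussian σ 0.05 of the saturation level; knockout
  truth wild type 0.12 with reductions (0.028, 0.027, 0.055) — PLOD3 ≈ half
  of the total — over all eight KO combinations, σ 0.004.

Not emulated: raw spectra or chromatograms (evidence enters at the
peptide-area level), retention behaviour, site-localization ambiguity,
feed/shift events as discrete process dynamics, clonal variability, or any
transcript-level behaviour. Passing tests therefore demonstrate estimator
correctness and round-trip consistency under the stated noise models, not
robustness to the full messiness of instrument data.

## Numerical choices

Digestion and quantification are exact arithmetic. Optimizers: bounded
trust-region least squares (tolerances 10⁻¹²) for the deconvolution fit and
the Emax point estimate. Problem sizes throughout (daily sampling over 10
days, 21-point titration panels, 24-row KO panels, 200-replicate
simulation studies) match the scale of the emulated experiments. Ties and
degenerate inputs: zero total area, zero wild-type fraction, flat product,
all-zero responses and rank-deficient designs raise typed errors rather than
returning NaNs; undefined per-species enrichment components are returned as
missing.
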