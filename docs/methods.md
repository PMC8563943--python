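# Methods

This note records the models, parameter choices and numerical conventions
behind `gossanms`, in the order the pipeline runs.

## Mass bookkeeping

Atomic monoisotopic masses are pinned in-code (CODATA/AME-derived, quoted
to ≥6 decimals) so derived quantities are bit-stable; the table covers
C, H, N, O, S, P plus the salt/matrix elements Na, K, Al, Fe, Si. All ion
m/z values carry the electron-mass correction
m/z = (m − z·m_e)/|z| with m_e = 5.48579909·10⁻⁴ Da. This matters for
printed two-decimal values: Na₃SO₄⁺ rounds to 164.92 only with the
correction applied.

DBE (rings plus double bonds) is computed as 1 + Σ n_i(v_i − 2)/2 over
CHNOSP valences, i.e. C − H/2 + N/2 + 1 for CHNOS compositions. Formulas
containing metals (salt clusters such as Na₃SO₄⁺ or K₂NaSO₃⁺) carry
DBE = undefined — the count has no structural meaning there. Fragment-ion
compositions may have half-integral DBE; the value is reported as-is.

Rounding for comparison with printed masses is round-half-to-even at the
stated decimals (deterministic ties across platforms).

## Formula assignment

The enumeration's semantics are exhaustive: every composition within the
element bounds whose theoretical m/z falls inside the tolerance appears
exactly once. The implementation iterates S, N, O and solves C, H from the
mass residual; the test suite pins it against an independent full-grid
oracle, so the pruning is an optimization, never the definition.

Defaults, and why:

- element bounds C 1–100, H 1–200, N 0–5, O 0–50, S 0–3 — spans the CHNOS
  space of natural organic matter below ~1000 Da without exploding the
  search;
- DBE 0–25, H/C 0.3–2.5, O/C 0–1.2 — standard dissolved-organic-matter
  validity windows;
- nitrogen (integral-DBE) rule applied only under the [M−H]⁻ /[M+H]⁺
  hypotheses; sputtered fragment cations are frequently even-electron
  species that violate naive parity heuristics, so the `fragment`
  hypothesis skips it;
- two tolerance profiles: `fticr` (0.2 ppm; internally calibrated
  magnet-class accuracy) and `sims` (0.005 Da absolute, converted to ppm
  per peak; two-decimal printed fragment masses imply ~5 mDa precision).

**Candidate ranking and parsimony.** The candidate list is sorted by
|error| (ties: fewer heteroatoms, lower DBE, lexicographic). The *chosen*
candidate additionally applies heteroatom parsimony across the
mass-indistinguishable set: all candidates within `parsimony_margin_ppm`
(default 0.2 ppm, the scale of calibration noise) of the minimum |error|
are treated as tied, and the one with fewest heteroatoms, then lowest
DBE, wins. Rationale: the CHNOS space contains near-isobar doublets —
exchanging C₇O₃ for H₈N₂S₃ shifts the mass by only ~0.2 mDa — which pure
|error| ranking decides by noise. Preferring the heteroatom-poor member
of an indistinguishable pair is the standard resolution in
natural-organic-matter assignment and is what lifts formula recovery on
0.1 ppm-noise synthetic spectra from ~98 % to ≥99.5 %. Setting the margin
to 0 restores strict |error| selection.

## Compound classes

Only two windows in van Krevelen space have printed, authoritative
bounds: the CRAM region (O/C 0.25–0.75, H/C 0.6–1.4) and the CHOS
hydrogen-saturation band (H/C 0.55–2.2). The remaining class windows are
standard literature rectangles, shipped as explicit, serializable
defaults precisely because published diagrams shade them without numeric
vertices:

| region (precedence order)    | H/C       | O/C       | extra        |
| ---------------------------- | --------- | --------- | ------------ |
| carbohydrate-like            | 1.5–2.2   | 0.67–1.2  |              |
| peptide-like                 | 1.2–2.0   | 0.15–0.6  | N ≥ 1        |
| saturated/unsaturated (lipid)| 1.7–2.2   | 0–0.3     |              |
| CRAM                         | 0.6–1.4   | 0.25–0.75 |              |
| highly unsaturated/aromatic  | ≤ 1.0     | —         | DBE > 3      |

First match in precedence order wins, which makes region assignment a
partition. Intensity weighting uses raw linear peak intensities with no
renormalization beyond the fraction denominators, matching the
relative-intensity dot-area convention of van Krevelen scatter plots.
Unassigned peaks are excluded from all denominators and reported
separately.

## Mass-difference networks

The shipped motif set is exactly CH₂, H₂, O₁…O₅, NH₁…NH₃, SO₁…SO₄. A pair
(m₁ < m₂) matches a motif of mass Δ when
|(m₂ − m₁ − Δ)/((m₁+m₂)/2)| ≤ tol. The ppm residual is referenced to the
mean of the two pair masses — the natural choice when neither peak is
privileged — and an absolute-Da mode is available. Each unordered pair
counts at most once per motif; whether a published histogram counts pairs
or series occurrences is generally unstated, and pair counting is the
choice here. Edges can be built in formula mode (element-count difference
exactly equals the motif; residual identically 0) or mass mode; on
noise-free data at ≤0.1 ppm the two coincide, which the tests check.

## Fragment library

The library (`data/fragment_library.csv`, 146 entries) transcribes the
diagnostic-ion lists for morphological groups G1–G9 plus the matrix,
PAH, sterol and amino-acid sets, with group tags, provenance notes and a
`discrepant` flag. Conventions:

- theoretical m/z is always recomputed from the formula; the printed
  two-decimal value is stored only as provenance;
- `discrepant` marks entries whose printed value does not equal the
  2-dp rounded theory. 56 of 131 printed masses are flagged; most sit
  0.005–0.03 Da high, a typical time-of-flight calibration offset, and
  two are outright identification mismatches (a printed 196.86 for
  K₂NaSO₃⁺ that matches K₂NaSO₄⁺ theory, and a printed 63.96 for SiO₂⁻
  that matches SO₂⁻). Flagged entries are reported, never corrected:
  author intent is not adjudicated here;
- positional mass↔formula lists with mismatched counts (one group's
  anion list prints 13 masses against 12 formulas; another's cation list
  11 against 10) are transcribed positionally where chemically sane, with
  inferred pairings flagged `inferred` in the provenance column;
- matching tolerance defaults to 0.005 Da; a peak is counted once per
  group even when several isobaric entries of that group match it.

Sphingolipid chemistry: the shipped sphingoid bases are sphingenine
C₁₈H₃₇NO₂, sphinganine C₁₈H₃₉NO₂, aminomethyl-nonadecane-triol
C₂₀H₄₁NO₃ and phytosphingosine C₂₀H₄₃NO₃; dehydration fragments are
[M+H−nH₂O]⁺ with n ∈ {1, 2}, requiring n available oxygens. Ammonium
adducts of hydrocarbons C_xH_y are C_xH_{y+4}N⁺, with a saturation sanity
check (H ≤ 2C + 4 for the adduct, i.e. the chain must be unsaturated)
that rejects compositions like CH₈N⁺.

## Fatty-acid series

Deprotonated fatty acids are recognized from best-candidate formulas
matching C_nH_{2n−1−2u}O₂⁻ (O₃⁻ when hydroxylated) with 11 ≤ n ≤ 30 and
0 ≤ u ≤ 5. "Even/odd" refers to the total carbon number including the
carboxyl carbon (standard n-Cx:y notation); the neutral acid of FA(n:u)
has DBE = u + 1 (carboxyl counts one), which the tests verify across the
whole grid. The headline statistic is the even:odd intensity ratio on the
≤C20 partition (cutoff configurable); a zero odd sum is reported as an
infinite-ratio flag rather than an error. Hydroxylated chains enter the
parity and partition sums and are also reported as their own saturation
class, since long-chain (≥C24) hydroxy acids carry separate source
information.

## Imaging

Cubes default to 64×64 pixels — instrument rasters are larger, but the
spatial statistics of interest (boundary recovery, support overlap) are
scale-free and the toy size keeps full-pipeline runs interactive.
Extraction conserves intensity exactly: the pixel sums of an ion image
equal the summed matched intensities in the cube, and block-sum
downsampling commutes with extraction. RGB overlays normalize each
channel independently to [0, 1] (the convention of common SIMS software;
an all-zero channel maps to 0). Colocalization reports Pearson r on raw
pixel intensities (undefined-flagged for constant images) and the Jaccard
overlap of supports thresholded by Otsu's method — chosen because it is
parameter-free; the thresholds are recorded in the output.

## Synthetic data

All generators are pure functions of (config, seed) via a dedicated
`numpy` Generator stream; identical inputs give byte-identical outputs.

- **FTICR-like spectra**: neutral CHNOS molecules are rejection-sampled
  per heteroatom class (CHO/CHNO/CHOS, default mix 0.39/0.51/0.10) under
  the same validity windows the assignment stage uses, with [M−H]⁻ m/z
  confined to 147.4–1000. Observed m/z = theory × (1 + ε),
  ε ~ N(0, 0.1 ppm); intensities are log-normal (σ = 1), heavy-tailed
  like real spectra. Not emulated: isotopologues, detector dead-time,
  peak-shape effects, and the true (unknown) composition of any real
  extract — passing recovery tests therefore demonstrates correctness of
  the assignment machinery under the stated noise model, not instrument
  fidelity.
- **SIMS-like spectra**: peaks at the library's theoretical masses for
  one marker group (level 100) over an always-present matrix background
  (level 20), with Da-scale jitter (default 2 mDa), log-normal intensity
  scatter (σ = 0.3) and uniform low-level chemical noise peaks; a
  zero-noise mode produces exact theoretical masses for support-recovery
  tests. Ionization matrix effects are deliberately not modeled.
- **Image cubes**: group recipes painted into layout masks (half-fields,
  random-walk filament strokes, ovoid ellipses — the morphologies of
  interest at toy scale) over the matrix background; masks are returned
  as ground truth. Disjoint layouts are enforced unless overlap is
  explicitly enabled.
- **Fatty-acid profiles**: peaks allocated round-robin over the
  (carbon, unsaturation, hydroxylation) grid with a smooth
  short-chain-dominant base profile; even-carbon ≤C20 weights are
  rescaled so the expected short-chain even:odd ratio equals the target
  exactly, then multiplied by mean-one log-normal noise (σ = 0.25, the
  scale of replicate intensity variability about a reference profile).
  At 200 peaks the recovered ratio scatters a few percent about the
  target.

## I/O and configuration

Delimited text is comma-separated UTF-8 with a mandatory header; peak
lists are `mz,intensity`, cubes travel long-format (`x,y,mz,intensity`)
next to a YAML manifest. Duplicate m/z rows merge by intensity sum with a
logged warning. mzML input (single centroided spectra; 32/64-bit float,
optional zlib, polarity from CV terms) is handled by a minimal reader in
`gossanms.io`. Every CLI run writes its resolved configuration
(`resolved_config.yaml`) next to its outputs, so a run is reproducible
from its artifacts alone.

## Known limitations

- Singly charged ions only; no isotopologue patterns or multiply charged
  deconvolution.
- The van Krevelen windows other than CRAM are declared approximations;
  region fractions depend on them and should be read comparatively, not
  absolutely.
- ToF-SIMS annotation is a library lookup at 5 mDa: it identifies
  compatible compositions, not structures, and inherits the printed
  lists' transcription ambiguities (flagged, not resolved).
- The synthetic generators define the statistical conditions the tests
  run under; none of the shipped numbers are estimates of any particular
  instrument's behavior.
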