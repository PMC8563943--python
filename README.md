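# gossanms

Molecular fingerprinting for mass-spectrometric biosignature studies of
gossan-type (oxidized, iron-rich) geological samples — and for any workflow
that pairs ultrahigh-resolution exact-mass peak lists with
time-of-flight secondary ion (ToF-SIMS) fragment spectra and ion images.

It is written for geobiologists and analytical chemists who need the
computational half of such a study to be reproducible: given centroided
peak lists, the package assigns elemental formulas, maps them into
compound-class space, detects homologous series, annotates diagnostic
lipid/amino-acid/phytochemical fragments, and renders and scores ion
images. A ground-truthed synthetic-data generator stands in for
instrument data, so every stage is testable offline.

## What it computes

**Formula assignment.** For a peak at m/z *x* with charge *z* = ±1, every
composition C_c H_h N_n O_o S_s inside configurable element bounds whose
theoretical ion mass

    m/z = (Σ count_i · m_i − z·m_e) / |z|        (m_e = electron mass)

lies within a ppm tolerance is enumerated, then filtered by chemical
validity: DBE = c − h/2 + n/2 + 1 in a configured window, H/C and O/C
ratio windows, and the nitrogen (integral-DBE) rule under the [M−H]⁻
hypothesis. Candidates are ranked by |mass error|; among candidates that
are mass-indistinguishable at calibration accuracy the chemically most
parsimonious (fewest heteroatoms, lowest DBE) is chosen.

**Compound classes.** Assigned formulas are labelled CHO/CHNO/CHOS/CHNOS
and placed in van Krevelen space (H/C versus O/C), with literature windows
for lipid-like, peptide-like, carbohydrate-like, condensed-aromatic
(DBE > 3) and CRAM material (O/C 0.25–0.75, H/C 0.6–1.4).

**Mass-difference networks.** Pair counts and edge lists for the motif set
CH₂, H₂, O₁…O₅, NH₁…NH₃, SO₁…SO₄ at sub-ppm tolerance — the fingerprint of
homologous-series structure in a complex mixture.

**ToF-SIMS annotation.** A curated library of 146 diagnostic ions
(matrix salts, NH₄⁺-bearing hydrocarbon adducts, fatty-acid carboxylates,
sulfate/sulfonate adducts, sphingolipid dehydration fragments
[M+H−nH₂O]⁺, amino-acid fragments, PAH cations, sterol fragments) tagged
by morphological marker groups G1–G9; per-group intensity summaries, PAH
intensity sums, and a discrepancy report comparing printed versus
theoretical masses.

**Fatty-acid series statistics.** Detection of carboxylate anions
C_n H_{2n−1−2u} O₂⁻ (C11–C30, 0–5 double bonds, optional hydroxylation)
and the parity statistics used as biogenicity indicators: even:odd
intensity ratio on the ≤C20 side, ≤C20 / >C20 partition, saturation
classes, and 20:5 / 20:4 polyunsaturated flags.

**Ion imaging.** Per-pixel peak-list cubes → ion images (window or library
group), intensity-conserving, with independently normalized RGB overlays
and colocalization scores (Pearson r, Jaccard overlap of Otsu-thresholded
supports).

## Worked example

```python
from gossanms.formula_assign import AssignmentConfig, assign_peaklist
from gossanms.composition_classes import summarize
from gossanms.synthetic import FticrSimConfig, gen_fticr_peaklist

peaks, truth = gen_fticr_peaklist(FticrSimConfig(n_peaks=1000, seed=42))
assigned = assign_peaklist(peaks, AssignmentConfig(tol_ppm=0.5))
s = summarize(assigned)
print(s.n_assigned, {k: round(v, 3) for k, v in s.class_count_fraction.items()})
```

prints

```
1000 {'CHO': 0.38, 'CHNO': 0.53, 'CHOS': 0.088, 'CHNOS': 0.002}
```

— all 1000 synthetic peaks received a formula, and the recovered class
fractions sit within sampling error of the generator's programmed mix
(0.39 / 0.51 / 0.10; the two CHNOS labels are the 0.2 % of peaks whose
best candidate differs from the generating formula). The same pipeline is
available from the shell:

```sh
gossanms simulate fticr --seed 42 --n-peaks 1000 --out sim
gossanms assign sim/peaks.csv --tol 0.5 --out assigned
gossanms annotate spectrum.csv --polarity positive --out annotated
```

Exact-mass bookkeeping is a one-liner:

```python
>>> from gossanms.masschem import ion
>>> ion("C20H42N", +1).mz_rounded(2)   # NH4+-bearing C20 adduct
296.33
>>> ion("C27H45SO4", -1).mz_rounded(2) # cholesteryl sulfate fragment
465.3
```

## Layout

| module                 | role |
| ---------------------- | ---- |
| `masschem`             | formulas, monoisotopic masses, ion m/z, DBE |
| `formula_assign`       | exact-mass CHNOS formula enumeration and assignment |
| `composition_classes`  | van Krevelen regions, CRAM, class summaries |
| `massdiff_network`     | mass-difference histograms and motif networks |
| `sims_annotation`      | diagnostic-fragment library and annotation |
| `series_stats`         | fatty-acid series detection and parity statistics |
| `imaging`              | ion image cubes, overlays, colocalization |
| `synthetic`            | ground-truthed synthetic data generators |
| `io` / `cli`           | delimited-text and mzML I/O, `gossanms` command |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
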