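# Methods

## Mass and isotope model

All neutral masses are monoisotopic daltons internally; "most abundant"
masses are derived from the isotope distribution on output, and both are
labeled wherever reported. m/z conversion uses the proton mass
1.007276466 Da: `m/z = (M + z·1.007276466) / z`.

Theoretical isotope patterns come from the averagine model: a protein of
mass M is assigned the elemental composition of `M / 111.1254` "average
amino acid" monomers (C 4.9384, H 7.7583, N 1.3577, O 1.4773, S 0.0417 per
monomer), with C/N/O/S counts rounded and the hydrogen count absorbing the
rounding residual. The aggregated (unit-neutron) isotopologue distribution
is computed by exact convolution of per-element isotope distributions
(binary exponentiation over atom counts, elemental data from the NIST
table shipped with pyteomics), tracking the probability-weighted centroid
mass of each aggregated peak. The distribution is anchored so its
monoisotopic peak sits exactly at the requested mass — an integer hydrogen
count cannot hit an arbitrary target mass, and anchoring keeps the
composition's role purely pattern-shaping. Peaks below `truncate_at`
(default 1e-4) of the apex are dropped and the remainder renormalized; for
proteins above ~25 kDa this removes the monoisotopic peak itself, so all
offsets are tracked from the true anchor rather than the first kept peak.
The implementation is verified against an independent brute-force
multinomial enumeration oracle in the test suite (≤1e-6 absolute
probability at ≤5 kDa; apex index and apex−mono offset at 20 kDa).

Modification deltas: phospho +79.96633, oxidation +15.99491, acetyl
+42.01057 Da. The mean aggregated isotopologue spacing is taken as
1.00235 Da.

## Synthetic run generator

The generator emulates a QTOF intact-protein acquisition: MS1 spectra at
1 Hz over 300–3000 m/z (optional quadrupole transmission floor), resolving
power 60 000, centroid by default (profile rendering available with
Gaussian peaks of FWHM = m/z / R). Each simulated proteoform contributes

* a unit-area Gaussian elution profile (`rt_sigma` default 0.15 min),
  scaled by `total_intensity × family loading × abundance`, so the total
  rendered ion current of a species equals its amplitude exactly;
* a discretized Gaussian charge envelope; in auto mode
  `z_center = round(sqrt(M)/4.5)` clipped to keep the envelope apex in the
  m/z range, `z_sigma = max(1.5, z_center/6)` — values that give plausible
  QTOF envelopes across 5–60 kDa;
* the averagine isotope pattern of its mass at every charge.

Noise terms: multiplicative log-normal intensity noise with a given CV
(unit mean), an additive per-peak baseline, and Poisson-rate spurious
peaks (uniform m/z, exponential intensity). No m/z jitter is simulated:
centroid positions are exact, which makes mass-recovery tests sharp but
means the generator does not probe mass-accuracy degradation, detector
saturation, coalescence of near-coincident peaks, chromatographic tailing,
or ion-statistics (shot-noise) effects. Conclusions from passing tests are
therefore about the algorithmic chain, not about instrument physics.

Runs are deterministic: one `numpy` Generator seeded from the config, and
a timestamp-free mzML writer, give byte-identical output for identical
config+seed.

### Fiber fixtures

`fiber_fixture` builds slow, fast, and hybrid fiber archetypes over a
built-in library of 12 sarcomeric proteins (slow/fast troponin I and C,
essential and regulatory myosin light chains, α/β tropomyosin, sarcomeric
α-actin). The library masses are synthetic placeholders in the realistic
16–42 kDa range — chosen so that no two co-eluting species (including
phospho satellites) sit within one isotope-cluster width (~45 Da at
33 kDa) of each other, mirroring real sequence spacings — and are clearly
flagged as mock values; no database download is involved. Elution centers
are spread over a 12.5 min window with 0.6 min between family partners
(≈4 elution sigma), emulating the reverse-phase separation of these
proteins on a compressed gradient. Slow fibers carry <10 % fast isoforms
per family and vice versa; the hybrid fiber mixes both, carries
mono-/bis-phospho satellites on the tropomyosins and regulatory light
chains (αTpm stoichiometry 0.14, β 0.08, MLC2F 0.32, MLC2S 0.28 mol
Pi/mol), and includes a +29.0 Da MLC2S satellite at 6 % of the MLC2S pool.
Family ion currents span roughly a sevenfold range (actin highest), a
modest stand-in for the unknown true dynamic range; both the splits and
the loadings are config-exposed.

## Deconvolution

**Isotopic route.** Working on a centroided (averaged) spectrum, seeds are
taken in descending intensity above 1e-3 of the base peak. Candidate
charges for a seed come from the gaps to its immediate neighbours; for
each candidate the cluster is grown greedily in both directions at spacing
`1.00235/z` with a 5 % per-step tolerance (re-anchored at each matched
peak, so errors do not accumulate). The charge is then re-derived from the
median observed spacing, which disambiguates adjacent charges (z vs z+1
differ by >2 % in spacing up to z≈50, well inside the re-derivation's
resolution on noise-free centroids). Clusters of ≥3 peaks are scored by
cosine similarity against the averagine pattern of the implied mass
(cached on a 200 Da grid); the best integer lag aligns observed members to
absolute isotopologue indices, and the monoisotopic mass is the
intensity-weighted mean of `z·(m/z − m_p) − offset(index)` over matched
members. Acceptance threshold 0.6; ties break to higher score, then lower
charge. Unassigned peaks are returned as a remainder list. Clusters
agreeing within 10 ppm across charges merge into one peak whose intensity
is the sum of cluster apex intensities.

**Envelope route.** A nonnegative mass-domain function h(M) on a grid of
step `M/(2R)` is fitted by multiplicative (Richardson–Lucy-type) updates so
that its rendering through every charge in range — linear resampling along
`M = z(m/z − m_p)` with the charge as Jacobian, blurred by a Gaussian of
FWHM `m/z / R` — reproduces the observed spectrum (centroid input is
blurred onto the same grid first, so both sides live in the same smoothed
domain). Iteration stops when the relative residual change falls below
1e-4 (cap 500). h is initialized uniform; there is no random state. An
optional entropy penalty (default weight 0) damps ripple. Local maxima
above 1e-3 of the h-maximum are parabolically refined, chained into
isotopologue series ~1.00235 Da apart, and each series is reported as one
peak: the averagine lag fit pins its monoisotopic mass, the intensity is
the summed member heights, and supporting charges are those contributing
>5 % of the series' rendered signal. The route follows the operational
contract of maximum-entropy-style vendor tools (zero-charge spectrum at a
stated resolving power) without claiming bit-compatibility; the stated
resolving power sets the peak-width model and the grid step.

## Isotopic fitting

`fit_isotopic_pattern` aligns the averagine distribution of a candidate
mass to an observed cluster with a single mass offset (coarse 0.001 Da
grid over ±0.5 Da, then centering on the intensity-weighted matched
residuals — the cosine objective is flat within the 0.05 Da match
tolerance, so the residual mean is what pins the mass) and a free scale.
`fit_score = 100 × cosine` between the aligned vectors, with unmatched
theoretical peaks scored against zero and unmatched observed peaks
penalizing the fit; the score is scale-free, 100 for a perfect match, and
strictly lower for a candidate displaced by one isotopologue (±1.00235 Da
cannot be absorbed by the ±0.5 Da offset). The cosine definition is a
design choice: the score formula of the desktop tools that print such
percentages is not public, so only the contract (scale freedom, 100 at
self-match, selectivity) is asserted, not numerical equivalence.

## Assignment

Each deconvoluted peak is tested against every target's modification
series — phospho up to the target's site count, ≤2 oxidations, ≤1 acetyl
(caps config-exposed) — and matched to the candidate with the smallest
|ppm| within the tolerance (default 10 ppm, QTOF-appropriate); ties break
to fewer total modifications, then lexicographic id, making assignment a
total order and fully deterministic. A peak matching nothing but lying
within `max_unknown_shift` (default 100 Da) of a target's *phospho* series
is reported as `shifted` with the residual delta rounded to 0.1 Da; the
phospho-only reference keeps a +29 Da satellite reading "+29.0" rather
than being re-expressed against an oxidation candidate, which is the
behaviour that lets unexplained biology surface. Everything else is
`unassigned`. Shifts are never absorbed into the ppm error.

## Quantification

* `proteoform_relative_abundance`: apex peak intensity of each proteoform
  over the summed intensities of that protein's series (integrated cluster
  intensity available by config; apex is the default reading of "highest
  peak intensity").
* `total_phosphorylation`: `Σ k_j I_j / Σ I_j`, bounded by the site count;
  algebraically identical to the site-count mean weighted by proteoform
  fractions (property-tested).
* `isoform_relative_abundance`: AUC fractions within a protein family,
  plus all pairwise AUC ratios.

`fiber_report` orchestrates one fiber: each protein's elution is located
by a coarse EIC over its theoretical top charges (apex ± 0.5 min window,
overridable per protein); scans in the window are averaged (centroid
clustering tolerance 0.01 m/z ≈ FWHM/1.7 at m/z 1000 and R 60 000); the
averaged spectrum goes through the isotopic deconvolution route,
assignment, series construction (entries below 0.5 % of the series maximum
are discarded as interference), and an isotope-pattern fit of the base
proteoform. A protein whose series contains no *matched* proteoform —
only shifts or nothing — is reported as undetected with zero abundance
and an explicit flag, keeping cross-fiber tables rectangular.

EIC windows are ±0.2 m/z around the most-abundant-isotopologue m/z of the
top 5–7 charge states (ranked by cluster apex intensity in the averaged
spectrum), pooling the window positions of all assigned modification
states by default, since the chromatographic trace of an isoform includes
its phospho forms. Two guards make AUC ratios honest in crowded spectra:
windows that would overlap the predicted charge-state clusters of any
co-eluting target are skipped (falling back to the most intense charges
if too few clean ones remain), and each isoform's AUC — integrated over
its own elution window, since an unbounded integral would sum unrelated
species eluting elsewhere — is divided by the apex-weighted fraction of
its charge envelope covered by the selected charges, so isoforms forced
onto different charge subsets remain comparable. Both the selected
charges and all tolerances are recorded in the report provenance.

No cross-fiber normalization or inferential statistics are computed; the
output is descriptive per-fiber tables.

## Problem sizes and numerical choices

Default fixtures use 12.5 min runs (751 scans at 1 Hz) with ~20 simulated
proteoforms, chosen so a full generate-and-quantify cycle completes in
seconds and multi-seed recovery studies in minutes on one core. The
acceptance script uses 10 seeds for its recovery medians; the test suite
uses 20 for the end-to-end recovery test. Degenerate inputs (empty spectra,
all-zero windows, undetected proteins, single-member series) return empty
or zero results with explicit flags rather than raising, except where a
caller error is unambiguous (invalid ranges, unknown modifications,
zero-intensity denominators).

## Known limitations

* Averagine is mass-only: real sequences with unusual composition (e.g.
  very cysteine-rich) deviate from the predicted pattern, lowering fit
  scores without the mass being wrong.
* The centroid simulator never coalesces near-coincident peaks, while a
  real QTOF profile would; species closer than about one isotope-cluster
  width interact only through the averaging tolerance here.
* The spacing-walk charge inference assumes isotopic resolution; it is not
  applicable to unresolved (very large or low-R) proteins, for which only
  the envelope route applies.
* Retention-time alignment across runs, MS/MS site localization, and
  absolute quantification are out of scope.
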