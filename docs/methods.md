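# Methods

## Scope and model

`cannatrace` implements the computational half of an untargeted
cannabinoid stability analysis: given per-sample feature tables
(m/z, retention time, CCS, intensity, S/N) and MS² spectra from a
UHPLC–TIMS–TOF experiment, it assigns elemental compositions, identifies
compounds against a reference spectral library, classifies unannotated
degradation products, and quantifies degradation trends across storage
conditions. Raw-data feature extraction, instrument calibration,
negative-ion mode and NMR structure elucidation are out of scope; CCS
values are taken as given rather than derived from mobilities.

## Mass arithmetic

Atomic masses and isotope abundances are pinned in-source
(¹H 1.00782503207, ¹²C 12 exactly, ¹⁶O 15.9949146196, ²H 2.0141017778,
electron 0.00054858 Da, with N and S available but disabled by default).
Ion m/z is `(M + Δ_adduct − z·mₑ)/|z|`; the electron mass is applied per
charge, so a protonated ion is the neutral mass plus 1.00727646 Da.
Deuterium is a first-class element symbol (`C21H27D3O2` for the
deuterated internal standard) and counts as hydrogen in RDBE.

The ppm sign convention is `(observed − theoretical)/theoretical × 1e6`.
Printed literature Δppm values cannot be reproduced consistently from
4-decimal m/z values (rounding dominates), so reported Δppm values are
treated as metadata; theoretical m/z values at 4 decimals are the
reproducible quantities.

Formula enumeration searches C 0–40, H 0–80, O 0–10 (configurable) with
RDBE constrained to [0, 25], solving the hydrogen count analytically per
(C, O) pair; tests verify exact set equality with an independent
brute-force nested-loop enumeration. Isotope envelopes are exact
per-element convolutions (exponentiation-by-squaring over atom
distributions), binned at 0.01 Da (abundance-weighted centroids), pruned
at 10⁻⁴ of the base peak. Envelope similarity aligns both patterns on
their base peak — the criterion scores the distribution's *shape*, so an
observed ion envelope is comparable with a theoretical neutral one — and
returns `1 − D/A`, where `D` accumulates absolute abundance differences
of matched peaks plus the abundance of unmatched peaks and `A` is the
total abundance of both patterns.

## Library matching

The packaged library holds 39 entries: the 35 compounds of the optimised
reference separation plus CBDH, CBDM, Δ9-THCH and the internal standard
D3-Δ9-THC. The published roster is ambiguous about the 39th compound;
the internal standard fills that slot here, with the ambiguity recorded
in its provenance field. Entries whose retention time, CCS or MS² were
not published carry placeholder values explicitly flagged
`synthetic ...` in provenance; quantitative tests rely only on
literature-backed entries or generator-planted spectra.

Matching applies five criteria with defaults |Δppm| ≤ 5,
|ΔRT| ≤ 0.2 min, ΔCCS ≤ 2 %, isotope score ≥ 0.8, MS² cosine ≥ 0.7.
The mass criterion is a hard gate (entries outside it are not reported);
candidates rank by criteria passed, then |Δppm|, then |ΔRT|. A feature
missing CCS, MS² or an observed isotope envelope *fails* those criteria
rather than skipping them, so a validated call always rests on all five.
The observed isotope envelope is assembled upstream by pairing each
feature with a co-eluting M+1 companion (+1.0034 ± 0.01 Da,
|ΔRT| ≤ 0.05 min, smaller intensity); the thresholds were chosen so that
published validations (ΔCCS ≤ 0.69 %) pass while the ~10 % ΔCCS isomer
cases fail the CCS criterion. `validated` requires all five criteria;
`putative` requires the mass gate plus at least one further criterion.

MS² similarity is a greedy closest-first peak-matched cosine (each peak
used once, unmatched peaks contribute to the norms only); it is
symmetric by construction and cross-checked against matchms's greedy
cosine in the tests.

## Unknown classification

Rules apply in a fixed order: (1) a feature linked as an in-source
artifact child is labelled `in-source-artifact` and never receives a
chemical class (children matching several co-eluting parents keep all
links and are demoted to low confidence); (2) diagnostic fragments
assign a core — the CBE rule (205.1227 + 135.0448) is evaluated before
the CBDH rule (207.1380) and the CBD/olivetol rule (193.1228), most
specific first; (3) the oxidation level follows from the composition
delta between the feature ion and the core parent (+O hydroxy, +2O
dihydroxy, +O−2H quinone, identical composition → isomer at a new
retention time), each candidate composition re-validated by independent
formula enumeration at 5 ppm; (4) hydroxylation increases polarity, so a
hydroxy label whose feature does not elute at least 0.3 min before its
parent is kept at low confidence — the direction is established
chemistry, the 0.3-min margin is this package's documented default.
Fragment-match tolerance is max(0.005 Da, 10 ppm), wide enough to absorb
the spread between independently quoted diagnostic masses (135.0442 vs
135.0448).

The CBD quinone ("HU-331-like") has no established fragmentation, so it
is called on composition and retention time alone (far from the HU-331
reference peak) when no fragment rule fires. The CBE stereoisomers are
separated on the pseudo-MS³ spectrum of the water-loss ion
([M−H₂O+H]⁺, m/z 313.216) by the I(245.1540)/I(231.1378) ratio with
threshold 2; which stereoisomer sits on the high-ratio side is not
established and is therefore a configuration parameter
(`stereo_high_ratio_class`), not an assertion.

## Trends and quantitation

Abundances are normalised per sample to the single internal-standard
feature (matched at 5 ppm / 0.1 min around the m/z computed from the
D3-Δ9-THC composition — never hard-coded); samples with zero or multiple
IS candidates are excluded and reported. The LOQ gate is S/N ≥ 10,
boundary inclusive. Trend cells report the mean and SD over quantifiable
replicates; below-LOQ replicates are counted, not imputed. For slope
fitting, a compound not detected in a sample is a genuine zero-abundance
observation (it anchors the day-1 point of late-forming degradants), and
a cell with no quantifiable replicate contributes zero. Monotonicity
uses an internally implemented Mann–Kendall test: for n ≤ 10 untied
observations the exact null of the S statistic is computed from the
inversion-count generating polynomial ∏ᵢ(1 + x + … + xⁱ⁻¹); larger or
tied series use the tie-corrected normal approximation with continuity
correction. Calibration curves are ordinary least squares; inversion
below the blank is reported as below-range rather than negative.

Source calls use fixed marker sets — plant: CBDV, CBDP, CBDH, 6α-OH-CBD,
7-OH-CBD; synthetic: the CBDH isomer — while compounds observed in both
sources (CBDB in particular) are reported but never discriminate.

## Synthetic-data generator

The generator emulates the study design: two sources, four storage
conditions (light/ambient, dark/ambient, stressed 40 °C/75 % RH,
refrigerated 4 °C), five replicates, sampling days 1/8/15/22/29.
Compound presence per source follows the published day-1 and
stressed-storage tables; features sit at theoretical ion m/z (computed,
not transcribed — printed table m/z are observed values) with Gaussian
ppm noise (default SD 0.5 ppm), Gaussian RT jitter (0.02 min),
multiplicative lognormal intensity noise (CV 10 %, mean-one
parameterisation) and 0.2 % CCS noise. S/N scales with intensity over a
fixed noise floor, placing day-1 trace impurities just above the LOQ.
Each feature carries an M+1 isotope companion at the exact theoretical
ratio and, for the dihydroxy-CBD / hydroxy-CBE parents, an in-source
water-loss child at 30 % of the parent intensity and identical RT.

Degradant kinetics are linear with a floor,
`I(t) = max(0, A₀ + k_condition·(t−1))`, with slope orderings encoding
the study's qualitative findings (CBE-type: stressed ≈ light > dark >
refrigerated; HU-331: refrigerated > dark > light, reflecting thermo-
and photo-lability; OH-CBE: highest at dark/ambient). Slope magnitudes
and the replicate CV are documented defaults — the source study prints
no y-axis units or error bars — so all trend acceptance rests on
recovered orderings and parameter recovery, never on absolute values.
Linearity is a deliberate simplification that keeps parameter recovery
exact and testable.

What the generator does **not** emulate: chromatographic peak shape and
co-elution interference, mass-dependent calibration drift, ion
suppression between analytes, missing MS² acquisitions, or nonlinear
(e.g. autocatalytic) degradation kinetics. Passing tests therefore
demonstrate correctness of the analysis logic under the stated noise
model, not robustness to every failure mode of real acquisitions.

## Numerical and design choices

- Determinism: all randomness flows through `numpy` SeedSequences spawned
  per sample from one integer seed; identical (seed, config) produce
  byte-identical output files (floats serialised via `repr`).
- Ranking ties in matching break by |Δppm| then |ΔRT|; enumeration ties
  by Hill string; artifact links sort by |ΔRT| then ids, making results
  independent of input order.
- Feature tables are per-sample UTF-8 CSV with mandatory header ('.'
  decimal, empty string for absent optionals), chosen over binary
  containers for diffability; MS² travels as MGF via pyteomics; the
  library uses an MSP-like text dialect with a hand-written parser
  because of its custom keys (ABBREV, RT_MIN, CCS_A2).
- Default problem sizes in tests: 30–100 random masses for
  enumeration-oracle equality, 10–20 seeded study replications for
  recovery statistics, 1000 features for noise-SD recovery — sizes at
  which the statistical tolerances (10–20 %) are comfortably resolved.
- The co-elution window for artifact attribution (0.05 min) and the
  classifier's 0.3-min hydroxylation margin are package defaults; the
  source study states the phenomena but not the windows.

## Known limitations

- Placeholder RT/CCS/MS² values for library entries without published
  measurements are internally consistent but not literature values;
  matching results against real data for those entries are only as good
  as a user-supplied library.
- The classifier's label set covers the degradation classes established
  for CBD e-liquids; novel cores fall back to `unclassified`.
- ΔCCS% is asymmetric (reference in the denominator) by definition;
  swapping measured and reference changes the value.
- Positional isomers (which OH position; CBE vs its stereoisomer's
  configuration) are beyond MS-level evidence and are deliberately not
  asserted.
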