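# Methods

## Pose-energy reduction

A docking engine returns, per compound–protein pair, an ensemble of
poses each with a binding energy in kcal/mol (negative = favourable).
The pipeline reduces this ensemble to one representative energy per
pair. The default is the **minimum** — the most stable predicted binding
mode, the conventional choice — with the **arithmetic mean** available
as an ensemble summary. Ties for the minimum resolve to the first pose
in file order; this cannot change the scalar value and only matters if a
pose index were reported. Only `REMARK VINA RESULT:` lines of a pose
file are interpreted; geometry is ignored. Energies and signs are taken
at face value from the files — no unit conversion or sign flipping.

The energy matrix is required to be dense: a missing compound–target
pair is a hard error listing every absent pair, never a silent
imputation, because the score formulas need all five energies. Runs for
pairs outside the requested index are dropped with a warning. Two
distinct compounds may share an external database identifier (the
packaged 51-compound panel contains one such CID collision); they are
kept as separate rows, with deduplication an explicit opt-in.

## Scoring model

With representative energies `E_t` for targets ERK2, JNK2, p38
(MAPK pathway), p65 (NFκB) and the anti-target IκBα, the two preset
schemes are

    score1 = E_ERK2 + E_JNK2 + E_p38 + 3·E_p65 − E_IκBα
    score2 = E_ERK2 + E_JNK2 + E_p38 +   E_p65 − E_IκBα

score1 balances the two pathways (MAPK's three proteins vs p65 weighted
3), score2 the five proteins directly; both subtract the anti-target
energy so strong IκBα binders are penalised. Scores are raw weighted
kcal/mol sums with no normalisation, ranked ascending; ties break by
ascending compound id so rankings are identical across platforms. The
weights are design constants, not fitted: the individual contribution of
each protein to the disease is unknown, so equal weighting within levels
is the stated assumption. A useful identity, exploited in the tests:
`score1 − score2 = 2·E_p65` for every compound.

The threshold filter is independent of the scores: a compound is
retained iff `E_t < c` strictly on every target and `E_antitarget ≥ c`
non-strictly, default `c = −7` kcal/mol. The two inequalities partition
exactly at the cutoff. Comparisons are exact floating-point — docking
energies are reported at 0.1 kcal/mol granularity, so an epsilon would
only blur the boundary.

## Structure quality

Receptor models are classified from the percentage of residues in the
most-favoured Ramachandran regions: `good` iff strictly greater than
90%. The underlying Ramachandran computation is out of scope; only the
classification rule is implemented.

## Drug-likeness

Lipinski's rule of 5 is evaluated with **inclusive boundaries**
(MW ≤ 500 g/mol, LogP ≤ 5, HBD ≤ 5, HBA ≤ 10 compliant). Prose
statements of the rule often write strict `<`, but published violation
counts score a compound with exactly 10 acceptors as compliant, which
forces the canonical inclusive reading; we adopt it uniformly.
`druglike` means zero violations; the common "≤ 1 violation" relaxation
is available via `max_violations`. Descriptors are ingested from tables
(database values, XLogP3-style LogP), not computed from structures —
the pipeline consumed curated descriptor tables, and recomputation
would change the question being asked.

## Candidate selection

From a ranked list: take the top N (default 10), keep compounds
annotated anti-inflammatory, then drop compounds flagged as already
known to act against the disease (they validate the screen but are not
novel candidates). With these operators the final set is
order-independent, but the audit code a rejected compound receives is
not, so the order is fixed as stated: a compound failing both filters is
audited `not_anti_inflammatory`. Annotation flags are curated inputs;
the literature review that produces them is out of scope. ADMET,
bioactivity and toxicity annotations are carried byte-for-byte as
pass-through strings, never interpreted.

## Assay statistics

* **Viability**: `100·(OD − blank)/(control_mean − blank)`; blank
  correction defaults to none (no blank wells are assumed — none are
  introduced silently). The ISO 10993-5 call (`noncytotoxic` iff ≥ 70%,
  inclusive) applies to the **group mean**, not per-replicate.
* **Nitrite**: ordinary least-squares line `OD = a·conc + b` through the
  kit standards, inverted for samples; negative inferred concentrations
  are clamped to 0 with a warning (the analyte is physically
  non-negative). Units follow the standards table (μM by convention).
* **Group comparison**: two-tailed unpaired t-test; Student
  (pooled variance, df = n_a + n_b − 2) is the default, matching the
  common default of plate-analysis software when the variance assumption
  is unstated; Welch is a flag. Two zero-variance groups with equal
  means return t = 0, p = 1 rather than an error. Each treatment is
  compared to control independently with no multiple-testing correction,
  matching the analysis design; a Holm flag could be layered on by the
  caller via statsmodels if desired. Stars: `*` p < 0.05, `**` p < 0.01,
  `***` p < 0.001, `****` p < 0.0001, strict, most extreme wins.

## Synthetic screens and plates

The generator emulates the study conditions: 51 compounds × 5 proteins,
10 **or** 20 poses per pair (docking runs are commonly configured with
one of those two pose counts; the parser accepts any positive count),
pose energies i.i.d. Normal(μ = −6, σ = 1) kcal/mol. Planted hits shift
the pair mean by `target_offset` (e.g. −5) on the four targets and by
`antitarget_offset` (default **+3**) on the anti-target. The +3 default
comes from an order-statistics argument: the representative energy is
the minimum over 10–20 poses, and with pose energies N(−3, 1) the
per-pose probability of falling below the −7 kcal/mol selectivity bound
is ≈ 3×10⁻⁵, so even the minimum of 20 poses stays above the bound in
more than 99.9% of screens — a planted hit is meant to pass the
anti-target condition, and a smaller offset (+2) fails that intent
about 2.7% of the time once the minimum is accounted for. Decoys share
one marginal distribution across all five proteins, so the anti-target
subtraction is exercised non-trivially rather than passed by
construction.

Decoy annotation flags are random (30% anti-inflammatory, 5% excluded —
loose rates that make the selection funnel non-trivial); planted hits
are always anti-inflammatory and never excluded, since recovery through
the funnel is the event under test. Descriptors are drawn from loose
drug-like ranges and feed only the rule-of-5 stage. Plates draw each
replicate OD from Normal(group true mean, noise_sd). Every generator
takes a mandatory seed and routes all randomness through one
`numpy.random.Generator`; identical seed and spec give byte-identical
outputs, including pose-file trees.

What the generator does **not** emulate: correlated energies across
targets of one compound (real binding-site similarity, e.g. among the
MAPK kinases, induces strong correlation), non-Gaussian energy tails,
pose-count/energy dependence, plate edge effects, or heteroscedastic
assay noise. Passing recovery tests therefore demonstrate the pipeline's
arithmetic and calibration under the stated noise model, not performance
on real docking output.

## Calibration and test sizes

The suite verifies, among others: type-I error of the default t-test at
α = 0.05 over 10,000 simulated null plates (3 replicates per group, the
typical plate design here), vectorised so the check runs in seconds;
planted-hit recovery (δ = −5 kcal/mol, 50 decoys, σ = 1) over 1,000
seeded screens, requiring rank 1 under score1 and end-to-end survival
through threshold and selection in ≥ 99% of screens; and exchangeability
of a zero-offset "hit" (rank uniform over 1..n, chi-square goodness of
fit at n = 8 over 250 seeds — a chi-square is used rather than a KS test
because ranks are discrete and the KS null distribution is miscalibrated
for atoms). Ranking is cross-checked against a brute-force
comparison-sort oracle that recomputes every weighted sum from scratch,
and the t-test against a closed-form pooled-variance oracle.

## Known limitations

* The scoring weights are fixed design constants; no data-driven weight
  learning is provided (deliberately out of scope).
* Descriptor ingestion trusts the table; no structure-based
  recomputation or sanity cross-check against a toolkit is performed.
* The deposited per-pair energy sheets of the original screen are not
  redistributed here, so the published 22-compound filter count and
  top-10 ordering are covered by the property suite on synthetic screens
  plus the printed-table reproductions, not by re-parsing the deposited
  XLSX (the reader for such sheets, `read_energy_matrix_xlsx`, is
  provided and tested on synthetic workbooks).
* Dose–response modelling (IC50/4PL), binding-pose geometry and
  interaction fingerprints are out of scope.
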