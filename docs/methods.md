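# Methods

## The model

`emitra` treats a process emission factor (kg of a species emitted per kg
of product manufactured) as a read-across endpoint: the unknown value for
a target chemical's process is inferred from the measured value of the
same endpoint for one or more structurally similar source chemicals with
comparable processes. The working assumptions are those of any
read-across: (i) structural similarity implies similar physicochemical
behaviour, so similar species escape similar processes at similar rates;
(ii) the inference is only defensible between *compatible* processes —
same catalyst class, comparable temperature, time and pollution controls;
(iii) within a homologous category, properties and emissions change
regularly (here: linearly, or log-linearly for quantities that span
decades) with an incremental structural descriptor such as carbon count.
Emission factors are carried on a mass basis (kg/kg) without molar
correction; a molar adjustment would double-count the property
differences that the read-across factor already expresses, and the
one-to-one worked example deliberately transfers values unchanged. A
molar-basis variant can be obtained by supplying a molecular-weight
read-across factor explicitly.

## Similarity and the fingerprint default

Analogue ranking uses the Tanimoto coefficient |A∩B|/|A∪B| over hashed
binary fingerprints. The default scheme is the **atom-pair** fingerprint
(all heavy-atom pairs annotated with topological distance, hashed to
2048 bits). Atom pairs encode overall molecular size and shape as well as
local substructure, which matters for this use: circular (Morgan)
fingerprints score a larger disubstituted homologue
(1,4-diisopropylbenzene) as *more* similar to p-cymene than cumene is,
because every circular environment of cumene recurs in the
bigger molecule; the atom-pair representation penalises the size
difference and ranks cumene first, matching the choice an exposure
assessor makes for this pair. Morgan (radius configurable) and RDKit
path fingerprints remain available; every fingerprint is stamped with a
`scheme_id` and cross-scheme comparisons are rejected.

Tanimoto *values* are not comparable across schemes — atom-pair scores
for accepted analogue pairs run far lower than circular-fingerprint
scores for the same pairs (a well-documented property of fingerprint
similarity distributions). All similarity thresholds are therefore
calibrated per scheme and exposed as configuration:

| scheme | analogue cutoff | grade "low" ≥ | grade "moderate" ≥ |
| --- | --- | --- | --- |
| atompair (default) | 0.3 | 0.5 | 0.25 |
| morgan / rdkit | 0.7 | 0.9 | 0.7 |

Two empty bitsets score 1 by convention (identity of empty molecules).
Ties in analogue ranking are broken by smaller molecular-weight
difference to the target, then lexicographic id, making the ranking
deterministic and invariant under library permutation.

## Molecular weights

Computed from a fixed internal table of conventional (abridged IUPAC)
atomic weights so that results are bit-reproducible across platforms and
RDKit versions; reports round to 1 decimal place, full precision is kept
internally.

## Category validation

Members are ordered by carbon count; each consecutive pair must share an
identical functional-group multiset (detected with a fixed SMARTS
dictionary: acids, esters, aldehydes, ketones, alcohols, ethers, amines,
amides, nitriles, halides, aromatic rings, alkenes, alkynes) and differ
by at most 2 carbon atoms. Failures are reported per pair with reasons,
never raised — an invalid category is a legitimate, reportable finding.

## Read-across factors and estimation modes

A per-property factor is the ratio target value / source value. The
overall factor combines selected per-property factors by geometric mean
(default), product, or is forced to `unity` when the assessor judges the
property differences insignificant. The default property subset for the
air medium is vapor pressure alone, since volatility dominates air
releases; the subset is configurable. Four modes produce estimates:
closest-analogue transfer, category trend (ordinary least squares on
log₁₀ emission vs. descriptor, evaluated at the target; extrapolation
outside the members' descriptor range is flagged), arithmetic average,
and conservative (maximum — the protective worst case for exposure; both
pooling modes require at least two sources). Every estimate stores its
source chain, factor breakdown and (for trend) the regression inputs, so
`audit_estimate` can recompute the value from the estimate's own record
and check bit-for-bit equality.

## Process compatibility

A catalyst-class mismatch blocks estimation. With matching catalysts,
warnings (not failures) are raised when |ΔT| > 50 °C, when the reaction
time ratio exceeds 2, or when the pollution-control sets differ; unknown
conditions raise nothing. The thresholds are configuration keys; the
defaults mark differences large enough that an assessor should inspect
the processes rather than trust the transfer silently.

## Uncertainty grading

Five drivers, each low/moderate/high; the overall grade is the worst.
Structural similarity is thresholded per scheme (table above); process
similarity maps compatible-without-warnings → low, warnings → moderate,
incompatible → high; source-data basis maps measured → low, estimated →
moderate, read-across → high (confidence in second-hand estimates rests
on the reliability of those estimates); any trend-filled property or any
extrapolation forces at least moderate. The driver set and the numeric
thresholds are this package's reconstruction of the qualitative
low/moderate/high rule — no published numeric criteria exist — and
trend-filled properties are allowed to feed read-across factors precisely
because the grade then records the added uncertainty. Degrading any
single driver never improves the overall grade (property-tested).

## Synthetic data

The generator builds n-alkylbenzene homologous series (6 ring carbons
plus an n-alkyl chain) whose properties and emissions follow stated
(log-)linear laws in total carbon count, with optional multiplicative
log-normal noise on emissions (emissions are positive and span decades;
additive Gaussian noise on log₁₀ is the natural model). A mandatory seed
makes generation reproducible, and the noise-free ground truth is
returned alongside the noisy records. Default validation sizes: 5–6
member series for exact recovery checks (zero noise, recovery to
relative error < 1e−9) and a 50-member series at noise σ = 0.2 log₁₀
units for slope-recovery checks (fitted slope within 3 standard errors
of the generating slope). What the generator does **not** emulate:
heteroscedastic measurement error, correlated emissions across species
in one process, non-monotone structure–emission relationships, and
multi-step processes. Passing tests on synthetic series therefore
demonstrate the estimator's correctness under the stated laws, not the
validity of the log-linear assumption for any real chemical family.

## Numerical choices and degenerate inputs

Trend fits use `numpy.polyfit` (degree 1); slope standard errors use
`scipy.stats.linregress`. A trend requires ≥ 2 members with data and
≥ 2 distinct descriptor values. Zero source property values make a
factor undefined and raise; non-positive factors are rejected under the
geometric mean. Emission values must be finite and ≥ 0 at the schema
boundary, with row/column coordinates in every validation error. CSV
emission values are written with `repr` so write∘read round-trips
float64 exactly.

## Known limitations

- Only structural analogy is modelled; metabolic/breakdown similarity and
  mechanistic analogues are out of scope.
- The case-study evidence base is a single one-to-one pair; multi-member
  category behaviour is validated on synthetic series only.
- Media other than air are accepted by the schema but no multi-media
  partitioning is attempted.
- Fugitive vs. point-source apportionment and control-device efficiency
  are not modelled; pollution controls enter only as a set-difference
  warning.
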