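# Methods

## The disease-state lattice

A structured periodontal diagnosis carries up to five attributes.  Three of
them — disease type, severity, extent — are ordinal and define the state used
for change classification:

| attribute | values (rank) |
|---|---|
| type | gingivitis (1) < periodontitis (2) |
| severity | mild (1) < mild-to-moderate (2) < moderate (3) < moderate-to-severe (4) < severe (5) |
| extent | localized (1) < generalized (2) |

States are ordered **lexicographically** with type ≻ severity ≻ extent.  This
is the package's own resolution of an ordering that published worked examples
constrain but do not fully specify: a type change dominates (mild gingivitis →
mild periodontitis is progression even though severity is unchanged), severity
decides within a type, and extent decides when type and severity tie
(generalized → localized mild periodontitis is improvement).  One consequence
is deliberate and worth flagging: *severe gingivitis → mild periodontitis*
classifies as progression, because any gingivitis-to-periodontitis move does.
No worked example covers that cross-type, opposite-severity case; the
lexicographic rule is the simplest total order consistent with all the cases
that are covered.

Intermediate severities interleave strictly between their neighbours.  They
appear in documented diagnosis inventories as distinct categories but never in
a transition example; strict interleaving is again the minimal choice.

States missing severity and/or extent are **partial**.  Two states compare on
the longest shared non-missing prefix; if that prefix ties and a compared-out
field is missing on either side, the pair is *incomparable* and classification
reports *unknown*.  Bare "periodontitis" can therefore still register a
type-level change against "gingivitis", but never a within-type change.
Location and onset are carried as metadata and never influence ordering — no
known classification rule uses them.

## Extraction

Notes are lowercased and split on non-alphanumeric runs (hyphens split, so
"mild-to-moderate" and "mild to moderate" normalize identically).  Token
n-grams are matched against the lexicon by Levenshtein distance (edlib).  The
per-term distance budget defaults to `max(1, len(term)//5)` capped at 2: one
typo is tolerated on short terms while "mild" (distance 6 from "moderate")
cannot collapse into another severity.  A global `--max-dist` cap can tighten
this.  Overlapping candidates resolve deterministically: lowest distance wins,
then longest span, then lexicon order, then position.  Compound severities are
3-token entries and win distance ties against their components, so "mild"
never shadows "mild to moderate"; a compound carrying typos in *two* of its
tokens exceeds a distance budget of 1 and falls back to the clean component —
the dominant residual error mode under heavy noise.

Assembly is bottom-up: each disease-type mention yields one record; severity /
extent / onset / location modifiers attach to the nearest type token within a
6-token window, preferring the following type token (the natural "generalized
mild periodontitis" order) and falling back to the preceding one
("periodontitis of the mandible").  Modifiers with no type token in range are
dropped.  Absent fields become explicit missing markers — graceful degradation
is the contract, and a note with no type match emits a single missing-bucket
record so note and record streams stay aligned.  Negation and uncertainty
("no periodontitis", "possible perio") are out of scope by design.

## Change classification

Two visits form an eligible transition only if they are at least
`min_gap_days` apart (default 90, **inclusive**: the source rule says "90 days
apart" without stating strictness, and ≥ is the weaker reading).  Two views
are computed:

* **Consecutive scan** — an anchor visit walks the timeline; closer-than-gap
  visits are ignored (anchor retained), identical-state visits are skipped
  (anchor advances), and remaining pairs are emitted as labelled transitions.
* **First-versus-last** — the headline cohort label compares the earliest and
  latest *classifiable* (non-missing-type) diagnoses; intermediate excursions
  are ignored by definition.  Patients with fewer than two classifiable
  diagnoses, a first-to-last gap under the minimum, or unorderable states are
  *unknown*.  Skipping unparseable missing-bucket rows before taking
  first/last is this package's choice; the alternative (letting them poison
  the comparison) would only enlarge *unknown*.

Same-day duplicate records collapse to the most complete record, later input
order breaking ties — the last-documented complete diagnosis is taken as the
visit's diagnosis.

## Density statistics

Observation time is last-minus-first visit date in days; years are
days/365.25 (the sources mix days, months and years without a conversion
rule).  Follow-up categories have inclusive upper bounds ("up to 5 years"
includes exactly 5.0 years, matching the ≤ in the adjacent categories) and
zero observation time is "no follow-up".  Interval summaries report mean,
median, sample SD (n−1) and the normal-approximation CI mean ± 1.96·s/√n;
"95% confidence interval" is not otherwise specified in the sources, and the
normal approximation is the convention for n in the hundreds.  A single
observation reports SD 0 and a point CI rather than an undefined value.  The
CI is asymptotic: coverage is verified in the suite at n = 100 on a mildly
skewed lognormal (log-sd 0.35), and heavily skewed gap distributions
(log-sd ≳ 0.9) undercover at that n — a limitation of the normal
approximation, not of the implementation.

## Evaluation

All metrics are computed from the four confusion-matrix cells in closed form;
zero-denominator metrics are explicit nulls in every output, never silent
zeros.  F1 is the harmonic mean of precision and recall.  Multiclass cohort
evaluation macro-averages one-vs-rest reports, the unweighted mean being the
neutral choice where no aggregation is specified.  Cohen's kappa uses the two
annotators' marginal frequencies for chance agreement; the degenerate
single-label case (p_e = p_o = 1) is defined as κ = 1, i.e. perfect
agreement.  scikit-learn implements the same quantities and serves as an
independent cross-check in the test suite, never as the implementation.

## Synthetic corpus generator

The generator emulates the *documentation structure* of longitudinal dental
records, with defaults fixed to the documented density profile of a large
dental-school EDR:

| parameter | default | rationale |
|---|---|---|
| visit-count distribution | 1: 58%, 2: 24%, 3: 8%, 4+: 10% | reported diagnoses-per-patient distribution; the 4+ bucket extends geometrically to 28 |
| inter-visit gap | lognormal, median 346 d, log-sd 0.9 | reported mean first-to-second interval 346 d; log-sd chosen so the implied SD (~550 d) approximates the reported 584 d, and the heavy tail reproduces clustered visits |
| trajectory mix | static 75%, progress 13%, improve 12% | reported cohort shares (72/13/11 of classifiable patients) renormalized over the three planted classes |
| severity dropout | 0.14 | share of bare "gingivitis"/"periodontitis" diagnoses in the reported inventory |
| extent dropout | 0.10 | extent appears in essentially every reported transition category |
| onset / location dropout | 0.80 / 0.70 | sparsely documented metadata; no reported figure, chosen once as realistic |
| typo rate | 0.05 per content token | single-character edits only |

Severity/extent/onset/location dropout is a **per-patient documentation
habit**, constant across a patient's visits: clinicians who write
"generalized mild periodontitis" tend to write it every time.  Drawing
dropout independently per visit instead makes almost every static multi-visit
patient incomparable (any partial state in a tied pair → unknown), which
contradicts the small *unknown* fractions seen in real multi-visit cohorts.
Disease-type dropout (2%) stays per-visit — the occasional unparseable note.

Trajectories are monotone walks on the 20-state lattice: static patients
repeat one state; progressing (improving) patients take non-decreasing
(non-increasing) steps with magnitudes drawn from {1: 0.70, 2: 0.25, 3: 0.05}
and a guaranteed strict first-versus-last change.  Notes render through a
small template set in the natural word order, every template carrying all
five field slots so the rendered text contains exactly the gold fields; typos
are single-character edits applied per content token.  Each patient has an
RNG stream derived from (seed, patient index), so corpora are byte-identical
across re-runs and robust to generation order.

What the generator does **not** emulate: real clinical-note dialects
(section headers, abbreviations beyond a few chart shorthands, negation),
correlated disease course and visit frequency, treatment effects, or
charting-number streams.  Passing the end-to-end recovery tests therefore
demonstrates the pipeline's correctness on statements of the modelled form,
not performance on any institution's actual notes.

## Problem sizes in the suite

The acceptance-style checks use exhaustive enumeration where the space is
small (all 400 ordered full-state pairs), 1,000-patient corpora for
end-to-end recovery, 10,000 random matrices for the metric closed forms, and
1,000 replicates of n = 100 for CI coverage — sizes at which every binomial /
CLT bound used in an assertion is tight enough to be meaningful while the
whole suite stays fast.
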