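# Methods

## The survey model

The atomic record is the use report: one informant citing one species
for one ailment. An informant citing the same species for two ailments
contributes two reports (Ui = 2) but only once to FC; this is the only
counting convention under which ΣUi ≥ FC holds row-wise and per-species
UV ≥ RFC follows identically. Respondents who did not complete the
interview are retained with `included = false` for demographic
bookkeeping but are barred from carrying reports and excluded from the
denominator N; all indices divide by the count of included informants.

Plant parts, preparation modes and administration routes are controlled
vocabularies; a report may carry several `;`-separated values.
Tabulations of these attributes use species-level multi-count
semantics: each *distinct* value recorded for a species counts once, so
83 species with a handful of two-part records can produce a parts
denominator of 91. Families are counted once per collected species,
knowledge sources once per (informant, source) pair.

Ailments are free text and are classified into the twelve ICPC primary
care categories through a total mapping table; an unmapped ailment is a
validation error, never a silent drop, because a dropped report would
silently deflate Nur.

### Name canonicalization

Cross-referencing and deduplication key on the authority-free binomial:
italics markup and author citations are stripped, whitespace collapsed,
genus capitalized, epithet lower-cased, and infraspecific ranks
(`var.`, `subsp.`) preserved with their epithets. The transform is
idempotent, so canonical names can be re-canonicalized at any module
boundary. No live nomenclature service is queried — matching is
deterministic from the input tables; users may pre-apply their own
synonym table if their references use different accepted names.

### Rounding

Indices are kept as exact `Fraction`s and displayed with half-up
rounding at a configurable number of digits (default 2). Half-up
matters because ratios of small integers over N = 80 produce exact
decimal ties (74/80 = 0.925 → 0.93); banker's rounding would disagree
with the published convention on half of them. Rounding goes through
exact decimal arithmetic, never through binary floats, so a tie is
recognised as a tie.

## Fic and its interpretation

`Fic = (Nur − Nt)/(Nur − 1)`. Nt is the number of distinct *taxa* cited
for the category. A natural-language gloss of Nt as "number of
respondents" circulates in the survey literature, but only the
distinct-taxa reading keeps Fic within [0, 1] with its usual endpoints
(1 = one taxon absorbs all reports, 0 = every report a different
taxon), and it is the reading under which the published category tables
reproduce exactly, so it is the one implemented. With Nur ≤ 1 the
denominator vanishes; such categories take a configured degenerate
value, default 0, matching how published tables print single-report
categories.

The interpretation step (`interpret_consensus`) screens categories at
`fic_threshold` (default 0.8), flags "common local disease" categories
at `nur_threshold` (default 50 reports), and ranks each retained
category's plants by category-restricted FC — distinct informants
citing the species *for that category* — which never exceeds global FC.
The thresholds are design defaults chosen to retain the handful of
high-consensus categories a survey of ~80 informants typically
discusses; both are config-exposed. All ties break lexicographically by
canonical name so reports are byte-reproducible.

## Cross-referencing

Overlap is exact set intersection of canonical binomials, reported as a
percentage of the survey checklist. Shared use requires a controlled
use vocabulary: survey ailments are mapped to use terms, each reference
supplies a species → use-term map, and a species counts as shared when
its surveyed terms intersect the reference's terms in *every* listed
reference. Novelty partitions the survey into matched and novel
species; novel (species, use) pairs are reported only for known species
by default — the uses of a wholly novel species are implied by its
novelty and are listed under it, not double-counted — switchable via
`include_novel_species_uses`. Infraspecific names match at full rank;
falling back to the binomial is deliberately off by default since it
can conflate a cultivated subspecies with its wild type.
Membership-only regulatory lists (food-raw-material lists,
pharmacopeias) are handled as references without use maps.

## Co-use rules and network

Baskets are per-informant deduplicated species sets (empty baskets are
retained so the support denominator equals N). Only pairwise rules are
mined: support is the number of co-citing informants, confidence the
support over the antecedent's citation count. At survey scale (≤ a few
hundred species) exact enumeration over observed pairs is instantaneous,
so no candidate-pruning machinery (apriori/FP-growth) is warranted; the
identity `confidence(A→B)·count(A) = support` holds exactly in integers
before any rounding. Counting units are informants, not report rows —
a single informant repeating a pair across ailments is one co-use.
Defaults `min_support = 2`, `min_confidence = 0.5` suppress
single-informant coincidences while keeping a survey-sized network
legible; both are config-exposed. Rules collapse into an undirected
networkx graph (edge: pair support plus both directed confidences;
node: global FC), exported as GraphML or an edge CSV, both lossless
under re-import.

## The synthetic generator

`generate_survey(SimConfig)` emulates the data structure the analysis
assumes, with known ground truth:

- **Informants** — exact gender stratification (default 45/80 female),
  categorical age/education/township draws; a configurable number of
  excluded respondents is emitted alongside.
- **Knowledge** — distinct species per informant is zero-truncated
  Poisson with a per-gender mean (defaults 6 female / 4 male; the
  truncation mirrors treating zero-knowledge respondents as excluded).
  With these means the implied female/male ratio is
  6.01/4.07 ≈ 1.48 after truncation.
- **Species choice** — each category holds a symmetric-Dirichlet
  probability vector over the species pool with per-category
  `concentration`: low concentration (e.g. 0.03) concentrates mass on
  few taxa → few taxa absorb the category's reports → high Fic; high
  concentration (≥ 1) spreads reports → Fic toward 0. This is the
  single dial mapping to consensus, and the per-category defaults are
  graded to produce the familiar spectrum from ~0.9 down to degenerate
  single-report categories.
- **Reports** — each (informant, species) citation yields 1 + Poisson
  extra reports (mean 1.1 total) on distinct ailments of the category;
  parts/preparations/routes follow fixed categorical laws in which
  whole plant, decoction, and oral administration dominate.
- **References** — `make_reference_flora` includes
  `round(coverage · n_species)` survey species and gives a matching use
  term to `round(agreement · n_cited_included)` of the cited ones, so
  overlap and shared-use percentages are set by construction.

All randomness flows from one seeded `numpy` generator; identical
configs give byte-identical CSVs across runs and platforms. What the
generator does **not** emulate: interviewer effects and saturation
stopping, correlation between demographics and *which* species an
informant knows (only how many), geographic structure among townships,
and free-text ailment noise (synthetic ailments are already controlled
vocabulary). Tests passing on synthetic data therefore validate the
counting and index arithmetic and the recovery of consensus/knowledge
parameters — not robustness to messy real-world transcription.

## Problem sizes used in the test batteries

Oracle-equivalence checks run the pairwise miner against brute-force
enumeration on 1,000 random fixtures of ≤ 10 informants × ≤ 8 species;
index invariants (UV ≥ RFC, ΣUi ≥ FC, Fic bounds and strict
monotonicity in Nt) are asserted over 10,000 random micro-datasets;
parameter recovery uses 100 replicates at the survey's own scale
(n = 80) for consensus ordering and a single n = 2000 run for the
knowledge-rate ratio. These sizes give exhaustive coverage of the small
combinatorics and tight Monte-Carlo error at negligible cost.

## Known limitations

- Demographic summaries report raw fractions only; published figures
  sometimes apply inconsistent integer rounding, which is left to the
  caller's display layer.
- A printed half-up tie can disagree with a source table that rounded
  the same value down elsewhere; the package always reports the
  computed rounding and leaves reconciliation to documentation.
- Shared-use agreement is only as good as the controlled use vocabulary
  mapping; free-text efficacy comparison is out of scope.
- Category-restricted FC and global FC can differ for the same species;
  both are reported, and consumers should cite which one they mean.
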