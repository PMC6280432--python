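# Methods

`ampliref` implements the curation workflow behind body-site-focused 16S
rRNA reference databases: species-level taxonomy is an operational
definition (a percent-identity/coverage threshold against a small set of
highly curated references), the reference set is grown iteratively from
clone libraries, amplicon-region choice is evaluated by how many species
it collapses, and body-site preference is a deterministic screen over a
taxon-by-site count table. This note records the models, the defaults
and why, the numerical conventions, and what the synthetic data do and
do not show.

## Species-level assignment

A query is assigned to the species of its best-scoring reference hit
when the hit reaches **98.5% identity over 98% query coverage** (both
inclusive). Best hits in the **[98, 98.5)% band with coverage met** are
*set aside*: they are reported as `ambiguous_band`, counted as NOT
identified in benchmark rows, and excluded from novel-taxon clustering,
so no new taxon is called where an existing taxon nearly matches.
Everything else is `unassigned`.

Identity and coverage follow blastn conventions, which the original
curation searches used:

* **identity** = matches / aligned columns, counting internal gap
  columns and excluding terminal overhangs;
* **coverage** = query span / query length (*query* coverage: queries
  are clones or reads, subjects are near-full-length references).

Scoring defaults are the blastn default task's: match +2, mismatch −3,
gap open −5, gap extend −2; a gap of length L costs open + L·extend.
`N` never counts as a match, including against another `N`. Hit ranking
uses the raw local-alignment score (an E-value would need database-size
statistics and adds nothing for ranking within one fixed database); ties
break by higher identity, then longer alignment, then lexicographically
smaller reference id.

### Alignment engines and determinism

Two Gotoh dynamic-programming engines share one scoring model: a local
(Smith–Waterman) aligner for classification and an end-gap-free global
aligner for comparing homologous amplicon regions of near-equal length.
Both are exact and deterministic. Where co-optimal alignments exist the
traceback convention is part of the contract: the end cell is the first
maximum in row-major scan order; diagonal steps are preferred over
subject-consuming gaps over query-consuming gaps; gaps close as early as
possible (shorter gaps win at equal score). The test suite checks the
production kernels against an independent naive pure-Python DP that
follows the same written convention, so identity/coverage agree exactly,
not just the score.

### Prescreen

Searching every query against every reference with full DP is wasteful
when most references are hopeless. `classify_set` first ranks references
by semi-global edit distance (edlib) and runs the exact scored alignment
only on references within `prescreen_margin` (default 16) edits of the
best. Near the assignment threshold, competing hits differ by a handful
of edits, so the margin retains every reference that could win the score
ranking; for sets of at most `prescreen_min_refs` (default 8) references
the search is always exhaustive, which also keeps small constructed test
cases on the exact path. A query far from all references may have its
sub-threshold "best" hit chosen among several similarly distant
references; its band is unaffected.

## Reference database model

Each species-level taxon carries a stable integer identifier (HMT
number) in the 100–999 namespace, a lineage (domain→genus), a naming and
cultivation status, a primary body site, and 1–6 curated reference
sequences whose ids start with the zero-padded 3-digit HMT number.
Numbers of deleted taxa are retired and never reallocated; allocation
returns the smallest integer not live and not retired (the original
scheme does not document an allocation rule; smallest-unused is chosen
for determinism). Reference-grade sequences must be pure A/C/G/T —
ambiguity codes always count as mismatches in search, so curated
references exclude them. Default loading is strict (reject, listing
offending ids); `ambiguity="mask"` converts non-ACGT to N and demotes
the record from reference grade.

Unnamed taxa carry a systematic provisional name: `Family [G-n]
bacterium HMT-xxx` for unnamed genera, `Genus bacterium HMT-xxx` for
unnamed species in a known (or display-string) genus. How genus indices
`[G-n]` are assigned when several unnamed genera share a family is not
derivable from any rule we know of; the index is therefore
caller-supplied, never inferred.

## Region resolvability and supraspecies

Regions are extracted between primer sites located with IUPAC-aware
mismatch counting (default 2 mismatches per primer; forward primer =
leftmost window, reverse primer matched as its reverse complement,
rightmost window). The extracted insert excludes the primer sites
(amplicon-insert convention). Built-in definitions: V1-V2 (27F/338R) and
V1-V3 (27F/534R); V3-V4 primers vary between labs and are caller
supplied.

The taxon-by-taxon identity matrix uses the end-gap-free global aligner
on extracted regions; taxa with several references contribute their
**maximum** inter-taxon identity (a pair is indistinguishable if any
reference pair is). Collapse at threshold *t* takes **single-linkage
connected components** of the graph with edges at identity ≥ *t*: the
conservative (largest-group) reading of "indistinguishable at a
threshold", stated in all outputs. At *t* = 100 the components coincide
with exact-string equivalence classes of the extracted regions, which
the tests verify against a hashing oracle.

Training sets label each within-genus indistinguishable group as a
supraspecies: genus + alphabetically sorted epithets joined by
underscores (`Staphylococcus_capitis_caprae`), preserving subgenus
resolution for naive-Bayes classification. Cross-genus groups, and
groups containing unnamed taxa (which have no epithet), are flagged and
left ungrouped for curator review. At the default grouping threshold of
100% identity the "mutually indistinguishable" invariant holds exactly
(equality is transitive); at lower thresholds single-linkage groups may
chain, which is why sub-100 grouping is not the default.

## Reference expansion

One round: classify → partition bands → greedily cluster the unassigned
sequences → promote supported clusters → re-classify.

* **Clustering**: greedy centroid clustering at ≥98.5% identity over
  ≥99% query coverage, processing sequences by descending length (ties:
  lexicographic id); a sequence joins the first centroid it matches,
  else founds a new one. The algorithm is deterministic and pluggable.
* **Minimum support**: only M-OTUs with ≥10 members become candidate
  taxa; smaller clusters are reported but not promoted.
* **Representative**: the medoid (highest mean identity to the other
  members; ties: longest, then smallest id). The original workflow chose
  representatives by visual inspection of cluster alignments and
  sometimes substituted superior public sequences; the medoid rule is
  the reproducible stand-in, and curators can replace representatives
  afterwards.
* **Placement**: a candidate's lineage and provisional name come from a
  caller-supplied family hint or, by default, a majority vote over the
  genera of its representative's top three sub-threshold hits
  (tie: lexicographically smallest genus). The vote is a heuristic of
  this package and is flagged in reports together with the nearest-
  reference identity so curators can triage; phylogenetic confirmation
  of candidates is out of scope.

The round never mutates its input reference set; failures abort before
any change. Because adding references can only raise any query's best
score, the identified percentage is monotone non-decreasing across a
round, and a second round over the same library proposes nothing new.

## Habitat preference

Steps, given a taxon × site count table: normalise every site column to
20,000 clones; express each taxon's normalised counts as percent of the
taxon's own total; divide the focal-site percent by the even-spread
expectation 100/n_sites (n_sites from the table, 21 in the motivating
data); rank taxa by focal-site normalised abundance (ties:
lexicographic id; whether the original ranking used raw or normalised
counts is ambiguous — normalised is used and noted); call a taxon
focal-site-preferred only if ranked ≤ 20 and ratio ≥ 2. With 21 sites
this requires a focal percent ≥ 200/21 ≈ 9.52%. The screen is a
deliberate lower bound — no call is ever forced — and is not a
statistical test. Scores are invariant to rescaling any column, since
normalisation absorbs sampling depth.

## Synthetic data

The generators plant known structure so every recovery claim is checked
against ground truth:

* **References**: one random backbone per seed; conserved islands (a
  10-nt pad + a 27F realisation, and the 338R/534R reverse-complement
  sites) copied verbatim into every taxon so extraction never fails
  unless a failure is planted; taxa diverge by substitutions confined to
  variable blocks at 2.5% per site by default (typical of congeneric
  16S distances). Substitution-only evolution keeps identity
  expectations analytic: two taxa at rate p differ at a variable site
  with probability 2p(1−p) + (2/3)p². Supraspecies are planted by
  copying one member's region into the others (forcing ≥1 difference
  outside); fixed region identities (e.g. a 99.2% chain) are planted by
  copying a source region and substituting an exact number of positions,
  disjoint across plantings from the same source.
* **Clone libraries**: uniform-abundance full-length copies of the
  references with 0.2% per-base substitution error (clone-library-scale
  error); planted novel taxa are fresh lineages at 5% divergence (so
  their reads fall below the 98% band floor) with configurable support.
* **Count tables**: per-site multinomial draws at 20,000 clones over 21
  sites and 25 taxa with gently decaying baseline abundances. A planted
  factor f sets the focal proportion so that the expected enrichment
  ratio **equals f**; unplanted taxa share the remaining focal mass pro
  rata and sit well below ratio 2.

What the synthetic data do **not** emulate: indels and chimeras (an
indel mode exists for aligner stress tests only), quality scores,
rRNA secondary structure, copy-number variation, realistic rank-
abundance skew, or taxonomies with misannotated references. Passing
recovery tests therefore demonstrates correctness of the algorithms
under the stated model, not end-to-end accuracy on real surveys.

## Problem sizes and numerics

The recovery suite runs at 40 taxa × 1,500 nt references, a 1,000-read
background library plus planted novel support {50, 12, 9}, and
50 random aligner-oracle pairs of length ≤ 300 — sizes chosen so the
full pipeline (two classification passes, clustering with medoid
selection, a region identity matrix over 780 taxon pairs) completes in
minutes on one core while leaving no planted structure untested.
Alignment DP uses 32-bit integer scores (no floating point in the
recursion, so results are platform-independent); fractions and
percentages are computed in double precision at the end. All generator
randomness derives from one integer seed through a single numpy
Generator per generator call.

## Known limitations

* E-values are not computed; ranking is score-based within one database.
* Multi-HSP hit combination is not attempted: one best local alignment
  per query/reference pair.
* Whether the original coverage gate was query- or subject-side is not
  documented; query coverage is assumed (flagged to users).
* The expansion loop is single-round by design; iteration is
  user-driven, with no automatic stopping rule.
* Habitat calls depend on the assignment step that produced the count
  table; this module scores whatever table it is given.
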