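# Methods

## The delineation model

The pipeline operationalizes distance-based DNA-barcode species
delineation for a protein-coding mitochondrial marker (COI, ~655 bp).
Its premise is the classical barcoding-gap assumption: within-species
divergence is small and roughly homogeneous across the assemblage,
between-species (congeneric) divergence is several-fold larger, and the
two distributions do not overlap. Everything downstream — thresholds,
anomaly flags, species verdicts — is a consequence of that premise plus
two standard estimators:

* **K2P distance.** For each sequence pair, transitions (A↔G, C↔T) and
  transversions are counted over columns where both sequences carry an
  unambiguous base (pairwise deletion), giving proportions *P* and *Q*
  and the distance d = −½·ln((1−2P−Q)·√(1−2Q)). Pairs for which either
  logarithm argument is non-positive (saturation) are recorded as
  undefined and excluded rather than aborting the run. The delta-method
  sampling variance (Kimura 1980) is exposed as `k2p_variance` and used
  wherever a tolerance must be justified.
* **Neighbor joining.** Saitou–Nei agglomeration with the
  Studier–Keppler Q-criterion. Ties in Q are broken by the lowest pair
  index in node-creation order, making trees reproducible across
  platforms; negative branch estimates are clamped to zero without
  length transfer. On additive inputs the generating topology and branch
  lengths are recovered exactly (this is an acceptance oracle).
  Bootstrap supports resample alignment columns with replacement,
  rebuild the tree, and report the percentage of replicates containing
  each original bipartition; replicates that produce an undefined pair
  are dropped and counted, and more than 10 % dropped aborts with an
  error.

## Thresholds, cohesion, and the dispersal screen

Defined pairs are partitioned by label metadata into conspecific,
congeneric, and cross-genus sets; cross-genus pairs never enter
thresholds or flags (the gap is defined within genera). The thresholds
are extreme order statistics:

* `max_conspecific` — maximum conspecific distance over *eligible*
  pairs;
* `min_congeneric` — minimum congeneric distance over eligible pairs;
* `gap_fold = min_congeneric / max_conspecific`, reported to two
  decimals.

Eligibility has two layers. The first is **species-level cohesion**: a
species' records must form an exclusive clade in the NJ tree (singleton
species are cohesive by convention; an optional minimum bootstrap
support on the separating edge is available but off by default, since
topology alone reproduces the intended behavior and support thresholds
add a tunable with little benefit on clean data).

The second layer exists because topology cannot catch everything: a
single deep-divergent record that attaches *sister to its own species*
still forms an exclusive clade with it, and — since thresholds are a
maximum — would silently inflate `max_conspecific` and thereby mask its
own anomaly. The original analysis resolved this by expert judgment of
the tree plot; the package formalizes it as a **dispersal screen**
anchored on the method's own premise. The gap assumption requires the
congeneric floor to be at least twice the conspecific ceiling; a record
whose *nearest* conspecific distance exceeds half the congeneric floor
(the floor computed over cohesive species) would by itself cap the gap
below two-fold, so it is marked *dispersed*: excluded from threshold
eligibility, kept in the analysis, and still exposed to flagging. The
factor 2 is the weakest gap any delineation threshold could tolerate,
not a fitted constant. Mislabeled records are caught by the same screen
(their nearest "conspecific" is a different species away), and their
host species additionally fail cohesion.

Flags are then evaluated against the thresholds over **all** defined
pairs:

| flag | condition | reading |
|---|---|---|
| `conspecific_merge` | congeneric pair, d ≤ max_conspecific | mislabeled record or synonymy |
| `deep_conspecific_divergence` | conspecific pair, d > max_conspecific | isolated lineage / cryptic species |
| `subthreshold_congeneric` | congeneric pair strictly inside the gap | gap erosion, inspect |

Boundary conventions: equality with the ceiling counts as a merge
(conservative flagging); equality with the floor is not flagged. A
species is **delineated** iff it is cohesive and none of its records
appears in any flag; otherwise it is **ambiguous** and carries its
flags. The spec for this analysis also sketches an iterative
re-estimation mode; the implementation is single-pass (cohesion →
dispersal screen → thresholds → flags) because the screen already
removes the records an iteration would remove, and a single pass keeps
the estimator deterministic and easy to reason about.

## Database-match classification

Best-hit tables (query species; database ∈ {genbank, bold}; match name
or `NO_MATCH`; % similarity) are banded at ≥97 / [92, 97) / <92 — the
published description leaves 91–92 unassigned, closed here as
"insignificant < 92". A species is **definitive** when every returned
match is same-named and significant; databases returning no match never
block this (a species identified by one database alone is still
identified). Otherwise categories are assigned per match and unioned
per species: cat1 (significant same-name *and* significant
foreign-name), cat2 (same-name both significant and insignificant),
cat3 (moderate same-name), cat4 (insignificant same-name with no
significant one), cat5 (no same-named match at all — missing reference
data). Two closure rules keep the classifier total and match how such
tables are read in practice: insignificant foreign hits are background
similarity and are ignored whenever any same-named match exists; and a
species whose only hits are foreign is cat5 regardless of band.

`resolve_with_flags` reconciles categories with the divergence/tree
anomalies, in order: cat3/cat4 plus a deep-divergence flag →
*inconclusive* (the conflicting record may be an independent lineage;
distance data cannot adjudicate); cat1/cat2 plus any flag → *identified
with a mislabel note* (the conflict traces to a deviant database
record); unflagged definitive or cat5 species → *identified* (the
latter delineated by tree and gap alone, contributing new reference
barcodes). Everything else stays inconclusive.

## The synthetic-data generator

`simulate_dataset` draws a star-of-stars phylogeny: a uniform-random
ancestral sequence, one branch per genus (U(inter.hi/2, inter.hi), so
cross-genus pairs sit clearly beyond the congeneric range), one per
species (U(inter.lo/2, inter.hi/2), so congeneric pair sums land inside
the configured congeneric range), one per individual
(U(intra.lo/2, intra.hi/2), likewise for conspecific pairs). Sequences
evolve by the exact K2P transition kernel per branch, so the K2P
estimator is correctly specified and parameter recovery is a clean
acceptance surface. Defaults are the study scale: 3 genera × 3 species
× 3 individuals, 655 sites, conspecific divergence U(0, 0.02),
congeneric U(0.10, 0.15), transition/transversion rate ratio κ = 4
(typical of fish mitochondrial COI; the analysis is insensitive to κ,
which only shapes the P/Q split).

Because COI is protein-coding and the QC stage enforces a stop-free
reading frame, the generator emulates purifying selection against
nonsense changes: the ancestral sequence is drawn stop-free in frame 1,
and any substitution that would create a vertebrate-mitochondrial stop
codon (TAA, TAG, AGA, AGG) is reverted. This suppresses realized
divergence by roughly 5 % relative to nominal branch lengths — inside
every tolerance used — and leaves ancestral base composition only
approximately uniform (A mildly depleted), which the composition sanity
check allows for (±0.04 around 0.25).

Injections, with full truth-table bookkeeping:

* **Mislabel** — one record's label swapped to a congeneric sister
  species; the sequence is untouched. This is exactly the failure mode
  of a misidentified database submission.
* **Deep lineage** — one individual re-evolved from its species
  ancestor along a longer branch. Branch draws control only the
  *expectation*, and at 655 sites a low realization would produce a
  record that is not actually deep — an incoherent test case. The
  generator therefore accepts on the realized quantity, redrawing the
  extra branch until the record's estimated nearest-conspecific K2P
  distance falls in intra.hi + [0.60, 0.95] of the gap (expected target
  drawn at 0.70–0.90). The injected case then matches its advertised
  role by construction: well past the conspecific ceiling, strictly
  below the congeneric floor.

What the simulator deliberately does not emulate: indels and alignment
error (the modeled marker has none), rate heterogeneity across sites,
within-species coalescent structure, uneven sampling across species,
and real database noise beyond the two injected anomaly types. Passing
tests therefore demonstrate correctness of the estimators and decision
rules under the model's own assumptions — not robustness to
misalignment or model misspecification on field data.

## Quality control

Records are kept when their ungapped length strictly exceeds 600 sites
(the boundary is strict: 601 passes, 600 fails) and at least one forward
reading frame is free of internal stops under the vertebrate
mitochondrial code; ambiguity codes never count as stops, and a stop in
a frame's final complete codon is terminal, not internal. Reverse
frames are not tested because barcode orientation is fixed by the
primers. The length floor is a NUMT proxy and is exposed as a
parameter, since surveys occasionally retain a few shorter sequences by
explicit choice.

## Numerical and reporting conventions

Distances are computed in double precision and reported to 3 decimals;
the fold gap to 2 decimals. Summary JSON is written with sorted keys
and fixed rounding, so identical configuration and seed give
byte-identical outputs; one seeded generator drives both the simulator
and the bootstrap. Pairwise deletion is the default (it preserves
information when ends are unevenly trimmed); complete deletion is
available as `--deletion complete`. Undefined pairs drop their records
from the tree stage with a logged warning. The YAML config file, when
given, takes precedence over command-line flags.

Test and acceptance problem sizes: simulated assemblages of 27 records
(9 species) over 20 seeds for threshold recovery and flag sensitivity;
bootstrap oracles at 1000 replicates on 10-taxon alignments; NJ oracles
on random additive trees of up to 10 leaves; K2P oracles exhaustively
over trinucleotide pairs and property-based over longer ones. These
sizes give each check sharp expectations (exact recovery, sensitivity
1.0, support 100) while keeping the whole suite fast.

## Known limitations

Thresholds are extreme order statistics and inherit their fragility:
one undetected anomalous record can move them. The dispersal screen
presumes the assemblage shares a common intra-species divergence
regime; a genuinely heterogeneous assemblage (some species old and
structured, others young) would trip it on honest records. Cohesion is
binary and unrooted-topological; paraphyly caused by a single database
record is treated the same as wholesale mixing. The match classifier
consumes best-hit tables as given — it does not model database
coverage, and its two closure rules (foreign-insignificant ignored,
foreign-only → cat5) are conventions for corners the published category
definitions leave open.
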