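# Methods

This note documents the models and numerical choices behind
`denticode`: what the disparity calculation assumes, how the shipped
distance matrices were constructed, what the synthetic generator does
and does not emulate, and where the design was genuinely open.

## The character schema

`denticles_v0.5` defines 46 discrete traits grouped by letter: overall
crown shape (A), anterior/posterior edge characteristics (B, C),
symmetry (D), cusps (E), overall ridge characteristics (F–H), central
and non-central ridge details (I, J), the central ridge system (K),
ridge size (L), depressions and dimples (M), surface texture (N), and
the subcutaneous base (O). Each trait enumerates consecutive integer
states starting at 0 or 1.

State 0, wherever it exists, is a sentinel with two readings that the
analysis deliberately treats identically: *broken/unobservable* (the
specimen does not preserve the character — common for edges, bases, and
surface detail of fossil crowns) and *inapplicable/absent-nested* (a
controlling character rules the trait out, e.g. cusp similarity on a
cuspless crown). Both are excluded from every distance computation;
collapsing them is safe precisely because neither carries comparable
morphological information. Eleven traits (A1, B3, C3, D1, E1, F1, G1,
G2, L1, M1, N1) have no 0 state: they are the first character of their
feature group and encode "feature absent" as an ordinary codable state
instead, which is what lets heavily broken specimens still share a
codable core.

Weights are read from the schema, never recomputed: the first character
describing a feature carries weight 1 (or 2 for the two globally
diagnostic traits, overall crown shape A1 and ridge system F1), and
nested characters elaborating on a feature carry 0.5 so that the
presence/absence of, say, ridges is not counted a dozen times.

Nesting rules are stored explicitly as (controller, triggering states,
required dependent values). Most requirements force a dependent to 0;
a smooth crown (F1 = 1) additionally forces the "none" states of the
counting traits that lack a 0 (G1 = 1, G2 = 1, L1 = 1, N1 = 1). Beyond
the implications evident in the state definitions for cusps, ridges,
central shapes, depressions, and textures, three follow directly from
state semantics and are encoded as rules rather than hard-coded: a
non-spade crown forces the spade subtype to 0; absence of a central
ridge forces central-ridge directionality and width to 0; absence of
dimples forces dimple shape to 0.

Versioning follows the published convention — new states bump the
version by 0.1, new traits by 1.0 — and the package bundles structural
stubs for the historical v0.1/v0.2/v0.4 entries (their matrices were
never published) so datasets referencing them remain loadable and
inspectable.

## Distance matrices: an ordinal reconstruction

The canonical numeric matrices for v0.5 live in external supplementary
material; the published text gives per-trait *verbal* descriptions of
which states are more or less alike. The shipped matrices therefore
encode only those orderings, via a fixed descriptor scale — identical 0,
similar/"more similar" 1, different/"equally different" 2,
very/significantly different 3, maximal 4 — with ordinal traits (cusp
counts, cusp-length bins, ridge-segment counts, texture coverage, the
crown-to-root angle sweep) expanded to unit steps. Two deliberate
irregularities: the many-ridged bins of G1 ("six–ten", "eleven or
more") sit at compressed half-step positions because types with that
many ridges routinely vary by a few segments; and M1's
"multiple-but-broken" state duplicates the distance row of "two
depressions", producing a legitimate off-diagonal zero.

Any strictly monotone mapping of the verbal scale yields the same NMDS
morphospace (NMDS is rank-based) and the same ordering relations, so
the specific integers are a convention, not a claim. The full list of
ordering relations the matrices must satisfy is machine-checked
(`denticode.orderings`, 71 assertions). Users holding the canonical
matrices can drop them in as a JSON/YAML schema file; nothing in the
pipeline assumes the bundled values.

The bundled `denticles_v0.5.json` is frozen output of
`denticode.definitions.build_v05()`; `scripts/build_schema_data.py`
regenerates it, and a test asserts the regeneration is an identity.

One open point, resolved conservatively: ridge length (L1) codes "no
ridges" as state 1, not 0, so a ridgeless crown *does* participate in
L1 distances against ridged crowns. This mirrors the first-character
convention of the other groups and is flagged here for review against
the canonical matrices.

## Disparity with missing data

For specimens *a*, *b* and shared codable set S = {t : a_t ≠ 0, b_t ≠ 0}:

    raw(a,b) = Σ_{t∈S} w_t d_t(a_t, b_t)
    D(a,b)   = raw / Σ_{t∈S} w_t max(d_t)

The denominator is pair-specific (the maximum attainable weighted
distance over that pair's overlap). This is the property that makes a
crown-only fossil commensurable with a complete modern specimen: both
kinds of pairs live on [0, 1]. The cost is that D is not a metric
(triangle inequality can fail across different overlaps), which is one
reason the morphospace uses NMDS rather than a metric embedding. A
global-denominator mode (divide every pair by the full-schema maximum)
and a raw mode are provided for diagnostics; per-pair is the default.

Pairs with empty overlap are `UNDEFINED` and are never imputed;
downstream ordination refuses matrices containing them and names the
offending specimens. Missing cells in input files are likewise hard
errors, not implicit zeros — silently imputing "broken" would bias
disparity downward.

The character jackknife recomputes the matrix on a schema copy with
chosen traits (or a whole letter group) removed and nesting rules
pruned, which is the standard sensitivity check that grouping is not
driven by any single character.

## Morphotypes

A morphotype is a unique combination of character states. At merge
tolerance 0 the partition is exact equality of the full state vector
(zeros equal only zeros). At tolerance k ∈ {1, 2} specimens are
single-linkage clustered at Hamming distance ≤ k counted over
*comparable* traits only — a broken character is unknown, not
different. Trait-count distance is used rather than weighted disparity
because near-duplicate merging is about "differing in one or two
specific traits"; a weighted-disparity threshold is exposed as an
option. Morphotype naming and ordering are deterministic: groups are
sorted by their lexicographically smallest canonical vector, and the
canonical code is the group's modal vector.

Gross types (the 18 controlled labels from "Arrowheads, Airplanes,
Diamonds, and Triangles" to "Other Meandering") ship as a vocabulary
file and are metadata only: they are visually determined groupings,
independent of the disparity calculation, and no classifier is
provided.

## NMDS morphospace

Default k = 3 dimensions, 20 random restarts, convergence at a stress
change below 1e-6 or 300 iterations. Minimization is delegated to
scikit-learn's SMACOF non-metric MDS; the final Kruskal stress-1 is
recomputed in-package from the configuration by isotonic regression of
configuration distances on the disparities, with weak (primary) tie
handling: tied disparities may take different fitted values. The best
restart by recomputed stress-1 is returned, coordinates centered at the
origin. Reported stress is comparable to vegan's `monoMDS` global-model
stress (a cross-implementation test holds them within 0.02 on a fixed
matrix).

`overlay_grouping` summarizes how a trait's states cluster in the
ordination (per-state centroids, spreads, and a between/within ratio),
which is the quantitative form of the observation that ridge system
(F1) is a strong grouping signal while overall crown shape (A1) is
less diagnostic.

## The synthetic generator

The generator exists so that every pipeline stage is testable with no
external data. It emulates three things: (i) valid coded specimens —
traits are drawn in schema order, uniformly over non-zero states except
where a nesting rule forces a value, so every draw validates by
construction; (ii) morphotype clusters — centroids are redrawn until
every pair differs in at least 5 comparable traits, then members are
point-mutated per trait at the configured rate, with dependents
re-drawn where a controller mutation changes their applicability;
(iii) taphonomic degradation — each zero-capable trait is independently
zeroed with the configured breakage probability, with forced values
cascaded so results validate, and fossil mode zeroes the whole O group
(bases are almost never preserved).

Reference study conditions: 5 morphotypes × 10 specimens, per-trait
mutation rate 0.05, breakage fraction 0.4 applied to every second
specimen. These sizes keep the full acceptance pipeline — generation,
50×50 disparity, clustering, multi-k NMDS — in the tens of seconds.

What the generator does *not* emulate, and hence what passing tests do
not show about real data: state frequencies are uniform rather than
taxon-specific; mutations are independent across traits with no
morphological covariance (real denticle characters co-vary strongly
along the ridge-system axis); breakage is independent per trait,
whereas real taphonomy breaks spatially contiguous regions (an eroded
posterior takes C1, C2, C3 together); and cluster centroids are random
states rather than realistic denticle morphologies. Recovery statistics
on synthetic clusters are therefore a consistency check of the
machinery, not a validation of morphotype recognition in nature.

A quantitative consequence worth stating plainly: with a per-trait
mutation rate of 0.05 over 46 traits, a member deviates from its
centroid at roughly Binomial(46, 0.05) traits — about 40% of members
deviate at 3 or more — so tolerance-2 single linkage necessarily leaves
some singleton splinters and the adjusted Rand index of label recovery
plateaus around 0.85–0.9 under the reference conditions (breakage, by
hiding deviating traits, slightly *raises* recovery). This is a
property of the stated study design, not of the disparity engine; the
within-type vs between-type disparity contrast remains unambiguous
(≈0.07 vs ≈0.56) under the same conditions.

## Numerical and interface choices

- Distances are floats; matrices are validated for symmetry, zero
  diagonal, and non-negativity on load, and malformed files name the
  offending trait.
- `NOT_COMPARABLE` (state-level) and `UNDEFINED` (pair-level) are
  distinct singletons, never numeric, so missingness cannot masquerade
  as similarity.
- Coding sheets are RFC-4180 CSV (or sniffed TSV); trait columns may
  appear in any order, canonical write order is schema order; the
  specimen-id column is first.
- The B2/C2 low-before-high edge-texture convention is validated only
  when the crown lacks directionality on both edges (B1 = 4 and
  C1 = 4), the only case the convention governs.
- PHYLIP lower-triangle export writes undefined pairs as −1 since the
  format has no missing-value convention; consumers must prune them.
- All randomness flows through `numpy.random.default_rng` seeds;
  identical configurations produce byte-identical output files.

## Known limitations

- The shipped matrices guarantee the documented orderings, not numeric
  parity with the canonical supplementary matrices.
- Single-linkage merging at tolerance k does not bound the diameter of
  a morphotype; long chains are possible in dense datasets.
- The catalog reader accepts integer state codes only; sheets coded
  with state labels need a label→integer mapping first.
- No significance testing of disparity differences is provided, and no
  taxonomic identification is attempted.
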