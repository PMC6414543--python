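# Methods

## Model and assumptions

ptmpanel treats a bottom-up MS experiment as a deterministic map from a
digestion setting to a set of observable modification sites. A *setting*
is a subset of a protease panel, digested in parallel (one aliquot per
protease) with the identified peptides pooled. The simulation assumes:

- digestion is governed purely by sequence specificity: a protease cleaves
  the bond after (C-side) or before (N-side) its recognition residues,
  optionally blocked by the residue that follows (e.g. the proline
  exception of high-specificity chymotrypsin);
- incomplete digestion is modelled by a per-protease missed-cleavage
  allowance *m*: every peptide spanning up to *m* + 1 consecutive fully
  cleaved fragments is a possible product, **in addition to** the fully
  cleaved ones (missed-cleavage products co-occur with their fully cleaved
  counterparts in real digests, they do not replace them);
- a peptide is observable iff it carries ≥ 1 modifiable residue and its
  length falls in a detection window; everything else about LC-MS
  (ionisation, abundance, co-elution) is out of model;
- all modifiable positions are equally important unless a predictor table
  or a target list says otherwise.

Coordinates are 1-based and inclusive throughout, matching site
nomenclature (S10 = serine at position 10).

## Default cleavage rules

Specificities are not part of the scientific claim and are shipped as
editable data, following the community-standard (PeptideCutter-style)
conventions: Arg-C after R; Asp-N before D; chymotrypsin after F/Y/W
unless P follows; Lys-C after K; Lys-N before K; trypsin/P after K/R with
no proline exception (that is what "/P" denotes); V8-DE after D/E; V8-E
after E; CNBr after M. CNBr, though a chemical, is represented as a
`ProteaseRule` like any enzyme. All default allowances are 0 missed
cleavages; a sanity cap of 10 guards against combinatorial blow-up.

## Scores

For a protein with modifiable-residue set R (default {S, T, Y}; X never
counts) and a retained peptide set after filtering:

- **maximal** = |{i : residue i ∈ R}| — digestion-independent ceiling.
- **ETD** = number of *distinct* protein positions covered by ≥ 1 retained
  peptide. Distinct-position counting (rather than per-peptide instances)
  is what keeps ETD ≤ maximal meaningful once missed cleavages and pooled
  proteases produce overlapping peptides.
- **CID** = Σᵢ 1/nᵢ over retained modified peptides, nᵢ = number of
  modifiable sites on peptide i. This is deliberately summed per peptide
  occurrence, not deduplicated: each detected peptide is an independent
  chance at CID localisation.
- **predicted matched / unmatched** = per-peptide sums of per-site
  predictor scores over the two pools produced by the **length filter**
  among site-bearing peptides. Site-free peptides carry no score mass, so
  only the length window materially splits it; this choice makes
  matched + unmatched invariant to the window — a conservation law the
  tests assert. The optional pattern filter shapes the retained set (ETD,
  CID, mono counts, target coverage) but not this partition.
- **mono-modified count** = retained peptides with nᵢ = 1.
- **target coverage** = intersection of the target-position list with the
  retained peptides' site positions; a targeted protein is "hit" when at
  least one of its targets is covered.

**Concordance** between a simulated site set S and an observed set O
reports matched = S∩O, false positives = S∖O, false negatives = O∖S and
100·|S∩O|/D. The denominator D defaults to |S∪O| (Jaccard); |O| and |S|
are selectable, since published percent-agreement figures rarely state
their denominator. Both empty sets give 0%.

## Search, summary, ranking

Enumeration of settings is exhaustive over all subsets of size 1..n —
realistic panels (≤ 14 agents, ≤ 6 parallel digestions) stay under 10⁴
combinations and complete in seconds, so no pruning heuristic is used.
Combinations are ordered by (size, alphabetical label) and the whole
pipeline is deterministic: identical inputs give identical CSV bytes
(`--deterministic` additionally suppresses the run-metadata timestamp).

The summarizer requires all per-protein tables to cover the same
combination set (a hard error otherwise) and sums the numeric scores
element-wise; target sites become one boolean column each
(`protein:position`). Ranking sorts descending by the chosen criterion
(targets, ETD, CID, or predicted-matched) with ties broken toward fewer
proteases — fewer wet-lab experiments — then higher CID, then label. The
tie-break order is this package's choice; only the primary criterion is
scientifically forced.

## Peptide filters

Each filter partitions its input (retained + rejected = input, order
preserved) and the canonical order is site → length → pattern; the
retained set is order-independent, which the property tests check. Length
bounds are inclusive (window [7, 40] keeps a 7-mer). Pattern matching is
regex *search*, not an anchored match: the cross-talk idiom `KSTGGK.`
(histone H3 K9/K14 acetylation) relies on "motif followed by at least one
residue", i.e. it rejects peptides that end at K14 — an acetylated lysine
blocks cleavage, so a genuine K9/K14 peptide cannot terminate there.

## Synthetic data

`ptmpanel.synthetic` generates the fixtures the tests and the acceptance
script run on:

- `generate_fixture_protein(length, weights, seed)` draws i.i.d. residues
  from an approximate vertebrate average composition (S+T+Y ≈ 15.4 mol%),
  so digest statistics and site densities resemble a typical human
  protein. It does **not** emulate domain structure, low-complexity
  regions, compositional autocorrelation, or real cleavage-site context —
  passing tests show the combinatorics, filters and scores are correct,
  not that any particular real protein reaches a given coverage.
- `generate_fixture_predictions` / `generate_fixture_targets` pick seeded
  random subsets of modifiable positions (scores uniform in (0, 1]).
- `histone_h3_tail_protein()` is the one real sequence used: the
  26-residue H3 N-terminal tail in mature (initiator-Met-removed)
  numbering, the standard substrate for K9/K14 acetylation cross-talk.

The acceptance script uses 3 synthetic proteins of 400 aa for the
coverage-improvement figures, 20 proteins for the digestion-oracle sweep
and 300 for the score-bound sweep — sizes chosen to exercise every rule
and missed-cleavage level many times over while the whole script stays in
the low seconds. All randomness derives from the `--seed` argument.

## Numerical and degenerate-input choices

- Duplicate prediction-table positions collapse to the maximum score, with
  a warning; negative scores and non-positive or non-integer positions are
  hard errors. Predictions or targets on non-modifiable residues are kept
  but warned about (they can never be covered) — the upstream predictor's
  residue model need not match the run's modifiable set.
- Average (not monoisotopic) residue masses are used for the protein-MW
  utility (computed via pyteomics), matching the database convention for
  "predicted MW"; mass is additive (mass(ab) = mass(a) + mass(b) − water).
- A single-residue protein, an empty digestion (no cut sites → one
  peptide), an empty prediction table and an all-covered or all-uncovered
  target list are all valid inputs; an empty target *file* is an error
  (silently optimising for nothing would mask a user mistake).
- Pooled digests keep duplicate (start, end) intervals from different
  proteases — provenance matters for the detail report — while all
  site-level scores deduplicate by position.

## Known limitations

- No modelling of peptide detectability beyond the length window (charge,
  hydrophobicity, flyability) — scores are upper bounds on what LC-MS can
  see, which is also why the concordance operation exists.
- Non-specific or semi-specific digestion is not modelled; specificity
  exceptions beyond one blocked-following-residue set per rule are not
  expressible.
- The predicted-score partition deliberately ignores the pattern filter
  (see above); users doing cross-talk studies should read the matched
  score as "length-compatible", not "pattern-selected".
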