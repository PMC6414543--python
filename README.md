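# ptmpanel

**ptmpanel** selects the protease panel that maximises coverage of
post-translational modification (PTM) sites in bottom-up mass-spectrometry
experiments.

Discovery of PTM sites (phosphorylation of S/T/Y, acetylation of K, ...)
relies on digesting the protein into peptides and identifying the modified
peptides by LC-MS. Trypsin alone misses many sites because not every
tryptic peptide falls in the length window that LC-MS detects well; the
standard remedy is *parallel digestions* — independent digestions of
aliquots with different proteases, whose identified peptides are pooled.
But a panel of *p* candidate proteases used in panels of up to *n* parallel
digestions allows Σₖ₌₁..ₙ C(p, k) distinct settings, and the best one is
unknown until the experiments are done. ptmpanel simulates all of them
first, so the wet lab only runs the winner.

## Method

For every protease combination, ptmpanel:

1. **digests** the protein in silico with each protease independently
   (cleavage rules are editable data; nine agents ship by default: Arg-C,
   Asp-N, chymotrypsin, Lys-C, Lys-N, trypsin/P, V8-DE, V8-E and CNBr, each
   with its own missed-cleavage allowance — peptides with up to *m* skipped
   internal cut sites are added alongside the fully cleaved ones) and pools
   the products;
2. **filters** the pooled peptides: keep only those carrying ≥ 1 modifiable
   residue, with length in the MS-compatible window (7–40 aa by default),
   optionally matching a regular expression (useful for cross-talk studies);
3. **scores** the setting:
   - *maximal* — number of modifiable residues in the protein (the ceiling),
   - *ETD* — distinct sites covered by ≥ 1 retained peptide (electron-transfer
     dissociation localises every site in a detected peptide),
   - *CID* — Σᵢ 1/nᵢ over the k retained modified peptides, where nᵢ is the
     number of sites peptide i carries (collision-induced dissociation is
     only reliable for mono-modified peptides, hence the 1/n weight),
   - *predicted matched / unmatched* — sums of per-site predictor scores
     (e.g. a PhosphoPICK "combined-score" table) over peptides kept vs
     rejected by the length window,
   - the mono-modified peptide count and, when a target-site list is given,
     the covered / uncovered target positions.

A summarizer merges the score tables of any number of proteins (one
boolean column per target site) and ranks settings by targets, ETD, CID or
predicted score; ties prefer fewer proteases, i.e. fewer experiments.
A concordance operation compares simulated site sets with experimentally
observed ones (matched / false-positive / false-negative sites, percent
agreement).

## Worked example

Score all 1–2-protease panels from {Arg-C, Lys-C, V8-E} for phosphosite
coverage of the histone H3 N-terminal tail (26 aa, five S/T/Y sites):

```python
from ptmpanel import FilterConfig, default_protease_panel, \
    score_all_combinations, scores_to_frame
from ptmpanel.synthetic import histone_h3_tail_protein

protein = histone_h3_tail_protein()
panel = [r for r in default_protease_panel()
         if r.name in ("Arg-C", "Lys-C", "V8-E")]
records = score_all_combinations(protein, panel, FilterConfig(), max_size=2)
print(scores_to_frame(records)[
    ["combination", "maximal", "etd", "cid", "mono_modified_count"]
].to_string(index=False))
```

```
combination  maximal  etd  cid  mono_modified_count
      Arg-C        5    3  1.5                    1
      Lys-C        5    0  0.0                    0
       V8-E        5    5  0.2                    0
Arg-C+Lys-C        5    3  1.5                    1
 Arg-C+V8-E        5    5  1.7                    1
 Lys-C+V8-E        5    5  0.2                    0
```

Reading the table: every Lys-C peptide of this tail is shorter than the
7-aa window floor, so Lys-C alone covers nothing. V8-E has no cut site here
at all — the "peptide" is the whole 26-mer, which covers all five sites
(ETD = maximal = 5) but carries them on one penta-modified peptide
(CID = 1/5), hopeless for CID localisation. Arg-C covers three sites on two
short peptides (CID = 1.5, one mono-modified). The best compromise is
Arg-C+V8-E: full site coverage with the highest CID score.

The same pipeline is available from a shell:

```sh
ptmpanel run --fasta proteins.fasta --max-parallel 3 \
    --targets p53.txt --mc "trypsin/P=1" -o results/
ptmpanel summarize results/*_scores.csv --criterion targets -o summary.csv
ptmpanel concordance --simulated sim.txt --observed obs.txt
```

`run` writes one score-table CSV, a detail report and a PTM map (text +
SVG) per protein, a summary table for multi-protein or targeted runs, and
a run-metadata file; `--deterministic` makes outputs byte-identical across
runs.

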