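# Methods

## Decision model

`contigscreen` treats decontamination as a two-stage classification over
an annotated genome. Stage one assigns each predicted protein a taxon
label at a single user-chosen rank from a fixed six-rank ladder
(superkingdom, kingdom, phylum, class, order, family), taken from the
best-scoring hit in a ranked homology search against a taxonomy-aware
protein reference. Stage two sums these per-protein labels over
contigs/scaffolds and removes a contig — with every protein it encodes —
when the alien fraction of its classified votes reaches a threshold.

Assumptions behind the model:

- **Contigs are taxonomically homogeneous.** Every protein on a contig
  comes from one organism, so one decision per contig is correct.
  Chimeric (mis-assembled) contigs violate this and are a known failure
  mode.
- **Reference breadth substitutes for reference exactness.** The exact
  contaminating organism is rarely in the database; a best hit from the
  right kingdom/phylum is enough, which is why decisions are made at a
  broad rank rather than at species level.
- **Contig context separates HGT from contamination.** An integrated
  horizontally transferred gene is surrounded by host genes and loses the
  vote; the model deliberately does not try to remove HGT. The converse
  limitation is accepted: a non-integrated plasmid acquired by HGT is
  indistinguishable from contamination and is removed.

## Per-protein calls

Hits are sorted by bitscore, ties broken by higher percent identity then
lexicographic subject id — the tie-break is arbitrary but fixed, so runs
are reproducible bit for bit. Two windows over the sorted list are
computed:

- the **trimmed prefix**: the maximal top-scoring run sharing the best
  hit's label at the decision rank. Its length (`n_hits_retained`)
  measures how many hits genuinely back the call; the non-fixed window
  makes the call robust to isolated mislabelled reference entries deep
  in the list. A hit with no label at the rank terminates the prefix.
- the **confidence window**: the top `min(cap, n)` hits with `cap = 10`;
  confidence is the fraction of them agreeing with the call. The fixed
  cap matches the window of the top-10 taxon support ratio diagnostic.
  With fewer than `cap` hits the available count is the denominator, so
  sparse families are not spuriously penalized.

Proteins with no hits, or whose best hit lacks a label at the rank, are
UNCLASSIFIED (confidence 0). Missing lineage entries are an explicit
ABSENT marker end to end; they are never coerced to a name, because that
would convert absence of evidence into a host or alien vote.

## Contig consensus

Each protein votes host, alien, or unclassified. With `h` host and `a`
alien votes, a contig is removed iff `h + a > 0` and
`a / (h + a) >= t`. Unclassified votes are excluded from the
denominator: counting them as host votes would conflate "nothing known"
with "confirmed host", and contigs with only unclassified votes are
always kept. Votes are unweighted (one protein, one vote); confidence is
reported per protein but does not weight the tally. The default
threshold `t = 0.5` (strict majority of classified votes) is exposed as
a flag, as is the decision rank (default kingdom); multi-rank screening
is a loop over single-rank runs.

The continuous score behind the ROC analysis is the contig alien
fraction assigned to each protein — exactly the quantity the threshold
cuts, so the operating point sits on the curve by construction.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `rank` | kingdom | — | broad enough that reference relatives exist for most contaminants |
| `threshold` | 0.5 | fraction | strict majority of classified votes |
| `min_pident` | 20 | % identity | floor under which hits are noise for this purpose |
| `cap` | 10 | hits | confidence window; matches the support-ratio diagnostic |
| `excluded_taxids` | query taxid (CLI) | — | the query's own database-deposited proteins would otherwise always confirm the host label and mask contamination |

## Synthetic data

`mock_reference` emulates a taxonomy-annotated protein reference at desk
scale: per taxon, `n_families` independent random amino-acid seed
sequences of 120 residues, each deposited as 3 variants mutated at a
per-position substitution rate (`divergence`, default 0.05).
`sample_proteome` draws genome proteomes as further mutated copies of
the same family seeds. Because family seeds are independent, different
taxa share k-mers only by chance, and the built-in search separates taxa
at every rank where their lineages differ.

`generate_mix` reproduces the spike-in protocol: a fixed number of donor
proteins (grid {100, 200, 400, 800, 1600, 3200}) sampled without
replacement and packed onto virtual contigs of {1, 2, 5, 10, 20}
proteins, ids namespaced, ground truth retained. `benchmark_sweep` runs
the full screen per replicate and reports AUC (Mann–Whitney midrank
formulation, verified in tests against an exhaustive pairwise oracle)
plus sensitivity/specificity at the operating threshold. The host
proteome (300 proteins on contigs of 10, by default) is sampled once per
sweep and searched once, mirroring the fixed-recipient design of
spike-in studies and avoiding redundant work; each replicate searches
only its spiked proteins. The default benchmark grid here uses spike
levels {100, 400}, contig sizes {1, 5, 20}, 10 replicates, and two mock
taxa of 50 families diverging at superkingdom.

What the mock does **not** emulate: real sequence evolution (no
substitution matrix, indels, or domain architecture), database label
noise, uneven taxon sampling, and genuinely undersampled lineages. A
perfect score on the mock therefore demonstrates the correctness of the
decision machinery, not the field performance of any particular
search engine or reference database; in real screens, classification
hardness lives almost entirely in the search and reference coverage.

## Built-in toy search

The bundled search (`ToySearcher`) is a deterministic shared-k-mer
counter (default k = 4): bitscore = 2 × (distinct shared k-mers), and
percent identity is approximated by query coverage of shared k-mers
along the best alignment diagonal. It exists so tests, examples and
benchmarks run with no external aligner; it is not a substitute for
DIAMOND/MMseqs on real data, which are supported through the engine
adapter and the tabular-hits parser.

## Numerical and degenerate-input choices

- Taxon labels compare case-sensitively after whitespace trimming.
- Dominant alien label ties break lexicographically.
- Multi-valued subject-taxid cells (`562;4932`) are an error by default;
  an explicit `first` policy takes the first value.
- Unknown taxids raise; they are never silently treated as unlabelled.
- Empty hit lists, empty contigs-of-unclassified, and queries absent
  from the hits file are all legal inputs with defined outcomes (see
  above), not errors.
- All stochastic components (mock generation, proteome sampling, mix
  replication, sweep seeds) derive from explicit integer seeds; reruns
  are byte-identical, which the tests assert on the written reports.

## Limitations

- Chimeric contigs and very fragmented assemblies (one or two genes per
  contig) weaken the consensus; at one protein per contig the method
  degenerates to per-protein classification.
- Genomes from undersampled lineages yield many unclassified proteins;
  since unclassified contigs are retained, contamination can escape
  detection there.
- Non-integrated mobile elements (plasmids) acquired horizontally are
  removed as contamination by design.
- The screen edits only the proteome and reports contig verdicts; it
  does not rewrite assemblies or annotations.
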