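# Methods

## Duplex model

An ASO:target duplex is modelled as an antiparallel, column-wise pairing of
the *whole* ASO (semi-global alignment; a therapeutic oligonucleotide
anneals as one molecule) against a window of the target sense strand with
free target ends. Each column is CANONICAL (Watson–Crick), WOBBLE (G·U/G·T
in either orientation), MISMATCH, or a single-stranded bulge on either
strand. T and U are interchangeable throughout (targets are pre-mRNA but
often supplied as DNA-alphabet FASTA); 5-methylcytosine pairs as C and is
retained only for display; degenerate bases (N) mismatch everything.

### Scoring and search

The published site calls this package reimplements were made by inspection
of duplex diagrams, so a concrete scoring scheme had to be fixed. Defaults:

| parameter | value | rationale |
|---|---|---|
| canonical | +2 | reference unit |
| wobble | +1 | stable, but current evidence suggests less well tolerated than once assumed — kept strictly between canonical and mismatch |
| mismatch | −1 | |
| bulge open / extend | −3 / −1 | affine; contiguous bulged run on one strand |
| max bulged nt | 2 | largest asymmetry seen among validated sites |
| report threshold | 26 | 2 × 13 canonical pairs, anchored at the weakest validated site |

These defaults reproduce all packaged site diagrams as unique optima and
are fully configurable (`ScanParams`).

The optimum is computed by dynamic programming over states (ASO prefix,
target prefix, bulged-nt budget used, last move), maximising the
lexicographic key *(score, canonical pairs, fewer bulged nt, more wobbles,
leftmost target start, smallest target end)*. The wobble term is not a
biological claim; it pins the pair-class composition of co-optimal
alignments so that independent implementations agree deterministically.
Co-optimal alignments may still differ in column arrangement (run
structure), which no additive tie-break can fix; tests therefore assert
score, span and class composition against the exhaustive oracle
(`oracle_align`), which enumerates every monotone alignment within the
bulge budget under the identical rules. Target bulges are restricted to
the duplex interior (a terminal unpaired target base is just a free end);
ASO bulges may occur anywhere, making a dangling ASO terminus a penalised
bulge — the 20-mer PMO aligned to an 18-nt restored site carries two such
columns.

Scanning a long target evaluates every end position of one DP pass, keeps
completions scoring above the threshold, and merges hits whose spans share
≥ 50 % of the shorter span (better key wins). Coordinates are 0-based
half-open internally and in BED, 1-based inclusive in every report. A
gapless fast mode (`scan_mismatch_only`) counts wobbles as mismatches, for
the kind of genome-scale screen where more than two mismatches already
yields unmanageably many loci.

## Chemistry competence rules

Grades NONE < WEAK < STRONG summarise whether a candidate duplex is
predicted to perturb splicing, given the ASO chemistry:

1. a perfect all-canonical duplex is STRONG for every chemistry (full
   complementarity experimentally rescues OMe and PMO); this clause is
   checked first so that perfect short ASOs (10-mers) are not blocked by
   the absolute canonical-pair floor below;
2. hard constraints, chemistry-independent: ≥ 13 canonical pairs (weakest
   validated site), a contiguous canonical run of ≥ 5 nt (a seed inside
   the 3–7 nt seeding range of the seed-and-zipper annealing model;
   exposed as a flag because only the range is established), and no
   non-canonical run > 3 (an unsurmountable barrier to zippering);
3. STRONG requires every non-canonical column to be charged to an
   MOE-modified ASO base, at most 5 non-canonical columns (the complement
   of the 13-pair floor on an 18-mer), and a longest uninterrupted MOE run
   of ≥ 6 on the ASO (below six, robust off-target activity is lost);
4. otherwise WEAK if the non-canonical count fits the weak budget of the
   dominant chemistry at the non-canonical columns (MOE 6, OMe 2, PMO 2;
   ties between chemistries resolve to the smaller budget, a conservative
   choice); otherwise NONE.

Charging each non-canonical column to the sugar modification of the ASO
base in that column (nearest base for bulges) is a deliberate
simplification: positional effects of mixed-chemistry designs are
exon-dependent in ways a single per-column rule cannot capture. Two known
divergences are accepted rather than tuned away: a 14-canonical-pair site
(the GOLGA4-like fixture) is over-called STRONG although the measured
effect was modest, and a 14-mer on a half-restored site (12 canonical
pairs) is under-called NONE although a partial effect was measured. PMO
budgets mirror OMe; PMO wobble tolerance is experimentally untested, so
that mirror is an assumption. Wobbles count against the non-canonical
budget at full weight.

## Splice and expression quantification

Per-sample PSI is length-normalised:
`PSI = (I/lI) / (I/lI + S/lS)`, undefined when `I+S = 0`. Effective
lengths default to 1 (plain-count PSI). ΔPSI is the difference of group
mean PSIs (treated − control).

The per-event significance test is an explicit stand-in for event-model
software whose internal paired likelihood model is out of scope here: a
likelihood-ratio test of two pooled binomials versus one, with
length-normalised counts as (possibly fractional) weights, referred to
χ²(1). Survivor identity may therefore differ at the margin from that
software; the three *filters* are reimplemented exactly: FDR < 0.05
(Benjamini–Hochberg, via `statsmodels`), |ΔPSI| ≥ 0.1, and mean raw
junction count ≥ 10 for *both* isoforms within at least one group. The
support rule's grouping is stated ambiguously in its source description;
the same-group reading (one group must support both isoforms) was chosen
as the stricter interpretation.

ΔΔCt uses the mean-of-ΔCt per condition (not per-replicate RQ averaging):
ΔCt = Ct_target − Ct_normalizer, ΔΔCt relative to the control condition,
RQ = 2^−ΔΔCt, control RQ ≡ 1. Gel percent inclusion divides each band by
the lane total. DE summaries count adj. P < 0.05 and |log2FC| > 1.

## Synthetic data

`plant_target_site` embeds a degraded perfect footprint (controlled
mismatch / wobble-swap / insert / delete edits) in i.i.d. background at a
configurable GC fraction; no higher-order sequence structure is modelled.
The two background bases adjacent to the site are pinned to mismatch the
ASO termini, otherwise a one-base bulged extension into the flank ties the
planted optimum whenever the neighbouring base happens to pair.

`simulate_event_table` draws per-sample inclusion counts Binomial(depth,
PSI) — optionally beta-binomial with intra-class correlation ρ for
overdispersion stress tests — with null events sharing one PSI ~
U(0.15, 0.85) between groups and true events differing by exactly the
planted ΔPSI (lower group U(0.15, 0.45), random direction), ranges chosen
so both isoforms stay above the 10-read support rule at depth 100. The
default design (200 events, 20 effects of |ΔPSI| = 0.4, 3 vs 3 samples,
depth 100) is the configuration the acceptance script reruns; it is small
enough for seconds-scale runtimes while leaving the filter's floors
clearly measurable. `simulate_qpcr_table` shifts mean ΔCt by −f for a
planted log2 fold change f and adds N(0, 0.1²) cycles of noise per Ct.

What passing these tests shows — and does not. The generators prove the
pipeline's internal consistency (planted truth round-trips through scan,
filter and ΔΔCt at the stated error bounds) but say nothing about mapping
bias, overdispersion beyond beta-binomial, correlated replicates, RNA
secondary structure or chromatin context in real data.

## Fixtures

The intron-7 32-mer and every ASO in the catalogue (the 18-mer MOE/OMe
pair, the 20-mer PMO, truncation and mixed-chemistry series) are
established literature sequences. The eight off-target site sequences are
**synthetic reconstructions**: each is the perfect 18-mer footprint with
exactly the reported degradations applied (e.g. the POLR2H-like site:
mismatches opposing the ASO 3′ end at exon positions 8 and 10, G·T wobbles
at 16 and 20, 14 canonical pairs; canonical-pair counts 13/15/15/15/14 for
the SERPINB7/PITHD1/REV3L/PRKRA/GOLGA4-like sites; every site ≥ 3
non-canonical features, ≥ 1 wobble, no non-canonical run > 3). Their base
identities are not the genomic sequences; their duplex *feature counts*
are the modelling target. Pinned mismatch bases were chosen so the
intended diagram is the unique alignment optimum. Scrambled controls are
deterministic same-composition shuffles. Where per-site counts are not on
record (RTTN- and PAK1-like sites), the reconstruction uses 15 canonical
pairs with one bulged target nucleotide, and 14 canonical pairs,
respectively, consistent with the class-level constraints.

## Known limitations

* No thermodynamics: scores are inspection-calibrated integers, not ΔG;
  no nearest-neighbour model, no Tm, no dose–response prediction.
* No target accessibility: RNA secondary structure of the target is
  ignored, although it is known to matter for silencer accessibility.
* The competence rules are threshold summaries of a small panel of
  validated sites; they are designed to rank and triage candidate sites,
  not to predict percent skipping.
* The LR test assumes independent binomial counts within groups; with
  strong biological overdispersion its p-values are anti-conservative
  (the beta-binomial generator exists precisely to probe this).
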