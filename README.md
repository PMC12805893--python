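# asoscan

Off-target annealing-site analysis for splice-switching antisense
oligonucleotides (ASOs), with the downstream splicing and expression
quantification that accompanies such experiments.

## The problem

Therapeutic splice-switching ASOs — the paradigm case being the 18-mer,
fully 2′-*O*-methoxyethyl (MOE)-modified, phosphorothioate ASO that targets
the ISS-N1 silencer in *SMN2* intron 7 — can anneal imperfectly to
ISS-N1-like sequences inside *other* exons. When such a sequence acts as an
exonic splicing enhancer (ESE), sequestering it triggers off-target exon
skipping. Whether an imperfect duplex is competent to do this depends on
the ASO's sugar chemistry: MOE tolerates several mismatch/wobble pairings,
2′-*O*-methyl (OMe) and morpholino (PMO) essentially none — unless
complementarity is fully restored.

`asoscan` provides, for people designing or auditing splice-switching ASOs:

1. **Duplex scanning** — a semi-global, antiparallel alignment of the whole
   ASO against target pre-mRNA allowing canonical pairs, G·U/G·T wobbles,
   mismatches, and a bounded number of bulged nucleotides. Default scoring:
   canonical +2, wobble +1, mismatch −1, bulge open −3 / extend −1, at most
   2 bulged nt, report threshold 26 (= 2 × 13 canonical pairs, the weakest
   validated off-target site). An exhaustive-enumeration oracle verifies
   the dynamic program on small instances.
2. **Chemistry competence rules** — hard constraints (≥ 13 canonical pairs,
   a ≥ 5 nt contiguous canonical seed, no non-canonical run > 3, following
   the seed-and-zipper model of oligonucleotide annealing) plus
   per-chemistry non-canonical budgets (STRONG: MOE ≤ 5, OMe/PMO 0; WEAK:
   MOE ≤ 6, OMe/PMO ≤ 2) and a ≥ 6 nt uninterrupted-MOE-run requirement.
   A perfect duplex is STRONG for every chemistry.
3. **Splice/expression quantification** — length-normalised PSI
   (`PSI = (I/lI)/(I/lI + S/lS)`), a pooled-binomial likelihood-ratio test
   for group ΔPSI, Benjamini–Hochberg FDR, and the event filter
   FDR < 0.05 ∧ |ΔPSI| ≥ 0.1 ∧ ≥ 10 mean junction reads per isoform in at
   least one group; gel-densitometry percent inclusion; ΔΔCt relative
   expression (RQ = 2^−ΔΔCt); DE-table threshold summaries.
4. **Synthetic data** — generators that plant target sites with controlled
   mismatch/wobble/bulge edits, event tables with planted ΔPSI effects, and
   Ct tables with planted fold changes; plus a packaged fixture catalogue
   (the intron-7 32-mer and ASO series are literature sequences; the eight
   off-target sites are synthetic reconstructions matching the reported
   duplex feature counts — see `asoscan/fixtures.py`).

## Worked example

```python
from asoscan import align_duplex, classify_competence, fixture_catalogue, render_duplex

cat = fixture_catalogue()
f18moe = cat["asos"]["F18MOE"]                  # the 18-mer MOE ASO
site = cat["targets"]["POLR2H"].site_seq        # its strongest off-target site
aln = align_duplex(f18moe, site)
print(render_duplex(f18moe, aln, site))
print(aln.features, classify_competence(f18moe, aln).grade.name)
```

prints

```
5'-ACTGCATTGTGAGAGTGA-3' (target)
    | |||||o|||o|||||
3'-GGTmCGTAATAmCTTTmCAmCT-5' (F18MOE)
DuplexFeatures(n_canonical=14, n_wobble=2, n_mismatch=2, n_bulge=0,
               max_noncanonical_run=1, max_canonical_run=5) STRONG
```

— 14 canonical pairs, two mismatches opposing the ASO 3′ end, two wobbles
mid-duplex; within the MOE tolerance budget, so the site is graded
competent (STRONG). The same duplex under OMe chemistry grades NONE, and
`examples/scan_off_targets.py` extends this to all eight packaged sites:

```
=== F18MOE ===
     target_id  start  end  score  n_canonical  n_wobble  n_mismatch  n_bulge context  grade
  GOLGA4_exon4     81   98   28.0           14         2           2        0  EXONIC STRONG
  ...
SERPINB7_exon4     81   98   27.0           13         3           2        0  EXONIC STRONG
```

(eight STRONG exonic sites for the MOE 18-mer, zero for its OMe
sequence-match). `examples/filter_splice_events.py` runs the event filter
on a synthetic table and prints:

```
events simulated:        200 (planted effects: 20)
events surviving filter: 20
planted effects found:   20/20 (false positives: 0)
min |dPSI| of survivors: 0.363 (floor 0.1)
min isoform support:     29.3 reads (floor 10)
```

The other examples cover truncation/mixed-chemistry panels
(`chemistry_panels.py`) and ΔΔCt / gel / DE summaries (`qpcr_gel_de.py`).
A thin CLI mirrors the library: `asoscan scan|splice-filter|gel-psi|ddct|
de-summary|simulate|demo` (see `asoscan --help`).

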