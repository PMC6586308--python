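# mousestr

STR-based authentication of mouse cell lines: allele calling from
capillary-electrophoresis (CE) peak tables, stutter-filter derivation,
profile matching, human-contamination screening, and interlaboratory
concordance scoring.

Misidentified and cross-contaminated mouse cell lines are a persistent source
of irreproducible results. A multiplex PCR assay targeting 19 tetranucleotide
mouse STR loci (plus two human loci, D8S1106 and D4S2408, as a contamination
screen) produces a fragment-length profile per line; this package implements
the downstream interpretation pipeline for that assay, starting from sized,
height-annotated peak tables (the kind exported by GeneMapper/GeneMarker) and
ending at authenticated-profile comparisons. It is intended for core
facilities and labs running the mouse STR assay, and for method work on STR
interpretation rules.

## What it computes

**Allele calling.** Fragment sizes are converted to alleles through *bins*
anchored on calibrants — sequenced diploid DNA of known repeat count — and
ladder-extended in ±4 bp steps (one tetranucleotide repeat) to alleles the
calibrants do not cover, with microvariant alleles (e.g. `20.3` = 20 repeats
plus 3 bases) on their own ladders. Peaks below 100 RFU are dropped; peaks in
stutter positions are filtered by the consensus rules: a peak one repeat
*below* a taller peak is an allele only if its stutter ratio (stutter height /
parent height) exceeds 20%, one repeat *above* only if it exceeds 10%.

**Stutter filters.** Marker-specific filter recommendations are the mean
stutter ratio across alleles at the locus plus three standard deviations
(allele-specific filters analogously per allele), computed from normal
diploid samples only. A Friedman rank test (markers as blocks, instruments
as treatments, ratios normalized for allele length) tests for instrument
effects.

**Profile matching.** Master's algorithm:

    percent match = 100 × (shared alleles) / (alleles in the questioned profile)

with set semantics per marker. Self-matches are 100%; derivatives of a
parental line score above 85%; lines of the same inbred strain can exceed 80%.

**Concordance.** Each allele call gets an agreement proportion — the fraction
of the other laboratories that also made it — averaged per marker and per
cell line; a line is concordant when all labs report identical calls at every
marker.

## Worked example

```python
import mousestr as M

profiles = {p.sample_id: p for p in M.load_fixture("table6")}
markers = M.load_panel(version="core18").mouse_markers

res = M.masters_match(profiles["RAW 264.7"],
                      profiles["RAW 264.7 gamma NO-"], markers)
print(res.shared_alleles, res.questioned_total, res.percent_rounded)

rep = M.line_agreement(M.load_fixture("table5"))
print(rep.total_calls, round(rep.per_line_mean, 3),
      rep.discordant_markers, rep.concordant)
```

prints

```
19 20 95
311 0.997 ['4-2'] False
```

The RAW 264.7 macrophage line shares 19 of its 20 alleles with its
nitric-oxide-deficient derivative: a 95% match, safely above the 85%
derivative threshold (`M.classify_relatedness(95.0)` →
`"same_or_derivative"`). The NIH/3T3 twelve-laboratory call table contains
311 allele calls with a mean agreement proportion of 0.997; a single lab
missed allele 20.3 at marker 4-2, leaving exactly one discordant marker, so
the line is classified not concordant.

A command-line front end mirrors the library:

```sh
mstr fixtures --name table6 --out t6.csv
mstr match --profiles t6.csv --questioned "RAW 264.7" --reference "RAW 264.7 gamma NO-"
mstr concord --calls src/mousestr/fixtures/table5_nih3t3_lab_calls.csv
mstr simulate stutter --seed 3 --out obs.csv && mstr stutter fit --obs obs.csv --out filters.csv
```

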