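# hiddenframe

Analysis of **hidden frame-shifted genes** in bacteria: genes whose +1 or −1
reading frame encodes a protein that could still be expressed — and remain
functional — because the shifted frame contains no strong stop codon.

A frameshift moves translation to the second (+1 fs) or third (−1 fs)
nucleotide of a coding sequence, rewriting every downstream codon.  Whether
the shifted product can be made at all is governed by the *hidden stops* that
appear in the shifted frame: termination efficiency is ordered
**TAA > TAG > TGA**, so TAG and especially TGA (the opal codon) are leaky and
can be read through, while TAA terminates reliably.  The screening rule at
the heart of this package is therefore:

> a gene whose +1 and −1 frames are both free of internal TAA is a candidate
> for carrying functional hidden frame-shifted proteins.

The package is aimed at microbial genomicists and synthetic biologists who
want to apply that screen to single genes or whole annotated genomes, and to
plan the validating experiments around it.  It provides:

- `hiddenframe.core` — frameshift construction (+1/−1/0), readthrough
  translation (stops rendered `*`, never terminating), and 1-based stop
  inventories per shifted frame;
- `hiddenframe.screen` — per-gene TAA-absence flags, a function-retention
  rule (TAA upstream of the functional domain ⇒ lost), and `genome_scan`
  over GenBank or GFF3+FASTA annotations with per-frame and both-frame
  percentages;
- `hiddenframe.properties` — length, molecular weight, net charge
  (Henderson–Hasselbalch, EMBOSS pKa set), isoelectric point (bisection) and
  Kyte–Doolittle GRAVY for wild-type vs frame-shifted proteins;
- `hiddenframe.massspec` — expected intact masses with M−Met removal and
  H⁺/K⁺ adducts (ESI-TOF conventions), tryptic digestion and singly-charged
  b/y fragment series (via pyteomics);
- `hiddenframe.variants` — 20^k stop-substitution libraries (two stops → 400
  variants) and the relative-toxicity statistic
  `100 × (1 − colonies with induction / colonies without)`;
- `hiddenframe.simulate` / `hiddenframe.fixtures` — synthetic CDS sets,
  annotated genomes with exact ground truth, constraint planting of stop
  codons at chosen shifted-frame positions, and toxin-sized stand-in ORFs.

## Worked example

Screen a gene carrying the hidden-DHFR stop geometry and compare its three
proteins:

```python
from hiddenframe import screen_gene, compare_variants
from hiddenframe.fixtures import dfrb3_like

cds = dfrb3_like()          # synthetic stand-in, 84 codons + stop
rec = screen_gene(cds)
print([(e.codon, e.index) for e in rec.stops_plus1])
print([(e.codon, e.index) for e in rec.stops_minus1])
print(rec.candidate_both_frames)
```

prints

```
[('TAG', 11), ('TGA', 50)]
[('TGA', 52), ('TGA', 74)]
True
```

i.e. the +1 frame carries only the two leaky stops TAG (11th codon) and TGA
(50th), the −1 frame two TGA (52nd, 74th), and neither frame contains TAA —
the gene is a candidate in both frames.  The property comparison, realizing
the +1 readthrough protein with P and K at the two stop positions (the
purified-construct convention):

```python
df = compare_variants(cds, stop_policy="PK")
print(df[["frame", "length", "mw", "net_charge_ph7", "pi", "gravy"]].round(2))
```

```
  frame  length       mw  net_charge_ph7     pi  gravy
0    wt      84  9429.72            0.60   7.21  -0.02
1    +1      84  9161.68           10.79  10.53   0.16
2    -1      84  9181.30            7.40  11.36  -0.53
```

showing how drastically a 5′ frameshift rewrites charge, pI and
hydropathy even at identical length.  A whole-genome scan is one call
(`hiddenframe scan --annotation genome.gbff --out outdir/`) and reports the
percentage of CDSs that are TAA-free per frame and in both frames.

The stand-ins in `hiddenframe.fixtures` are synthetic: they reproduce the
published stop geometries and protein sizes at the nucleotide level but are
not the natural gene sequences.  To analyze the real genes, pass their
FASTA/GenBank records to the same functions.

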