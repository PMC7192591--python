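# Methods

## The screening model

A bacterial coding sequence read in its +1 frame (from nucleotide 2) or −1
frame (from nucleotide 3) encodes an entirely different protein.  Whether
that protein can be expressed at full length depends on the stop codons the
shifted frame happens to contain.  Termination efficiency is ordered
TAA > TAG > TGA; TGA in particular is leaky enough that ribosomal
readthrough of one or two TGA/TAG codons is plausible, while an internal
TAA terminates reliably.  The package therefore models shifted-frame
translation as pure readthrough — stops are inventoried, rendered `*`, and
never terminate — and uses *absence of TAA in a shifted frame* as the
predictor that the frame's protein is expressible and potentially
functional.  The two-frame candidate criterion (no TAA in either shifted
frame) is the default for genome screening; per-frame percentages are
always reported alongside because genome-wide counts are sensitive to which
criterion is applied.

One refinement mirrors a known exception: a TAA lying 3′ of the frame's
functional domain need not abolish function.  `predict_function_retention`
returns `exception-possible` when every TAA lies beyond a user-supplied
domain-end codon, and an optional `taa_tail_tolerance` (fraction *f* of the
3′ end ignored, default 0) lets the screen forgive TAA codons immediately
before the terminus, as seen in a toxic +1 frame carrying a TAA at its
penultimate codon.

Conventions: codon indices are 1-based within the shifted frame ("the 11th
codon"); the canonical stop codon's nucleotides remain part of the shifted
frames (a frameshift destroys the original terminator); 1–2 trailing
nucleotides that no longer complete a codon are dropped, not padded;
genetic code is NCBI table 11 (configurable); codons containing N translate
to `X` and are never counted as stops; IUPAC ambiguity codes other than N
are rejected outright because stop detection would be ill-defined on them.
We keep the +1/−1 labels for reading from nucleotide 2/3 even though some
of the literature calls the latter "+2".

## Genome scanning

`genome_scan` consumes CDSs extracted from GenBank flat files (Biopython,
which resolves strand and `join` locations) or GFF3+FASTA (gffutils +
pyfaidx), applying `codon_start`/phase offsets so each sequence starts at
its canonical frame.  Skip rules — pseudogenes, partial features, length
not divisible by 3, N fraction above 10% — are applied per `ScanPolicy`
and every skip is logged with a reason; the summary percentage is
`100 × n_TAA-free / (n_total − n_skipped)`, reported to one decimal.
Frameshift analysis presumes an intact ORF, hence the defaults.

## Physicochemistry

Net charge is the Henderson–Hasselbalch sum over D, E, C, Y, H, K, R and
the two termini: basic groups contribute `+n/(1+10^(pH−pKa))`, acidic
groups `−n/(1+10^(pKa−pH))`.  The pKa set is the EMBOSS table (N-term 8.6,
K 10.8, R 12.5, H 6.5, C-term 3.6, D 3.9, E 4.1, C 8.5, Y 10.1); it is a
registry entry, so alternative sets can be supplied.  The charge is
strictly decreasing in pH, so the isoelectric point is the unique zero
crossing; it is found by bisection on [0, 14] to 10⁻³ pH by default (the
test suite checks the bisection against an exhaustive 10⁻⁴ grid).
Hydrophobicity is the Kyte–Doolittle GRAVY (mean per-residue hydropathy,
table taken from Biopython).  `X` residues are excluded from charge and
GRAVY with a warning but count toward length, so N-containing codons
cannot silently bias the scalars.  Proteins containing `*` are rejected:
the caller must first choose a readthrough realization (substitute each
stop with a residue, e.g. `"PK"`) or truncate at a stop — both modes are
explicit and recorded in the comparison table.

## Mass spectrometry expectations

Intact masses default to *average* masses (what ESI-TOF deconvolution of a
~10 kDa protein reports); fragment ions default to *monoisotopic* (tandem
MS of peptides).  Intact expectations optionally strip the initiator Met
and add a cation adduct: H⁺ = +1.00728 Da; K⁺ = +38.9632 Da (monoisotopic
potassium minus an electron) by default with the average-mass alternative
(+39.0978 Da) selectable.  Residue masses come from pyteomics.  Tryptic
digestion cleaves C-terminal of K/R except before P; the digest is an
ordered list whose zero-missed-cleavage peptides concatenate exactly back
to the input, and missed cleavages emit every merge of up to m+1 adjacent
peptides.  b/y series are singly charged: `b_i = Σ(first i residues) + H⁺`,
`y_j = Σ(last j residues) + H₂O + H⁺`; multiply charged ions, PTMs and
spectrum parsing are out of scope.

## Variant libraries and toxicity

A k-stop frame yields exactly 20^k amino-acid substitution variants,
enumerated as the Cartesian product of the 20 residues over stop positions
in ascending order (lexicographic by label), with a 20⁴ cap against
accidental blowup.  Substitutions are realized as DNA with the most
frequent E. coli K-12 codon per residue; since laboratory libraries are
built by NNN randomization and sequencing, only the amino-acid enumeration
is normative and the codon choice is a convention.  Relative toxicity is
`100 × (1 − counts_with_induction / counts_without)`, clamped to [0, 100]
with a warning on negative values and undefined when the reference plate
is empty.

## Synthetic data

The generator emulates bacterial CDS sets: ATG start, i.i.d. internal
codons from a per-base or codon-usage model with in-frame stops rejected,
and a model-weighted terminal stop (TGA when the model cannot emit a stop,
e.g. with pA = 0, since TGA's single A cannot seed a TAA in any frame).
Default lengths are uniform over 100–400 codons, bracketing the bacterial
average of roughly 300; calibration checks use short fixed lengths (20
codons) so that the analytic i.i.d. approximation `(1 − 1/64)^m` for the
per-frame TAA-free probability is accurate — at that length the test suite
also carries an exact dynamic-programming oracle over codon junctions and
a brute-force enumeration of all 4-codon genes.  Sense-codon rejection
slightly enriches TA/AA dinucleotides, so the approximation degrades for
genes of hundreds of codons; the calibration is therefore a short-gene
statement, which is also why passing it says nothing about codon-usage
bias, GC skew, operonic structure or overlapping genes in real genomes.

`plant_shifted_frame_stops` builds fixtures with a prescribed stop
geometry: target codons pin nucleotides (conflicts between overlapping
constraints are detected and reported), forbidden stop codons elsewhere
are removed by bounded random local search (default 10,000 proposals, one
free nucleotide of an offending codon mutated per proposal), and the
result is re-screened before being returned.  The planting route is
nucleotide-level and independent of the stop-inventory scan it is later
checked against.  `simulate_annotated_genome` lays the genes onto
multi-contig GenBank/GFF3+FASTA with both strands and a two-part `join`
feature, giving the scanner's extraction logic an exactly known truth
table.  All randomness flows through one seeded NumPy generator; equal
seeds give byte-identical files.

The named fixtures (`ibsc_like`, `dfrb3_like`, `tisb_like`, `ghot_like`)
are synthetic stand-ins.  The natural genes' nucleotide sequences are not
bundled (they are published as supplementary material without deposited
accessions), so the stand-ins reproduce the published *geometry* — a
19-codon hydrophobic ORF whose +1 frame opens on TGA with a second TGA at
codon 8 and a near-terminal TAA; an 84-codon gene with exactly TAG@11 and
TGA@50 in +1, TGA@52 and TGA@74 in −1, TAA-free in both; 29- and
57-residue toxin-sized ORFs.  Tests against them validate shift
conventions, 1-based indexing and screening logic, not the natural
sequences themselves; analyses of the real genes and the genome-wide
percentages for specific organisms require the user to supply those
sequences (`data/reference/`, `data/genomes/` — see the failing checks in
the acceptance test module for exact paths).

## Known limitations

- Readthrough is treated as all-or-none by stop identity; no kinetic model
  of termination or context effects (e.g. the base following the stop).
- No start-codon discovery for hidden frames, no expression evidence, no
  homology search; the screen is purely sequence-based.
- Genome percentages depend on annotation version and skip policy; both
  candidate criteria are reported to make that sensitivity visible.
- The problem sizes in tests and the acceptance script (hundreds to
  thousands of short genes) were chosen as the smallest sets at which the
  analytic expectations are sharp; real genome scans simply stream every
  CDS through the same code path.
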