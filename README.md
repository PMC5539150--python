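# luxcassette

Tools for surveying LuxI/LuxR quorum-sensing homologs in bacterial genomes —
in particular the question of whether Gram-positive bacteria, whose
cell-to-cell signalling normally runs on peptides and two-component systems,
carry functional N-acyl homoserine lactone (AHL) circuitry acquired from
Gram-negative donors.

The package implements the full analysis chain as a tested library plus a
thin CLI:

* **mining** — select candidate LuxI synthases (autoinducer-synthase domain,
  InterPro IPR001690) and LuxR regulators (two-domain rule: a C-terminal
  helix-turn-helix DNA-binding domain *and* an N-terminal
  autoinducer/ligand-binding domain) from domain-annotation tables, with
  length windows (LuxR 200–300 aa).
* **redundancy** — CD-HIT-style greedy clustering at an identity threshold
  (default 30%) using full Needleman–Wunsch global alignments.
* **cassette topology** — pair *luxI*/*luxR* loci on a replicon under a
  distance criterion (gap ≤ 3400 bp between ORF boundaries) and render the
  arrangement as a compact pattern: `R>I>` (adjacent co-oriented), `R><I`
  (convergent), `<I X(2) R>` (two intervening genes), `R> X(>7) <I` (more
  than seven).
* **composition** — per-residue amino-acid composition, Comp(x) = A_x / N,
  compared between groups by fold change FC = mean₁/mean₂ with a Welch
  t-test; significant when FC ≤ 0.80 or ≥ 1.20 and p < 0.05.
* **conservation** — per-position identity of alignment rows to a reference
  sequence (e.g. *Vibrio fischeri* LuxI, UniProt P12747), reported on
  ungapped reference coordinates.
* **phylogenetics** — neighbor joining on p- or Poisson-corrected protein
  distances (d = −ln(1 − p)), column-bootstrap supports, Robinson–Foulds
  distances, HGT calls from supported Gram-mixed clades that contradict a
  16S rRNA reference tree, and classification of cassette co-transfer as
  simultaneous / individual / unclear across LuxI, LuxR and concatenated
  trees.
* **synthetic data** — seeded generators for every input format with planted
  ground truth (cassette topologies, composition shifts, transfer events),
  so the whole chain is testable offline.

## Worked example

The six published Gram-positive *luxI*/*luxR* cassettes ship with the
package as coordinate data. Pairing and classifying them:

```python
from luxcassette.datasets import published_cassette_features
from luxcassette.cassette_topology import pair_cassettes, orf_length_aa

features, class_map, expected = published_cassette_features()
result = pair_cassettes(features, max_gap_bp=3400)
for p in result.pairs:
    print(f"{p.replicon_id:8s} {p.luxI.locus_tag:13s} {p.luxR.locus_tag:13s} "
          f"gap={p.gap_bp:5d} X={p.n_intervening}  {p.pattern.render}")
```

prints

```
Af_rep1  ADL14_12710   ADL14_22475   gap= 3258 X=8  R> X(>7) <I
Af_rep2  ADL14_01865   ADL14_01860   gap=  222 X=0  R>I>
Af_rep3  ADL14_19790   ADL14_09775   gap=  162 X=0  R><I
Mf_rep1  LK11_10605    LK11_10615    gap=  730 X=2  <I X(2) R>
Sp_rep1  ADL19_05265   ADL19_05260   gap=  211 X=0  R>I>
Ss_rep1  SSCH_1110008  SSCH_1100006  gap=  883 X=8  R> X(>7) <I
```

— six canonical cassettes, each with its intergenic gap in bp, intervening
gene count and topology render. Tightening the threshold to 3000 bp drops
the widest pair (*Asanoa ferruginea*, gap 3258 bp), leaving five. The
minimum synthase ORF among these loci is
`min(orf_length_aa(f) for f in features if f.gene_class == "luxI")` =
**191 aa** (the coordinates include the stop codon:
(end − start + 1)/3 − 1 residues).

The CLI mirrors the library:

```bash
luxcassette simulate trees --seed 7 --outdir scratch/sim
luxcassette tree --msa scratch/sim/luxI.aln.fasta --bootstrap 100 --seed 7 \
    --out scratch/sim/luxI.nwk
luxcassette hgt --gene-tree scratch/sim/luxI.nwk \
    --ref-tree scratch/sim/16S.nwk --meta scratch/sim/tips.tsv \
    --out scratch/sim/hgt.tsv
luxcassette run --config config.yaml   # the full survey pipeline
```

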