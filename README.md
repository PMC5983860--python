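# pepdca

Mean-field direct coupling analysis (DCA) for protein families, extended to
joint protein+peptide-ligand alignments in which each protein sequence may
carry several fixed-length ligands, plus the downstream site-level analysis:
pair-to-site score collapsing, entropy-based conservation scoring,
structural contact-map evaluation, weighted Kolmogorov–Smirnov enrichment
and an exact 2×2 decoupling test. A synthetic-data module generates
planted-coupling alignments, ligand datasets with anchor-residue
specificity, toy structures and enrichment calibration fixtures, so the
whole pipeline is testable without any downloads.

## Layout

| module | contents |
| --- | --- |
| `pepdca.alignment_io` | FASTA/Stockholm alignments, gap-column filtering, species subsetting, ligand/stability/allele-frequency tables |
| `pepdca.dca_core` | sequence reweighting (Meff), regularized frequencies, covariance inversion in the reduced gauge, direct information, pair ranking |
| `pepdca.dca_peptides` | joint protein+ligand frequency model (per-ligand weight `w_a / N_a`), intra/inter-molecular pair splitting |
| `pepdca.site_metrics` | pairs→sites collapsing, conservation scores (`1 + Σ f log f / log 20`, gaps omitted), threshold labeling |
| `pepdca.structure_eval` | heavy-atom contact maps (inclusive thresholds), precision curves, per-residue contact counts |
| `pepdca.enrichment_stats` | weighted-KS running sum + permutation p-values, Fisher's exact depletion test |
| `pepdca.synthetic_data` | Gibbs-sampled planted-coupling MSAs, ligand anchor-rule datasets, toy PDB structures, ranking fixtures |

## Command-line usage

Seven console scripts, one per pipeline stage. All tables are TSV with
`#`-prefixed headers; enrichment results are JSON.

```sh
# simulate a planted-coupling alignment, then run DCA on it
simulate potts --n-columns 30 --n-sequences 2000 \
    --planted 0:10:1.0,1:11:1.0 --seed 7 --out potts.fasta
dca --alignment potts.fasta --top-frac 0.25 --out pairs.tsv

# multi-ligand run: intra-protein and inter-molecular pair tables
simulate ligands --n-proteins 300 --seed 7 \
    --out-alignment prot.fasta --out-ligands ligands.csv
dcapep --alignment prot.fasta --ligands ligands.csv --ligand-length 9 \
    --out-intra intra.tsv --out-inter inter.tsv

# per-site scores, conservation labels, enrichment
sites --pairs intra.tsv --alignment-subset prot.fasta --out sites.tsv
enrich --sites sites.tsv --rank-by dca --label-threshold 0.01 \
    --n-perm 10000 --seed 0 --out enrichment.json

# structural evaluation
simulate structure --n-residues 20 --geometry helix --out toy.pdb
contacts --pdb toy.pdb --threshold 5 --out contacts.tsv
precision --pairs pairs.tsv --pdb toy.pdb --threshold 8 --out precision.tsv
```

## Notes

- The per-column score is a *conservation* measure (1 = perfectly conserved,
  0 = uniform over 20 amino acids). Thresholded labels expose both naming
  senses explicitly; the default hit set for enrichment is the
  below-threshold set.
- The gap state is gauged out of the covariance matrix, giving the
  `(L·20)²` reduced dimension for the 21-letter alphabet; alphabet size is
  generic, so small simulation alphabets work throughout.
- Inter-molecular pairs are never sequence-separation filtered (distinct
  chains); intra-chain rankings use `|i−j| > 4` by default.
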