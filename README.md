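# exstab

Comparative sequence and structure analysis of **extremostable proteins**
(from thermophiles, halophiles, acidophiles, alkalophiles, psychrophiles)
against their non-extremostable orthologs.

Organisms adapted to extreme temperature, salinity or pH carry proteins
whose sequences and structures differ systematically from those of their
mesophilic counterparts: shifted amino-acid composition (more Gly/Ala/
Val/Ile, less Gln/His/Met/Cys), lower isoelectric points, more surface
salt bridges, and subtle backbone distortions such as non-planar peptide
bonds. `exstab` implements the full pipeline for quantifying these
differences over a set of ortholog pairs:

- **composition** — per-protein residue percentages and 2-point-wide
  abundance bins ([0,2), [2,4), …, [18,20]) compared across groups with
  Student's t-tests;
- **physchem** — Henderson–Hasselbalch net charge
  `Q(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH))`,
  isoelectric point by bisection (pI: Q(pI)=0), and hydrophobic /
  polar / nonpolar residue-class percentages;
- **global alignment** — Needleman–Wunsch with affine gaps
  (BLOSUM62, open 10.0, extend 0.5, end gaps free) reporting identity,
  similarity and gap percentages over the full alignment length;
- **superposition** — alignment-guided Cα pairing, closed-form Kabsch
  rotation (SVD with reflection correction) and iterative outlier
  rejection (5 cycles, 2.0 Å cutoff) yielding RMSD in Å;
- **geometry** — backbone φ/ψ/ω torsions, peptide-bond planarity
  classes (trans non-planar when |ω| < 170°, cis non-planar when
  |ω| > 20°), Ramachandran region labels, flanking-residue statistics
  for non-planar bonds, and O–N distance salt-bridge detection
  (cutoff 3.2 Å);
- **statistics** — pooled/Welch two-sample t-tests and per-category
  Pearson correlation of alignment identity with RMSD;
- **synthetic data** — group-biased sequence sampling, a NeRF backbone
  builder with plantable torsions, salt-bridge planting, and calibrated
  noisy ortholog pairs, so the entire pipeline runs and is testable
  with no downloads.

## Worked example

Generate a synthetic dataset of five extremophile/mesophile pairs and
run the group comparison:

```sh
exstab simulate --seed 42 --n-per-group 5 --out-dir demo
exstab run demo/manifest.tsv --out-dir demo/report
```

`demo/report/descriptor_tests.tsv` then contains (abridged):

```
parameter        mean_a   mean_b   t       p
pI               5.073    7.678    -2.576  0.0328
net_charge_pH7   -7.990   2.013    -2.204  0.0586
hydrophobic_pct  50.540   50.140   0.270   0.7937
```

The synthetic extremophile group (side *a*) has a lower mean
isoelectric point (5.07 vs 7.68, p = 0.033) and a more negative net
charge at pH 7, while the hydrophobic fraction barely differs —
exactly the kind of group contrast the descriptor t-tests are designed
to surface. Per-pair alignment results are in `per_pair.tsv`
(unrelated random sequences align at ~4–16% identity).

With structures, the same machinery yields RMSDs. A synthetic ortholog
pair with 20% planted substitutions and 0.5 Å coordinate noise:

```python
from exstab import (make_ortholog_pair, chain_sequence, needleman_wunsch,
                    pair_ca_atoms, refine_superposition)

ref, var = make_ortholog_pair(seed=42, length=120, n_mutations=24,
                              rmsd_target=0.5)
aln = needleman_wunsch(chain_sequence(ref, "A"), chain_sequence(var, "A"))
fit = refine_superposition(pair_ca_atoms(aln, ref.chains[0], var.chains[0]))
print(f"identity {aln.identity_pct:.1f}%  rmsd {fit.rmsd:.3f} Å")
# identity 80.0%  rmsd 0.507 Å
```

Both planted parameters are recovered: 24/120 substitutions give 80%
identity, and the fitted RMSD (0.507 Å) sits at the 0.5 Å noise target.

Other subcommands (`compose`, `physchem`, `align`, `superpose`,
`torsions`, `saltbridges`) expose the individual stages on standard
FASTA/PDB files; see `exstab --help`.

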