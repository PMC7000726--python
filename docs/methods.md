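# Methods

This note documents the models, conventions and numerical choices
behind `exstab`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Domain model and parsing policies

Coordinates are read with gemmi and converted to a small hierarchy
(Structure → Chain → Residue → Atom, positions in Å). Policies where
the PDB format admits choices:

- only the **first MODEL** is kept (single-conformer analysis);
- **alternate locations** resolve to the highest-occupancy conformer,
  ties broken by file order;
- waters and non-amino-acid HETATM residues are excluded from chains;
  HETATM amino acids (e.g. MSE) are retained and MSE maps to Met;
- residues are ordered by author numbering plus insertion code;
  numbering gaps do not split a chain — chain continuity is decided
  geometrically (below);
- resolution is taken from the REMARK 2 header when present.

Sequences for alignment are derived from the ATOM records of the
analyzed chain, not SEQRES, so every aligned column corresponds to a
residue with coordinates; unknown residues appear as `X`.

## Physicochemical descriptors

Net charge is the Henderson–Hasselbalch sum over side chains
(D, E, C, Y acidic; H, K, R basic) and the two termini. The default
pKa table (EMBOSS-style) is N-term 8.6, C-term 3.6, K 10.8, R 12.5,
H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1; it is explicit and swappable
because published pI values from web calculators rest on undocumented
tables. The charge is strictly decreasing in pH, so the isoelectric
point is the unique root on [0, 14]; bisection is run to bracket
convergence (interval < 1e-6 pH and residual charge < 1e-4 e), which
also pins shallow titration curves such as di-glycine (pI exactly the
terminal-pKa midpoint, 6.10).

Residue classes are configurable sets with declared defaults:
hydrophobic {A,V,L,I,M,F,W,C,G,P}; polar {D,E,H,K,N,Q,R,S,T} with the
nonpolar class its complement. Cys/Tyr/Trp sit on the border in the
literature; they default to nonpolar and can be reassigned. X residues
are excluded from all composition denominators.

## Global alignment

Three-state Gotoh dynamic programming. A gap run of length L costs
`open + (L−1)·extend`; this convention is forced by the requirement
that `extend = open` degenerate to linear gap scoring. End gaps are
free by default (global alignment of orthologs of unequal length).
Defaults BLOSUM62 / open 10.0 / extend 0.5 mirror the published
defaults of the standard global aligner whose identity convention is
also adopted: identity, similarity (positive substitution score) and
gaps are all percentages of the **full alignment length** including
gap columns. `X` scores 0 against everything. Traceback tie-breaking
is deterministic (diagonal, then up, then left). The implementation is
validated against exhaustive enumeration of all alignments (lengths
≤ 6) and against an independent aligner on longer random pairs.

## Superposition

Cα atoms are paired per aligned (non-gap) column; columns lacking a Cα
on either side are skipped; fewer than three pairs is an error. The
Kabsch rotation comes from the SVD of the cross-covariance matrix with
the reflection case corrected by flipping the smallest singular
direction, so the rotation is always proper. Near-collinear point sets
(second singular value ≈ 0) raise a degeneracy error rather than
returning an arbitrary rotation. Iterative refinement repeats
{fit, drop pairs beyond 2.0 Å} up to 5 cycles — the documented default
behaviour of the interactive tool whose RMSDs the pipeline mirrors —
and both refined and unrefined modes are exposed, because published
RMSDs for divergent pairs can correspond to either.

## Backbone geometry

Torsions follow the IUPAC sign convention, verified against an
independent implementation; φ(i) = C(i−1)–N(i)–CA(i)–C(i),
ψ(i) = N(i)–CA(i)–C(i)–N(i+1), and ω(i) is assigned to the peptide
bond **preceding** residue i (CA(i−1)–C(i−1)–N(i)–CA(i)). Angles are
undefined at termini, wherever a backbone atom is missing, and across
chain breaks, defined geometrically as peptide C–N > 2.5 Å.

Planarity thresholds are interpreted on |ω| (the published inequalities
are unsigned): a trans bond (|ω| > 90°) is non-planar when |ω| < 170°
— i.e. Δω = 180 − |ω| > 10° — and a cis bond when |ω| > 20°. The four
classes partition (−180°, 180°]. Flanking statistics count the residue
before the bond (ω_a) and after it (ω_b) for each non-planar bond.

Ramachandran regions are rectangles — beta φ∈[−180,−45], ψ∈[90,180];
alpha_R φ∈[−145,−35], ψ∈[−70,−10]; alpha_L φ∈[35,100], ψ∈[−20,90] —
chosen as conventional core boxes since the reference tool's exact
polygons are unpublished; they are configurable and non-overlapping.

Salt bridges are detected by side-chain O–N distance only (Asp OD1/OD2,
Glu OE1/OE2 vs Lys NZ, Arg NE/NH1/NH2; His ND1/NE2 opt-in), default
cutoff 3.2 Å, one bridge per residue pair with the closest contact
recorded. No angular criterion is applied: none is defined precisely
enough in the literature this pipeline follows, so the option is left
out rather than guessed.

## Statistics

Two-sample comparisons default to the pooled-variance Student's t with
two-sided p-values (Welch by flag). Zero-variance degeneracies are
resolved by contract: equal means → t = 0, p = 1; unequal means →
flagged infinite t. Pearson r per category requires ≥ 3 complete
pairs; smaller categories are skipped with a warning. No multiple-
testing correction is applied, matching the analysis this package
reimplements.

## Synthetic data: what it emulates and what it does not

Sequences are i.i.d. multinomial draws from group-biased residue
frequencies over a background of average globular-protein composition;
the extremostable profile shifts +1.2 points each onto G/A/V/I and the
same mass off Q/H/M/C, with lengths ~N(250, 30). This reproduces the
*composition-level* structure the group comparisons consume, and
nothing else: no positional conservation, secondary-structure
propensity, or phylogenetic covariance. Passing recovery tests
therefore show the statistics detect planted compositional and
geometric signals at realistic sizes — not that real extremophile
proteomes behave like the generator.

Backbones are built by the natural-extension reference frame (NeRF)
construction from ideal internal coordinates (N–CA 1.458 Å, CA–C
1.525 Å, C–N 1.329 Å; angles 111.2°, 116.2°, 121.7°), so planted
φ/ψ/ω are recovered to ≪ 1e-6° and ω-planarity counts are exact by
construction. Only N/CA/C atoms are placed (plus planted O/N contact
atoms); all consumers tolerate missing side chains. Benchmark pairs
apply a random rigid transform plus isotropic Gaussian noise with
per-axis σ = target/√3, giving expected post-fit RMSD ≈ target for
chains long enough (n = 200 used) that the six fitted degrees of
freedom are negligible; at that size the measured RMSD sits within a
few percent of the target.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated
data: 100 replicate groups of 30 sequences for the composition-shift
power check, ortholog pairs of 80–120 residues for alignment/RMSD
recovery, 200-residue clouds for superposition benchmarks. All
randomness flows from explicit integer seeds; re-running any entry
point with the same seed reproduces byte-identical output.

## Known limitations

- Published per-pair values (identities, RMSDs, non-planar counts,
  category correlations) can only be recomputed when the user supplies
  the corresponding coordinate files and supplementary table; the two
  tests covering them fail with an explanation otherwise.
- One published RMSD (15.86 Å for a nucleoside-diphosphate-kinase
  pair) is inconsistent with a refined superposition of homologs;
  both refined and unrefined modes are provided, but which produced
  the printed value cannot be determined from the publication.
- pKa values are sequence-level constants; no structure-aware shifts.
- The aligner is O(n·m) in pure Python: adequate for single-domain
  chains (hundreds of residues in ~0.1 s), not for proteome scans.
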