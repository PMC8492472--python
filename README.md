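# allokit

Tools for studying how the two subgenomes of an allo-tetraploid fish genome
(common carp, *Cyprinus carpio*, and goldfish, *Carassius auratus* — both
2n = 100) coexist and diverge after whole-genome duplication by
hybridisation. The package covers the full comparative workflow around a
progenitor-like diploid (*Puntius tetrazona*), an outgroup diploid
(*Paracanthobrama guichenoti*) and zebrafish:

- **Subgenome assignment** — classify 1:1:1:2:2 "heptad" gene-family trees:
  after rooting on zebrafish, the tetraploid copies clading with the
  *P. tetrazona* orthologue are subB, their sisters subA; chromosomes are
  assigned A/B by majority vote with a one-A/one-B constraint per
  homoeologous pair.
- **Homoeologous-exchange (HE) detection** — genes whose phylogenetic label
  disagrees with their host chromosome's subgenome, with one-sided rank-sum
  validation from progenitor read-depth bias.
- **Ka/Ks and molecular-clock dating** — a Nei–Gojobori (1986) pairwise
  estimator (synonymous-site fractions over single-nucleotide neighbours,
  all minimal mutational pathways averaged, Jukes–Cantor correction), KDE
  modes of Ks distributions, and dating via T = Ks / (2r) with
  r = 3.51×10⁻⁹ synonymous substitutions/site/year.
- **Ancestral synteny** — ancestral-region (AR) calling from seven-genome
  MAF blocks (> 1 kb, ≥ 4 genomes concordant), translocation/inversion
  fractions, retention/loss densities per Mb, and Dollo-parsimony losses of
  gene families on the species tree.
- **Homoeolog expression divergence** — per-tissue dominance (χ² against
  50:50), conservation with the outgroup (Pearson r > 0.66, p ≤ 0.05 over
  nine tissues), divergence (top-decile Euclidean distance or r < 0.66 on
  log2(TPM+1)), average-linkage clustering, functionalization classes
  (coexpressed / non-F / sub-F / neo-F), cotranscription, pseudo-ancestral
  dosage, Ka/Ks–divergence trends, DEG balance and trans-splicing
  classification.
- **Population genomics** — windowed π, θw, Tajima's D, Fu & Li's D*/F*,
  weighted Weir–Cockerham Fst with Z-transformation, joint top-5 %
  π-ratio/ZFst sweep calling, and LD decay with its half-maximum distance.
- **Synthetic data with planted truth** — every input above can be
  generated at desk scale (codon-evolved heptad families, expression
  panels, alignment blocks, two-population genotypes), so every detector is
  testable end to end without any external download.

## Worked example

```python
import allokit as ak
from allokit.io_formats import read_newick
from allokit.subgenome_assignment import (
    assign_chromosome_subgenomes, classify_heptad_topology,
    detect_homoeologous_exchanges)
from allokit.synthetic_data import simulate_heptad_families

ds = simulate_heptad_families(n_families=300, he_rate=0.03, seed=7)
clss = [classify_heptad_topology(read_newick(f.tree_newick), family_id=f.family_id)
        for f in ds.families]
print(f"canonical families: {sum(c.status == 'canonical' for c in clss)}/300")

assigns = assign_chromosome_subgenomes(clss, ds.locations, ds.truth.homoeolog_pairs)
he = detect_homoeologous_exchanges(clss, ds.locations, assigns)
print(f"HE events detected: {len(he.events)} (planted: {len(ds.truth.he_genes)})")

ks = [r.ks for r in (ak.compute_kaks(a, b) for a, b in ds.pairs("A_vs_B"))
      if r.ks is not None]
mode = ak.estimate_ks_mode(ks).mode
print(f"A-vs-B Ks mode: {mode:.3f}")
print(f"divergence time: {ak.ks_to_divergence_time(mode).time_ma_1dp} Ma")
```

prints

```
canonical families: 300/300
HE events detected: 8 (planted: 8)
A-vs-B Ks mode: 0.180
divergence time: 25.7 Ma
```

All 300 noise-free families show the canonical topology, the eight planted
homoeologous exchanges are recovered exactly, and the kernel-density mode
of the pairwise Ks values between A- and B-lineage copies (0.18 here, at
300 families; the planted branch value is 0.19) converts to a divergence
time of ~26 Ma under the 3.51×10⁻⁹ clock.

A thin CLI mirrors the main entry points, e.g.

```
allokit date --ks-mode 0.19            # -> 27.1
allokit simulate genotypes --seed 1 --out sim/ --n 100
allokit scan --vcf sim/genotypes.vcf --pops sim/pops.tsv
```

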