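# chapbind

Co-translational chaperone binding prediction and selective ribosome
profiling (SeRP) analysis for bacterial proteomes.

During translation, the chaperones Trigger Factor (TF) and DnaK engage
nascent chains that have begun to fold but cannot yet complete their
native structure. `chapbind` implements the **unsatisfied-residue
model** of this process: from a predicted native structure it simulates
vectorial synthesis codon by codon and scores, at every nascent length
*L*, the native contacts whose N-terminal partner has emerged from the
ribosomal exit tunnel while the C-terminal partner has not. Summed
contact strengths of such *unsatisfied* residues — intra-domain
contacts for TF, inter-domain contacts for DnaK — yield per-codon
binding profiles that can be compared directly against SeRP enrichment
data. The package also provides the SeRP statistics themselves
(windowed Agresti–Coull confidence intervals, engagement scores,
binding onsets, metagenes), DTW/Ward substrate clustering, and a
synthetic-data module that plants known truth for every stage.

## The model in brief

Contacts are extracted from a predicted structure: residue pairs with
any atom pair ≤ 6 Å, both pLDDT ≥ 70, predicted aligned error ≤ 5 Å,
and sequence separation ≥ 6; the contact weight is the number of atoms
involved. At nascent length *L*, the C-terminal 30 residues are
tunnel-masked. Each contact *(i, j)*, *i < j*, is then

* **category I** — *i* not yet emerged (ignored),
* **category II** — *i* emerged, *j* not: residue *i* is unsatisfied,
* **category III** — both emerged: part of a compacted region.

A delayed-folding gate admits category-II contacts only where the
C→N cumulative sum of per-residue category-III strengths (individual
strengths < 20 ignored) exceeds 750. The TF score at *L* is the summed
strength of gated intra-domain category-II contacts; for DnaK,
inter-domain contacts never reach category III (domains stay separated
until termination) and the gated inter-domain contacts are summed. A
molten-globule alternative — every emerged residue of a domain counts
its full native strength until the domain is completely synthesized —
is included for comparison.

On the data side, per-codon enrichment of the chaperone-selected over
the total translatome uses the binomial construction *p* = a/(a+b) on
centered window sums, a 95% Agresti–Coull interval on *p*, and the map
*r* = p/(1−p) scaled by the library-size ratio. Engagement scores take
the maximum replicate-averaged lower CI bound (45-codon window, first
30 / last 10 codons trimmed); onsets are CI-supported calls against a
1.5-fold threshold with peaks shorter than 6 codons discarded. Model
and data are compared by normalized cross-correlation (NCC) at zero
lag, which is invariant to the presentation-level profile scaling.

## Worked example

```python
import numpy as np
from chapbind import (SyntheticProteinSpec, make_structure, predict_gene,
                      SyntheticSerpSpec, simulate_serp, windowed_enrichment,
                      average_replicates, engagement_score, binding_onset, ncc)

# a planted two-domain toy protein (60+60 residues, 8-residue linker)
model, pae, candidates = make_structure(SyntheticProteinSpec(n_domains=2, seed=42))
pred = predict_gene(model, pae, candidates)
print(f"protein length: {model.n_residues} residues, "
      f"{len(pred.contact_map.contacts)} filtered contacts")
print(f"TF raw peak {pred.tf.raw.max():.0f} at codon {pred.tf.raw.argmax() + 1}; "
      f"DnaK raw at termination {pred.dnak.raw[-1]:.0f}")

# simulate two-replicate SeRP counts whose truth is the TF prediction
truth = 1 + 3 * pred.tf.raw / pred.tf.raw.max()
reps = simulate_serp(SyntheticSerpSpec(gene_id=model.protein_id,
                                       length=model.n_residues,
                                       enrichment=truth, mu=50.0, seed=7))
profiles = [windowed_enrichment(sel, tot) for sel, tot in reps]
avg = average_replicates(profiles)
call = binding_onset(profiles)
print(f"engagement score: {engagement_score(reps).score:.2f}")
print(f"binding onset: codon {call.onset}, peaks {call.peaks}")
print(f"NCC(model, lower CI): {ncc(pred.tf.raw, avg.ci_low):.3f}")
```

Output:

```
protein length: 128 residues, 312 filtered contacts
TF raw peak 299 at codon 83; DnaK raw at termination 120
engagement score: 1.88
binding onset: codon 71, peaks [(71, 91)]
NCC(model, lower CI): 0.912
```

The TF profile peaks while domain 1 is emerging and decays once its
contacts become satisfied; the planted inter-domain interface (total
strength 120) stays unsatisfied to termination, so the DnaK score never
returns to zero. The onset call at codon 71 marks where both
replicates' lower CI bounds clear the 1.5-fold threshold, and the NCC
of 0.91 quantifies model–data agreement for this gene.

A command-line interface mirrors the library
(`chapbind simulate | contacts | predict | serp | onsets | cluster |
compare | fixture`); every run writes a JSON run log with the config
snapshot, seed and input digests.

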