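# Methods

## Unsatisfied-residue binding model

The model assumes nascent chains can adopt native-like tertiary
contacts as soon as the participating residues have emerged from the
ribosomal exit tunnel, and that stable chaperone binding is driven by
*unsatisfied* residues: residues already embedded in partial folds
whose native contact partners are still untranslated or tunnel-masked.

**Contact extraction.** A residue pair (i, j), i < j, is a contact when
at least one cross-residue atom pair lies within `max_atom_dist` (6 Å),
both residues have pLDDT ≥ `min_plddt` (70), the predicted aligned
error passes `max_pae` (5 Å), and j − i ≥ `min_seq_sep` (6; this
removes the near-diagonal contacts inside single α-helices). The
interaction strength is the number of distinct atoms, over both
residues, participating in at least one qualifying pair. Two readings
of "atoms involved" are possible; counting distinct atoms is the
default and counting qualifying atom pairs is available as
`ContactParams.strength_mode="pairs"`. PAE matrices are not symmetric,
so a pair is excluded when max(PAE[i,j], PAE[j,i]) exceeds the cutoff —
the conservative, symmetric resolution. All atoms present in the file
are used; if alternate conformers occur, the reader keeps the
highest-occupancy one per atom name.

**Domain annotation.** Candidate intervals (e.g. from a CATH-style
similarity search) are accepted greedily in rank order: length must
exceed 10 residues, and overlap with the union of already-accepted
domains must be ≤ 5% of the candidate's own length (the lower-ranked
domain is the overlap denominator). Rank ties break deterministically:
longer candidate first, then smaller start. Contacts with both residues
in one accepted domain are *intra*, in two different accepted domains
*inter*, and otherwise *unassigned*; unassigned contacts feed neither
chaperone model.

**Vectorial emergence.** At nascent length L (codons = residues), the
C-terminal `tunnel_len` (30) residues are masked; residues 1..L−30 have
emerged. The mask applies at every L including L = N — profiles
describe translation, not the released chain — so C-terminal contacts
remain unsatisfied at termination. Each contact is category I (i not
emerged), II (only i emerged; i unsatisfied) or III (both emerged).

**Delayed folding.** Folding can lag emergence for entropic and kinetic
reasons, so category-II contacts only count inside stable partial
folds: per-residue category-III strengths s_r are computed at each L,
values below `res_strength_min` (20 atom-count units) are zeroed, the
cumulative sum runs from residue L down to residue 1, and residue r is
eligible when that sum strictly exceeds `cum_threshold` (750).
Eligibility is tested on the emerged (N-terminal) residue of a
category-II contact — the residue that is physically available.
Whether the cumulative sum runs over residues or over contacts, and
whether the threshold is strict, are config switches
(`cumulative_over`, `strict_cum`); defaults are residues and strict.

**TF, DnaK and molten-globule scores.** TF(L) sums eligible
intra-domain category-II strengths. For DnaK, inter-domain contacts are
never allowed to reach category III — native inter-domain contacts are
assumed to form only post-translationally, so interfaces stay exposed —
and DnaK(L) sums eligible inter-domain strengths. The eligibility gate
for DnaK is computed from the unreclassified category-III table by
default (the compacted region is defined by all formed tertiary
contacts); `dnak_gate_reclassified=True` recomputes it after the
III→II reclassification. The molten-globule alternative gives every
emerged residue of a domain its total native contact strength until the
domain's last residue is attached, after which the whole domain is
satisfied at once. A per-codon structured fraction (emerged residues
with ≥ 1 category-III contact) summarizes tertiary structure formation.

**Normalization.** Raw profiles are in atom-count units. For display
against SeRP data, a profile is mapped affinely from
[min(raw), max(raw)] onto [`norm_floor` (0.25), engagement score of the
gene]; constant profiles collapse to the floor. All quantitative
comparisons (NCC) use raw profiles, so results do not depend on this
scaling.

## SeRP statistics

**Windowed enrichment.** For each codon, selected (a) and total (b)
counts are summed over a centered window truncated at the gene ends (no
padding; profile length equals gene length). The 15-codon window is
used for per-codon profiles and onset calls, the 45-codon window for
engagement scores. The ratio CI uses the binomial construction
p = a/(a+b), a 95% Agresti–Coull interval on p (z = 1.959964, via
statsmodels), and r = p/(1−p) scaled by total/selected library sizes —
the standard way to put a proportion interval on an IP/total ratio.
Windows with a + b = 0 are masked missing and treated as not bound;
b = 0 windows give unbounded ratios and are clamped at `ratio_cap`
(100), far above the 1.5 onset threshold. Replicates are averaged on
ratios and bounds, not counts; a position is missing if missing in any
replicate.

**Engagement score.** Maximum replicate-averaged lower CI bound over
codons 31..N−10 (`head_trim` 30 avoids initiation artifacts,
`tail_trim` 10 avoids downstream genes). Genes of ≤ 40 codons raise an
error.

**Binding onset.** Per replicate and codon: 1 if the lower CI bound
exceeds 1.5, 0.2 if the CI straddles it, 0 if the upper bound is below.
Replicate values are averaged and binarized at > 0.6 (so a single
confident replicate is not enough), runs shorter than 6 codons are
discarded, and the onset is the 5′-most codon of the first surviving
peak. Because the 15-codon window is centered, a sharp enrichment step
bleeds up to 7 codons 5′-ward; at high coverage, called onsets
therefore sit systematically ~2–4 codons before a planted step — an
intrinsic property of windowed CIs, visible in the onset-recovery
statistics of `scripts/acceptance.py`.

**Metagenes.** Gene profiles (replicate-averaged), optionally shifted
30 codons 5′-ward so positions refer to tunnel-exposed residues, are
aligned to start or stop, binned in 6-codon bins (mean within bin), and
averaged across genes; bins conserve mass exactly (bin mean × bin size
sums to the raw profile sum). The across-gene CI is the normal
approximation mean ± 1.96·SEM; the domain-wise variant resamples every
(domain, following-linker) instance to 30 + 10 bins and excludes
linkers longer than 40 residues. Resampling partitions indices by
floor(i·B/n); when an interval is shorter than its bin count the
untouched bins are NaN and excluded from averages.

**Occupancy statistics.** Per-fragment single-molecule occupancies are
events/molecules/time normalized to sum to one; the standard error of
proportion is sqrt(p_n(1−p_n)/N_n) with N_n the molecules measured for
that fragment.

## Clustering and comparison

DTW uses the classic unconstrained dynamic program over
{match, insert, delete} with |a−b| local cost; the tslearn-style
squared-Euclidean-with-final-square-root variant is a config switch.
Profiles are trimmed (30 head / 10 tail), genes shorter than 50 codons
excluded, and pairwise costs clipped at 500 before Ward linkage
(scipy) on the cost matrix treated as a distance matrix — a pragmatic
use of Ward on non-Euclidean distances. The tree is cut at k = 2 and
the cluster with the higher median engagement score is labelled A.
NCC is the zero-lag Pearson form (mean-subtracted, unit-normalized);
constant signals return 0 by convention, and the statistic is invariant
to affine rescaling of either input.

## Synthetic data

The generators exercise the statistics; they do not imitate real
protein geometry or ribosome dwell times. Toy proteins place each
domain's residues on a 4 Å grid (row length 6, so grid neighbours pass
the sequence-separation filter), park linker residues far away with
pLDDT 50 (below the confidence cutoff), and relocate designated residue
pairs from consecutive domains to isolated interface sites, giving an
inter-domain interaction of controllable total strength
(2 × `atoms_per_residue` per pair). PAE is 1.5 Å within and 3 Å across
domains by default.

SeRP counts model the total translatome as negative binomial with mean
μ (default 50 per codon, a typical deep ribosome-profiling coverage)
and dispersion φ = 10 (codon counts are strongly overdispersed), and
the selected translatome as Poisson with mean μ·e(c)·s, where e(c) is
the planted enrichment and s the selected/total library-size ratio
(defaults 10⁶/10⁷ = 0.1, reflecting that an affinity-purified library
covers a fraction of the translatome). With these choices the
library-size-scaled enrichment ratio is an unbiased estimate of e(c).
The end-to-end fixture plants truth enrichments equal to the scaled TF
model prediction of its own toy structures (baseline 1, peak 4), so
onset- and NCC-recovery can be measured against known ground truth.
What passing these tests shows is that the pipeline recovers planted
signals of realistic depth and dispersion; it does not show that the
biological model is correct for real proteins, which requires the
deposited experimental data.

## Problem sizes and determinism

Tests and the acceptance script use toy proteins of ≤ 210 residues,
panels of 8–12 genes, 200 planted-onset genes, 10,000-replicate
coverage simulations and 50 clustering seeds — sizes chosen so the full
suite runs in well under a minute while keeping Monte-Carlo error small
relative to the asserted margins. All generators take explicit seeds
and are bit-reproducible; identical config + seed gives byte-identical
outputs.

## Known limitations

* The model ignores folding kinetics beyond the cumulative-strength
  gate, ribosome-surface effects, and the steric occlusion that limits
  TF binding to C-terminal domains of large proteins.
* The supplementary molten-globule variants that allow early contacts
  among secondary-structure or hydrophobic (I/L/V/F) residues are not
  implemented.
* Ward linkage on a clipped DTW cost matrix is heuristic; the k = 2 cut
  is a fixed convention.
* Read processing (trimming, alignment, P-site offsetting) is out of
  scope: inputs are codon-resolved count tables.
* Multi-chain assemblies are not handled; the first chain of the first
  model is read.
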