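"""Residue–residue contact extraction from predicted structures.

Contacts are defined on AlphaFold-style models: two residues are in
contact when at least one cross-residue atom pair lies within
``max_atom_dist`` (default 6 Å), both residues have pLDDT ≥ ``min_plddt``
(default 70), the predicted aligned error for the pair is ≤ ``max_pae``
(default 5 Å), and the residues are at least ``min_seq_sep`` (default 6)
positions apart on the chain — the last filter removes the trivial
contacts inside individual α-helices.  The interaction strength of a
contact is the number of distinct atoms (union over both residues) that
participate in at least one qualifying atom pair.

Domain intervals are accepted greedily by similarity rank: candidates of
length ≤ 10 are dropped, and a lower-ranked candidate is dropped when it
overlaps the already-accepted set by more than 5% of its own length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "StructureModel",
    "PAEMatrix",
    "ContactParams",
    "ResidueContact",
    "ContactMap",
    "DomainCandidate",
    "DomainAnnotation",
    "extract_contacts",
    "assign_domains",
    "label_contact_domains",
]

INTRA = "intra"
INTER = "inter"
UNASSIGNED = "unassigned"


@dataclass
class StructureModel:
    """A single-chain structure with per-residue confidence.

    Atoms are stored flat: ``atom_xyz[k]`` is the coordinate (Å) of atom
    ``k`` and ``atom_res[k]`` its 1-based residue index.  ``plddt`` holds
    the per-residue confidence in [0, 100] (the B-factor column of
    AlphaFold-DB mmCIF files).
    """

    protein_id: str
    n_residues: int
    atom_xyz: np.ndarray
    atom_res: np.ndarray
    plddt: np.ndarray
    atom_elements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.atom_xyz = np.asarray(self.atom_xyz, dtype=float).reshape(-1, 3)
        self.atom_res = np.asarray(self.atom_res, dtype=int)
        self.plddt = np.asarray(self.plddt, dtype=float)
        if self.atom_res.shape[0] != self.atom_xyz.shape[0]:
            raise ValueError("atom_res and atom_xyz length mismatch")
        if self.plddt.shape[0] != self.n_residues:
            raise ValueError(
                f"{self.protein_id}: plddt has {self.plddt.shape[0]} entries "
                f"for {self.n_residues} residues"
            )
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ValueError("pLDDT outside [0, 100]")
        present = np.unique(self.atom_res)
        if not np.array_equal(present, np.arange(1, self.n_residues + 1)):
            raise ValueError(
                f"{self.protein_id}: residue indices must be contiguous "
                "1..n_residues with at least one atom each"
            )


@dataclass
class PAEMatrix:
    """Predicted aligned error (Å); square, one row/column per residue."""

    protein_id: str
    pae: np.ndarray

    def __post_init__(self) -> None:
        self.pae = np.asarray(self.pae, dtype=float)
        if self.pae.ndim != 2 or self.pae.shape[0] != self.pae.shape[1]:
            raise ValueError("PAE matrix must be square")
        if np.any(self.pae < 0):
            raise ValueError("PAE values must be non-negative")

    @property
    def n_residues(self) -> int:
        return self.pae.shape[0]


@dataclass(frozen=True)
class ContactParams:
    max_atom_dist: float = 6.0
    min_plddt: float = 70.0
    max_pae: float = 5.0
    min_seq_sep: int = 6
    # "number of atoms involved": count distinct atoms ("atoms", default)
    # or qualifying atom pairs ("pairs").
    strength_mode: str = "atoms"

    def __post_init__(self) -> None:
        if min(self.max_atom_dist, self.min_plddt, self.max_pae, self.min_seq_sep) <= 0:
            raise ValueError("ContactParams thresholds must be strictly positive")
        if self.strength_mode not in ("atoms", "pairs"):
            raise ValueError("strength_mode must be 'atoms' or 'pairs'")


@dataclass(frozen=True)
class ResidueContact:
    i: int
    j: int
    strength: int
    domain_label: str = UNASSIGNED


@dataclass
class ContactMap:
    protein_id: str
    n_residues: int
    contacts: list[ResidueContact]

    def total_strength(self) -> int:
        return sum(c.strength for c in self.contacts)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, strength, label) as parallel numpy arrays."""
        n = len(self.contacts)
        i = np.fromiter((c.i for c in self.contacts), int, n)
        j = np.fromiter((c.j for c in self.contacts), int, n)
        s = np.fromiter((c.strength for c in self.contacts), int, n)
        lab = np.array([c.domain_label for c in self.contacts], dtype=object)
        return i, j, s, lab


@dataclass(frozen=True)
class DomainCandidate:
    start: int
    end: int
    rank: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"domain {self.id}: start > end")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class DomainAnnotation:
    protein_id: str
    domains: list[DomainCandidate]

    def domain_index(self, n_residues: int) -> np.ndarray:
        """Per-residue accepted-domain id (0-based position -> index
        into ``domains``, -1 outside every accepted domain)."""
        idx = np.full(n_residues + 1, -1, dtype=int)  # 1-based addressing
        for k, d in enumerate(self.domains):
            idx[d.start : d.end + 1] = k
        return idx


def extract_contacts(
    model: StructureModel, pae: PAEMatrix, params: ContactParams | None = None
) -> ContactMap:
    """All filtered residue–residue contacts of one structure.

    A k-d tree over the atom cloud finds atom pairs within
    ``max_atom_dist``; pairs are then reduced to residue pairs and run
    through the pLDDT, PAE and sequence-separation filters.  A residue
    pair is excluded when max(PAE[i,j], PAE[j,i]) > max_pae.
    """
    params = params or ContactParams()
    if pae.n_residues != model.n_residues:
        raise ValueError(
            f"{model.protein_id}: PAE dimension {pae.n_residues} does not "
            f"match {model.n_residues} residues"
        )
    tree = cKDTree(model.atom_xyz)
    pairs = tree.query_pairs(params.max_atom_dist, output_type="ndarray")
    contacts: list[ResidueContact] = []
    if pairs.size:
        ra = model.atom_res[pairs[:, 0]]
        rb = model.atom_res[pairs[:, 1]]
        lo = np.minimum(ra, rb)
        hi = np.maximum(ra, rb)
        keep = (
            (hi - lo >= params.min_seq_sep)
            & (model.plddt[lo - 1] >= params.min_plddt)
            & (model.plddt[hi - 1] >= params.min_plddt)
            & (np.maximum(pae.pae[lo - 1, hi - 1], pae.pae[hi - 1, lo - 1]) <= params.max_pae)
        )
        pairs, lo, hi = pairs[keep], lo[keep], hi[keep]
        buckets: dict[tuple[int, int], set[int]] = {}
        npairs: dict[tuple[int, int], int] = {}
        for (a, b), i, j in zip(pairs, lo, hi):
            key = (int(i), int(j))
            buckets.setdefault(key, set()).update((int(a), int(b)))
            npairs[key] = npairs.get(key, 0) + 1
        for (i, j), atoms in sorted(buckets.items()):
            strength = len(atoms) if params.strength_mode == "atoms" else npairs[(i, j)]
            contacts.append(ResidueContact(i, j, strength))
    return ContactMap(model.protein_id, model.n_residues, contacts)


def assign_domains(
    candidates: list[DomainCandidate],
    n_residues: int,
    protein_id: str = "",
    min_len: int = 10,
    max_overlap_frac: float = 0.05,
) -> DomainAnnotation:
    """Greedy rank-ordered acceptance of candidate domain intervals.

    Candidates must be longer than ``min_len`` residues and may overlap
    the union of already-accepted (higher-ranked) domains by at most
    ``max_overlap_frac`` of their own length.  Rank ties break
    deterministically: longer candidate first, then smaller start.
    """
    for c in candidates:
        if c.end > n_residues:
            raise ValueError(f"candidate {c.id} exceeds protein length {n_residues}")
    order = sorted(candidates, key=lambda c: (c.rank, -len(c), c.start))
    covered = np.zeros(n_residues + 2, dtype=bool)
    accepted: list[DomainCandidate] = []
    for c in order:
        if len(c) <= min_len:
            continue
        overlap = int(covered[c.start : c.end + 1].sum())
        if overlap > max_overlap_frac * len(c):
            continue
        accepted.append(c)
        covered[c.start : c.end + 1] = True
    accepted.sort(key=lambda c: c.start)
    return DomainAnnotation(protein_id, accepted)


def label_contact_domains(cmap: ContactMap, ann: DomainAnnotation) -> ContactMap:
    """Label each contact intra / inter / unassigned from accepted domains."""
    if ann.protein_id and cmap.protein_id and ann.protein_id != cmap.protein_id:
        raise ValueError("annotation and contact map refer to different proteins")
    idx = ann.domain_index(cmap.n_residues)
    labelled = []
    for c in cmap.contacts:
        di, dj = idx[c.i], idx[c.j]
        if di >= 0 and di == dj:
            lab = INTRA
        elif di >= 0 and dj >= 0:
            lab = INTER
        else:
            lab = UNASSIGNED
        labelled.append(replace(c, domain_label=lab))
    return ContactMap(cmap.protein_id, cmap.n_residues, labelled)
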