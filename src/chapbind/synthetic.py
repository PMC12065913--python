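"""Synthetic structures and SeRP counts with planted ground truth.

The generators exist to exercise every stage of the pipeline without
external downloads.  Toy proteins place each domain's residues on a
compact 3D grid (4 Å spacing) so that intra-domain contacts are dense
and pass the 6-residue sequence-separation filter, while domains sit
hundreds of Å apart except for designated interface residue pairs that
are relocated to shared sites.  Interaction strengths are controllable
because every residue carries the same small pseudo-atom cloud.

SeRP counts model the total translatome as negative-binomial
(overdispersed) codon coverage and the chaperone-selected translatome
as Poisson counts proportional to a planted per-codon enrichment
profile, with the selected library scaled to a fraction of the total
library as in an affinity-purified subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import DomainCandidate, PAEMatrix, StructureModel
from .serp import CodonCounts

__all__ = [
    "SyntheticProteinSpec",
    "SyntheticSerpSpec",
    "PlantedTruth",
    "FixturePanel",
    "make_structure",
    "simulate_serp",
    "end_to_end_fixture",
]

GRID_SPACING = 4.0  # Å between residue centers inside a domain
GRID_NX = 6  # residues per grid row; row neighbours are 6 apart in sequence
ATOM_JITTER = 0.3  # Å, uniform cube jitter of atoms around the residue center


@dataclass(frozen=True)
class SyntheticProteinSpec:
    protein_id: str = "synth"
    n_domains: int = 2
    residues_per_domain: int = 60
    linker_len: int = 8
    interface_strength: float = 120.0
    atoms_per_residue: int = 5
    plddt_domain: float = 90.0
    plddt_linker: float = 50.0
    pae_intra: float = 1.5
    pae_cross: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_domains, self.residues_per_domain, self.atoms_per_residue) < 1:
            raise ValueError("spec fields must be positive")
        if self.linker_len < 0 or self.interface_strength < 0:
            raise ValueError("spec fields must be non-negative")

    @property
    def n_residues(self) -> int:
        return (
            self.n_domains * self.residues_per_domain
            + (self.n_domains - 1) * self.linker_len
        )


@dataclass
class SyntheticSerpSpec:
    gene_id: str = "gene"
    length: int = 200
    enrichment: np.ndarray | float = 1.0
    mu: float = 50.0
    phi: float = 10.0
    selected_library: float = 1e6
    total_library: float = 1e7
    replicates: int = 2
    seed: int = 0

    def truth(self) -> np.ndarray:
        e = np.broadcast_to(np.asarray(self.enrichment, dtype=float), (self.length,))
        if np.any(e < 0) or not np.all(np.isfinite(e)):
            raise ValueError("enrichment must be finite and non-negative")
        return np.array(e)


@dataclass
class PlantedTruth:
    gene_id: str
    enrichment: np.ndarray
    domains: list[tuple[int, int]]
    expected_onset: int | None
    expected_score: float


@dataclass
class FixturePanel:
    structures: dict[str, StructureModel]
    pae: dict[str, PAEMatrix]
    candidates: dict[str, list[DomainCandidate]]
    counts: dict[str, list[tuple[CodonCounts, CodonCounts]]]  # per replicate
    truth: dict[str, PlantedTruth]
    model_tf_raw: dict[str, np.ndarray]
    model_dnak_raw: dict[str, np.ndarray]


def _domain_grid(n: int) -> np.ndarray:
    """Residue-center offsets of a compact grid domain (n × 3)."""
    t = np.arange(n)
    ix = t % GRID_NX
    iy = (t // GRID_NX) % GRID_NX
    iz = t // (GRID_NX * GRID_NX)
    return GRID_SPACING * np.stack([ix, iy, iz], axis=1).astype(float)


def make_structure(
    spec: SyntheticProteinSpec,
) -> tuple[StructureModel, PAEMatrix, list[DomainCandidate]]:
    """Build a toy multi-domain structure with planted contacts.

    Returns the structure, its PAE matrix (low within domains,
    ``pae_cross`` across), and domain candidates matching the planted
    boundaries (rank = domain order).
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.n_residues
    centers = np.zeros((N + 1, 3))  # 1-based
    plddt = np.full(N, spec.plddt_linker)
    domains: list[tuple[int, int]] = []
    pos = 1
    for d in range(spec.n_domains):
        start = pos
        end = pos + spec.residues_per_domain - 1
        domains.append((start, end))
        offs = _domain_grid(spec.residues_per_domain)
        centers[start : end + 1] = np.array([0.0, 0.0, 1000.0 * d]) + offs
        plddt[start - 1 : end] = spec.plddt_domain
        pos = end + 1
        if d < spec.n_domains - 1:  # linker residues parked far away
            for k in range(spec.linker_len):
                centers[pos + k] = np.array([-1000.0, 40.0 * (pos + k), 0.0])
            pos += spec.linker_len

    # interface: relocate residue pairs from consecutive domains to
    # shared, isolated sites; each pair contributes 2*atoms_per_residue
    # atoms of interaction strength
    per_pair = 2 * spec.atoms_per_residue
    n_pairs = int(round(spec.interface_strength / per_pair)) if per_pair else 0
    if n_pairs > spec.residues_per_domain // 3:
        raise ValueError("interface_strength infeasible for this domain size")
    site = 0
    for d in range(max(spec.n_domains - 1, 0 if n_pairs == 0 else 1)):
        if d >= spec.n_domains - 1:
            break
        s1, _ = domains[d]
        s2, _ = domains[d + 1]
        half = spec.residues_per_domain // 2
        for p in range(n_pairs):
            ri = s1 + half + p
            rj = s2 + half + p
            origin = np.array([1000.0 + 500.0 * d, 25.0 * site, -500.0])
            centers[ri] = origin
            centers[rj] = origin + np.array([GRID_SPACING, 0.0, 0.0])
            site += 1

    app = spec.atoms_per_residue
    jitter = rng.uniform(-ATOM_JITTER, ATOM_JITTER, size=(N * app, 3))
    atom_res = np.repeat(np.arange(1, N + 1), app)
    atom_xyz = centers[atom_res] + jitter
    model = StructureModel(
        spec.protein_id, N, atom_xyz, atom_res, plddt,
        atom_elements=["C"] * (N * app),
    )

    dom_of = np.zeros(N + 1, dtype=int)
    for k, (s, e) in enumerate(domains, start=1):
        dom_of[s : e + 1] = k
    same = dom_of[1:, None] == dom_of[None, 1:]
    pae = np.where(same, spec.pae_intra, spec.pae_cross)
    np.fill_diagonal(pae, 0.0)
    pae_m = PAEMatrix(spec.protein_id, pae)

    cands = [
        DomainCandidate(s, e, rank=k + 1, id=f"D{k + 1}")
        for k, (s, e) in enumerate(domains)
    ]
    return model, pae_m, cands


def simulate_serp(spec: SyntheticSerpSpec) -> list[tuple[CodonCounts, CodonCounts]]:
    """Two-library codon counts per replicate with a planted enrichment.

    Total counts are negative binomial with mean ``mu`` and dispersion
    ``phi`` (variance mu + mu²/phi); selected counts are Poisson with
    mean mu·e(c)·s, where s = selected_library/total_library so that
    the library-size-scaled enrichment ratio estimates e(c).
    """
    rng = np.random.default_rng(spec.seed)
    e = spec.truth()
    s = spec.selected_library / spec.total_library
    p_nb = spec.phi / (spec.phi + spec.mu)
    out = []
    for r in range(spec.replicates):
        total = rng.negative_binomial(spec.phi, p_nb, size=spec.length)
        selected = rng.poisson(spec.mu * e * s)
        rep = f"rep{r + 1}"
        out.append(
            (
                CodonCounts(spec.gene_id, rep, "selected", selected, spec.selected_library),
                CodonCounts(spec.gene_id, rep, "total", total, spec.total_library),
            )
        )
    return out


def end_to_end_fixture(
    seed: int,
    n_genes: int = 12,
    mu: float = 50.0,
    onset_threshold: float = 1.5,
) -> FixturePanel:
    """Panel of synthetic genes whose planted SeRP enrichment is the
    (scaled) TF model prediction of their own planted structures.

    The truth enrichment is 1 + 3·tf_raw/max(tf_raw) (baseline 1, peak
    4), so the recorded expected onset is the 5'-most codon where the
    truth exceeds the onset threshold.
    """
    from .binding import predict_gene  # deferred: avoids import cycle

    master = np.random.default_rng(seed)
    structures: dict[str, StructureModel] = {}
    paes: dict[str, PAEMatrix] = {}
    cands: dict[str, list[DomainCandidate]] = {}
    counts: dict[str, list[tuple[CodonCounts, CodonCounts]]] = {}
    truths: dict[str, PlantedTruth] = {}
    tf_raws: dict[str, np.ndarray] = {}
    dk_raws: dict[str, np.ndarray] = {}
    for g in range(n_genes):
        gid = f"g{g + 1:02d}"
        n_domains = 1 + g % 3
        rpd = int(master.choice([50, 60, 70]))
        pspec = SyntheticProteinSpec(
            protein_id=gid,
            n_domains=n_domains,
            residues_per_domain=rpd,
            interface_strength=100.0 if n_domains > 1 else 0.0,
            seed=int(master.integers(2**31 - 1)),
        )
        model, pae, cand = make_structure(pspec)
        pred = predict_gene(model, pae, cand)
        tf = pred.tf.raw
        dk = pred.dnak.raw
        e = np.ones_like(tf) if tf.max() == 0 else 1.0 + 3.0 * tf / tf.max()
        sspec = SyntheticSerpSpec(
            gene_id=gid,
            length=len(e),
            enrichment=e,
            mu=mu,
            seed=int(master.integers(2**31 - 1)),
        )
        above = np.flatnonzero(e > onset_threshold)
        onset = int(above[0]) + 1 if above.size else None
        trimmed = e[30 : len(e) - 10]
        structures[gid], paes[gid], cands[gid] = model, pae, cand
        counts[gid] = simulate_serp(sspec)
        truths[gid] = PlantedTruth(
            gid, e, [(d.start, d.end) for d in cand], onset,
            float(trimmed.max()) if trimmed.size else float(e.max()),
        )
        tf_raws[gid] = tf
        dk_raws[gid] = dk
    return FixturePanel(structures, paes, cands, counts, truths, tf_raws, dk_raws)
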