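"""Vectorial-synthesis chaperone binding models.

The nascent chain is elongated one codon at a time.  The C-terminal 30
residues sit in the ribosomal exit tunnel and cannot form contacts; the
remainder has emerged.  At every nascent length L each native contact
(i < j) falls into one category:

* I   — neither residue can form the contact (j untranslated or both in
        the tunnel region);
* II  — the N-terminal residue i has emerged but j has not; i is
        "unsatisfied";
* III — both residues have emerged; the contact is part of a compacted
        region.

A delayed-folding gate restricts which unsatisfied residues count:
per-residue category-III strengths below ``res_strength_min`` are
ignored, the remaining strengths are summed cumulatively from the
C- toward the N-terminus, and only residues where that cumulative sum
exceeds ``cum_threshold`` are considered part of a stable partial fold.

Trigger Factor binding is scored as the summed strength of eligible
intra-domain category-II contacts; DnaK as the summed strength of
eligible inter-domain contacts, with inter-domain contacts never
allowed to reach category III (domains stay separated until
termination).  The molten-globule alternative instead lets every
emerged residue of a domain contribute its full native contact
strength until the whole domain has been synthesized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import (
    INTER,
    INTRA,
    ContactMap,
    ContactParams,
    DomainAnnotation,
    DomainCandidate,
    PAEMatrix,
    StructureModel,
    assign_domains,
    extract_contacts,
    label_contact_domains,
)

__all__ = [
    "ModelParams",
    "NascentState",
    "BindingProfile",
    "nascent_state",
    "categorize",
    "folded_region_mask",
    "tf_raw",
    "dnak_raw",
    "molten_globule_raw",
    "structured_fraction",
    "normalize_profile",
    "predict_gene",
    "GenePrediction",
]

CAT_I, CAT_II, CAT_III = 1, 2, 3


@dataclass(frozen=True)
class ModelParams:
    tunnel_len: int = 30
    res_strength_min: float = 20.0
    cum_threshold: float = 750.0
    norm_floor: float = 0.25
    # cumulative compaction sum over residues (default) or contacts
    cumulative_over: str = "residues"
    # eligibility threshold strict (> cum_threshold, default) or >=
    strict_cum: bool = True
    # compute the DnaK eligibility gate from the unreclassified category
    # table (default) or after the inter-domain III->II reclassification
    dnak_gate_reclassified: bool = False

    def __post_init__(self) -> None:
        if min(self.tunnel_len, self.res_strength_min, self.cum_threshold, self.norm_floor) <= 0:
            raise ValueError("ModelParams must be strictly positive")


@dataclass(frozen=True)
class NascentState:
    L: int
    N: int
    tunnel_len: int

    @property
    def n_emerged(self) -> int:
        return max(0, self.L - self.tunnel_len)

    @property
    def emerged(self) -> frozenset[int]:
        return frozenset(range(1, self.n_emerged + 1))

    @property
    def tunnel(self) -> frozenset[int]:
        return frozenset(range(self.n_emerged + 1, self.L + 1))


@dataclass
class BindingProfile:
    protein_id: str
    model: str  # TF | DnaK | molten_globule
    raw: np.ndarray
    normalized: np.ndarray | None = None


def nascent_state(L: int, N: int, params: ModelParams | None = None) -> NascentState:
    params = params or ModelParams()
    if not 1 <= L <= N:
        raise ValueError(f"nascent length {L} outside 1..{N}")
    return NascentState(L, N, params.tunnel_len)


def categorize(cmap: ContactMap, state: NascentState) -> np.ndarray:
    """Category (1/2/3) per contact at one nascent length."""
    i, j, _, _ = cmap.as_arrays()
    return _categories(i, j, state.n_emerged)


def _categories(i: np.ndarray, j: np.ndarray, n_emerged: int) -> np.ndarray:
    cat = np.full(i.shape, CAT_I, dtype=int)
    cat[(i <= n_emerged) & (j > n_emerged)] = CAT_II
    cat[j <= n_emerged] = CAT_III
    return cat


def _eligibility(
    i: np.ndarray,
    j: np.ndarray,
    s: np.ndarray,
    cat: np.ndarray,
    L: int,
    N: int,
    params: ModelParams,
) -> np.ndarray:
    """Delayed-folding gate: per-residue boolean eligibility (1-based)."""
    sr = np.zeros(N + 1, dtype=float)
    mask3 = cat == CAT_III
    np.add.at(sr, i[mask3], s[mask3])
    np.add.at(sr, j[mask3], s[mask3])
    sr[sr < params.res_strength_min] = 0.0
    if params.cumulative_over == "contacts":
        # cumulative over contacts ordered by their C-terminal residue
        contrib = np.zeros(N + 1, dtype=float)
        ok3 = mask3 & (s >= params.res_strength_min)
        np.add.at(contrib, j[ok3], s[ok3])
        sr = contrib
    cum = np.zeros(N + 1, dtype=float)
    cum[1 : L + 1] = np.cumsum(sr[1 : L + 1][::-1])[::-1]
    if params.strict_cum:
        elig = cum > params.cum_threshold
    else:
        elig = cum >= params.cum_threshold
    elig[0] = False
    return elig


def folded_region_mask(
    cmap: ContactMap, state: NascentState, params: ModelParams | None = None
) -> np.ndarray:
    """Per-residue eligibility (index 1..N; element 0 unused, False)."""
    params = params or ModelParams()
    i, j, s, _ = cmap.as_arrays()
    cat = _categories(i, j, state.n_emerged)
    return _eligibility(i, j, s.astype(float), cat, state.L, state.N, params)


def _score_at(
    cmap: ContactMap,
    L: int,
    params: ModelParams,
    label: str,
) -> float:
    """Raw unsatisfied-contact score for one model at one length."""
    i, j, s, lab = cmap.as_arrays()
    s = s.astype(float)
    n_emerged = max(0, L - params.tunnel_len)
    cat = _categories(i, j, n_emerged)
    elig = _eligibility(i, j, s, cat, L, cmap.n_residues, params)
    if label == INTRA:
        active = (cat == CAT_II) & (lab == INTRA)
    else:  # DnaK: inter-domain contacts never satisfy (III -> II)
        if params.dnak_gate_reclassified:
            cat_gate = cat.copy()
            cat_gate[(lab == INTER) & (cat == CAT_III)] = CAT_II
            elig = _eligibility(i, j, s, cat_gate, L, cmap.n_residues, params)
        active = (cat >= CAT_II) & (lab == INTER)
    active &= elig[i]
    return float(s[active].sum())


def tf_raw(cmap: ContactMap, ann: DomainAnnotation, L: int, params: ModelParams | None = None) -> float:
    """TF score: eligible unsatisfied intra-domain contact strength."""
    params = params or ModelParams()
    return _score_at(label_contact_domains(cmap, ann), L, params, INTRA)


def dnak_raw(cmap: ContactMap, ann: DomainAnnotation, L: int, params: ModelParams | None = None) -> float:
    """DnaK score: eligible unsatisfied inter-domain contact strength."""
    params = params or ModelParams()
    return _score_at(label_contact_domains(cmap, ann), L, params, INTER)


def molten_globule_raw(
    cmap: ContactMap, ann: DomainAnnotation, L: int, params: ModelParams | None = None
) -> float:
    """Molten-globule score at nascent length L.

    Every tunnel-emerged residue of an annotated domain counts its total
    native contact strength until the domain's last residue is attached
    to the chain, at which point the whole domain is satisfied at once.
    """
    params = params or ModelParams()
    i, j, s, _ = cmap.as_arrays()
    res_strength = np.zeros(cmap.n_residues + 1, dtype=float)
    np.add.at(res_strength, i, s.astype(float))
    np.add.at(res_strength, j, s.astype(float))
    n_emerged = max(0, L - params.tunnel_len)
    total = 0.0
    for d in ann.domains:
        if d.end <= L:  # fully available -> satisfied immediately
            continue
        hi = min(d.end, n_emerged)
        if hi >= d.start:
            total += float(res_strength[d.start : hi + 1].sum())
    return total


def structured_fraction(cmap: ContactMap, L: int, params: ModelParams | None = None) -> float:
    """Fraction of emerged residues engaged in ≥1 category-III contact."""
    params = params or ModelParams()
    n_emerged = max(0, L - params.tunnel_len)
    if n_emerged == 0:
        return 0.0
    i, j, _, _ = cmap.as_arrays()
    mask3 = j <= n_emerged
    in3 = np.zeros(cmap.n_residues + 1, dtype=bool)
    in3[i[mask3]] = True
    in3[j[mask3]] = True
    return float(in3[1 : n_emerged + 1].sum()) / n_emerged


def normalize_profile(
    raw: np.ndarray, engagement_score: float, params: ModelParams | None = None
) -> np.ndarray:
    """Affine map of [min(raw), max(raw)] onto [norm_floor, score].

    The profile maximum lands exactly on the gene's measured engagement
    score (floored at norm_floor); constant profiles collapse to the
    floor everywhere.  Presentation-level only — comparisons use raw.
    """
    params = params or ModelParams()
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty profile")
    if engagement_score <= 0:
        raise ValueError("engagement score must be positive")
    lo, hi = float(raw.min()), float(raw.max())
    top = max(engagement_score, params.norm_floor)
    if hi == lo:
        return np.full_like(raw, params.norm_floor)
    return params.norm_floor + (raw - lo) / (hi - lo) * (top - params.norm_floor)


@dataclass
class GenePrediction:
    protein_id: str
    tf: BindingProfile
    dnak: BindingProfile
    molten_globule: BindingProfile
    structured_fraction: np.ndarray
    annotation: DomainAnnotation
    contact_map: ContactMap


def predict_gene(
    model: StructureModel,
    pae: PAEMatrix,
    candidates: list[DomainCandidate],
    contact_params: ContactParams | None = None,
    model_params: ModelParams | None = None,
) -> GenePrediction:
    """Full per-codon prediction: contacts → domains → per-L scoring.

    Returns raw TF, DnaK and molten-globule profiles (length N) plus the
    per-codon structured fraction.  Normalization against a measured
    engagement score is applied separately via :func:`normalize_profile`.
    """
    contact_params = contact_params or ContactParams()
    mp = model_params or ModelParams()
    cmap = extract_contacts(model, pae, contact_params)
    ann = assign_domains(candidates, model.n_residues, model.protein_id)
    cmap = label_contact_domains(cmap, ann)
    N = model.n_residues
    i, j, s, lab = cmap.as_arrays()
    s = s.astype(float)
    tf = np.zeros(N)
    dk = np.zeros(N)
    mg = np.zeros(N)
    sf = np.zeros(N)
    for L in range(1, N + 1):
        n_emerged = max(0, L - mp.tunnel_len)
        cat = _categories(i, j, n_emerged)
        elig = _eligibility(i, j, s, cat, L, N, mp)
        tf_active = (cat == CAT_II) & (lab == INTRA) & elig[i]
        tf[L - 1] = s[tf_active].sum()
        if mp.dnak_gate_reclassified:
            cat_gate = cat.copy()
            cat_gate[(lab == INTER) & (cat == CAT_III)] = CAT_II
            elig_dk = _eligibility(i, j, s, cat_gate, L, N, mp)
        else:
            elig_dk = elig
        dk_active = (cat >= CAT_II) & (lab == INTER) & elig_dk[i]
        dk[L - 1] = s[dk_active].sum()
        mg[L - 1] = molten_globule_raw(cmap, ann, L, mp)
        sf[L - 1] = structured_fraction(cmap, L, mp)
    return GenePrediction(
        model.protein_id,
        BindingProfile(model.protein_id, "TF", tf),
        BindingProfile(model.protein_id, "DnaK", dk),
        BindingProfile(model.protein_id, "molten_globule", mg),
        sf,
        ann,
        cmap,
    )
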