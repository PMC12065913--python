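"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results with naive, readable
algorithms (all-pairs scans, memoized recursions) so that the package's
vectorized implementations are checked against an independent path.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from chapbind.contacts import ContactParams, PAEMatrix, StructureModel


def random_structure(
    rng: np.random.Generator,
    n_residues: int = 15,
    atoms_per_residue: int = 3,
    box: float = 20.0,
) -> tuple[StructureModel, PAEMatrix]:
    """Random atom cloud in a box; random pLDDT and (symmetrizable) PAE."""
    centers = rng.uniform(0, box, size=(n_residues, 3))
    atom_res = np.repeat(np.arange(1, n_residues + 1), atoms_per_residue)
    xyz = centers[atom_res - 1] + rng.uniform(-1.5, 1.5, size=(len(atom_res), 3))
    plddt = rng.uniform(50, 100, size=n_residues)
    pae = rng.uniform(0, 10, size=(n_residues, n_residues))
    np.fill_diagonal(pae, 0.0)
    model = StructureModel("rand", n_residues, xyz, atom_res, plddt)
    return model, PAEMatrix("rand", pae)


def brute_force_contacts(
    model: StructureModel, pae: PAEMatrix, params: ContactParams | None = None
) -> dict[tuple[int, int], int]:
    """All-pairs O(A^2) contact enumeration; returns {(i,j): strength}."""
    params = params or ContactParams()
    n = model.n_residues
    atoms_of = {r: np.flatnonzero(model.atom_res == r) for r in range(1, n + 1)}
    out: dict[tuple[int, int], int] = {}
    for i in range(1, n + 1):
        for j in range(i + params.min_seq_sep, n + 1):
            if model.plddt[i - 1] < params.min_plddt:
                continue
            if model.plddt[j - 1] < params.min_plddt:
                continue
            if max(pae.pae[i - 1, j - 1], pae.pae[j - 1, i - 1]) > params.max_pae:
                continue
            involved: set[int] = set()
            npairs = 0
            for a in atoms_of[i]:
                for b in atoms_of[j]:
                    d = np.linalg.norm(model.atom_xyz[a] - model.atom_xyz[b])
                    if d <= params.max_atom_dist:
                        involved.update((int(a), int(b)))
                        npairs += 1
            if involved:
                out[(i, j)] = (
                    len(involved) if params.strength_mode == "atoms" else npairs
                )
    return out


def dtw_brute(x, y) -> float:
    """Memoized brute-force DTW recursion with |a-b| local cost."""
    x = tuple(float(v) for v in x)
    y = tuple(float(v) for v in y)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        c = abs(x[i] - y[j])
        if i == 0 and j == 0:
            return c
        best = np.inf
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        return c + best

    return rec(len(x) - 1, len(y) - 1)


def agresti_coull_interval(a: float, n: float, z: float = 1.959964):
    """Closed-form Agresti–Coull 95% interval on a proportion."""
    n_t = n + z * z
    p_t = (a + z * z / 2.0) / n_t
    half = z * np.sqrt(p_t * (1.0 - p_t) / n_t)
    return max(0.0, p_t - half), min(1.0, p_t + half)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
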