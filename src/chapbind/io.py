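"""File formats, run configuration and run logging.

Readers return the typed containers of the other modules and validate
their invariants; writers emit the same formats the readers consume, so
synthetic fixtures round-trip.  Structures travel as AlphaFold-DB-style
mmCIF (per-residue pLDDT in the B-factor column), aligned-error
matrices as AlphaFold-DB PAE JSON, everything tabular as TSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .binding import GenePrediction, ModelParams, normalize_profile
from .contacts import (
    ContactMap,
    ContactParams,
    DomainAnnotation,
    DomainCandidate,
    PAEMatrix,
    ResidueContact,
    StructureModel,
)
from .serp import CodonCounts, EnrichmentProfile, OnsetCall, SerpParams

__all__ = [
    "read_structure",
    "write_structure",
    "read_pae",
    "write_pae",
    "read_counts",
    "write_counts",
    "read_domains",
    "write_domains",
    "write_contacts",
    "read_contacts",
    "write_profile_table",
    "write_enrichment",
    "RunConfig",
    "read_config",
    "write_config",
    "RunLog",
]


# ---------------------------------------------------------------- structures

def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a single-chain mmCIF with pLDDT in the B-factor column."""
    st = gemmi.Structure()
    st.name = model.protein_id
    gm = gemmi.Model("1")
    ch = gemmi.Chain("A")
    for r in range(1, model.n_residues + 1):
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(r, " ")
        sel = np.flatnonzero(model.atom_res == r)
        for k, a in enumerate(sel):
            at = gemmi.Atom()
            el = model.atom_elements[a] if model.atom_elements else "C"
            at.name = f"{el}{k + 1}"
            at.element = gemmi.Element(el)
            x, y, z = model.atom_xyz[a]
            at.pos = gemmi.Position(float(x), float(y), float(z))
            at.b_iso = float(model.plddt[r - 1])
            at.occ = 1.0
            res.add_atom(at)
        ch.add_residue(res)
    gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))


def read_structure(path: str | Path) -> StructureModel:
    """Read an AlphaFold-DB-dialect mmCIF (first model, first chain)."""
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as ex:
        raise ValueError(f"{path}: cannot parse mmCIF: {ex}") from ex
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError(f"{path}: no model/chain in file")
    chain = st[0][0]
    xyz, res_idx, elements, plddt = [], [], [], []
    for n, res in enumerate(chain, start=1):
        if res.seqid.num != n:
            raise ValueError(
                f"{path}: residue numbering not contiguous at seqid {res.seqid.num}"
            )
        if len(res) == 0:
            raise ValueError(f"{path}: residue {n} has no atoms")
        # altloc handling: keep the highest-occupancy conformer per atom name
        best: dict[str, gemmi.Atom] = {}
        for at in res:
            prev = best.get(at.name)
            if prev is None or at.occ > prev.occ:
                best[at.name] = at
        for at in best.values():
            xyz.append([at.pos.x, at.pos.y, at.pos.z])
            res_idx.append(n)
            elements.append(at.element.name)
        plddt.append(best[next(iter(best))].b_iso)
    return StructureModel(
        st.name or path.stem, len(plddt), np.array(xyz), np.array(res_idx),
        np.array(plddt), elements,
    )


def write_pae(pae: PAEMatrix, path: str | Path) -> None:
    payload = [
        {
            "predicted_aligned_error": np.round(pae.pae, 2).tolist(),
            "max_predicted_aligned_error": float(pae.pae.max(initial=0.0)),
        }
    ]
    Path(path).write_text(json.dumps(payload))


def read_pae(path: str | Path, protein_id: str = "") -> PAEMatrix:
    """Read AlphaFold-DB PAE JSON (list-wrapped or bare object)."""
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as ex:
        raise ValueError(f"{path}:{ex.lineno}: invalid JSON: {ex.msg}") from ex
    if isinstance(obj, list):
        if not obj:
            raise ValueError(f"{path}: empty PAE JSON list")
        obj = obj[0]
    if "predicted_aligned_error" not in obj:
        raise ValueError(f"{path}: missing 'predicted_aligned_error' key")
    return PAEMatrix(protein_id or path.stem, np.asarray(obj["predicted_aligned_error"]))


# -------------------------------------------------------------------- counts

def write_counts(
    pairs: dict[str, list[tuple[CodonCounts, CodonCounts]]], path: str | Path
) -> None:
    """Long-format TSV with '# library_size' header lines."""
    lines = []
    seen = {}
    rows = []
    for gene, reps in pairs.items():
        for sel, tot in reps:
            for cc in (sel, tot):
                seen[(cc.replicate, cc.library)] = cc.library_size
                for codon, cnt in enumerate(cc.counts, start=1):
                    rows.append((gene, cc.replicate, cc.library, codon, int(cnt)))
    for (rep, lib), size in sorted(seen.items()):
        lines.append(f"# library_size\t{rep}\t{lib}\t{size:g}")
    lines.append("gene_id\treplicate\tlibrary\tcodon\tcount")
    lines.extend("\t".join(map(str, r)) for r in rows)
    Path(path).write_text("\n".join(lines) + "\n")


def read_counts(path: str | Path) -> dict[str, list[tuple[CodonCounts, CodonCounts]]]:
    """Read the counts TSV back into per-gene replicate (selected, total) pairs."""
    path = Path(path)
    lib_sizes: dict[tuple[str, str], float] = {}
    header_rows = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_rows += 1
            parts = line[1:].strip().split("\t")
            if parts[0] != "library_size" or len(parts) != 4:
                raise ValueError(f"{path}:{header_rows}: malformed header line")
            lib_sizes[(parts[1], parts[2])] = float(parts[3])
    df = pd.read_csv(path, sep="\t", skiprows=header_rows)
    required = {"gene_id", "replicate", "library", "codon", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    out: dict[str, list[tuple[CodonCounts, CodonCounts]]] = {}
    for gene, gdf in df.groupby("gene_id", sort=True):
        n = int(gdf["codon"].max())
        reps = []
        for rep in sorted(gdf["replicate"].unique()):
            per_lib = {}
            for lib in ("selected", "total"):
                sub = gdf[(gdf["replicate"] == rep) & (gdf["library"] == lib)]
                counts = np.zeros(n, dtype=int)
                counts[sub["codon"].to_numpy() - 1] = sub["count"].to_numpy()
                size = lib_sizes.get((rep, lib), float(counts.sum()))
                per_lib[lib] = CodonCounts(str(gene), str(rep), lib, counts, size)
            reps.append((per_lib["selected"], per_lib["total"]))
        out[str(gene)] = reps
    return out


# ------------------------------------------------------------------- domains

def write_domains(cands: dict[str, list[DomainCandidate]], path: str | Path) -> None:
    rows = [
        (pid, c.start, c.end, c.rank, c.id or f"{pid}_d{c.rank}")
        for pid, cs in cands.items()
        for c in cs
    ]
    pd.DataFrame(rows, columns=["protein_id", "start", "end", "rank", "id"]).to_csv(
        path, sep="\t", index=False
    )


def read_domains(path: str | Path) -> dict[str, list[DomainCandidate]]:
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "start", "end", "rank", "id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    out: dict[str, list[DomainCandidate]] = {}
    for k, row in df.iterrows():
        try:
            cand = DomainCandidate(
                int(row["start"]), int(row["end"]), int(row["rank"]), str(row["id"])
            )
        except (ValueError, TypeError) as ex:
            raise ValueError(f"{path}: line {k + 2}: {ex}") from ex
        out.setdefault(str(row["protein_id"]), []).append(cand)
    return out


# ------------------------------------------------------------------ contacts

def write_contacts(cmap: ContactMap, path: str | Path) -> None:
    rows = [(c.i, c.j, c.strength, c.domain_label) for c in cmap.contacts]
    pd.DataFrame(rows, columns=["i", "j", "strength", "domain_label"]).to_csv(
        path, sep="\t", index=False
    )


def read_contacts(path: str | Path, protein_id: str, n_residues: int) -> ContactMap:
    df = pd.read_csv(path, sep="\t")
    contacts = [
        ResidueContact(int(r.i), int(r.j), int(r.strength), str(r.domain_label))
        for r in df.itertuples()
    ]
    return ContactMap(protein_id, n_residues, contacts)


# ------------------------------------------------------------------ profiles

def write_profile_table(
    pred: GenePrediction,
    path: str | Path,
    engagement_score: float | None = None,
    params: ModelParams | None = None,
) -> pd.DataFrame:
    """Per-codon model outputs; normalized columns need a measured score."""
    params = params or ModelParams()
    n = len(pred.tf.raw)
    score = engagement_score if engagement_score is not None else params.norm_floor
    df = pd.DataFrame(
        {
            "protein_id": pred.protein_id,
            "codon": np.arange(1, n + 1),
            "tf_raw": pred.tf.raw,
            "dnak_raw": pred.dnak.raw,
            "mg_raw": pred.molten_globule.raw,
            "tf_norm": normalize_profile(pred.tf.raw, score, params),
            "dnak_norm": normalize_profile(pred.dnak.raw, score, params),
            "structured_fraction": pred.structured_fraction,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df


def write_enrichment(profiles: list[EnrichmentProfile], path: str | Path) -> None:
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": p.gene_id,
                    "replicate": p.replicate,
                    "codon": np.arange(1, len(p) + 1),
                    "ratio": p.ratio,
                    "ci_low": p.ci_low,
                    "ci_high": p.ci_high,
                    "missing": p.missing.astype(int),
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.6g")


def peaks_to_bed(call: OnsetCall, chrom: str | None = None) -> pd.DataFrame:
    """Peak intervals as BED-like rows (0-based half-open conversion)."""
    return pd.DataFrame(
        [(chrom or call.gene_id, s - 1, e, f"peak{k + 1}") for k, (s, e) in enumerate(call.peaks)],
        columns=["chrom", "start", "end", "name"],
    )


# -------------------------------------------------------------------- config

@dataclass
class RunConfig:
    contact: ContactParams = field(default_factory=ContactParams)
    model: ModelParams = field(default_factory=ModelParams)
    serp: SerpParams = field(default_factory=SerpParams)
    dtw_metric: str = "abs"
    dtw_clip: float = 500.0
    cluster_min_len: int = 50
    seed: int = 0


def _from_mapping(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


def read_config(path: str | Path) -> RunConfig:
    """YAML config; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    top = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, cls in (("contact", ContactParams), ("model", ModelParams), ("serp", SerpParams)):
        if key in data:
            sub = dict(data[key])
            if key == "serp" and "exclude_genes" in sub:
                sub["exclude_genes"] = tuple(sub["exclude_genes"])
            kwargs[key] = _from_mapping(cls, sub)
    for key in ("dtw_metric", "dtw_clip", "cluster_min_len", "seed"):
        if key in data:
            kwargs[key] = data[key]
    return RunConfig(**kwargs)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg)))


# ------------------------------------------------------------------- run log

@dataclass
class RunLog:
    command: str
    config: RunConfig
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    records: dict[str, int] = field(default_factory=dict)
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add_input(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.inputs[str(path)] = digest

    def write(self, path: str | Path) -> None:
        payload = {
            "timestamp": self.timestamp,
            "command": self.command,
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
            "inputs": self.inputs,
            "records": self.records,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))
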