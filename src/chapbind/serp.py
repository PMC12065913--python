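"""Selective ribosome profiling (SeRP) enrichment statistics.

The chaperone-selected translatome is compared to the total translatome
codon-wise.  For each codon a centered sliding window (truncated at the
gene ends) sums selected counts ``a`` and total counts ``b``; the
enrichment ratio and its 95% confidence interval come from the binomial
construction p = a/(a+b), an Agresti–Coull interval on p, and the map
r = p/(1-p) scaled by the library-size ratio (total/selected).

On top of the windowed profiles the module computes per-gene engagement
scores (max lower CI bound with a 45-codon window, gene ends trimmed),
CI-supported binding-onset calls against a 1.5-fold threshold, metagene
summaries (start/stop aligned and domain-wise resampled), and the
normalized single-molecule occupancy statistics with their standard
error of proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .contacts import DomainAnnotation

__all__ = [
    "CodonCounts",
    "SerpParams",
    "EnrichmentProfile",
    "EngagementScore",
    "OnsetCall",
    "OccupancyStats",
    "windowed_enrichment",
    "average_replicates",
    "engagement_score",
    "binding_onset",
    "metagene",
    "domain_metagene",
    "occupancy_stats",
]

Z95 = 1.959964  # two-sided 95% normal quantile


@dataclass
class CodonCounts:
    gene_id: str
    replicate: str
    library: str  # "selected" | "total"
    counts: np.ndarray
    library_size: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("negative codon counts")
        if self.library not in ("selected", "total"):
            raise ValueError("library must be 'selected' or 'total'")
        if self.library_size < self.counts.sum():
            raise ValueError("library_size smaller than the gene's summed counts")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class SerpParams:
    ci_window_profile: int = 15
    ci_window_score: int = 45
    ci_level: float = 0.95
    onset_threshold: float = 1.5
    binding_high: float = 1.0
    binding_low: float = 0.2
    binding_none: float = 0.0
    onset_binding_cut: float = 0.6
    min_peak_len: int = 6
    head_trim: int = 30
    tail_trim: int = 10
    metagene_bin: int = 6
    tunnel_shift: int = 30
    domain_bins: int = 30
    linker_bins: int = 10
    max_linker: int = 40
    ratio_cap: float = 100.0
    exclude_genes: tuple[str, ...] = ("tufA", "tufB", "dnaK", "groL")


@dataclass
class EnrichmentProfile:
    gene_id: str
    replicate: str
    ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.missing is None:
            self.missing = np.zeros(len(self.ratio), dtype=bool)

    def __len__(self) -> int:
        return len(self.ratio)


@dataclass(frozen=True)
class EngagementScore:
    gene_id: str
    score: float


@dataclass
class OnsetCall:
    gene_id: str
    peaks: list[tuple[int, int]]  # 1-based closed codon intervals
    onset: int | None


@dataclass
class OccupancyStats:
    fraction: np.ndarray  # normalized occupancies, sum to 1
    se: np.ndarray


def _window_sums(x: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding sums, truncated at the ends (length preserved)."""
    n = len(x)
    half_lo = (window - 1) // 2
    half_hi = window // 2
    cs = np.concatenate([[0], np.cumsum(x, dtype=float)])
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    return cs[hi] - cs[lo]


def windowed_enrichment(
    selected: CodonCounts,
    total: CodonCounts,
    window: int | None = None,
    params: SerpParams | None = None,
) -> EnrichmentProfile:
    """Per-codon enrichment ratio with Agresti–Coull 95% CI.

    ``ratio = p/(1-p) * total_library/selected_library`` with
    p = a/(a+b) over the window sums; CI bounds are the interval bounds
    on p pushed through the same map and clamped to [0, ratio_cap].
    Windows with a + b = 0 are flagged missing.
    """
    params = params or SerpParams()
    window = window or params.ci_window_profile
    if len(selected) != len(total):
        raise ValueError(f"{selected.gene_id}: selected/total length mismatch")
    if window < 1:
        raise ValueError("window must be >= 1")
    a = _window_sums(selected.counts, window)
    b = _window_sums(total.counts, window)
    n = a + b
    missing = n == 0
    scale = total.library_size / selected.library_size
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(missing, np.nan, a / np.where(missing, 1, n))
        lo, hi = proportion_confint(a, np.where(missing, 1, n), alpha=1 - params.ci_level,
                                    method="agresti_coull")
        lo = np.clip(lo, 0.0, 1.0)
        hi = np.clip(hi, 0.0, 1.0)
        ratio = _odds(p) * scale
        ci_low = _odds(lo) * scale
        ci_high = _odds(hi) * scale
    cap = params.ratio_cap
    ratio = np.clip(np.nan_to_num(ratio, nan=0.0, posinf=cap), 0.0, cap)
    ci_low = np.clip(np.nan_to_num(ci_low, nan=0.0, posinf=cap), 0.0, cap)
    ci_high = np.clip(np.nan_to_num(ci_high, nan=0.0, posinf=cap), 0.0, cap)
    ratio[missing] = ci_low[missing] = ci_high[missing] = 0.0
    return EnrichmentProfile(selected.gene_id, selected.replicate, ratio, ci_low, ci_high, missing)


def _odds(p: np.ndarray) -> np.ndarray:
    return np.where(p >= 1.0, np.inf, p / (1.0 - p))


def average_replicates(profiles: list[EnrichmentProfile]) -> EnrichmentProfile:
    """Position-wise mean of ratio and CI bounds across replicates."""
    if not profiles:
        raise ValueError("no profiles to average")
    n = len(profiles[0])
    if any(len(p) != n for p in profiles):
        raise ValueError("replicate profiles differ in length")
    ratio = np.mean([p.ratio for p in profiles], axis=0)
    lo = np.mean([p.ci_low for p in profiles], axis=0)
    hi = np.mean([p.ci_high for p in profiles], axis=0)
    missing = np.any([p.missing for p in profiles], axis=0)
    return EnrichmentProfile(profiles[0].gene_id, "avg", ratio, lo, hi, missing)


def engagement_score(
    replicate_pairs: list[tuple[CodonCounts, CodonCounts]],
    params: SerpParams | None = None,
) -> EngagementScore:
    """Max replicate-averaged lower CI bound, 45-codon window, ends trimmed.

    ``replicate_pairs`` is a list of (selected, total) per replicate.
    """
    params = params or SerpParams()
    n = len(replicate_pairs[0][0])
    if n <= params.head_trim + params.tail_trim:
        raise ValueError(
            f"gene of {n} codons too short for trims "
            f"{params.head_trim}+{params.tail_trim}"
        )
    profs = [
        windowed_enrichment(sel, tot, params.ci_window_score, params)
        for sel, tot in replicate_pairs
    ]
    avg = average_replicates(profs)
    lo = avg.ci_low[params.head_trim : n - params.tail_trim]
    keep = ~avg.missing[params.head_trim : n - params.tail_trim]
    score = float(lo[keep].max()) if keep.any() else 0.0
    return EngagementScore(replicate_pairs[0][0].gene_id, score)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as 1-based closed intervals."""
    out = []
    start = None
    for k, v in enumerate(mask):
        if v and start is None:
            start = k
        elif not v and start is not None:
            out.append((start + 1, k))
            start = None
    if start is not None:
        out.append((start + 1, len(mask)))
    return out


def binding_onset(
    profiles: list[EnrichmentProfile], params: SerpParams | None = None
) -> OnsetCall:
    """CI-supported binding onset against the enrichment threshold.

    Per replicate each codon scores 1 (lower CI above threshold), 0.2
    (CI straddles it) or 0 (upper CI below it); replicate scores are
    averaged and binarized at > onset_binding_cut, runs shorter than
    ``min_peak_len`` are dropped, and the onset is the 5'-most codon of
    the first surviving peak.  Missing windows count as not bound.
    """
    params = params or SerpParams()
    if not profiles:
        raise ValueError("no replicate profiles")
    t = params.onset_threshold
    vals = []
    for p in profiles:
        v = np.full(len(p), params.binding_low)
        v[p.ci_low > t] = params.binding_high
        v[p.ci_high < t] = params.binding_none
        v[p.missing] = params.binding_none
        vals.append(v)
    mean = np.mean(vals, axis=0)
    bound = mean > params.onset_binding_cut
    peaks = [(s, e) for s, e in _runs(bound) if e - s + 1 >= params.min_peak_len]
    return OnsetCall(profiles[0].gene_id, peaks, peaks[0][0] if peaks else None)


def _shift_5prime(x: np.ndarray, shift: int) -> np.ndarray:
    """Move a ribosome-position profile toward the 5' end by ``shift``
    codons (value at codon c becomes the value observed at c + shift)."""
    if shift <= 0:
        return x
    return x[shift:]


def metagene(
    profiles: list[EnrichmentProfile],
    align: str = "start",
    params: SerpParams | None = None,
    shift: int = 0,
):
    """Across-gene binned mean enrichment with a 95% CI per bin.

    Gene profiles (already replicate-averaged) are aligned to the start
    or stop codon, optionally shifted toward the 5' end to account for
    the exit tunnel, binned (mean within ``metagene_bin``-codon bins)
    and averaged across genes; the CI is mean ± 1.96·SEM.

    Returns a dict of numpy arrays: bin (1-based), mean, ci_low,
    ci_high, n_genes.
    """
    params = params or SerpParams()
    if align not in ("start", "stop"):
        raise ValueError("align must be 'start' or 'stop'")
    if not profiles:
        raise ValueError("no profiles")
    w = params.metagene_bin
    per_gene = []
    for p in profiles:
        x = _shift_5prime(p.ratio, shift)
        if align == "stop":
            x = x[::-1]
        nb = int(np.ceil(len(x) / w))
        means = np.array([x[k * w : (k + 1) * w].mean() for k in range(nb)])
        per_gene.append(means)
    nbins = max(len(m) for m in per_gene)
    mat = np.full((len(per_gene), nbins), np.nan)
    for r, m in enumerate(per_gene):
        mat[r, : len(m)] = m
    n_genes = np.sum(~np.isnan(mat), axis=0)
    mean = np.nanmean(mat, axis=0)
    sem = _nan_sem(mat, n_genes)
    return {
        "bin": np.arange(1, nbins + 1),
        "mean": mean,
        "ci_low": mean - Z95 * sem,
        "ci_high": mean + Z95 * sem,
        "n_genes": n_genes,
    }


def _nan_sem(mat: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Column-wise SEM over non-NaN rows; 0 where fewer than 2 values."""
    sem = np.zeros(mat.shape[1])
    multi = n > 1
    if multi.any():
        sem[multi] = np.nanstd(mat[:, multi], axis=0, ddof=1) / np.sqrt(n[multi])
    return sem


def _resample_bins(x: np.ndarray, nbins: int) -> np.ndarray:
    """Mean of ``x`` within ``nbins`` equal partitions of its index range.

    Index i maps to bin floor(i * nbins / len(x)); when len(x) < nbins
    the untouched bins are NaN.
    """
    n = len(x)
    out = np.full(nbins, np.nan)
    if n == 0:
        return out
    which = (np.arange(n) * nbins) // n
    for b in range(nbins):
        sel = which == b
        if sel.any():
            out[b] = x[sel].mean()
    return out


def domain_metagene(
    profiles: dict[str, EnrichmentProfile],
    annotations: dict[str, DomainAnnotation],
    params: SerpParams | None = None,
):
    """Domain-wise metagene: each (domain, following linker) instance is
    resampled to ``domain_bins`` + ``linker_bins`` bins and averaged
    across instances; linkers longer than ``max_linker`` residues are
    excluded.  Returns dict with bin, mean, ci_low, ci_high, n.
    """
    params = params or SerpParams()
    nb = params.domain_bins + params.linker_bins
    rows = []
    for gene, ann in annotations.items():
        if gene not in profiles:
            continue
        x = profiles[gene].ratio
        doms = ann.domains
        for k, d in enumerate(doms[:-1]):
            nxt = doms[k + 1]
            linker_len = nxt.start - d.end - 1
            if linker_len > params.max_linker:
                continue
            row = np.full(nb, np.nan)
            row[: params.domain_bins] = _resample_bins(
                x[d.start - 1 : d.end], params.domain_bins
            )
            if linker_len > 0:
                row[params.domain_bins :] = _resample_bins(
                    x[d.end : nxt.start - 1], params.linker_bins
                )
            rows.append(row)
    if not rows:
        raise ValueError("no domain/linker instances to average")
    mat = np.vstack(rows)
    n = np.sum(~np.isnan(mat), axis=0)
    mean = np.full(mat.shape[1], np.nan)
    mean[n > 0] = np.nanmean(mat[:, n > 0], axis=0)
    sem = _nan_sem(mat, n)
    return {
        "bin": np.arange(1, nb + 1),
        "mean": mean,
        "ci_low": mean - Z95 * sem,
        "ci_high": mean + Z95 * sem,
        "n": n,
    }


def occupancy_stats(
    events: np.ndarray, molecules: np.ndarray, time: np.ndarray
) -> OccupancyStats:
    """Normalized per-fragment binding occupancy with SE of proportion.

    Per fragment n: fraction = events / molecules / time, normalized so
    the fractions sum to one; SE_n = sqrt(p_n (1 - p_n) / N_n) with N_n
    the molecules measured for fragment n.
    """
    events = np.asarray(events, dtype=float)
    molecules = np.asarray(molecules, dtype=float)
    time = np.asarray(time, dtype=float)
    if np.any(molecules <= 0):
        raise ValueError("each fragment needs at least one molecule")
    if np.any(time <= 0):
        raise ValueError("measurement time must be positive")
    frac = events / molecules / time
    total = frac.sum()
    if total == 0:
        raise ValueError("no binding events in any fragment")
    p = frac / total
    se = np.sqrt(p * (1.0 - p) / molecules)
    return OccupancyStats(p, se)
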