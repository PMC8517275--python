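"""TF-motif enrichment over accessibility co-clusters and ChIP-seq association.

Motif enrichment compares, for each (motif, accessibility co-cluster) pair,
the motif frequency among the co-cluster's accessible loci (averaged over
its cell types) against the same quantity on the complement loci and cell
types, through the score (r - n)/(r + n).  A permutation null — one global
permutation of the motif matrix's locus labels per replicate — calibrates a
score cutoff at a target FDR.

ChIP-seq peaks are associated with locus clusters by counting loci whose
window contains a peak summit, scaling by the expected count under uniform
placement, and testing the overlap between ChIP-enriched and accessible
clusters with a hypergeometric tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .peak_matrix import PeakSet, ScoredWindow, TssAnnotation

__all__ = [
    "MotifHitMatrix",
    "EnrichmentResult",
    "ScaledCounts",
    "filter_distal",
    "raw_score",
    "null_score",
    "enrichment_score",
    "score_matrix",
    "permutation_cutoff",
    "chip_overlap",
    "scaled_counts",
    "association_test",
]


@dataclass
class MotifHitMatrix:
    """Binary loci x motifs matrix A (1 = motif present at locus)."""

    locus_names: list[str]
    motif_names: list[str]
    entries: np.ndarray

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=np.uint8)
        if self.entries.shape != (len(self.locus_names), len(self.motif_names)):
            raise ValueError("entries shape does not match loci/motifs")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.entries, index=self.locus_names,
                     columns=self.motif_names).to_csv(path, sep="\t", index_label="locus")

    @classmethod
    def from_tsv(cls, path) -> "MotifHitMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(i) for i in df.index], [str(c) for c in df.columns],
                   df.to_numpy(dtype=np.uint8))


def filter_distal(tss_annotation: TssAnnotation) -> np.ndarray:
    """Boolean mask of TSS-distal loci (the enrichment substrate)."""
    return np.asarray(tss_annotation.classes) == "distal"


def _mean_motif_fraction(M_sub: np.ndarray, A_sub: np.ndarray) -> np.ndarray:
    """Per-motif mean over cell types of the motif fraction among accessible loci.

    M_sub: (loci, cells) binary; A_sub: (loci, motifs) binary.  Cell types
    with zero accessible loci are skipped; all skipped -> NaN.
    """
    acc = M_sub.astype(np.float64)              # (L, C)
    denom = acc.sum(axis=0)                     # accessible loci per cell type
    keep = denom > 0
    if not keep.any():
        return np.full(A_sub.shape[1], np.nan)
    numer = acc[:, keep].T @ A_sub.astype(np.float64)   # (C_kept, motifs)
    fracs = numer / denom[keep][:, None]
    return fracs.mean(axis=0)


def raw_score(M: np.ndarray, A: np.ndarray, locus_mask: np.ndarray,
              cell_mask: np.ndarray) -> np.ndarray:
    """Raw co-cluster score r per motif (vectorised over A's columns)."""
    return _mean_motif_fraction(M[np.ix_(locus_mask, cell_mask)],
                                A[locus_mask])


def null_score(M: np.ndarray, A: np.ndarray, locus_mask: np.ndarray,
               cell_mask: np.ndarray) -> np.ndarray:
    """Raw null score n on complement loci x complement cell types."""
    return _mean_motif_fraction(M[np.ix_(~locus_mask, ~cell_mask)],
                                A[~locus_mask])


def enrichment_score(r, n_null):
    """(r - n)/(r + n); 0 where both are 0 (flagged by the zero itself)."""
    r = np.asarray(r, dtype=np.float64)
    n = np.asarray(n_null, dtype=np.float64)
    tot = r + n
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, (r - n) / np.where(tot > 0, tot, 1.0), 0.0)
    out = np.where(np.isnan(r) | np.isnan(n), np.nan, out)
    return out if out.ndim else float(out)


def score_matrix(M: np.ndarray, A: np.ndarray,
                 locus_masks: list[np.ndarray],
                 cell_masks: list[np.ndarray]) -> np.ndarray:
    """Enrichment scores, shape (n_coclusters, n_motifs)."""
    rows = []
    for lm, cm in zip(locus_masks, cell_masks):
        r = raw_score(M, A, lm, cm)
        n = null_score(M, A, lm, cm)
        rows.append(enrichment_score(r, n))
    return np.stack(rows)


@dataclass
class EnrichmentResult:
    scores: np.ndarray           # (coclusters, motifs)
    cutoff: float
    calls: np.ndarray            # bool, same shape
    motif_names: list[str] | None = None
    cocluster_ids: list[int] | None = None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("cocluster\tmotif\tscore\tcall\n")
            for i in range(self.scores.shape[0]):
                cid = self.cocluster_ids[i] if self.cocluster_ids else i
                for m in range(self.scores.shape[1]):
                    name = self.motif_names[m] if self.motif_names else str(m)
                    fh.write(f"{cid}\t{name}\t{self.scores[i, m]:.6g}"
                             f"\t{int(self.calls[i, m])}\n")


def permutation_cutoff(M: np.ndarray, A: np.ndarray,
                       locus_masks: list[np.ndarray],
                       cell_masks: list[np.ndarray],
                       fdr: float = 0.05, n_perm: int = 50,
                       seed: int = 0) -> EnrichmentResult:
    """Permutation-calibrated enrichment cutoff at the target FDR.

    Each replicate permutes A's locus labels globally (breaking locus-motif
    association, preserving per-motif frequencies and M), recomputes all
    scores, and the cutoff is the smallest observed score c for which
    (mean null count >= c) / (observed count >= c) <= fdr.  No passing c
    yields cutoff = +inf and zero calls.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    rng = np.random.default_rng(seed)
    obs = score_matrix(M, A, locus_masks, cell_masks)
    obs_flat = obs[~np.isnan(obs)].ravel()
    null_flat = []
    L = A.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(L)
        s = score_matrix(M, A[perm], locus_masks, cell_masks)
        null_flat.append(s[~np.isnan(s)].ravel())
    null_flat = np.concatenate(null_flat)
    null_sorted = np.sort(null_flat)
    obs_sorted = np.sort(obs_flat)
    cands = np.unique(obs_flat)
    n_obs = len(obs_sorted) - np.searchsorted(obs_sorted, cands, side="left")
    mean_null = (len(null_sorted)
                 - np.searchsorted(null_sorted, cands, side="left")) / n_perm
    ok = (n_obs > 0) & (mean_null / np.maximum(n_obs, 1) <= fdr)
    cutoff = float(cands[ok].min()) if ok.any() else np.inf
    calls = np.zeros_like(obs, dtype=bool) if np.isinf(cutoff) else \
        np.nan_to_num(obs, nan=-np.inf) >= cutoff
    return EnrichmentResult(scores=obs, cutoff=cutoff, calls=calls)


def chip_overlap(master: list[ScoredWindow], chip_peaks: PeakSet) -> np.ndarray:
    """Binary vector: locus contains >= 1 ChIP peak summit (half-open window)."""
    summits: dict[str, list[int]] = {}
    for chrom, start, end, offset, _ in chip_peaks.peaks:
        summits.setdefault(chrom, []).append(start + offset)
    summits = {c: np.sort(np.asarray(v)) for c, v in summits.items()}
    hits = np.zeros(len(master), dtype=np.uint8)
    for i, w in enumerate(master):
        pos = summits.get(w.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end - 1, side="right")
        if hi > lo:
            hits[i] = 1
    return hits


@dataclass
class ScaledCounts:
    cluster_ids: np.ndarray
    raw: np.ndarray
    expected: np.ndarray
    scaled: np.ndarray           # raw / expected; NaN when no hits at all

    @property
    def enriched(self) -> np.ndarray:
        """Cluster ids with scaled count > 1."""
        return self.cluster_ids[np.nan_to_num(self.scaled) > 1]


def scaled_counts(hits: np.ndarray, row_labels: np.ndarray) -> ScaledCounts:
    """Per-cluster ChIP hit counts scaled by a uniform-placement expectation."""
    hits = np.asarray(hits)
    row_labels = np.asarray(row_labels)
    ids = np.unique(row_labels)
    raw = np.array([hits[row_labels == j].sum() for j in ids], dtype=np.float64)
    sizes = np.array([(row_labels == j).sum() for j in ids], dtype=np.float64)
    total_hits = raw.sum()
    expected = total_hits * sizes / sizes.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(expected > 0, raw / np.where(expected > 0, expected, 1), np.nan)
    if total_hits == 0:
        scaled = np.full_like(raw, np.nan)
    return ScaledCounts(cluster_ids=ids, raw=raw, expected=expected, scaled=scaled)


def association_test(enriched_clusters: set, accessible_clusters: set,
                     total_clusters: int) -> float:
    """Upper-tail hypergeometric p-value of the enriched/accessible overlap."""
    enriched = set(enriched_clusters)
    accessible = set(accessible_clusters)
    k_obs = len(enriched & accessible)
    return float(hypergeom.sf(k_obs - 1, total_clusters,
                              len(accessible), len(enriched)))
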