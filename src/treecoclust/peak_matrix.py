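"""Binary accessibility matrix construction from per-cell-type peak calls.

Each ATAC-seq peak contributes a fixed-width window centred on its summit
(250 bp up- and downstream by default, i.e. a 500 bp window).  Windows from
all cell types are pooled and reduced, per chromosome and 5'->3', to a
greedy *master list* of non-overlapping loci: at each step the scan gathers
the current window plus all subsequent windows intersecting it, keeps the
one with the highest quality score, then resumes at the next window that
does not intersect the kept locus.  The binary matrix M has one row per
master locus and one column per cell type; an entry is 1 iff any of that
cell type's original peak intervals overlaps the locus by at least one base.

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScoredWindow",
    "PeakSet",
    "AccessibilityMatrix",
    "TssAnnotation",
    "read_narrowpeak",
    "peaks_to_windows",
    "build_master_loci",
    "build_matrix",
    "split_cell_specific",
    "classify_tss",
]


@dataclass(frozen=True)
class ScoredWindow:
    chrom: str
    start: int
    end: int
    score: float
    source_cell: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"degenerate window {self.chrom}:{self.start}-{self.end}")

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "ScoredWindow") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class PeakSet:
    """Peak calls for one cell type, sorted by (chrom, start).

    ``peaks`` rows are (chrom, start, end, summit_offset, score); the summit
    offset is relative to the peak start and lies within the peak.
    """

    cell_type: str
    peaks: list[tuple[str, int, int, int, float]]
    score_source: str = "qValue"

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: (p[0], p[1]))


NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "summit",
]


def read_narrowpeak(path, cell_type: str | None = None) -> PeakSet:
    """Read a narrowPeak (BED6+4) file into a :class:`PeakSet`.

    The per-peak quality score is taken from the qValue column; where the
    qValue is missing (-1) the BED score column is used instead.  A summit
    offset of -1 is replaced by the peak midpoint.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLS,
                         comment="#", dtype={"chrom": str})
    except Exception as exc:  # noqa: BLE001 - surface parse failures with path
        raise ValueError(f"cannot parse narrowPeak file {path}: {exc}") from exc
    if df.shape[1] != 10 or df[["start", "end", "summit"]].isna().any().any():
        raise ValueError(f"{path}: not a 10-column narrowPeak file")
    peaks = []
    used_fallback = False
    for ln, row in enumerate(df.itertuples(index=False), 1):
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise ValueError(f"{path}:{ln}: start >= end")
        summit = int(row.summit)
        if summit == -1:
            summit = (end - start) // 2
        if not 0 <= summit < end - start:
            raise ValueError(f"{path}:{ln}: summit offset {summit} outside peak of length {end - start}")
        q = float(row.qValue)
        if q == -1:
            q = float(row.score)
            used_fallback = True
        peaks.append((str(row.chrom), start, end, summit, q))
    if cell_type is None:
        cell_type = str(path)
    return PeakSet(cell_type=cell_type, peaks=peaks,
                   score_source="score" if used_fallback else "qValue")


def peaks_to_windows(peaks: PeakSet, halfwidth: int = 250) -> list[ScoredWindow]:
    """Fixed-width summit windows [summit-halfwidth, summit+halfwidth), left-clipped at 0."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    out = []
    for chrom, start, end, offset, score in peaks.peaks:
        summit = start + offset
        out.append(ScoredWindow(chrom, max(summit - halfwidth, 0), summit + halfwidth,
                                score, peaks.cell_type))
    return out


def build_master_loci(window_sets: list[list[ScoredWindow]]) -> list[ScoredWindow]:
    """Greedy master list of pairwise non-overlapping loci.

    Ties on score are broken by leftmost start, then source cell name; the
    output is sorted and every locus is one of the input windows.
    """
    pooled: dict[str, list[ScoredWindow]] = {}
    for ws in window_sets:
        for w in ws:
            pooled.setdefault(w.chrom, []).append(w)
    master: list[ScoredWindow] = []
    for chrom in sorted(pooled):
        wins = sorted(pooled[chrom], key=lambda w: (w.start, w.end, w.source_cell or ""))
        i, n = 0, len(wins)
        while i < n:
            cur = wins[i]
            # gather cur plus all subsequent windows intersecting cur
            j = i + 1
            best = cur
            while j < n and wins[j].start < cur.end:
                w = wins[j]
                if w.score > best.score or (
                    w.score == best.score
                    and (w.start, w.source_cell or "") < (best.start, best.source_cell or "")
                ):
                    best = w
                j += 1
            master.append(best)
            # resume at the next window not overlapping the added locus
            i = j
            while i < n and wins[i].start < best.end:
                i += 1
    return master


@dataclass
class AccessibilityMatrix:
    """Binary loci x cell-types matrix M."""

    loci: list[ScoredWindow]
    cell_types: list[str]
    entries: np.ndarray  # uint8, shape (n_loci, n_cell_types)

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=np.uint8)
        if self.entries.shape != (len(self.loci), len(self.cell_types)):
            raise ValueError("entries shape does not match loci/cell_types")

    @property
    def locus_names(self) -> list[str]:
        return [w.name for w in self.loci]

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    # -- io ------------------------------------------------------------
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.entries, index=self.locus_names, columns=self.cell_types)
        df.to_csv(path, sep="\t", index_label="locus")

    @classmethod
    def from_tsv(cls, path) -> "AccessibilityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        loci = []
        for name in df.index:
            chrom, rest = str(name).rsplit(":", 1)
            start, end = rest.split("-")
            loci.append(ScoredWindow(chrom, int(start), int(end), 0.0))
        return cls(loci, [str(c) for c in df.columns], df.to_numpy(dtype=np.uint8))

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for w in self.loci:
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.name}\t{w.score}\n")

    def to_sparse_triplets(self, path) -> None:
        rows, cols = np.nonzero(self.entries)
        with open(path, "w") as fh:
            fh.write(f"# {len(self.loci)} {len(self.cell_types)}\n")
            for r, c in zip(rows, cols):
                fh.write(f"{r}\t{c}\t1\n")


def build_matrix(master: list[ScoredWindow], peak_sets: list[PeakSet]) -> AccessibilityMatrix:
    """Entry (l, c) = 1 iff any original peak of cell type c overlaps locus l."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    order = sorted(range(len(master)), key=lambda i: (master[i].chrom, master[i].start))
    master = [master[i] for i in order]
    for idx, w in enumerate(master):
        by_chrom.setdefault(w.chrom, []).append((w.start, w.end, idx))
    for chrom, triples in list(by_chrom.items()):
        starts = np.array([t[0] for t in triples])
        ends = np.array([t[1] for t in triples])
        idxs = np.array([t[2] for t in triples])
        by_chrom[chrom] = (starts, ends, idxs)
    entries = np.zeros((len(master), len(peak_sets)), dtype=np.uint8)
    for ci, ps in enumerate(peak_sets):
        if not ps.peaks:
            warnings.warn(f"cell type {ps.cell_type!r} has zero peaks; all-zero column")
            continue
        for chrom, s, e, _, _ in ps.peaks:
            if chrom not in by_chrom:
                continue
            starts, ends, idxs = by_chrom[chrom]
            # loci with start < e and end > s; loci are disjoint and sorted
            lo = np.searchsorted(ends, s, side="right")
            hi = np.searchsorted(starts, e, side="left")
            if hi > lo:
                entries[idxs[lo:hi], ci] = 1
    return AccessibilityMatrix(master, [ps.cell_type for ps in peak_sets], entries)


def split_cell_specific(M: AccessibilityMatrix, max_cells: int = 2
                        ) -> tuple[AccessibilityMatrix, AccessibilityMatrix]:
    """Split rows accessible in <= max_cells cell types (cell-specific) from the rest."""
    rs = M.entries.sum(axis=1)
    spec_mask = rs <= max_cells
    def take(mask):
        idx = np.nonzero(mask)[0]
        return AccessibilityMatrix([M.loci[i] for i in idx], list(M.cell_types),
                                   M.entries[idx])
    return take(spec_mask), take(~spec_mask)


@dataclass
class TssAnnotation:
    """Distance from each locus midpoint to the nearest TSS, and its class.

    proximal: distance <= 500 bp; distal: > 3000 bp; else intermediate.
    """

    distances: np.ndarray
    classes: np.ndarray  # array of {'proximal','distal','intermediate'}

    PROXIMAL_BP = 500
    DISTAL_BP = 3000


def classify_tss(master: list[ScoredWindow], tss: dict[str, list[int]]) -> TssAnnotation:
    """Nearest-TSS distance per locus (0 if a TSS falls inside the locus)."""
    sorted_tss = {c: np.sort(np.asarray(pos)) for c, pos in tss.items() if len(pos)}
    dist = np.full(len(master), np.inf)
    for i, w in enumerate(master):
        pos = sorted_tss.get(w.chrom)
        if pos is None:
            continue
        inside_lo = np.searchsorted(pos, w.start, side="left")
        inside_hi = np.searchsorted(pos, w.end - 1, side="right")
        if inside_hi > inside_lo:
            dist[i] = 0
            continue
        mid = (w.start + w.end) // 2
        j = np.searchsorted(pos, mid)
        cands = []
        if j > 0:
            cands.append(abs(mid - pos[j - 1]))
        if j < len(pos):
            cands.append(abs(mid - pos[j]))
        dist[i] = min(cands)
    classes = np.where(dist <= TssAnnotation.PROXIMAL_BP, "proximal",
                       np.where(dist > TssAnnotation.DISTAL_BP, "distal", "intermediate"))
    return TssAnnotation(distances=dist, classes=classes)
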