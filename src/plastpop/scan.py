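"""Comparative-plastomics scan: trim, bin, profile variability, rank hotspots.

The scan tiles a trimmed plastome alignment into fixed-length bins and records,
per bin, the GC content, the number of segregating SNP sites, the number of
indel events (maximal gap runs, identical-extent runs shared by several samples
counted once — an indel is one mutational event) and the number of cpSSR loci.
Bins with the highest combined SNP + indel counts are ranked into mutational
hotspot regions; SSR loci whose repeat number differs among samples are
screened as polymorphic cpSSRs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import AlignmentError, PlastpopError
from .io import AlignedSet, CANONICAL

__all__ = [
    "SsrLocus",
    "BinProfile",
    "HotspotRegion",
    "PolymorphicSsr",
    "trim_alignment",
    "profile_bins",
    "detect_ssrs",
    "spearman_rho",
    "rank_hotspots",
    "screen_polymorphic_ssrs",
    "map_ssrs_to_alignment",
    "gap_run_events",
]


@dataclass(frozen=True)
class SsrLocus:
    """A perfect tandem repeat. Coordinates are 1-based closed.

    ``start``/``end`` refer to the coordinate system the locus was detected or
    mapped in: the ungapped sequence for :func:`detect_ssrs` output, alignment
    columns after :func:`map_ssrs_to_alignment`.
    """

    sample_id: str
    start: int
    end: int
    motif: str
    units: int

    @property
    def length(self) -> int:
        return self.units * len(self.motif)


@dataclass(frozen=True)
class BinProfile:
    bin_index: int  # 1-based ordinal
    start: int  # alignment column, 1-based closed
    end: int
    gc: float  # NaN when the bin is all-gap
    snp_count: int
    indel_count: int
    ssr_count: int


@dataclass(frozen=True)
class HotspotRegion:
    start: int
    end: int
    snp_total: int
    indel_total: int
    rank: int

    @property
    def score(self) -> int:
        return self.snp_total + self.indel_total


@dataclass(frozen=True)
class PolymorphicSsr:
    """A cluster of homologous SSR loci whose repeat number varies."""

    motif: str  # canonical (lexicographically smallest rotation)
    start: int  # alignment columns spanned by the cluster
    end: int
    alleles: dict  # sample_id -> unit count (0 = locus absent in that sample)


# ---------------------------------------------------------------------------
# trimming

def trim_alignment(aln: AlignedSet) -> tuple[AlignedSet, list[int]]:
    """Remove every column carrying an ambiguous character in any sequence.

    Characters outside ``{A,C,G,T,-}`` (N, IUPAC codes, ...) are ambiguous.
    Returns the trimmed alignment and the list of retained original columns
    (1-based), mapping trimmed column *i* (0-based) to original column
    ``kept[i]``.
    """
    mat = aln.to_matrix()
    ok = np.isin(mat, np.frombuffer(b"ACGT-", dtype=np.uint8)).all(axis=0)
    kept0 = np.flatnonzero(ok)
    if kept0.size == 0:
        raise AlignmentError("all columns ambiguous; nothing left after trimming")
    return aln.with_columns(kept0.tolist()), (kept0 + 1).tolist()


# ---------------------------------------------------------------------------
# gap-run (indel event) bookkeeping

def gap_run_events(aln: AlignedSet, sample_ids: Sequence[str] | None = None) -> list[tuple[int, int]]:
    """Distinct maximal gap runs among the given samples, 1-based closed.

    A run is one indel event; runs with identical extent in several samples
    are one shared event. Runs carried by every sample represent no variation
    among them and are not events. Sorted by (start, end).
    """
    mat = aln.to_matrix(sample_ids)
    gap = mat == ord("-")
    carriers: dict[tuple[int, int], int] = {}
    for row in gap:
        padded = np.concatenate(([False], row, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1) - 1
        for s, e in zip((starts + 1).tolist(), (ends + 1).tolist()):
            carriers[(s, e)] = carriers.get((s, e), 0) + 1
    return sorted(ext for ext, k in carriers.items() if k < mat.shape[0])


# ---------------------------------------------------------------------------
# bin profiling

def profile_bins(
    aln: AlignedSet,
    bin_length: int = 400,
    ingroup: Iterable[str] | None = None,
    ssrs: Sequence[SsrLocus] = (),
) -> list[BinProfile]:
    """Tile the alignment into bins and profile per-bin variability.

    ``snp_count`` counts segregating sites (columns with >= 2 distinct non-gap
    bases among the ingroup). ``indel_count`` assigns each distinct gap-run
    event to the single bin containing its leftmost column. ``gc`` is computed
    over ingroup non-gap bases only. ``ssr_count`` counts loci (already mapped
    to alignment coordinates) whose leftmost column falls in the bin.
    """
    if bin_length < 1:
        raise ValueError("bin_length must be >= 1")
    ids = list(ingroup) if ingroup is not None else aln.sample_ids
    if not ids:
        raise ValueError("empty ingroup")
    unknown = set(ids) - set(aln.sample_ids)
    if unknown:
        raise ValueError(f"ingroup samples not in alignment: {sorted(unknown)}")

    mat = aln.to_matrix(ids)
    L = mat.shape[1]
    gap = mat == ord("-")
    gc_base = (mat == ord("G")) | (mat == ord("C"))

    # segregating columns: >= 2 distinct non-gap bases among ingroup
    present = np.stack([(mat == c).any(axis=0) for c in b"ACGT"])
    seg = present.sum(axis=0) >= 2

    events = gap_run_events(aln.subset(ids), ids)

    n_bins = int(np.ceil(L / bin_length))
    profiles = []
    ssr_starts = np.array([loc.start for loc in ssrs], dtype=int) if ssrs else np.empty(0, int)
    event_starts = np.array([s for s, _ in events], dtype=int) if events else np.empty(0, int)
    for b in range(n_bins):
        lo0, hi0 = b * bin_length, min((b + 1) * bin_length, L)  # 0-based half-open
        nongap = ~gap[:, lo0:hi0]
        denom = int(nongap.sum())
        gc = float(gc_base[:, lo0:hi0].sum() / denom) if denom else float("nan")
        profiles.append(
            BinProfile(
                bin_index=b + 1,
                start=lo0 + 1,
                end=hi0,
                gc=gc,
                snp_count=int(seg[lo0:hi0].sum()),
                indel_count=int(((event_starts >= lo0 + 1) & (event_starts <= hi0)).sum()),
                ssr_count=int(((ssr_starts >= lo0 + 1) & (ssr_starts <= hi0)).sum()),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# SSR detection

def _is_primitive(motif: str) -> bool:
    """True if the motif is not itself a repetition of a shorter unit."""
    m = len(motif)
    for p in range(1, m):
        if m % p == 0 and motif == motif[: p] * (m // p):
            return False
    return True


def detect_ssrs(
    seq: str,
    min_mono: int = 8,
    min_multi: int = 5,
    max_motif: int = 6,
    sample_id: str = "",
) -> list[SsrLocus]:
    """Find perfect tandem repeats (cpSSRs) in an ungapped sequence.

    Motif lengths 1..``max_motif``; mononucleotide loci need >= ``min_mono``
    units, longer motifs >= ``min_multi`` units (the GMATo-style thresholds).
    Loci are reported once, at their smallest period; overlapping candidates
    are resolved leftmost-longest. Coordinates are 1-based closed on ``seq``.
    """
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")
    n = len(seq)
    candidates: list[tuple[int, int, str, int]] = []  # (start0, length, motif, units)
    for m in range(1, max_motif + 1):
        i = 0
        while i + m <= n:
            # extend the maximal m-periodic stretch starting at i
            j = i + m
            while j < n and seq[j] == seq[j - m]:
                j += 1
            stretch = j - i
            units = stretch // m
            threshold = min_mono if m == 1 else min_multi
            motif = seq[i : i + m]
            if units >= threshold and _is_primitive(motif):
                candidates.append((i, units * m, motif, units))
            # next possible stretch cannot start before j - m + 1
            i = max(i + 1, j - m + 1) if units >= 2 else i + 1
    # leftmost-longest resolution
    candidates.sort(key=lambda c: (c[0], -c[1], len(c[2])))
    chosen: list[SsrLocus] = []
    occupied_end = -1
    for start0, length, motif, units in candidates:
        if start0 > occupied_end:
            chosen.append(
                SsrLocus(sample_id=sample_id, start=start0 + 1, end=start0 + length, motif=motif, units=units)
            )
            occupied_end = start0 + length - 1
    return chosen


def map_ssrs_to_alignment(aligned_seq: str, loci: Sequence[SsrLocus]) -> list[SsrLocus]:
    """Translate loci found on the ungapped sequence to alignment columns."""
    cols = [i + 1 for i, ch in enumerate(aligned_seq) if ch != "-"]  # ungapped pos -> column
    out = []
    for loc in loci:
        out.append(replace(loc, start=cols[loc.start - 1], end=cols[loc.end - 1]))
    return out


# ---------------------------------------------------------------------------
# correlation

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with two-sided p-value.

    Average ranks; p from the large-sample t approximation. Constant input
    yields ``(nan, nan)`` — an undefined correlation, distinct from zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# hotspot ranking

def rank_hotspots(
    profiles: Sequence[BinProfile],
    k: int = 27,
    merge_adjacent: bool = True,
) -> list[HotspotRegion]:
    """Select the top-k most variable regions from a bin profile.

    Bins are scored by ``snp_count + indel_count`` (ties: higher snp_count,
    then lower start coordinate) and added greedily; adjacent selected bins
    fuse into one region whose totals are the summed counts. Selection stops
    when k regions exist or variable bins run out (then a warning is issued).
    """
    if not profiles:
        raise ValueError("empty profile list")
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(
        (p for p in profiles if p.snp_count + p.indel_count > 0),
        key=lambda p: (-(p.snp_count + p.indel_count), -p.snp_count, p.start),
    )
    by_index = {p.bin_index: p for p in profiles}
    selected: set[int] = set()

    def regions_of(sel: set[int]) -> list[list[int]]:
        out: list[list[int]] = []
        for idx in sorted(sel):
            if out and idx == out[-1][-1] + 1 and merge_adjacent:
                out[-1].append(idx)
            else:
                out.append([idx])
        return out

    for p in ranked:
        if len(regions_of(selected)) >= k and not (
            merge_adjacent and (p.bin_index - 1 in selected or p.bin_index + 1 in selected)
        ):
            continue
        trial = selected | {p.bin_index}
        if len(regions_of(trial)) > k:
            continue
        selected = trial
        if len(regions_of(selected)) == k:
            break
    regs = regions_of(selected)
    if len(regs) < k:
        warnings.warn(
            f"only {len(regs)} variable regions available, fewer than requested k={k}",
            stacklevel=2,
        )
    out = []
    for bins in regs:
        ps = [by_index[i] for i in bins]
        out.append(
            HotspotRegion(
                start=ps[0].start,
                end=ps[-1].end,
                snp_total=sum(p.snp_count for p in ps),
                indel_total=sum(p.indel_count for p in ps),
                rank=0,
            )
        )
    out.sort(key=lambda r: (-r.score, -r.snp_total, r.start))
    return [replace(r, rank=i + 1) for i, r in enumerate(out)]


# ---------------------------------------------------------------------------
# polymorphic cpSSR screening

def _canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def screen_polymorphic_ssrs(
    aln: AlignedSet,
    ingroup: Iterable[str] | None = None,
    min_mono: int = 8,
    min_multi: int = 5,
    max_motif: int = 6,
) -> list[PolymorphicSsr]:
    """Find homologous SSR loci whose repeat number differs among samples.

    SSRs are detected on each ungapped ingroup sequence, mapped back to
    alignment columns, and clustered when their alignment spans overlap and
    their canonical motifs agree. A cluster is polymorphic when unit counts
    differ among samples carrying the locus, or when some ingroup sample lacks
    it entirely (absent alleles are reported as 0 units).
    """
    ids = list(ingroup) if ingroup is not None else aln.sample_ids
    per_sample: list[tuple[str, SsrLocus]] = []
    for sid in ids:
        aligned = aln.sequence(sid)
        ungapped = aligned.replace("-", "")
        loci = detect_ssrs(ungapped, min_mono, min_multi, max_motif, sample_id=sid)
        for loc in map_ssrs_to_alignment(aligned, loci):
            per_sample.append((sid, loc))

    # union-find over loci: same canonical motif + overlapping alignment span
    n = len(per_sample)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    canon = [_canonical_rotation(loc.motif) for _, loc in per_sample]
    order = sorted(range(n), key=lambda i: per_sample[i][1].start)
    for ii, i in enumerate(order):
        _, li = per_sample[i]
        for j in order[ii + 1 :]:
            _, lj = per_sample[j]
            if lj.start > li.end:
                break
            if canon[i] == canon[j]:
                union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    out = []
    for members in clusters.values():
        alleles = {ids_i: 0 for ids_i in ids}
        start = min(per_sample[i][1].start for i in members)
        end = max(per_sample[i][1].end for i in members)
        for i in members:
            sid, loc = per_sample[i]
            alleles[sid] = max(alleles[sid], loc.units)
        observed = set(alleles.values())
        if len(observed) >= 2:
            out.append(
                PolymorphicSsr(
                    motif=canon[members[0]], start=start, end=end, alleles=alleles
                )
            )
    out.sort(key=lambda c: c.start)
    return out
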