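"""Haplotype identification and Nei diversity statistics.

Aligned marker sequences are collapsed into haplotypes over two kinds of
characters: substitution columns (segregating sites after masking) and indel
characters (each maximal shared gap run is one binary presence/absence
character — an indel is a single mutation event). Terminal gaps are treated as
missing data, and columns inside long mononucleotide runs are excluded, since
homopolymer length variation is scored separately as cpSSR variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError
from .io import AlignedSet

__all__ = [
    "HaplotypeTable",
    "DistanceMatrix",
    "collapse_haplotypes",
    "haplotype_diversity",
    "nucleotide_diversity",
    "haplotype_frequency_report",
]

MISSING = "?"


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal matrix of mutational steps between haplotypes."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal not zero")
        if (v < 0).any():
            raise ValueError("negative distances")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class HaplotypeTable:
    """Distinct haplotypes, their character-state signatures and counts.

    ``signatures`` holds one state tuple per haplotype over the analyzed
    characters; ``char_kinds`` marks each character as ``"sub"`` (substitution
    column) or ``"indel"`` (binary gap-run presence). ``counts`` is a
    haplotype x population table; ``L_effective`` is the number of ungapped,
    unmasked alignment columns available for per-site statistics.
    """

    hap_ids: list[str]
    signatures: list[tuple]
    char_kinds: list[str]
    char_positions: list[tuple]  # column (1-based,) for subs; (start, end) for indels
    counts: pd.DataFrame  # haplotypes x populations
    sample_to_hap: dict[str, str]
    n_total: int
    L_effective: int
    masked_columns: list[int] = field(default_factory=list)

    def global_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def distance_matrix(self, kinds: set[str] | None = None) -> DistanceMatrix:
        """Pairwise haplotype distances over characters of the given kinds.

        Characters where either haplotype is missing do not contribute.
        """
        use = np.array(
            [kinds is None or k in kinds for k in self.char_kinds], dtype=bool
        )
        H = len(self.hap_ids)
        d = np.zeros((H, H))
        for i in range(H):
            for j in range(i + 1, H):
                si, sj = self.signatures[i], self.signatures[j]
                steps = sum(
                    1
                    for c in np.flatnonzero(use)
                    if si[c] != MISSING and sj[c] != MISSING and si[c] != sj[c]
                )
                d[i, j] = d[j, i] = steps
        return DistanceMatrix(list(self.hap_ids), d)

    def substitution_distances(self) -> DistanceMatrix:
        return self.distance_matrix({"sub"})


def _terminal_gap_mask(row: np.ndarray) -> np.ndarray:
    """Boolean mask of leading/trailing gap positions in one sequence row."""
    nongap = np.flatnonzero(row != ord("-"))
    mask = np.zeros(row.size, dtype=bool)
    if nongap.size == 0:
        mask[:] = True
        return mask
    mask[: nongap[0]] = True
    mask[nongap[-1] + 1 :] = True
    return mask


def _mononucleotide_columns(mat: np.ndarray, min_run: int) -> np.ndarray:
    """Columns inside a run of >= min_run identical bases in any sequence."""
    n, L = mat.shape
    masked = np.zeros(L, dtype=bool)
    for row in mat:
        start = 0
        while start < L:
            ch = row[start]
            end = start
            while end + 1 < L and row[end + 1] == ch:
                end += 1
            if ch in b"ACGT" and end - start + 1 >= min_run:
                masked[start : end + 1] = True
            start = end + 1
    return masked


def collapse_haplotypes(
    aln: AlignedSet,
    exclude_mononucleotide_repeats: bool = True,
    mono_run_min: int = 8,
) -> tuple[HaplotypeTable, DistanceMatrix]:
    """Collapse an aligned, trimmed marker set into haplotypes.

    Processing order: terminal gaps become per-sample missing data; columns in
    mononucleotide runs of >= ``mono_run_min`` bp (in any sample) are masked
    when the flag is set; every distinct maximal internal gap-run extent is
    recoded as one binary indel character; remaining segregating columns give
    substitution characters. Haplotype ids ``H1, H2, ...`` are assigned by
    decreasing global count, ties by first occurrence after sample-id sort.

    Returns the table and the full (substitution + indel) distance matrix.
    """
    order = sorted(aln.sample_ids)
    mat = aln.to_matrix(order)
    n, L = mat.shape

    term = np.stack([_terminal_gap_mask(row) for row in mat])
    masked = (
        _mononucleotide_columns(mat, mono_run_min)
        if exclude_mononucleotide_repeats
        else np.zeros(L, dtype=bool)
    )

    # indel characters: distinct maximal internal gap-run extents
    gap = (mat == ord("-")) & ~term
    extents: list[tuple[int, int]] = []
    carrier: dict[tuple[int, int], set[int]] = {}
    for i in range(n):
        row = gap[i]
        padded = np.concatenate(([False], row, [False]))
        diff = np.diff(padded.astype(np.int8))
        for s, e in zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1) - 1):
            if masked[s : e + 1].all():
                continue  # gap entirely inside a masked homopolymer
            ext = (int(s) + 1, int(e) + 1)  # 1-based closed
            carrier.setdefault(ext, set()).add(i)
    extents = sorted(carrier)

    # substitution characters: segregating unmasked columns
    votes = ~term & (mat != ord("-"))
    sub_cols = []
    for c in np.flatnonzero(~masked):
        bases = set(mat[votes[:, c], c].tolist())
        if len(bases) >= 2:
            sub_cols.append(int(c))

    char_kinds = ["sub"] * len(sub_cols) + ["indel"] * len(extents)
    char_positions: list[tuple] = [(c + 1,) for c in sub_cols] + list(extents)

    signatures = []
    for i in range(n):
        states: list = []
        for c in sub_cols:
            states.append(chr(mat[i, c]) if votes[i, c] else MISSING)
        for ext in extents:
            if term[i, ext[0] - 1]:  # extent falls in this sample's missing flank
                states.append(MISSING)
            else:
                states.append(1 if i in carrier[ext] else 0)
        signatures.append(tuple(states))

    if not char_kinds:
        warnings.warn("no polymorphic characters; all samples form one haplotype", stacklevel=2)

    # group samples by signature, first-occurrence order over sample-id sort
    sig_order: list[tuple] = []
    members: dict[tuple, list[str]] = {}
    for sid, sig in zip(order, signatures):
        if sig not in members:
            members[sig] = []
            sig_order.append(sig)
        members[sig].append(sid)

    # id assignment: decreasing global count, ties by first occurrence
    ranked = sorted(sig_order, key=lambda s: (-len(members[s]), sig_order.index(s)))
    hap_ids = [f"H{i + 1}" for i in range(len(ranked))]
    sample_to_hap = {
        sid: hap_ids[ranked.index(sig)] for sig, sids in members.items() for sid in sids
    }

    pop_of = {sid: aln.population_of.get(sid, "all") for sid in order}
    pops = sorted(set(pop_of.values()))
    counts = pd.DataFrame(0, index=hap_ids, columns=pops, dtype=int)
    for sid in order:
        counts.loc[sample_to_hap[sid], pop_of[sid]] += 1

    # effective length: unmasked columns with no gap/missing in any sample
    complete = ~masked & ~(gap | term).any(axis=0)
    table = HaplotypeTable(
        hap_ids=hap_ids,
        signatures=ranked,
        char_kinds=char_kinds,
        char_positions=char_positions,
        counts=counts,
        sample_to_hap=sample_to_hap,
        n_total=n,
        L_effective=int(complete.sum()),
        masked_columns=(np.flatnonzero(masked) + 1).tolist(),
    )
    return table, table.distance_matrix()


def haplotype_diversity(counts) -> float:
    """Nei's unbiased haplotype (gene) diversity.

    ``Hd = n/(n-1) * (1 - sum p_i^2)`` with ``p_i = count_i / n``.
    """
    c = np.asarray(list(counts), dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity needs n >= 2 samples")
    p = c / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def nucleotide_diversity(counts, dists: DistanceMatrix, L_effective: int) -> float:
    """Nucleotide diversity Pi from haplotype counts and substitution distances.

    ``Pi = n/(n-1) * sum_{i<j} 2 p_i p_j d_ij / L``; indel characters must be
    excluded from ``dists`` (use :meth:`HaplotypeTable.substitution_distances`).
    """
    c = np.asarray(list(counts), dtype=float)
    n = c.sum()
    if n < 2:
        raise UndefinedStatisticError("nucleotide diversity needs n >= 2 samples")
    if L_effective < 1:
        raise UndefinedStatisticError("no analyzable sites (L_effective = 0)")
    p = c / n
    d = dists.values
    pair = 0.0
    for i in range(len(c)):
        for j in range(i + 1, len(c)):
            pair += 2 * p[i] * p[j] * d[i, j]
    return float(n / (n - 1) * pair / L_effective)


def haplotype_frequency_report(table: HaplotypeTable) -> pd.DataFrame:
    """Global and per-population haplotype frequencies in percent (2 decimals)."""
    counts = table.counts
    out = pd.DataFrame(index=counts.index)
    out["count"] = counts.sum(axis=1)
    out["global_pct"] = (out["count"] / table.n_total * 100).round(2)
    for pop in counts.columns:
        tot = counts[pop].sum()
        out[f"{pop}_pct"] = (
            (counts[pop] / tot * 100).round(2) if tot else float("nan")
        )
    return out
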