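"""Readers, writers and in-memory containers for alignments and sample maps.

All coordinates reported by this package are 1-based, closed intervals over
alignment columns. TSV artifacts are tab-separated with ``#``-prefixed header
comments carrying the tool version, the parameters of the run and the seed.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, FormatError

__all__ = [
    "AlignedSet",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_population_map",
    "write_population_map",
    "write_tsv",
]

#: Canonical unambiguous alignment alphabet. Anything else is ambiguous.
CANONICAL = frozenset("ACGT-")


@dataclass
class AlignedSet:
    """A gapped multiple sequence alignment with optional population labels.

    Sequences are stored uppercase; all must share one length. ``population_of``
    maps a subset of the sample ids to population names, ``group_of`` maps
    population names to higher-level group names (used by hierarchical AMOVA).
    """

    records: list[tuple[str, str]]
    population_of: dict[str, str] = field(default_factory=dict)
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no sequences")
        self.records = [(sid, seq.upper()) for sid, seq in self.records]
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
        if 0 in lengths:
            raise AlignmentError("alignment length is zero")
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sample ids: {dupes}")
        if any(not sid for sid in ids):
            raise FormatError("empty sample id")
        missing = set(self.population_of) - set(ids)
        if missing:
            raise FormatError(f"population map refers to unknown samples: {sorted(missing)}")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_samples(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    def sequence(self, sample_id: str) -> str:
        for sid, seq in self.records:
            if sid == sample_id:
                return seq
        raise KeyError(sample_id)

    def to_matrix(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """Alignment as a 2-D byte matrix (rows follow ``sample_ids`` order)."""
        ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        seqs = {sid: seq for sid, seq in self.records}
        return np.array(
            [np.frombuffer(seqs[sid].encode("ascii"), dtype=np.uint8) for sid in ids]
        )

    def subset(self, sample_ids: Iterable[str]) -> "AlignedSet":
        keep = set(sample_ids)
        return AlignedSet(
            records=[(sid, seq) for sid, seq in self.records if sid in keep],
            population_of={s: p for s, p in self.population_of.items() if s in keep},
            group_of=dict(self.group_of),
        )

    def with_columns(self, columns_0based: Sequence[int]) -> "AlignedSet":
        """New alignment keeping only the given columns, order preserved."""
        cols = list(columns_0based)
        if not cols:
            raise AlignmentError("no columns left in alignment")
        mat = self.to_matrix()
        sub = mat[:, cols]
        recs = [
            (sid, sub[i].tobytes().decode("ascii"))
            for i, sid in enumerate(self.sample_ids)
        ]
        return AlignedSet(recs, dict(self.population_of), dict(self.group_of))

    def populations(self) -> dict[str, list[str]]:
        """Population name -> ordered list of member sample ids."""
        out: dict[str, list[str]] = {}
        for sid, _ in self.records:
            pop = self.population_of.get(sid)
            if pop is not None:
                out.setdefault(pop, []).append(sid)
        return out


def read_fasta_alignment(
    path: str | Path,
    population_of: Mapping[str, str] | None = None,
    group_of: Mapping[str, str] | None = None,
) -> AlignedSet:
    """Read an aligned FASTA file into an :class:`AlignedSet`.

    Record order is preserved and sequences are uppercased. Records must all
    have the same length; violation raises :class:`AlignmentError`.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if len(records) < 2:
        raise FormatError(f"{path}: FASTA alignment needs >= 2 records, found {len(records)}")
    return AlignedSet(records, dict(population_of or {}), dict(group_of or {}))


def write_fasta_alignment(aln: AlignedSet, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.records]
    SeqIO.write(recs, str(path), "fasta-2line")


def read_population_map(path: str | Path) -> pd.DataFrame:
    """Read a sample->population (optionally ->group) TSV.

    Expected columns: ``sample_id``, ``population``, optional ``group``.
    Lines starting with ``#`` are comments. One row per sample.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "population"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: population map must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise FormatError(f"{path}: duplicate sample_id rows: {dupes}")
    if df["population"].isna().any() or (df["population"].str.len() == 0).any():
        raise FormatError(f"{path}: empty population name")
    if "group" not in df.columns:
        df["group"] = pd.NA
    return df[["sample_id", "population", "group"]].reset_index(drop=True)


def write_population_map(popmap: pd.DataFrame, path: str | Path, header: str = "") -> None:
    write_tsv(popmap, path, header)


def _header_block(header: str) -> str:
    if not header:
        return ""
    lines = [f"# {line}".rstrip() for line in header.splitlines()]
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path: str | Path, header: str = "") -> None:
    """Write a DataFrame as TSV with a ``#``-comment header block."""
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    Path(path).write_text(_header_block(header) + buf.getvalue())


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
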