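"""Synthetic plastome populations with the structure the analyses assume.

Three generators:

* a reference plastome with quadripartite structure (LSC + IRa + SSC + IRb,
  the second inverted repeat the reverse complement of the first), AT-biased
  mutational hotspot intervals and seeded cpSSR loci;
* a population alignment: a pool of haplotypes produced by a two-tier star
  mutation process (deme founders radiate from the ancestral reference at a
  controlled divergence, within-deme haplotypes derive from their founder by
  about one further step), with SNPs and indels placed preferentially in
  hotspots, indels realized directly as gap runs in the alignment coordinate
  frame, SSR repeat numbers varying among haplotypes, and optional admixture
  between demes;
* haploid multilocus cpSSR genotype matrices with cluster-specific allele
  frequencies, for testing the admixture clusterer.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SpecError
from .io import AlignedSet

__all__ = [
    "Hotspot",
    "PlastomeSpec",
    "DemographySpec",
    "simulate_reference_plastome",
    "simulate_population_alignment",
    "simulate_cpssr_genotypes",
    "default_demo_spec",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Hotspot:
    """A mutational hotspot interval (1-based closed reference coordinates)."""

    start: int
    end: int
    gc_local: float = 0.25  # AT-biased by default, as real plastome hotspots are
    snp_rate: float = 0.0
    indel_rate: float = 0.0
    ssr_seeds: tuple = ()  # ((motif, units), ...)


@dataclass
class PlastomeSpec:
    lsc_length: int
    ssc_length: int
    ir_length: int
    gc_background: float = 0.37
    hotspots: list[Hotspot] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.lsc_length, self.ssc_length) < 1 or self.ir_length < 0:
            raise SpecError("region lengths must be positive (IR may be zero)")
        if not 0 < self.gc_background < 1:
            raise SpecError("gc_background must lie in (0, 1)")
        spans = sorted((h.start, h.end) for h in self.hotspots)
        for (s, e) in spans:
            if not 1 <= s <= e <= self.total_length:
                raise SpecError(f"hotspot ({s}, {e}) outside [1, {self.total_length}]")
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise SpecError(f"overlapping hotspot intervals ({s1},{e1}) and ({s2},{e2})")
        for h in self.hotspots:
            for r in (h.snp_rate, h.indel_rate):
                if not 0 <= r <= 1:
                    raise SpecError("per-site rates must lie in [0, 1]")
            if not 0 < h.gc_local < 1:
                raise SpecError("hotspot gc_local must lie in (0, 1)")
            if self.ir_length and h.end > self.core_length:
                raise SpecError(
                    "hotspot overlaps the second IR copy; place hotspots in "
                    "LSC, IRa or SSC (the IR mirror would overwrite them)"
                )

    @property
    def core_length(self) -> int:
        return self.lsc_length + self.ir_length + self.ssc_length

    @property
    def total_length(self) -> int:
        return self.core_length + self.ir_length


@dataclass
class DemographySpec:
    """Sampling design: demes, sizes, divergence and admixture."""

    populations: list[tuple[str, int, str]]  # (name, n_samples, group)
    haplotype_pool_size: int = 8
    divergence_steps: float = 5.0
    within_deme_steps: float = 1.0
    admixture: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.populations:
            raise SpecError("no populations declared")
        for name, n, _ in self.populations:
            if n < 1:
                raise SpecError(f"population {name} has n_samples < 1")
        if not 0 <= self.admixture <= 1:
            raise SpecError("admixture must lie in [0, 1]")
        if self.haplotype_pool_size < len(self.populations):
            raise SpecError("haplotype pool smaller than the number of demes")


def _draw_bases(n: int, gc: np.ndarray | float, rng: np.random.Generator) -> np.ndarray:
    gc = np.broadcast_to(np.asarray(gc, dtype=float), (n,))
    is_gc = rng.random(n) < gc
    pick = rng.integers(0, 2, n)
    out = np.where(is_gc, np.where(pick == 0, ord("G"), ord("C")),
                   np.where(pick == 0, ord("A"), ord("T"))).astype(np.uint8)
    return out


def simulate_reference_plastome(
    spec: PlastomeSpec, seed: int | None = None
) -> tuple[str, dict]:
    """Generate a quadripartite reference plastome.

    Returns the sequence (length lsc + ir + ssc + ir; the trailing IR copy is
    the reverse complement of the leading one) and an annotation dict with the
    region intervals, the hotspot intervals and the realized SSR seed loci
    (all 1-based closed).
    """
    rng = np.random.default_rng(seed)
    core = spec.core_length
    gc = np.full(core, spec.gc_background)
    for h in spec.hotspots:
        gc[h.start - 1 : h.end] = h.gc_local
    seq = _draw_bases(core, gc, rng)

    ssr_loci = []
    for h in spec.hotspots:
        pos = h.start - 1  # 0-based cursor
        for motif, units in h.ssr_seeds:
            block = (motif.upper() * units).encode("ascii")
            if pos + len(block) > h.end:
                raise SpecError(
                    f"SSR seeds do not fit in hotspot ({h.start}, {h.end})"
                )
            seq[pos : pos + len(block)] = np.frombuffer(block, dtype=np.uint8)
            ssr_loci.append(
                {"motif": motif.upper(), "units": units, "start": pos + 1, "end": pos + len(block)}
            )
            pos += len(block) + 5  # spacer between seeded loci

    text = seq.tobytes().decode("ascii")
    if spec.ir_length:
        ira = text[spec.lsc_length : spec.lsc_length + spec.ir_length]
        text = text + revcomp(ira)

    lsc, ir, ssc = spec.lsc_length, spec.ir_length, spec.ssc_length
    annotation = {
        "regions": {
            "LSC": (1, lsc),
            **({"IRA": (lsc + 1, lsc + ir)} if ir else {}),
            "SSC": (lsc + ir + 1, lsc + ir + ssc),
            **({"IRB": (core + 1, core + ir)} if ir else {}),
        },
        "hotspots": [(h.start, h.end) for h in spec.hotspots],
        "ssr_loci": ssr_loci,
    }
    return text, annotation


# ---------------------------------------------------------------------------
# population alignments


def _site_weights(spec: PlastomeSpec, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-site SNP and indel placement weights: hotspot rate inside hotspot
    intervals, one tenth of the maximum hotspot rate elsewhere."""
    max_snp = max((h.snp_rate for h in spec.hotspots), default=0.0)
    max_indel = max((h.indel_rate for h in spec.hotspots), default=0.0)
    snp_w = np.full(length, max_snp / 10.0)
    indel_w = np.full(length, max_indel / 10.0)
    for h in spec.hotspots:
        snp_w[h.start - 1 : h.end] = h.snp_rate
        indel_w[h.start - 1 : h.end] = h.indel_rate
    return snp_w, indel_w


def _mutations(
    n_events: int,
    snp_w: np.ndarray,
    indel_w: np.ndarray,
    rng: np.random.Generator,
    gc: float,
) -> list[tuple]:
    """Draw private mutation events: sites by weight, type by relative rate."""
    total = snp_w + indel_w
    wsum = total.sum()
    if wsum <= 0 or n_events == 0:
        return []
    prob = total / wsum
    events = []
    used_cols: set[int] = set()
    for _ in range(n_events):
        for _attempt in range(20):
            col = int(rng.choice(total.size, p=prob))
            if col not in used_cols:
                break
        used_cols.add(col)
        p_snp = snp_w[col] / total[col] if total[col] > 0 else 1.0
        if rng.random() < p_snp:
            events.append(("snp", col, int(rng.integers(0, 3))))
        else:
            length = int(rng.integers(1, 11))  # 1-10 columns
            if rng.random() < 0.5:
                events.append(("del", col, length))
            else:
                ins = _draw_bases(length, gc, rng).tobytes().decode("ascii")
                events.append(("ins", col, ins))
    return events


def simulate_population_alignment(
    reference: str,
    demography: DemographySpec,
    spec: PlastomeSpec,
    annotation: dict | None = None,
) -> tuple[AlignedSet, pd.DataFrame, pd.DataFrame]:
    """Simulate a structured population sample as a gapped alignment.

    Returns (alignment, truth, popmap): ``truth`` records each sample's true
    haplotype identity, ``popmap`` is the sample -> population -> group table.
    Insertions are realized as gap columns in all non-carrier samples, so the
    output is already aligned; no re-alignment step exists or is needed.
    """
    rng = np.random.default_rng(demography.seed)
    L = len(reference)
    snp_w, indel_w = _site_weights(spec, min(L, spec.total_length))
    if snp_w.size < L:  # reference may lack the IR copy
        snp_w = np.pad(snp_w, (0, L - snp_w.size), constant_values=snp_w.min() if snp_w.size else 0)
        indel_w = np.pad(indel_w, (0, L - indel_w.size), constant_values=indel_w.min() if indel_w.size else 0)
    ref = np.frombuffer(reference.upper().encode("ascii"), dtype=np.uint8).copy()

    demes = [name for name, _, _ in demography.populations]
    D = len(demes)
    H = demography.haplotype_pool_size
    deme_of_hap = {h: h % D for h in range(H)}

    # two-tier star: founders radiate from the ancestor, others from founders
    founders = {d: min(h for h in range(H) if deme_of_hap[h] == d) for d in range(D)}
    hap_events: dict[int, list[tuple]] = {}
    mutable = snp_w.sum() + indel_w.sum() > 0
    for d in range(D):
        # >= 1 step per founder keeps pool haplotypes sequence-distinct
        n_mut = max(1, int(rng.poisson(demography.divergence_steps))) if mutable else 0
        hap_events[founders[d]] = _mutations(n_mut, snp_w, indel_w, rng, spec.gc_background)
    for h in range(H):
        if h in hap_events:
            continue
        extra = max(1, int(rng.poisson(demography.within_deme_steps))) if mutable else 0
        hap_events[h] = list(hap_events[founders[deme_of_hap[h]]]) + _mutations(
            extra, snp_w, indel_w, rng, spec.gc_background
        )

    # SSR repeat-number variation: up to 3 extra units per haplotype and locus
    ssr_loci = (annotation or {}).get("ssr_loci", [])
    max_extra = 3
    ssr_extra = {
        (h, i): int(rng.integers(0, max_extra + 1))
        for h in range(H)
        for i in range(len(ssr_loci))
    }

    # column plan: reference columns + insertion blocks, ordered by position
    blocks: list[tuple] = []  # (after_col0, kind, key, width, payload)
    for h in range(H):
        for i, ev in enumerate(hap_events[h]):
            if ev[0] == "ins":
                blocks.append((ev[1], "ins", (h, i), len(ev[2]), ev[2]))
    for i, loc in enumerate(ssr_loci):
        width = max_extra * len(loc["motif"])
        blocks.append((loc["end"] - 1, "ssr", i, width, loc["motif"]))
    blocks.sort(key=lambda b: (b[0], b[1], str(b[2])))

    # insertion events inherited from a founder are the same tuples in every
    # descendant's list: deduplicate blocks by (position, payload) so shared
    # insertions occupy one column block, then record which haplotypes carry it
    dedup: list[tuple] = []
    seen: set[tuple] = set()
    for after, kind, key, width, payload in blocks:
        sig = (after, kind, payload) if kind == "ins" else (after, kind, key)
        if sig in seen:
            continue
        seen.add(sig)
        dedup.append((after, kind, key, width, payload))
    blocks = dedup
    block_owner: dict[tuple, set[int]] = {
        key: {
            h
            for h in range(H)
            for ev in hap_events[h]
            if ev[0] == "ins" and ev[1] == after and ev[2] == payload
        }
        for after, kind, key, width, payload in blocks
        if kind == "ins"
    }

    def build_row(h: int) -> str:
        row = ref.copy()
        for ev in hap_events[h]:  # substitutions first, gaps overwrite them
            if ev[0] == "snp":
                col, k = ev[1], ev[2]
                alts = [b for b in b"ACGT" if b != row[col]]
                row[col] = alts[k]
        for ev in hap_events[h]:
            if ev[0] == "del":
                col, length = ev[1], ev[2]
                row[col : col + length] = ord("-")
        pieces: list[str] = []
        cursor = 0
        for after, kind, key, width, payload in blocks:
            pieces.append(row[cursor : after + 1].tobytes().decode("ascii"))
            cursor = after + 1
            if kind == "ins":
                pieces.append(payload if h in block_owner[key] else "-" * width)
            else:  # ssr pad: carried extra units, gap-filled to block width
                filled = payload * ssr_extra[(h, key)]
                pieces.append(filled + "-" * (width - len(filled)))
        pieces.append(row[cursor:].tobytes().decode("ascii"))
        return "".join(pieces)

    hap_rows = {h: build_row(h) for h in range(H)}

    records: list[tuple[str, str]] = []
    population_of: dict[str, str] = {}
    group_of: dict[str, str] = {}
    truth_rows = []
    for d, (name, n, group) in enumerate(demography.populations):
        group_of[name] = group
        own_pool = [h for h in range(H) if deme_of_hap[h] == d]
        for s in range(n):
            src_deme = d
            if demography.admixture > 0 and D > 1 and rng.random() < demography.admixture:
                others = [x for x in range(D) if x != d]
                src_deme = int(rng.choice(others))
            pool = [h for h in range(H) if deme_of_hap[h] == src_deme] or own_pool
            hap = int(rng.choice(pool))
            sid = f"{name}_s{s + 1}"
            records.append((sid, hap_rows[hap]))
            population_of[sid] = name
            truth_rows.append((sid, name, group, f"hap{hap}", demes[src_deme]))

    aln = AlignedSet(records, population_of, group_of)
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "population", "group", "haplotype", "source_deme"]
    )
    popmap = truth[["sample_id", "population", "group"]].copy()
    return aln, truth, popmap


# ---------------------------------------------------------------------------
# cpSSR genotype matrices


def simulate_cpssr_genotypes(
    k_true: int,
    n_loci: int,
    samples_per_cluster: int | list[int],
    divergence: float = 0.2,
    admixture_alpha: float = 0.0,
    seed: int | None = None,
    n_alleles: int = 4,
    fixed_alternate: bool = False,
):
    """Simulate haploid cpSSR genotypes from K clusters.

    Per cluster and locus, allele frequencies are drawn from a symmetric
    Dirichlet with concentration ``divergence`` (small values give strongly
    diverged, near-fixed clusters). ``admixture_alpha = 0`` yields pure
    cluster membership; larger values spread each sample's admixture vector
    Q_i ~ Dirichlet(alpha * 1 + e_home). ``fixed_alternate`` forces cluster k
    to be fixed for allele ``(k + l) mod n_alleles`` at locus l (degenerate,
    fully diverged clusters). Allele codes are fragment-length-like integers
    (8, 9, ...). Returns (GenotypeMatrix, truth Q, truth P).
    """
    from .cluster import GenotypeMatrix

    if k_true < 1 or n_loci < 1:
        raise SpecError("k_true and n_loci must be >= 1")
    if divergence <= 0:
        raise SpecError("divergence (Dirichlet concentration) must be > 0")
    rng = np.random.default_rng(seed)
    sizes = (
        [samples_per_cluster] * k_true
        if isinstance(samples_per_cluster, int)
        else list(samples_per_cluster)
    )
    if len(sizes) != k_true:
        raise SpecError("samples_per_cluster list must have k_true entries")
    N = sum(sizes)

    P = np.empty((k_true, n_loci, n_alleles))
    if fixed_alternate:
        P[:] = 0.0
        for k in range(k_true):
            for l in range(n_loci):
                P[k, l, (k + l) % n_alleles] = 1.0
    else:
        for k in range(k_true):
            for l in range(n_loci):
                P[k, l] = rng.dirichlet([divergence] * n_alleles)

    home = np.repeat(np.arange(k_true), sizes)
    if admixture_alpha == 0:
        Q = np.eye(k_true)[home]
    else:
        Q = np.vstack(
            [
                rng.dirichlet(admixture_alpha * np.ones(k_true) + np.eye(k_true)[h])
                for h in home
            ]
        )

    alleles = np.empty((N, n_loci), dtype=int)
    for i in range(N):
        for l in range(n_loci):
            z = rng.choice(k_true, p=Q[i])
            alleles[i, l] = 8 + rng.choice(n_alleles, p=P[z, l])

    gm = GenotypeMatrix(
        sample_ids=[f"s{i + 1}" for i in range(N)],
        locus_names=[f"L{l + 1}" for l in range(n_loci)],
        alleles=alleles,
        populations=[f"C{h + 1}" for h in home],
    )
    return gm, Q, P


def default_demo_spec() -> tuple[PlastomeSpec, DemographySpec]:
    """A compact plastome and demography used by the CLI demo pipeline.

    Scaled-down quadripartite structure (12 kb total) with four AT-rich
    hotspots carrying seeded cpSSRs, five demes of realistic sizes.
    """
    hotspots = [
        Hotspot(1200, 1799, gc_local=0.20, snp_rate=0.02, indel_rate=0.008,
                ssr_seeds=(("A", 10), ("AT", 6))),
        Hotspot(3600, 4199, gc_local=0.22, snp_rate=0.02, indel_rate=0.008,
                ssr_seeds=(("T", 9),)),
        Hotspot(6200, 6799, gc_local=0.20, snp_rate=0.02, indel_rate=0.008,
                ssr_seeds=(("TA", 6), ("AAG", 5))),
        Hotspot(8300, 8899, gc_local=0.24, snp_rate=0.02, indel_rate=0.008,
                ssr_seeds=(("A", 11),)),
    ]
    spec = PlastomeSpec(
        lsc_length=6000, ssc_length=1200, ir_length=2400,
        gc_background=0.37, hotspots=hotspots,
    )
    demography = DemographySpec(
        populations=[
            ("Huoshan", 9, "Anhui"),
            ("Luan", 7, "Anhui"),
            ("Huangshan", 2, "Anhui"),
            ("Longhushan", 6, "Jiangxi"),
            ("Funiushan", 4, "Henan"),
        ],
        haplotype_pool_size=11,
        divergence_steps=5.0,
        admixture=0.0,
    )
    return spec, demography
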