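"""Population differentiation: Hs/Ht/Gst/Nst estimators and AMOVA.

Two complementary views of chloroplast population structure:

* Pons & Petit gene-diversity estimators on haplotype frequencies — within-
  population diversity Hs, total diversity Ht, Gst = 1 - Hs/Ht, and their
  distance-weighted analogs vS, vT, Nst = 1 - vS/vT. Nst exceeding Gst means
  closely related haplotypes co-occur within populations: phylogeographic
  structure. The excess is tested by permuting haplotype identities on the
  distance matrix.
* AMOVA: squared inter-sample distances partitioned among hierarchical strata
  (groups / populations within groups / within populations), variance
  components by the method of moments, fixation indices Phi, and permutation
  p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SpecError, UndefinedStatisticError
from .haplo import DistanceMatrix

__all__ = [
    "DifferentiationStats",
    "AmovaResult",
    "permut_diversity",
    "test_nst_gt_gst",
    "amova",
    "sample_distance_matrix",
]


@dataclass
class DifferentiationStats:
    Hs: float
    Ht: float
    Gst: float
    vS: float
    vT: float
    Nst: float
    n_populations: int


def _prep_counts(counts: pd.DataFrame) -> pd.DataFrame:
    sizes = counts.sum(axis=0)
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(
            f"populations with n < 2 excluded from diversity estimators: {small}",
            stacklevel=3,
        )
        counts = counts.drop(columns=small)
    if counts.shape[1] < 2:
        raise UndefinedStatisticError("need >= 2 populations with n >= 2")
    return counts


def permut_diversity(counts: pd.DataFrame, dists: DistanceMatrix) -> DifferentiationStats:
    """Pons & Petit diversity and differentiation estimators.

    ``counts`` is a haplotype x population table; ``dists`` the haplotype
    distance matrix (mutational steps). Populations enter with equal weight;
    the total-diversity correction uses the harmonic mean sample size. The
    unordered statistics use haplotype identity alone; the ordered (v / Nst)
    statistics replace ``1 - sum p^2`` by the distance-weighted
    ``sum_{i != j} p_i p_j d_ij``, so with all inter-haplotype distances equal
    Nst reduces exactly to Gst.
    """
    counts = _prep_counts(counts)
    if list(dists.labels) != list(counts.index):
        raise ValueError("distance matrix labels do not match haplotype counts index")
    C = counts.to_numpy(dtype=float)
    n_k = C.sum(axis=0)
    P = C.shape[1]
    freqs = C / n_k
    d = dists.values

    corr = n_k / (n_k - 1)
    h_k = corr * (1.0 - (freqs**2).sum(axis=0))
    v_k = corr * np.einsum("ik,jk,ij->k", freqs, freqs, d)

    Hs = float(h_k.mean())
    vS = float(v_k.mean())
    n_tilde = P / (1.0 / n_k).sum()
    pbar = freqs.mean(axis=1)
    Ht = float(1.0 - (pbar**2).sum() + Hs / (n_tilde * P))
    vT = float(pbar @ d @ pbar + vS / (n_tilde * P))

    if Ht <= 0:
        raise UndefinedStatisticError("Ht = 0 (monomorphic data): Gst undefined")
    Gst = 1.0 - Hs / Ht
    Nst = 1.0 - vS / vT if vT > 0 else float("nan")
    return DifferentiationStats(Hs, Ht, Gst, vS, vT, Nst, P)


def test_nst_gt_gst(
    counts: pd.DataFrame,
    dists: DistanceMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, DifferentiationStats]:
    """Permutation test for phylogeographic structure (Nst > Gst).

    The null keeps haplotype frequencies fixed and shuffles haplotype
    identities on the distance matrix, destroying any association between
    haplotype relatedness and geography. p = (1 + #{Nst-Gst >= observed}) /
    (n_perm + 1). Returns (p, observed statistics).
    """
    if counts.shape[0] < 2:
        raise UndefinedStatisticError("Nst/Gst test needs >= 2 haplotypes")
    obs = permut_diversity(counts, dists)
    observed = obs.Nst - obs.Gst
    rng = np.random.default_rng(seed)
    H = len(dists.labels)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(H)
        d_perm = DistanceMatrix(list(dists.labels), dists.values[np.ix_(perm, perm)])
        stat = permut_diversity(counts, d_perm)
        if stat.Nst - stat.Gst >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1), obs


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    table: pd.DataFrame  # source, df, SS, variance component, pct of total
    phi: dict  # {'phi_st': .., optionally 'phi_ct', 'phi_sc'}
    p_values: dict  # same keys, permutation p-values (absent if n_perm == 0)
    n_samples: int
    grouped: bool


def sample_distance_matrix(
    sample_to_hap: dict[str, str], hap_dists: DistanceMatrix, sample_ids: list[str]
) -> np.ndarray:
    """Expand haplotype distances to a sample-level matrix of steps."""
    idx = {h: i for i, h in enumerate(hap_dists.labels)}
    rows = [idx[sample_to_hap[s]] for s in sample_ids]
    return hap_dists.values[np.ix_(rows, rows)]


def _ssd(delta2: np.ndarray, members: list[np.ndarray]) -> float:
    """Sum over strata of (1/n_s) * sum_{i<j in s} delta^2_ij."""
    total = 0.0
    for m in members:
        if m.size < 2:
            continue
        sub = delta2[np.ix_(m, m)]
        total += sub[np.triu_indices(m.size, 1)].sum() / m.size
    return total


def _components(
    delta2: np.ndarray, pop_idx: np.ndarray, grp_idx: np.ndarray | None
) -> dict:
    """Variance components from the squared-distance decomposition."""
    N = delta2.shape[0]
    pops = np.unique(pop_idx)
    pop_members = [np.flatnonzero(pop_idx == p) for p in pops]
    n_k = np.array([m.size for m in pop_members], dtype=float)
    Pn = len(pops)

    ssd_total = _ssd(delta2, [np.arange(N)])
    ssd_wp = _ssd(delta2, pop_members)

    if grp_idx is None:
        ssd_ap = ssd_total - ssd_wp
        df_ap, df_wp = Pn - 1, N - Pn
        ms_ap = ssd_ap / df_ap
        ms_wp = ssd_wp / df_wp if df_wp else 0.0
        n_prime = (N - (n_k**2).sum() / N) / (Pn - 1)
        sigma_c = ms_wp
        sigma_a = (ms_ap - ms_wp) / n_prime
        return {
            "rows": [
                ("Among populations", df_ap, ssd_ap, sigma_a),
                ("Within populations", df_wp, ssd_wp, sigma_c),
            ],
            "sigma": (sigma_a, None, sigma_c),
        }

    groups = np.unique(grp_idx)
    G = len(groups)
    grp_members = [np.flatnonzero(grp_idx == g) for g in groups]
    N_g = np.array([m.size for m in grp_members], dtype=float)
    ssd_wg = _ssd(delta2, grp_members)
    ssd_ag = ssd_total - ssd_wg
    ssd_ap_wg = ssd_wg - ssd_wp
    df_ag, df_ap, df_wp = G - 1, Pn - G, N - Pn
    ms_ag = ssd_ag / df_ag
    ms_ap = ssd_ap_wg / df_ap if df_ap else 0.0
    ms_wp = ssd_wp / df_wp if df_wp else 0.0

    # group of each population
    pop_group = np.array([grp_idx[pop_idx == p][0] for p in pops])
    S_g = np.array(
        [
            (n_k[pop_group == g] ** 2).sum() / N_g[gi]
            for gi, g in enumerate(groups)
        ]
    )
    n1 = (N - S_g.sum()) / (Pn - G) if Pn > G else 0.0
    n2 = (S_g.sum() - (n_k**2).sum() / N) / (G - 1)
    n3 = (N - (N_g**2).sum() / N) / (G - 1)

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1 if n1 else 0.0
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return {
        "rows": [
            ("Among groups", df_ag, ssd_ag, sigma_a),
            ("Among populations within groups", df_ap, ssd_ap_wg, sigma_b),
            ("Within populations", df_wp, ssd_wp, sigma_c),
        ],
        "sigma": (sigma_a, sigma_b, sigma_c),
    }


def _phi(sigma: tuple, grouped: bool) -> dict:
    a, b, c = sigma
    if not grouped:
        tot = a + c
        return {"phi_st": a / tot if tot else float("nan")}
    tot = a + b + c
    return {
        "phi_ct": a / tot if tot else float("nan"),
        "phi_sc": b / (b + c) if (b + c) else float("nan"),
        "phi_st": (a + b) / tot if tot else float("nan"),
    }


def amova(
    sample_dists: np.ndarray,
    populations: list[str],
    groups: list[str] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    squared: bool = True,
) -> AmovaResult:
    """Analysis of molecular variance on inter-sample distances.

    ``sample_dists[i, j]`` is the number of mutational steps between samples i
    and j; by default the decomposition uses squared distances (Excoffier's
    delta^2); ``squared=False`` uses the raw steps as delta^2 for sensitivity
    analysis. ``populations`` (and optionally ``groups``) give the stratum of
    each sample, aligned with the matrix rows.

    Permutation schemes: Phi_st permutes samples among populations; Phi_sc
    permutes samples among populations within their group; Phi_ct permutes
    whole populations among groups. Negative variance components are reported
    as computed.
    """
    d = np.asarray(sample_dists, dtype=float)
    N = d.shape[0]
    if N < 3:
        raise SpecError("AMOVA needs >= 3 samples")
    if len(populations) != N or (groups is not None and len(groups) != N):
        raise SpecError("stratum labels must align with the distance matrix")
    delta2 = d**2 if squared else d.copy()

    pop_names, pop_idx = np.unique(populations, return_inverse=True)
    if groups is not None:
        grp_names, grp_idx = np.unique(groups, return_inverse=True)
        # a population must sit in exactly one group
        for p in range(len(pop_names)):
            if len(np.unique(grp_idx[pop_idx == p])) != 1:
                raise SpecError(f"population {pop_names[p]} spans multiple groups")
        if len(grp_names) < 2:
            grp_idx = None  # degenerate: falls back to one-level design
    else:
        grp_idx = None
    grouped = grp_idx is not None

    res = _components(delta2, pop_idx, grp_idx)
    sigma = res["sigma"]
    phi = _phi(sigma, grouped)

    comps = [s for s in sigma if s is not None]
    tot = sum(comps)
    rows = []
    for name, df, ss, comp in res["rows"]:
        pct = comp / tot * 100 if tot else float("nan")
        rows.append((name, df, ss, comp, pct))
    rows.append(("Total", sum(r[1] for r in res["rows"]), sum(r[2] for r in res["rows"]), tot, float("nan")))
    table = pd.DataFrame(
        rows, columns=["source", "df", "SS", "variance_component", "pct_variation"]
    )

    p_values: dict = {}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        p_values = _amova_permutations(delta2, pop_idx, grp_idx, phi, n_perm, rng)

    return AmovaResult(table, phi, p_values, N, grouped)


def _amova_permutations(delta2, pop_idx, grp_idx, phi_obs, n_perm, rng) -> dict:
    N = delta2.shape[0]
    grouped = grp_idx is not None
    hits = {k: 0 for k in phi_obs}

    def stat(pi, gi):
        res = _components(delta2, pi, gi)
        return _phi(res["sigma"], grouped)

    for _ in range(n_perm):
        # Phi_st: samples among populations (labels shuffled over all samples)
        perm = rng.permutation(N)
        ph = stat(pop_idx[perm], grp_idx[perm] if grouped else None)
        if ph["phi_st"] >= phi_obs["phi_st"] - 1e-12:
            hits["phi_st"] += 1
        if grouped:
            # Phi_sc: samples among populations within groups
            pi = pop_idx.copy()
            for g in np.unique(grp_idx):
                m = np.flatnonzero(grp_idx == g)
                pi[m] = pi[m[rng.permutation(m.size)]]
            ph = stat(pi, grp_idx)
            if ph["phi_sc"] >= phi_obs["phi_sc"] - 1e-12:
                hits["phi_sc"] += 1
            # Phi_ct: whole populations among groups
            pops = np.unique(pop_idx)
            pop_grp = np.array([grp_idx[pop_idx == p][0] for p in pops])
            shuffled = pop_grp[rng.permutation(pop_grp.size)]
            gi = shuffled[np.searchsorted(pops, pop_idx)]
            if len(np.unique(gi)) > 1:
                ph = stat(pop_idx, gi)
                if ph["phi_ct"] >= phi_obs["phi_ct"] - 1e-12:
                    hits["phi_ct"] += 1
    p = {k: (1 + h) / (n_perm + 1) for k, h in hits.items()}
    return {k: v for k, v in p.items() if k in phi_obs and not np.isnan(phi_obs[k])}
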