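"""Model-based clustering of haploid multilocus cpSSR genotypes.

A STRUCTURE-style admixture model for haploid data: each sample i carries an
admixture vector Q_i over K clusters, each cluster k has per-locus allele
frequencies P_{kl}. The latent origin z_il of the allele at locus l is drawn
from Q_i and the allele from P_{z,l}. Inference is by Gibbs sampling with
conjugate Dirichlet updates (independent allele-frequency prior, Dirichlet
lambda per locus; admixture prior Dirichlet alpha0, fixed). The model
log-probability estimate lnPD = mean(lnL) - var(lnL)/2 over post-burn-in
sweeps feeds the Evanno delta-K statistic for choosing K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "GenotypeMatrix",
    "ClusterResult",
    "fit_admixture",
    "evanno_delta_k",
    "align_cluster_labels",
    "read_genotype_tsv",
]

MISSING_CODE = -9


@dataclass
class GenotypeMatrix:
    """Haploid samples x loci allele-code table (missing = -9)."""

    sample_ids: list[str]
    locus_names: list[str]
    alleles: np.ndarray  # int matrix, raw allele codes
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.alleles, dtype=int)
        if a.shape != (len(self.sample_ids), len(self.locus_names)):
            raise ValueError("allele matrix shape mismatch")
        self.alleles = a

    def encoded(self) -> tuple[np.ndarray, list[np.ndarray]]:
        """Locus-local 0-based codes (missing = -1) and allele inventories."""
        X = np.full(self.alleles.shape, -1, dtype=int)
        inventories = []
        for l in range(self.alleles.shape[1]):
            col = self.alleles[:, l]
            obs = np.unique(col[col != MISSING_CODE])
            inventories.append(obs)
            lookup = {int(v): i for i, v in enumerate(obs)}
            for i, v in enumerate(col):
                if v != MISSING_CODE:
                    X[i, l] = lookup[int(v)]
        return X, inventories


@dataclass
class ClusterResult:
    K: int
    Q: np.ndarray  # samples x K, rows sum to 1
    P: list[np.ndarray]  # per locus: K x n_alleles, rows sum to 1
    lnpd: float
    trace: np.ndarray  # post-burn-in per-sweep log-likelihoods
    seed: int | None
    sample_ids: list[str] = field(default_factory=list)
    model: str = "admixture, independent allele frequencies, haploid"

    def q_frame(self) -> pd.DataFrame:
        cols = [f"Q{k + 1}" for k in range(self.K)]
        idx = self.sample_ids or list(range(self.Q.shape[0]))
        return pd.DataFrame(self.Q, index=idx, columns=cols)


def _categorical_rows(prob: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one category per row of a (rows x K) probability matrix."""
    cum = prob.cumsum(axis=1)
    cum /= cum[:, -1:]
    u = rng.random((prob.shape[0], 1))
    return (u > cum).sum(axis=1)


def fit_admixture(
    g: GenotypeMatrix,
    K: int,
    burnin: int = 5_000,
    iters: int = 20_000,
    alpha0: float = 0.1,
    lam: float = 1.0,
    seed: int | None = None,
) -> ClusterResult:
    """Gibbs sampler for the haploid admixture model.

    ``iters`` counts post-burn-in sweeps. Posterior means of Q and P are
    averaged over post-burn-in sweeps; the returned ``lnpd`` is the
    mean-minus-half-variance estimator of ln P(D) used for model choice.

    ``alpha0`` is the fixed symmetric Dirichlet admixture prior. With haploid
    data each sample contributes only one allele draw per locus, so the prior
    competes directly with at most L observations: the posterior mean of a
    pure sample's home proportion is bounded by (alpha0 + L)/(K*alpha0 + L).
    The weak default 0.1 lets few-locus cpSSR panels express near-pure
    membership; alpha0 = 1 would cap it near 0.92 for K = 2, L = 10.
    Empty loci (all missing) are dropped with a warning. Deterministic for a
    fixed seed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    if K > len(g.sample_ids):
        raise ValueError(f"K={K} exceeds the number of samples ({len(g.sample_ids)})")
    X, inventories = g.encoded()
    keep = [l for l in range(X.shape[1]) if (X[:, l] >= 0).any()]
    if len(keep) < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - len(keep)} loci with no observed alleles",
            stacklevel=2,
        )
    X = X[:, keep]
    inventories = [inventories[l] for l in keep]
    N, L = X.shape
    if L < 1:
        raise ValueError("no loci with observed alleles")
    n_alleles = [len(inv) for inv in inventories]
    obs = X >= 0
    Xc = np.where(obs, X, 0)

    rng = np.random.default_rng(seed)
    z = rng.integers(0, K, size=(N, L))

    Q_sum = np.zeros((N, K))
    P_sum = [np.zeros((K, A)) for A in n_alleles]
    lnls = np.empty(iters)

    rows = np.arange(N)[:, None]
    for sweep in range(burnin + iters):
        # P | z : Dirichlet(lam + counts)
        P = []
        for l in range(L):
            counts = np.zeros((K, n_alleles[l]))
            m = obs[:, l]
            np.add.at(counts, (z[m, l], X[m, l]), 1.0)
            draws = rng.gamma(lam + counts)
            P.append(draws / draws.sum(axis=1, keepdims=True))
        # Q | z : Dirichlet(alpha0 + per-sample origin counts)
        occ = np.zeros((N, K))
        np.add.at(occ, (np.repeat(np.arange(N), L)[obs.ravel()], z[obs]), 1.0)
        qd = rng.gamma(alpha0 + occ)
        Q = qd / qd.sum(axis=1, keepdims=True)
        # z | P, Q : categorical proportional to q_ik * p_{k,l,x_il}
        lnl = 0.0
        for l in range(L):
            like = Q * P[l][:, Xc[:, l]].T  # N x K
            m = obs[:, l]
            z[m, l] = _categorical_rows(like[m], rng)
            tot = like[m].sum(axis=1)
            lnl += float(np.log(tot).sum())
        if sweep >= burnin:
            t = sweep - burnin
            Q_sum += Q
            for l in range(L):
                P_sum[l] += P[l]
            lnls[t] = lnl

    Q_mean = Q_sum / iters
    P_mean = [ps / iters for ps in P_sum]
    lnpd = float(lnls.mean() - lnls.var() / 2.0)
    return ClusterResult(
        K=K,
        Q=Q_mean,
        P=P_mean,
        lnpd=lnpd,
        trace=lnls,
        seed=seed,
        sample_ids=list(g.sample_ids),
    )


def evanno_delta_k(lnpd_runs: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno delta-K table from per-K replicate lnPD values.

    ``deltaK(K) = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K))`` with L(K) the mean
    over runs and sd the sample standard deviation. Defined only for interior
    K with sd > 0; elsewhere NaN. Requires >= 3 consecutive K values and >= 2
    runs per K.
    """
    ks = sorted(lnpd_runs)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    for k in ks:
        if len(lnpd_runs[k]) < 2:
            raise ValueError(f"K={k}: need >= 2 runs for a standard deviation")
    mean = {k: float(np.mean(lnpd_runs[k])) for k in ks}
    sd = {k: float(np.std(lnpd_runs[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1] or sd[k] == 0:
            dk = float("nan")
        else:
            dk = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
        rows.append((k, len(lnpd_runs[k]), mean[k], sd[k], dk))
    df = pd.DataFrame(rows, columns=["K", "runs", "mean_lnpd", "sd_lnpd", "delta_k"])
    return df


def best_k(delta_table: pd.DataFrame) -> int:
    """K maximizing delta-K (NaN rows ignored)."""
    valid = delta_table.dropna(subset=["delta_k"])
    if valid.empty:
        raise ValueError("delta-K undefined for every K")
    return int(valid.loc[valid["delta_k"].idxmax(), "K"])


def align_cluster_labels(results: list[ClusterResult]) -> list[ClusterResult]:
    """Resolve label switching across runs by matching Q columns to run 1.

    Columns are matched by minimum-cost assignment on summed absolute Q
    differences against the first run; the permutation is applied to Q and P.
    """
    if not results:
        return []
    K = results[0].K
    if any(r.K != K for r in results):
        raise ValueError("all runs must share K")
    ref = results[0].Q
    out = [results[0]]
    for r in results[1:]:
        cost = np.zeros((K, K))
        for a in range(K):
            for b in range(K):
                cost[a, b] = np.abs(ref[:, a] - r.Q[:, b]).sum()
        _, perm = linear_sum_assignment(cost)
        out.append(
            ClusterResult(
                K=K,
                Q=r.Q[:, perm],
                P=[p[perm, :] for p in r.P],
                lnpd=r.lnpd,
                trace=r.trace,
                seed=r.seed,
                sample_ids=r.sample_ids,
            )
        )
    return out


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read a STRUCTURE-convention haploid genotype TSV.

    Columns: ``sample_id``, ``population``, then one integer column per locus;
    missing alleles coded -9.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    loci = [c for c in df.columns if c not in ("sample_id", "population")]
    return GenotypeMatrix(
        sample_ids=df["sample_id"].tolist(),
        locus_names=loci,
        alleles=df[loci].to_numpy(dtype=int),
        populations=df["population"].tolist() if "population" in df.columns else None,
    )
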