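"""Admixture-model population structure via Gibbs sampling, with Evanno
ΔK model selection and Q-threshold summaries.

The model: each of K clusters has its own allele-frequency vector per
locus (uncorrelated across clusters, symmetric Dirichlet(λ) prior), and
each individual i has admixture proportions q_i (Dirichlet(α) prior).
Every allele copy carries a latent cluster assignment z.  The sampler
iterates

1. z | p, q — each copy assigned to cluster k with probability
   ∝ q_ik · p_k(allele);
2. p | z   — per cluster and locus, Dirichlet(λ + assignment counts);
3. q | z   — per individual, Dirichlet(α + per-sample counts);

missing loci contribute nothing.  The marginal data likelihood is
estimated from the post-burn-in trace of ln L = Σ log Σ_k q_ik p_k(a) as
``mean(lnL) − var(lnL)/2`` (the harmonic-style estimator STRUCTURE
reports as ln P(D)).

ΔK (Evanno) is the second difference of the mean ln P(D) across K,
normalised by the between-replicate standard deviation:
``ΔK = |L(K+1) − 2·L(K) + L(K−1)| / sd(L(K))``; its peak estimates the
number of subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genotypes import GenotypeMatrix

__all__ = [
    "GibbsAdmixture",
    "RunSet",
    "gibbs_admixture",
    "delta_k",
    "q_threshold_summary",
    "align_q",
]


def _as_allele_array(X) -> np.ndarray:
    """Coerce to an (n, L, 2) int array with 0 = missing."""
    if isinstance(X, GenotypeMatrix):
        return X.calls
    A = np.asarray(X)
    if A.ndim == 2:  # (n, 2L) layout: locus-major column pairs
        if A.shape[1] % 2:
            raise ValueError("expected an even number of allele columns")
        A = A.reshape(A.shape[0], A.shape[1] // 2, 2)
    if A.ndim != 3 or A.shape[2] != 2:
        raise ValueError("expected (n, loci, 2) allele sizes")
    return A.astype(np.int64)


class GibbsAdmixture(BaseEstimator):
    """STRUCTURE-style admixture model fitted by Gibbs sampling.

    Parameters
    ----------
    n_clusters : int
        Number of ancestral clusters K (K=1 is allowed and trivial).
    n_sweeps : int
        Total MCMC sweeps.
    burn_in : int or None
        Sweeps discarded before accumulating estimates; default 10 % of
        ``n_sweeps``.
    lam : float
        Symmetric Dirichlet prior on cluster allele frequencies.
    alpha : float
        Symmetric Dirichlet prior on individual admixture proportions.
    update_alpha : bool
        If True, α is given a Metropolis update (uniform proposal,
        sd 0.025) instead of staying fixed.
    random_state : int or None
        Seed; a fixed seed gives bit-identical results.

    Attributes
    ----------
    Q_ : ndarray of shape (n_samples, K)
        Posterior-mean admixture proportions (rows sum to 1).
    log_prob_ : float
        Estimated ln P(D) (model-selection score used by ΔK).
    loglik_trace_ : ndarray
        ln L at every post-burn-in sweep.
    alpha_ : float
        Final α (equals ``alpha`` unless ``update_alpha``).
    """

    def __init__(
        self,
        n_clusters: int = 2,
        n_sweeps: int = 2000,
        burn_in: int | None = None,
        lam: float = 1.0,
        alpha: float = 1.0,
        update_alpha: bool = False,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.n_sweeps = n_sweeps
        self.burn_in = burn_in
        self.lam = lam
        self.alpha = alpha
        self.update_alpha = update_alpha
        self.random_state = random_state

    def fit(self, X, y=None):
        calls = _as_allele_array(X)
        K = int(self.n_clusters)
        if K < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.lam <= 0 or self.alpha <= 0:
            raise ValueError("lam and alpha must be positive")
        burn = (
            int(round(0.1 * self.n_sweeps))
            if self.burn_in is None
            else int(self.burn_in)
        )
        if not 0 <= burn < self.n_sweeps:
            raise ValueError("burn_in must lie in [0, n_sweeps)")
        rng = np.random.default_rng(self.random_state)
        n, L, _ = calls.shape
        if np.any((calls[:, :, 0] == 0).all(axis=1)):
            raise ValueError("every sample needs at least one scored locus")

        # per-locus allele index maps; obs[l] is (m_l,) allele idx for the
        # flattened copies of the samples scored at locus l
        obs_idx: list[np.ndarray] = []
        obs_samples: list[np.ndarray] = []
        n_alleles: list[int] = []
        for l in range(L):
            scored = calls[:, l, 0] != 0
            sizes = np.unique(calls[scored, l, :])
            lookup = {s: i for i, s in enumerate(sizes.tolist())}
            samp = np.repeat(np.flatnonzero(scored), 2)
            flat = calls[scored, l, :].reshape(-1)
            obs_idx.append(np.array([lookup[s] for s in flat.tolist()]))
            obs_samples.append(samp)
            n_alleles.append(max(len(sizes), 1))

        alpha = float(self.alpha)
        z = [rng.integers(0, K, size=len(o)) for o in obs_idx]
        q = np.full((n, K), 1.0 / K)
        lnl_trace = np.empty(self.n_sweeps - burn)
        q_sum = np.zeros((n, K))
        alpha_trace = []

        for sweep in range(self.n_sweeps):
            # p | z
            p = []
            for l in range(L):
                counts = np.zeros((K, n_alleles[l]))
                np.add.at(counts, (z[l], obs_idx[l]), 1.0)
                pk = rng.gamma(self.lam + counts)
                pk /= pk.sum(axis=1, keepdims=True)
                p.append(pk)
            # q | z
            qc = np.zeros((n, K))
            for l in range(L):
                np.add.at(qc, (obs_samples[l], z[l]), 1.0)
            q = rng.gamma(alpha + qc)
            q /= q.sum(axis=1, keepdims=True)
            # z | p, q  (vectorised per locus)
            lnl = 0.0
            for l in range(L):
                w = q[obs_samples[l], :] * p[l][:, obs_idx[l]].T
                tot = w.sum(axis=1, keepdims=True)
                lnl += float(np.log(tot).sum())
                u = rng.random((len(obs_idx[l]), 1)) * tot
                z[l] = (w.cumsum(axis=1) < u).sum(axis=1)
            if self.update_alpha and K > 1:
                alpha = self._alpha_step(alpha, q, rng)
            if sweep >= burn:
                lnl_trace[sweep - burn] = lnl
                q_sum += q
                alpha_trace.append(alpha)

        self.Q_ = q_sum / (self.n_sweeps - burn)
        self.Q_ /= self.Q_.sum(axis=1, keepdims=True)
        self.loglik_trace_ = lnl_trace
        self.log_prob_ = float(lnl_trace.mean() - lnl_trace.var() / 2.0)
        self.alpha_ = alpha
        self.n_features_in_ = L * 2
        return self

    @staticmethod
    def _alpha_step(alpha: float, q: np.ndarray, rng) -> float:
        from scipy.special import gammaln

        prop = alpha + rng.normal(0.0, 0.025)
        if prop <= 0 or prop > 10.0:
            return alpha
        n, K = q.shape

        def lp(a: float) -> float:
            return n * (gammaln(K * a) - K * gammaln(a)) + (
                (a - 1.0) * np.log(q).sum()
            )

        if np.log(rng.random()) < lp(prop) - lp(alpha):
            return prop
        return alpha

    def fit_predict(self, X, y=None):
        self.fit(X)
        return self.Q_.argmax(axis=1)


def gibbs_admixture(
    matrix: GenotypeMatrix | np.ndarray,
    n_clusters: int,
    n_sweeps: int = 2000,
    burn_in: int | None = None,
    lam: float = 1.0,
    alpha: float = 1.0,
    update_alpha: bool = False,
    seed: int | None = None,
) -> tuple[np.ndarray, float]:
    """Functional wrapper: returns ``(Q, ln P(D))``."""
    est = GibbsAdmixture(
        n_clusters=n_clusters,
        n_sweeps=n_sweeps,
        burn_in=burn_in,
        lam=lam,
        alpha=alpha,
        update_alpha=update_alpha,
        random_state=seed,
    ).fit(matrix)
    return est.Q_, est.log_prob_


@dataclass(frozen=True)
class RunSet:
    """ln P(D) estimates for replicate runs over a contiguous K range."""

    log_probs: dict[int, tuple[float, ...]]

    def __post_init__(self) -> None:
        ks = sorted(self.log_probs)
        if ks != list(range(ks[0], ks[-1] + 1)):
            raise ValueError("K values must form a contiguous range")
        if len(ks) < 3:
            raise ValueError("need a K range of length >= 3")
        if any(len(v) < 2 for v in self.log_probs.values()):
            raise ValueError("need >= 2 replicates per K")

    @property
    def k_values(self) -> list[int]:
        return sorted(self.log_probs)


def delta_k(runs: RunSet | dict[int, tuple[float, ...]]) -> pd.DataFrame:
    """Evanno ΔK table.

    Returns a DataFrame indexed by K with columns ``mean_lnp``,
    ``sd_lnp`` and ``delta_k`` (NaN at the boundary K values and where
    the replicate sd is zero).  ``df.attrs["best_k"]`` holds the argmax,
    ties broken toward smaller K.
    """
    if not isinstance(runs, RunSet):
        runs = RunSet({k: tuple(v) for k, v in runs.items()})
    ks = runs.k_values
    mean = {k: float(np.mean(runs.log_probs[k])) for k in ks}
    sd = {k: float(np.std(runs.log_probs[k], ddof=1)) for k in ks}
    dk: dict[int, float] = {}
    for k in ks[1:-1]:
        if sd[k] == 0.0:
            dk[k] = np.nan
        else:
            dk[k] = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
    df = pd.DataFrame(
        {
            "mean_lnp": [mean[k] for k in ks],
            "sd_lnp": [sd[k] for k in ks],
            "delta_k": [dk.get(k, np.nan) for k in ks],
        },
        index=pd.Index(ks, name="K"),
    )
    finite = df["delta_k"].dropna()
    df.attrs["best_k"] = int(finite.idxmax()) if len(finite) else None
    return df


def align_q(q: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Permute the columns of ``q`` to best match ``reference``.

    Admixture clusters are identifiable only up to relabelling; this
    resolves label switching by minimising mean |q − reference| over all
    column permutations (exact, via the Hungarian assignment).
    """
    from scipy.optimize import linear_sum_assignment

    q = np.asarray(q, float)
    ref = np.asarray(reference, float)
    cost = np.abs(q[:, :, None] - ref[:, None, :]).mean(axis=0)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty_like(rows)
    perm[cols] = rows
    return q[:, perm]


def q_threshold_summary(
    q: np.ndarray,
    groups: list[str] | np.ndarray,
    thresholds: tuple[float, ...] = (0.6, 0.8, 0.9),
) -> pd.DataFrame:
    """Count samples per group by their maximum admixture proportion.

    For each group: how many samples have max-Q below the first
    threshold, and how many meet each threshold (columns ``Q<t0`` and
    ``Q>=t`` for every t).  A ``Total`` row sums the groups.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    q = np.asarray(q, float)
    groups = np.asarray(groups)
    qmax = q.max(axis=1)
    labels = list(dict.fromkeys(groups.tolist()))
    t0 = thresholds[0]
    cols = [f"Q<{t0:g}"] + [f"Q>={t:g}" for t in thresholds]
    rows = {}
    for g in labels:
        m = qmax[groups == g]
        rows[g] = [int((m < t0).sum())] + [
            int((m >= t).sum()) for t in thresholds
        ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.insert(0, "n", [int((groups == g).sum()) for g in labels])
    df.loc["Total"] = df.sum(axis=0)
    df.index.name = "group"
    return df
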