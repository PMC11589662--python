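"""Admixture estimation and gene-flow summary statistics.

Cluster-assignment (Q) matrices are estimated from biallelic genotypes by
maximum-likelihood EM under the standard K-population admixture model: the
alternate-allele count of individual *i* at site *j* is Binomial(2, f_ij)
with f_ij = sum_k q_ik p_kj, where q_i are the individual's ancestry
proportions and p_k the cluster allele frequencies. Externally produced
Q-matrices (e.g. from a Bayesian clustering program) can be substituted via
:func:`pairflow.io.read_qmatrix`; every statistic below is a function of Q
only.

Gene flow between a pair of lineages is summarised two ways:

* **mean admixture frequency** -- the average, over all individuals of both
  lineages, of the assignment probability to the cluster representing the
  *other* lineage, reported as a percentage;
* **proportion admixed** -- the fraction of individuals with any nonzero
  other-lineage assignment at reporting precision (3 decimals by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "QMatrix",
    "CladeClusterMap",
    "GeneFlowEstimate",
    "MappingError",
    "fit_admixture",
    "choose_k",
    "map_clusters_to_clades",
    "mean_admixture_frequency",
    "proportion_admixed",
    "estimate_gene_flow",
    "delimit_by_assignment",
    "align_q_columns",
]

_P_EPS = 1e-6  # allele-frequency clamp


class MappingError(ValueError):
    """Clustering is uninformative about the clades (e.g. two clades map
    to the same cluster)."""


@dataclass
class QMatrix:
    """Individuals x clusters assignment-probability matrix."""

    samples: list[str]
    q: np.ndarray
    loglik: float | None = None
    n_iter: int | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.samples):
            raise ValueError("q must be n_samples x K")
        self.validate()

    @property
    def n_clusters(self) -> int:
        return self.q.shape[1]

    def validate(self, tol: float = 1e-9) -> None:
        if np.any(self.q < -tol) or np.any(self.q > 1 + tol):
            raise ValueError("assignment probabilities outside [0, 1]")
        if np.any(np.abs(self.q.sum(axis=1) - 1.0) > tol):
            raise ValueError("Q rows must sum to 1")

    def row(self, sample: str) -> np.ndarray:
        return self.q[self.samples.index(sample)]


@dataclass
class CladeClusterMap:
    """Injective mapping clade label -> cluster index, plus any clusters
    left unassociated (the K > number-of-clades case)."""

    mapping: dict
    unmapped: list[int] = field(default_factory=list)

    def other_cluster(self, clade) -> int:
        """Cluster mapped to the clade *other* than ``clade`` (two-clade use)."""
        others = [c for k, c in self.mapping.items() if k != clade]
        if len(others) != 1:
            raise MappingError("other_cluster requires exactly two mapped clades")
        return others[0]


@dataclass
class GeneFlowEstimate:
    pair_id: object
    mean_admixture_freq: float  # percent, 0-100
    prop_admixed: float  # proportion, 0-1
    n_individuals: int


def _em_once(G, K, rng, max_iter, tol):
    """One EM run from a random start. G is n x J float with NaN missing."""
    n, J = G.shape
    obs = ~np.isnan(G)
    G0 = np.nan_to_num(G)
    n_called = obs.sum(axis=1).astype(float)
    if np.any(n_called == 0):
        raise ValueError("individual with no called genotypes")

    # init P around observed alt frequencies, Q from a flat Dirichlet
    with np.errstate(invalid="ignore"):
        pobs = np.nansum(G, axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1))
    P = np.clip(pobs[None, :] + rng.uniform(-0.1, 0.1, size=(K, J)), _P_EPS, 1 - _P_EPS)
    Q = rng.dirichlet(np.ones(K), size=n)

    prev_ll = -np.inf
    trace = []
    for it in range(1, max_iter + 1):
        F = np.clip(Q @ P, _P_EPS, 1 - _P_EPS)
        ll = float(np.sum((G0 * np.log(F) + (2 - G0) * np.log1p(-F))[obs]))
        trace.append(ll)
        if ll + 1e-9 < prev_ll:
            raise AssertionError("EM log-likelihood decreased")
        if it > 1 and ll - prev_ll < tol:
            prev_ll = ll
            break
        prev_ll = ll

        # responsibilities, accumulated per cluster (K is small)
        Qnew = np.empty_like(Q)
        Pnum = np.empty_like(P)
        Pden = np.empty_like(P)
        for k in range(K):
            a = Q[:, k : k + 1] * P[k][None, :] / F          # alt-allele resp.
            b = Q[:, k : k + 1] * (1 - P[k][None, :]) / (1 - F)  # ref-allele resp.
            alt = np.where(obs, G0 * a, 0.0)
            ref = np.where(obs, (2 - G0) * b, 0.0)
            Qnew[:, k] = (alt + ref).sum(axis=1) / (2.0 * n_called)
            Pnum[k] = alt.sum(axis=0)
            Pden[k] = (alt + ref).sum(axis=0)
        Q = Qnew / Qnew.sum(axis=1, keepdims=True)
        P = np.clip(Pnum / np.maximum(Pden, 1e-300), _P_EPS, 1 - _P_EPS)
    return Q, P, prev_ll, len(trace), trace


def fit_admixture(
    g,
    K: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_restarts: int = 5,
) -> QMatrix:
    """Maximum-likelihood Q-matrix for ``K`` clusters by EM.

    Runs ``n_restarts`` EM chains from seeds derived deterministically from
    ``seed`` and keeps the best log-likelihood (ties broken by lowest
    restart index). Missing genotypes contribute nothing to the likelihood.

    Parameters
    ----------
    g : GenotypeMatrix
        Filtered genotypes (see :func:`pairflow.io.filter_snps`).
    K : int
        Number of ancestral clusters, ``1 <= K <= n_samples``.
    """
    G = np.asarray(g.calls, dtype=float)
    n = G.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")
    if K == 1:
        q = np.ones((n, 1))
        return QMatrix(list(g.samples), q)

    seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        Q, P, ll, n_iter, _ = _em_once(G, K, rng, max_iter, tol)
        if best is None or ll > best[0] + 1e-12:
            best = (ll, r, Q, n_iter)
    ll, _, Q, n_iter = best
    return QMatrix(list(g.samples), Q, loglik=ll, n_iter=n_iter)


def choose_k(g, k_max: int, n_pcs: int = 10, seed: int = 0) -> int:
    """Pick the number of clusters by k-means BIC on leading genotype PCs.

    Mirrors the common ordination-based model selection for RADseq data:
    mean-impute, PCA, run k-means for k = 1..k_max and return the k
    minimising ``n*log(WSS/n) + k*log(n)``.
    """
    from sklearn.cluster import KMeans

    from .divergence import genotype_pca

    n = len(g.samples)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds the number of samples ({n})")
    model = genotype_pca(g)
    scores = model.scores[:, : min(n_pcs, model.scores.shape[1])]
    bics = []
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scores)
        wss = max(km.inertia_, 1e-12)
        bics.append(n * np.log(wss / n) + k * np.log(n))
    return int(np.argmin(bics)) + 1


def _clades_series(meta, samples):
    meta = meta.set_index("sample") if "sample" in getattr(meta, "columns", []) else meta
    try:
        return meta.loc[samples, "clade"]
    except KeyError as exc:
        raise KeyError(f"sample metadata missing entries: {exc}") from exc


def map_clusters_to_clades(q: QMatrix, meta, assign_threshold: float = 0.999) -> CladeClusterMap:
    """Associate each clade with one cluster.

    A clade maps to the cluster of its confidently assigned individuals
    (max assignment probability >= ``assign_threshold``, the operational
    reading of "100% assignment"); if no individual passes, to the cluster
    with the highest clade-mean assignment. With K greater than the number
    of clades, leftover clusters are reported as unmapped. Two clades
    resolving to the same cluster raises :class:`MappingError`.
    """
    clades = _clades_series(meta, q.samples)
    mapping = {}
    for clade in pd.unique(clades):
        rows = q.q[np.asarray(clades == clade)]
        confident = rows[rows.max(axis=1) >= assign_threshold]
        if len(confident):
            counts = np.bincount(confident.argmax(axis=1), minlength=q.n_clusters)
            mapping[clade] = int(counts.argmax())
        else:
            mapping[clade] = int(rows.mean(axis=0).argmax())
    if len(set(mapping.values())) < len(mapping):
        raise MappingError(f"clades map to the same cluster: {mapping}")
    unmapped = sorted(set(range(q.n_clusters)) - set(mapping.values()))
    return CladeClusterMap(mapping, unmapped)


def _other_clade_probs(q: QMatrix, cmap: CladeClusterMap, meta, renormalize: bool):
    clades = _clades_series(meta, q.samples)
    if len(cmap.mapping) != 2:
        raise MappingError("gene-flow statistics require exactly two mapped clades")
    probs = np.empty(len(q.samples))
    for i, clade in enumerate(clades):
        own = cmap.mapping[clade]
        other = cmap.other_cluster(clade)
        p = q.q[i, other]
        if renormalize:
            denom = q.q[i, own] + q.q[i, other]
            p = p / denom if denom > 0 else 0.0
        probs[i] = p
    return probs


def mean_admixture_frequency(
    q: QMatrix, cmap: CladeClusterMap, meta, renormalize: bool = False
) -> float:
    """Mean assignment probability to the other clade's cluster, in percent.

    With K > 2 the probability mass on unmapped clusters is ignored by
    default; ``renormalize=True`` instead rescales over the two mapped
    clusters.
    """
    return float(_other_clade_probs(q, cmap, meta, renormalize).mean() * 100.0)


def proportion_admixed(
    q: QMatrix,
    cmap: CladeClusterMap,
    meta,
    zero_decimals: int = 3,
    renormalize: bool = False,
) -> float:
    """Fraction of individuals with a nonzero other-clade probability.

    "Nonzero" is judged after rounding to ``zero_decimals`` decimals,
    matching the precision at which assignment probabilities are reported.
    """
    probs = _other_clade_probs(q, cmap, meta, renormalize)
    admixed = np.round(probs, zero_decimals) > 0
    return float(admixed.mean())


def estimate_gene_flow(
    q: QMatrix, meta, pair_id=None, assign_threshold: float = 0.999, **kwargs
) -> GeneFlowEstimate:
    """Convenience wrapper: map clusters to clades and compute both gene-flow
    statistics for a two-clade comparison."""
    cmap = map_clusters_to_clades(q, meta, assign_threshold)
    return GeneFlowEstimate(
        pair_id=pair_id,
        mean_admixture_freq=mean_admixture_frequency(q, cmap, meta, **kwargs),
        prop_admixed=proportion_admixed(q, cmap, meta, **kwargs),
        n_individuals=len(q.samples),
    )


def delimit_by_assignment(q: QMatrix, meta, clade_set, prob_threshold: float = 0.90) -> bool:
    """Assignment arm of the dual-criterion species delimitation.

    A candidate species (a set of clade labels) passes iff every one of its
    individuals is assigned with probability > ``prob_threshold`` to one
    common cluster, and that cluster is not the majority cluster of any
    individual outside the set.
    """
    clades = _clades_series(meta, q.samples)
    inside = np.asarray(clades.isin(list(clade_set)))
    if not inside.any():
        raise ValueError("clade_set matches no samples")
    qin = q.q[inside]
    winners = qin.argmax(axis=1)
    if len(set(winners.tolist())) != 1:
        return False
    c = winners[0]
    if not np.all(qin[:, c] > prob_threshold):
        return False
    qout = q.q[~inside]
    if len(qout) and np.any(qout.argmax(axis=1) == c):
        return False
    return True


def align_q_columns(q_est: np.ndarray, q_true: np.ndarray) -> np.ndarray:
    """Permute the columns of ``q_est`` to best match ``q_true``.

    Cluster labels are arbitrary under the likelihood; alignment minimises
    the summed absolute difference over column permutations (Hungarian
    assignment on the column-distance matrix).
    """
    from scipy.optimize import linear_sum_assignment

    K = q_true.shape[1]
    cost = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = np.abs(q_est[:, j] - q_true[:, i]).sum()
    _, perm = linear_sum_assignment(cost)
    return q_est[:, perm]
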