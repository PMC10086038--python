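"""Group-level inference on residual planar gradients.

Spatiotemporal cluster-based permutation testing of the participant-level
median residuals against zero: pointwise one-sample t-tests are thresholded
at the two-tailed parametric critical value, supra-threshold points are
grouped into clusters under spatial (sensor-neighbourhood) x temporal
(consecutive-sample) adjacency separately for positive and negative
deviations, cluster mass is the summed t-value, and the family-wise null is
the distribution of the maximum |mass| over random (or exhaustive) sign
flips of participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2_contingency
from scipy.stats import t as t_dist

from .layout import SensorLayout

__all__ = [
    "AdjacencyGraph",
    "Cluster",
    "ClusterStats",
    "cluster_onesample_test",
    "duration_mask",
    "lateralization_timecourse",
    "paired_hemisphere_ttest",
    "proportion_tests",
]


@dataclass
class AdjacencyGraph:
    """Symmetric site-adjacency relation (no self-edges)."""

    matrix: np.ndarray  # (n_sites, n_sites) bool

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=bool)
        if not (m == m.T).all():
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(m, False)
        self.matrix = m

    @classmethod
    def from_layout(cls, layout: SensorLayout) -> "AdjacencyGraph":
        return cls(layout.adjacency())

    @classmethod
    def chain(cls, n: int = 1) -> "AdjacencyGraph":
        """Trivial graph for time-only clustering (n isolated sites)."""
        return cls(np.zeros((n, n), dtype=bool))

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]


@dataclass
class Cluster:
    sites: np.ndarray      # flat arrays of member (site, sample) pairs
    samples: np.ndarray
    mass: float            # summed t-values (signed)
    p: float


@dataclass
class ClusterStats:
    clusters: list
    t_obs: np.ndarray           # (n_sites, n_samples)
    sig_mask: np.ndarray        # bool, union of clusters with p <= alpha
    alpha: float
    threshold: float
    n_perm: int
    seed: int
    sfreq: float | None = None
    null_max_mass: np.ndarray = field(default_factory=lambda: np.empty(0))


def _grid_adjacency(adj_sites: np.ndarray, n_time: int) -> sparse.csr_matrix:
    """Sparse adjacency over the (site, time) grid.

    Edges: temporal neighbours at the same site (consecutive samples) and
    spatially adjacent sites at the same sample.
    """
    n_sites = adj_sites.shape[0]
    n = n_sites * n_time
    rows, cols = [], []
    node = np.arange(n).reshape(n_sites, n_time)
    # temporal edges
    rows.append(node[:, :-1].ravel())
    cols.append(node[:, 1:].ravel())
    # spatial edges (upper triangle of the site graph)
    si, sj = np.nonzero(np.triu(adj_sites, 1))
    if si.size:
        rows.append((node[si, :]).ravel())
        cols.append((node[sj, :]).ravel())
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    m = sparse.coo_matrix((np.ones(len(r), dtype=np.int8), (r, c)), shape=(n, n))
    return (m + m.T).tocsr()


def _t_map(data: np.ndarray, signs: np.ndarray | None = None) -> np.ndarray:
    """One-sample t across participants, optionally under a sign flip."""
    n = data.shape[0]
    if signs is None:
        flipped = data
    else:
        flipped = data * signs[:, None, None]
    mean = flipped.mean(axis=0)
    var = flipped.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[~np.isfinite(t)] = 0.0
    return t


def _find_clusters(tmap: np.ndarray, threshold: float, grid: sparse.csr_matrix):
    """Signed supra-threshold clusters: list of (flat_node_indices, mass)."""
    out = []
    flat = tmap.ravel()
    for sign in (1.0, -1.0):
        mask = sign * flat > threshold
        nodes = np.flatnonzero(mask)
        if nodes.size == 0:
            continue
        sub = grid[nodes][:, nodes]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = nodes[labels == c]
            out.append((members, float(flat[members].sum())))
    return out


def _null_max_mass(tmap, threshold, grid) -> float:
    cl = _find_clusters(tmap, threshold, grid)
    return max((abs(m) for _, m in cl), default=0.0)


def cluster_onesample_test(residuals: np.ndarray, graph: AdjacencyGraph,
                           alpha: float = 0.05, n_perm: int = 1000,
                           seed: int = 0, threshold: float | None = None,
                           exact: bool = False, sfreq: float | None = None) -> ClusterStats:
    """Spatiotemporal cluster-permutation test of residuals against zero.

    residuals: (n_participants, n_sites, n_samples). The cluster-forming
    threshold defaults to the two-tailed parametric critical t at ``alpha``
    with df = n - 1. The null is built from random participant sign flips
    (``exact=True`` enumerates all 2^n flips); each cluster's p-value is
    (1 + #{null max-|mass| >= |mass|}) / (1 + n_perm) for the Monte-Carlo
    null, or the plain enumeration fraction for the exact null.
    """
    residuals = np.asarray(residuals, dtype=float)
    n, n_sites, n_time = residuals.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if graph.n_sites != n_sites:
        raise ValueError("adjacency graph does not cover all sites")
    if not exact and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    df = n - 1
    if threshold is None:
        threshold = float(t_dist.ppf(1.0 - alpha / 2.0, df))
    grid = _grid_adjacency(graph.matrix, n_time)
    t_obs = _t_map(residuals)
    observed = _find_clusters(t_obs, threshold, grid)

    if exact:
        all_signs = np.array(
            [[1 if (i >> b) & 1 else -1 for b in range(n)] for i in range(2**n)],
            dtype=float)
        null = np.array([_null_max_mass(_t_map(residuals, s), threshold, grid)
                         for s in all_signs])
        n_eff = len(null)
        p_of = lambda m: float((null >= abs(m) - 1e-12).sum()) / n_eff
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            s = rng.choice([-1.0, 1.0], size=n)
            null[i] = _null_max_mass(_t_map(residuals, s), threshold, grid)
        p_of = lambda m: (1.0 + float((null >= abs(m) - 1e-12).sum())) / (1.0 + n_perm)

    clusters = []
    sig = np.zeros(n_sites * n_time, dtype=bool)
    for members, mass in observed:
        p = p_of(mass)
        sites, samples = np.unravel_index(members, (n_sites, n_time))
        clusters.append(Cluster(sites=sites, samples=samples, mass=mass, p=p))
        if p <= alpha:
            sig[members] = True
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterStats(clusters=clusters, t_obs=t_obs,
                        sig_mask=sig.reshape(n_sites, n_time), alpha=alpha,
                        threshold=threshold, n_perm=(2**n if exact else n_perm),
                        seed=seed, sfreq=sfreq, null_max_mass=null)


def duration_mask(stats: ClusterStats, sfreq: float | None = None,
                  min_dur: float = 0.0125, convention: str = "span") -> np.ndarray:
    """Sites with a contiguous significant run lasting at least ``min_dur``.

    The default duration convention is the spanned interval
    (n_run - 1) / sfreq; ``convention="count"`` uses n_run / sfreq instead.
    """
    sf = sfreq if sfreq is not None else stats.sfreq
    if sf is None:
        raise ValueError("sampling rate required for the duration criterion")
    mask = stats.sig_mask
    out = np.zeros(mask.shape[0], dtype=bool)
    for s in range(mask.shape[0]):
        run = 0
        best = 0
        for v in mask[s]:
            run = run + 1 if v else 0
            best = max(best, run)
        span = (best - 1) / sf if convention == "span" else best / sf
        out[s] = best > 0 and span >= min_dur - 1e-12
    return out


def lateralization_timecourse(residuals: np.ndarray, layout: SensorLayout,
                              site_subset=None, alpha: float = 0.05,
                              n_perm: int = 1000, seed: int = 0,
                              sfreq: float | None = None):
    """Left-minus-right median residual trace per participant + time cluster test.

    ``site_subset``: optional site indices (e.g. the occipital or parietal
    group) on which to repeat the contrast. Returns (diff (n_participants,
    n_samples), ClusterStats over time only).
    """
    hemi = layout.hemisphere
    idx = np.arange(layout.n_sites) if site_subset is None else np.asarray(site_subset)
    left = idx[hemi[idx] == "left"]
    right = idx[hemi[idx] == "right"]
    if left.size == 0 or right.size == 0:
        raise ValueError("both hemispheres must be represented")
    diff = (np.median(residuals[:, left, :], axis=1)
            - np.median(residuals[:, right, :], axis=1))
    cs = cluster_onesample_test(diff[:, None, :], AdjacencyGraph.chain(1),
                                alpha=alpha, n_perm=n_perm, seed=seed, sfreq=sfreq)
    return diff, cs


def paired_hemisphere_ttest(left_values, right_values):
    """One-sample t-test on the left-minus-right paired differences.

    Returns (t, df, p). Identical hemispheres give (0, df, 1); a nonzero
    constant difference with zero variance is signalled as an infinite-t
    sentinel with p = 0.
    """
    d = np.asarray(left_values, dtype=float) - np.asarray(right_values, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 paired values")
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * t_dist.sf(abs(t), df))
    return t, df, p


def _log_beta_binom_marginal(k: int, n: int, a: float) -> float:
    """log integral of Binom(k | n, p) over the Beta(a, a) prior (numerical)."""
    from scipy.integrate import quad
    from scipy.special import betaln, gammaln

    log_choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    def integrand(p):
        return p ** (k + a - 1) * (1 - p) ** (n - k + a - 1)

    val, _ = quad(integrand, 0.0, 1.0, epsabs=1e-12, epsrel=1e-10)
    return float(log_choose + np.log(val) - betaln(a, a))


def proportion_tests(count_left_sig: int, n_left: int, count_right_sig: int,
                     n_right: int, prior_a: float = 1.0, n_windows: int = 2) -> dict:
    """Compare the proportions of significant sensors between hemispheres.

    Pearson chi-square on the 2x2 (significant/not x hemisphere) table, with
    a Bonferroni adjustment over the ``n_windows`` pre-saccadic windows
    tested, plus the Bayes factor for different-vs-equal proportions under
    an independent-binomial (independent-multinomial rows) model with
    Beta(a, a) priors, computed by numerical integration. BF < 1 favours
    equal proportions.
    """
    if n_left <= 0 or n_right <= 0:
        raise ValueError("hemisphere totals must be positive")
    if count_left_sig > n_left or count_right_sig > n_right:
        raise ValueError("counts cannot exceed totals")
    table = np.array([[count_left_sig, n_left - count_left_sig],
                      [count_right_sig, n_right - count_right_sig]], dtype=float)
    if np.allclose(table[0] / n_left, table[1] / n_right):
        x2, p = 0.0, 1.0
    else:
        x2, p, _, _ = chi2_contingency(table, correction=False)[:4]
    # H1: independent proportions; H0: one common proportion
    log_m1 = (_log_beta_binom_marginal(count_left_sig, n_left, prior_a)
              + _log_beta_binom_marginal(count_right_sig, n_right, prior_a))
    from scipy.integrate import quad
    from scipy.special import betaln, gammaln
    lc = (gammaln(n_left + 1) - gammaln(count_left_sig + 1)
          - gammaln(n_left - count_left_sig + 1)
          + gammaln(n_right + 1) - gammaln(count_right_sig + 1)
          - gammaln(n_right - count_right_sig + 1))
    ktot = count_left_sig + count_right_sig
    ntot = n_left + n_right

    def integrand0(p_):
        return p_ ** (ktot + prior_a - 1) * (1 - p_) ** (ntot - ktot + prior_a - 1)

    val0, _ = quad(integrand0, 0.0, 1.0, epsabs=1e-12, epsrel=1e-10)
    log_m0 = float(lc + np.log(val0) - betaln(prior_a, prior_a))
    bf10 = float(np.exp(log_m1 - log_m0))
    return {
        "chi2": float(x2),
        "df": 1,
        "p": float(p),
        "p_bonferroni": float(min(1.0, n_windows * p)),
        "bf10": bf10,
    }
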