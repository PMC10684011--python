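"""Statistical engine for the phase-contrast analyses.

Implements, from first principles, the inferential machinery the analyses
rely on: spatiotemporal (and spatio-spectral) cluster-based permutation
t tests with sign-flip nulls, the Wilcoxon signed-rank test with an exact
small-sample distribution, two-way repeated-measures ANOVA with
generalized eta squared and Greenhouse-Geisser correction, hierarchical
linear-mixed-model comparison of cardiac-distance models, paired Cohen's d,
and a-priori power analysis for the paired/one-sample t test.

Permutation p values use the +1 finite-sample correction
``p = (1 + #{null >= obs}) / (1 + n_perm)``, which guarantees validity;
with full enumeration the raw proportion over all sign patterns is exact
and is used instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as st

from .exceptions import CardioMotorError, ParameterError

# ---------------------------------------------------------------------------
# channel adjacency
# ---------------------------------------------------------------------------

@dataclass
class Adjacency:
    """Symmetric channel neighbour graph for spatial clustering."""

    labels: list[str]
    neighbors: dict[str, set[str]]

    def __post_init__(self):
        for a, nbrs in self.neighbors.items():
            for b in nbrs:
                if a == b:
                    raise ParameterError("self-edges are not allowed")
                if a not in self.neighbors.get(b, set()):
                    raise ParameterError("adjacency must be symmetric")

    def matrix(self) -> np.ndarray:
        n = len(self.labels)
        m = np.zeros((n, n), dtype=bool)
        for i, a in enumerate(self.labels):
            for b in self.neighbors.get(a, ()):
                if b in self.labels:
                    m[i, self.labels.index(b)] = True
        return m

    @classmethod
    def none(cls, labels: list[str]) -> "Adjacency":
        return cls(list(labels), {l: set() for l in labels})


def montage_adjacency(labels: list[str], threshold_m: float = 0.055) -> Adjacency:
    """Distance-threshold neighbour graph on the standard 10-10 montage.

    Electrode positions come from the standard montage shipped with MNE;
    two electrodes are neighbours when closer than ``threshold_m`` (the
    default links each site to its immediate ring on a 10-10 cap).
    """
    import mne

    montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    missing = [l for l in labels if l not in pos]
    if missing:
        raise ParameterError(f"no montage position for {missing}")
    xyz = np.array([pos[l] for l in labels])
    nbrs = {l: set() for l in labels}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j and np.linalg.norm(xyz[i] - xyz[j]) < threshold_m:
                nbrs[a].add(b)
                nbrs[b].add(a)
    return Adjacency(list(labels), nbrs)


def read_adjacency_tsv(path, labels: list[str]) -> Adjacency:
    """User-supplied adjacency as a two-column TSV edge list."""
    nbrs = {l: set() for l in labels}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2 or parts[0].startswith("#"):
                continue
            a, b = parts[:2]
            if a in nbrs and b in nbrs and a != b:
                nbrs[a].add(b)
                nbrs[b].add(a)
    return Adjacency(list(labels), nbrs)


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    members: list[tuple]     # index tuples into the data grid
    mass: float              # sum of t over members (signed)
    p: float
    sign: int


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    mask: np.ndarray         # samples inside significant clusters
    null_max: np.ndarray     # null distribution of max |mass| (both tails)
    n_perm: int
    seed: int | None
    method: str              # "montecarlo" or "exact"
    cluster_alpha: float = 0.05
    t_obs: np.ndarray = field(default=None, repr=False)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.cluster_alpha]


def _find_clusters(t: np.ndarray, thresh: float, adj: np.ndarray | None):
    """Sign-separated connected components of suprathreshold samples.

    The first axis is space (connected through ``adj``); remaining axes use
    chain adjacency (+-1).  Returns a list of (member index tuples, mass).
    """
    clusters = []
    for sign in (1, -1):
        supra = (sign * t) > thresh
        visited = np.zeros_like(supra, dtype=bool)
        it = np.argwhere(supra)
        for start in map(tuple, it):
            if visited[start]:
                continue
            stack = [start]
            visited[start] = True
            members = []
            while stack:
                node = stack.pop()
                members.append(node)
                # chain neighbours along non-spatial axes
                for ax in range(1, t.ndim):
                    for d in (-1, 1):
                        nb = list(node)
                        nb[ax] += d
                        if 0 <= nb[ax] < t.shape[ax]:
                            nb = tuple(nb)
                            if supra[nb] and not visited[nb]:
                                visited[nb] = True
                                stack.append(nb)
                # spatial neighbours
                if adj is not None:
                    for s2 in np.flatnonzero(adj[node[0]]):
                        nb = (s2,) + node[1:]
                        if supra[nb] and not visited[nb]:
                            visited[nb] = True
                            stack.append(nb)
            mass = float(t[tuple(np.array(members).T)].sum())
            clusters.append((members, mass))
    return clusters


def _paired_t(diff_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics for each row of sign patterns; diff_flat is n x D."""
    n = diff_flat.shape[0]
    mean = signs @ diff_flat / n
    ss = np.sum(diff_flat ** 2, axis=0)  # invariant under sign flips
    var = (ss - n * mean ** 2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return mean / np.sqrt(var / n)


def cluster_perm_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: Adjacency | np.ndarray | None = None,
    n_perm: int = 1000,
    sample_alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int | None = 0,
    max_exhaustive: int = 4096,
) -> ClusterTestResult:
    """Paired cluster-based permutation t test.

    ``cond_a``/``cond_b`` are ``participants x space x [freq x] time``
    arrays of paired observations.  Per-sample paired t values are
    thresholded at the two-tailed critical value for ``sample_alpha``
    (df = n - 1); suprathreshold samples are clustered by adjacency
    separately per sign, each cluster scored by its mass (sum of t).  The
    null distribution records the maximum absolute cluster mass under
    random within-participant sign flips of the paired differences; when
    ``2**n <= max_exhaustive`` all sign patterns are enumerated and p
    values are exact.  Because the max statistic pools both tails, the
    resulting p values are already two-tailed: a cluster is significant at
    p < ``cluster_alpha`` (default 0.05), which calibrates the family-wise
    error to the nominal level.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError(f"condition shapes differ: {a.shape} vs {b.shape}")
    if a.ndim < 2 or a.shape[0] < 2:
        raise ParameterError("need participants x space x ... with n >= 2")
    diff = a - b
    n = diff.shape[0]
    grid_shape = diff.shape[1:]
    flat = diff.reshape(n, -1)

    if isinstance(adjacency, Adjacency):
        adj = adjacency.matrix()
    else:
        adj = adjacency
    thresh = st.t.ppf(1 - sample_alpha / 2, n - 1)

    t_obs = _paired_t(flat, np.ones((1, n)))[0].reshape(grid_shape)
    obs_clusters = _find_clusters(t_obs, thresh, adj)

    exact = 2 ** n <= max_exhaustive
    if exact:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        if n_perm < 100:
            import warnings
            warnings.warn("n_perm < 100 gives a very coarse null", stacklevel=2)
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))

    t_null = _paired_t(flat, signs)
    null_max = np.zeros(signs.shape[0])
    for i in range(signs.shape[0]):
        cl = _find_clusters(t_null[i].reshape(grid_shape), thresh, adj)
        if cl:
            null_max[i] = max(abs(m) for _, m in cl)

    clusters = []
    mask = np.zeros(grid_shape, dtype=bool)
    for members, mass in obs_clusters:
        if exact:
            p = float(np.mean(null_max >= abs(mass)))
        else:
            p = float((1 + np.sum(null_max >= abs(mass))) / (1 + signs.shape[0]))
        c = Cluster(members, mass, p, 1 if mass > 0 else -1)
        clusters.append(c)
        if p < cluster_alpha:
            for m in members:
                mask[m] = True
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterTestResult(
        clusters, mask, null_max,
        n_perm=signs.shape[0], seed=seed,
        method="exact" if exact else "montecarlo",
        cluster_alpha=cluster_alpha, t_obs=t_obs,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    V: float
    p: float
    n: int       # non-zero differences used
    method: str  # "exact" or "normal"


def wilcoxon_signed_rank(diffs: np.ndarray, exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    V is the sum of ranks of positive differences; zero differences are
    dropped and ties receive midranks.  The exact null distribution (all
    2^n equiprobable sign assignments of the observed ranks) is used for
    n <= ``exact_max_n``; beyond that a normal approximation with tie and
    continuity corrections applies.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise CardioMotorError("all differences are zero; V undefined")
    ranks = st.rankdata(np.abs(d))
    V = float(ranks[d > 0].sum())
    total = n * (n + 1) / 2

    if n <= exact_max_n:
        # distribution of V over sign assignments via subset-sum counting;
        # doubling makes midranks integral
        r2 = np.round(2 * ranks).astype(int)
        counts = np.zeros(int(r2.sum()) + 1)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[:-r].copy() if r else counts.copy()
        counts /= 2 ** n
        v2 = int(round(2 * V))
        p_le = counts[: v2 + 1].sum()
        p_ge = counts[v2:].sum()
        p = float(min(1.0, 2 * min(p_le, p_ge)))
        return WilcoxonResult(V, p, n, "exact")

    mean = total / 2
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - np.sum(
        tie_counts ** 3 - tie_counts) / 48
    z = (V - mean - 0.5 * np.sign(V - mean)) / np.sqrt(var)
    p = float(2 * st.norm.sf(abs(z)))
    return WilcoxonResult(V, min(p, 1.0), n, "normal")


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _mauchly_gg(scores: np.ndarray):
    """Mauchly sphericity test and Greenhouse-Geisser epsilon.

    ``scores`` is subjects x levels.  Returns (W, p, epsilon).
    """
    n, k = scores.shape
    # orthonormal contrast basis (Helmert, normalised)
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1)
        c[i] /= np.linalg.norm(c[i])
    cov = np.cov(scores, rowvar=False, ddof=1)
    s = c @ cov @ c.T
    eig = np.linalg.eigvalsh(s)
    eig = np.maximum(eig, 1e-30)
    k1 = k - 1
    W = float(np.prod(eig) / (np.mean(eig) ** k1))
    f = (2 * k1 ** 2 + k1 + 2) / (6 * k1 * (n - 1))
    chi2 = -(n - 1) * (1 - f) * np.log(W)
    df = k * (k - 1) / 2 - 1
    p = float(st.chi2.sf(chi2, df))
    eps = float(np.sum(eig) ** 2 / (k1 * np.sum(eig ** 2)))
    return W, p, eps


def rm_anova_2way(values: np.ndarray,
                  factor_names: tuple[str, str] = ("time", "phase")) -> dict:
    """Two-way fully within-subject ANOVA with ges and GG correction.

    ``values`` is ``subjects x levels_A x levels_B`` with no missing cells.
    Returns one entry per effect (two main effects and the interaction)
    with F, degrees of freedom, p, and generalized eta squared
    ``ges = SS_effect / (SS_effect + all subject-related error SS)``.
    Sphericity (Mauchly) is assessed for any within factor with more than
    two levels; Greenhouse-Geisser-corrected degrees of freedom are applied
    when Mauchly's p < 0.05.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 3:
        raise ParameterError("values must be subjects x A x B")
    if np.any(~np.isfinite(x)):
        raise ParameterError("missing cells are not supported")
    ns, na, nb = x.shape
    gm = x.mean()
    m_s = x.mean(axis=(1, 2))
    m_a = x.mean(axis=(0, 2))
    m_b = x.mean(axis=(0, 1))
    m_ab = x.mean(axis=0)
    m_as = x.mean(axis=2)
    m_bs = x.mean(axis=1)

    ss_s = na * nb * np.sum((m_s - gm) ** 2)
    ss_a = ns * nb * np.sum((m_a - gm) ** 2)
    ss_b = ns * na * np.sum((m_b - gm) ** 2)
    ss_ab = ns * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_as = nb * np.sum(
        (m_as - m_a[None, :] - m_s[:, None] + gm) ** 2)
    ss_bs = na * np.sum(
        (m_bs - m_b[None, :] - m_s[:, None] + gm) ** 2)
    ss_tot = np.sum((x - gm) ** 2)
    ss_abs = ss_tot - ss_s - ss_a - ss_b - ss_ab - ss_as - ss_bs
    ss_abs = max(ss_abs, 0.0)

    err_all = ss_s + ss_as + ss_bs + ss_abs

    def effect(name, ss_eff, ss_err, df1, df2, sphericity_scores):
        flat = ss_err < 1e-12 * max(ss_tot, 1.0)
        F = 0.0 if flat else float((ss_eff / df1) / (ss_err / df2))
        eps, gg_applied, mauchly_p = 1.0, False, None
        if sphericity_scores is not None and sphericity_scores.shape[1] > 2 \
                and not flat:
            _, mauchly_p, eps = _mauchly_gg(sphericity_scores)
            gg_applied = mauchly_p < 0.05
        d1, d2 = (df1 * eps, df2 * eps) if gg_applied else (df1, df2)
        p = 1.0 if flat else float(st.f.sf(F, d1, d2))
        denom = ss_eff + err_all
        return {
            "F": F, "df1": d1, "df2": d2, "p": p,
            "ges": float(ss_eff / denom) if denom > 0 else 0.0,
            "gg_applied": gg_applied, "epsilon": eps,
            "mauchly_p": mauchly_p, "flat": flat,
        }

    # sphericity inputs: factor scores collapsed over the other factor;
    # for the interaction (with one two-level factor) the difference scores
    inter_scores = None
    if nb == 2 and na > 2:
        inter_scores = x[:, :, 0] - x[:, :, 1]
    elif na == 2 and nb > 2:
        inter_scores = x[:, 0, :] - x[:, 1, :]

    a_name, b_name = factor_names
    return {
        a_name: effect(a_name, ss_a, ss_as, na - 1, (na - 1) * (ns - 1), m_as),
        b_name: effect(b_name, ss_b, ss_bs, nb - 1, (nb - 1) * (ns - 1), m_bs),
        f"{a_name}:{b_name}": effect(
            "inter", ss_ab, ss_abs, (na - 1) * (nb - 1),
            (na - 1) * (nb - 1) * (ns - 1), inter_scores),
    }


# ---------------------------------------------------------------------------
# linear-mixed-effects distance models
# ---------------------------------------------------------------------------

@dataclass
class LmeComparison:
    loglik: dict
    n_params: dict
    lrt: dict            # {"linear_vs_null": (chi2, df, p), ...}
    singular: bool
    coefficients: dict


def lme_distance_models(
    mep_uv: np.ndarray,
    distance_ms: np.ndarray,
    participant: np.ndarray,
) -> LmeComparison:
    """Hierarchical comparison of cardiac-distance models for MEP size.

    Fits, by maximum likelihood, three nested models of ln(MEP) with a
    participant random intercept: intercept only, + linear distance,
    + quadratic distance.  Likelihood-ratio chi2 = 2 * delta loglik with
    1 df per step.  With a single participant the models reduce to ordinary
    least squares.  MEP amplitudes must be positive (log transform).
    """
    amp = np.asarray(mep_uv, dtype=float)
    if np.any(amp <= 0):
        raise ParameterError("MEP amplitudes must be positive for the log model")
    y = np.log(amp)
    dist = np.asarray(distance_ms, dtype=float) / 1000.0  # seconds: conditioning
    groups = np.asarray(participant)

    const = np.ones_like(y)
    designs = {
        "null": np.column_stack([const]),
        "linear": np.column_stack([const, dist]),
        "quadratic": np.column_stack([const, dist, dist ** 2]),
    }

    single = len(np.unique(groups)) == 1
    loglik, n_params, coefs = {}, {}, {}
    singular = False
    if single:
        for name, X in designs.items():
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            n = y.size
            sigma2 = float(resid @ resid) / n
            loglik[name] = float(
                -0.5 * n * (np.log(2 * np.pi * sigma2) + 1))
            n_params[name] = X.shape[1] + 1
            coefs[name] = beta.tolist()
    else:
        import warnings

        from statsmodels.regression.mixed_linear_model import MixedLM
        for name, X in designs.items():
            model = MixedLM(y, X, groups=groups)
            fit = None
            # the RE variance can sit on the boundary (zero); some optimizers
            # then report a non-finite profiled likelihood — fall through
            for method in (None, "powell", "cg"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        cand = (model.fit(reml=False) if method is None
                                else model.fit(reml=False, method=method))
                    except (np.linalg.LinAlgError, ValueError):
                        continue
                if np.isfinite(cand.llf):
                    fit = cand
                    break
            if fit is None:
                raise CardioMotorError(f"mixed model {name!r} failed to fit")
            loglik[name] = float(fit.llf)
            n_params[name] = X.shape[1] + 2  # + residual var + RE var
            coefs[name] = fit.fe_params.tolist()
            if not np.all(np.isfinite(np.asarray(fit.bse_fe))) or \
                    float(np.asarray(fit.cov_re).ravel()[0]) <= 1e-12:
                singular = True

    def lrt(full, reduced):
        chi2 = max(2 * (loglik[full] - loglik[reduced]), 0.0)
        df = n_params[full] - n_params[reduced]
        return chi2, df, float(st.chi2.sf(chi2, df))

    return LmeComparison(
        loglik, n_params,
        {"linear_vs_null": lrt("linear", "null"),
         "quadratic_vs_linear": lrt("quadratic", "linear")},
        singular, coefs,
    )


# ---------------------------------------------------------------------------
# power, effect size, distance profile
# ---------------------------------------------------------------------------

def paired_t_power(n: int, d: float, alpha: float = 0.05) -> float:
    """Two-sided power of the paired/one-sample t test at effect size d."""
    df = n - 1
    tcrit = st.t.ppf(1 - alpha / 2, df)
    nc = d * np.sqrt(n)
    return float(st.nct.sf(tcrit, df, nc) + st.nct.cdf(-tcrit, df, nc))


def power_n_paired(d: float, power: float = 0.8, alpha: float = 0.05,
                   rounding: str = "nearest", n_max: int = 1_000_000) -> int:
    """Required sample size for the two-sided paired/one-sample t test.

    Solves the noncentral-t power equation continuously in n (fractional
    degrees of freedom, the convention of the standard power calculators)
    and converts to an integer.  ``rounding="nearest"`` reports the sample
    size as such calculators are conventionally quoted (e.g. d = 0.48 at
    80 % power and alpha = 0.05 gives a continuous solution of 36.03,
    quoted as N = 36); ``rounding="ceil"`` instead guarantees
    ``paired_t_power(n) >= power > paired_t_power(n - 1)``.
    """
    if d <= 0:
        raise ParameterError("effect size must be positive")
    if rounding not in ("nearest", "ceil"):
        raise ParameterError("rounding must be 'nearest' or 'ceil'")

    def gap(n):
        df = n - 1
        tcrit = st.t.ppf(1 - alpha / 2, df)
        nc = d * np.sqrt(n)
        return st.nct.sf(tcrit, df, nc) + st.nct.cdf(-tcrit, df, nc) - power

    if gap(2.0) >= 0:
        return 2
    hi = 4.0
    while gap(hi) < 0:  # noncentral-t is numerically safe on a grown bracket
        hi *= 2
        if hi > n_max:
            raise CardioMotorError("required n exceeds n_max")
    from scipy.optimize import brentq
    root = brentq(gap, hi / 2, hi, xtol=1e-8)
    if rounding == "nearest":
        return max(int(round(root)), 2)
    return max(int(np.ceil(root - 1e-9)), 2)


def cohens_d_paired(diffs: np.ndarray) -> float:
    """d = mean(diff) / sd(diff); infinite (flagged) when sd is zero."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ParameterError("need at least two differences")
    sd = d.std(ddof=1)
    if sd == 0:
        return float(np.inf) if d.mean() != 0 else 0.0
    return float(d.mean() / sd)


def binned_mep_profile(
    amplitudes: np.ndarray,
    distance_ms: np.ndarray,
    width_ms: float = 50.0,
    max_ms: float | None = None,
) -> dict:
    """Mean MEP amplitude in fixed-width bins of distance from the R-peak."""
    amp = np.asarray(amplitudes, dtype=float)
    dist = np.asarray(distance_ms, dtype=float)
    ok = np.isfinite(dist) & np.isfinite(amp)
    amp, dist = amp[ok], dist[ok]
    if max_ms is None:
        max_ms = float(np.max(dist)) if dist.size else width_ms
    edges = np.arange(0.0, max_ms + width_ms, width_ms)
    centers, means, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dist >= lo) & (dist < hi)
        centers.append((lo + hi) / 2)
        counts.append(int(sel.sum()))
        means.append(float(amp[sel].mean()) if sel.any() else np.nan)
    return {"center_ms": np.array(centers), "mean_uv": np.array(means),
            "count": np.array(counts)}
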