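"""Transposable-element content, enrichment statistics and phylogenetic
regression.

Repeat annotations come in as RepeatMasker ``.out`` tables; content is the
proportion of masked bases (union of annotated intervals / region length).
Locus-vs-genome enrichment is a log2 ratio, tested across species with an
exact two-sided Wilcoxon signed-rank test and Benjamini-Hochberg FDR
control.  The association between locus TE content and gene copy number is
fit by phylogenetic generalized least squares (PGLS) with Pagel's λ
estimated by maximum likelihood, so shared ancestry does not masquerade as
signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .architecture import DatedTree
from .errors import InvalidInputError, ParseError, UndefinedValueError

logger = logging.getLogger(__name__)

TE_CLASSES = ("SINE", "LINE", "LTR", "DNA")
DEFAULT_PSEUDOCOUNT = 1e-4
EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class RepeatAnnotation:
    interval: tuple[int, int]  # 0-based half-open on the target
    family: str
    te_class: str  # SINE | LINE | LTR | DNA | other
    target_id: str


@dataclass
class TEProfile:
    species: str
    locus_prop: float
    genome_prop: float
    per_class_props: dict[str, tuple[float, float]]
    copy_number: int


@dataclass
class EnrichmentResult:
    key: str
    log2_enrichment: float
    p_value: float
    q_value: float


@dataclass
class PGLSFit:
    slope: float
    intercept: float
    lam: float
    sigma2: float
    r_squared: float
    slope_p: float
    lambda_lrt_p: float
    loglik: float


@dataclass
class CorrelationResult:
    rho: float
    partial_rho: float | None
    p: float


def _classify(class_family: str) -> str:
    head = class_family.split("/")[0]
    return head if head in TE_CLASSES else "other"


def parse_repeat_annotations(path: str) -> list[RepeatAnnotation]:
    """Read a RepeatMasker ``.out`` file.

    The standard layout has three header lines followed by whitespace-
    separated columns; query begin/end are 1-based inclusive and are
    converted to 0-based half-open here.  The repeat class is the part of
    the class/family column before "/".
    """
    annotations: list[RepeatAnnotation] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno <= 3:  # header block (two title lines + blank)
            continue
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 11:
            raise ParseError(
                f"expected ≥11 whitespace-separated columns, got {len(fields)}",
                lineno,
            )
        try:
            begin = int(fields[5])
            end = int(fields[6])
        except ValueError as exc:
            raise ParseError(f"non-integer coordinates: {exc}", lineno) from None
        if begin < 1 or end < begin:
            raise ParseError(f"invalid 1-based interval [{begin}, {end}]", lineno)
        annotations.append(
            RepeatAnnotation(
                interval=(begin - 1, end),
                family=fields[9],
                te_class=_classify(fields[10]),
                target_id=fields[4],
            )
        )
    return annotations


def te_proportion(
    annotations: list[RepeatAnnotation], region_length: int
) -> float:
    """Masked-base proportion: union of annotation intervals / region length.

    Overlapping annotations are never double-counted.
    """
    if region_length <= 0:
        raise InvalidInputError("region_length must be positive")
    ivs = sorted(a.interval for a in annotations)
    covered = 0
    cur_start: int | None = None
    cur_end = 0
    for start, end in ivs:
        if start < 0 or end > region_length:
            raise InvalidInputError(
                f"annotation [{start}, {end}) outside region [0, {region_length})"
            )
        if cur_start is None:
            cur_start, cur_end = start, end
        elif start <= cur_end:
            cur_end = max(cur_end, end)
        else:
            covered += cur_end - cur_start
            cur_start, cur_end = start, end
    if cur_start is not None:
        covered += cur_end - cur_start
    return covered / region_length


def log2_enrichment(
    p_locus: float, p_genome: float, pseudo: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """log2((p_locus + pseudo) / (p_genome + pseudo)).

    The pseudocount (default 1e-4, i.e. 0.01 percentage points) keeps
    zero-proportion repeat families finite.
    """
    if p_genome + pseudo <= 0:
        raise UndefinedValueError(
            "enrichment undefined: genome proportion and pseudocount are both zero"
        )
    if p_locus + pseudo <= 0:
        raise UndefinedValueError(
            "enrichment undefined: locus proportion and pseudocount are both zero"
        )
    return math.log2((p_locus + pseudo) / (p_genome + pseudo))


def _signed_rank_distribution(doubled_ranks: list[int]) -> np.ndarray:
    """Exact null distribution of the (doubled) positive-rank sum W+.

    Returns counts over achievable values 0..sum(doubled_ranks); under the
    null each difference is positive or negative with probability 1/2
    independently, so the distribution is the convolution of {0, r_i}.
    """
    total = sum(doubled_ranks)
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(paired_diffs: list[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value.

    Zero differences are discarded and tied magnitudes mid-ranked.  For
    n ≤ 25 the p-value is exact (full enumeration of the 2^n sign
    assignments via convolution of the rank distribution); above that a
    normal approximation with tie correction and a 0.5 continuity
    correction is used.
    """
    diffs = np.asarray([d for d in paired_diffs if d != 0], dtype=float)
    n = len(diffs)
    if n == 0:
        logger.warning("all paired differences are zero; returning p = 1.0")
        return 1.0
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        doubled = [int(round(2 * r)) for r in ranks]
        w2 = int(round(2 * w_plus))
        counts = _signed_rank_distribution(doubled)
        total_assignments = counts.sum()
        s2 = sum(doubled)
        low, high = min(w2, s2 - w2), max(w2, s2 - w2)
        p = (counts[: low + 1].sum() + counts[high:].sum()) / total_assignments
        return min(1.0, float(p))
    mu = n * (n + 1) / 4.0
    tie_groups = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_groups**3 - tie_groups
    ) / 48.0
    z = (abs(w_plus - mu) - 0.5) / math.sqrt(var)
    return float(2 * stats.norm.sf(z))


def bh_adjust(pvals: list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_tests(
    profiles: list[TEProfile], pseudo: float = DEFAULT_PSEUDOCOUNT
) -> list[EnrichmentResult]:
    """Per-class Wilcoxon signed-rank tests of locus-vs-genome proportions
    across species, BH-adjusted, with the median log2 enrichment reported."""
    results: list[EnrichmentResult] = []
    pvals = []
    keys = ["all"] + list(TE_CLASSES)
    for key in keys:
        if key == "all":
            pairs = [(pr.locus_prop, pr.genome_prop) for pr in profiles]
        else:
            pairs = [
                pr.per_class_props[key]
                for pr in profiles
                if key in pr.per_class_props
            ]
        if not pairs:
            continue
        diffs = [lo - ge for lo, ge in pairs]
        enr = float(
            np.median([log2_enrichment(lo, ge, pseudo) for lo, ge in pairs])
        )
        p = wilcoxon_signed_rank(diffs)
        results.append(EnrichmentResult(key, enr, p, q_value=math.nan))
        pvals.append(p)
    qvals = bh_adjust(pvals)
    for res, q in zip(results, qvals):
        res.q_value = float(q)
    return results


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)


def _pearson_p(r: float, df: int) -> float:
    if df <= 0:
        return math.nan
    r = min(1.0 - 1e-15, max(-1.0 + 1e-15, r))
    t = r * math.sqrt(df / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df))


def spearman_partial(
    x: list[float], y: list[float], z: list[float]
) -> CorrelationResult:
    """Spearman correlation of x and y, plus the rank partial correlation
    controlling for z (correlation of residuals after regressing the ranks
    of x and y on the ranks of z).  p is for the partial correlation by the
    t approximation with n − 3 degrees of freedom."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    n = len(x)
    if not (len(y) == len(z) == n) or n < 4:
        raise InvalidInputError("inputs must have equal length ≥ 4")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.ptp(v) == 0:
            raise UndefinedValueError(f"correlation undefined: {name} is constant")
    rx, ry, rz = _rank(x), _rank(y), _rank(z)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    design = np.column_stack([np.ones(n), rz])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    partial = float(np.corrcoef(res_x, res_y)[0, 1])
    return CorrelationResult(rho=rho, partial_rho=partial, p=_pearson_p(partial, n - 3))


# ---------------------------------------------------------------------------
# PGLS with Pagel's lambda
# ---------------------------------------------------------------------------


def phylogenetic_covariance(tree: DatedTree, tip_order: list[str]) -> np.ndarray:
    """Brownian-motion covariance: C[i, j] = shared root-to-MRCA path length."""
    labels = list(tip_order)
    if set(labels) != set(tree.tip_labels):
        raise InvalidInputError("tip order does not match the tree's tips")
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    T = tree.height
    n = len(labels)
    C = np.empty((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                C[i, j] = T
            else:
                d = pdm.patristic_distance(taxa[a], taxa[b])
                C[i, j] = T - d / 2.0
    return C


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _gls_profile(
    X: np.ndarray, y: np.ndarray, V: np.ndarray
) -> tuple[np.ndarray, float, float, np.ndarray]:
    """Profile (beta, sigma2_ML, loglik, XtVinvX) for fixed covariance V."""
    from scipy.linalg import solve_triangular

    n = len(y)
    L = np.linalg.cholesky(V)
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return beta, sigma2, loglik, XtX


def pgls_fit(tree: DatedTree, x: dict[str, float], y: dict[str, float]) -> PGLSFit:
    """Fit y = a + b·x with phylogenetically correlated errors.

    ε ~ N(0, σ²·C(λ)) where C(1) is the Brownian-motion shared-path-length
    matrix and C(λ) scales its off-diagonal entries by λ ∈ [0, 1].  λ is
    estimated by bounded 1-D maximum likelihood (tolerance 1e-6) with
    (a, b, σ²) profiled analytically at each λ.  The λ = 0 likelihood-ratio
    test uses a plain χ²(1) reference, which is conservative at the
    boundary.
    """
    tips = sorted(tree.tip_labels)
    if set(x) != set(tips) or set(y) != set(tips):
        raise InvalidInputError("trait tip sets must match the tree's tips")
    n = len(tips)
    if n < 4:
        raise InvalidInputError("PGLS needs at least 4 tips")
    xv = np.array([x[t] for t in tips])
    yv = np.array([y[t] for t in tips])
    C = phylogenetic_covariance(tree, tips)
    if np.linalg.matrix_rank(C) < n:
        raise InvalidInputError("singular phylogenetic covariance matrix")
    X = np.column_stack([np.ones(n), xv])

    def negloglik(lam: float) -> float:
        V = _lambda_cov(C, lam)
        try:
            return -_gls_profile(X, yv, V)[2]
        except np.linalg.LinAlgError:
            return np.inf

    opt = optimize.minimize_scalar(
        negloglik, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6}
    )
    lam = float(opt.x)
    # snap to the boundary when it is at least as good (the bounded search
    # never evaluates the exact endpoints)
    for edge in (0.0, 1.0):
        if negloglik(edge) <= opt.fun + 1e-10:
            lam = edge
            break
    V = _lambda_cov(C, lam)
    beta, sigma2, loglik, XtX = _gls_profile(X, yv, V)
    # whitened-space R^2 against the GLS intercept-only model
    from scipy.linalg import solve_triangular

    L = np.linalg.cholesky(V)
    yw = solve_triangular(L, yv, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    ones_w = Xw[:, 0]
    b0 = float(ones_w @ yw) / float(ones_w @ ones_w)
    tss = float(np.sum((yw - b0 * ones_w) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    # slope test with the unbiased error variance
    sigma2_unbiased = rss / (n - 2)
    cov_beta = sigma2_unbiased * np.linalg.inv(XtX)
    se_slope = math.sqrt(cov_beta[1, 1])
    t_stat = beta[1] / se_slope if se_slope > 0 else math.inf
    slope_p = float(2 * stats.t.sf(abs(t_stat), n - 2))
    ll0 = _gls_profile(X, yv, _lambda_cov(C, 0.0))[2]
    lrt = max(0.0, 2.0 * (loglik - ll0))
    lambda_lrt_p = float(stats.chi2.sf(lrt, df=1))
    return PGLSFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        lam=lam,
        sigma2=sigma2,
        r_squared=max(0.0, min(1.0, r2)),
        slope_p=slope_p,
        lambda_lrt_p=lambda_lrt_p,
        loglik=loglik,
    )
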