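"""Statistical layer shared by the integration pipeline.

Overlap enrichment against assay-intersection backgrounds, empirical
p-values from randomized-network / label-permutation nulls, the
sign-consistency test used to compare replicate cultures, fold-change
correlations, a light-weight differential-expression caller to drive
permutation machinery, and per-pair variant-expression association with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OverlapTest",
    "EmpiricalNull",
    "AssociationResult",
    "hypergeom_upper",
    "fisher_overlap",
    "empirical_p",
    "sign_consistency_test",
    "sign_consistency_exact",
    "correlate_differentials",
    "simple_de",
    "permutation_de_null",
    "subnet_overlap_null",
    "variant_expression_fit",
    "bh_adjust",
]


@dataclass(frozen=True)
class OverlapTest:
    """Result of a one-sided (enrichment) overlap test between two id sets."""

    n_a: int
    n_b: int
    overlap: int
    n_background: int
    p: float
    odds_ratio: float


@dataclass
class EmpiricalNull:
    """An observed statistic together with its null replicate values.

    Two reporting conventions are emitted because published empirical
    p-values are often stated loosely as bounds: ``paper`` reports the
    plain exceedance fraction b/R with a "<(b+1)/R" bound string, and
    ``conservative`` reports (b+1)/(R+1), which can never be zero.
    """

    observed: float
    null_values: np.ndarray

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if self.null_values.size < 1:
            raise ValueError("empirical null requires at least one replicate")

    @property
    def n_replicates(self) -> int:
        return int(self.null_values.size)

    @property
    def n_exceeding(self) -> int:
        # strict ">" matches the convention "had a statistic > observed"
        return int(np.sum(self.null_values > self.observed))


@dataclass(frozen=True)
class AssociationResult:
    """A single variant-expression linear fit (q filled in by the caller)."""

    gene_id: str
    variant_id: str
    slope: float
    adjusted_r2: float
    p: float
    q: float = float("nan")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes when drawing ``n`` items without replacement from a
    background of ``N`` items of which ``K`` are marked. This is the
    one-sided enrichment test used for every set-overlap comparison.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(
            f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def fisher_overlap(
    a: set[str], b: set[str], background: set[str]
) -> OverlapTest:
    """One-sided Fisher's exact test for enrichment of ``a`` ∩ ``b``.

    Both sets must be drawn from ``background`` (typically the genes
    detected in both assays being compared).
    """
    if not background:
        raise ValueError("background must be non-empty")
    if not a <= background or not b <= background:
        raise ValueError("both sets must be subsets of the background")
    k = len(a & b)
    table = [
        [k, len(a) - k],
        [len(b) - k, len(background) - len(a) - len(b) + k],
    ]
    odds, p = sps.fisher_exact(table, alternative="greater")
    return OverlapTest(
        n_a=len(a),
        n_b=len(b),
        overlap=k,
        n_background=len(background),
        p=float(p),
        odds_ratio=float(odds),
    )


def empirical_p(
    null: EmpiricalNull,
    convention: Literal["paper", "conservative"] = "conservative",
) -> dict:
    """Empirical p-value of ``null.observed`` against its null replicates.

    Returns a dict with ``estimate`` and ``bound`` (a "<x" string for the
    paper convention, the estimate itself for the conservative one).
    """
    b = null.n_exceeding
    R = null.n_replicates
    if convention == "paper":
        estimate = b / R
        bound = f"<{(b + 1) / R:g}"
    elif convention == "conservative":
        estimate = (b + 1) / (R + 1)
        bound = f"{estimate:g}"
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return {"estimate": estimate, "bound": bound, "n_exceeding": b, "n_replicates": R}


def sign_consistency_test(n_same: int, n_opposite: int) -> float:
    """Two-sided normal-approximation sign test for direction consistency.

    Under the null that each shared protein is equally likely to change in
    the same or the opposite direction between two experiments, the number
    changing in the same direction is Binomial(n, 1/2). The test statistic
    is z = (n_same - n/2) / sqrt(n/4) with no continuity correction.
    """
    n = n_same + n_opposite
    if n < 1:
        raise ValueError("need at least one informative pair")
    z = (n_same - n / 2) / np.sqrt(n / 4)
    return float(2 * sps.norm.sf(abs(z)))


def sign_consistency_exact(n_same: int, n_opposite: int) -> float:
    """Exact two-sided binomial oracle for :func:`sign_consistency_test`."""
    n = n_same + n_opposite
    if n < 1:
        raise ValueError("need at least one informative pair")
    return float(sps.binomtest(n_same, n, 0.5, alternative="two-sided").pvalue)


def correlate_differentials(
    x: dict[str, float],
    y: dict[str, float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> dict:
    """Correlate two per-id differential tables over their id intersection."""
    shared = sorted(set(x) & set(y))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared ids, got {len(shared)}")
    xv = np.array([x[i] for i in shared])
    yv = np.array([y[i] for i in shared])
    if method == "pearson":
        r, p = sps.pearsonr(xv, yv)
    elif method == "spearman":
        r, p = sps.spearmanr(xv, yv)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"r": float(r), "p": float(p), "n": len(shared)}


def _log_cpm(counts: pd.DataFrame, offset: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a small offset (library-size normalized)."""
    lib = counts.sum(axis=0).astype(float)
    cpm = counts.div(lib, axis=1) * 1e6
    return np.log2(cpm + offset)


def simple_de(
    counts: pd.DataFrame,
    labels: Sequence[str],
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Two-group differential expression on log-normalized counts.

    A deliberately simple caller — Welch t-test per gene on log2
    counts-per-million — used where the pipeline only needs *a*
    differential statistic to permute, not a production DE method.

    Parameters
    ----------
    counts : genes x samples non-negative integer matrix.
    labels : per-sample group labels; exactly two distinct groups, each
        with >= 2 samples.

    Returns a frame indexed by gene with columns lfc, p, q, is_de.
    """
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    mask_b = labels == groups[1]
    if mask_b.sum() < 2 or (~mask_b).sum() < 2:
        raise ValueError("each group needs at least two samples")
    log_expr = _log_cpm(counts)
    a = log_expr.loc[:, ~mask_b].to_numpy()
    b = log_expr.loc[:, mask_b].to_numpy()
    lfc = b.mean(axis=1) - a.mean(axis=1)
    t, p = sps.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_adjust(p)
    return pd.DataFrame(
        {"lfc": lfc, "p": p, "q": q, "is_de": q < fdr}, index=counts.index
    )


def permutation_de_null(
    counts: pd.DataFrame,
    labels: Sequence[str],
    n_permutations: int,
    seed: int | None = None,
    fdr: float = 0.1,
) -> EmpiricalNull:
    """Null distribution of the DEG count under condition-label permutation.

    Group sizes are preserved by permuting the label vector itself; the
    observed DEG count on the unpermuted labels is the test statistic.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = int(simple_de(counts, labels, fdr=fdr)["is_de"].sum())
    null = np.empty(n_permutations)
    for r in range(n_permutations):
        perm = rng.permutation(labels)
        null[r] = simple_de(counts, perm, fdr=fdr)["is_de"].sum()
    return EmpiricalNull(observed=observed, null_values=null)


def subnet_overlap_null(
    deg_lists: Sequence[set[str]], subnet: set[str], observed_degs: set[str]
) -> EmpiricalNull:
    """Null distribution of |DEG set ∩ subnet| over permutation DEG lists."""
    if not subnet:
        raise ValueError("subnet must be non-empty")
    null = np.array([len(degs & subnet) for degs in deg_lists], dtype=float)
    return EmpiricalNull(observed=len(observed_degs & subnet), null_values=null)


def variant_expression_fit(
    expression: np.ndarray, genotype: np.ndarray
) -> tuple[float, float, float]:
    """OLS fit of normalized expression on genotype dosage for one pair.

    Returns (slope, adjusted R^2, p) where p is the two-sided t-test on
    the slope and adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 2).
    """
    expression = np.asarray(expression, dtype=float)
    genotype = np.asarray(genotype, dtype=float)
    n = expression.size
    if n < 3:
        raise ValueError("need at least three samples")
    if np.ptp(genotype) == 0:
        raise ValueError("constant genotype is untestable")
    fit = sps.linregress(genotype, expression)
    r2 = fit.rvalue**2
    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - 2)
    return float(fit.slope), float(adj_r2), float(fit.pvalue)


def associate_variants(
    expression: pd.DataFrame,
    genotypes: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Fit every (gene, variant) pair and BH-adjust across the family.

    Constant-genotype pairs are flagged untestable and excluded from the
    BH family (their q is NaN).
    """
    rows: list[dict] = []
    for gene, variant in pairs:
        expr = expression.loc[gene].to_numpy()
        geno = genotypes.loc[variant].to_numpy()
        try:
            slope, adj_r2, p = variant_expression_fit(expr, geno)
            rows.append(
                {"gene_id": gene, "variant_id": variant, "slope": slope,
                 "adjusted_r2": adj_r2, "p": p, "testable": True}
            )
        except ValueError:
            rows.append(
                {"gene_id": gene, "variant_id": variant, "slope": np.nan,
                 "adjusted_r2": np.nan, "p": np.nan, "testable": False}
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    testable = out["testable"].to_numpy()
    if testable.any():
        out.loc[testable, "q"] = bh_adjust(out.loc[testable, "p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
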