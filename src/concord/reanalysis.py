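"""Per-screen statistical re-analysis.

The raw intensity matrices are quantile-normalised, each gene is tested
for a vulnerable-vs-resistant difference with Welch's unequal-variance t
test, p-values are adjusted by the Benjamini-Hochberg step-up, and the
per-gene records are filtered on adjusted significance and fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from concord.io import ExpressionMatrix, ScreenResult


@dataclass(frozen=True)
class DeFilterParams:
    """Significance / effect-size filter.

    ``fold_min`` is on the linear scale and applied as
    ``|log2fc| >= log2(fold_min)``; the defaults keep genes with
    adjusted p below 0.05 and at least a 1.5-fold change.
    """

    q_max: float = 0.05
    fold_min: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.q_max <= 1):
            raise ValueError(f"q_max must be in (0, 1], got {self.q_max}")
        if self.fold_min < 1:
            raise ValueError(f"fold_min must be >= 1, got {self.fold_min}")

    @property
    def log2_fold_min(self) -> float:
        return float(np.log2(self.fold_min))


@dataclass
class FilteredScreen:
    """A filtered screen plus the kept/up/down tally."""

    screen: ScreenResult
    n_kept: int
    n_up: int
    n_down: int


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto one common value distribution.

    Columns are sorted, the reference distribution is the vector of
    row-wise means of the column-sorted matrix, and each column's values
    are replaced by the reference values at their ranks.  Ties within a
    column receive the mean of the reference values across the sorted
    positions the tied group occupies, which makes the result
    deterministic and independent of input row order.
    """
    values = matrix.values.to_numpy(float)
    if values.size == 0:
        raise ValueError("empty expression matrix")
    if np.isnan(values).any():
        raise ValueError("missing values present; impute or drop before normalising")

    order = np.argsort(values, axis=0, kind="stable")
    reference = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    n_genes, n_samples = values.shape
    positions = np.arange(n_genes)
    for j in range(n_samples):
        col_sorted = values[order[:, j], j]
        assigned = reference.copy()
        # ties: average the reference over the run of equal input values
        start = 0
        for stop in range(1, n_genes + 1):
            if stop == n_genes or col_sorted[stop] != col_sorted[start]:
                if stop - start > 1:
                    assigned[start:stop] = reference[start:stop].mean()
                start = stop
        out[order[:, j], j] = assigned[positions]

    normalised = pd.DataFrame(
        out, index=matrix.values.index, columns=matrix.values.columns
    )
    return ExpressionMatrix(values=normalised, groups=matrix.groups.copy())


def _moderated_pvalues(
    vuln: np.ndarray, resi: np.ndarray, log2fc: np.ndarray
) -> np.ndarray:
    """Empirical-Bayes moderated t-test p-values.

    Per-gene pooled variances are shrunk toward a common prior fitted by
    matching the moments of log(s^2) to its scaled-F sampling
    distribution; the moderated t then has d0 + d_g degrees of freedom.
    With few replicates per group this borrows strength across genes and
    is the standard for microarray re-analysis.
    """
    from scipy.special import digamma, polygamma

    n1, n2 = vuln.shape[1], resi.shape[1]
    d_g = n1 + n2 - 2
    s2 = (
        (vuln - vuln.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1) + ((resi - resi.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = s2 / d_g

    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("too few genes with positive variance for moderation")
    z = np.log(s2[ok])
    e_bar = z.mean() - digamma(d_g / 2) + np.log(d_g / 2)
    excess = z.var(ddof=1) - float(polygamma(1, d_g / 2))

    if excess <= 0:  # no evidence of variance heterogeneity: pool fully
        d0 = np.inf
        s0_sq = np.exp(e_bar)
    else:
        # invert trigamma(d0/2) = excess by Newton iteration
        y = 0.5 + 1 / excess
        for _ in range(50):
            tri = float(polygamma(1, y))
            delta = tri * (1 - tri / excess) / float(polygamma(2, y))
            y += delta
            if abs(delta) < 1e-10 * y:
                break
        d0 = 2 * y
        s0_sq = np.exp(e_bar + digamma(d0 / 2) - np.log(d0 / 2))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g

    se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = log2fc / se
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    # zero posterior variance can only arise from an all-degenerate matrix
    p = np.where(se == 0, np.where(log2fc == 0, 1.0, 0.0), p)
    return p


def de_test(
    matrix: ExpressionMatrix,
    *,
    screen_id: str = "screen",
    species: str = "mouse",
    method: str = "welch",
) -> ScreenResult:
    """Per-gene two-group comparison on log2 intensities.

    log2fc is mean(vulnerable) - mean(resistant); q comes from the
    Benjamini-Hochberg adjustment over all tested genes.  With
    ``method='welch'`` (default) p is the two-sided Welch
    unequal-variance t test per gene; ``method='moderated'`` shrinks the
    per-gene variances toward a common empirical-Bayes prior, which is
    substantially more powerful at the 2-4 replicates per group typical
    of these screens.  Genes with identical values in both groups get
    p = 1 by convention.
    """
    matrix.require_testable()
    vuln = matrix.values[matrix.samples_in("vulnerable")].to_numpy(float)
    resi = matrix.values[matrix.samples_in("resistant")].to_numpy(float)

    log2fc = vuln.mean(axis=1) - resi.mean(axis=1)
    if method == "moderated":
        p = _moderated_pvalues(vuln, resi, log2fc)
    elif method == "welch":
        import warnings

        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # near-identical groups are handled explicitly below
            warnings.filterwarnings("ignore", message="Precision loss occurred")
            t, p = stats.ttest_ind(vuln, resi, axis=1, equal_var=False)
        # zero variance in both groups: Welch is undefined; identical means
        # are a perfect null (p = 1), distinct means a perfect separation.
        degenerate = (vuln.var(axis=1) == 0) & (resi.var(axis=1) == 0)
        p = np.where(degenerate & (log2fc == 0), 1.0, p)
        p = np.where(degenerate & (log2fc != 0), 0.0, p)
        p = np.nan_to_num(p, nan=1.0)
    else:
        raise ValueError(f"method must be 'welch' or 'moderated', got {method!r}")

    records = pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "log2fc": log2fc,
            "p": p,
            "q": bh_adjust(p),
        }
    )
    return ScreenResult(screen_id, species, records)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Equivalent to q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_de(result: ScreenResult, params: DeFilterParams | None = None) -> FilteredScreen:
    """Keep records with q < q_max and |log2fc| >= log2(fold_min)."""
    params = params or DeFilterParams()
    rec = result.records
    keep = (rec["q"] < params.q_max) & (rec["log2fc"].abs() >= params.log2_fold_min)
    kept = rec[keep].reset_index(drop=True)
    screen = ScreenResult(result.screen_id, result.species, kept)
    return FilteredScreen(
        screen=screen,
        n_kept=len(kept),
        n_up=int((kept["log2fc"] > 0).sum()),
        n_down=int((kept["log2fc"] < 0).sum()),
    )
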