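"""Two-group differential testing with BH-FDR control and direction calls.

Four test families share one result layout (:class:`DifferentialTable`):

* ``wilcoxon_de`` — two-sided Wilcoxon rank-sum per feature, for log2
  microarray intensities and for promoter beta values. Exact enumeration
  for small tie-free samples (total n <= 12), otherwise the normal
  approximation with continuity and tie correction.
* ``nb_exact_de`` — a simplified negative-binomial conditional exact test
  for RNA-seq counts: median-of-ratios normalization, a single common
  dispersion estimated by method of moments, and a per-gene conditional
  test on the equalized group totals (reducing to the conditional binomial
  when the dispersion is zero).
* ``fisher_binary_de`` — two-sided Fisher's exact test on binary
  alteration calls (CNV peaks, mutations).
* ``call_dm_genes`` — aggregates significant differentially methylated
  loci to gene-level hyper/hypomethylation calls; genes with loci in both
  directions are excluded as bidirectional.

Raw p values are adjusted across the whole tested family with the
Benjamini-Hochberg step-up procedure; a feature is declared significant
when its q value is strictly below the configured FDR threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    BinaryAlterationMatrix,
    ExpressionMatrix,
    GroupAssignment,
    MethylationMatrix,
)
from .grouping import met_nonmet_ids

__all__ = [
    "DifferentialTable",
    "bh_adjust",
    "wilcoxon_de",
    "nb_exact_de",
    "fisher_binary_de",
    "call_dm_genes",
    "median_of_ratios_factors",
    "estimate_common_dispersion",
]

UP = "up_in_met"
DOWN = "down_in_met"
TIED = "tied"

# relative guard when summing outcome probabilities "as or less likely than
# observed" (two-sided exact tests); absorbs float rounding at equal pmf
_MINLIK_GUARD = 1.0 + 1e-7


@dataclass
class DifferentialTable:
    """Per-feature test results for one two-group comparison.

    ``table`` columns: feature_id, statistic, p_raw, q_bh, direction.
    """

    table: pd.DataFrame
    test_name: str
    n_met: int
    n_nonmet: int

    def significant(self, fdr_threshold: float) -> pd.DataFrame:
        """Features with q strictly below the FDR threshold."""
        return self.table[self.table["q_bh"] < fdr_threshold].reset_index(drop=True)

    @classmethod
    def from_frame(
        cls,
        table: pd.DataFrame,
        test_name: str = "external",
        n_met: int = 0,
        n_nonmet: int = 0,
        readjust: bool = False,
    ) -> "DifferentialTable":
        """Adapter for an external tool's per-feature p-value table.

        ``table`` needs columns feature_id, p_raw and direction;
        statistic defaults to NaN and q_bh is recomputed from p_raw when
        absent (or when ``readjust`` is set), so downstream concordance
        and enrichment can consume results produced outside this package.
        """
        required = {"feature_id", "p_raw", "direction"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"adapter table lacks columns: {sorted(missing)}")
        df = table.copy()
        if "statistic" not in df.columns:
            df["statistic"] = np.nan
        if "q_bh" not in df.columns or readjust:
            df["q_bh"] = bh_adjust(df["p_raw"].to_numpy())
        cols = ["feature_id", "statistic", "p_raw", "q_bh", "direction"]
        return cls(df[cols].reset_index(drop=True), test_name, n_met, n_nonmet)

    def __len__(self) -> int:
        return len(self.table)


def bh_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _split_columns(values: pd.DataFrame, groups: Sequence[GroupAssignment]):
    met_ids, nonmet_ids = met_nonmet_ids(groups)
    if not met_ids:
        raise ValueError("metastasis group is empty")
    if not nonmet_ids:
        raise ValueError("non_metastasis group is empty")
    missing = [s for s in met_ids + nonmet_ids if s not in values.columns]
    if missing:
        raise ValueError(f"samples missing from matrix: {missing[:5]}")
    return values[met_ids], values[nonmet_ids]


def _directions(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direction of the location contrast (met vs non-met).

    Sign of the median difference, falling back to the mean difference
    when medians tie; ``tied`` only when both contrasts are exactly zero.
    """
    med = np.median(x, axis=1) - np.median(y, axis=1)
    mean = x.mean(axis=1) - y.mean(axis=1)
    contrast = np.where(med != 0, med, mean)
    out = np.full(x.shape[0], TIED, dtype=object)
    out[contrast > 0] = UP
    out[contrast < 0] = DOWN
    return out


def _rank_sum_pvalues(x: np.ndarray, y: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    n1, n2 = x.shape[1], y.shape[1]
    n_tot = n1 + n2
    stats_u = np.empty(x.shape[0])
    pvals = np.empty(x.shape[0])
    use_exact = method == "exact" or (method == "auto" and n_tot <= 12)
    if use_exact:
        for i in range(x.shape[0]):
            row = np.concatenate([x[i], y[i]])
            has_ties = np.unique(row).size < n_tot
            m = "asymptotic" if has_ties else "exact"
            res = stats.mannwhitneyu(
                x[i], y[i], alternative="two-sided", method=m
            )
            stats_u[i], pvals[i] = res.statistic, res.pvalue
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", axis=1
            )
        stats_u[:] = res.statistic
        pvals[:] = res.pvalue
    return stats_u, pvals


def wilcoxon_de(
    matrix: ExpressionMatrix | MethylationMatrix | pd.DataFrame,
    groups: Sequence[GroupAssignment],
    fdr_threshold: float = 0.2,
    method: str = "auto",
) -> DifferentialTable:
    """Two-sided Wilcoxon rank-sum test per feature, BH-adjusted.

    ``method`` is ``auto`` (exact when the two groups together hold at
    most 12 tie-free observations, asymptotic otherwise), ``exact`` or
    ``asymptotic``. Features constant across all grouped samples get
    p = 1 and direction ``tied``.
    """
    if isinstance(matrix, ExpressionMatrix):
        values = matrix.values
    elif isinstance(matrix, MethylationMatrix):
        values = matrix.betas
    else:
        values = matrix
    x_df, y_df = _split_columns(values, groups)
    x, y = x_df.to_numpy(float), y_df.to_numpy(float)
    n1, n2 = x.shape[1], y.shape[1]

    both = np.concatenate([x, y], axis=1)
    constant = np.ptp(both, axis=1) == 0

    stats_u, pvals = _rank_sum_pvalues(x, y, method)
    stats_u[constant] = n1 * n2 / 2.0
    pvals[constant] = 1.0
    pvals = np.clip(pvals, 0.0, 1.0)

    direction = _directions(x, y)
    direction[constant] = TIED

    table = pd.DataFrame(
        {
            "feature_id": values.index,
            "statistic": stats_u,
            "p_raw": pvals,
            "q_bh": bh_adjust(pvals),
            "direction": direction,
        }
    ).reset_index(drop=True)
    return DifferentialTable(table, "wilcoxon_rank_sum", n1, n2)


# ---------------------------------------------------------------------------
# negative-binomial conditional exact test for counts
# ---------------------------------------------------------------------------


def median_of_ratios_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference = per-gene geometric mean over genes with all-positive
    counts; falls back to library-size ratios when no such gene exists.
    """
    arr = counts.to_numpy(float)
    allpos = (arr > 0).all(axis=1)
    if allpos.any():
        logref = np.log(arr[allpos]).mean(axis=1)
        sf = np.exp(np.median(np.log(arr[allpos]) - logref[:, None], axis=0))
    else:
        lib = arr.sum(axis=0)
        if (lib == 0).any():
            raise ValueError("column with zero library size")
        sf = lib / np.exp(np.mean(np.log(lib)))
    return sf / np.exp(np.mean(np.log(sf)))


def estimate_common_dispersion(
    norm_counts: np.ndarray, is_met: np.ndarray
) -> float:
    """Common NB dispersion by pooled within-group method of moments.

    For NB, var = mu + phi * mu^2; per gene phi_hat = (s2 - mu) / mu^2
    using within-group means/variances pooled across the two groups; the
    common value is the mean over informative genes, floored at 0.
    """
    phis = []
    for mask in (is_met, ~is_met):
        sub = norm_counts[:, mask]
        if sub.shape[1] < 2:
            continue
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        ok = mu > 0
        contrib = (s2[ok] - mu[ok]) / mu[ok] ** 2
        w = np.full(contrib.shape, sub.shape[1] - 1, dtype=float)
        phis.append((contrib, w))
    if not phis:
        return 0.0
    vals = np.concatenate([c for c, _ in phis])
    wts = np.concatenate([w for _, w in phis])
    if vals.size == 0:
        return 0.0
    return float(max(0.0, np.average(vals, weights=wts)))


def _nb_group_logpmf(a: np.ndarray, n_samples: int, mu_per_sample: float, phi: float) -> np.ndarray:
    """log pmf of the sum of ``n_samples`` iid NB(mu, phi) at values ``a``.

    The sum is NB with mean n*mu and dispersion phi/n, i.e. size r = n/phi.
    """
    mean = n_samples * mu_per_sample
    if phi <= 0:
        return stats.poisson.logpmf(a, mean)
    r = n_samples / phi
    p = r / (r + mean)
    return stats.nbinom.logpmf(a, r, p)


def conditional_nb_pvalue(
    y_a: int, y_b: int, n_a: int, n_b: int, phi: float
) -> float:
    """Two-sided conditional exact p for group totals (y_a, y_b).

    Conditions on the total t = y_a + y_b; the null distribution of the
    group-A total is the NB-convolution conditional (exactly
    Binomial(t, n_a/(n_a+n_b)) when phi = 0). The two-sided p sums the
    probabilities of all group-A totals as or less likely than observed.
    """
    t = y_a + y_b
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    if phi <= 0:
        logp = stats.binom.logpmf(a, t, n_a / (n_a + n_b))
    else:
        mu = t / (n_a + n_b)
        logp = _nb_group_logpmf(a, n_a, mu, phi) + _nb_group_logpmf(
            t - a, n_b, mu, phi
        )
        logp -= logsumexp(logp)
    obs = logp[y_a]
    keep = logp <= obs + np.log(_MINLIK_GUARD)
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def nb_exact_de(
    counts: ExpressionMatrix,
    groups: Sequence[GroupAssignment],
    fdr_threshold: float = 0.2,
    dispersion: float | None = None,
) -> DifferentialTable:
    """Simplified NB exact test for two-group RNA-seq counts.

    Pipeline: median-of-ratios normalization -> common dispersion by
    method of moments (overridable via ``dispersion``) -> per-gene
    conditional exact test on rounded group totals at equalized library
    size -> BH adjustment. Direction is the sign of the normalized log2
    fold change. All-zero genes get p = 1.
    """
    if counts.scale != "raw_count":
        raise ValueError("nb_exact_de requires a raw_count matrix")
    x_df, y_df = _split_columns(counts.values, groups)
    sub = pd.concat([x_df, y_df], axis=1)
    n_a, n_b = x_df.shape[1], y_df.shape[1]
    is_met = np.arange(n_a + n_b) < n_a

    sf = median_of_ratios_factors(sub)
    norm = sub.to_numpy(float) / sf[None, :]
    phi = (
        estimate_common_dispersion(norm, is_met)
        if dispersion is None
        else float(dispersion)
    )

    y_a = np.rint(norm[:, is_met].sum(axis=1)).astype(np.int64)
    y_b = np.rint(norm[:, ~is_met].sum(axis=1)).astype(np.int64)

    pvals = np.ones(sub.shape[0])
    for i in range(sub.shape[0]):
        if y_a[i] + y_b[i] > 0:
            pvals[i] = conditional_nb_pvalue(
                int(y_a[i]), int(y_b[i]), n_a, n_b, phi
            )

    rate_a = y_a / n_a
    rate_b = y_b / n_b
    lfc = np.log2((rate_a + 0.125) / (rate_b + 0.125))
    direction = np.full(sub.shape[0], TIED, dtype=object)
    direction[rate_a > rate_b] = UP
    direction[rate_a < rate_b] = DOWN

    table = pd.DataFrame(
        {
            "feature_id": sub.index,
            "statistic": lfc,
            "p_raw": pvals,
            "q_bh": bh_adjust(pvals),
            "direction": direction,
        }
    ).reset_index(drop=True)
    t = DifferentialTable(table, "nb_conditional_exact", n_a, n_b)
    t.dispersion = phi
    return t


def fisher_binary_de(
    calls: BinaryAlterationMatrix,
    groups: Sequence[GroupAssignment],
    fdr_threshold: float = 0.2,
) -> DifferentialTable:
    """Two-sided Fisher's exact test per binary feature, BH-adjusted."""
    x_df, y_df = _split_columns(calls.calls, groups)
    x = x_df.to_numpy(int)
    y = y_df.to_numpy(int)
    n_a, n_b = x.shape[1], y.shape[1]
    a = x.sum(axis=1)  # altered in met
    c = y.sum(axis=1)  # altered in non-met
    pvals = np.empty(x.shape[0])
    stats_or = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        tab = [[int(a[i]), n_a - int(a[i])], [int(c[i]), n_b - int(c[i])]]
        odds, p = stats.fisher_exact(tab, alternative="two-sided")
        stats_or[i], pvals[i] = odds, p
    rate_a, rate_b = a / n_a, c / n_b
    direction = np.full(x.shape[0], TIED, dtype=object)
    direction[rate_a > rate_b] = UP
    direction[rate_a < rate_b] = DOWN
    table = pd.DataFrame(
        {
            "feature_id": calls.calls.index,
            "statistic": stats_or,
            "p_raw": pvals,
            "q_bh": bh_adjust(pvals),
            "direction": direction,
        }
    ).reset_index(drop=True)
    return DifferentialTable(table, "fisher_exact", n_a, n_b)


# ---------------------------------------------------------------------------
# gene-level differential-methylation calls
# ---------------------------------------------------------------------------

HYPER = "hypermethylated"
HYPO = "hypomethylated"
BIDIRECTIONAL = "excluded_bidirectional"


def call_dm_genes(
    dm_loci: pd.DataFrame,
    methylation: MethylationMatrix,
    groups: Sequence[GroupAssignment],
) -> pd.DataFrame:
    """Aggregate significant DM loci into gene-level methylation calls.

    ``dm_loci`` is the significant subset of a locus-level
    :class:`DifferentialTable` (column ``feature_id``). A locus is
    hypermethylated when its mean beta in the metastasis group exceeds
    the non-metastasis mean. A gene with at least one DM locus becomes a
    DM gene; genes carrying both hyper- and hypomethylated loci are
    flagged ``excluded_bidirectional``. Mean betas per gene are averaged
    over that gene's DM loci.
    """
    loci = list(dm_loci["feature_id"])
    pmap = methylation.promoter_map
    mapped = set(pmap["locus_id"])
    missing = [l for l in loci if l not in mapped]
    if missing:
        raise ValueError(
            f"DM loci absent from promoter map: {missing[:5]}"
        )
    if not loci:
        return pd.DataFrame(
            columns=[
                "gene_id",
                "n_dm_loci",
                "call",
                "mean_beta_met",
                "mean_beta_nonmet",
            ]
        )
    met_ids, nonmet_ids = met_nonmet_ids(groups)
    betas = methylation.betas.loc[loci]
    mean_met = betas[met_ids].mean(axis=1)
    mean_non = betas[nonmet_ids].mean(axis=1)
    locus_call = np.where(mean_met > mean_non, HYPER, HYPO)

    per_locus = pd.DataFrame(
        {
            "locus_id": loci,
            "call": locus_call,
            "mean_beta_met": mean_met.to_numpy(),
            "mean_beta_nonmet": mean_non.to_numpy(),
        }
    ).merge(pmap, on="locus_id")

    rows = []
    for gene, grp in per_locus.groupby("gene_id", sort=True):
        calls = set(grp["call"])
        call = BIDIRECTIONAL if len(calls) > 1 else next(iter(calls))
        rows.append(
            (
                gene,
                len(grp),
                call,
                float(grp["mean_beta_met"].mean()),
                float(grp["mean_beta_nonmet"].mean()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "n_dm_loci",
            "call",
            "mean_beta_met",
            "mean_beta_nonmet",
        ],
    )
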