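"""Concordance scoring between signed gene lists, with a binomial null.

Two differential-expression analyses that share *k* genes, of which *s*
agree in direction (up/down), get a concordance score of 100*s/k percent.
Under the null that the two analyses are unrelated, each shared gene
agrees in direction with probability Pe (0.5 for a symmetric up/down
split), so the chance of observing at least *s* agreements is the
upper-tail cumulative Binomial(k, Pe) probability. The same machinery
scores the agreement between promoter-methylation direction and
expression direction (hypermethylated genes vs down-regulation,
hypomethylated vs up-regulation).

Tail probabilities are additionally reported on the log10 scale: for
large k the upper tail can fall below the smallest positive float even
though its logarithm is perfectly representable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .differential import DOWN, HYPER, HYPO, TIED, UP, DifferentialTable

__all__ = [
    "SignedGeneList",
    "ConcordanceResult",
    "binomial_upper_tail",
    "binomial_upper_tail_exact",
    "binomial_upper_tail_log10",
    "concordance",
    "methylation_expression_concordance",
    "signed_list_from_differential",
]


@dataclass(frozen=True)
class SignedGeneList:
    """Genes with an up/down direction label, from one comparison."""

    label: str
    signs: Mapping[str, str]  # gene_id -> "up" | "down"

    def __post_init__(self) -> None:
        bad = {s for s in self.signs.values() if s not in ("up", "down")}
        if bad:
            raise ValueError(f"invalid signs in {self.label!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.signs)


def signed_list_from_differential(
    dt: DifferentialTable, fdr_threshold: float, label: str
) -> SignedGeneList:
    """Significant features as a signed list; tied features are dropped."""
    sig = dt.significant(fdr_threshold)
    signs = {
        str(r.feature_id): ("up" if r.direction == UP else "down")
        for r in sig.itertuples(index=False)
        if r.direction != TIED
    }
    return SignedGeneList(label, signs)


def _check_pe(pe: float) -> None:
    if not (0.0 < pe < 1.0):
        raise ValueError(f"Pe must lie strictly in (0, 1), got {pe}")


def binomial_upper_tail(s: int, k: int, pe: float = 0.5) -> float:
    """P(X >= s) for X ~ Binomial(k, pe); underflows to 0 for huge tails."""
    _check_pe(pe)
    if s <= 0:
        return 1.0
    if s > k:
        return 0.0
    return float(stats.binom.sf(s - 1, k, pe))


def binomial_upper_tail_exact(s: int, k: int, pe: Fraction | float = Fraction(1, 2)) -> Fraction:
    """P(X >= s) in exact rational arithmetic (practical for k <= ~64).

    Oracle mode for auditing the float tail; ``pe`` is coerced to an
    exact fraction.
    """
    pe = Fraction(pe)
    if not (0 < pe < 1):
        raise ValueError(f"Pe must lie strictly in (0, 1), got {pe}")
    if s <= 0:
        return Fraction(1)
    if s > k:
        return Fraction(0)
    return sum(
        Fraction(math.comb(k, i)) * pe**i * (1 - pe) ** (k - i)
        for i in range(s, k + 1)
    )


def binomial_upper_tail_log10(s: int, k: int, pe: float = 0.5) -> float:
    """log10 of P(X >= s), summed in log space (safe for extreme tails)."""
    _check_pe(pe)
    if s <= 0:
        return 0.0
    if s > k:
        return -math.inf
    i = np.arange(s, k + 1)
    return float(logsumexp(stats.binom.logpmf(i, k, pe)) / math.log(10.0))


@dataclass(frozen=True)
class ConcordanceResult:
    """(k, s, score, binomial p) for one pair of signed lists.

    ``score`` and ``p_binomial`` are None (reported as NA) when the lists
    share no genes; ``sources`` holds the two list labels, sorted, so the
    result is symmetric in its arguments field for field.
    """

    k: int
    s: int
    score: float | None
    p_binomial: float | None
    log10_p: float | None
    pe: float
    concordant_ids: tuple[str, ...]
    discordant_ids: tuple[str, ...]
    sources: tuple[str, str] = ("", "")

    @property
    def score_display(self) -> float | None:
        """Score rounded to one decimal, the conventional display form."""
        return None if self.score is None else round(self.score, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source_a": self.sources[0],
                    "source_b": self.sources[1],
                    "k_shared": self.k,
                    "s_concordant": self.s,
                    "score_pct": np.nan if self.score is None else self.score,
                    "p_binomial": np.nan
                    if self.p_binomial is None
                    else self.p_binomial,
                    "log10_p": np.nan if self.log10_p is None else self.log10_p,
                    "pe": self.pe,
                }
            ]
        )


def concordance(
    list_a: SignedGeneList, list_b: SignedGeneList, pe: float = 0.5
) -> ConcordanceResult:
    """Concordance score and binomial significance for two signed lists.

    k counts genes present in both lists; s counts those whose directions
    agree; score = 100*s/k. Significance is the upper-tail cumulative
    Binomial(k, pe) probability of at least s agreements. Symmetric in
    its two arguments. k = 0 yields NA score and p.
    """
    _check_pe(pe)
    shared = sorted(set(list_a.signs) & set(list_b.signs))
    concordant = tuple(g for g in shared if list_a.signs[g] == list_b.signs[g])
    discordant = tuple(g for g in shared if list_a.signs[g] != list_b.signs[g])
    k, s = len(shared), len(concordant)
    if k == 0:
        return ConcordanceResult(
            0, 0, None, None, None, pe, (), (), tuple(sorted([list_a.label, list_b.label]))
        )
    return ConcordanceResult(
        k,
        s,
        100.0 * s / k,
        binomial_upper_tail(s, k, pe),
        binomial_upper_tail_log10(s, k, pe),
        pe,
        concordant,
        discordant,
        tuple(sorted([list_a.label, list_b.label])),
    )


def methylation_expression_concordance(
    dm_genes: pd.DataFrame,
    de: SignedGeneList,
    mode: str,
    pe: float = 0.5,
) -> ConcordanceResult:
    """Agreement between promoter-methylation and expression direction.

    ``mode="hyper_vs_down"``: k = hypermethylated DM genes that are also
    differentially expressed, s = those down-regulated in the metastasis
    group (promoter hypermethylation silencing the gene).
    ``mode="hypo_vs_up"`` is the symmetric case. Bidirectional DM genes
    must have been excluded upstream and are ignored here.
    """
    if mode == "hyper_vs_down":
        meth_call, expr_sign = HYPER, "down"
    elif mode == "hypo_vs_up":
        meth_call, expr_sign = HYPO, "up"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    genes = set(dm_genes.loc[dm_genes["call"] == meth_call, "gene_id"])
    meth_list = SignedGeneList(
        f"methylation_{meth_call}", {g: expr_sign for g in genes}
    )
    res = concordance(meth_list, de, pe=pe)
    return ConcordanceResult(
        res.k,
        res.s,
        res.score,
        res.p_binomial,
        res.log10_p,
        res.pe,
        res.concordant_ids,
        res.discordant_ids,
        (meth_list.label, de.label),
    )
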