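"""Compositional divergence of whole-genome-duplication (ohnolog) pairs.

Budding yeast retains several hundred duplicated gene pairs from an ancient
whole-genome duplication.  If an amino acid is costly in highly expressed
proteins, the higher-expressed member of a pair should tend to carry fewer
copies of it.  Each pair is classified, for a chosen amino acid, as

* Class A — the higher-expressed member has strictly *fewer* residues,
* Class B — the higher-expressed member has strictly *more* residues,

with pairs tied on the residue count, or missing expression for either
member, excluded.  Biased retention (more A than B) is assessed with an
exact binomial sign test against p = 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .composition import STANDARD_AAS

LABEL_A = "A"
LABEL_B = "B"
LABEL_TIE = "excluded_tie"
LABEL_MISSING = "excluded_missing"


@dataclass(frozen=True)
class OhnologPair:
    """One duplicated gene pair with per-member residue counts and expression.

    ``aa_counts1``/``aa_counts2`` map one-letter amino-acid codes to counts;
    ``expression1``/``expression2`` are translation-rate proxies (arbitrary
    nonnegative units, e.g. Ribo-Seq footprint density), ``None`` if missing.
    """

    pair_id: str
    gene1: str
    gene2: str
    aa_counts1: Mapping[str, int]
    aa_counts2: Mapping[str, int]
    expression1: float | None = None
    expression2: float | None = None

    def __post_init__(self) -> None:
        if self.gene1 == self.gene2:
            raise ValueError(f"{self.pair_id}: pair members must be distinct genes")
        for counts in (self.aa_counts1, self.aa_counts2):
            if any(v < 0 for v in counts.values()):
                raise ValueError(f"{self.pair_id}: negative amino-acid count")


@dataclass(frozen=True)
class PairClassification:
    pair_id: str
    amino_acid: str
    label: str  # one of A / B / excluded_tie / excluded_missing


@dataclass
class DivergenceSummary:
    """Tally and sign test of one amino acid over a set of ohnolog pairs."""

    amino_acid: str
    n_A: int
    n_B: int
    n_tie: int
    n_missing: int
    log2_ratio_B_over_A: float
    ratio_defined: bool
    p_one_sided: float | None
    p_two_sided: float | None = None

    @property
    def n_classified(self) -> int:
        return self.n_A + self.n_B


def classify_pair(pair: OhnologPair, amino_acid: str = "C") -> PairClassification:
    """Label one pair for one amino acid (A / B / tie / missing).

    Symmetric under swapping the member order.  Equal expression values are
    treated as missing information (ties in a continuous rate carry no sign).
    """
    try:
        c1 = pair.aa_counts1[amino_acid]
        c2 = pair.aa_counts2[amino_acid]
    except KeyError:
        raise ValueError(
            f"{pair.pair_id}: no {amino_acid!r} count for one or both members"
        ) from None
    if pair.expression1 is None or pair.expression2 is None or (
        not math.isfinite(pair.expression1) or not math.isfinite(pair.expression2)
    ):
        label = LABEL_MISSING
    elif c1 == c2:
        label = LABEL_TIE
    elif pair.expression1 == pair.expression2:
        label = LABEL_MISSING
    else:
        hi_count = c1 if pair.expression1 > pair.expression2 else c2
        lo_count = c2 if pair.expression1 > pair.expression2 else c1
        label = LABEL_A if hi_count < lo_count else LABEL_B
    return PairClassification(pair.pair_id, amino_acid, label)


def exact_binomial_test(n_A: int, n_B: int, alternative: str = "greater") -> float:
    """Exact binomial sign test of n_A successes in n_A + n_B trials at p = 1/2.

    ``alternative='greater'`` returns P(X >= n_A); ``'two-sided'`` doubles
    the smaller tail, capped at 1.
    """
    if n_A < 0 or n_B < 0:
        raise ValueError("counts must be nonnegative")
    n = n_A + n_B
    if n == 0:
        raise ValueError("sign test undefined with zero classified pairs")
    upper = float(stats.binom.sf(n_A - 1, n, 0.5))  # P(X >= n_A)
    lower = float(stats.binom.cdf(n_A, n, 0.5))  # P(X <= n_A)
    if alternative == "greater":
        return upper
    if alternative == "less":
        return lower
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"unknown alternative: {alternative!r}")


def divergence_summary(
    pairs: Iterable[OhnologPair],
    amino_acid: str = "C",
    haldane: bool = False,
) -> DivergenceSummary:
    """Classify all pairs for one amino acid, tally, and run the sign test.

    ``log2_ratio_B_over_A`` follows the convention of reporting B/A, so a
    deficit of the amino acid in higher-expressed members gives a negative
    value.  With an empty class the ratio is signed infinity and flagged
    undefined unless ``haldane`` adds a +0.5 continuity correction to both
    counts.
    """
    tallies = {LABEL_A: 0, LABEL_B: 0, LABEL_TIE: 0, LABEL_MISSING: 0}
    for pair in pairs:
        tallies[classify_pair(pair, amino_acid).label] += 1
    n_A, n_B = tallies[LABEL_A], tallies[LABEL_B]

    if haldane:
        log2_ratio = math.log2((n_B + 0.5) / (n_A + 0.5))
        defined = True
    elif n_A > 0 and n_B > 0:
        log2_ratio = math.log2(n_B / n_A)
        defined = True
    elif n_A == 0 and n_B == 0:
        log2_ratio = math.nan
        defined = False
    else:
        log2_ratio = math.inf if n_A == 0 else -math.inf
        defined = False

    if n_A + n_B >= 1:
        p1 = exact_binomial_test(n_A, n_B, "greater")
        p2 = exact_binomial_test(n_A, n_B, "two-sided")
    else:
        p1 = p2 = None
    return DivergenceSummary(
        amino_acid=amino_acid,
        n_A=n_A,
        n_B=n_B,
        n_tie=tallies[LABEL_TIE],
        n_missing=tallies[LABEL_MISSING],
        log2_ratio_B_over_A=log2_ratio,
        ratio_defined=defined,
        p_one_sided=p1,
        p_two_sided=p2,
    )


def divergence_panel(
    pairs: Sequence[OhnologPair],
    amino_acids: str | Sequence[str] = STANDARD_AAS,
    haldane: bool = False,
) -> pd.DataFrame:
    """Per-amino-acid divergence summaries (one row per amino acid).

    Reproduces the 20-residue panel: log2(B/A) ratios with their unadjusted
    sign-test p-values.
    """
    rows = []
    for aa in amino_acids:
        s = divergence_summary(pairs, aa, haldane=haldane)
        rows.append(
            {
                "amino_acid": aa,
                "n_A": s.n_A,
                "n_B": s.n_B,
                "n_tie": s.n_tie,
                "n_missing": s.n_missing,
                "log2_ratio_B_over_A": s.log2_ratio_B_over_A,
                "ratio_defined": s.ratio_defined,
                "p_one_sided": s.p_one_sided,
                "p_two_sided": s.p_two_sided,
            }
        )
    return pd.DataFrame(rows).set_index("amino_acid")


@dataclass
class PropensityEstimate:
    """Class-A proportion among classified pairs with an exact CI."""

    estimate: float
    ci_low: float
    ci_high: float
    n_A: int
    n_B: int
    confidence: float = 0.95


def estimate_class_a_propensity(
    pairs: Iterable[OhnologPair] | None = None,
    amino_acid: str = "C",
    confidence: float = 0.95,
    counts: tuple[int, int] | None = None,
) -> PropensityEstimate:
    """Estimate P(Class A) = n_A / (n_A + n_B) with a Clopper–Pearson interval.

    Either ``pairs`` (classified for ``amino_acid``) or precomputed
    ``counts=(n_A, n_B)`` may be supplied.
    """
    if counts is not None:
        n_A, n_B = counts
    elif pairs is not None:
        s = divergence_summary(pairs, amino_acid)
        n_A, n_B = s.n_A, s.n_B
    else:
        raise ValueError("supply either pairs or counts")
    n = n_A + n_B
    if n == 0:
        raise ValueError("no classified (non-tie) pairs")
    res = stats.binomtest(n_A, n, 0.5)
    ci = res.proportion_ci(confidence_level=confidence, method="exact")
    return PropensityEstimate(
        estimate=n_A / n,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_A=n_A,
        n_B=n_B,
        confidence=confidence,
    )


def pairs_from_tables(
    pair_table: pd.DataFrame,
    aa_counts: pd.DataFrame,
    expression: Mapping[str, float] | pd.Series | None = None,
) -> list[OhnologPair]:
    """Assemble ``OhnologPair`` objects from tabular inputs.

    ``pair_table`` needs columns ``pair_id``, ``gene1``, ``gene2``;
    ``aa_counts`` is indexed by gene id with one column per amino acid (as
    produced by :func:`yeastburden.composition.aa_counts_table`);
    ``expression`` maps gene id to a translation-rate proxy.
    """
    if expression is None:
        expression = {}
    elif isinstance(expression, pd.Series):
        expression = expression.to_dict()
    pairs = []
    for row in pair_table.itertuples(index=False):
        g1, g2 = row.gene1, row.gene2
        e1 = expression.get(g1)
        e2 = expression.get(g2)
        pairs.append(
            OhnologPair(
                pair_id=str(row.pair_id),
                gene1=g1,
                gene2=g2,
                aa_counts1=aa_counts.loc[g1].to_dict(),
                aa_counts2=aa_counts.loc[g2].to_dict(),
                expression1=None if e1 is None or pd.isna(e1) else float(e1),
                expression2=None if e2 is None or pd.isna(e2) else float(e2),
            )
        )
    return pairs
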