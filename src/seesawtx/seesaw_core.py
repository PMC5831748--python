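"""Seesaw gene calling.

A "seesaw" gene changes expression in opposite directions after the two
dauer-inducing stresses: its postdauer/control (PD/CON) log2 fold change is
positive in one contrast (pheromone, "Phe") and negative in the other
(starvation, "Stv"). Significant seesaw calls require FDR < alpha in both
contrasts; trend calls require only a >= min_fold inverse change.

Quadrant orientation (joint sign of the two fold changes):

* Q1: Phe up,   Stv down   (the canonical seesaw direction of CSR-1 targets)
* Q2: Phe down, Stv down
* Q3: Phe down, Stv up     (the inverse seesaw direction)
* Q4: Phe up,   Stv up
* BOUNDARY: either fold change exactly 0 (excluded from quadrant tallies)
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

QUADRANTS = ("Q1", "Q2", "Q3", "Q4", "BOUNDARY")


class MutantDisruptionCategory(enum.Enum):
    """How a mutant disrupts (or retains) a wild-type seesaw call.

    ``INVERTED_BOTH`` is the retained-seesaw-with-inverted-orientation case:
    the mutant is significant in both conditions with opposite signs, but the
    orientation is flipped relative to wild-type.
    """

    INVERTED_BOTH = "inverted_both"
    FOLLOWS_PHE = "follows_phe"
    FOLLOWS_STV = "follows_stv"
    LOSS_OF_SIGNIFICANCE = "loss_of_significance"
    RETAINED_SEESAW_SAME = "retained_seesaw_same"


@dataclass(frozen=True)
class SeesawCallSet:
    """Directional seesaw calls plus same-direction overlaps at one alpha."""

    alpha: float
    up_down: frozenset  # Phe up :: Stv down
    down_up: frozenset  # Phe down :: Stv up
    shared_up: frozenset
    shared_down: frozenset
    universe: frozenset

    @property
    def seesaw(self) -> frozenset:
        return self.up_down | self.down_up

    def __post_init__(self):
        assert not (self.up_down & self.down_up)


@dataclass(frozen=True)
class TrendCallSet:
    min_fold: float
    up_down: frozenset
    down_up: frozenset
    universe: frozenset


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input.

    q_i = min over ranks j >= rank(i) of p_(j) * m / j, clipped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_quadrant(log2fc_phe: float, log2fc_stv: float) -> str:
    """Quadrant label for a single (Phe, Stv) fold-change pair."""
    if not (math.isfinite(log2fc_phe) and math.isfinite(log2fc_stv)):
        raise ValueError("fold changes must be finite")
    if log2fc_phe == 0 or log2fc_stv == 0:
        return "BOUNDARY"
    if log2fc_phe > 0:
        return "Q1" if log2fc_stv < 0 else "Q4"
    return "Q3" if log2fc_stv > 0 else "Q2"


def quadrant_labels(de_phe: pd.DataFrame, de_stv: pd.DataFrame) -> pd.Series:
    """Vectorized quadrant labels over the common gene universe."""
    m = _merge(de_phe, de_stv)
    phe, stv = m["log2fc_phe"].to_numpy(), m["log2fc_stv"].to_numpy()
    if not (np.isfinite(phe).all() and np.isfinite(stv).all()):
        raise ValueError("fold changes must be finite")
    lab = np.full(len(m), "BOUNDARY", dtype=object)
    lab[(phe > 0) & (stv < 0)] = "Q1"
    lab[(phe < 0) & (stv < 0)] = "Q2"
    lab[(phe < 0) & (stv > 0)] = "Q3"
    lab[(phe > 0) & (stv > 0)] = "Q4"
    return pd.Series(lab, index=m["gene_id"].to_numpy(), name="quadrant")


def _merge(de_phe: pd.DataFrame, de_stv: pd.DataFrame) -> pd.DataFrame:
    m = de_phe.merge(de_stv, on="gene_id", suffixes=("_phe", "_stv"))
    if m.empty:
        raise ValueError("DE tables share no genes (disjoint universes)")
    return m


def call_significant_seesaw(de_phe: pd.DataFrame, de_stv: pd.DataFrame,
                            alpha: float = 0.05, loose: bool = False) -> SeesawCallSet:
    """Call significant seesaw genes at an FDR cutoff per contrast.

    Default (strict) rule: FDR < alpha in *both* contrasts with opposite
    fold-change signs. The non-default ``loose`` variant requires FDR < alpha
    in at least one contrast plus an opposite-signed fold change in the other.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    m = _merge(de_phe, de_stv)
    gid = m["gene_id"].to_numpy()
    phe, stv = m["log2fc_phe"].to_numpy(), m["log2fc_stv"].to_numpy()
    qp, qs = m["fdr_phe"].to_numpy(), m["fdr_stv"].to_numpy()
    if loose:
        sig = (qp < alpha) | (qs < alpha)
    else:
        sig = (qp < alpha) & (qs < alpha)
    both_sig = (qp < alpha) & (qs < alpha)
    return SeesawCallSet(
        alpha=alpha,
        up_down=frozenset(gid[sig & (phe > 0) & (stv < 0)]),
        down_up=frozenset(gid[sig & (phe < 0) & (stv > 0)]),
        shared_up=frozenset(gid[both_sig & (phe > 0) & (stv > 0)]),
        shared_down=frozenset(gid[both_sig & (phe < 0) & (stv < 0)]),
        universe=frozenset(gid),
    )


def trend_seesaw(de_phe: pd.DataFrame, de_stv: pd.DataFrame,
                 min_fold: float = 2.0) -> TrendCallSet:
    """Directional >= min_fold inverse-trend sets, ignoring significance.

    Threshold is inclusive: |log2fc| >= log2(min_fold) in both contrasts with
    opposite signs.
    """
    if min_fold <= 1:
        raise ValueError("min_fold must exceed 1")
    thr = math.log2(min_fold)
    m = _merge(de_phe, de_stv)
    gid = m["gene_id"].to_numpy()
    phe, stv = m["log2fc_phe"].to_numpy(), m["log2fc_stv"].to_numpy()
    return TrendCallSet(
        min_fold=min_fold,
        up_down=frozenset(gid[(phe >= thr) & (stv <= -thr)]),
        down_up=frozenset(gid[(phe <= -thr) & (stv >= thr)]),
        universe=frozenset(gid),
    )


def percentage_report(numerator: int, denominator: int, decimals: int = 0) -> float:
    """100*numerator/denominator rounded half-away-from-zero to ``decimals``.

    This is the reporting arithmetic used for all printed percentages
    (e.g. 249/441 -> 56, 12454/18570 at 1 decimal -> 67.1).
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    x = 100.0 * numerator / denominator
    scale = 10 ** decimals
    rounded = math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)
    return rounded if decimals > 0 else int(rounded)


@dataclass
class MutantDisruptionResult:
    categories: pd.Series  # gene_id -> MutantDisruptionCategory
    frequency: pd.DataFrame  # category, count, percent

    def percent(self, category: MutantDisruptionCategory) -> float:
        row = self.frequency.loc[self.frequency["category"] == category.value]
        return float(row["percent"].iloc[0]) if len(row) else 0.0


def mutant_disruption_classify(wt_orientation: dict, mut_de_phe: pd.DataFrame,
                               mut_de_stv: pd.DataFrame, alpha: float = 0.05,
                               genes=None) -> MutantDisruptionResult:
    """Categorize how a mutant disrupts wild-type seesaw calls.

    ``wt_orientation`` maps gene_id -> (sign_phe, sign_stv) for the wild-type
    call (signs +1/-1, opposite by construction). Precedence per gene:

    1. mutant significant in both conditions with opposite signs ->
       ``RETAINED_SEESAW_SAME`` if the orientation matches wild-type, else
       ``INVERTED_BOTH`` (retained seesaw, inverted orientation);
    2. mutant significant in both with equal signs -> ``FOLLOWS_PHE`` if the
       shared sign equals the wild-type Phe sign, else ``FOLLOWS_STV``;
    3. otherwise ``LOSS_OF_SIGNIFICANCE``.
    """
    m = _merge(mut_de_phe, mut_de_stv).set_index("gene_id")
    if genes is None:
        genes = [g for g in m.index if g in wt_orientation]
    cats = {}
    for g in genes:
        if g not in wt_orientation:
            raise KeyError(f"gene {g!r} has no wild-type seesaw call")
        if g not in m.index:
            raise KeyError(f"gene {g!r} missing from mutant tables")
        wt_phe, wt_stv = wt_orientation[g]
        if wt_phe * wt_stv >= 0:
            raise ValueError(f"wild-type call for {g!r} is not a seesaw orientation")
        row = m.loc[g]
        sp = np.sign(row["log2fc_phe"])
        ss = np.sign(row["log2fc_stv"])
        sig_both = row["fdr_phe"] < alpha and row["fdr_stv"] < alpha
        if sig_both and sp * ss < 0:
            cats[g] = (MutantDisruptionCategory.RETAINED_SEESAW_SAME
                       if (sp == wt_phe and ss == wt_stv)
                       else MutantDisruptionCategory.INVERTED_BOTH)
        elif sig_both and sp == ss and sp != 0:
            cats[g] = (MutantDisruptionCategory.FOLLOWS_PHE
                       if sp == wt_phe else MutantDisruptionCategory.FOLLOWS_STV)
        else:
            cats[g] = MutantDisruptionCategory.LOSS_OF_SIGNIFICANCE
    series = pd.Series(cats, name="category")
    freq = category_frequency(list(cats.values()))
    return MutantDisruptionResult(categories=series, frequency=freq)


def category_frequency(categories) -> pd.DataFrame:
    """Counts and rounded percentages per disruption category."""
    total = len(categories)
    rows = []
    for cat in MutantDisruptionCategory:
        n = sum(1 for c in categories if c is cat)
        if n:
            rows.append({"category": cat.value, "count": n,
                         "percent": percentage_report(n, total, 0)})
    return pd.DataFrame(rows, columns=["category", "count", "percent"])
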