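"""Sister-clade contrasts in host diversity versus species richness.

The oscillation hypothesis predicts that, of two sister clades, the one with
the more diverse host use should contain more species. Each contrast pairs
two (putative) sister clades differing in host diversity — the number of
distinct plant orders recorded across the clade — by at least a minimum
number of orders, so that weak differences (which are the most sensitive to
incomplete host records) never enter the test. The comparison statistics
are:

* a two-tailed exact sign test on the number of contrasts in the predicted
  direction (more species on the higher-diversity side);
* a one-sample t-test on the log10 relative richness values
  ``log10(R1/R2)`` against zero (positive contrasts give positive logs);
* a concordance sign test asking whether the higher-diversity side also
  holds the single most polyphagous species of the pair.

Contrast construction is a deterministic greedy post-order sweep: at each
binary node whose two daughter clades contain no already-used taxon, the
daughters form a candidate pair; if their host-diversity difference (on the
union of host-order sets per side) meets the threshold the pair is emitted,
otherwise the daughters simply merge at the next ancestor. Merging thus
proceeds strictly by tree adjacency — never by diversity-sorted cherry
picking — which keeps the selection free of outcome-driven bias. Emitted
pairs never share taxa, so contrasts are phylogenetically independent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DegenerateDataError, InputError
from .hostdata import GenusTraits
from .treeio import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastPair",
    "ContrastSet",
    "PairedTResult",
    "build_contrasts",
    "relative_richness",
    "sign_test",
    "paired_log_t",
    "concordance_most_polyphagous",
    "hd_maxpoly_correlation",
]


@dataclass(frozen=True)
class ContrastPair:
    """One pair of putative sister clades; side 1 is the higher-diversity side.

    ``max_poly_side`` records which side holds the single most polyphagous
    species (1, 2, or "tie"); ``None`` when polyphagy data are unavailable.
    """

    clade1: frozenset[str]
    clade2: frozenset[str]
    hd1: int
    hd2: int
    r1: int
    r2: int
    max_poly_side: int | str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.hd1 <= self.hd2:
            raise InputError(
                f"{self.name or self.clade1}: side 1 must be the higher-HD "
                f"side (hd1={self.hd1}, hd2={self.hd2})"
            )
        if self.r1 < 1 or self.r2 < 1:
            raise InputError("richness must be >= 1 on both sides")

    @property
    def rel(self) -> float:
        """Relative richness R1/R2."""
        return self.r1 / self.r2

    @property
    def log10rel(self) -> float:
        return math.log10(self.rel)

    @property
    def positive(self) -> bool:
        """Contrast in the predicted direction: more species on side 1."""
        return self.r1 > self.r2

    @property
    def tied(self) -> bool:
        return self.r1 == self.r2


@dataclass
class ContrastSet:
    """Phylogenetically independent contrasts under one HD-difference rule."""

    pairs: list[ContrastPair]
    min_hd_diff: int = 1

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.pairs:
            taxa = p.clade1 | p.clade2
            reused = taxa & seen
            if reused:
                raise InputError(f"taxa reused across pairs: {sorted(reused)}")
            seen |= taxa
            if p.hd1 - p.hd2 < self.min_hd_diff:
                raise InputError(
                    f"{p.name or sorted(p.clade1)}: HD difference "
                    f"{p.hd1 - p.hd2} below minimum {self.min_hd_diff}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def k_positive(self) -> int:
        return sum(p.positive for p in self.pairs)

    def n_untied(self) -> int:
        return sum(not p.tied for p in self.pairs)

    def to_frame(self) -> pd.DataFrame:
        """Table with the conventional contrast columns."""
        return pd.DataFrame(
            {
                "Sister pairing": [p.name or "-".join(
                    ["+".join(sorted(p.clade1)), "+".join(sorted(p.clade2))]
                ) for p in self.pairs],
                "HD 1": [p.hd1 for p in self.pairs],
                "HD 2": [p.hd2 for p in self.pairs],
                "R1": [p.r1 for p in self.pairs],
                "R2": [p.r2 for p in self.pairs],
                "Sign": ["Pos" if p.positive else ("Tie" if p.tied else "Neg")
                         for p in self.pairs],
                "Rel.": [p.rel for p in self.pairs],
                "Log": [p.log10rel for p in self.pairs],
            }
        )


@dataclass(frozen=True)
class PairedTResult:
    """One-sample t-test of the mean log relative richness against zero."""

    mean: float
    sd: float
    se: float
    t: float
    df: int
    p_two_tailed: float


def build_contrasts(
    tree: PhyloTree,
    traits: Iterable[GenusTraits],
    min_hd_diff: int = 3,
) -> ContrastSet:
    """Greedy post-order construction of independent sister-clade contrasts.

    Every tip of the tree must have a trait entry. Binary nodes whose two
    daughter clades are entirely unused form candidates; a candidate is
    emitted iff the host-diversity difference between the daughter clades
    (each side's diversity = union of its taxa's host-order sets) is at
    least ``min_hd_diff``. Polytomous candidates are skipped with a warning.
    Setting ``min_hd_diff=1`` gives the "any sister pair with any
    difference" variant.
    """
    if min_hd_diff < 1:
        raise InputError("min_hd_diff must be >= 1")
    by_taxon = {t.taxon: t for t in traits}
    missing = [lab for lab in tree.tip_labels if lab not in by_taxon]
    if missing:
        raise InputError(f"tips without trait entries: {missing}")

    used: set[str] = set()
    pairs: list[ContrastPair] = []
    for v in range(tree.n_nodes):
        kids = tree.children[v]
        if not kids:
            continue
        if len(kids) != 2:
            logger.warning(
                "polytomy at node %d (%d children): skipped as a contrast "
                "candidate", v, len(kids)
            )
            continue
        side_a = tree.clade_tips(kids[0])
        side_b = tree.clade_tips(kids[1])
        if (side_a | side_b) & used:
            continue
        stats_ = []
        for side in (side_a, side_b):
            orders: set[str] = set()
            for lab in side:
                orders |= by_taxon[lab].host_orders
            stats_.append(
                (
                    len(orders),
                    sum(by_taxon[lab].n_species for lab in side),
                    max(by_taxon[lab].max_polyphagy for lab in side),
                    side,
                )
            )
        stats_.sort(key=lambda s: -s[0])
        (hd1, r1, mp1, c1), (hd2, r2, mp2, c2) = stats_
        if hd1 - hd2 < min_hd_diff:
            continue
        if mp1 > mp2:
            mp_side: int | str = 1
        elif mp2 > mp1:
            mp_side = 2
        else:
            mp_side = "tie"
        pairs.append(
            ContrastPair(
                clade1=frozenset(c1),
                clade2=frozenset(c2),
                hd1=hd1,
                hd2=hd2,
                r1=r1,
                r2=r2,
                max_poly_side=mp_side,
            )
        )
        used |= side_a | side_b
    return ContrastSet(pairs=pairs, min_hd_diff=min_hd_diff)


def relative_richness(pair: ContrastPair) -> tuple[float, float]:
    """(R1/R2, log10(R1/R2)) for one contrast."""
    return pair.rel, pair.log10rel


def sign_test(k_positive: int, n: int) -> float:
    """Two-tailed exact sign test: P under Binomial(n, 1/2).

    Ties must already be excluded from ``n``. Equals
    ``min(1, 2*min(P(X<=k), P(X>=k)))`` for the symmetric null.
    """
    if n < 1:
        raise DegenerateDataError("sign test undefined for n = 0")
    if not 0 <= k_positive <= n:
        raise InputError(f"k={k_positive} outside [0, {n}]")
    return float(scipy.stats.binomtest(k_positive, n, 0.5).pvalue)


def paired_log_t(contrast_set: ContrastSet) -> PairedTResult:
    """One-sample t of the log10 relative richness values against zero.

    Tests whether the average log richness ratio across contrasts is
    significantly above zero — the parametric companion to the sign test.
    Invariant to contrast order and to rescaling all richness values by a
    common positive constant.
    """
    logs = np.array([p.log10rel for p in contrast_set.pairs])
    n = len(logs)
    if n < 2:
        raise DegenerateDataError("paired t-test needs at least 2 contrasts")
    sd = float(logs.std(ddof=1))
    if sd == 0:
        raise DegenerateDataError("all log ratios identical; t undefined")
    mean = float(logs.mean())
    se = sd / math.sqrt(n)
    t = mean / se
    p = float(2.0 * scipy.stats.t.sf(abs(t), n - 1))
    return PairedTResult(mean=mean, sd=sd, se=se, t=t, df=n - 1,
                         p_two_tailed=p)


def concordance_most_polyphagous(
    contrast_set: ContrastSet,
    traits: Iterable[GenusTraits] | None = None,
) -> tuple[int, int, float]:
    """Does the higher-diversity side also hold the most polyphagous species?

    Per pair, the single most polyphagous species of each side is compared
    (max over the side's taxa of per-taxon maximum polyphagy); the pair is
    concordant iff side 1 strictly exceeds side 2. Ties drop from ``n``.
    Returns (k_concordant, n, two-tailed sign-test p). When ``traits`` is
    given it overrides any stored ``max_poly_side`` annotations.
    """
    if traits is not None:
        by_taxon = {t.taxon: t for t in traits}

        def side_of(p: ContrastPair) -> int | str:
            try:
                m1 = max(by_taxon[lab].max_polyphagy for lab in p.clade1)
                m2 = max(by_taxon[lab].max_polyphagy for lab in p.clade2)
            except KeyError as exc:
                raise InputError(f"taxon missing from traits: {exc}") from exc
            return 1 if m1 > m2 else (2 if m2 > m1 else "tie")

        sides = [side_of(p) for p in contrast_set.pairs]
    else:
        sides = [p.max_poly_side for p in contrast_set.pairs]
        if any(s is None for s in sides):
            raise InputError(
                "pairs lack max_poly_side annotations; pass traits"
            )
    n = sum(s != "tie" for s in sides)
    if n == 0:
        raise DegenerateDataError("all pairs tied on maximum polyphagy")
    k = sum(s == 1 for s in sides)
    return k, n, sign_test(k, n)


def hd_maxpoly_correlation(
    traits: Sequence[GenusTraits],
) -> tuple[float, float]:
    """Squared Pearson correlation of host diversity vs maximum polyphagy.

    Measures, across genus-level taxa, how tightly clade-level host
    diversity tracks the polyphagy of the clade's single most polyphagous
    species. Returns (r_squared, two-tailed p).
    """
    taxa = [t for t in traits if t.hd > 0]
    if len(taxa) < 3:
        raise InputError("need at least 3 taxa with hd > 0")
    hd = np.array([t.hd for t in taxa], dtype=float)
    mp = np.array([t.max_polyphagy for t in taxa], dtype=float)
    if hd.std() == 0 or mp.std() == 0:
        raise DegenerateDataError("zero variance in hd or max_polyphagy")
    r, p = scipy.stats.pearsonr(hd, mp)
    return float(r * r), float(p)
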