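"""Instrument selection and strength grading.

An MR instrument must associate with the exposure at genome-wide significance
(P < 5e-8), be independent of the other instruments (pairwise LD r^2 below a
threshold), and be strong (F-statistic > 10, the conventional weak-instrument
bound). This module implements the filter, a greedy LD pruner working from a
user-supplied r^2 matrix, and both common F-statistic formulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .summary_io import DataError, VariantAssociation

GW_SIGNIFICANCE = 5e-8
LD_R2_THRESHOLD = 0.01
F_STRONG = 10.0


@dataclass
class InstrumentReport:
    """Strength summary for one candidate instrument.

    ``f_stat_wald`` is (beta/se)^2, always computable. When the effect-allele
    frequency and sample size are known, the variance in the (standardized)
    exposure explained by the variant is ``r2 = 2 p (1-p) beta^2`` and
    ``f_stat_r2 = r2 (n-2) / (1-r2)``.
    """

    rsid: str
    pass_gw_significance: bool
    f_stat_wald: float
    f_stat_r2: float | None = None
    r2_explained: float | None = None

    @property
    def strong(self) -> bool:
        f = self.f_stat_r2 if self.f_stat_r2 is not None else self.f_stat_wald
        return f > F_STRONG


def gw_filter(
    assocs: Sequence[VariantAssociation], p_threshold: float = GW_SIGNIFICANCE
) -> list[VariantAssociation]:
    """Keep associations with p-value below the significance threshold."""
    for a in assocs:
        if a.pvalue is None:
            raise DataError(f"gw_filter: {a.rsid} has no p-value")
    return [a for a in assocs if a.pvalue < p_threshold]


def read_r2_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square LD r^2 table (TSV with rsid row and column labels)."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    return m


def ld_prune(
    assocs: Sequence[VariantAssociation],
    r2_matrix: pd.DataFrame | Mapping[tuple[str, str], float],
    r2_threshold: float = LD_R2_THRESHOLD,
) -> list[VariantAssociation]:
    """Greedy LD pruning: keep the most significant variant, drop its LD partners.

    Repeatedly selects the remaining record with the smallest p-value (ties
    broken by rsid, for determinism) and removes every other record with
    r^2 >= ``r2_threshold`` against it. The survivors are returned in input
    order and are pairwise below the threshold.
    """

    def r2(a: str, b: str) -> float:
        if a == b:
            return 1.0
        if isinstance(r2_matrix, pd.DataFrame):
            if a not in r2_matrix.index or b not in r2_matrix.columns:
                raise DataError(f"ld_prune: pair ({a}, {b}) missing from r2 matrix")
            return float(r2_matrix.loc[a, b])
        for key in ((a, b), (b, a)):
            if key in r2_matrix:
                return float(r2_matrix[key])
        raise DataError(f"ld_prune: pair ({a}, {b}) missing from r2 matrix")

    for a in assocs:
        if a.pvalue is None:
            raise DataError(f"ld_prune: {a.rsid} has no p-value")

    remaining = list(assocs)
    kept_rsids: set[str] = set()
    while remaining:
        best = min(remaining, key=lambda a: (a.pvalue, a.rsid))
        kept_rsids.add(best.rsid)
        remaining = [
            a
            for a in remaining
            if a.rsid != best.rsid and r2(best.rsid, a.rsid) < r2_threshold
        ]
    return [a for a in assocs if a.rsid in kept_rsids]


def f_statistic(assoc: VariantAssociation) -> InstrumentReport:
    """Instrument-strength report for one variant.

    The Wald form (beta/se)^2 needs only the association estimate. The
    variance-explained form additionally uses EAF and N, assuming the exposure
    is standardized (beta in SD units), and equals the F of the one-variant
    regression: R^2 (n-2) / (1 - R^2).
    """
    f_wald = (assoc.beta / assoc.se) ** 2
    r2 = f_r2 = None
    if assoc.eaf is not None and assoc.n is not None:
        r2 = 2.0 * assoc.eaf * (1.0 - assoc.eaf) * assoc.beta**2
        if r2 >= 1.0:
            raise DataError(
                f"f_statistic: {assoc.rsid} implies R^2 = {r2:.3f} >= 1 "
                "(inconsistent beta/EAF for a standardized trait)"
            )
        f_r2 = r2 * (assoc.n - 2) / (1.0 - r2)
    passes = assoc.pvalue is not None and assoc.pvalue < GW_SIGNIFICANCE
    return InstrumentReport(
        rsid=assoc.rsid,
        pass_gw_significance=passes,
        f_stat_wald=f_wald,
        f_stat_r2=f_r2,
        r2_explained=r2,
    )
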