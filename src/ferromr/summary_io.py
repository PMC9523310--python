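"""Reading, validation, and harmonization of GWAS summary statistics.

Two-sample MR starts from two tables of per-variant association estimates:
one for the exposure (e.g. serum iron, in SD units per effect allele) and one
for the outcome (a liver biomarker in SD units, or a disease on the log-odds
scale). Before any estimator can run, the two tables must be *harmonized*:
each shared variant's outcome effect is re-expressed relative to the
exposure's effect allele, resolving swapped alleles, strand flips, and
palindromic (A/T, C/G) ambiguity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("ferromr")

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Fixed column order for harmonized-instrument TSV output.
HARMONIZED_COLUMNS = [
    "rsid",
    "effect_allele",
    "other_allele",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
    "eaf_exposure",
    "eaf_outcome",
    "flipped",
    "palindromic",
]

#: Canonical field names for summary-statistic tables.
SUMMARY_COLUMNS = [
    "rsid",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "eaf",
    "n",
]


class ConfigError(ValueError):
    """A configuration problem (missing column mapping, bad option value)."""


class DataError(ValueError):
    """A data problem (invalid row, duplicate rsid, unresolvable alleles)."""


@dataclass
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is the additive per-effect-allele estimate: SD units for
    continuous traits, log-odds for binary traits.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float | None = None
    eaf: float | None = None
    n: int | None = None
    trait: str = ""
    trait_type: Literal["continuous", "binary"] = "continuous"

    def validate(self) -> None:
        if not self.rsid:
            raise DataError("empty rsid")
        ea, oa = self.effect_allele, self.other_allele
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            raise DataError(f"{self.rsid}: alleles must be A/C/G/T, got {ea}/{oa}")
        if ea == oa:
            raise DataError(f"{self.rsid}: effect and other allele identical ({ea})")
        if not math.isfinite(self.beta):
            raise DataError(f"{self.rsid}: non-finite beta")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise DataError(f"{self.rsid}: standard error must be > 0, got {self.se}")
        if self.pvalue is not None and not (0 < self.pvalue <= 1):
            raise DataError(f"{self.rsid}: p-value must lie in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise DataError(f"{self.rsid}: EAF must lie in [0, 1], got {self.eaf}")
        if self.n is not None and self.n <= 0:
            raise DataError(f"{self.rsid}: sample size must be positive, got {self.n}")

    @property
    def palindromic(self) -> bool:
        """True for A/T or C/G variants, whose strand is ambiguous."""
        return self.other_allele == COMPLEMENT[self.effect_allele]


@dataclass
class HarmonizedInstrument:
    """A variant's exposure and outcome effects on a shared effect allele.

    ``flipped`` records that the outcome record's alleles were swapped
    (its beta negated, its EAF reflected); ``palindromic`` flags A/T and
    C/G variants retained under a permissive palindrome policy.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    flipped: bool = False
    palindromic: bool = False


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se")
_OPTIONAL_FIELDS = ("pvalue", "eaf", "n")


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    if delimiter is None:
        # auto-detect among tab / comma / whitespace from the header line
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else "," if "," in header else r"\s+"
    # round_trip parsing keeps betas/SEs bit-identical through write/read
    return pd.read_csv(path, sep=delimiter, float_precision="round_trip")


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: Literal["continuous", "binary"] = "continuous",
    trait: str = "",
    strict: bool = True,
    delimiter: str | None = None,
) -> list[VariantAssociation]:
    """Read a delimited GWAS summary-statistics table.

    Parameters
    ----------
    column_map
        Mapping from canonical field names (``rsid``, ``effect_allele``,
        ``other_allele``, ``beta``, ``se``, optionally ``pvalue``, ``eaf``,
        ``n``) to the source file's column names. ``None`` assumes the file
        already uses canonical names.
    strict
        If True, a row failing validation aborts the read with an error
        naming the offending rsid; otherwise the row is dropped with a
        logged reason.
    """
    df = _read_table(path, delimiter)
    cmap = dict(column_map) if column_map else {c: c for c in SUMMARY_COLUMNS}
    missing = [f for f in _REQUIRED_FIELDS if f not in cmap]
    if missing:
        raise ConfigError(f"column_map missing required fields: {missing}")
    for canonical, source in cmap.items():
        if canonical in _REQUIRED_FIELDS and source not in df.columns:
            raise ConfigError(
                f"{path}: mapped column {source!r} (for {canonical!r}) not in header"
            )

    records: list[VariantAssociation] = []
    for idx, row in df.iterrows():
        kwargs: dict = {"trait": trait, "trait_type": trait_type}
        for canonical in _REQUIRED_FIELDS:
            kwargs[canonical] = row[cmap[canonical]]
        for canonical in _OPTIONAL_FIELDS:
            source = cmap.get(canonical)
            if source is not None and source in df.columns:
                value = row[source]
                kwargs[canonical] = None if pd.isna(value) else value
        kwargs["rsid"] = str(kwargs["rsid"])
        kwargs["effect_allele"] = str(kwargs["effect_allele"]).upper()
        kwargs["other_allele"] = str(kwargs["other_allele"]).upper()
        kwargs["beta"] = float(kwargs["beta"])
        kwargs["se"] = float(kwargs["se"])
        if kwargs.get("pvalue") is not None:
            kwargs["pvalue"] = float(kwargs["pvalue"])
        if kwargs.get("eaf") is not None:
            kwargs["eaf"] = float(kwargs["eaf"])
        if kwargs.get("n") is not None:
            kwargs["n"] = int(kwargs["n"])
        assoc = VariantAssociation(**kwargs)
        try:
            assoc.validate()
        except DataError as err:
            if strict:
                raise DataError(f"row {idx}: {err}") from None
            logger.warning("dropping row %s: %s", idx, err)
            continue
        records.append(assoc)
    return records


def write_summary_stats(assocs: Sequence[VariantAssociation], path: str | Path) -> None:
    """Write associations as a canonical-column TSV (round-trips with read)."""
    rows = [
        {
            "rsid": a.rsid,
            "effect_allele": a.effect_allele,
            "other_allele": a.other_allele,
            "beta": a.beta,
            "se": a.se,
            "pvalue": a.pvalue,
            "eaf": a.eaf,
            "n": a.n,
        }
        for a in assocs
    ]
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS[:8]).to_csv(path, sep="\t", index=False)


def write_harmonized(
    instruments: Sequence[HarmonizedInstrument], path: str | Path
) -> None:
    """Write harmonized instruments as TSV with the fixed column order."""
    rows = [{c: getattr(h, c) for c in HARMONIZED_COLUMNS} for h in instruments]
    pd.DataFrame(rows, columns=HARMONIZED_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def _index_by_rsid(
    assocs: Iterable[VariantAssociation], label: str
) -> dict[str, VariantAssociation]:
    out: dict[str, VariantAssociation] = {}
    for a in assocs:
        if a.rsid in out:
            raise DataError(f"duplicate rsid {a.rsid!r} in {label} summary statistics")
        out[a.rsid] = a
    return out


def _eaf_ambiguous(eaf: float | None, window: float) -> bool:
    return eaf is None or abs(eaf - 0.5) <= window


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindromic_policy: Literal["drop_all", "drop_ambiguous", "keep"] = "drop_ambiguous",
    eaf_ambiguity_window: float = 0.08,
) -> list[HarmonizedInstrument]:
    """Align outcome associations to each exposure variant's effect allele.

    For each rsid present in both tables: matching alleles copy through;
    swapped alleles negate the outcome beta and reflect its EAF; complementary
    alleles (reported on the opposite strand) are complemented first, then the
    same logic applies. Palindromic variants — where the strand cannot be told
    from alleles — are handled per ``palindromic_policy``:

    - ``drop_all``: always removed;
    - ``drop_ambiguous`` (default): removed only when either EAF is missing or
      within ``eaf_ambiguity_window`` of 0.5; otherwise aligned by EAF
      concordance (discordant frequencies imply the outcome is on the other
      strand, i.e. the effect allele roles are swapped);
    - ``keep``: aligned by allele labels alone, assuming a shared strand.

    Unresolvable allele sets are dropped with a logged reason. Order follows
    the exposure list.
    """
    exp_by_rsid = _index_by_rsid(exposure, "exposure")
    out_by_rsid = _index_by_rsid(outcome, "outcome")
    shared = [r for r in exp_by_rsid if r in out_by_rsid]
    if not shared:
        logger.warning("harmonize: no shared rsids between exposure and outcome")
        return []

    harmonized: list[HarmonizedInstrument] = []
    for rsid in shared:
        e, o = exp_by_rsid[rsid], out_by_rsid[rsid]
        is_palindromic = e.palindromic
        if is_palindromic:
            if palindromic_policy == "drop_all":
                logger.info("harmonize: dropping palindromic variant %s", rsid)
                continue
            if palindromic_policy == "drop_ambiguous" and (
                _eaf_ambiguous(e.eaf, eaf_ambiguity_window)
                or _eaf_ambiguous(o.eaf, eaf_ambiguity_window)
            ):
                logger.info(
                    "harmonize: dropping palindromic variant %s (EAF ambiguous)", rsid
                )
                continue

        o_ea, o_oa = o.effect_allele, o.other_allele
        flipped = False
        if (o_ea, o_oa) == (e.effect_allele, e.other_allele):
            flipped = False
        elif (o_ea, o_oa) == (e.other_allele, e.effect_allele):
            flipped = True
        else:
            # try strand complement, then direct/swap again
            c_ea, c_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
            if (c_ea, c_oa) == (e.effect_allele, e.other_allele):
                flipped = False
            elif (c_ea, c_oa) == (e.other_allele, e.effect_allele):
                flipped = True
            else:
                logger.warning(
                    "harmonize: dropping %s, alleles %s/%s vs %s/%s unresolvable",
                    rsid, e.effect_allele, e.other_allele, o_ea, o_oa,
                )
                continue

        # for an unambiguous palindrome, allele labels cannot distinguish the
        # strands — frequency concordance decides the orientation instead
        if is_palindromic and palindromic_policy == "drop_ambiguous":
            flipped = (e.eaf < 0.5) != (o.eaf < 0.5)

        beta_outcome = -o.beta if flipped else o.beta
        eaf_outcome = o.eaf
        if flipped and eaf_outcome is not None:
            eaf_outcome = 1.0 - eaf_outcome

        harmonized.append(
            HarmonizedInstrument(
                rsid=rsid,
                effect_allele=e.effect_allele,
                other_allele=e.other_allele,
                beta_exposure=e.beta,
                se_exposure=e.se,
                beta_outcome=beta_outcome,
                se_outcome=o.se,
                eaf_exposure=e.eaf,
                eaf_outcome=eaf_outcome,
                flipped=flipped,
                palindromic=is_palindromic,
            )
        )
    return harmonized


def orient_exposure(
    assocs: Sequence[VariantAssociation],
    direction: Literal["increase", "decrease"] = "increase",
) -> list[VariantAssociation]:
    """Express exposure effects per SD increase or per SD decrease.

    ``decrease`` negates each beta and swaps the allele labels (and reflects
    the EAF accordingly), so that e.g. transferrin instruments can be read as
    "per SD *decrease* of transferrin", the direction in which iron status
    rises. Applying ``decrease`` twice restores the input.
    """
    if not assocs:
        raise DataError("orient_exposure: empty association list")
    if direction == "increase":
        return list(assocs)
    if direction != "decrease":
        raise ConfigError(f"unknown direction {direction!r}")
    return [
        replace(
            a,
            beta=-a.beta,
            effect_allele=a.other_allele,
            other_allele=a.effect_allele,
            eaf=None if a.eaf is None else 1.0 - a.eaf,
        )
        for a in assocs
    ]
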