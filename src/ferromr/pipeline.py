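"""Study orchestration: run an exposure x outcome x method grid of MR analyses.

A study configuration lists exposures (each with its instrument rsids and
summary-statistics file) and outcomes (each with a trait type and optional
scale transforms), and the estimators to apply. ``run_study`` harmonizes
every pair, computes per-SNP Wald ratios, pools them with each requested
method, and emits one row per cell — the shape of a forest-plot table.
Reverse MR (disease liability -> biomarker levels) is the same machinery
with the roles swapped in the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .estimators import (
    EstimationError,
    MREstimate,
    ivw_fixed,
    mr_egger,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from .summary_io import (
    ConfigError,
    HarmonizedInstrument,
    VariantAssociation,
    harmonize,
    orient_exposure,
    read_summary_stats,
)

logger = logging.getLogger("ferromr")

METHODS = ("ivw_fixed", "weighted_median", "mr_egger")

RESULT_COLUMNS = [
    "exposure",
    "outcome",
    "stratum",
    "method",
    "status",
    "n_snps",
    "theta",
    "se",
    "ci_low",
    "ci_high",
    "pvalue",
    "or_",
    "or_ci_low",
    "or_ci_high",
    "significant_nominal",
]


@dataclass
class ExposureSpec:
    name: str
    path: str | Path | None = None
    column_map: Mapping[str, str] | None = None
    instruments: Sequence[str] = ()
    direction: Literal["increase", "decrease"] = "increase"
    assocs: Sequence[VariantAssociation] | None = None  # in-memory alternative


@dataclass
class OutcomeSpec:
    name: str
    path: str | Path | None = None
    column_map: Mapping[str, str] | None = None
    trait_type: Literal["continuous", "binary"] = "continuous"
    stratum: Literal["all", "female", "male"] = "all"
    phenotype_sd: float | None = None  # divide betas by this to standardize
    case_fraction: float | None = None  # linear-model beta -> log-odds via mu(1-mu)
    assocs: Sequence[VariantAssociation] | None = None


@dataclass
class StudyConfig:
    """Declarative description of a full MR study grid."""

    exposures: Sequence[ExposureSpec]
    outcomes: Sequence[OutcomeSpec]
    methods: Sequence[str] = ("ivw_fixed",)
    alpha: float = 0.05
    se_order: Literal["first", "second"] = "first"
    palindromic_policy: Literal["drop_all", "drop_ambiguous", "keep"] = "drop_ambiguous"
    n_boot: int = 10_000
    seed: int | None = None

    def validate(self) -> None:
        for m in self.methods:
            if m not in METHODS:
                raise ConfigError(f"unknown method {m!r}; choose from {METHODS}")
        for e in self.exposures:
            if not e.instruments and e.assocs is None:
                raise ConfigError(f"exposure {e.name!r} lists no instrument rsids")
        for o in self.outcomes:
            if o.trait_type not in ("continuous", "binary"):
                raise ConfigError(f"outcome {o.name!r}: bad trait_type {o.trait_type!r}")


@dataclass
class StudyResultRow:
    """One exposure x outcome x method cell of the results grid."""

    exposure: str
    outcome: str
    stratum: str
    method: str
    status: str = "ok"
    n_snps: int = 0
    theta: float | None = None
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    pvalue: float | None = None
    or_: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    significant_nominal: bool | None = None


# ---------------------------------------------------------------------------
# Loading and transforms
# ---------------------------------------------------------------------------


def load_study_config(path: str | Path) -> StudyConfig:
    """Load a StudyConfig from a YAML file (keys mirror the dataclasses)."""
    raw = yaml.safe_load(Path(path).read_text())
    exposures = [ExposureSpec(**e) for e in raw.get("exposures", [])]
    outcomes = [OutcomeSpec(**o) for o in raw.get("outcomes", [])]
    kwargs = {
        k: raw[k]
        for k in ("methods", "alpha", "se_order", "palindromic_policy", "n_boot", "seed")
        if k in raw
    }
    cfg = StudyConfig(exposures=exposures, outcomes=outcomes, **kwargs)
    cfg.validate()
    return cfg


def _load_exposure(spec: ExposureSpec) -> list[VariantAssociation]:
    if spec.assocs is not None:
        assocs = list(spec.assocs)
    else:
        assocs = read_summary_stats(spec.path, spec.column_map, trait="exposure")
    if spec.instruments:
        wanted = set(spec.instruments)
        assocs = [a for a in assocs if a.rsid in wanted]
    return orient_exposure(assocs, spec.direction)


def _load_outcome(spec: OutcomeSpec) -> list[VariantAssociation]:
    if spec.assocs is not None:
        assocs = list(spec.assocs)
    else:
        assocs = read_summary_stats(
            spec.path, spec.column_map, trait_type=spec.trait_type, trait=spec.name
        )
    return [apply_outcome_scale(a, spec) for a in assocs]


def apply_outcome_scale(
    a: VariantAssociation, spec: OutcomeSpec
) -> VariantAssociation:
    """Rescale an outcome association per the outcome's configured transforms.

    ``phenotype_sd`` divides beta and SE by the trait's phenotypic SD,
    turning natural-unit effects into SD units. ``case_fraction`` (mu)
    converts a linear-model beta on a 0/1 outcome into log-odds via division
    by mu(1-mu), the standard linear-probability approximation. Both are
    explicit configuration, never inferred.
    """
    from dataclasses import replace

    scale = 1.0
    if spec.phenotype_sd is not None:
        scale /= spec.phenotype_sd
    if spec.case_fraction is not None:
        mu = spec.case_fraction
        scale /= mu * (1.0 - mu)
    if scale == 1.0:
        return a
    return replace(a, beta=a.beta * scale, se=a.se * scale)


# ---------------------------------------------------------------------------
# Core analysis
# ---------------------------------------------------------------------------


def analyze_pair(
    instruments: Sequence[HarmonizedInstrument],
    methods: Sequence[str],
    binary: bool,
    alpha: float,
    se_order: str = "first",
    n_boot: int = 10_000,
    seed: int | None = None,
) -> list[tuple[str, MREstimate | None, str]]:
    """Apply each requested estimator to one harmonized instrument set.

    Returns (method label, estimate or None, status) triples; Egger
    contributes separate slope and intercept entries.
    """
    results: list[tuple[str, MREstimate | None, str]] = []
    if not instruments:
        return [(m, None, "no_instruments") for m in methods]
    per_snp = [wald_ratio(h, se_order=se_order) for h in instruments]
    for method in methods:
        try:
            if method == "ivw_fixed":
                results.append(("ivw_fixed", ivw_fixed(per_snp), "ok"))
            elif method == "weighted_median":
                est = weighted_median(instruments, n_boot=n_boot, seed=seed)
                results.append(("weighted_median", est, "ok"))
            elif method == "mr_egger":
                slope, intercept = mr_egger(instruments)
                results.append(("mr_egger_slope", slope, "ok"))
                results.append(("mr_egger_intercept", intercept, "ok"))
        except EstimationError as err:
            logger.warning("%s failed: %s", method, err)
            label = "mr_egger_slope" if method == "mr_egger" else method
            results.append((label, None, "too_few_instruments"))
    return results


def _row_from_estimate(
    exposure: str,
    outcome_spec: OutcomeSpec,
    method: str,
    est: MREstimate | None,
    status: str,
    n_snps: int,
    alpha: float,
) -> StudyResultRow:
    row = StudyResultRow(
        exposure=exposure,
        outcome=outcome_spec.name,
        stratum=outcome_spec.stratum,
        method=method,
        status=status,
        n_snps=n_snps,
    )
    if est is not None:
        row.theta = est.theta
        row.se = est.se
        row.ci_low = est.ci_low
        row.ci_high = est.ci_high
        row.pvalue = est.pvalue
        row.significant_nominal = est.pvalue < alpha
        row.n_snps = est.n_snps
        if outcome_spec.trait_type == "binary" and method != "mr_egger_intercept":
            row.or_, row.or_ci_low, row.or_ci_high = to_odds_ratio(est)
    return row


def run_study(cfg: StudyConfig, out_dir: str | Path | None = None) -> list[StudyResultRow]:
    """Run the full exposure x outcome x method grid.

    An instrument absent from an outcome file shrinks the analysis to the
    remaining instruments (recorded in ``n_snps``); a pair with no shared
    instruments yields a status-flagged row rather than an error. When
    ``out_dir`` is given, a results TSV and a run manifest (inputs, version,
    seed, per-pair instrument counts) are written there.
    """
    cfg.validate()
    rows: list[StudyResultRow] = []
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "methods": list(cfg.methods),
        "alpha": cfg.alpha,
        "pairs": [],
    }
    for exp in cfg.exposures:
        exp_assocs = _load_exposure(exp)
        for out in cfg.outcomes:
            out_assocs = _load_outcome(out)
            instruments = harmonize(
                exp_assocs, out_assocs, palindromic_policy=cfg.palindromic_policy
            )
            requested = len(exp.instruments) or len(exp_assocs)
            if len(instruments) < requested:
                logger.warning(
                    "%s x %s: %d of %d instruments harmonized",
                    exp.name, out.name, len(instruments), requested,
                )
            manifest["pairs"].append(
                {
                    "exposure": exp.name,
                    "outcome": out.name,
                    "stratum": out.stratum,
                    "n_instruments": len(instruments),
                    "dropped": requested - len(instruments),
                }
            )
            for method, est, status in analyze_pair(
                instruments,
                cfg.methods,
                binary=out.trait_type == "binary",
                alpha=cfg.alpha,
                se_order=cfg.se_order,
                n_boot=cfg.n_boot,
                seed=cfg.seed,
            ):
                rows.append(
                    _row_from_estimate(
                        exp.name, out, method, est, status, len(instruments), cfg.alpha
                    )
                )
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "results.tsv").write_text(render_report(rows, "tsv"))
        (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return rows


def run_reverse(cfg: StudyConfig, out_dir: str | Path | None = None) -> list[StudyResultRow]:
    """Reverse-direction MR: identical machinery, roles already swapped in cfg.

    The caller configures the disease-liability GWAS as the exposure (with
    its instrument set, e.g. the 12 NAFLD variants) and the biomarkers as
    outcomes; this is a pure function of the configuration and shares no
    state with any forward run.
    """
    return run_study(cfg, out_dir=out_dir)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def results_frame(rows: Sequence[StudyResultRow]) -> pd.DataFrame:
    """Results as a DataFrame, deterministically sorted for reporting."""
    if not rows:
        raise ValueError("results_frame: no rows")
    df = pd.DataFrame([vars(r) for r in rows], columns=RESULT_COLUMNS)
    return df.sort_values(
        ["outcome", "exposure", "stratum", "method"], kind="mergesort"
    ).reset_index(drop=True)


def render_report(rows: Sequence[StudyResultRow], format: str = "tsv") -> str:
    """Render rows grouped by outcome then exposure, forest-plot ready.

    Binary outcomes carry exponentiated (OR) columns; continuous outcomes
    leave them empty. ``format`` is ``tsv`` or ``markdown``; both print the
    same numbers (6 significant digits).
    """
    df = results_frame(rows)
    num_cols = [c for c in df.columns if df[c].dtype.kind == "f"]
    out = df.copy()
    for c in num_cols:
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    if format == "tsv":
        return out.to_csv(sep="\t", index=False)
    if format == "markdown":
        header = "| " + " | ".join(out.columns) + " |"
        sep = "| " + " | ".join("---" for _ in out.columns) + " |"
        body = [
            "| " + " | ".join("" if pd.isna(v) else str(v) for v in rec) + " |"
            for rec in out.itertuples(index=False)
        ]
        return "\n".join([header, sep, *body]) + "\n"
    raise ConfigError(f"unknown report format {format!r}")
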