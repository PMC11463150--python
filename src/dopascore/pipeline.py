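"""End-to-end orchestration: files in, report tables out.

``run_full_analysis`` executes the whole chain — genotype parsing,
per-locus counts and Hardy-Weinberg tests, multilocus scoring and
dichotomization, phenotype derivation (BMI, waist-to-height ratio, WHO
weight class, instrument scores), the stratified Mann-Whitney battery,
the food-addiction prevalence contrast and the MLGS correlations — and
returns an :class:`AnalysisReport` whose tables mirror the study's
published layout:

* ``table1``: genotype-class counts, percentages and HWE X^2 per locus
  (per-locus denominators: every non-missing call at that locus);
* ``table2``: the MLGS score-frequency distribution (complete-case);
* ``table3``/``table4``: anthropometric respectively eating-behavior
  variables as mean ± SD by signaling group, overall, per weight-status
  stratum and per sex, with two-sided Mann-Whitney p-values;
* ``fa_prevalence``: food-addiction prevalence by group per stratum
  (Fisher exact by default);
* ``correlations``: Spearman correlations of the continuous MLGS with
  behavioral and anthropometric variables per stratum.

All MLGS-grouped results are complete-case (all four loci genotyped);
the manifest accounts for every exclusion.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    compare_groups_stratified,
    prevalence_test,
    spearman,
)
from .genotype import (
    DEFAULT_LOCI,
    GenotypeParseError,
    count_genotypes,
    hwe_chi_square,
    parse_genotype,
)
from .mlgs import (
    DEFAULT_THRESHOLD,
    MLGS_LOCI,
    SignalingGroup,
    compute_mlgs,
    default_scoring_maps,
    score_frequency_table,
)
from .phenotypes import (
    bmi,
    classify_weight_status,
    score_rvfq,
    score_tfeq,
    score_yfas,
    waist_height_ratio,
)

__all__ = [
    "InputError",
    "PipelineConfigError",
    "RunConfig",
    "AnalysisReport",
    "run_full_analysis",
    "render_tables",
]

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Unreadable or schema-incompatible input data."""


class PipelineConfigError(ValueError):
    """Invalid run configuration."""


ANTHROPOMETRIC_VARIABLES = (
    "age",
    "weight_kg",
    "height_m",
    "bmi",
    "waist_height_ratio",
    "waist_cm",
    "body_fat_pct",
)

BEHAVIOR_VARIABLES = (
    "cr",
    "ee",
    "ue",
    "pct_food_choice",
    "energy_kcal",
    "protein_g",
    "carbs_g",
    "fiber_g",
    "lipids_g",
    "safa_g",
    "mufa_g",
    "pufa_g",
    "trans_g",
    "cholesterol_mg",
    "omega3_mg",
    "omega6_mg",
    "iron_mg",
    "fa_symptoms",
)

CORRELATION_VARIABLES = (
    "cr",
    "ee",
    "ue",
    "pct_food_choice",
    "bmi",
    "body_fat_pct",
    "fa_symptoms",
)

STRATA_ORDER = ("normal", "overweight", "obese")


@dataclass
class RunConfig:
    """Paths, column maps and test conventions for one analysis run."""

    genotypes: str | Path
    phenotypes: Optional[str | Path] = None
    outdir: Optional[str | Path] = None
    genotype_columns: dict = field(default_factory=dict)   # rsid -> file column
    phenotype_columns: dict = field(default_factory=dict)  # canonical -> file column
    subject_id_column: str = "subject_id"
    rs6277_mode: str = "het_half"
    threshold: float = DEFAULT_THRESHOLD
    continuity_correction: bool = True
    fa_test: str = "fisher"
    correlation_method: str = "spearman"
    separate_underweight: bool = False
    yfas_min_symptoms: int = 3
    formats: tuple = ("tsv",)

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 4.0:
            raise PipelineConfigError(f"threshold {self.threshold} outside [0, 4]")
        if self.fa_test not in ("fisher", "chi2"):
            raise PipelineConfigError(f"unknown fa_test {self.fa_test!r}")
        if self.correlation_method not in ("spearman", "pearson"):
            raise PipelineConfigError(
                f"unknown correlation method {self.correlation_method!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise PipelineConfigError(f"cannot read config {path}: {exc}") from exc
        raw.pop("generator", None)  # generator section belongs to `simulate`
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config option(s): {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)


@dataclass
class AnalysisReport:
    """All output tables plus the run manifest."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    mlgs: pd.DataFrame                    # per-subject scores and group
    table3: Optional[pd.DataFrame]
    table4: Optional[pd.DataFrame]
    fa_prevalence: Optional[pd.DataFrame]
    correlations: Optional[pd.DataFrame]
    manifest: dict


def _read_table(path: str | Path, dtype=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep, dtype=dtype, keep_default_na=dtype is None)
    except Exception as exc:  # malformed delimited text
        raise InputError(f"cannot parse {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{what}: missing column(s) {missing}")


def read_genotypes(config: RunConfig) -> pd.DataFrame:
    """Genotype table with canonical rsID column names, calls as text."""
    df = _read_table(config.genotypes, dtype=str)
    colmap = {config.genotype_columns.get(rsid, rsid): rsid for rsid in MLGS_LOCI}
    df = df.rename(columns=colmap)
    sid = config.subject_id_column
    _require_columns(df, [sid, *MLGS_LOCI], "genotype table")
    df = df.rename(columns={sid: "subject_id"})
    df[list(MLGS_LOCI)] = df[list(MLGS_LOCI)].fillna("")
    return df


def read_phenotypes(config: RunConfig) -> pd.DataFrame:
    """Phenotype table with canonical column names, instruments scored.

    Accepts either precomputed instrument scores (``cr``/``ue``/``ee``,
    ``pct_food_choice``, ``fa_symptoms``/``fa_distress``/``fa_diagnosis``)
    or raw item columns (``tfeq_01``..``tfeq_18``, ``rvfq_01``..``rvfq_12``,
    ``yfas_s1``..``yfas_s7`` + ``yfas_distress``), which are scored here.
    """
    df = _read_table(config.phenotypes)
    rename = {actual: canonical for canonical, actual in config.phenotype_columns.items()}
    df = df.rename(columns=rename)
    sid = config.subject_id_column if config.subject_id_column in df.columns else "subject_id"
    _require_columns(df, [sid], "phenotype table")
    df = df.rename(columns={sid: "subject_id"})

    tfeq_items = [f"tfeq_{i:02d}" for i in range(1, 19)]
    if "cr" not in df.columns and all(c in df.columns for c in tfeq_items):
        scores = df[tfeq_items].apply(
            lambda row: pd.Series(score_tfeq(row.tolist())), axis=1
        )
        df = pd.concat([df, scores], axis=1)

    rvfq_items = [f"rvfq_{i:02d}" for i in range(1, 13)]
    if "pct_food_choice" not in df.columns and all(c in df.columns for c in rvfq_items):
        scored = df[rvfq_items].apply(
            lambda row: pd.Series(
                score_rvfq(row.astype(bool).tolist()),
                index=["pct_food_choice", "rvfq_breakpoint"],
            ),
            axis=1,
        )
        df = pd.concat([df, scored], axis=1)

    yfas_items = [f"yfas_s{i}" for i in range(1, 8)]
    if "fa_symptoms" not in df.columns and all(c in df.columns for c in yfas_items):
        if "yfas_distress" not in df.columns:
            raise InputError("phenotype table: yfas_s1..s7 present but yfas_distress missing")
        scored = df.apply(
            lambda row: pd.Series(
                score_yfas(
                    row[yfas_items].astype(bool).tolist(),
                    bool(row["yfas_distress"]),
                    config.yfas_min_symptoms,
                ),
                index=["fa_symptoms", "fa_diagnosis"],
            ),
            axis=1,
        )
        df = pd.concat([df, scored], axis=1)
        df["fa_distress"] = df["yfas_distress"].astype(int)
    if (
        "fa_diagnosis" not in df.columns
        and "fa_symptoms" in df.columns
        and "fa_distress" in df.columns
    ):
        df["fa_diagnosis"] = (
            (df["fa_symptoms"] >= config.yfas_min_symptoms) & (df["fa_distress"] > 0)
        ).astype(int)
    return df


def _genotype_stage(config: RunConfig, genotypes: pd.DataFrame):
    """Parse calls, build Table 1 and per-subject MLGS results."""
    calls_by_locus = {rsid: [] for rsid in MLGS_LOCI}
    for rsid in MLGS_LOCI:
        locus = DEFAULT_LOCI[rsid]
        for raw in genotypes[rsid]:
            try:
                calls_by_locus[rsid].append(parse_genotype(raw, locus))
            except GenotypeParseError as exc:
                raise InputError(str(exc)) from exc

    rows = []
    for rsid in MLGS_LOCI:
        locus = DEFAULT_LOCI[rsid]
        counts = count_genotypes(calls_by_locus[rsid], locus)
        hwe = hwe_chi_square(counts) if counts.n_typed else None
        n = counts.n_typed
        rows.append(
            {
                "rsid": rsid,
                "gene": locus.gene_label,
                "n_typed": n,
                "n_missing": counts.n_missing,
                "n_low_hom": counts.n_low_hom,
                "n_het": counts.n_het,
                "n_high_hom": counts.n_high_hom,
                "pct_low_hom": 100.0 * counts.n_low_hom / n if n else np.nan,
                "pct_het": 100.0 * counts.n_het / n if n else np.nan,
                "pct_high_hom": 100.0 * counts.n_high_hom / n if n else np.nan,
                "p_low": hwe.p_low if hwe else np.nan,
                "hwe_chi2": hwe.chi2 if hwe else np.nan,
                "hwe_p": hwe.p_value if hwe else np.nan,
                "hwe_applicable": hwe.applicable if hwe else False,
            }
        )
    table1 = pd.DataFrame(rows)

    maps = default_scoring_maps(config.rs6277_mode)
    results = []
    for i, sid in enumerate(genotypes["subject_id"]):
        calls = [calls_by_locus[rsid][i] for rsid in MLGS_LOCI]
        results.append(compute_mlgs(calls, maps, config.threshold, subject_id=sid))
    mlgs_df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in results],
            **{
                f"score_{rsid}": [r.per_locus[rsid] for r in results]
                for rsid in MLGS_LOCI
            },
            "mlgs_total": [r.total for r in results],
            "mlgs_group": [r.group.value for r in results],
        }
    )
    return table1, results, mlgs_df


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Execute the full analysis chain for one cohort."""
    warnings: list[str] = []
    genotypes = read_genotypes(config)
    n_total = len(genotypes)
    if n_total == 0:
        raise InputError("genotype table is empty")

    table1, results, mlgs_df = _genotype_stage(config, genotypes)
    complete = [r for r in results if r.is_complete]
    if not complete:
        raise InputError("no subject is genotyped at all four loci (complete-case n = 0)")
    freq = score_frequency_table(complete, config.threshold)
    table2 = freq.to_frame()

    manifest: dict = {
        "software": "dopascore",
        "version": __version__,
        "n_subjects": n_total,
        "n_complete_case": len(complete),
        "n_excluded_missing": n_total - len(complete),
        "per_locus_typed": {
            row["rsid"]: int(row["n_typed"]) for _, row in table1.iterrows()
        },
        "threshold": config.threshold,
        "rs6277_mode": config.rs6277_mode,
        "conventions": {
            "mann_whitney_continuity": config.continuity_correction,
            "fa_test": config.fa_test,
            "correlation_method": config.correlation_method,
            "underweight_pooled_with_normal": not config.separate_underweight,
        },
        "pct_score_at_or_above_threshold": freq.pct_at_or_above,
        "n_tests_performed": 0,
        "warnings": warnings,
    }

    if config.phenotypes is None:
        warnings.append("no phenotype table supplied: report truncated after the score-frequency stage")
        logger.warning(warnings[-1])
        return AnalysisReport(table1, table2, mlgs_df, None, None, None, None, manifest)

    pheno = read_phenotypes(config)
    merged = mlgs_df.merge(pheno, on="subject_id", how="inner")
    if len(merged) < n_total:
        warnings.append(
            f"{n_total - len(merged)} genotyped subject(s) had no phenotype record"
        )
    merged["bmi"] = [bmi(w, h) for w, h in zip(merged["weight_kg"], merged["height_m"])]
    merged["waist_height_ratio"] = [
        waist_height_ratio(w, h) for w, h in zip(merged["waist_cm"], merged["height_m"])
    ]
    merged["weight_status"] = [
        classify_weight_status(b, config.separate_underweight).value
        for b in merged["bmi"]
    ]

    analysed = merged[merged["mlgs_group"] != SignalingGroup.UNDEFINED.value]
    strata_present = [s for s in STRATA_ORDER if (analysed["weight_status"] == s).any()]
    for s in STRATA_ORDER:
        if s not in strata_present:
            warnings.append(f"stratum {s!r} empty: column omitted from stratified tables")
            logger.warning(warnings[-1])

    anthro_vars = [v for v in ANTHROPOMETRIC_VARIABLES if v in analysed.columns]
    behav_vars = [v for v in BEHAVIOR_VARIABLES if v in analysed.columns]
    table3 = compare_groups_stratified(
        analysed, anthro_vars,
        sex_col="sex" if "sex" in analysed.columns else None,
        continuity=config.continuity_correction, strata_order=strata_present,
    )
    table4 = compare_groups_stratified(
        analysed, behav_vars,
        sex_col="sex" if "sex" in analysed.columns else None,
        continuity=config.continuity_correction, strata_order=strata_present,
    )

    fa_rows = []
    if "fa_diagnosis" in analysed.columns:
        for stratum in ["all", *strata_present]:
            sub = analysed if stratum == "all" else analysed[analysed["weight_status"] == stratum]
            low = sub[sub["mlgs_group"] == SignalingGroup.LOW.value]
            high = sub[sub["mlgs_group"] == SignalingGroup.HIGH.value]
            if low.empty or high.empty:
                warnings.append(f"stratum {stratum!r}: FA comparison skipped (empty group)")
                continue
            table = [
                [int((low["fa_diagnosis"] > 0).sum()), int((low["fa_diagnosis"] == 0).sum())],
                [int((high["fa_diagnosis"] > 0).sum()), int((high["fa_diagnosis"] == 0).sum())],
            ]
            cmp_ = prevalence_test(table, test=config.fa_test)
            fa_rows.append(
                {
                    "stratum": stratum,
                    "n_low": cmp_.n_low,
                    "n_high": cmp_.n_high,
                    "fa_pct_low_signaling": cmp_.prevalence_low,
                    "fa_pct_high_signaling": cmp_.prevalence_high,
                    "test": cmp_.test,
                    "p_value": cmp_.p_value,
                }
            )
    fa_prevalence = pd.DataFrame(fa_rows) if fa_rows else None

    corr_rows = []
    corr_vars = [v for v in CORRELATION_VARIABLES if v in analysed.columns]
    for stratum in ["all", *strata_present]:
        sub = analysed if stratum == "all" else analysed[analysed["weight_status"] == stratum]
        if len(sub) < 3:
            continue
        for var in corr_vars:
            res = spearman(
                sub["mlgs_total"], sub[var], "mlgs_total", var,
                stratum=stratum, method=config.correlation_method,
            )
            corr_rows.append(
                {
                    "stratum": stratum,
                    "variable": var,
                    "method": res.method,
                    "n": res.n,
                    "r": res.r,
                    "p_value": res.p_value,
                    "defined": res.defined,
                }
            )
    correlations = pd.DataFrame(corr_rows) if corr_rows else None

    manifest["n_analysed_with_phenotypes"] = int(len(analysed))
    manifest["n_tests_performed"] = int(
        len(table3) + len(table4) + len(fa_rows) + len(corr_rows)
    )
    return AnalysisReport(
        table1, table2, mlgs_df, table3, table4, fa_prevalence, correlations, manifest
    )


_TABLE_ATTRS = (
    "table1",
    "table2",
    "mlgs",
    "table3",
    "table4",
    "fa_prevalence",
    "correlations",
)


def render_tables(
    report: AnalysisReport, outdir: str | Path, formats: Sequence[str] = ("tsv",)
) -> dict[str, Path]:
    """Write the report as delimited text (and optionally aligned text).

    ``formats`` may contain ``"tsv"`` (always machine-readable, one file
    per table) and ``"txt"`` (aligned rendering, percentages to one
    decimal).  The manifest is always written as JSON.
    """
    for fmt in formats:
        if fmt not in ("tsv", "txt"):
            raise ValueError(f"unknown output format {fmt!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in _TABLE_ATTRS:
        frame = getattr(report, name)
        if frame is None:
            continue
        if "tsv" in formats:
            path = outdir / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
            written[name] = path
        if "txt" in formats:
            path = outdir / f"{name}.txt"
            text = frame.round(1).to_string(index=False)
            if name == "table2":
                pct = report.manifest["pct_score_at_or_above_threshold"]
                thr = report.manifest["threshold"]
                n_above = int(round(pct * report.manifest["n_complete_case"] / 100.0))
                text += (
                    f"\nscore >= {thr:g}: {round(pct):.0f}% "
                    f"({n_above}/{report.manifest['n_complete_case']})"
                )
            path.write_text(text + "\n")
            written[f"{name}_txt"] = path
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(report.manifest, indent=2, sort_keys=True) + "\n"
    )
    written["manifest"] = manifest_path
    return written
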