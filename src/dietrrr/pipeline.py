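"""End-to-end sex-stratified pipeline and report rendering.

Per sex stratum the pipeline runs: cohort generation (or CSV/NHANES
ingestion) -> inclusion and misreporting screen -> usual-intake estimation
-> energy adjustment of the nutrient responses -> z-standardization ->
reduced rank regression -> loadings -> simplified patterns -> quintiles ->
descriptive quintile tables -> trend / chi-square / partial-correlation
tests -> unadjusted and adjusted outcome regressions. Every analytic stage
(standardization, quintiles, regressions) operates strictly within the
stratum. All stage outputs are written as delimited text and the run is
deterministic given seed and config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .associations import (
    AssociationResult,
    categorical_quintile_test,
    outcome_regression,
    partial_correlation,
    quintile_trend_test,
)
from .exposures import energy_adjust, estimate_usual_intake
from .foodgroups import GROUP_IDS, GROUP_LABELS
from .rrr import RRRModel, SimplifiedPattern, fit_rrr, simplify_pattern, standardize_columns
from .screening import ScreeningConfig, apply_inclusion_filters

logger = logging.getLogger("dietrrr")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "render_report", "analyze_stratum", "plot_loadings"]

#: categorical/binary variables compared across quintiles and between sexes
CATEGORICAL_VARS = ("race", "education", "vigorous_work", "vigorous_rec", "lipid_med", "supplement")
CONTINUOUS_DEMO_VARS = ("age", "bmi", "pir")


@dataclass
class PipelineConfig:
    """Configuration of one full run."""

    mode: str = "synthetic"  # "synthetic" | "csv"
    sexes: tuple[str, ...] = ("female", "male")
    n_per_sex: int = 800
    seed: int = 0
    input_csv: dict = field(default_factory=dict)  # sex -> path, for mode="csv"
    n_factors: int = 2
    loading_threshold: float = 0.20
    loading_kind: str = "correlation"
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    outdir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.loading_threshold < 1.0:
            raise ValueError("loading_threshold must be in (0, 1)")
        if self.n_factors not in (1, 2):
            raise ValueError("n_factors must be 1 or 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "screening" in raw:
            raw["screening"] = ScreeningConfig(**raw["screening"])
        if "sexes" in raw:
            raw["sexes"] = tuple(raw["sexes"])
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the analytic configuration (output paths excluded)."""
        payload = asdict(self)
        payload["screening"] = asdict(self.screening)
        payload.pop("outdir", None)
        payload.pop("log_level", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class StratumResult:
    """All analytic artifacts of one sex stratum."""

    sex: str
    data: pd.DataFrame  # screened participant table
    filter_log: dict
    usual: pd.DataFrame  # n x 34 usual intakes
    X: pd.DataFrame  # standardized predictors
    Y: pd.DataFrame  # standardized (energy-adjusted) responses
    energy_kcal: pd.Series  # mean-of-days energy, covariate
    model: RRRModel
    patterns: list[SimplifiedPattern]
    partial_corr: pd.DataFrame
    quintile_tables: dict[str, pd.DataFrame]
    chi_square: pd.DataFrame
    regressions: pd.DataFrame


@dataclass
class RunReport:
    """Outputs of a full run, mirroring the published table set."""

    config: PipelineConfig
    strata: dict[str, StratumResult]
    demographics: pd.DataFrame | None
    provenance: dict


def _day_matrices(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    d1 = df[[f"{g}_day1" for g in GROUP_IDS]].copy()
    d1.columns = list(GROUP_IDS)
    d2 = df[[f"{g}_day2" for g in GROUP_IDS]].copy()
    d2.columns = list(GROUP_IDS)
    return d1, d2


def analyze_stratum(
    df: pd.DataFrame,
    sex: str,
    config: PipelineConfig,
) -> StratumResult:
    """Run every analytic stage for one (already loaded) sex stratum."""
    screened, flog = apply_inclusion_filters(df, config.screening)
    logger.info("%s: %d -> %d after screening %s", sex, len(df), len(screened), flog)

    day1, day2 = _day_matrices(screened)
    usual = estimate_usual_intake(day1, day2)

    energy = screened[["energy_kcal_day1", "energy_kcal_day2"]].mean(axis=1)
    energy.name = "energy_kcal"
    zn_adj = energy_adjust(screened["zn_intake_mg"], energy)
    pufa_adj = energy_adjust(screened["pufa_intake_g"], energy)
    responses = pd.DataFrame({"zn": zn_adj, "pufa": pufa_adj})

    X, _ = standardize_columns(usual)
    Y, _ = standardize_columns(responses)
    model = fit_rrr(X, Y, n_factors=config.n_factors, loading_kind=config.loading_kind)

    patterns = [
        simplify_pattern(model, X, factor=k, threshold=config.loading_threshold)
        for k in range(1, config.n_factors + 1)
    ]

    # partial correlations (score vs raw responses, adjusted for energy)
    pc_rows = []
    for pat in patterns:
        for resp_name, resp in (("pufa", screened["pufa_intake_g"]), ("zn", screened["zn_intake_mg"])):
            res = partial_correlation(pat.score, resp, energy)
            pc_rows.append(
                {"pattern": pat.factor_index, "response": resp_name, "r": res.estimate, "p_value": res.p_value, "n": res.n_used}
            )
    pc_table = pd.DataFrame(pc_rows)

    bmi = screened["weight_kg"] / (screened["height_cm"] / 100.0) ** 2
    quintile_tables: dict[str, pd.DataFrame] = {}
    chi_rows = []
    for pat in patterns:
        q = pat.quintile
        # food groups + nutrients: trend adjusted for energy; serum: unadjusted
        rows = []
        for g in GROUP_IDS:
            rows.append(_quintile_row(f"{GROUP_LABELS[g]} (g/day)", usual[g], q, energy, adjust=True))
        rows.append(_quintile_row("Zn intake (mg/day)", screened["zn_intake_mg"], q, energy, adjust=True))
        rows.append(_quintile_row("PUFA intake (g/day)", screened["pufa_intake_g"], q, energy, adjust=True))
        rows.append(_quintile_row("Serum Zn (ug/dL)", screened["serum_zn"], q, energy, adjust=False))
        rows.append(_quintile_row("Serum DGLA (umol/L)", screened["serum_dgla"], q, energy, adjust=False))
        rows.append(
            _quintile_row("Serum LA/DGLA ratio", screened["serum_la"] / screened["serum_dgla"], q, energy, adjust=False)
        )
        quintile_tables[f"pattern{pat.factor_index}"] = pd.DataFrame(rows)

        for var in CATEGORICAL_VARS:
            res = categorical_quintile_test(screened[var], q)
            chi_rows.append(
                {"pattern": pat.factor_index, "variable": var, "chi2": res.estimate, "p_value": res.p_value, "dof": res.notes["dof"]}
            )
    chi_table = pd.DataFrame(chi_rows)

    covariates = pd.DataFrame(
        {
            "age": screened["age"],
            "energy_kcal": energy,
            "pir": screened["pir"],
            "bmi": bmi,
            "race": screened["race"],
            "education": screened["education"],
            "vigorous_work": screened["vigorous_work"],
            "vigorous_rec": screened["vigorous_rec"],
            "lipid_med": screened["lipid_med"],
            "supplement": screened["supplement"],
        }
    )
    reg_rows = []
    outcomes = {
        "dgla": screened["serum_dgla"],
        "la_dgla_ratio": screened["serum_la"] / screened["serum_dgla"],
    }
    for pat in patterns:
        for out_name, out_vec in outcomes.items():
            for model_name in ("model1", "model2"):
                res = outcome_regression(out_vec, pat.score, covariates=covariates, model=model_name)
                reg_rows.append(
                    {
                        "pattern": pat.factor_index,
                        "outcome": out_name,
                        "model": model_name,
                        "coef": res.estimate,
                        "se": res.se,
                        "p_value": res.p_value,
                        "adj_r2": res.adj_r2,
                        "n_used": res.n_used,
                    }
                )
    reg_table = pd.DataFrame(reg_rows)

    return StratumResult(
        sex=sex,
        data=screened,
        filter_log=flog,
        usual=usual,
        X=X,
        Y=Y,
        energy_kcal=energy,
        model=model,
        patterns=patterns,
        partial_corr=pc_table,
        quintile_tables=quintile_tables,
        chi_square=chi_table,
        regressions=reg_table,
    )


def _quintile_row(label: str, values: pd.Series, quintile: pd.Series, energy: pd.Series, adjust: bool) -> dict:
    row: dict = {"variable": label}
    vals = np.asarray(values, dtype=float)
    q = np.asarray(quintile)
    for k in range(1, 6):
        sel = vals[q == k]
        row[f"Q{k}_median"] = float(np.median(sel)) if len(sel) else float("nan")
        row[f"Q{k}_min"] = float(np.min(sel)) if len(sel) else float("nan")
        row[f"Q{k}_max"] = float(np.max(sel)) if len(sel) else float("nan")
    res = quintile_trend_test(values, quintile, adjust_energy=adjust, energy=energy if adjust else None)
    row["trend_slope"] = res.estimate
    row["trend_p"] = res.p_value
    row["energy_adjusted"] = adjust
    return row


def demographic_table(female: pd.DataFrame, male: pd.DataFrame) -> pd.DataFrame:
    """Between-sex comparison: Welch t-tests for continuous variables,
    chi-square for categorical ones (labelled in the ``test`` column)."""
    rows = []
    fem = female.assign(bmi=female["weight_kg"] / (female["height_cm"] / 100.0) ** 2)
    mal = male.assign(bmi=male["weight_kg"] / (male["height_cm"] / 100.0) ** 2)
    for var in CONTINUOUS_DEMO_VARS:
        t, p = sps.ttest_ind(fem[var], mal[var], equal_var=False)
        rows.append(
            {
                "variable": var,
                "female": f"{fem[var].mean():.1f} +/- {fem[var].std(ddof=1):.1f}",
                "male": f"{mal[var].mean():.1f} +/- {mal[var].std(ddof=1):.1f}",
                "test": "welch_t",
                "p_value": float(p),
            }
        )
    for var in CATEGORICAL_VARS:
        table = pd.crosstab(
            pd.concat([fem[var], mal[var]]),
            np.repeat(["female", "male"], [len(fem), len(mal)]),
        )
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        fperc = fem[var].value_counts(normalize=True).round(3).to_dict()
        mperc = mal[var].value_counts(normalize=True).round(3).to_dict()
        rows.append({"variable": var, "female": str(fperc), "male": str(mperc), "test": "chi_square", "p_value": float(p)})
    return pd.DataFrame(rows)


def _load_stratum(config: PipelineConfig, sex: str):
    if config.mode == "synthetic":
        from .synth import default_spec, generate_cohort

        offset = {"female": 0, "male": 1}[sex]
        spec = default_spec(sex, n_participants=config.n_per_sex, seed=config.seed * 2 + offset)
        df, truth = generate_cohort(spec)
        return df, truth
    if config.mode == "csv":
        path = config.input_csv.get(sex)
        if path is None:
            raise ValueError(f"no input CSV configured for sex={sex}")
        return pd.read_csv(path, index_col="participant_id"), None
    raise ValueError(f"unknown mode {config.mode!r}")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full sex-stratified analysis and write all artifacts."""
    strata: dict[str, StratumResult] = {}
    outdir = Path(config.outdir) if config.outdir else None
    for sex in config.sexes:
        try:
            df, truth = _load_stratum(config, sex)
            result = analyze_stratum(df, sex, config)
        except Exception as exc:  # add stage context
            raise RuntimeError(f"pipeline failed in stratum {sex!r}: {exc}") from exc
        strata[sex] = result
        if outdir is not None:
            d = outdir / sex
            d.mkdir(parents=True, exist_ok=True)
            df.to_csv(d / "cohort_raw.csv")
            result.data.to_csv(d / "cohort_screened.csv")
            result.usual.to_csv(d / "usual_intake.csv")
            result.model.to_csvs(d / "rrr")
            for pat in result.patterns:
                pd.DataFrame(
                    {"score": pat.score, "quintile": pat.quintile}
                ).to_csv(d / f"pattern{pat.factor_index}_scores.csv")
            result.partial_corr.to_csv(d / "partial_correlations.csv", index=False)
            for name, tbl in result.quintile_tables.items():
                tbl.to_csv(d / f"quintile_table_{name}.csv", index=False)
            result.chi_square.to_csv(d / "chi_square_tests.csv", index=False)
            result.regressions.to_csv(d / "regressions.csv", index=False)
            with open(d / "filter_log.json", "w") as fh:
                json.dump(result.filter_log, fh, indent=2)
            if truth is not None:
                from .synth import truth_summary

                truth_summary(truth).to_csv(d / "truth_summary.csv", index=False)

    demo = None
    if {"female", "male"} <= set(strata):
        demo = demographic_table(strata["female"].data, strata["male"].data)
        if outdir is not None:
            demo.to_csv(outdir / "demographics.csv", index=False)

    provenance = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
    }
    if outdir is not None:
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)
    return RunReport(config=config, strata=strata, demographics=demo, provenance=provenance)


def _fmt_cell(median: float, lo: float, hi: float) -> str:
    return f"{median:.3g} ({lo:.3g}-{hi:.3g})"


def render_report(report: RunReport) -> str:
    """Human-readable tables (median (min-max) cell convention)."""
    import warnings

    lines: list[str] = [f"dietrrr run report (seed={report.config.seed}, config={report.provenance['config_digest']})"]
    if report.demographics is not None:
        lines.append("\n== Demographics (female vs male) ==")
        lines.append(report.demographics.to_string(index=False))
    for sex, res in report.strata.items():
        lines.append(f"\n==== Stratum: {sex} (n={len(res.data)}) ====")
        lines.append(f"filter log: {res.filter_log}")
        lines.append("\n-- Explained variation --")
        lines.append(res.model.explained.to_string())
        for pat in res.patterns:
            if pat.quintile is None or pat.quintile.nunique() != 5:
                raise ValueError(f"expected 5 quintiles for pattern {pat.factor_index} in stratum {sex}")
            contrib = ", ".join(f"{g}({'+' if s > 0 else '-'}{abs(l):.2f})" for g, s, l in pat.contributing_groups)
            lines.append(f"\n-- Simplified pattern {pat.factor_index}: {contrib}")
            tbl = res.quintile_tables[f"pattern{pat.factor_index}"]
            show = tbl.copy()
            for k in range(1, 6):
                show[f"Q{k}"] = [
                    _fmt_cell(m, lo, hi) for m, lo, hi in zip(tbl[f"Q{k}_median"], tbl[f"Q{k}_min"], tbl[f"Q{k}_max"])
                ]
            cols = ["variable", "Q1", "Q3", "Q5", "trend_p"]
            lines.append(show[cols].to_string(index=False))
        if res.partial_corr.empty or res.regressions.empty:
            warnings.warn(f"association section empty for stratum {sex}; omitted", stacklevel=2)
        else:
            lines.append("\n-- Partial correlations (energy-adjusted) --")
            lines.append(res.partial_corr.to_string(index=False))
            lines.append("\n-- Outcome regressions --")
            lines.append(res.regressions.to_string(index=False))
    return "\n".join(lines)


def plot_loadings(model: RRRModel, path) -> None:
    """Bar chart of factor loadings, one panel per factor."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = model.n_factors
    fig, axes = plt.subplots(k, 1, figsize=(10, 3.2 * k), squeeze=False)
    for i in range(k):
        ax = axes[i][0]
        vals = model.loadings.iloc[:, i]
        ax.bar(range(len(vals)), vals.to_numpy())
        ax.axhline(0.2, ls="--", c="grey", lw=0.8)
        ax.axhline(-0.2, ls="--", c="grey", lw=0.8)
        ax.set_xticks(range(len(vals)))
        ax.set_xticklabels(vals.index, rotation=90, fontsize=6)
        ax.set_ylabel(f"factor {i + 1} loading")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
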