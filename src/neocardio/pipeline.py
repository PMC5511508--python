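"""End-to-end orchestration: generate -> derive -> centiles -> shape -> stats.

Each stage reads/writes plain CSV/JSON under one output directory; a
RunReport records per-stage status, output-file hashes and element counts,
so a rerun with the same config and seed reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from . import centiles as cent
from . import echo, shape, stats
from .cohort import Cohort, default_calibration, generate_cohort, write_cohort_csv
from .config import GeneratorConfig
from .contours import write_contours_csv

__all__ = ["RunConfig", "RunReport", "run_all", "summarize_table2",
           "percent_changes", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("generate", "derive", "centiles", "shape", "stats")

#: Table-2-style summary rows: (label, column, unit)
SUMMARY_MEASURES = [
    ("LV EDV", "lv_edv", "ml"),
    ("LV EDV index", "lv_edvi", "ml/m^2"),
    ("LV ESV", "lv_esv", "ml"),
    ("LV ESV index", "lv_esvi", "ml/m^2"),
    ("IVS diameter", "ivsd", "cm"),
    ("PWd", "pwd", "cm"),
    ("LV mass", "lv_mass", "g"),
    ("LV mass index", "lvmi", "g/m^2"),
    ("LV mass/EDV", "mass_edv_ratio", "g/ml"),
    ("LV ejection fraction", "ef", "%"),
    ("Stroke volume", "sv", "ml"),
    ("E/A", "ea_ratio", ""),
    ("Lateral E'", "lat_e_prime", "cm/s"),
    ("Lateral E/E'", "e_over_eprime", ""),
    ("RV EDV", "rv_edv", "ml"),
    ("RV EDV index", "rv_edvi", "ml/m^2"),
    ("RV mass", "rv_mass", "g"),
    ("RV mass index", "rvmi", "g/m^2"),
    ("TAPSE", "tapse", "cm"),
    ("RV ejection fraction", "rv_ef", "%"),
]


@dataclass
class RunConfig:
    generator: GeneratorConfig | None = None
    config_path: str | None = None
    cohort_csv: str | None = None
    outdir: str = "phg_out"
    stages: tuple = STAGES
    seed: int = 0
    rounding: int = 2

    def resolve_generator(self) -> GeneratorConfig | None:
        if self.generator is not None:
            return self.generator
        if self.config_path is not None:
            return GeneratorConfig.from_json(self.config_path)
        return None

    def validate(self):
        if (self.generator is None and self.config_path is None
                and self.cohort_csv is None):
            raise ValueError("need a generator config or a cohort CSV")
        k = len(self.stages)
        if k == 0 or tuple(self.stages) != STAGES[:k]:
            raise ValueError(f"stages must form a prefix of {STAGES}")


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    hashes: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    seed: int = 0

    def to_json(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _flag(p: float) -> str:
    if p < 0.001:
        return "†"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize_table2(derived: pd.DataFrame, rounding: int = 2) -> pd.DataFrame:
    """Group x stage mean (SD) summary with two-group significance flags.

    One row per measure and stage; columns preterm, term, flag (Welch test
    p-value thresholds 0.05/0.01/0.001 -> * / ** / †).
    """
    if "group" not in derived.columns:
        raise ValueError("derived table must carry a 'group' column")
    rows = []
    for stage in ("birth", "followup"):
        sub = derived[derived["stage"] == stage]
        for label, col, unit in SUMMARY_MEASURES:
            if col not in sub.columns:
                continue
            vals = {}
            for g in ("preterm", "term"):
                v = sub.loc[sub["group"] == g, col].dropna()
                if len(v) == 0:
                    raise ValueError(f"empty group {g!r} for {col} at {stage}")
                vals[g] = v
            t = stats.two_group_test(vals["preterm"], vals["term"], "welch")
            r = rounding
            rows.append({
                "stage": stage, "measure": label, "unit": unit,
                "preterm": f"{vals['preterm'].mean():.{r}f} "
                           f"({vals['preterm'].std(ddof=1):.{r}f})",
                "term": f"{vals['term'].mean():.{r}f} "
                        f"({vals['term'].std(ddof=1):.{r}f})",
                "p_value": t.p_value, "flag": _flag(t.p_value),
            })
    return pd.DataFrame(rows)


def percent_changes(derived: pd.DataFrame) -> pd.DataFrame:
    """Per-infant percent change in LV/RV mass index, birth -> follow-up."""
    b = derived[derived["stage"] == "birth"].set_index("subject_id")
    f = derived[derived["stage"] == "followup"].set_index("subject_id")
    common = b.index.intersection(f.index)
    out = pd.DataFrame(index=common)
    out["group"] = b.loc[common, "group"]
    out["ga_birth"] = b.loc[common, "ga_birth"]
    for col, name in (("lvmi", "dlvmi_pct"), ("rvmi", "drvmi_pct"),
                      ("lv_mass_linear", "dlvm_linear_pct")):
        out[name] = 100.0 * (f.loc[common, col] - b.loc[common, col]) \
            / b.loc[common, col]
    for cov in ("birthweight_z", "hypertension", "cesarean", "apgar5",
                "steroids"):
        if cov in b.columns:
            out[cov] = b.loc[common, cov]
    return out.reset_index()


def _centiles_stage(table: pd.DataFrame, outdir: Path, report: RunReport):
    """Fit the term fetal-to-postnatal standard, score preterm infants."""
    results = {}
    # the standard: term-delivering pregnancies, fetal scans through 3 months
    std_rows = table[table["group"] == "term"]
    pre_rows = table[(table["group"] == "preterm")
                     & table["stage"].isin(["birth", "followup"])]
    for outcome in ("lv_mass", "rv_mass"):
        model = cent.fit_centile_model(std_rows, outcome, repeated=True)
        model.to_json(outdir / f"centiles_{outcome}.json")
        ages = np.linspace(*model.age_range_, 60)
        curves = pd.DataFrame({
            "pma": ages,
            "c3": model.centile(ages, 3.0),
            "c50": model.centile(ages, 50.0),
            "c97": model.centile(ages, 97.0),
        })
        curves.to_csv(outdir / f"centile_curves_{outcome}.csv", index=False)
        birth = pre_rows[pre_rows["stage"] == "birth"].dropna(subset=[outcome])
        z = model.zscore(birth["pma"].to_numpy(), birth[outcome].to_numpy(),
                         extrapolate=True)
        pre_model = cent.fit_centile_model(pre_rows, outcome, repeated=True)
        gap49 = cent.trajectory_difference(pre_model, model, 49.0, 50.0,
                                           extrapolate=True)
        below95 = float(np.mean(z < _norm.ppf(0.95)))
        results[outcome] = {
            "powers": list(model.mean_fp_.powers_),
            "sigma": model.sigma_,
            "preterm_birth_z_mean": float(np.mean(z)),
            "preterm_birth_z_sd": float(np.std(z, ddof=1)),
            "preterm_birth_frac_below_c95": below95,
            "centile50_gap_at_49wk": float(gap49),
        }
    with open(outdir / "centiles_summary.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2)
    report.counts["centile_outcomes"] = len(results)
    return results


def _shape_stage(cohort: Cohort, outdir: Path, report: RunReport,
                 max_mode: int = 8):
    """Fit the PDM on endocardial borders, test modes, select the LDA."""
    sub = cohort.subjects.set_index("subject_id")
    keys, arrs = [], []
    for (sid, stage), (endo, _epi) in sorted(cohort.contours.items()):
        keys.append((sid, stage, sub.loc[sid, "group"]))
        arrs.append(endo.points)
    if len(arrs) < 10:
        raise ValueError("shape stage needs at least 10 contours")
    shapes = np.stack(arrs)
    aligned = shape.generalized_procrustes(shapes, retain_scale=True)
    pdm = shape.PointDistributionModel(n_modes=max_mode).fit(aligned.shapes)
    scores = pdm.transform(aligned.shapes, standardized=True)

    meta = pd.DataFrame(keys, columns=["subject_id", "stage", "group"])
    out = {"eigenvalues": list(map(float, pdm.eigenvalues_)),
           "explained": list(map(float, pdm.explained_variance_ratio_())),
           "conditions": {}}

    birth_mask = (meta["stage"] == "birth").to_numpy()
    fu_mask = (meta["stage"] == "followup").to_numpy()
    labels = meta["group"].to_numpy()

    for cond, mask in (("birth", birth_mask), ("followup", fu_mask)):
        p = shape.per_mode_group_test(scores[mask], labels[mask])
        out["conditions"][cond] = {"per_mode_p": list(map(float, p))}
    # growth: follow-up minus birth scores per subject
    b = pd.DataFrame(scores[birth_mask],
                     index=meta.loc[birth_mask, "subject_id"])
    f = pd.DataFrame(scores[fu_mask], index=meta.loc[fu_mask, "subject_id"])
    common = b.index.intersection(f.index)
    growth = (f.loc[common] - b.loc[common]).to_numpy()
    glabels = sub.loc[common, "group"].to_numpy()
    p = shape.per_mode_group_test(growth, glabels)
    out["conditions"]["growth"] = {"per_mode_p": list(map(float, p))}

    subset, curve = shape.select_mode_subset(
        scores[birth_mask], labels[birth_mask], max_mode=max_mode,
        positive_class="preterm")
    lda = shape.train_lda(scores[birth_mask], labels[birth_mask], subset,
                          positive_class="preterm")
    birth_scores = lda.decision_function(scores[birth_mask])
    fu_scores = lda.decision_function(scores[fu_mask])
    t_birth = stats.two_group_test(
        birth_scores[labels[birth_mask] == "preterm"],
        birth_scores[labels[birth_mask] == "term"], "welch")
    t_fu = stats.two_group_test(
        fu_scores[labels[fu_mask] == "preterm"],
        fu_scores[labels[fu_mask] == "term"], "welch")
    out["lda"] = {
        "mode_subset": list(subset),
        "auc_curve": [{"subset": list(s), "loo_auc": a} for s, a in curve],
        "resub_auc": lda.auc_,
        "birth_p": t_birth.p_value,
        "followup_p": t_fu.p_value,
    }
    with open(outdir / "shape_model.json", "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=2)

    # discriminant-axis shape extremes, +-3 SD, for plotting
    w = np.zeros(len(pdm.eigenvalues_))
    for m, wv in zip(subset, lda.coef_):
        w[m - 1] = wv
    w /= np.linalg.norm(w)
    rows = []
    for sd_mult in (-3.0, 3.0):
        pts = pdm.reconstruct(w, sd_multiple=sd_mult)
        for i, (x, y) in enumerate(pts):
            rows.append({"sd": sd_mult, "point_index": i, "x_cm": x, "y_cm": y})
    pd.DataFrame(rows).to_csv(outdir / "shape_mode_extremes.csv", index=False)
    report.counts["shapes"] = len(arrs)
    return out


def _stats_stage(derived: pd.DataFrame, outdir: Path, report: RunReport,
                 rounding: int):
    summary = summarize_table2(derived[derived["cohort"] == "neonatal"],
                               rounding)
    summary.to_csv(outdir / "table2_summary.csv", index=False)
    md = ["| Stage | Measure | Preterm | Term | p |",
          "|---|---|---|---|---|"]
    for _, r in summary.iterrows():
        md.append(f"| {r['stage']} | {r['measure']} | {r['preterm']} | "
                  f"{r['term']} | {r['p_value']:.3g}{r['flag']} |")
    (outdir / "table2_summary.md").write_text("\n".join(md), encoding="utf-8")

    pct = percent_changes(derived[derived["cohort"] == "neonatal"])
    res = {}
    for col, name in (("dlvmi_pct", "lv"), ("drvmi_pct", "rv")):
        pre = pct.loc[pct["group"] == "preterm", col].dropna()
        term = pct.loc[pct["group"] == "term", col].dropna()
        t = stats.two_group_test(pre, term, "welch")
        rr = stats.pearson_r(pct["ga_birth"].to_numpy(), pct[col].to_numpy())
        multi = stats.forced_entry_ols(
            pct[col].to_numpy(),
            pct[["ga_birth", "birthweight_z"]].astype(float))
        res[name] = {
            "mean_pct_change_preterm": float(pre.mean()),
            "mean_pct_change_term": float(term.mean()),
            "group_test_p": t.p_value,
            "corr_ga_change": rr.estimate,
            "corr_p": rr.p_value,
            "multivariate_B": multi.params,
            "multivariate_p": multi.pvalues,
        }
    birth_rows = derived[derived["stage"] == "birth"]
    res["mde_sd_units"] = stats.mde_two_sample(
        int((birth_rows["group"] == "term").sum()),
        int((birth_rows["group"] == "preterm").sum()))
    with open(outdir / "stats_summary.json", "w", encoding="utf-8") as fh:
        json.dump(res, fh, indent=2)
    report.counts["summary_rows"] = len(summary)
    return res


def run_all(config: RunConfig) -> RunReport:
    """Run the staged pipeline; deterministic for a fixed config and seed."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    logging.getLogger().addHandler(fh)

    cohort = None
    table = None
    try:
        for stage in config.stages:
            log.info("stage %s", stage)
            if stage == "generate":
                gen = config.resolve_generator()
                if gen is None:
                    table = pd.read_csv(config.cohort_csv)
                    report.stages[stage] = "skipped (cohort CSV supplied)"
                    continue
                cohort = generate_cohort(gen, config.seed)
                write_cohort_csv(outdir / "cohort.csv", cohort)
                if cohort.contours:
                    write_contours_csv(outdir / "contours.csv", cohort.contours)
                table = cohort.table()
                report.counts["subjects"] = len(cohort.subjects)
                report.counts["visits"] = len(cohort.visits)
            elif stage == "derive":
                if table is None:
                    table = pd.read_csv(config.cohort_csv)
                table = echo.derive_table(table)
                table.to_csv(outdir / "derived.csv", index=False)
            elif stage == "centiles":
                _centiles_stage(table, outdir, report)
            elif stage == "shape":
                if cohort is None or not cohort.contours:
                    report.stages[stage] = "skipped (no contours)"
                    continue
                _shape_stage(cohort, outdir, report)
            elif stage == "stats":
                _stats_stage(table, outdir, report, config.rounding)
            report.stages.setdefault(stage, "ok")
    except Exception as exc:
        report.stages[stage] = f"failed: {exc}"
        report.to_json(outdir / "report.json")
        raise RuntimeError(f"pipeline halted at stage {stage!r}: {exc}") from exc
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()

    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name not in ("report.json", "run.log"):
            report.hashes[p.name] = _sha256(p)
    report.to_json(outdir / "report.json")
    return report
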