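"""Synthetic preterm/term neonatal echo cohorts.

Generates subject and visit tables (plus optional ventricular contours)
whose statistical structure matches a two-group neonatal echo study:
preterm (mean GA ~34 weeks) and term (~39 weeks) infants scanned at birth
and at 3 months, a subset followed from 15 weeks of gestation, and a
separate fetal reference cohort with 1-5 scans per fetus.

The headline mechanism is the gestational-age effect on postnatal mass
accrual: per-infant percent change in ventricular mass index from birth to
follow-up is

    dPct = alpha + beta * GA_birth + eps,   eps ~ N(0, sigma_eps^2)

with (alpha, beta, sigma_eps) solved in closed form so that the two group
means and the population GA/dPct correlation equal their calibration
targets exactly (:func:`solve_ga_effect`).

Group gestational ages are drawn from truncated normals whose location is
solved so the *truncated* mean equals the configured group mean; the
calibration passes the truncated SDs into :func:`solve_ga_effect`, so the
generated population reproduces the target correlation without bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import echo
from .config import (
    ECHO_SAMPLED_BIRTH,
    ECHO_SAMPLED_FOLLOWUP,
    GROUPS,
    FetalModel,
    GAEffect,
    GeneratorConfig,
    HCModel,
    Normal,
    ShapeParams,
)
from .contours import generate_contour

__all__ = [
    "Cohort",
    "default_calibration",
    "solve_ga_effect",
    "generate_cohort",
    "truncnorm_mean_matched",
    "write_cohort_csv",
    "read_cohort_csv",
]


# ---------------------------------------------------------------------------
# truncated-normal helpers
# ---------------------------------------------------------------------------

def truncnorm_mean_matched(target_mean: float, sd: float, lower: float,
                           upper: float) -> tuple[float, float]:
    """Location parameter and realised SD of a truncated normal whose
    truncated mean equals ``target_mean``.

    Returns (loc, truncated_sd).  With sd == 0 the distribution is a point
    mass at target_mean.
    """
    if sd == 0:
        return target_mean, 0.0
    if not lower < target_mean < upper:
        raise ValueError("target mean must lie inside the truncation bounds")

    def gap(loc):
        a, b = (lower - loc) / sd, (upper - loc) / sd
        return stats.truncnorm.mean(a, b, loc, sd) - target_mean

    loc = optimize.brentq(gap, lower, upper)
    a, b = (lower - loc) / sd, (upper - loc) / sd
    return loc, float(stats.truncnorm.std(a, b, loc, sd))


def _draw_truncnorm(rng, mean, sd, lower, upper, size):
    """Symmetric-bound-respecting truncated normal draw (plain truncation)."""
    if sd == 0:
        return np.full(size, mean)
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


# ---------------------------------------------------------------------------
# GA-effect calibration
# ---------------------------------------------------------------------------

def solve_ga_effect(mean_pre: float, mean_term: float, ga_mean_pre: float,
                    ga_mean_term: float, ga_sd_pre: float, ga_sd_term: float,
                    w_pre: float, target_r: float) -> GAEffect:
    """Closed-form (alpha, beta, sigma_eps) for the percent-change model.

    Under dPct = alpha + beta*GA + eps with GA from the two-component normal
    mixture (weight w_pre on the preterm component), the group means equal
    mean_pre / mean_term exactly and the population Pearson correlation
    between GA and dPct equals target_r:

        beta      = (mean_pre - mean_term) / (ga_mean_pre - ga_mean_term)
        sigma_eps = |beta| * sigma_GA_mix * sqrt(1/r^2 - 1)

    where sigma_GA_mix^2 is the mixture variance of GA.  Degenerate case:
    equal group means force beta = 0 and (with it) sigma_eps = 0 regardless
    of target_r.
    """
    if ga_mean_pre == ga_mean_term:
        raise ValueError("group GA means must differ")
    if not 0.0 < w_pre < 1.0:
        raise ValueError("w_pre must lie in (0, 1)")
    if not abs(target_r) < 1 or target_r == 0:
        raise ValueError("target_r must satisfy 0 < |r| < 1")
    beta = (mean_pre - mean_term) / (ga_mean_pre - ga_mean_term)
    alpha = mean_pre - beta * ga_mean_pre
    if beta == 0.0:
        return GAEffect(alpha=alpha, beta=0.0, sigma_eps=0.0)
    if math.copysign(1.0, target_r) != math.copysign(1.0, beta):
        raise ValueError(
            "target_r sign conflicts with the sign of beta implied by the "
            "group means: no noise level can produce it")
    var_mix = (w_pre * ga_sd_pre ** 2 + (1 - w_pre) * ga_sd_term ** 2
               + w_pre * (1 - w_pre) * (ga_mean_pre - ga_mean_term) ** 2)
    sigma_eps = abs(beta) * math.sqrt(var_mix) * math.sqrt(1.0 / target_r ** 2 - 1.0)
    return GAEffect(alpha=alpha, beta=beta, sigma_eps=sigma_eps)


# ---------------------------------------------------------------------------
# default calibration (group sizes, GA, echo means/SDs, effects, shapes)
# ---------------------------------------------------------------------------

def _n(mean, sd):
    return Normal(mean=mean, sd=sd)


def default_calibration() -> GeneratorConfig:
    """Fully populated configuration for the emulated two-group study.

    Group sizes 121/134; GA at delivery 33.9 (2.2) vs 39.4 (1.3) weeks;
    birth and 3-month echo means/SDs per group; percent mass-change model
    calibrated to group means 57.8/27.3 % (LV) and 39.3/16.6 % (RV) with
    GA/change correlations -0.49 and -0.37 on the combined cohort.
    """
    cfg = GeneratorConfig()
    cfg.ga_birth = {"preterm": _n(33.9, 2.2), "term": _n(39.4, 1.3)}
    cfg.echo_birth = {
        "preterm": {
            "lvmi": _n(18.8, 3.9), "lv_edvi": _n(16.8, 5.5),
            "lv_esvi": _n(7.0, 2.4), "rvmi": _n(16.3, 5.6),
            "rv_edvi": _n(11.1, 4.4), "ivsd": _n(0.33, 0.08),
            "pwd": _n(0.29, 0.06), "lvidd": _n(1.7, 0.2),
            "tapse": _n(0.7, 0.2), "lat_e_prime": _n(6.1, 1.8),
            "ea": _n(1.0, 0.2), "e_over_eprime": _n(8.5, 2.5),
            "rv_ef": _n(49.0, 12.0),
        },
        "term": {
            "lvmi": _n(20.7, 3.9), "lv_edvi": _n(18.5, 4.3),
            "lv_esvi": _n(6.8, 2.6), "rvmi": _n(17.9, 4.3),
            "rv_edvi": _n(14.7, 5.7), "ivsd": _n(0.39, 0.08),
            "pwd": _n(0.30, 0.07), "lvidd": _n(1.9, 0.2),
            "tapse": _n(0.9, 0.2), "lat_e_prime": _n(6.6, 1.7),
            "ea": _n(1.0, 0.3), "e_over_eprime": _n(7.9, 2.5),
            "rv_ef": _n(51.0, 8.0),
        },
    }
    cfg.echo_followup = {
        "preterm": {
            "lv_edvi": _n(27.6, 5.8), "lv_esvi": _n(11.7, 3.3),
            "rv_edvi": _n(15.4, 5.7), "ivsd": _n(0.44, 0.08),
            "pwd": _n(0.38, 0.07), "lvidd": _n(2.4, 0.25),
            "tapse": _n(1.4, 0.3), "lat_e_prime": _n(9.4, 2.3),
            "ea": _n(1.1, 0.2), "e_over_eprime": _n(10.1, 2.7),
            "rv_ef": _n(56.0, 13.0),
        },
        "term": {
            "lv_edvi": _n(26.8, 5.0), "lv_esvi": _n(10.9, 2.7),
            "rv_edvi": _n(15.2, 4.4), "ivsd": _n(0.43, 0.08),
            "pwd": _n(0.35, 0.06), "lvidd": _n(2.5, 0.25),
            "tapse": _n(1.5, 0.3), "lat_e_prime": _n(10.2, 2.2),
            "ea": _n(1.0, 0.2), "e_over_eprime": _n(9.4, 2.7),
            "rv_ef": _n(56.0, 13.0),
        },
    }
    cfg.birthweight = {"preterm": _n(2053.0, 587.0), "term": _n(3315.0, 563.0)}
    cfg.birthweight_z = {"preterm": _n(-0.38, 1.1), "term": _n(0.16, 1.1)}
    cfg.weight_followup = {"preterm": _n(4960.0, 967.0), "term": _n(6051.0, 894.0)}
    cfg.age_birth_visit = {"preterm": _n(6.6, 5.4), "term": _n(4.0, 5.5)}
    cfg.age_followup_visit = {"preterm": _n(99.1, 15.1), "term": _n(98.0, 13.8)}
    cfg.covariate_probs = {
        "preterm": {"steroids": 93 / 121, "cesarean": 77 / 121,
                    "hypertension": 70 / 121, "male": 60 / 121,
                    "multiple": 0.092, "smoker": 7 / 121},
        "term": {"steroids": 1 / 134, "cesarean": 36 / 134,
                 "hypertension": 81 / 134, "male": 59 / 134,
                 "multiple": 0.015, "smoker": 4 / 134},
    }
    # GA-effect: pass the *sampling* (truncated) SDs so the generated
    # population correlation matches the target exactly.
    w_pre = cfg.n_preterm / (cfg.n_preterm + cfg.n_term)
    _, sd_pre = truncnorm_mean_matched(
        cfg.ga_birth["preterm"].mean, cfg.ga_birth["preterm"].sd,
        cfg.ga_floor, cfg.preterm_cutoff)
    _, sd_term = truncnorm_mean_matched(
        cfg.ga_birth["term"].mean, cfg.ga_birth["term"].sd,
        cfg.preterm_cutoff,
        cfg.ga_birth["term"].mean + cfg.truncation_sds * cfg.ga_birth["term"].sd)
    cfg.ga_effect = {
        "lv": solve_ga_effect(57.8, 27.3, 33.9, 39.4, sd_pre, sd_term,
                              w_pre, -0.49),
        "rv": solve_ga_effect(39.3, 16.6, 33.9, 39.4, sd_pre, sd_term,
                              w_pre, -0.37),
    }
    # shape family: preterm more globular and smaller at birth; shape
    # difference resolved by follow-up while both hearts have grown.
    cfg.shape_params = {
        "preterm": {
            "birth": ShapeParams(globularity=0.6, size_scale=1.25),
            "followup": ShapeParams(globularity=0.1, size_scale=1.85),
        },
        "term": {
            "birth": ShapeParams(globularity=-0.2, size_scale=1.45),
            "followup": ShapeParams(globularity=0.1, size_scale=1.95),
        },
    }
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Generated cohort: subject covariates, visit rows, optional contours.

    subjects: one row per infant/fetus; visits: one row per assessment;
    contours: {(subject_id, stage): (endo, epi)} for postnatal visits.
    """

    subjects: pd.DataFrame
    visits: pd.DataFrame
    contours: dict

    def table(self) -> pd.DataFrame:
        """Visits with subject covariates joined on subject_id."""
        return self.visits.merge(self.subjects, on="subject_id", how="left")


def _sample_group_subjects(cfg, group, n, rng, start_id):
    ga_cfg = cfg.ga_birth[group]
    if group == "preterm":
        lo, hi = cfg.ga_floor, cfg.preterm_cutoff
    else:
        lo = cfg.preterm_cutoff
        hi = ga_cfg.mean + cfg.truncation_sds * ga_cfg.sd
    loc, _ = truncnorm_mean_matched(ga_cfg.mean, ga_cfg.sd, lo, hi)
    ga = _draw_truncnorm(rng, loc, ga_cfg.sd, lo, hi, n)

    bw_cfg = cfg.birthweight[group]
    slope = cfg.birthweight_ga_slope[group]
    resid_var = max(bw_cfg.sd ** 2 - slope ** 2 * np.var(ga), bw_cfg.sd ** 2 * 0.1)
    bw = bw_cfg.mean + slope * (ga - ga.mean()) + rng.normal(
        0.0, math.sqrt(resid_var), n)
    bw = np.maximum(bw, 300.0)

    z_cfg = cfg.birthweight_z[group]
    # birthweight z mildly tracks the weight residual within group
    zr = rng.normal(0.0, 1.0, n)
    bw_std = (bw - bw.mean()) / max(bw.std(), 1e-9)
    bwz = z_cfg.mean + z_cfg.sd * (0.5 * bw_std + math.sqrt(1 - 0.25) * zr)

    probs = cfg.covariate_probs[group]
    apgar_p = {"preterm": ([10, 9, 8, 7], [0.60, 0.25, 0.10, 0.05]),
               "term": ([10, 9, 8], [0.80, 0.15, 0.05])}[group]
    sub = pd.DataFrame({
        "subject_id": [f"{group[0].upper()}{start_id + i:05d}" for i in range(n)],
        "group": group,
        "ga_birth": ga,
        "birthweight": bw,
        "birthweight_z": bwz,
        "steroids": rng.random(n) < probs["steroids"],
        "cesarean": rng.random(n) < probs["cesarean"],
        "hypertension": rng.random(n) < probs["hypertension"],
        "multiple": rng.random(n) < probs["multiple"],
        "sex": np.where(rng.random(n) < probs["male"], "M", "F"),
        "apgar5": rng.choice(apgar_p[0], size=n, p=apgar_p[1]),
    })
    return sub


def _hc_curve(hc: HCModel, pma):
    return hc.asymptote * np.exp(-np.exp(-hc.rate * (pma - hc.midpoint)))


def _sample_echo_block(cfg, group, stage, n, rng):
    """Sample the per-visit echo quantities for one group x stage block."""
    block = (cfg.echo_birth if stage == "birth" else cfg.echo_followup)[group]
    names = ECHO_SAMPLED_BIRTH if stage == "birth" else ECHO_SAMPLED_FOLLOWUP
    t = cfg.truncation_sds
    out = {}
    for name in names:
        if name in ("lv_edvi", "lv_esvi"):
            continue  # sampled jointly below
        m = block[name]
        floor = 1e-3 if name not in ("rv_ef",) else 1.0
        out[name] = _draw_truncnorm(
            rng, m.mean, m.sd, max(m.mean - t * m.sd, floor), m.mean + t * m.sd, n)
    # EDVI/ESVI correlated pair; resample pairs violating 0 < ESVI < EDVI
    edv_m, esv_m = block["lv_edvi"], block["lv_esvi"]
    rho = cfg.edv_esv_corr
    edvi = np.empty(n)
    esvi = np.empty(n)
    todo = np.arange(n)
    for _ in range(100):
        k = len(todo)
        z1 = rng.normal(size=k)
        z2 = rho * z1 + math.sqrt(1 - rho ** 2) * rng.normal(size=k)
        e = edv_m.mean + edv_m.sd * np.clip(z1, -t, t)
        s = esv_m.mean + esv_m.sd * np.clip(z2, -t, t)
        edvi[todo], esvi[todo] = e, s
        bad = (esvi[todo] <= 0.05 * edvi[todo]) | (esvi[todo] >= 0.98 * edvi[todo]) \
            | (edvi[todo] <= 0)
        todo = todo[bad]
        if len(todo) == 0:
            break
    out["lv_edvi"], out["lv_esvi"] = edvi, esvi
    return out


def _postnatal_visit_rows(cfg, sub, stage, rng):
    """Build raw visit rows for one postnatal stage across all subjects."""
    n = len(sub)
    rows = {"subject_id": sub["subject_id"].to_numpy(), "stage": stage}
    parts = []
    for group in GROUPS:
        mask = (sub["group"] == group).to_numpy()
        k = int(mask.sum())
        if k == 0:
            continue
        age_cfg = (cfg.age_birth_visit if stage == "birth"
                   else cfg.age_followup_visit)[group]
        age = _draw_truncnorm(rng, age_cfg.mean, age_cfg.sd,
                              max(0.0, age_cfg.mean - cfg.truncation_sds * age_cfg.sd),
                              age_cfg.mean + cfg.truncation_sds * age_cfg.sd, k)
        ga = sub.loc[mask, "ga_birth"].to_numpy()
        pma = ga + age / 7.0
        if stage == "birth":
            weight = sub.loc[mask, "birthweight"].to_numpy()
        else:
            w_cfg = cfg.weight_followup[group]
            bw_cfg = cfg.birthweight[group]
            bw = sub.loc[mask, "birthweight"].to_numpy()
            rho = cfg.weight_tracking_corr
            z = rho * (bw - bw_cfg.mean) / bw_cfg.sd \
                + math.sqrt(1 - rho ** 2) * rng.normal(size=k)
            weight = np.maximum(w_cfg.mean + w_cfg.sd * np.clip(
                z, -cfg.truncation_sds, cfg.truncation_sds), 1000.0)
        hc_off = sub.loc[mask, "_hc_offset"].to_numpy()
        hc = np.maximum(_hc_curve(cfg.hc_model, pma) + hc_off
                        + rng.normal(0, cfg.hc_model.noise_sd, k), 5.0)
        e = _sample_echo_block(cfg, group, stage, k, rng)
        parts.append((mask, age, pma, weight, hc, e))

    age = np.empty(n); pma = np.empty(n); weight = np.empty(n); hc = np.empty(n)
    echo_cols = {}
    for mask, a, p, w, h, e in parts:
        age[mask], pma[mask], weight[mask], hc[mask] = a, p, w, h
        for kname, vals in e.items():
            echo_cols.setdefault(kname, np.full(n, np.nan))[mask] = vals
    rows.update({"age_days": age, "pma": pma, "weight": weight, "hc": hc})
    rows.update(echo_cols)
    return pd.DataFrame(rows)


def _finalize_postnatal(df, sub, cfg, dpct_lv, dpct_rv, birth_df=None):
    """Convert sampled indices to raw measures; apply the GA-effect at
    follow-up (mass index = birth index * (1 + dPct/100))."""
    bsa = echo.boyd_bsa(df["weight"].to_numpy())
    if birth_df is None:  # birth stage: indices as sampled
        lvmi = df.pop("lvmi").to_numpy()
        rvmi = df.pop("rvmi").to_numpy()
    else:
        b = birth_df.set_index("subject_id")
        birth_lvmi = (b["lv_mass"] / echo.boyd_bsa(b["weight"].to_numpy())
                      ).reindex(df["subject_id"]).to_numpy()
        birth_rvmi = (b["rv_mass"] / echo.boyd_bsa(b["weight"].to_numpy())
                      ).reindex(df["subject_id"]).to_numpy()
        # dpct is capped at -95% upstream, so the follow-up index stays
        # strictly positive (>= 5% of the birth index)
        lvmi = birth_lvmi * (1.0 + dpct_lv / 100.0)
        rvmi = birth_rvmi * (1.0 + dpct_rv / 100.0)
    df["lv_mass"] = lvmi * bsa
    df["rv_mass"] = rvmi * bsa
    df["lv_edv"] = df.pop("lv_edvi").to_numpy() * bsa
    df["lv_esv"] = df.pop("lv_esvi").to_numpy() * bsa
    df["rv_edv"] = df.pop("rv_edvi").to_numpy() * bsa
    e_prime = df["lat_e_prime"].to_numpy()
    df["mv_e"] = df.pop("e_over_eprime").to_numpy() * e_prime
    df["mv_a"] = df["mv_e"].to_numpy() / df.pop("ea").to_numpy()
    return df


def _fetal_visit_rows(cfg, sub, rng):
    """Fetal scan rows for subjects flagged with antenatal follow-up."""
    fm = cfg.fetal
    rows = []
    b0, b1, b2 = fm.log_mass_coef
    for _, s in sub.iterrows():
        n_vis = int(rng.choice(np.arange(1, len(fm.visit_count_probs) + 1),
                               p=fm.visit_count_probs))
        upper = min(fm.age_max, s["ga_birth"] - 0.5)
        if upper <= fm.age_min:
            continue
        first = rng.uniform(fm.age_min, max(fm.age_min + 1e-6,
                                            upper - fm.visit_spacing * (n_vis - 1)))
        ages = first + fm.visit_spacing * np.arange(n_vis) \
            + rng.uniform(-fm.spacing_jitter, fm.spacing_jitter, n_vis)
        ages = np.sort(np.clip(ages, fm.age_min, upper))
        u = rng.normal(0.0, fm.subject_sd)
        for t in ages:
            mu = b0 + b1 * math.log(t) + b2 * t
            lv = math.exp(mu + u + rng.normal(0.0, fm.noise_sd))
            rv = math.exp(mu + fm.rv_log_offset + u + rng.normal(0.0, fm.noise_sd))
            hc = max(_hc_curve(cfg.hc_model, t) + s["_hc_offset"]
                     + rng.normal(0.0, cfg.hc_model.noise_sd), 2.0)
            rows.append({"subject_id": s["subject_id"], "stage": "fetal",
                         "pma": t, "hc": hc, "lv_mass": lv, "rv_mass": rv})
    return pd.DataFrame(rows)


def _make_contours(cfg, sub, visits, rng):
    contours = {}
    n_pts = cfg.contour_points
    post = visits[visits["stage"].isin(["birth", "followup"])]
    sp_all = cfg.shape_params
    sub_idx = sub.set_index("subject_id")
    for _, v in post.iterrows():
        sid = v["subject_id"]
        group = sub_idx.loc[sid, "group"]
        sp = sp_all[group][v["stage"]]
        g = float(np.clip(rng.normal(sp.globularity, sp.globularity_sd), -1, 1))
        size = max(sp.size_scale * (1.0 + rng.normal(0.0, sp.size_cv)), 0.2)
        child = np.random.default_rng(rng.integers(2 ** 31))
        contours[(sid, v["stage"])] = generate_contour(
            g, size, sp.annulus_ratio, sp.wall_thickness, n_pts,
            sp.noise_sd, child, length_width_ratio=(
                sp.length_width_ratio if sp.length_width_ratio is not None
                else None))
    return contours


def generate_cohort(config: GeneratorConfig, seed: int,
                    with_contours: bool | None = None) -> Cohort:
    """Generate a full synthetic cohort. Deterministic for a fixed seed.

    Returns a :class:`Cohort` with raw (not derived) echo measures; run
    :func:`neocardio.echo.derive_table` to append derived indices.
    """
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise TypeError("seed must be an integer")
    config.validate()
    rng = np.random.default_rng(int(seed))
    if with_contours is None:
        with_contours = config.with_contours

    sub_pre = _sample_group_subjects(config, "preterm", config.n_preterm, rng, 0)
    sub_term = _sample_group_subjects(config, "term", config.n_term, rng, 0)
    neonatal = pd.concat([sub_pre, sub_term], ignore_index=True)
    neonatal["cohort"] = "neonatal"

    # fetal-only reference pregnancies (uncomplicated, term-delivering)
    if config.n_fetal > 0:
        fet = _sample_group_subjects(config, "term", max(config.n_fetal, 2),
                                     rng, 90000).iloc[: config.n_fetal]
        fet = fet.copy()
        fet["subject_id"] = [f"F{90000 + i:05d}" for i in range(len(fet))]
        fet["cohort"] = "fetal"
        subjects = pd.concat([neonatal, fet], ignore_index=True)
    else:
        fet = neonatal.iloc[0:0]
        subjects = neonatal

    subjects["_hc_offset"] = rng.normal(0.0, config.hc_model.subject_sd,
                                        len(subjects))

    # antenatal follow-up flags: the configured overlap subset plus all
    # fetal-only pregnancies get fetal scans
    overlap_ids = []
    for group, k in config.n_fetal_overlap.items():
        ids = subjects.loc[(subjects["group"] == group)
                           & (subjects["cohort"] == "neonatal"), "subject_id"]
        overlap_ids.extend(ids.iloc[: min(k, len(ids))])
    fetal_sub = subjects[subjects["subject_id"].isin(overlap_ids)
                         | (subjects["cohort"] == "fetal")]

    neo_mask = subjects["cohort"] == "neonatal"
    neo = subjects[neo_mask].reset_index(drop=True)

    # per-infant percent mass change from the GA-effect model
    ga = neo["ga_birth"].to_numpy()
    eff_lv, eff_rv = config.ga_effect["lv"], config.ga_effect["rv"]
    dpct_lv = eff_lv.alpha + eff_lv.beta * ga + rng.normal(
        0.0, eff_lv.sigma_eps, len(neo))
    dpct_rv = eff_rv.alpha + eff_rv.beta * ga + rng.normal(
        0.0, eff_rv.sigma_eps, len(neo))
    dpct_lv = np.maximum(dpct_lv, -95.0)
    dpct_rv = np.maximum(dpct_rv, -95.0)

    birth = _postnatal_visit_rows(config, neo, "birth", rng)
    birth = _finalize_postnatal(birth, neo, config, dpct_lv, dpct_rv)
    follow = _postnatal_visit_rows(config, neo, "followup", rng)
    follow = _finalize_postnatal(follow, neo, config, dpct_lv, dpct_rv,
                                 birth_df=birth)
    fetal = _fetal_visit_rows(config, fetal_sub, rng)

    visits = pd.concat([fetal, birth, follow], ignore_index=True)
    order = {"fetal": 0, "birth": 1, "followup": 2}
    visits = visits.sort_values(
        ["subject_id", "stage"], key=lambda c: c.map(order) if c.name == "stage" else c
    ).reset_index(drop=True)
    # enforce strictly increasing HC along each subject's trajectory: the
    # growth signal dominates but measurement noise could dip between
    # closely spaced visits
    hc = visits.groupby("subject_id", sort=False)["hc"].cummax()
    bump = visits.groupby("subject_id", sort=False).cumcount() * 1e-3
    visits["hc"] = hc + bump

    contours = (_make_contours(config, subjects, visits, rng)
                if with_contours else {})

    subjects = subjects.drop(columns=["_hc_offset"])
    return Cohort(subjects=subjects, visits=visits, contours=contours)


# ---------------------------------------------------------------------------
# CSV IO: one row per visit, subject covariates joined on subject_id
# ---------------------------------------------------------------------------

def write_cohort_csv(path, cohort: Cohort) -> None:
    cohort.table().to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
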