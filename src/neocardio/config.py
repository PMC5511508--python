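"""Generator configuration: every calibration constant of the synthetic cohort.

The configuration is a plain nested dataclass tree so it can be serialized
to/from JSON, diffed, and validated without any schema machinery.  Units are
stated per field: gestational and postmenstrual ages in weeks, weights in
grams, linear echo measures in cm, velocities in cm/s, indexed quantities in
g/m^2 or ml/m^2, percent changes in %.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "Normal",
    "GAEffect",
    "ShapeParams",
    "HCModel",
    "FetalModel",
    "GeneratorConfig",
]


@dataclass
class Normal:
    """A mean/SD pair defining a (possibly truncated) normal distribution."""

    mean: float
    sd: float

    def validate(self, name: str = "Normal") -> None:
        if self.sd < 0:
            raise ValueError(f"{name}: sd must be >= 0, got {self.sd}")


@dataclass
class GAEffect:
    """Linear gestational-age effect on percent mass change.

    Per-infant percent change is drawn as ``alpha + beta * ga_birth + eps``
    with ``eps ~ Normal(0, sigma_eps**2)``.  ``alpha`` in %, ``beta`` in
    %/week, ``sigma_eps`` in %.
    """

    alpha: float
    beta: float
    sigma_eps: float

    def validate(self, name: str = "GAEffect") -> None:
        if self.sigma_eps < 0:
            raise ValueError(f"{name}: sigma_eps must be >= 0")


@dataclass
class ShapeParams:
    """Parametric ventricular silhouette family for one group x stage cell.

    globularity in [-1, 1] maps to the length/width ratio and superellipse
    exponent (+1 = globular, -1 = conical); size_scale is the maximal
    endocardial width in cm; annulus_ratio is the annulus chord width as a
    fraction of the maximal width; wall_thickness in cm; noise_sd is i.i.d.
    Gaussian point jitter in cm.
    """

    globularity: float
    globularity_sd: float = 0.25
    annulus_ratio: float = 0.85
    wall_thickness: float = 0.30
    size_scale: float = 1.4
    size_cv: float = 0.08
    noise_sd: float = 0.02
    length_width_ratio: float | None = None  # optional override of the mapping

    def validate(self, name: str = "ShapeParams") -> None:
        if not -1.0 <= self.globularity <= 1.0:
            raise ValueError(f"{name}: globularity must lie in [-1, 1]")
        if not 0.0 < self.annulus_ratio < 1.0:
            raise ValueError(f"{name}: annulus_ratio must lie in (0, 1)")
        if self.wall_thickness <= 0 or self.size_scale <= 0:
            raise ValueError(f"{name}: wall_thickness and size_scale must be > 0")
        for attr in ("globularity_sd", "size_cv", "noise_sd"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{name}: {attr} must be >= 0")


@dataclass
class HCModel:
    """Head circumference as a monotone (Gompertz) function of PMA.

    hc(t) = asymptote * exp(-exp(-rate * (t - midpoint))) + subject offset.
    Defaults reproduce the printed birth/follow-up HC means to ~0.4 cm and a
    plausible 15-week fetal HC (~12 cm).
    """

    asymptote: float = 47.0
    rate: float = 0.0592
    midpoint: float = 20.4
    subject_sd: float = 1.2
    noise_sd: float = 0.3

    def validate(self) -> None:
        if self.asymptote <= 0 or self.rate <= 0:
            raise ValueError("HCModel: asymptote and rate must be > 0")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("HCModel: SDs must be >= 0")


@dataclass
class FetalModel:
    """Fetal ventricular mass trajectory and visit schedule.

    ln(mass) = b0 + b1*ln(pma) + b2*pma + subject intercept + visit noise.
    The default coefficients put LV mass at 0.07 g at 15 weeks and 4.7 g at
    40 weeks (the term-birth mean), with the RV a constant log-offset below
    the LV matching the printed term-birth RV/LV mass ratio.
    visit_count_probs emulate the observed 1-5 scans per fetus
    (110/43/21/12/6 of 192).
    """

    log_mass_coef: tuple[float, float, float] = (-18.81700, 6.43232, -0.08409)
    subject_sd: float = 0.12
    noise_sd: float = 0.10
    rv_log_offset: float = math.log(4.1 / 4.7)
    visit_count_probs: tuple[float, ...] = (
        110 / 192,
        43 / 192,
        21 / 192,
        12 / 192,
        6 / 192,
    )
    age_min: float = 15.0
    age_max: float = 40.0
    visit_spacing: float = 4.0
    spacing_jitter: float = 1.0

    def validate(self) -> None:
        if abs(sum(self.visit_count_probs) - 1.0) > 1e-9:
            raise ValueError("FetalModel: visit_count_probs must sum to 1")
        if any(p < 0 for p in self.visit_count_probs):
            raise ValueError("FetalModel: visit_count_probs must be >= 0")
        if not 0 < self.age_min < self.age_max:
            raise ValueError("FetalModel: need 0 < age_min < age_max")


GROUPS = ("preterm", "term")
STAGES = ("fetal", "birth", "followup")

#: echo measures sampled directly from configured Normals at postnatal stages
ECHO_SAMPLED_BIRTH = (
    "lvmi",
    "lv_edvi",
    "lv_esvi",
    "rvmi",
    "rv_edvi",
    "ivsd",
    "pwd",
    "lvidd",
    "tapse",
    "lat_e_prime",
    "ea",
    "e_over_eprime",
    "rv_ef",
)
# at follow-up the mass indices come from the GA-effect model, not a Normal
ECHO_SAMPLED_FOLLOWUP = tuple(
    m for m in ECHO_SAMPLED_BIRTH if m not in ("lvmi", "rvmi")
)


@dataclass
class GeneratorConfig:
    """All calibration constants for :func:`neocardio.cohort.generate_cohort`."""

    n_preterm: int = 121
    n_term: int = 134
    n_fetal: int = 137  # fetal-only reference pregnancies (term standard)
    n_fetal_overlap: dict[str, int] = field(
        default_factory=lambda: {"preterm": 10, "term": 45}
    )
    ga_birth: dict[str, Normal] = field(default_factory=dict)
    preterm_cutoff: float = 37.0  # weeks; preterm GA < cutoff <= term GA
    ga_floor: float = 24.0  # viability floor for preterm GA, weeks
    echo_birth: dict[str, dict[str, Normal]] = field(default_factory=dict)
    echo_followup: dict[str, dict[str, Normal]] = field(default_factory=dict)
    edv_esv_corr: float = 0.9  # within-subject EDVI/ESVI correlation
    ga_effect: dict[str, GAEffect] = field(default_factory=dict)  # 'lv', 'rv'
    covariate_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    birthweight: dict[str, Normal] = field(default_factory=dict)
    birthweight_ga_slope: dict[str, float] = field(
        default_factory=lambda: {"preterm": 150.0, "term": 120.0}  # g/week
    )
    birthweight_z: dict[str, Normal] = field(default_factory=dict)
    weight_followup: dict[str, Normal] = field(default_factory=dict)
    weight_tracking_corr: float = 0.7  # birth vs follow-up weight correlation
    age_birth_visit: dict[str, Normal] = field(default_factory=dict)  # days
    age_followup_visit: dict[str, Normal] = field(default_factory=dict)  # days
    hc_model: HCModel = field(default_factory=HCModel)
    fetal: FetalModel = field(default_factory=FetalModel)
    shape_params: dict[str, dict[str, ShapeParams]] = field(default_factory=dict)
    contour_points: int = 50
    with_contours: bool = True
    truncation_sds: float = 4.0  # two-sided truncation of sampled measures
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_preterm < 2 or self.n_term < 2:
            raise ValueError("n_preterm and n_term must each be >= 2")
        if self.n_fetal < 0:
            raise ValueError("n_fetal must be >= 0")
        if not 0 < self.ga_floor < self.preterm_cutoff:
            raise ValueError("need 0 < ga_floor < preterm_cutoff")
        for g in GROUPS:
            if g not in self.ga_birth:
                raise ValueError(f"ga_birth missing group {g!r}")
            self.ga_birth[g].validate(f"ga_birth[{g}]")
        if not self.ga_birth["preterm"].mean < self.preterm_cutoff:
            raise ValueError("preterm GA mean must lie below the cutoff")
        if not self.ga_birth["term"].mean >= self.preterm_cutoff:
            raise ValueError("term GA mean must lie at or above the cutoff")
        for block, names in (
            (self.echo_birth, ECHO_SAMPLED_BIRTH),
            (self.echo_followup, ECHO_SAMPLED_FOLLOWUP),
        ):
            for g in GROUPS:
                for m in names:
                    if m not in block.get(g, {}):
                        raise ValueError(f"echo config missing {g}/{m}")
                    block[g][m].validate(f"echo[{g}][{m}]")
        for v in ("lv", "rv"):
            if v not in self.ga_effect:
                raise ValueError(f"ga_effect missing ventricle {v!r}")
            self.ga_effect[v].validate(f"ga_effect[{v}]")
        for g in GROUPS:
            for k, p in self.covariate_probs.get(g, {}).items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"covariate_probs[{g}][{k}] not in [0,1]")
            for stage in ("birth", "followup"):
                sp = self.shape_params.get(g, {}).get(stage)
                if sp is None:
                    raise ValueError(f"shape_params missing {g}/{stage}")
                sp.validate(f"shape_params[{g}][{stage}]")
        if not -1.0 < self.edv_esv_corr < 1.0:
            raise ValueError("edv_esv_corr must lie in (-1, 1)")
        if self.contour_points < 20:
            raise ValueError("contour_points must be >= 20")
        self.hc_model.validate()
        self.fetal.validate()

    # ------------------------------------------------------------------
    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=indent)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "GeneratorConfig":
        """Load from a JSON string or a path to a JSON file."""
        text = source
        if "{" not in source:
            with open(source, encoding="utf-8") as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorConfig":
        def normals(block):
            return {g: {k: Normal(**v) for k, v in sub.items()} for g, sub in block.items()}

        kwargs = dict(d)
        kwargs["ga_birth"] = {g: Normal(**v) for g, v in d["ga_birth"].items()}
        kwargs["echo_birth"] = normals(d["echo_birth"])
        kwargs["echo_followup"] = normals(d["echo_followup"])
        kwargs["ga_effect"] = {v: GAEffect(**e) for v, e in d["ga_effect"].items()}
        for key in ("birthweight", "birthweight_z", "weight_followup",
                    "age_birth_visit", "age_followup_visit"):
            kwargs[key] = {g: Normal(**v) for g, v in d[key].items()}
        kwargs["hc_model"] = HCModel(**d["hc_model"])
        fetal = dict(d["fetal"])
        fetal["log_mass_coef"] = tuple(fetal["log_mass_coef"])
        fetal["visit_count_probs"] = tuple(fetal["visit_count_probs"])
        kwargs["fetal"] = FetalModel(**fetal)
        kwargs["shape_params"] = {
            g: {s: ShapeParams(**sp) for s, sp in sub.items()}
            for g, sub in d["shape_params"].items()
        }
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
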