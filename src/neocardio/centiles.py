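"""Fractional-polynomial growth centiles and z-scores.

Smoothed centile standards for ventricular mass (or mass/HC) versus
postmenstrual age are built by fitting a fractional polynomial to the
natural-log outcome and modelling the residual SD on the log scale
(constant by default).  Centiles and z-scores follow from the log-normal
assumption:

    centile_p(t) = exp(mu(t) + z_p * sigma(t))
    z(t, y)      = (ln y - mu(t)) / sigma(t)

The candidate power set is the standard {-2, -1, -0.5, 0, 0.5, 1, 2, 3}
(0 denoting ln age, repeated powers using the x^p * ln x convention); the
degree-2 search enumerates all 36 pairs with repetition and keeps the
lowest-deviance fit.

Repeated measures per subject are handled by a between/within moment
decomposition of the residuals: the subject-level intercept variance is
estimated, subject intercepts are shrunken (BLUP) and the mean curve refit
on intercept-centred data; the centile SD then combines both components.
"""

from __future__ import annotations

import itertools
import json
import math
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "POWER_SET",
    "FractionalPolynomial",
    "CentileModel",
    "fit_fp_mean",
    "fit_centile_model",
    "centile",
    "zscore",
    "trajectory_difference",
]

POWER_SET = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def fp_design(t: np.ndarray, powers: Sequence[float]) -> np.ndarray:
    """Design matrix (with intercept) for fractional-polynomial powers.

    Power 0 denotes ln(t); a repeated power p contributes x^p and
    x^p * ln(x) (Royston-Altman convention).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("ages must be > 0 for fractional polynomials")
    cols = [np.ones_like(t)]
    logt = np.log(t)
    seen: dict[float, int] = {}
    for p in powers:
        base = logt if p == 0 else t ** p
        k = seen.get(p, 0)
        cols.append(base * logt ** k)
        seen[p] = k + 1
    return np.column_stack(cols)


def _gaussian_deviance(rss: float, n: int) -> float:
    rss = max(rss, 1e-300)
    return n * math.log(2.0 * math.pi * rss / n) + n


def _candidate_pairs(degree: int):
    if degree == 1:
        return [(p,) for p in POWER_SET]
    return list(itertools.combinations_with_replacement(POWER_SET, degree))


def _tie_key(powers: tuple) -> tuple:
    """Tie-break preference: conventional linear powers first, then
    lexicographically smallest."""
    linear = tuple([1.0] * len(powers))
    return (0 if powers == linear else 1, powers)


class FractionalPolynomial(RegressorMixin, BaseEstimator):
    """Least-squares fractional-polynomial regression with power search.

    Parameters
    ----------
    degree : 1 or 2
        Number of FP terms.
    powers : tuple or None
        Fixed powers; if None an exhaustive search over the candidate set is
        performed and the lowest-deviance model kept (ties broken toward the
        linear powers, then lexicographically).

    Fitted attributes: powers_, coef_ (incl. intercept as coef_[0]),
    deviance_, deviances_ (per candidate), n_ and rss_.
    """

    def __init__(self, degree: int = 2, powers: tuple | None = None):
        self.degree = degree
        self.powers = powers

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if len(t) < 10:
            raise ValueError("need at least 10 points to fit")
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        if np.ptp(t) == 0:
            raise ValueError(
                "singular design: all ages identical (constant transform)")

        candidates = ([tuple(self.powers)] if self.powers is not None
                      else _candidate_pairs(self.degree))
        results = {}
        for powers in candidates:
            Xd = fp_design(t, powers)
            if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
                continue
            coef, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
            rss = float(np.sum((y - Xd @ coef) ** 2))
            results[powers] = (_gaussian_deviance(rss, len(t)), coef, rss)
        if not results:
            raise ValueError("singular design for every candidate transform")
        best_dev = min(d for d, _, _ in results.values())
        tied = [p for p, (d, _, _) in results.items() if d <= best_dev + 1e-10]
        best = min(tied, key=_tie_key)
        self.powers_ = best
        self.deviance_, self.coef_, self.rss_ = results[best]
        self.deviances_ = {p: d for p, (d, _, _) in results.items()}
        self.n_ = len(t)
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return fp_design(t, self.powers_) @ self.coef_


class CentileModel(BaseEstimator):
    """Log-normal growth standard: FP mean plus residual SD on the log scale.

    Parameters
    ----------
    degree : FP degree for the mean curve (default 2).
    sd_model : 'constant' (default) or 'fp' (degree-1 FP of age fitted to
        the squared residuals).
    repeated : account for repeated measures per subject via the
        between/within moment decomposition (requires subject_ids in fit).

    Fitted attributes: mean_fp_ (FractionalPolynomial on ln y), sigma_,
    intercept_sd_, age_range_, and sd_fp_coef_/sd_fp_powers_ when
    sd_model='fp'.
    """

    def __init__(self, degree: int = 2, sd_model: str = "constant",
                 repeated: bool = False):
        self.degree = degree
        self.sd_model = sd_model
        self.repeated = repeated

    # -- fitting -------------------------------------------------------
    def fit(self, age, y, subject_ids=None):
        t = np.asarray(age, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if np.any(y <= 0):
            raise ValueError("outcome must be > 0 (log transformed)")
        if len(np.unique(t)) < 10:
            raise ValueError("visits must span at least 10 distinct ages")
        lny = np.log(y)
        fp = FractionalPolynomial(degree=self.degree).fit(t, lny)
        resid = lny - fp.predict(t)

        self.intercept_sd_ = 0.0
        if self.repeated:
            if subject_ids is None:
                raise ValueError("repeated=True requires subject_ids")
            sid = np.asarray(subject_ids)
            ids, inv, counts = np.unique(sid, return_inverse=True,
                                         return_counts=True)
            if np.sum(counts >= 2) < 2:
                raise ValueError(
                    "repeated=True needs >= 2 subjects with repeat visits")
            means = np.bincount(inv, resid) / counts
            within = resid - means[inv]
            dof = len(resid) - len(ids)
            sigma_e2 = float(np.sum(within ** 2) / max(dof, 1))
            between = float(np.var(means, ddof=1))
            sigma_u2 = max(0.0, between - sigma_e2 * float(np.mean(1.0 / counts)))
            shrink = sigma_u2 / (sigma_u2 + sigma_e2 / counts) if sigma_u2 > 0 \
                else np.zeros_like(counts, dtype=float)
            blup = means * shrink
            # refit the mean on intercept-centred data
            fp = FractionalPolynomial(degree=self.degree).fit(t, lny - blup[inv])
            resid = lny - blup[inv] - fp.predict(t)
            self.intercept_sd_ = math.sqrt(sigma_u2)

        self.mean_fp_ = fp
        p = len(fp.coef_)
        resid_sd = math.sqrt(float(np.sum(resid ** 2)) / max(len(resid) - p, 1))
        self.sigma_ = math.sqrt(resid_sd ** 2 + self.intercept_sd_ ** 2)
        if self.sd_model == "fp":
            sd_fp = FractionalPolynomial(degree=1).fit(t, resid ** 2)
            self.sd_fp_powers_ = sd_fp.powers_
            self.sd_fp_coef_ = sd_fp.coef_
            self._sd_floor = 0.25 * resid_sd
        elif self.sd_model != "constant":
            raise ValueError("sd_model must be 'constant' or 'fp'")
        self.age_range_ = (float(t.min()), float(t.max()))
        return self

    # -- evaluation ----------------------------------------------------
    def _check_age(self, age, extrapolate):
        t = np.asarray(age, dtype=float)
        lo, hi = self.age_range_
        if not extrapolate and (np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9)):
            raise ValueError(
                f"age outside the model's validity range [{lo:.1f}, {hi:.1f}] "
                "weeks (pass extrapolate=True to override)")
        return t

    def mu(self, age):
        return self.mean_fp_.predict(np.atleast_1d(np.asarray(age, float)))

    def sigma(self, age):
        t = np.atleast_1d(np.asarray(age, dtype=float))
        if self.sd_model == "fp":
            var = fp_design(t, self.sd_fp_powers_) @ self.sd_fp_coef_
            var = var + self.intercept_sd_ ** 2
            return np.sqrt(np.maximum(var, self._sd_floor ** 2))
        return np.full(t.shape, self.sigma_)

    def centile(self, age, p: float, extrapolate: bool = False):
        """Value of the p-th centile curve at the given age(s)."""
        if not 0.0 < p < 100.0:
            raise ValueError("centile p must lie in (0, 100)")
        t = self._check_age(age, extrapolate)
        z = stats.norm.ppf(p / 100.0)
        out = np.exp(self.mu(t) + z * self.sigma(t))
        return float(out[0]) if np.isscalar(age) else out

    def zscore(self, age, y, extrapolate: bool = False):
        """Standardised deviation of observation(s) y from the standard."""
        t = self._check_age(age, extrapolate)
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise ValueError("y must be > 0")
        out = (np.log(np.atleast_1d(y)) - self.mu(t)) / self.sigma(t)
        return float(out[0]) if np.isscalar(age) else out

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "degree": self.degree,
            "sd_model": self.sd_model,
            "repeated": self.repeated,
            "powers": list(self.mean_fp_.powers_),
            "coef": list(map(float, self.mean_fp_.coef_)),
            "sigma": self.sigma_,
            "intercept_sd": self.intercept_sd_,
            "age_range": list(self.age_range_),
        }
        if self.sd_model == "fp":
            d["sd_fp_powers"] = list(self.sd_fp_powers_)
            d["sd_fp_coef"] = list(map(float, self.sd_fp_coef_))
            d["sd_floor"] = self._sd_floor
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CentileModel":
        m = cls(degree=d["degree"], sd_model=d["sd_model"], repeated=d["repeated"])
        fp = FractionalPolynomial(degree=d["degree"], powers=tuple(d["powers"]))
        fp.powers_ = tuple(d["powers"])
        fp.coef_ = np.asarray(d["coef"], dtype=float)
        m.mean_fp_ = fp
        m.sigma_ = d["sigma"]
        m.intercept_sd_ = d["intercept_sd"]
        m.age_range_ = tuple(d["age_range"])
        if d["sd_model"] == "fp":
            m.sd_fp_powers_ = tuple(d["sd_fp_powers"])
            m.sd_fp_coef_ = np.asarray(d["sd_fp_coef"], dtype=float)
            m._sd_floor = d["sd_floor"]
        return m

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CentileModel":
        text = source
        if "{" not in source:
            with open(source, encoding="utf-8") as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimators
# ---------------------------------------------------------------------------

def fit_fp_mean(age, y, degree: int = 2) -> FractionalPolynomial:
    """Exhaustive FP search for ln(y) on age; returns the fitted estimator."""
    return FractionalPolynomial(degree=degree).fit(age, np.log(np.asarray(y)))


def fit_centile_model(visits, outcome: str, age_col: str = "pma",
                      repeated: bool = False, degree: int = 2,
                      sd_model: str = "constant") -> CentileModel:
    """Fit a growth standard from a visits table (rows with the outcome)."""
    df = visits.dropna(subset=[outcome, age_col])
    df = df[df[outcome] > 0]
    model = CentileModel(degree=degree, sd_model=sd_model, repeated=repeated)
    model.fit(df[age_col].to_numpy(), df[outcome].to_numpy(),
              subject_ids=df["subject_id"].to_numpy() if repeated else None)
    return model


def centile(model: CentileModel, age, p: float, extrapolate: bool = False):
    return model.centile(age, p, extrapolate=extrapolate)


def zscore(model: CentileModel, age, y, extrapolate: bool = False):
    return model.zscore(age, y, extrapolate=extrapolate)


def trajectory_difference(model_a: CentileModel, model_b: CentileModel,
                          age, p: float = 50.0,
                          extrapolate: bool = False) -> float:
    """centile(a) - centile(b) at one age, in outcome units."""
    return (model_a.centile(age, p, extrapolate=extrapolate)
            - model_b.centile(age, p, extrapolate=extrapolate))
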