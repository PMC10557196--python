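"""Nested case-control association of plasma heteroplasmy with cancer incidence.

Plasma heteroplasmy levels are dichotomized at a natural 10% cut-off
(HL < 10%: wild type, HL ≥ 10%: mutated).  The crude odds ratio comes from
the 2×2 table with a Wald interval on the log scale; adjusted odds ratios
come from maximum-likelihood logistic regression (IRLS via statsmodels)
with four nested covariate sets:

* model1: age, BMI
* model2: + education, smoking, alcohol
* model3: + activity at work, activity at home
* model4: + diabetes, hypertension, family history of cancer

Categorical covariates are expanded to indicator contrasts against the
lowest category; binary covariates take absence as the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

WILD_TYPE = "wild_type"
MUTATED = "mutated"

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

CATEGORICAL_COVARIATES = (
    "education", "smoking", "alcohol", "activity_work", "activity_home",
)
BINARY_COVARIATES = ("diabetes", "hypertension", "family_history")
CONTINUOUS_COVARIATES = ("age", "bmi")

COVARIATE_SETS: dict[str, tuple[str, ...]] = {
    "none": (),
    "model1": ("age", "bmi"),
    "model2": ("age", "bmi", "education", "smoking", "alcohol"),
    "model3": (
        "age", "bmi", "education", "smoking", "alcohol",
        "activity_work", "activity_home",
    ),
    "model4": (
        "age", "bmi", "education", "smoking", "alcohol",
        "activity_work", "activity_home",
        "diabetes", "hypertension", "family_history",
    ),
}


class SeparationError(RuntimeError):
    """The likelihood is maximised at infinity for some coefficient."""


class CollinearityError(ValueError):
    """Rank-deficient design matrix."""


@dataclass(frozen=True)
class OrResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: str
    n_cases: int
    n_controls: int
    term: str = "exposure"
    corrected: bool = False  # Haldane–Anscombe 0.5 applied


def dichotomize(hl: float, cutoff: float = 0.10) -> str:
    """``mutated`` iff HL ≥ cutoff (boundary inclusive)."""
    if not 0 <= hl <= 1:
        raise ValueError(f"heteroplasmy fraction {hl} outside [0, 1]")
    return MUTATED if hl >= cutoff else WILD_TYPE


def crude_or(a: int, b: int, c: int, d: int) -> OrResult:
    """Odds ratio of the 2×2 table [cases mutated/wild; controls mutated/wild].

    estimate = (a·d)/(b·c); 95% Wald CI on the log scale.  Any zero cell
    triggers the Haldane–Anscombe 0.5 continuity correction (flagged).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 if corrected else x for x in (a, b, c, d))
    est = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return OrResult(
        estimate=est,
        ci_low=est * math.exp(-Z_95 * se),
        ci_high=est * math.exp(Z_95 * se),
        model="crude",
        n_cases=a + b,
        n_controls=c + d,
        corrected=corrected,
    )


def records_from_counts(
    a: int, b: int, c: int, d: int, hl_mutated: float = 0.5
) -> pd.DataFrame:
    """Expand a 2×2 table into one record per subject (for logistic fits)."""
    rows = []
    for outcome, state, n in (
        ("case", MUTATED, a), ("case", WILD_TYPE, b),
        ("control", MUTATED, c), ("control", WILD_TYPE, d),
    ):
        hl = hl_mutated if state == MUTATED else 0.0
        rows.extend({"outcome": outcome, "hl": hl} for _ in range(n))
    df = pd.DataFrame(rows)
    df["subject_id"] = [f"S{i:04d}" for i in range(len(df))]
    return df


def _outcome_vector(df: pd.DataFrame) -> np.ndarray:
    y = df["outcome"]
    if y.dtype == object:
        return (y == "case").to_numpy(dtype=float)
    return y.to_numpy(dtype=float)


def build_design(
    df: pd.DataFrame,
    exposure: str = "dichotomized",
    covariate_set: str = "none",
    cutoff: float = 0.10,
) -> pd.DataFrame:
    """Design matrix with intercept, exposure column and covariate contrasts."""
    if covariate_set not in COVARIATE_SETS:
        raise ValueError(f"unknown covariate set {covariate_set!r}")
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    if exposure == "dichotomized":
        X["exposure"] = [
            1.0 if dichotomize(h, cutoff) == MUTATED else 0.0 for h in df["hl"]
        ]
    elif exposure == "hl_continuous":
        X["exposure"] = df["hl"].astype(float)
    else:
        raise ValueError(f"unknown exposure {exposure!r}")
    for cov in COVARIATE_SETS[covariate_set]:
        if cov in CONTINUOUS_COVARIATES or cov in BINARY_COVARIATES:
            X[cov] = df[cov].astype(float)
        else:  # categorical: indicators against the lowest level
            levels = sorted(df[cov].unique())
            for level in levels[1:]:
                X[f"{cov}[{level}]"] = (df[cov] == level).astype(float)
    return X


def logistic_fit(
    records: pd.DataFrame,
    exposure: str = "dichotomized",
    covariate_set: str = "none",
    cutoff: float = 0.10,
) -> tuple[OrResult, pd.DataFrame]:
    """ML logistic regression of case status on the exposure and covariates.

    Returns the exposure term's odds ratio with its Wald 95% CI, plus the
    full coefficient table (log-odds scale).
    """
    y = _outcome_vector(records)
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if n_cases == 0 or n_controls == 0:
        raise SeparationError("need at least one case and one control")
    X = build_design(records, exposure, covariate_set, cutoff)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise CollinearityError(
            "rank-deficient design; drop a collinear covariate"
        )
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-8)
    params = res.params
    bse = res.bse
    huge = params.abs() > 15  # log-OR beyond e^15: effectively infinite
    if huge.any():
        raise SeparationError(
            f"separation detected for term(s): {list(params.index[huge])}"
        )
    table = pd.DataFrame(
        {"coef": params, "se": bse, "p": res.pvalues}
    )
    beta, se = float(params["exposure"]), float(bse["exposure"])
    or_result = OrResult(
        estimate=math.exp(beta),
        ci_low=math.exp(beta - Z_95 * se),
        ci_high=math.exp(beta + Z_95 * se),
        model=covariate_set if covariate_set != "none" else "crude",
        n_cases=n_cases,
        n_controls=n_controls,
    )
    return or_result, table


class CaseControlModel:
    """Thin model object over a case-control table; ``fit`` per covariate set."""

    def __init__(self, records: pd.DataFrame, cutoff: float = 0.10):
        self.records = records
        self.cutoff = cutoff

    @classmethod
    def from_tsv(cls, path, cutoff: float = 0.10) -> "CaseControlModel":
        return cls(pd.read_csv(path, sep="\t"), cutoff)

    def crude_table(self) -> tuple[int, int, int, int]:
        df = self.records
        states = df["hl"].map(lambda h: dichotomize(h, self.cutoff))
        case = _outcome_vector(df).astype(bool)
        a = int(((states == MUTATED) & case).sum())
        b = int(((states == WILD_TYPE) & case).sum())
        c = int(((states == MUTATED) & ~case).sum())
        d = int(((states == WILD_TYPE) & ~case).sum())
        return a, b, c, d

    def crude(self) -> OrResult:
        return crude_or(*self.crude_table())

    def fit(
        self, exposure: str = "dichotomized", covariate_set: str = "none"
    ) -> tuple[OrResult, pd.DataFrame]:
        return logistic_fit(self.records, exposure, covariate_set, self.cutoff)

    def summary(self, exposure: str = "dichotomized") -> pd.DataFrame:
        """Crude plus model1..model4 exposure ORs, one row per model."""
        rows = [self.crude().__dict__]
        for cs in ("model1", "model2", "model3", "model4"):
            rows.append(self.fit(exposure, cs)[0].__dict__)
        return pd.DataFrame(rows).set_index("model")
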