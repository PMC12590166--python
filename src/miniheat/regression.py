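"""Pooled OLS models linking indoor temperature to outdoor conditions and
household characteristics.

The response is 5-min-averaged indoor temperature; regressors combine a
continuous outdoor temperature (and optionally its 6-hour lag), ordinal
building attributes (EPC band B→0 … E→3, self-rated condition 0 worst …
3 best, IMD group as provided) and dummy-encoded categoricals (tenure
with "homeowner with mortgage" as reference; house type with
"flat/apartment (high-rise on a low floor, or low-rise)" as reference).
Household attributes are broadcast over time rows — a single pooled
equation, classical homoskedastic standard errors, significance read at
p < 0.01.  No clustering or autocorrelation correction is applied; noted
as a limitation in the methods note.

Five standard specifications are provided:

1. outdoor temperature + condition + EPC + IMD (base)
2. base + house-type dummies
3. base + tenure dummies
4. base + tenure + house-type dummies
5. model 4 + 6-hour lagged outdoor temperature
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

P_SIGNIFICANT = 0.01
LAG_STEPS_DEFAULT = 72  # 6 h at 5-min resolution

EPC_CODES = {"B": 0, "C": 1, "D": 2, "E": 3}

CONDITION_CODES = {
    "very poor condition, in need of urgent repair": 0,
    "poor condition, in need of repair": 1,
    "not new but in reasonable condition": 2,
    "new and/or in good condition": 3,
}

TENURE_REFERENCE = "homeowner with mortgage"
TENURE_DUMMIES = {
    "renting from a local authority/council": "tenure_council",
    "renting from a housing association/housing co-operative or charitable trust": "tenure_housing_association",
    "renting from a housing association/housing cooperative or charitable trust": "tenure_housing_association",
    "renting from a private landlord": "tenure_private_landlord",
    "shared ownership": "tenure_shared_ownership",
}

HOUSE_TYPE_REFERENCE = "flat/apartment (high-rise on a low floor, or low-rise)"
HOUSE_TYPE_DUMMIES = {
    "flat/apartment (high-rise, on a mid to high floor)": "htype_highrise_midhigh",
    "terraced house": "htype_terraced",
}

TENURE_COLUMNS = (
    "tenure_council",
    "tenure_housing_association",
    "tenure_private_landlord",
    "tenure_shared_ownership",
)
HOUSE_TYPE_COLUMNS = ("htype_highrise_midhigh", "htype_terraced")
BASE_COLUMNS = ("T_out", "condition", "epc", "imd")


@dataclass(frozen=True)
class RegressionSpec:
    """One model specification: which regressor blocks enter the design."""

    model_id: int
    house_type: bool = False
    tenure: bool = False
    lag: bool = False

    @classmethod
    def standard(cls, model_id: int) -> "RegressionSpec":
        if model_id == 1:
            return cls(1)
        if model_id == 2:
            return cls(2, house_type=True)
        if model_id == 3:
            return cls(3, tenure=True)
        if model_id == 4:
            return cls(4, house_type=True, tenure=True)
        if model_id == 5:
            return cls(5, house_type=True, tenure=True, lag=True)
        raise ValueError(f"unknown model id {model_id}")

    def columns(self) -> list[str]:
        cols = list(BASE_COLUMNS)
        if self.lag:
            cols.insert(1, "T_out_lag")
        if self.tenure:
            cols.extend(TENURE_COLUMNS)
        if self.house_type:
            cols.extend(HOUSE_TYPE_COLUMNS)
        return cols


@dataclass
class RegressionResult:
    """Coefficient estimates with classical OLS inference and fit metrics."""

    model_id: int
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r_squared: float
    adj_r_squared: float
    n_obs: int
    significant: pd.Series = field(default=None)

    def __post_init__(self):
        if self.significant is None:
            self.significant = self.pvalues < P_SIGNIFICANT

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "std_err": self.bse,
                "t": self.tvalues,
                "p_value": self.pvalues,
                "significant_0.01": self.significant,
            }
        )


def _encode_ordinal(values: pd.Series, codes: dict, name: str) -> pd.Series:
    def one(v):
        if isinstance(v, str):
            if v not in codes:
                raise ValueError(f"unknown {name} category {v!r}")
            return codes[v]
        iv = int(v)
        if iv not in set(codes.values()):
            raise ValueError(f"unknown {name} code {v!r}")
        return iv

    return values.map(one).astype(int)


def encode_households(profiles: pd.DataFrame) -> pd.DataFrame:
    """Encode raw household attributes into the regression feature table.

    Expects columns sensor_id, epc, imd, tenure, house_type, condition.
    EPC and condition accept either labels or their integer codes; IMD is
    passed through as an ordinal.  Returns one row per household indexed
    by sensor_id.  Raises ``ValueError`` on unknown categories.
    """
    out = pd.DataFrame(index=pd.Index(profiles["sensor_id"], name="sensor_id"))
    prof = profiles.set_index("sensor_id")
    out["epc"] = _encode_ordinal(prof["epc"], EPC_CODES, "EPC")
    out["condition"] = _encode_ordinal(prof["condition"], CONDITION_CODES, "condition")
    out["imd"] = pd.to_numeric(prof["imd"]).astype(int)

    for col in TENURE_COLUMNS + HOUSE_TYPE_COLUMNS:
        out[col] = 0
    for sid, tenure in prof["tenure"].items():
        if tenure == TENURE_REFERENCE:
            continue
        if tenure not in TENURE_DUMMIES:
            raise ValueError(f"unknown tenure category {tenure!r}")
        out.loc[sid, TENURE_DUMMIES[tenure]] = 1
    for sid, htype in prof["house_type"].items():
        if htype == HOUSE_TYPE_REFERENCE:
            continue
        if htype not in HOUSE_TYPE_DUMMIES:
            raise ValueError(f"unknown house type category {htype!r}")
        out.loc[sid, HOUSE_TYPE_DUMMIES[htype]] = 1
    return out


def build_design(
    joined: pd.DataFrame,
    encoded_profiles: pd.DataFrame,
    spec: RegressionSpec,
    lag_steps: int = LAG_STEPS_DEFAULT,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble (X, y) for one specification.

    ``joined`` is a long table with columns sensor_id, timestamp, T_in,
    T_out at 5-min resolution.  The lagged regressor shifts T_out by
    ``lag_steps`` rows within each sensor (6 h = 72 steps at 5 min); rows
    whose lag is unavailable are dropped, never imputed.  Household
    features broadcast to every time row of their sensor.
    """
    df = joined[["sensor_id", "timestamp", "T_in", "T_out"]].copy()
    df = df.sort_values(["sensor_id", "timestamp"], kind="stable")
    if spec.lag:
        df["T_out_lag"] = df.groupby("sensor_id")["T_out"].shift(lag_steps)
        df = df.dropna(subset=["T_out_lag"])

    needed = [c for c in spec.columns() if c not in ("T_out", "T_out_lag")]
    missing = [c for c in needed if c not in encoded_profiles.columns]
    if missing:
        raise ValueError(f"profiles lack required features: {missing}")

    merged = df.merge(
        encoded_profiles[needed], left_on="sensor_id", right_index=True, how="inner"
    )
    merged = merged.dropna(subset=["T_in", "T_out"])
    y = merged["T_in"].rename("T_in")
    X = sm.add_constant(merged[spec.columns()], has_constant="add")
    return X, y


def fit_ols(X: pd.DataFrame, y: pd.Series, model_id: int = 0) -> RegressionResult:
    """Fit by ordinary least squares with classical standard errors.

    Raises ``ValueError`` on rank deficiency, naming the offending
    columns, and if there are no more observations than columns.
    """
    Xv = np.asarray(X, dtype=float)
    if Xv.shape[0] <= Xv.shape[1]:
        raise ValueError("need more observations than design columns")
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # pivoted QR: columns with a negligible diagonal in R are dependent
        _, r, piv = scipy.linalg.qr(Xv, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(Xv.shape) * np.finfo(float).eps
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        raise ValueError(f"design matrix is rank deficient; offending columns: {bad}")
    fit = sm.OLS(y, X).fit()
    r2 = float(fit.rsquared)
    adj = float(fit.rsquared_adj)
    if not np.isfinite(r2):  # constant response: nothing to explain
        r2, adj = 0.0, 0.0
    return RegressionResult(
        model_id=model_id,
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        r_squared=r2,
        adj_r_squared=adj,
        n_obs=int(fit.nobs),
    )


def run_model_suite(
    joined: pd.DataFrame,
    encoded_profiles: pd.DataFrame,
    model_ids=(1, 2, 3, 4, 5),
    lag_steps: int = LAG_STEPS_DEFAULT,
) -> dict[int, RegressionResult | Exception]:
    """Fit each specification on its maximal estimable sample.

    A failure in one model (e.g. a missing feature) is recorded as the
    exception for that id without aborting the rest.
    """
    results: dict[int, RegressionResult | Exception] = {}
    for mid in model_ids:
        try:
            spec = RegressionSpec.standard(mid)
            X, y = build_design(joined, encoded_profiles, spec, lag_steps)
            results[mid] = fit_ols(X, y, model_id=mid)
        except Exception as exc:  # noqa: BLE001 - isolate per-model failures
            results[mid] = exc
    return results


def comparison_table(results: dict[int, RegressionResult | Exception]) -> pd.DataFrame:
    """Coefficients by model, one column per fitted specification, with
    R², adjusted R² and n appended as rows."""
    cols = {}
    for mid, res in sorted(results.items()):
        if isinstance(res, Exception):
            continue
        col = res.params.copy()
        col.loc["R2"] = res.r_squared
        col.loc["adj_R2"] = res.adj_r_squared
        col.loc["n_obs"] = res.n_obs
        cols[f"Model {mid}"] = col
    table = pd.DataFrame(cols)
    table.index.name = "variable"
    return table
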