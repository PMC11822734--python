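"""Linear mixed models of metabolite concentration drift over delay time.

For each parameter × material × phase stratum a linear mixed model

    value_ij = beta0 + beta1 * t_ij + b_i + eps_ij,   b_i ~ N(0, var_donor)

is fitted by REML, where ``i`` indexes donors and ``t`` the controlled
room-temperature delay in hours. The fixed intercept ``beta0`` estimates
the concentration at zero delay and the fixed slope ``beta1`` the drift
rate (units per hour). An optional "cellcount" variant augments the mean
structure with a time × cell-count interaction, letting the drift rate
scale with the cellular component of the sample.

The public surface follows the model/results idiom: :class:`DriftLMM`
is built from a long-format DataFrame and ``fit()`` returns a
:class:`DriftModel` results object carrying estimates, variance
components, Nakagawa r² and diagnostics. :func:`fit_all` fits every
stratum of a dataset into a serializable :class:`ModelStore`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelSpec",
    "DriftModel",
    "DriftLMM",
    "ModelStore",
    "read_timecourse_table",
    "filter_missingness",
    "fit_drift_model",
    "fit_all",
    "split_donors",
]

TIMECOURSE_COLUMNS = ("donor_id", "material", "phase", "time_h", "parameter", "value")

STORE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the drift-model fit.

    variant
        ``"base"`` fits ``value ~ time_h``; ``"cellcount"`` fits
        ``value ~ time_h + time_h:cell_count``; ``"auto"`` picks
        "cellcount" when cell counts are present in the stratum, since
        models with the cellular component tend to explain more variance.
        Cell count enters the mean structure (not a donor-grouped random
        slope) because it is constant within donor and a donor-grouped
        random slope on a donor-constant covariate is not identifiable
        alongside the donor random intercept.
    formula
        Optional patsy formula overriding the variant's mean structure,
        so alternative readings of the cell-count term can be run
        without code changes.
    reml
        Restricted maximum likelihood (default) vs ML.
    min_donors
        Minimum donors with ≥ 2 time points required to fit a stratum.
    max_missing_fraction
        Strata-level missingness filter threshold (strict ``>`` removes).
    """

    variant: str = "auto"
    formula: str | None = None
    reml: bool = True
    min_donors: int = 3
    max_missing_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.variant not in {"auto", "base", "cellcount"}:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")


@dataclass
class DriftModel:
    """Fitted drift model for one parameter × material × phase stratum.

    beta0, beta1
        Fixed intercept (concentration at zero delay, native units) and
        fixed slope (units per hour). For the cellcount variant beta1 is
        the drift rate at the stratum's mean cell count.
    var_donor, var_resid
        Random-intercept and residual variance components.
    r2_marginal, r2_conditional
        Nakagawa variance decomposition: fraction of variance explained
        by fixed effects alone, and by fixed plus random effects.
    degraded
        True when the mixed fit failed (singular/non-convergent) and a
        pooled OLS fallback with var_donor = 0 was used instead.
    """

    parameter: str
    material: str
    phase: str
    beta0: float
    beta1: float
    beta1_se: float
    var_donor: float
    var_resid: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_donors: int
    variant: str
    degraded: bool = False

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.parameter, self.material, self.phase)

    def predict(self, t_h: float | np.ndarray, baseline: float | None = None):
        """Population-level predicted concentration at delay ``t_h``.

        With ``baseline`` given, the donor-specific intercept replaces
        the population intercept (used for validation from time-0
        observations).
        """
        b0 = self.beta0 if baseline is None else baseline
        return b0 + self.beta1 * np.asarray(t_h, dtype=float)

    def summary(self) -> str:
        lines = [
            f"Drift model: {self.parameter} | {self.material} | {self.phase}centrifugation",
            f"  variant: {self.variant}" + ("  [degraded: pooled OLS fallback]" if self.degraded else ""),
            f"  n_obs = {self.n_obs}, n_donors = {self.n_donors}",
            f"  beta0 (intercept)  = {self.beta0:.6g}",
            f"  beta1 (slope /h)   = {self.beta1:.6g}  (SE {self.beta1_se:.3g})",
            f"  var(donor)         = {self.var_donor:.6g}",
            f"  var(residual)      = {self.var_resid:.6g}",
            f"  r2 marginal        = {self.r2_marginal:.4f}",
            f"  r2 conditional     = {self.r2_conditional:.4f}",
        ]
        return "\n".join(lines)


def read_timecourse_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format timecourse table (comma or tab delimited)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in TIMECOURSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"timecourse table missing columns: {missing}")
    df["time_h"] = df["time_h"].astype(float)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    if "cell_count" in df.columns:
        df["cell_count"] = pd.to_numeric(df["cell_count"], errors="coerce")
    return df


def filter_missingness(
    data: pd.DataFrame, max_missing_fraction: float = 0.30
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove parameters whose missing fraction exceeds the threshold.

    Applied per material × phase stratum; a parameter is removed from a
    stratum iff its fraction of missing values is *strictly* greater
    than ``max_missing_fraction``. Returns the filtered data and a log
    of removals (parameter, material, phase, missing_fraction).
    """
    if data.empty:
        raise ValueError("empty timecourse dataset")
    removed = []
    keep = pd.Series(True, index=data.index)
    grouped = data.groupby(["parameter", "material", "phase"], sort=False, observed=True)
    for (parameter, material, phase), idx in grouped.groups.items():
        sub = data.loc[idx, "value"]
        frac = float(sub.isna().mean())
        if frac > max_missing_fraction:
            keep.loc[idx] = False
            removed.append(
                {
                    "parameter": parameter,
                    "material": material,
                    "phase": phase,
                    "missing_fraction": frac,
                }
            )
    log = pd.DataFrame(removed, columns=["parameter", "material", "phase", "missing_fraction"])
    return data.loc[keep].copy(), log


def _nakagawa_r2(
    fixed_pred: np.ndarray, var_donor: float, var_resid: float
) -> tuple[float, float]:
    """Nakagawa marginal/conditional r² for a Gaussian mixed model."""
    var_fixed = float(np.var(fixed_pred))
    denom = var_fixed + var_donor + var_resid
    if denom <= 0:
        return 0.0, 0.0
    r2m = var_fixed / denom
    r2c = (var_fixed + var_donor) / denom
    return r2m, min(r2c, 1.0)


class DriftLMM:
    """Drift model for a single stratum, built from long-format data.

    Parameters
    ----------
    data
        Rows of one parameter × material × phase stratum with columns
        donor_id, time_h, value and optionally cell_count. Rows with a
        missing value are dropped listwise.
    spec
        Fit configuration (variant, REML, thresholds).

    Use :meth:`from_dataframe` to select the stratum from a full
    timecourse table. ``fit()`` returns a :class:`DriftModel`.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec = ModelSpec()):
        required = {"donor_id", "time_h", "value"}
        if not required.issubset(data.columns):
            raise ValueError(f"stratum data needs columns {sorted(required)}")
        for col in ("parameter", "material", "phase"):
            if col in data.columns and data[col].nunique() > 1:
                raise ValueError(f"stratum data mixes multiple values of {col!r}")
        self.spec = spec
        df = data.dropna(subset=["value"]).copy()
        df["time_h"] = df["time_h"].astype(float)
        self.data = df
        self.parameter = str(data["parameter"].iloc[0]) if "parameter" in data.columns else ""
        self.material = str(data["material"].iloc[0]) if "material" in data.columns else ""
        self.phase = str(data["phase"].iloc[0]) if "phase" in data.columns else ""

        has_cc = "cell_count" in df.columns and df["cell_count"].notna().all() and len(df) > 0
        if spec.variant == "auto":
            self.variant = "cellcount" if has_cc else "base"
        else:
            self.variant = spec.variant
        if self.variant == "cellcount" and not has_cc:
            raise ValueError("cellcount variant requires complete cell_count values")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        parameter: str,
        material: str,
        phase: str,
        spec: ModelSpec = ModelSpec(),
    ) -> "DriftLMM":
        mask = (
            (data["parameter"] == parameter)
            & (data["material"] == material)
            & (data["phase"] == phase)
        )
        sub = data.loc[mask]
        if sub.empty:
            raise ValueError(f"no data for stratum ({parameter}, {material}, {phase})")
        return cls(sub, spec)

    @property
    def n_donors(self) -> int:
        counts = self.data.groupby("donor_id")["time_h"].nunique()
        return int((counts >= 2).sum())

    def _formula(self) -> str:
        if self.spec.formula is not None:
            return self.spec.formula
        if self.variant == "cellcount":
            return "value ~ time_h + time_h:cell_count"
        return "value ~ time_h"

    def fit(self) -> DriftModel:
        """REML-fit the stratum; fall back to pooled OLS if degenerate.

        A singular or non-convergent mixed fit is retried once from a
        perturbed start; if still failing, a pooled ordinary least
        squares fit with ``var_donor = 0`` is returned and the model is
        flagged ``degraded``. A single-donor stratum reduces to simple
        regression directly (the donor intercept is not identifiable).
        """
        df = self.data
        if df.empty:
            raise ValueError("no non-missing observations in stratum")
        n_donors_total = df["donor_id"].nunique()
        if self.n_donors < self.spec.min_donors and n_donors_total > 1:
            raise ValueError(
                f"stratum has {self.n_donors} donors with >= 2 time points; "
                f"min_donors = {self.spec.min_donors}"
            )
        formula = self._formula()
        if n_donors_total == 1:
            return self._fit_ols(formula, degraded=False)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                result = self._fit_mixed(formula)
        except Exception:
            result = None
        if result is None:
            try:  # one restart from a perturbed variance start
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    result = self._fit_mixed(formula, start_scale=0.5)
            except Exception:
                result = None
        if result is None:
            warnings.warn(
                f"mixed fit failed for stratum ({self.parameter}, {self.material}, "
                f"{self.phase}); falling back to pooled OLS",
                stacklevel=2,
            )
            return self._fit_ols(formula, degraded=True)
        return result

    def _fit_mixed(self, formula: str, start_scale: float | None = None) -> DriftModel:
        df = self.data
        model = smf.mixedlm(formula, df, groups=df["donor_id"])
        kwargs = {"reml": self.spec.reml}
        if start_scale is not None:
            free = sm.regression.mixed_linear_model.MixedLMParams.from_components(
                fe_params=None, cov_re=np.eye(model.k_re) * start_scale
            )
            kwargs["start_params"] = free
        res = model.fit(method=["lbfgs", "bfgs"], maxiter=2000, **kwargs)
        if not res.converged:
            raise RuntimeError("mixed model did not converge")
        # res.cov_re is already on the response scale
        var_donor = float(res.cov_re.iloc[0, 0])
        var_resid = float(res.scale)
        beta0, beta1, beta1_se = self._effective_coefficients(res.fe_params, res.bse_fe)
        if not np.all(np.isfinite([beta0, beta1, var_donor, var_resid])):
            raise RuntimeError("non-finite estimates from mixed fit")
        fixed_pred = np.asarray(model.exog @ res.fe_params.values)
        r2m, r2c = _nakagawa_r2(fixed_pred, var_donor, var_resid)
        return DriftModel(
            parameter=self.parameter,
            material=self.material,
            phase=self.phase,
            beta0=beta0,
            beta1=beta1,
            beta1_se=beta1_se,
            var_donor=var_donor,
            var_resid=var_resid,
            r2_marginal=r2m,
            r2_conditional=r2c,
            n_obs=int(len(df)),
            n_donors=int(df["donor_id"].nunique()),
            variant=self.variant,
        )

    def _effective_coefficients(self, fe_params, bse) -> tuple[float, float, float]:
        """Reduce the mean structure to an intercept and a slope in time.

        For the cellcount variant the time × cell-count interaction is
        folded into an effective slope at the stratum's mean cell count,
        with the SE propagated through the same linear combination.
        """
        beta0 = float(fe_params.get("Intercept", 0.0))
        beta1 = float(fe_params.get("time_h", 0.0))
        se = float(bse.get("time_h", np.nan))
        inter_name = next((n for n in fe_params.index if ":" in n), None)
        if inter_name is not None:
            cc_mean = float(self.data["cell_count"].mean())
            beta1 = beta1 + float(fe_params[inter_name]) * cc_mean
            # SE of beta_t + cc_mean * beta_txcc, ignoring their covariance
            # would understate; use the conservative sum of variances.
            se = float(np.sqrt(bse.get("time_h", 0.0) ** 2 + (cc_mean * bse.get(inter_name, 0.0)) ** 2))
        return beta0, beta1, se

    def _fit_ols(self, formula: str, degraded: bool) -> DriftModel:
        df = self.data
        model = smf.ols(formula, df)
        res = model.fit()
        var_resid = float(res.mse_resid) if res.df_resid > 0 else 0.0
        beta0, beta1, beta1_se = self._effective_coefficients(res.params, res.bse)
        fixed_pred = np.asarray(res.fittedvalues)
        r2m, r2c = _nakagawa_r2(fixed_pred, 0.0, var_resid)
        return DriftModel(
            parameter=self.parameter,
            material=self.material,
            phase=self.phase,
            beta0=beta0,
            beta1=beta1,
            beta1_se=beta1_se,
            var_donor=0.0,
            var_resid=var_resid,
            r2_marginal=r2m,
            r2_conditional=r2c,
            n_obs=int(len(df)),
            n_donors=int(df["donor_id"].nunique()),
            variant=self.variant,
            degraded=degraded,
        )


def fit_drift_model(data: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> DriftModel:
    """Fit one stratum's drift model (data already restricted to it)."""
    return DriftLMM(data, spec).fit()


class ModelStore:
    """Collection of fitted DriftModels keyed by parameter × material × phase.

    Serializes to a versioned JSON document; coefficients round-trip at
    full double precision.
    """

    def __init__(self, models: Sequence[DriftModel] = ()):
        self._models: dict[tuple[str, str, str], DriftModel] = {}
        for m in models:
            self.add(m)

    def add(self, model: DriftModel) -> None:
        self._models[model.key] = model

    def get(self, parameter: str, material: str, phase: str) -> DriftModel | None:
        return self._models.get((parameter, material, phase))

    def __len__(self) -> int:
        return len(self._models)

    def __iter__(self) -> Iterator[DriftModel]:
        return iter(self._models.values())

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return key in self._models

    @property
    def parameters(self) -> list[str]:
        return sorted({m.parameter for m in self})

    @property
    def materials(self) -> list[str]:
        return sorted({m.material for m in self})

    def subset(self, material: str | None = None, phase: str | None = None) -> "ModelStore":
        return ModelStore(
            [
                m
                for m in self
                if (material is None or m.material == material)
                and (phase is None or m.phase == phase)
            ]
        )

    def to_json(self) -> str:
        doc = {
            "format": "metabodrift-model-store",
            "version": STORE_FORMAT_VERSION,
            "models": [asdict(m) for m in self],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelStore":
        doc = json.loads(text)
        if doc.get("format") != "metabodrift-model-store":
            raise ValueError("not a model store document")
        if doc.get("version") != STORE_FORMAT_VERSION:
            raise ValueError(f"unsupported model store version {doc.get('version')}")
        return cls([DriftModel(**rec) for rec in doc["models"]])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ModelStore":
        return cls.from_json(Path(path).read_text())


def fit_all(
    data: pd.DataFrame, spec: ModelSpec = ModelSpec()
) -> tuple[ModelStore, pd.DataFrame]:
    """Fit a drift model for every parameter × material × phase stratum.

    Applies the missingness filter first, then fits each remaining
    stratum; strata failing preconditions (too few donors, no data) are
    skipped and logged with reasons. Returns ``(store, skip_log)``.
    """
    store = ModelStore()
    skipped: list[dict] = []
    if data.empty:
        warnings.warn("empty timecourse dataset; empty model store", stacklevel=2)
        return store, pd.DataFrame(columns=["parameter", "material", "phase", "reason"])
    filtered, removed = filter_missingness(data, spec.max_missing_fraction)
    for _, row in removed.iterrows():
        skipped.append(
            {
                "parameter": row["parameter"],
                "material": row["material"],
                "phase": row["phase"],
                "reason": f"missing fraction {row['missing_fraction']:.2f} > {spec.max_missing_fraction}",
            }
        )
    grouped = filtered.groupby(["parameter", "material", "phase"], sort=True, observed=True)
    for (parameter, material, phase), sub in grouped:
        try:
            model = DriftLMM(sub, spec).fit()
        except ValueError as exc:
            skipped.append(
                {"parameter": parameter, "material": material, "phase": phase, "reason": str(exc)}
            )
            continue
        store.add(model)
    return store, pd.DataFrame(skipped, columns=["parameter", "material", "phase", "reason"])


def split_donors(
    donors: Sequence[str], train_fraction: float = 2.0 / 3.0, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Donor-level model/validation split (default two thirds / one third).

    The split is by donor, not by observation, so that validation
    donors are entirely unseen by the fitted models.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    unique = sorted(set(donors))
    n_train = int(round(train_fraction * len(unique)))
    n_train = min(max(n_train, 1), len(unique) - 1) if len(unique) > 1 else len(unique)
    perm = rng.permutation(len(unique))
    train = sorted(unique[i] for i in perm[:n_train])
    test = sorted(unique[i] for i in perm[n_train:])
    return train, test
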