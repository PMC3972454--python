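"""Model specification, covariate logic, fitting and export.

This is the exploratory modelling layer: a
:class:`ModelSpec` names a dependent variable, an independent variable
(optionally smooth), user covariates and an optional interaction
variable.  *System covariates* — scanner device identity, socio-economic
factors and genetic ancestry proportion factors — are curated nuisance
terms that are enabled by default and can be toggled off.

Domain-aware expansions applied automatically:

* an interaction always brings its own main effect into the design;
* of K ancestry proportion columns (which sum to 1 and would make the
  design rank deficient next to the intercept) only K-1 enter, dropping
  the last in canonical (lexicographic) order;
* the scanner device enters as a factor;
* sessions with a missing value in any model variable are removed before
  fitting (listwise deletion), and repeated visits of one subject
  trigger a cross-sectional-analysis warning.

Everything runs through the :class:`~neurocohort.gam.GAMRegressor`
estimator; with the smooth flag off the fit is exactly ordinary least
squares.
"""

from __future__ import annotations

import dataclasses
import json
import subprocess
import sys
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, complete_cases
from .dictionary import DataDictionary
from .gam import (
    FactorTerm,
    GAMError,
    GAMRegressor,
    LinearByFactorTerm,
    LinearTerm,
    SmoothByFactorTerm,
    SmoothTerm,
    term_label,
    term_variables,
)

__all__ = [
    "ModelSpec",
    "SystemColumns",
    "ModelTerms",
    "FitResult",
    "PredictionCurve",
    "validate_spec",
    "build_terms",
    "fit_model",
    "predict_curves",
    "partial_residuals",
    "compare_models",
    "export_bundle",
    "run_bundle_script",
]


class ModelError(ValueError):
    pass


@dataclasses.dataclass
class ModelSpec:
    dependent: str
    independent: str
    smooth: bool = True
    covariates: list[str] = dataclasses.field(default_factory=list)
    interaction: str | None = None
    use_device: bool = True
    use_ses: bool = True
    use_ancestry: bool = True

    def to_dict(self) -> dict:
        return {
            "dependent": self.dependent,
            "independent": self.independent,
            "smooth": self.smooth,
            "covariates": list(self.covariates),
            "interaction": self.interaction,
            "system": {
                "device": self.use_device,
                "ses": self.use_ses,
                "ancestry": self.use_ancestry,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        system = d.get("system", {})
        return cls(
            dependent=d["dependent"],
            independent=d["independent"],
            smooth=bool(d.get("smooth", True)),
            covariates=list(d.get("covariates", [])),
            interaction=d.get("interaction"),
            use_device=bool(system.get("device", True)),
            use_ses=bool(system.get("ses", True)),
            use_ancestry=bool(system.get("ancestry", True)),
        )


@dataclasses.dataclass
class SystemColumns:
    """Where the system covariates live in the cohort table."""

    device: str = "Device_SerialNumber"
    ses: tuple[str, ...] = ("Household_Income", "Parental_Education")
    ancestry_prefix: str = "GAF_"

    def ancestry_names(self, measures: Sequence[str]) -> list[str]:
        return sorted(m for m in measures if m.startswith(self.ancestry_prefix))


@dataclasses.dataclass
class ModelTerms:
    """Dependent variable plus the ordered design terms."""

    dependent: str
    terms: tuple

    @property
    def variables(self) -> list[str]:
        return [self.dependent] + term_variables(self.terms)

    @property
    def model_string(self) -> str:
        rhs = " + ".join(term_label(t) for t in self.terms) or "1"
        return f"{self.dependent} ~ {rhs}"


def validate_spec(spec: ModelSpec, dictionary: DataDictionary) -> list[str]:
    """Return the full list of specification problems (empty == valid).

    Unknown names come back with nearest-match suggestions, mirroring the
    immediate feedback a user gets while typing a model.
    """
    errors: list[str] = []
    names = [("dependent", spec.dependent), ("independent", spec.independent)]
    names += [("covariate", c) for c in spec.covariates]
    if spec.interaction:
        names.append(("interaction", spec.interaction))
    for role, name in names:
        if name not in dictionary:
            suggestions = dictionary.suggest(name)
            hint = f"; did you mean {suggestions[0]!r}?" if suggestions else ""
            errors.append(f"unknown {role} term {name!r}{hint}")
    if spec.dependent == spec.independent:
        errors.append("dependent and independent variables must differ")
    if spec.interaction and spec.interaction in spec.covariates:
        errors.append(
            f"interaction variable {spec.interaction!r} may not also be a covariate"
        )
    return errors


def build_terms(
    spec: ModelSpec,
    ancestry_names: Sequence[str] = (),
    ses_names: Sequence[str] = SystemColumns().ses,
    device_name: str = SystemColumns().device,
) -> ModelTerms:
    """Expand a spec into the ordered design term list.

    The independent variable enters smooth or linear; an interaction adds
    both the factor main effect and the interaction term; enabled system
    blocks append the device factor, SES terms, and K-1 of the K ancestry
    proportion columns (last dropped in canonical order).
    """
    terms: list = []
    if spec.smooth:
        terms.append(SmoothTerm(spec.independent, role="independent"))
    else:
        terms.append(LinearTerm(spec.independent, role="independent"))
    if spec.interaction:
        terms.append(FactorTerm(spec.interaction, role="interaction_main"))
        if spec.smooth:
            terms.append(
                SmoothByFactorTerm(spec.independent, spec.interaction, role="interaction")
            )
        else:
            terms.append(
                LinearByFactorTerm(spec.independent, spec.interaction, role="interaction")
            )
    for cov in spec.covariates:
        terms.append(LinearTerm(cov, role="covariate"))
    if spec.use_device:
        terms.append(FactorTerm(device_name, role="device"))
    if spec.use_ses:
        for name in ses_names:
            terms.append(LinearTerm(name, role="ses"))
    if spec.use_ancestry:
        ancestry = sorted(ancestry_names)
        if not ancestry:
            raise ModelError(
                "ancestry covariates enabled but no ancestry proportion "
                "columns were provided"
            )
        for name in ancestry[:-1]:  # drop-one: proportions sum to 1
            terms.append(LinearTerm(name, role="ancestry"))
    return ModelTerms(spec.dependent, tuple(terms))


@dataclasses.dataclass
class FitResult:
    """Fitted-model summary: the unit the toolkit reports and exports."""

    estimator: GAMRegressor
    model_terms: ModelTerms
    data: pd.DataFrame            # complete-case rows actually used
    data_version: str = ""

    @property
    def n_used(self) -> int:
        return self.estimator.n_used_

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.estimator.design_.column_names, self.estimator.coef_))

    @property
    def term_pvalues(self) -> dict[str, float]:
        return {t["term"]: t["p_value"] for t in self.estimator.term_summaries_}

    @property
    def variance_explained(self) -> float:
        return self.estimator.r2_

    @property
    def deviance_explained(self) -> float:
        return self.estimator.deviance_explained_

    @property
    def adjusted_r2(self) -> float:
        return self.estimator.adjusted_r2_

    @property
    def aic(self) -> float:
        return self.estimator.aic_

    @property
    def bic(self) -> float:
        return self.estimator.bic_

    @property
    def model_string(self) -> str:
        return self.model_terms.model_string

    @property
    def session_keys(self) -> frozenset:
        return frozenset(self.data.index)

    @property
    def independent(self) -> str:
        return self.model_terms.terms[0].name

    @property
    def interaction(self) -> str | None:
        for t in self.model_terms.terms:
            if getattr(t, "role", None) == "interaction_main":
                return t.name
        return None

    def summary_dict(self) -> dict:
        return {
            "model": self.model_string,
            "data_version": self.data_version,
            "n_used": self.n_used,
            "edf": self.estimator.edf_,
            "lambda": self.estimator.lam_,
            "variance_explained": self.variance_explained,
            "deviance_explained": self.deviance_explained,
            "adjusted_r2": self.adjusted_r2,
            "aic": self.aic,
            "bic": self.bic,
            "term_p_values": self.term_pvalues,
            "coefficients": self.coefficients,
        }


def _resolve_factor_covariates(df: pd.DataFrame, model_terms: ModelTerms) -> ModelTerms:
    """Promote non-numeric covariate/SES linear terms to factors."""
    new_terms = []
    for t in model_terms.terms:
        if isinstance(t, LinearTerm) and t.role in ("covariate", "ses"):
            if not pd.api.types.is_numeric_dtype(df[t.name]):
                t = FactorTerm(t.name, role=t.role)
        new_terms.append(t)
    return ModelTerms(model_terms.dependent, tuple(new_terms))


def fit_model(
    table: CohortTable | pd.DataFrame,
    model_terms: ModelTerms,
    lam_grid=None,
) -> FitResult:
    """Listwise-delete, fit the additive model, and summarise.

    Uses exactly the complete-case rows over all model variables.  A
    subject appearing at more than one visit triggers a warning that the
    analysis stream is cross-sectional.
    """
    if isinstance(table, CohortTable):
        ct = complete_cases(table, model_terms.variables)
        df, version = ct.data, table.version_label
    else:
        missing = [v for v in model_terms.variables if v not in table.columns]
        if missing:
            raise ModelError(f"unknown variable(s): {', '.join(missing)}")
        df, version = table.dropna(subset=model_terms.variables), ""
    if df.empty:
        raise ModelError("no rows remain after removing sessions with missing values")
    if isinstance(df.index, pd.MultiIndex):
        subjects = df.index.get_level_values(0)
        if subjects.duplicated().any():
            warnings.warn(
                "repeated visits detected for some subjects; the analysis "
                "stream is cross-sectional and treats visits as independent "
                "sessions",
                stacklevel=2,
            )
    model_terms = _resolve_factor_covariates(df, model_terms)
    est = GAMRegressor(terms=model_terms.terms, lam_grid=lam_grid)
    est.fit(df, np.asarray(df[model_terms.dependent], float))
    return FitResult(est, model_terms, df, version)


@dataclasses.dataclass
class PredictionCurve:
    level: str                 # interaction level, or "all"
    grid: np.ndarray
    fitted: np.ndarray
    se: np.ndarray


def _reference_row(df: pd.DataFrame, skip: Sequence[str]) -> dict:
    """Covariate reference values: mean for numeric, mode for factors."""
    ref = {}
    for col in df.columns:
        if col in skip:
            continue
        if pd.api.types.is_numeric_dtype(df[col]):
            ref[col] = float(df[col].mean())
        else:
            ref[col] = df[col].mode().iloc[0]
    return ref


def predict_curves(fit: FitResult, n_grid: int = 100) -> list[PredictionCurve]:
    """Mean curves over the observed independent range, one per level.

    Covariates are held at reference values (mean of used rows for
    continuous terms, mode for factors).
    """
    indep = fit.independent
    x = np.asarray(fit.data[indep], float)
    grid = np.linspace(x.min(), x.max(), n_grid)
    inter = fit.interaction
    levels = (
        sorted(fit.data[inter].astype(str).unique()) if inter else ["all"]
    )
    ref = _reference_row(fit.data, skip=[indep, fit.model_terms.dependent] +
                         ([inter] if inter else []))
    curves = []
    for level in levels:
        frame = {indep: grid}
        for col, val in ref.items():
            frame[col] = np.repeat(val, n_grid)
        if inter:
            frame[inter] = np.repeat(level, n_grid)
        newdata = pd.DataFrame(frame)
        curves.append(
            PredictionCurve(
                level=level,
                grid=grid,
                fitted=fit.estimator.predict(newdata),
                se=fit.estimator.predict_se(newdata),
            )
        )
    return curves


#: term roles whose fitted contribution is removed from residualized points
NUISANCE_ROLES = ("covariate", "device", "ses", "ancestry")


def partial_residuals(fit: FitResult) -> pd.DataFrame:
    """Observed response minus fitted nuisance-covariate contributions.

    The independent-variable, interaction and intercept contributions are
    kept, so the points scatter around the prediction curves.  Each point
    carries the subject id plus gender/age demographics when available.
    """
    est = fit.estimator
    nuisance = est.contribution(NUISANCE_ROLES)
    # re-centre: removed covariate contributions have a nonzero mean
    points = est.y_ - (nuisance - nuisance.mean())
    out = pd.DataFrame(
        {
            "independent": np.asarray(fit.data[fit.independent], float),
            "partial_residual": points,
        },
        index=fit.data.index,
    )
    if isinstance(fit.data.index, pd.MultiIndex):
        out["subject_id"] = fit.data.index.get_level_values(0)
    else:
        out["subject_id"] = fit.data.index.astype(str)
    for extra, cols in (("gender", ("Gender",)),
                        ("age", ("Age_At_IMGExam", "Age", "Age_At_NPExam"))):
        for col in cols:
            if col in fit.data.columns:
                out[extra] = fit.data[col].to_numpy()
                break
    if fit.interaction and "gender" not in out.columns:
        out["gender"] = fit.data[fit.interaction].to_numpy()
    return out


def compare_models(fit_a: FitResult, fit_b: FitResult) -> dict:
    """AIC/BIC comparison; only valid on the identical session subset."""
    if fit_a.session_keys != fit_b.session_keys:
        raise ModelError(
            "models were fitted on different session subsets "
            f"({fit_a.n_used} vs {fit_b.n_used} rows); information criteria "
            "are not comparable"
        )
    delta_aic = fit_b.aic - fit_a.aic
    delta_bic = fit_b.bic - fit_a.bic
    preferred = "A" if fit_a.aic <= fit_b.aic else "B"
    return {"delta_aic": delta_aic, "delta_bic": delta_bic, "preferred": preferred}


# ---------------------------------------------------------------------------
# reproducibility bundle
# ---------------------------------------------------------------------------

_TERM_TAGS = {
    LinearTerm: "linear",
    FactorTerm: "factor",
    SmoothTerm: "smooth",
    SmoothByFactorTerm: "smooth_by",
    LinearByFactorTerm: "linear_by",
}
_TAG_TERMS = {v: k for k, v in _TERM_TAGS.items()}


def terms_to_json(model_terms: ModelTerms) -> list[dict]:
    out = []
    for t in model_terms.terms:
        d = {"kind": _TERM_TAGS[type(t)], "name": t.name, "role": t.role}
        if hasattr(t, "by"):
            d["by"] = t.by
        if hasattr(t, "n_splines"):
            d["n_splines"] = t.n_splines
        out.append(d)
    return out


def terms_from_json(dependent: str, items: Sequence[dict]) -> ModelTerms:
    terms = []
    for d in items:
        cls = _TAG_TERMS[d["kind"]]
        kwargs = {"name": d["name"], "role": d["role"]}
        if "by" in d:
            kwargs["by"] = d["by"]
        if "n_splines" in d and d["kind"] in ("smooth", "smooth_by"):
            kwargs["n_splines"] = d["n_splines"]
        terms.append(cls(**kwargs))
    return ModelTerms(dependent, tuple(terms))


_ANALYSIS_SCRIPT = '''\
"""Self-contained re-analysis script emitted by export_bundle.

Re-fits the exported model on the exported data snapshot and writes the
coefficient vector to refit_coefficients.json; the result reproduces the
original fit.
"""
import json
from pathlib import Path

import pandas as pd

from neurocohort.models import fit_model, terms_from_json

here = Path(__file__).parent
meta = json.loads((here / "model.json").read_text())
data = pd.read_csv(here / "data.csv").set_index(meta["key_columns"])
mt = terms_from_json(meta["dependent"], meta["terms"])
fit = fit_model(data, mt)
(here / "refit_coefficients.json").write_text(
    json.dumps(fit.coefficients, indent=1)
)
print(json.dumps({"n_used": fit.n_used,
                  "variance_explained": fit.variance_explained}))
'''


def export_bundle(
    fit: FitResult,
    out_dir: str | Path,
    n_grid: int = 100,
) -> Path:
    """Write a self-contained bundle documenting one fitted model.

    Contents: ``data.csv`` (used rows), ``model.json`` (term list +
    summary), ``curves.csv`` (level, grid, fitted, se), ``scatter.pdf``
    (vector graphic of residualized points and curves), ``analysis.py``
    (script that re-fits the model on the snapshot).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ModelError(f"cannot write bundle to {out}: {exc}") from exc

    key_columns = list(fit.data.index.names) if fit.data.index.names[0] else []
    data = fit.data[[c for c in fit.model_terms.variables]]
    data.reset_index().to_csv(out / "data.csv", index=False)

    meta = {
        "dependent": fit.model_terms.dependent,
        "terms": terms_to_json(fit.model_terms),
        "key_columns": key_columns,
        "summary": fit.summary_dict(),
    }
    (out / "model.json").write_text(json.dumps(meta, indent=1))

    curves = predict_curves(fit, n_grid=n_grid)
    rows = []
    for c in curves:
        for g, f, s in zip(c.grid, c.fitted, c.se):
            rows.append({"level": c.level, "grid": g, "fitted": f, "se": s})
    pd.DataFrame(rows).to_csv(out / "curves.csv", index=False)

    _scatter_pdf(fit, curves, out / "scatter.pdf")
    (out / "analysis.py").write_text(_ANALYSIS_SCRIPT)
    return out


def _scatter_pdf(fit: FitResult, curves: list[PredictionCurve], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    points = partial_residuals(fit)
    fig, ax = plt.subplots(figsize=(7, 5))
    inter = fit.interaction
    if inter:
        groups = fit.data[inter].astype(str).to_numpy()
        for level in sorted(set(groups)):
            m = groups == level
            ax.scatter(points["independent"][m], points["partial_residual"][m],
                       s=8, alpha=0.5, label=level)
    else:
        ax.scatter(points["independent"], points["partial_residual"],
                   s=8, alpha=0.5, color="gray")
    for c in curves:
        ax.plot(c.grid, c.fitted, label=f"fit: {c.level}")
        ax.fill_between(c.grid, c.fitted - 2 * c.se, c.fitted + 2 * c.se, alpha=0.2)
    ax.set_xlabel(fit.independent)
    ax.set_ylabel(fit.model_terms.dependent)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, format="pdf")
    plt.close(fig)


def run_bundle_script(bundle_dir: str | Path) -> dict[str, float]:
    """Execute the emitted analysis script; return the refit coefficients."""
    bundle_dir = Path(bundle_dir)
    proc = subprocess.run(
        [sys.executable, str(bundle_dir / "analysis.py")],
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        raise ModelError(f"bundle script failed:\n{proc.stderr}")
    return json.loads((bundle_dir / "refit_coefficients.json").read_text())
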