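"""Behavioral mixed-model statistics.

Fits the two logistic mixed-effects models of the paradigm —

* Intervening-task errors: ``logit(error) ~ WMCondition * Int`` with
  per-participant random intercepts and slopes,
* WM-task errors: ``logit(error) ~ ModalityWM * DomainWM * Int`` likewise,

— runs Wald chi-square omnibus tests on the coefficients, extracts all
needed pairwise simple effects by cycling which factor level is treatment
coded as baseline, and applies the Holm-Bonferroni step-down correction.

The estimation backend is pluggable: ``"map"`` uses statsmodels'
Bayesian mixed GLM at its posterior mode (Laplace covariance) to carry
the random-effects structure; ``"logit"`` is an ordinary logistic
regression with cluster-robust (by participant) covariance.  If a mixed
fit fails it falls back, with a logged message, to simpler random
structures and finally to ``"logit"`` — never silently.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec", "GlmmFit", "PosthocResult", "behavioral_table",
    "fit_glmm", "anova_on_coefficients", "cycle_baselines",
    "holm_bonferroni", "default_needed_pairs",
]

_FACTORS = {
    "wm": {"response": "wm_error",
           "factors": ("wm_modality", "wm_domain", "intervening"),
           "baselines": {"wm_modality": "auditory", "wm_domain": "temporal",
                         "intervening": "none"}},
    "intervening": {"response": "intervening_error",
                    "factors": ("wm_condition", "intervening"),
                    "baselines": {"wm_condition": "AT", "intervening": "AT"}},
}


@dataclass
class ModelSpec:
    """Which model to fit, its treatment-coding baselines and backend.

    Backends: ``"lme4"`` calls R's glmer through Rscript (the reference
    estimator for random-slope logistic models), ``"map"`` uses
    statsmodels' Bayesian mixed GLM at its posterior mode, ``"logit"``
    is ordinary logistic regression with cluster-robust covariance, and
    ``"auto"`` tries map then logit.
    """

    formula_id: str = "wm"                  # "wm" or "intervening"
    baselines: dict = field(default_factory=dict)
    random: str = "intercepts"              # "slopes", "intercepts" or "none"
    backend: str = "auto"                   # "auto", "lme4", "map" or "logit"

    def __post_init__(self) -> None:
        if self.formula_id not in _FACTORS:
            raise ValueError("formula_id must be 'wm' or 'intervening'")
        defaults = dict(_FACTORS[self.formula_id]["baselines"])
        defaults.update(self.baselines)
        self.baselines = defaults

    @property
    def factors(self) -> tuple:
        return _FACTORS[self.formula_id]["factors"]

    @property
    def response(self) -> str:
        return _FACTORS[self.formula_id]["response"]

    def formula(self) -> str:
        terms = " * ".join(
            f"C({f}, Treatment('{self.baselines[f]}'))" for f in self.factors)
        return f"{self.response} ~ {terms}"


@dataclass
class GlmmFit:
    """Fixed-effect estimates with covariance and fit diagnostics."""

    params: pd.Series
    cov: pd.DataFrame
    spec: ModelSpec
    backend_used: str
    converged: bool
    n_obs: int
    messages: list = field(default_factory=list)

    def term_of(self, name: str) -> str:
        """Map a design-matrix column to its model term."""
        if name == "Intercept":
            return "Intercept"
        parts = name.split(":")
        factors = []
        for p in parts:
            factors.append(p.split("C(")[1].split(",")[0].strip())
        return " x ".join(factors)


def behavioral_table(trials: pd.DataFrame, task: str) -> pd.DataFrame:
    """Rows of the trial table relevant to one task's error model."""
    df = trials.copy()
    if task == "intervening":
        df = df[df["intervening"] != "none"].copy()
        df["intervening_error"] = df["intervening_error"].astype(int)
    else:
        df["wm_error"] = df["wm_error"].astype(int)
    return df


def _check_degenerate(df: pd.DataFrame, spec: ModelSpec) -> None:
    rates = df.groupby(list(spec.factors))[spec.response].mean()
    bad = rates[(rates == 0) | (rates == 1)]
    if len(bad):
        raise ValueError(
            f"separation: all-0/all-1 cells after pooling: {list(bad.index)}")


def fit_glmm(table: pd.DataFrame, spec: ModelSpec) -> GlmmFit:
    """Fit the logistic (mixed) model given by ``spec``.

    Backend "map" keeps participant random intercepts (and, with
    ``spec.random == 'slopes'``, independent random slopes per factor);
    backend "logit" fits ordinary logistic regression with
    cluster-robust covariance by participant.  With ``backend='auto'``
    mixed fits that fail fall back in the order slopes -> intercepts ->
    logit, each attempt logged.
    """
    df = behavioral_table(table, spec.formula_id)
    if spec.response not in df.columns:
        raise ValueError(f"table lacks response column {spec.response}")
    df[spec.response] = df[spec.response].astype(int)
    _check_degenerate(df, spec)
    messages: list[str] = []

    order = {"map": ["map"], "logit": ["logit"], "lme4": ["lme4"],
             "auto": ["map", "logit"]}[spec.backend]
    # a single participant cannot support participant random effects
    if df["participant"].nunique() < 2 and "logit" in order:
        order = ["logit"]
        messages.append("single participant: random effects dropped")

    last_err: Exception | None = None
    for backend in order:
        structures = ([spec.random] if backend == "lme4"
                      else [spec.random] if backend != "map"
                      else {"slopes": ["slopes", "intercepts"],
                            "intercepts": ["intercepts"],
                            "none": ["intercepts"]}[spec.random])
        for structure in structures:
            try:
                if backend == "map":
                    fit = _fit_map(df, spec, structure)
                elif backend == "lme4":
                    fit = _fit_lme4(df, spec, structure)
                else:
                    fit = _fit_logit(df, spec)
                fit.messages = messages + fit.messages
                return fit
            except Exception as err:  # noqa: BLE001 - fallback is the contract
                last_err = err
                msg = f"{backend}/{structure} fit failed: {err}"
                logger.warning(msg)
                messages.append(msg)
    raise RuntimeError(f"all backends failed: {last_err}")


def _vc_formulas(spec: ModelSpec, structure: str) -> dict:
    vc = {"participant": "0 + C(participant)"}
    if structure == "slopes":
        for f in spec.factors:
            vc[f"slope_{f}"] = (f"0 + C(participant):"
                                f"C({f}, Treatment('{spec.baselines[f]}'))")
    return vc


def _fit_map(df: pd.DataFrame, spec: ModelSpec, structure: str) -> GlmmFit:
    import warnings

    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
    model = BinomialBayesMixedGLM.from_formula(
        spec.formula(), _vc_formulas(spec, structure), df)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        # generous iteration budget: the default BFGS budget leaves
        # high-dimensional random-slope posteriors visibly under-optimized
        res = model.fit_map(minim_opts={"maxiter": 1000, "gtol": 1e-4})
    messages = [str(w.message) for w in caught
                if "did not converge" in str(w.message)]
    for m in messages:
        logger.warning("map/%s: %s", structure, m)
    names = list(model.exog_names)
    k = len(names)
    params = pd.Series(res.params[:k], index=names)
    if not np.isfinite(params.to_numpy()).all():
        raise RuntimeError("map fit produced non-finite fixed effects")
    cov = res.cov_params()
    cov = pd.DataFrame(np.asarray(cov)[:k, :k], index=names, columns=names)
    if not np.isfinite(np.diag(cov)).all() or (np.diag(cov) <= 0).any():
        raise RuntimeError("map fit produced an invalid covariance")
    return GlmmFit(params=params, cov=cov, spec=spec,
                   backend_used=f"map/{structure}",
                   converged=not messages, n_obs=len(df),
                   messages=messages)


_LME4_TEMPLATE = """
suppressMessages(library(lme4))
df <- read.csv("{csv}")
df$participant <- factor(df$participant)
{relevels}
m <- glmer({formula}, data = df, family = binomial, nAGQ = {nagq},
           control = glmerControl(optimizer = "nloptwrap",
                                  calc.derivs = FALSE,
                                  optCtrl = list(xtol_abs = 1e-5,
                                                 ftol_abs = 1e-5)))
fe <- fixef(m)
V <- as.matrix(vcov(m))
write.csv(data.frame(name = names(fe), beta = fe), "{fe_out}",
          row.names = FALSE)
write.csv(V, "{cov_out}", row.names = FALSE)
cat(ifelse(length(m@optinfo$conv$lme4) == 0, "converged", "not-converged"))
"""


def _lme4_name_map(spec: ModelSpec, df: pd.DataFrame) -> dict:
    """Map lme4 coefficient names to the patsy treatment-coded names."""
    single = {"(Intercept)": "Intercept"}
    for f in spec.factors:
        base = spec.baselines[f]
        for level in sorted(df[f].unique()):
            if level != base:
                single[f"{f}{level}"] = f"C({f}, Treatment('{base}'))[T.{level}]"

    def translate(name: str) -> str:
        return ":".join(single.get(part, part) for part in name.split(":"))

    return translate


def _fit_lme4(df: pd.DataFrame, spec: ModelSpec, structure: str,
              nagq: int = 0) -> GlmmFit:
    """Fit the model with R's glmer (lme4) through Rscript.

    Random slopes are fitted as independent terms (the `||` form),
    matching the variance-component structure of the map backend.
    ``nagq=0`` uses the fast penalized-least-squares approximation, which
    is accurate for datasets of this size and balance.
    """
    import subprocess
    import tempfile

    fixed = " * ".join(spec.factors)
    if structure == "slopes":
        rand = f"(1 + {' + '.join(spec.factors)} || participant)"
    else:
        rand = "(1 | participant)"
    formula = f"{spec.response} ~ {fixed} + {rand}"
    with tempfile.TemporaryDirectory() as tmp:
        csv = f"{tmp}/table.csv"
        fe_out, cov_out = f"{tmp}/fe.csv", f"{tmp}/vcov.csv"
        df.to_csv(csv, index=False)
        relevels = "\n".join(
            f'df${f} <- relevel(factor(df${f}), "{spec.baselines[f]}")'
            for f in spec.factors)
        script = f"{tmp}/fit.R"
        with open(script, "w") as fh:
            fh.write(_LME4_TEMPLATE.format(csv=csv, relevels=relevels,
                                           formula=formula, nagq=nagq,
                                           fe_out=fe_out, cov_out=cov_out))
        proc = subprocess.run(["Rscript", "--vanilla", script],
                              capture_output=True, text=True, timeout=600)
        if proc.returncode != 0:
            raise RuntimeError(f"glmer failed: {proc.stderr.strip()[-500:]}")
        converged = proc.stdout.strip().endswith("converged") and \
            not proc.stdout.strip().endswith("not-converged")
        fe = pd.read_csv(fe_out)
        V = pd.read_csv(cov_out).to_numpy()
    translate = _lme4_name_map(spec, df)
    names = [translate(n) for n in fe["name"]]
    params = pd.Series(fe["beta"].to_numpy(), index=names)
    cov = pd.DataFrame(V, index=names, columns=names)
    return GlmmFit(params=params, cov=cov, spec=spec,
                   backend_used=f"lme4/{structure}", converged=converged,
                   n_obs=len(df))


def _fit_logit(df: pd.DataFrame, spec: ModelSpec) -> GlmmFit:
    many = df["participant"].nunique() > 1
    model = smf.glm(spec.formula(), df, family=sm.families.Binomial())
    if many:
        res = model.fit(cov_type="cluster",
                        cov_kwds={"groups": df["participant"].to_numpy()})
    else:
        res = model.fit()
    return GlmmFit(params=res.params, cov=res.cov_params(), spec=spec,
                   backend_used="logit", converged=bool(res.converged)
                   if hasattr(res, "converged") else True,
                   n_obs=len(df))


def anova_on_coefficients(fit: GlmmFit) -> pd.DataFrame:
    """Wald chi-square omnibus test per model term (main effects and
    interactions), from the coefficient vector and its covariance."""
    groups: dict[str, list[str]] = {}
    for name in fit.params.index:
        term = fit.term_of(name)
        if term == "Intercept":
            continue
        groups.setdefault(term, []).append(name)
    rows = []
    V = fit.cov.to_numpy()
    names = list(fit.params.index)
    for term, cols in groups.items():
        idx = [names.index(c) for c in cols]
        beta = fit.params.to_numpy()[idx]
        sub = V[np.ix_(idx, idx)]
        try:
            w = float(beta @ np.linalg.solve(sub, beta))
        except np.linalg.LinAlgError as err:
            raise ValueError(f"rank-deficient design for term {term}") from err
        df_term = len(idx)
        rows.append({"term": term, "chi2": w, "df": df_term,
                     "p": float(stats.chi2.sf(w, df_term))})
    return pd.DataFrame(rows)


# ----------------------------------------------------------- post hocs

@dataclass
class PosthocResult:
    """One pairwise simple-effect contrast read from a refit model."""

    factor: str
    level_a: str          # baseline level in the refit
    level_b: str
    within: tuple         # (factor, level) restrictions defining the cell
    beta: float
    se: float
    p_raw: float
    p_holm_significant: bool | None = None


def default_needed_pairs(spec: ModelSpec) -> list:
    """The within-task pairwise comparisons reported for this paradigm.

    WM model: Intervening-condition pairs within each WM condition
    (modality x domain cell).  Intervening model: WM-condition pairs
    within each Intervening task.
    """
    pairs = []
    if spec.formula_id == "wm":
        for m in ("auditory", "visual"):
            for d in ("temporal", "spatial"):
                within = (("wm_modality", m), ("wm_domain", d))
                for a, b in combinations(("none", "AT", "AS"), 2):
                    pairs.append(("intervening", a, b, within))
    else:
        for i in ("AT", "AS"):
            within = (("intervening", i),)
            for a, b in combinations(("AT", "AS", "VT", "VS"), 2):
                pairs.append(("wm_condition", a, b, within))
    return pairs


def cycle_baselines(table: pd.DataFrame, spec: ModelSpec,
                    needed_pairs: list | None = None) -> list:
    """Extract each needed pairwise simple effect by baseline cycling.

    The model is refit under rotated treatment-coding baselines; the
    coefficient for factor level ``b`` when ``a`` is baseline (and the
    ``within`` restriction levels are the other factors' baselines) is the
    simple effect of ``b`` vs ``a`` in that cell.  Each pair is extracted
    exactly once.  Raises if a pair cannot be reached.
    """
    needed = needed_pairs if needed_pairs is not None else \
        default_needed_pairs(spec)
    results: dict[tuple, PosthocResult] = {}
    fits: dict[tuple, GlmmFit] = {}
    for factor, a, b, within in needed:
        key = (factor, frozenset((a, b)), within)
        if key in results:
            continue
        baselines = dict(spec.baselines)
        baselines[factor] = a
        for f, level in within:
            if f not in baselines:
                raise ValueError(f"within factor {f} not in the model")
            baselines[f] = level
        bkey = tuple(sorted(baselines.items()))
        if bkey not in fits:
            fits[bkey] = fit_glmm(table, replace(spec, baselines=baselines))
        fit = fits[bkey]
        col = f"C({factor}, Treatment('{a}'))[T.{b}]"
        if col not in fit.params.index:
            raise ValueError(f"pair ({a}, {b}) of {factor} not reachable "
                             f"under the formula (no column {col})")
        beta = float(fit.params[col])
        se = float(np.sqrt(fit.cov.loc[col, col]))
        z = beta / se if se > 0 else np.inf
        results[key] = PosthocResult(
            factor=factor, level_a=a, level_b=b, within=within,
            beta=beta, se=se, p_raw=float(2 * stats.norm.sf(abs(z))))
    out = list(results.values())
    flags = holm_bonferroni(np.array([r.p_raw for r in out]))
    for r, flag in zip(out, flags):
        r.p_holm_significant = bool(flag)
    return out


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down significance flags at familywise level ``alpha``.

    Sort p ascending; the i-th smallest is significant iff every j <= i
    satisfies ``p_(j) <= alpha / (m - j + 1)`` (1-based).
    """
    p = np.asarray(p_values, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("p-values must be finite")
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            flags[idx] = True
        else:
            break
    return flags
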