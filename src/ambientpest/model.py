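"""Case-control odds-ratio models.

The analysis engine for unmatched case-control data: unconditional
logistic regression of case status on a binary exposure indicator,
mutually adjusted for co-occurring pesticide exposures and dummy-coded
breast-cancer risk factors, with Wald 95% confidence intervals and the
``>10%`` change-in-estimate confounder screen.

The public surface follows the model/results idiom:

>>> model = ExposureOddsModel.from_study(persons, flags, target="chlorpyrifos",
...                                      co_chemicals=["organochlorines"])
>>> res = model.fit()
>>> res.odds_ratio, res.conf_int
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .classify import COMBINED_BOTH, COMBINED_DISCORDANT, COMBINED_NEITHER
from .io import PERSON_CATEGORIES

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: Risk factors every model adjusts for (dummy-coded unless continuous).
DEFAULT_COVARIATES = (
    "age",
    "ses_quintile",
    "bmi_cat",
    "menarche_cat",
    "menopause_cat",
    "births_cat",
    "oc_cat",
    "ht_cat",
    "alcohol_weekly",
    "years_in_counties",
)

_CONTINUOUS = {"age", "years_in_counties"}
_BINARY = {"alcohol_weekly", "ever_farm_live", "ever_farm_work"}

#: |coefficient| beyond which a logistic estimate is treated as diverging
#: (odds ratio > e^15 ~ 3x10^6): the practical signature of separation.
SEPARATION_COEF = 15.0


class DesignError(ValueError):
    """The design matrix violates a precondition of the fit."""


def _ridge_logit(
    y: np.ndarray, X: np.ndarray, alpha: float = 1e-4, maxiter: int = 200
) -> np.ndarray:
    """Newton iterations on an L2-penalised logistic likelihood; the ridge
    keeps the Hessian invertible under separation or collinearity."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        p = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -500, 500)))
        grad = X.T @ (y - p) - alpha * beta
        if np.max(np.abs(grad)) < 1e-8:
            break
        w = np.clip(p * (1 - p), 1e-10, None)
        H = (X.T * w) @ X + alpha * np.eye(len(beta))
        beta = beta + np.linalg.solve(H, grad)
    return beta


@dataclass
class ModelResult:
    """Maximum-likelihood logistic fit with Wald inference."""

    terms: list[str]
    params: pd.Series
    cov_params: pd.DataFrame
    n_used: int
    converged: bool
    separation: bool

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.terms)

    def or_table(self) -> pd.DataFrame:
        se = self.bse
        est = self.params
        with np.errstate(over="ignore"):
            return self._or_table(est, se)

    def _or_table(self, est, se) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": est.values,
                "SE": se.values,
                "OR": np.exp(est.values),
                "CI_low": np.exp(est.values - Z_95 * se.values),
                "CI_high": np.exp(est.values + Z_95 * se.values),
                "n_used": self.n_used,
                "converged": self.converged,
            }
        )

    def summary(self) -> str:
        lines = [
            f"Logistic regression (n={self.n_used}, converged={self.converged}"
            + (", SEPARATION SUSPECTED" if self.separation else "")
            + ")",
            f"{'term':<28}{'OR':>10}{'CI low':>10}{'CI high':>10}",
        ]
        for _, r in self.or_table().iterrows():
            lines.append(
                f"{r['term']:<28}{r['OR']:>10.3f}{r['CI_low']:>10.3f}{r['CI_high']:>10.3f}"
            )
        return "\n".join(lines)


def fit_logistic(outcome: pd.Series | np.ndarray, design: pd.DataFrame) -> ModelResult:
    """Fit a logistic model by Newton/IRLS (gradient tolerance 1e-8,
    at most 100 iterations), with separation diagnostics.

    ``design`` must not contain an intercept column; one is added.
    Constant (zero-variance) predictors and one-class outcomes are
    rejected up front.
    """
    y = np.asarray(outcome, dtype=float)
    if y.min() == y.max():
        raise DesignError("outcome takes a single value; nothing to fit")
    variances = design.var(axis=0)
    constant = [c for c in design.columns if variances[c] == 0]
    if constant:
        raise DesignError(f"zero-variance predictors: {constant}")
    X = sm.add_constant(design.astype(float), has_constant="raise")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(
                method="newton", tol=1e-8, maxiter=100, disp=0, warn_convergence=False
            )
            params = fit.params
            cov = fit.cov_params()
            converged = bool(fit.mle_retvals.get("converged", False))
        except np.linalg.LinAlgError:
            # singular Hessian (separation or collinearity): ridge-penalised
            # Newton yields finite, flagged estimates instead of a crash
            beta = _ridge_logit(y, X.to_numpy(float))
            params = pd.Series(beta, index=X.columns)
            cov = pd.DataFrame(
                np.full((len(beta), len(beta)), np.nan),
                index=X.columns,
                columns=X.columns,
            )
            converged = False
    separation = (not converged) or bool(
        np.any(np.abs(params.values) > SEPARATION_COEF)
    )
    return ModelResult(
        terms=list(X.columns),
        params=params,
        cov_params=pd.DataFrame(np.asarray(cov), index=X.columns, columns=X.columns),
        n_used=len(y),
        converged=converged,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# design-matrix construction
# ---------------------------------------------------------------------------


def dummy_code(persons: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    """Dummy-code the covariate block; reference = lowest category."""
    blocks: list[pd.DataFrame] = []
    for cov in covariates:
        if cov in _CONTINUOUS:
            blocks.append(persons[[cov]].astype(float))
        elif cov in _BINARY:
            blocks.append(persons[[cov]].astype(int))
        elif cov == "ses_quintile":
            cat = pd.Categorical(persons[cov], categories=[1, 2, 3, 4, 5])
            d = pd.get_dummies(cat, prefix="ses", drop_first=True).astype(int)
            d.index = persons.index
            blocks.append(d)
        elif cov in PERSON_CATEGORIES:
            cat = pd.Categorical(persons[cov], categories=PERSON_CATEGORIES[cov])
            d = pd.get_dummies(cat, prefix=cov, drop_first=True).astype(int)
            d.index = persons.index
            blocks.append(d)
        else:
            raise DesignError(f"unknown covariate '{cov}'")
    if not blocks:
        return pd.DataFrame(index=persons.index)
    out = pd.concat(blocks, axis=1)
    # drop empty dummy levels so the design stays full rank
    return out.loc[:, out.var(axis=0) > 0]


def exposure_indicators(
    flags: pd.DataFrame, chemicals: list[str], contrast: str
) -> pd.DataFrame:
    """Wide binary indicator frame (index person_id) from long flags.

    contrast 'both_vs_neither': indicator = exposed at both settings;
    'any': indicator = exposed at either setting.
    """
    wide = {}
    for chem in chemicals:
        sub = flags[flags["chemical"] == chem].set_index("person_id")
        if sub.empty:
            raise DesignError(f"no flags for chemical '{chem}'")
        if contrast == "both_vs_neither":
            wide[chem] = (sub["combined"] == COMBINED_BOTH).astype(int)
        elif contrast == "any":
            wide[chem] = (
                (sub["residential_exposed"].astype(int) == 1)
                | (sub["workplace_exposed"].astype(int) == 1)
            ).astype(int)
        else:
            raise DesignError(f"unknown contrast '{contrast}'")
    return pd.DataFrame(wide)


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------


class ExposureOddsModel:
    """Mutually adjusted logistic model for one target exposure.

    Parameters
    ----------
    data
        Analysis frame indexed by person_id: ``case_status``, one binary
        column per chemical/group indicator, plus covariate columns.
    target
        Column name of the exposure of interest.
    co_chemicals
        Other exposure indicator columns entered as adjustment terms.
    covariates
        Risk-factor columns (see :data:`DEFAULT_COVARIATES`).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        target: str,
        co_chemicals: tuple[str, ...] = (),
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    ):
        self.data = data
        self.target = target
        self.co_chemicals = tuple(co_chemicals)
        self.covariates = tuple(covariates)
        tab = pd.crosstab(data["case_status"], data[target])
        for cs in (0, 1):
            for ex in (0, 1):
                n = tab.at[cs, ex] if (cs in tab.index and ex in tab.columns) else 0
                if n == 0:
                    cell = ("case" if cs else "control") + (
                        " exposed" if ex else " unexposed"
                    )
                    raise DesignError(f"empty contrast cell: no {cell} subjects")

    @classmethod
    def from_study(
        cls,
        persons: pd.DataFrame,
        flags: pd.DataFrame,
        target: str,
        co_chemicals: tuple[str, ...] = (),
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        contrast: str = "both_vs_neither",
    ) -> "ExposureOddsModel":
        """Assemble the analysis frame from the persons table and the
        long-format flags table.

        Under the primary both-vs-neither contrast, persons discordant for
        the *target* (exposed at exactly one setting) are excluded; other
        chemicals' indicators follow the same exposure definition but do
        not trigger exclusions.
        """
        chems = [target, *co_chemicals]
        ind = exposure_indicators(flags, chems, contrast)
        base = persons.drop(columns=[c for c in chems if c in persons.columns])
        df = base.set_index("person_id").join(ind, how="inner")
        if contrast == "both_vs_neither":
            target_flags = flags[flags["chemical"] == target].set_index("person_id")
            keep = target_flags.loc[
                target_flags["combined"] != COMBINED_DISCORDANT
            ].index
            df = df.loc[df.index.intersection(keep)]
        return cls(df, target, tuple(co_chemicals), tuple(covariates))

    def design(self) -> tuple[pd.Series, pd.DataFrame]:
        X = pd.concat(
            [
                self.data[[self.target, *self.co_chemicals]].astype(int),
                dummy_code(self.data, self.covariates),
            ],
            axis=1,
        )
        return self.data["case_status"].astype(int), X

    def fit(self) -> "ExposureOddsResults":
        y, X = self.design()
        return ExposureOddsResults(self, fit_logistic(y, X))


class ExposureOddsResults:
    """Results of an :class:`ExposureOddsModel` fit."""

    def __init__(self, model: ExposureOddsModel, result: ModelResult):
        self.model = model
        self.result = result

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def odds_ratio(self) -> float:
        """OR for the target exposure term."""
        return float(np.exp(self.result.params[self.model.target]))

    @property
    def conf_int(self) -> tuple[float, float]:
        """Wald 95% CI for the target OR."""
        est = self.result.params[self.model.target]
        se = self.result.bse[self.model.target]
        return (float(np.exp(est - Z_95 * se)), float(np.exp(est + Z_95 * se)))

    @property
    def converged(self) -> bool:
        return self.result.converged

    @property
    def separation(self) -> bool:
        return self.result.separation

    @property
    def n_used(self) -> int:
        return self.result.n_used

    def or_table(self) -> pd.DataFrame:
        return self.result.or_table()

    def summary(self) -> str:
        lo, hi = self.conf_int
        head = (
            f"Exposure: {self.model.target} "
            f"(adjusted for {', '.join(self.model.co_chemicals) or 'no co-exposures'})\n"
            f"OR = {self.odds_ratio:.2f}; 95% CI = {lo:.2f}, {hi:.2f}\n"
        )
        return head + self.result.summary()


# ---------------------------------------------------------------------------
# confounder screening and co-exposure tables
# ---------------------------------------------------------------------------


def change_in_estimate_screen(
    persons: pd.DataFrame,
    flags: pd.DataFrame,
    target: str,
    core_covariates: tuple[str, ...],
    candidate_covariates: tuple[str, ...],
    co_chemicals: tuple[str, ...] = (),
    threshold: float = 0.10,
    contrast: str = "both_vs_neither",
    scale: str = "or",
) -> dict:
    """One-at-a-time change-in-estimate confounder screen.

    Each candidate is added alone to the core model; it is selected when
    the target OR moves by more than ``threshold`` (relative, on the OR
    scale by default or the log-OR scale with ``scale='log_or'``).
    Returns a dict with the selected candidates, per-candidate relative
    changes, and candidates whose refit failed to converge.
    """
    if set(core_covariates) & set(candidate_covariates):
        raise DesignError("candidates must be disjoint from core covariates")
    base = ExposureOddsModel.from_study(
        persons, flags, target, co_chemicals, core_covariates, contrast
    ).fit()
    base_or = base.odds_ratio
    changes: dict[str, float] = {}
    selected: list[str] = []
    unevaluable: list[str] = []
    for cand in candidate_covariates:
        res = ExposureOddsModel.from_study(
            persons, flags, target, co_chemicals,
            tuple(core_covariates) + (cand,), contrast,
        ).fit()
        if not res.converged:
            unevaluable.append(cand)
            continue
        if scale == "or":
            rel = abs(res.odds_ratio - base_or) / base_or
        else:
            rel = abs(np.log(res.odds_ratio) - np.log(base_or)) / abs(np.log(base_or))
        changes[cand] = float(rel)
        if rel > threshold:
            selected.append(cand)
    return {
        "base_or": float(base_or),
        "selected": selected,
        "changes": changes,
        "unevaluable": unevaluable,
    }


@dataclass(frozen=True)
class CoexposureTable:
    """Joint exposure pattern for a chemical pair within a stratum."""

    chemical_a: str
    chemical_b: str
    stratum: str
    n_both: int
    n_neither: int
    n_exactly_one: int

    @property
    def n_total(self) -> int:
        return self.n_both + self.n_neither + self.n_exactly_one

    @property
    def proportions(self) -> tuple[float, float, float]:
        n = self.n_total
        return (self.n_both / n, self.n_neither / n, self.n_exactly_one / n)

    def summary(self) -> str:
        pb, pn, po = self.proportions
        return (
            f"{self.chemical_a} x {self.chemical_b} ({self.stratum}, n={self.n_total}): "
            f"both {100 * pb:.1f}%, neither {100 * pn:.1f}%, "
            f"exactly one {100 * po:.1f}%"
        )


def coexposure_table(
    flags: pd.DataFrame,
    chemical_a: str,
    chemical_b: str,
    stratum_ids,
    stratum_name: str = "stratum",
    definition: str = "any",
) -> CoexposureTable:
    """Cross-tabulate exposure to two chemicals within a person stratum."""
    ids = pd.Index(stratum_ids)
    if len(ids) == 0:
        raise ValueError("empty stratum")
    ind = exposure_indicators(flags, [chemical_a, chemical_b], definition)
    ind = ind.loc[ind.index.intersection(ids)]
    if ind.empty:
        raise ValueError("stratum contains no persons with flags")
    a = ind[chemical_a].astype(bool)
    b = ind[chemical_b].astype(bool)
    return CoexposureTable(
        chemical_a,
        chemical_b,
        stratum_name,
        n_both=int((a & b).sum()),
        n_neither=int((~a & ~b).sum()),
        n_exactly_one=int((a ^ b).sum()),
    )
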