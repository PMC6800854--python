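"""Linear mixed models and language-model comparison.

The regression engine is a maximum-likelihood linear mixed model with
crossed random intercepts (subject, item, optionally list) and optional
per-group random slopes.  The marginal covariance is

``V = sigma^2 (I + sum_k theta_k Z_k Z_k')``

with one variance ratio ``theta_k >= 0`` per random-effect block.  Both
the fixed effects and the residual variance profile out in closed form,
so only the ratios are optimized — by bounded quasi-Newton (L-BFGS-B)
from fixed starting values, which makes fits deterministic.  All linear
algebra runs in the random-effect coefficient space via the Woodbury
identity, so fits stay fast even with hundreds of crossed levels.

Model comparison follows the deviance logic: every language model is
added as one fixed-effect predictor to a design-specific baseline, and
ranked by the decrease in ML deviance (equivalently AIC, with a
likelihood-ratio chi-square p-value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .surprisal import SurprisalVector


@dataclass
class RegressionSpec:
    """What to regress on what, with which random-effect structure."""

    dependent: str
    fixed_effects: list[str]
    random_intercepts: list[str]
    random_slopes: list[tuple[str, str]] = field(default_factory=list)
    predictor_of_interest: str | None = None


@dataclass
class FitResult:
    """ML fit summary; ``aic = deviance + 2 * n_params`` by construction."""

    log_likelihood: float
    deviance: float
    aic: float
    n_params: int
    coefficients: dict[str, tuple[float, float]]
    converged: bool
    n_obs: int
    variance_components: dict[str, float] = field(default_factory=dict)
    sigma2: float = math.nan


@dataclass
class ComparisonRow:
    model_name: str
    aic: float
    delta_deviance: float
    p_value: float


class LinearMixedModel:
    """ML linear mixed model built from a tidy data frame.

    Parameters
    ----------
    data
        One row per observation; must contain the dependent, all fixed
        covariates, and the grouping columns.
    spec
        The regression specification.  Continuous fixed effects are
        standardized (mean 0, SD 1) before fitting; the intercept is
        added automatically.
    """

    def __init__(self, data: pd.DataFrame, spec: RegressionSpec) -> None:
        cols = (
            [spec.dependent]
            + spec.fixed_effects
            + spec.random_intercepts
            + [f for f, _c in spec.random_slopes]
            + [c for _f, c in spec.random_slopes]
        )
        missing = [c for c in dict.fromkeys(cols) if c not in data.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing}")
        sub = data[list(dict.fromkeys(cols))].dropna()
        if sub.empty:
            raise ValueError("no complete rows to fit")
        self.spec = spec
        self.data = sub.reset_index(drop=True)
        self.n = len(self.data)

        y = self.data[spec.dependent].to_numpy(float)
        X = [np.ones(self.n)]
        names = ["(Intercept)"]
        for cname in spec.fixed_effects:
            v = self.data[cname].to_numpy(float)
            sd = v.std(ddof=0)
            v = (v - v.mean()) / sd if sd > 0 else v - v.mean()
            X.append(v)
            names.append(cname)
        self.y = y
        self.X = np.column_stack(X)
        self.fixed_names = names

        blocks: list[np.ndarray] = []
        block_names: list[str] = []
        for factor in spec.random_intercepts:
            levels = self.data[factor].astype("category")
            if levels.cat.categories.size < 2:
                raise ValueError(f"grouping factor {factor!r} has < 2 levels")
            Z = pd.get_dummies(levels).to_numpy(float)
            blocks.append(Z)
            block_names.append(f"{factor} (Intercept)")
        for factor, cov in spec.random_slopes:
            levels = self.data[factor].astype("category")
            Z = pd.get_dummies(levels).to_numpy(float)
            v = self.data[cov].to_numpy(float)
            blocks.append(Z * v[:, None])
            block_names.append(f"{factor} ({cov})")
        self.blocks = blocks
        self.block_names = block_names
        Zall = np.hstack(blocks) if blocks else np.zeros((self.n, 0))
        self._block_slices = []
        start = 0
        for Z in blocks:
            self._block_slices.append(slice(start, start + Z.shape[1]))
            start += Z.shape[1]
        self.q = Zall.shape[1]
        # sufficient statistics: everything below runs in q-space
        self._ZtZ = Zall.T @ Zall
        self._ZtX = Zall.T @ self.X
        self._Zty = Zall.T @ y
        self._XtX = self.X.T @ self.X
        self._Xty = self.X.T @ y
        self._yty = float(y @ y)

    # -- profiled ML criterion --------------------------------------------

    def _profile(self, theta: np.ndarray):
        n, p = self.n, self.X.shape[1]
        if self.q:
            d = np.concatenate([
                np.full(sl.stop - sl.start, math.sqrt(max(t, 0.0)))
                for sl, t in zip(self._block_slices, theta)
            ])
            A = np.eye(self.q) + d[:, None] * self._ZtZ * d[None, :]
            L = np.linalg.cholesky(A)
            logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            DZtX = d[:, None] * self._ZtX
            DZty = d * self._Zty
            u = np.linalg.solve(L, np.column_stack([DZtX, DZty]))
            uX, uy = u[:, :-1], u[:, -1]
            XtVX = self._XtX - uX.T @ uX
            XtVy = self._Xty - uX.T @ uy
            ytVy = self._yty - float(uy @ uy)
        else:
            logdet = 0.0
            XtVX, XtVy, ytVy = self._XtX, self._Xty, self._yty
        # pinv: collinear fixed effects (e.g. a duplicated covariate) must
        # fit with the same likelihood rather than fail
        beta = np.linalg.pinv(XtVX) @ XtVy
        rss = ytVy - float(beta @ XtVy)
        rss = max(rss, 1e-12)
        sigma2 = rss / n
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
        return ll, beta, sigma2, XtVX

    def _neg_ll(self, theta: np.ndarray) -> float:
        return -self._profile(theta)[0]

    def fit(self) -> FitResult:
        nb = len(self.blocks)
        converged = True
        if nb:
            res = optimize.minimize(
                self._neg_ll,
                x0=np.ones(nb),
                method="L-BFGS-B",
                bounds=[(0.0, 1e6)] * nb,
                options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
            )
            theta = res.x
            converged = bool(res.success)
        else:
            theta = np.zeros(0)
        ll, beta, sigma2, XtVX = self._profile(theta)
        cov_beta = sigma2 * np.linalg.pinv(XtVX)
        se = np.sqrt(np.diag(cov_beta))
        coefficients = {
            nm: (float(b), float(s))
            for nm, b, s in zip(self.fixed_names, beta, se)
        }
        n_params = len(beta) + nb + 1  # fixed + variance ratios + residual
        deviance = -2.0 * ll
        return FitResult(
            log_likelihood=float(ll),
            deviance=float(deviance),
            aic=float(deviance + 2 * n_params),
            n_params=n_params,
            coefficients=coefficients,
            converged=converged,
            n_obs=self.n,
            variance_components={
                nm: float(t * sigma2)
                for nm, t in zip(self.block_names, theta)
            },
            sigma2=float(sigma2),
        )


def summary(result: FitResult) -> str:
    """Plain-text summary table for a fit."""
    lines = [
        f"ML linear mixed model  (n = {result.n_obs}, "
        f"converged = {result.converged})",
        f"deviance = {result.deviance:.3f}   AIC = {result.aic:.3f}   "
        f"k = {result.n_params}",
        "",
        f"{'coefficient':<24}{'estimate':>12}{'SE':>12}",
    ]
    for nm, (b, s) in result.coefficients.items():
        lines.append(f"{nm:<24}{b:>12.4f}{s:>12.4f}")
    lines.append("")
    lines.append(f"{'variance component':<24}{'variance':>12}")
    for nm, v in result.variance_components.items():
        lines.append(f"{nm:<24}{v:>12.4f}")
    lines.append(f"{'residual':<24}{result.sigma2:>12.4f}")
    return "\n".join(lines)


def fit_lmm(spec: RegressionSpec, data: pd.DataFrame) -> FitResult:
    """Fit the mixed model described by *spec* on *data* (ML, not REML)."""
    return LinearMixedModel(data, spec).fit()


def compare_to_baseline(
    baseline: FitResult, augmented: FitResult, df: int = 1
) -> ComparisonRow:
    """Likelihood-ratio comparison of nested ML fits on the same rows."""
    if baseline.n_obs != augmented.n_obs:
        raise ValueError(
            f"fits use different rows ({baseline.n_obs} vs {augmented.n_obs}); "
            "apply a shared missing-data mask before fitting"
        )
    delta = baseline.deviance - augmented.deviance
    if delta < -1e-6:
        raise ValueError(
            "augmented deviance exceeds baseline: non-nested models or "
            "optimizer failure"
        )
    delta = max(delta, 0.0)
    p = float(stats.chi2.sf(delta, df)) if delta > 0 else 1.0
    name = augmented.coefficients and list(augmented.coefficients)[-1]
    return ComparisonRow(
        model_name=str(name), aic=augmented.aic,
        delta_deviance=float(delta), p_value=p,
    )


# ---------------------------------------------------------------------------
# design-specific analysis drivers
# ---------------------------------------------------------------------------

MEASURES = ("GD", "FFD", "GmF")


def baseline_spec(design: str, dependent: str) -> RegressionSpec:
    """Per-design baseline: controls and random-effect structure."""
    if design == "exp1":
        return RegressionSpec(
            dependent=dependent,
            fixed_effects=["presentation_order"],
            random_intercepts=["subject", "item"],
        )
    if design == "exp2":
        return RegressionSpec(
            dependent=dependent,
            fixed_effects=["presentation_order", "launch_site"],
            random_intercepts=["subject", "item", "list_id"],
            random_slopes=[("subject", "position_coded")],
        )
    raise ValueError(f"unknown design {design!r}")


def _analysis_frame(
    measures: pd.DataFrame,
    surprisals: Mapping[str, SurprisalVector],
) -> pd.DataFrame:
    data = measures.loc[~measures["excluded"]].copy()
    if "row_position" in data.columns and data["row_position"].notna().any():
        data["position_coded"] = np.where(
            data["row_position"] == 5, 0.5, -0.5
        )
    for name, vec in surprisals.items():
        mapped = data["item"].map(vec.values)
        missing = sorted(data.loc[mapped.isna(), "item"].unique())
        if missing:
            raise ValueError(
                f"model {name!r} has no surprisal for retained items: "
                f"{missing[:10]}"
            )
        data[name] = mapped
    return data


def _rank_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(r.model_name, r.aic, r.delta_deviance, r.p_value) for r in rows],
        columns=["model", "AIC", "delta_deviance", "p_value"],
    )
    return df.sort_values(
        "delta_deviance", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def run_model_ranking(
    measures: pd.DataFrame,
    surprisals: Mapping[str, SurprisalVector],
    design: str,
    dependents: Sequence[str] = MEASURES,
    extra_baseline: Sequence[str] = (),
) -> dict[str, pd.DataFrame]:
    """Rank language models by deviance decrease, per dependent measure.

    For each measure the baseline holds the design's control predictors
    (plus any *extra_baseline* columns) and the random effects; each
    candidate model adds its surprisal as one fixed effect.  Rows dropped
    for missing values (GmF) are dropped from that measure's baseline as
    well, never from the other measures.
    """
    data = _analysis_frame(measures, surprisals)
    out: dict[str, pd.DataFrame] = {}
    for dep in dependents:
        spec0 = baseline_spec(design, dep)
        spec0.fixed_effects += [
            c for c in extra_baseline if c not in spec0.fixed_effects
        ]
        # shared mask: complete rows for every compared predictor
        need = (
            [dep] + spec0.fixed_effects + list(surprisals)
            + spec0.random_intercepts
            + [c for _f, c in spec0.random_slopes]
        )
        rows_ok = data[need].notna().all(axis=1)
        sub = data.loc[rows_ok]
        base = fit_lmm(spec0, sub)
        comparisons = []
        for name in surprisals:
            if name in spec0.fixed_effects:
                continue
            spec1 = RegressionSpec(
                dependent=dep,
                fixed_effects=spec0.fixed_effects + [name],
                random_intercepts=spec0.random_intercepts,
                random_slopes=spec0.random_slopes,
                predictor_of_interest=name,
            )
            aug = fit_lmm(spec1, sub)
            row = compare_to_baseline(base, aug, df=1)
            row.model_name = name
            comparisons.append(row)
        out[dep] = _rank_frame(comparisons)
    return out


def joint_with_word_unigram(
    measures: pd.DataFrame,
    surprisals: Mapping[str, SurprisalVector],
    design: str,
    word_unigram_name: str = "word_unigram",
    dependents: Sequence[str] = MEASURES,
) -> dict[str, pd.DataFrame]:
    """Rankings with the word unigram model inside the baseline.

    Each model's deviance decrease then measures its improvement beyond
    surface frequency.
    """
    if word_unigram_name not in surprisals:
        raise ValueError(f"{word_unigram_name!r} not among surprisal vectors")
    return run_model_ranking(
        measures, surprisals, design,
        dependents=dependents, extra_baseline=[word_unigram_name],
    )


def correlations(
    measures: pd.DataFrame,
    predictors: pd.DataFrame,
    dependents: Sequence[str] = MEASURES,
) -> pd.DataFrame:
    """Item-level Pearson correlations with significance stars.

    Measures are first averaged over subjects per item; *predictors* is
    an item-indexed frame of covariates and model surprisals.  Constant
    columns yield missing correlations.
    """
    data = measures.loc[~measures["excluded"]]
    item_means = data.groupby("item")[list(dependents)].mean()
    joined = item_means.join(predictors, how="inner")
    rows = []
    for pred in predictors.columns:
        for dep in dependents:
            sub = joined[[pred, dep]].dropna()
            x, y = sub[pred].to_numpy(float), sub[dep].to_numpy(float)
            if len(sub) < 3 or np.std(x) == 0 or np.std(y) == 0:
                rows.append((pred, dep, math.nan, math.nan, ""))
                continue
            r, p = stats.pearsonr(x, y)
            stars = (
                "***" if p < 0.001 else "**" if p < 0.01
                else "*" if p < 0.05 else ""
            )
            rows.append((pred, dep, float(r), float(p), stars))
    return pd.DataFrame(
        rows, columns=["predictor", "measure", "r", "p", "stars"]
    )
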