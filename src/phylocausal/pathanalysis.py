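"""Phylogenetic path analysis: claim tests, Fisher's C, CICc, and averaging.

Each candidate causal DAG is scored by testing its d-separation basis set
with a phylogenetic regression: for a claim ``x _||_ y | S`` the response
``y`` is regressed on ``x`` and ``S`` under the phylogenetic correlation and
the p-value of ``x``'s coefficient is recorded. The claim p-values combine
into Fisher's ``C = -2 sum(ln p)`` (chi-square with 2k df under the model),
which is penalized for complexity by ``CICc = C + 2 q n / (n - 1 - q)``.
Models are ranked by CICc; those within 2 of the best with non-significant
C are retained, and their standardized path coefficients are conditionally
averaged with CICc weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dags import CausalDAG, IndependenceClaim, basis_set
from .regression import (
    FitError,
    RegressionFit,
    pgls_fit,
    phylo_logistic_claim_test,
    phylo_logistic_fit,
    standardize_paths,
)

# p-values are floored before logs so that C stays finite
P_FLOOR = 1e-300

ENGINES = ("logistic", "gls")


@dataclass(frozen=True)
class ClaimTest:
    claim: IndependenceClaim
    coefficient: float
    p_value: float


@dataclass
class PathModelResult:
    model_id: str
    dag: CausalDAG
    claim_tests: list
    n: int

    @property
    def k(self) -> int:
        return len(self.claim_tests)

    @property
    def q(self) -> int:
        return self.dag.q()

    @property
    def C(self) -> float:
        return fisher_c([t.p_value for t in self.claim_tests])

    @property
    def model_p(self) -> float:
        return model_p_value(self.C, self.k)

    @property
    def CICc(self) -> float:
        return cicc(self.C, self.q, self.n)


@dataclass(frozen=True)
class AveragedPath:
    source: str
    target: str
    estimate: float
    lower95: float
    upper95: float
    contributing_models: tuple
    weights: tuple


@dataclass
class AveragedModel:
    paths: list
    mode: str
    model_ids: tuple

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "models": list(self.model_ids),
            "paths": [
                {
                    "from": p.source,
                    "to": p.target,
                    "estimate": p.estimate,
                    "lower95": p.lower95,
                    "upper95": p.upper95,
                    "models": list(p.contributing_models),
                    "weights": list(p.weights),
                }
                for p in self.paths
            ],
        }


def _fit(y, X, corr, engine: str) -> RegressionFit:
    if engine == "logistic":
        return phylo_logistic_fit(y, X, corr)
    if engine == "gls":
        return pgls_fit(y, X, corr)
    raise ValueError(f"unknown engine {engine!r}; expected one of {ENGINES}")


def _design(traits: pd.DataFrame, predictors) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": np.ones(len(traits))}, index=traits.index)
    for p in predictors:
        X[p] = traits[p].to_numpy(dtype=float)
    return X


def test_claim(
    claim: IndependenceClaim,
    traits: pd.DataFrame,
    corr: np.ndarray,
    engine: str = "logistic",
) -> ClaimTest:
    """Test one independence claim; returns the coefficient and p-value of x."""
    for v in (claim.x, claim.y, *claim.conditioning_set):
        if v not in traits.columns:
            raise KeyError(f"claim variable {v!r} not in trait matrix")
    predictors = [claim.x] + sorted(claim.conditioning_set)
    X = _design(traits, predictors)
    y = traits[claim.y].to_numpy(dtype=float)
    if engine == "logistic":
        # score-type one-step test: stable even when the claim is strongly
        # violated and the full model separates
        fit = phylo_logistic_claim_test(y, X, corr, test_col=claim.x)
    else:
        fit = _fit(y, X, corr, engine)
    if not fit.converged:
        raise FitError(f"claim test did not converge: {claim}")
    p = max(float(fit.p_value(claim.x)), P_FLOOR)
    return ClaimTest(claim=claim, coefficient=fit.coef(claim.x), p_value=p)


def fisher_c(p_values) -> float:
    """Fisher's statistic ``C = -2 sum(ln p)`` over claim p-values."""
    ps = np.asarray(list(p_values), dtype=float)
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(-2.0 * np.sum(np.log(ps)))


def model_p_value(C: float, k: int) -> float:
    """Upper-tail chi-square probability of C with 2k degrees of freedom."""
    if C < 0:
        raise ValueError("C must be non-negative")
    if k < 1:
        raise ValueError("k must be at least 1")
    return float(stats.chi2.sf(C, 2 * k))


def cicc(C: float, q: int, n: int) -> float:
    """Small-sample information criterion ``C + 2 q n / (n - 1 - q)``."""
    if n <= q + 1:
        raise ValueError(f"n = {n} must exceed q + 1 = {q + 1}")
    return float(C + 2.0 * q * n / (n - 1.0 - q))


def fit_path_model(
    dag: CausalDAG,
    traits: pd.DataFrame,
    corr: np.ndarray,
    engine: str = "logistic",
    claim_cache: dict | None = None,
) -> PathModelResult:
    """Test all of a DAG's independence claims against the data.

    ``claim_cache`` (keyed by claim) lets identical claims shared between
    models be tested once across a model set.
    """
    tests = []
    for claim in basis_set(dag):
        if claim_cache is not None and claim in claim_cache:
            tests.append(claim_cache[claim])
            continue
        try:
            t = test_claim(claim, traits, corr, engine)
        except FitError as exc:
            raise FitError(f"model {dag.model_id!r}: {exc}") from exc
        if claim_cache is not None:
            claim_cache[claim] = t
        tests.append(t)
    return PathModelResult(model_id=dag.model_id, dag=dag,
                           claim_tests=tests, n=len(traits))


def compare_models(results) -> pd.DataFrame:
    """Rank fitted path models by CICc.

    Returns a frame with columns model, CICc, delta_CICc, rel_likelihood,
    weight, k, q, C, p sorted ascending by CICc (ties broken by fewer
    parameters, then model id); weights normalize exp(-delta/2) over all rows.
    """
    results = list(results)
    if not results:
        raise ValueError("no fitted models to compare")
    ns = {r.n for r in results}
    if len(ns) > 1:
        raise ValueError(f"models were fitted on different sample sizes: {sorted(ns)}")
    rows = [
        {
            "model": r.model_id,
            "CICc": r.CICc,
            "k": r.k,
            "q": r.q,
            "C": r.C,
            "p": r.model_p,
        }
        for r in results
    ]
    df = pd.DataFrame(rows).sort_values(
        ["CICc", "q", "model"], kind="mergesort"
    ).reset_index(drop=True)
    df["delta_CICc"] = df["CICc"] - df["CICc"].iloc[0]
    df["rel_likelihood"] = np.exp(-df["delta_CICc"] / 2.0)
    df["weight"] = df["rel_likelihood"] / df["rel_likelihood"].sum()
    return df[["model", "CICc", "delta_CICc", "rel_likelihood", "weight",
               "k", "q", "C", "p"]]


def select_top_models(
    table: pd.DataFrame,
    delta_threshold: float = 2.0,
    alpha: float = 0.05,
) -> list:
    """Models within ``delta_threshold`` of the best whose C is non-significant."""
    if table.empty:
        raise ValueError("empty comparison table")
    keep = table[(table["delta_CICc"] <= delta_threshold) & (table["p"] >= alpha)]
    if keep.empty:
        raise ValueError(
            "no model passes the CICc and p-value cuts; inspect the "
            "comparison table — every candidate is rejected by its claims"
        )
    return list(keep["model"])


def path_coefficients(
    dag: CausalDAG,
    traits: pd.DataFrame,
    corr: np.ndarray,
    engine: str = "logistic",
) -> list:
    """Standardized coefficients of every directed edge in ``dag``.

    Each child is regressed on all of its parents jointly; coefficients are
    standardized by predictor standard deviations.
    """
    coeffs = []
    children = sorted({e for _, e in dag.edges})
    for child in children:
        parents = sorted(dag.parents(child))
        X = _design(traits, parents)
        y = traits[child].to_numpy(dtype=float)
        fit = _fit(y, X, corr, engine)
        coeffs.extend(standardize_paths(fit, traits, target=child))
    return coeffs


def average_paths(
    fits: dict,
    weights: dict,
    mode: str = "conditional",
) -> AveragedModel:
    """CICc-weighted average of standardized path coefficients.

    ``fits`` maps model_id -> list of :class:`PathCoefficient`; ``weights``
    maps model_id -> CICc weight (renormalized internally). In the default
    conditional mode each path is averaged only over the models that contain
    it, with weights renormalized within that subset, so paths unique to one
    model pass through unchanged. In full mode absent paths count as zero.
    Interval bounds are averaged with the same weights as the estimates.
    """
    if mode not in ("conditional", "full"):
        raise ValueError("mode must be 'conditional' or 'full'")
    ids = list(fits)
    total = sum(weights[m] for m in ids)
    if total <= 0:
        raise ValueError("weights must sum to a positive value")
    w = {m: weights[m] / total for m in ids}

    keys: list = []
    for m in ids:
        for pc in fits[m]:
            key = (pc.source, pc.target)
            if key not in keys:
                keys.append(key)
    paths = []
    for source, target in keys:
        members = {
            m: pc for m in ids for pc in fits[m]
            if (pc.source, pc.target) == (source, target)
        }
        if mode == "conditional":
            wsum = sum(w[m] for m in members)
            ws = {m: w[m] / wsum for m in members}
            est = sum(ws[m] * members[m].estimate for m in members)
            lo = sum(ws[m] * members[m].lower95 for m in members)
            hi = sum(ws[m] * members[m].upper95 for m in members)
            used = tuple(members)
            used_w = tuple(ws[m] for m in members)
        else:
            est = sum(w[m] * members[m].estimate for m in members)
            lo = sum(w[m] * members[m].lower95 for m in members)
            hi = sum(w[m] * members[m].upper95 for m in members)
            used = tuple(ids)
            used_w = tuple(w[m] for m in ids)
        paths.append(AveragedPath(
            source=source, target=target, estimate=float(est),
            lower95=float(lo), upper95=float(hi),
            contributing_models=used, weights=used_w,
        ))
    return AveragedModel(paths=paths, mode=mode, model_ids=tuple(ids))


def run_path_analysis(
    traits: pd.DataFrame,
    corr: np.ndarray,
    models: dict,
    engine: str = "logistic",
    delta_threshold: float = 2.0,
    alpha: float = 0.05,
    average_mode: str = "conditional",
):
    """Fit a model set, rank it, and conditionally average the top models.

    Returns ``(table, averaged, results)``; ``averaged`` is None when no
    model passes the selection cuts.
    """
    cache: dict = {}
    results = [
        fit_path_model(dag, traits, corr, engine=engine, claim_cache=cache)
        for dag in models.values()
    ]
    table = compare_models(results)
    try:
        top = select_top_models(table, delta_threshold, alpha)
    except ValueError:
        return table, None, results
    weights = dict(zip(table["model"], table["weight"]))
    fits = {
        mid: path_coefficients(models[mid], traits, corr, engine=engine)
        for mid in top
    }
    averaged = average_paths(fits, {m: weights[m] for m in top}, mode=average_mode)
    return table, averaged, results
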