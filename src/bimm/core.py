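"""The iterative binary mixed-model (BiMM) forest algorithm.

BiMM alternates two fits on the training table until the mixed model's
posterior log-likelihood stabilises:

1. fit a classification forest on the current working outcome;
2. take its fitted class-1 probabilities as the single fixed effect of a
   Bayesian logistic random-intercept model (one intercept per person);
3. extract the mixed model's fitted probabilities Q_it and its posterior
   log-likelihood;
4. if the absolute change in posterior log-likelihood since the previous
   iteration falls below the tolerance, stop; otherwise update the working
   outcome to h(Y_it + Q_it) via the chosen split function and repeat.

The returned model predicts with the final forest alone — a
population-level rule, since random effects of unseen persons are zero by
definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cohort import OUTCOME_COL, PERSON_COL, covariate_columns, validate_cohort
from .exceptions import BimmError
from .mixed_model import P_CLAMP, MixedModelFit, fit_mixed
from .split_functions import SplitFunctionSpec, apply_spec


@dataclass(frozen=True)
class RFParams:
    """Forest configuration shared by plain RF and the forest inside BiMM.

    ``majority_class_weight`` is the training weight on the majority
    outcome class with the minority class fixed at 1 — e.g. 0.37 gives the
    minority class 1/0.37 ~ 2.7 times more influence. ``None`` weights the
    classes equally.
    """

    n_trees: int = 500
    majority_class_weight: float | None = None
    max_features: str | int | float = "sqrt"
    min_samples_leaf: int = 1
    #: feed the mixed model out-of-bag probabilities (the forest's honest
    #: fitted values); in-bag probabilities are nearly 0/1 on training rows,
    #: which makes the mixed model's q collapse onto y and the outcome
    #: update a no-op
    use_oob_probabilities: bool = True

    def class_weight(self, y: np.ndarray) -> dict | None:
        if self.majority_class_weight is None:
            return None
        ones = float(np.mean(y))
        majority = 1 if ones > 0.5 else 0
        return {majority: self.majority_class_weight, 1 - majority: 1.0}

    def fit_forest(self, x: np.ndarray, y: np.ndarray, seed: int) -> RandomForestClassifier:
        """Build and fit a forest; rows without OOB votes are handled by the
        in-bag fallback in :meth:`fitted_probabilities`, so sklearn's OOB
        coverage warning is suppressed."""
        forest = self.build(y, seed)
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message=".*do not have OOB scores.*"
            )
            return forest.fit(x, y)

    def build(self, y: np.ndarray, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            class_weight=self.class_weight(y),
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            oob_score=self.use_oob_probabilities,
            random_state=seed,
            n_jobs=1,
        )

    def fitted_probabilities(self, forest: RandomForestClassifier, x: np.ndarray) -> np.ndarray:
        """Training-row class-1 probabilities fed to the mixed model.

        Out-of-bag by default; rows that were in-bag for every tree (rare
        with enough trees) fall back to the in-bag probability.
        """
        in_bag = forest.predict_proba(x)[:, 1]
        if not self.use_oob_probabilities:
            return in_bag
        oob = forest.oob_decision_function_[:, 1]
        return np.where(np.isnan(oob), in_bag, oob)


@dataclass
class BiMMModel:
    """A trained BiMM: the final forest plus the iteration trajectory.

    ``trajectory`` is a DataFrame with one row per iteration — columns
    ``iteration``, ``posterior_log_likelihood``, ``n_outcome_flips`` (the
    number of working-outcome labels changed by the update performed at the
    end of that iteration; 0 for the final one).
    """

    final_forest: RandomForestClassifier
    split_spec: SplitFunctionSpec | None
    n_iterations: int
    trajectory: pd.DataFrame
    tolerance: float
    rf_params: RFParams
    feature_names: list[str]
    mixed_fit: MixedModelFit | None
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def importances(self) -> pd.Series:
        """Mean Decrease Gini score per covariate, descending."""
        s = pd.Series(self.final_forest.feature_importances_, index=self.feature_names)
        return s.sort_values(ascending=False, kind="stable")


def update_outcome(
    y,
    q,
    spec: SplitFunctionSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Elementwise split-function update ``h(y + q)``.

    ``q`` must lie strictly in (0, 1); h3 consumes draws from ``rng``.
    """
    y = np.asarray(y)
    q = np.asarray(q, dtype=float)
    if y.shape != q.shape:
        raise BimmError("y and q must have equal lengths")
    if np.any(q <= 0.0) or np.any(q >= 1.0):
        raise BimmError("q must lie strictly in (0, 1)")
    return np.asarray(apply_spec(y, q, spec, rng))


def fit_bimm(
    train: pd.DataFrame,
    spec: SplitFunctionSpec,
    rf_params: RFParams | None = None,
    tolerance: float = 0.5,
    max_iter: int = 50,
    seed: int = 0,
) -> BiMMModel:
    """Run the iterative BiMM algorithm on a training cohort.

    The forest is refit with the same ``random_state`` each iteration, and
    the h3 random stream is seeded from ``seed``, so identical inputs give
    identical trajectories and predictions. Stops when the absolute change
    in posterior log-likelihood drops below ``tolerance`` (checked from the
    second iteration onward), when the updated outcome would collapse to a
    single class (the previous iteration's model is returned, flagged), or
    at ``max_iter`` (flagged as unconverged).
    """
    validate_cohort(train, require_pairs=False)
    if tolerance <= 0:
        raise BimmError("tolerance must be positive")
    if max_iter < 1:
        raise BimmError("max_iter must be at least 1")
    rf_params = rf_params or RFParams()
    features = covariate_columns(train)
    x = train[features].to_numpy(dtype=float)
    person_ids = train[PERSON_COL].to_numpy()
    y_work = train[OUTCOME_COL].to_numpy(dtype=int).copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))

    rows = []
    prev_pll: float | None = None
    forest = None
    mixed = None
    converged = False
    collapsed = False
    for iteration in range(1, max_iter + 1):
        new_forest = rf_params.fit_forest(x, y_work, seed)
        p = np.clip(
            rf_params.fitted_probabilities(new_forest, x), P_CLAMP, 1.0 - P_CLAMP
        )
        new_mixed = fit_mixed(y_work, p, person_ids)
        forest, mixed = new_forest, new_mixed
        pll = mixed.posterior_log_likelihood
        rows.append(
            {
                "iteration": iteration,
                "posterior_log_likelihood": pll,
                "n_outcome_flips": 0,
            }
        )
        if prev_pll is not None and abs(pll - prev_pll) < tolerance:
            converged = True
            break
        prev_pll = pll
        if iteration == max_iter:
            break
        y_new = update_outcome(y_work, mixed.fitted_q, spec, rng)
        n_flips = int(np.sum(y_new != y_work))
        rows[-1]["n_outcome_flips"] = n_flips
        if len(np.unique(y_new)) < 2:
            collapsed = True
            break
        y_work = y_new

    trajectory = pd.DataFrame(rows)
    return BiMMModel(
        final_forest=forest,
        split_spec=spec,
        n_iterations=len(rows),
        trajectory=trajectory,
        tolerance=tolerance,
        rf_params=rf_params,
        feature_names=features,
        mixed_fit=mixed,
        diagnostics={
            "converged": converged,
            "outcome_collapsed": collapsed,
            "max_iter_reached": not converged and not collapsed,
            "seed": seed,
        },
    )


def predict_bimm(model: BiMMModel, data: pd.DataFrame) -> np.ndarray:
    """Class-1 probabilities from the final forest for new rows.

    ``data`` may be a cohort table or a bare covariate frame; either way
    its covariate columns must match the training schema. Predictions are
    population-level: unseen persons' random effects are zero.
    """
    cols = [c for c in data.columns if c in model.feature_names]
    if cols != model.feature_names:
        missing = set(model.feature_names) - set(data.columns)
        raise BimmError(f"covariate schema mismatch; missing/misordered: {sorted(missing)}")
    x = data[model.feature_names].to_numpy(dtype=float)
    return model.final_forest.predict_proba(x)[:, 1]


def fit_plain_rf(
    train: pd.DataFrame, rf_params: RFParams | None = None, seed: int = 0
) -> BiMMModel:
    """A standard random forest on the original outcome, wrapped in the
    same container as a BiMM for uniform evaluation (single iteration, no
    mixed model refits beyond the one used for the trajectory record)."""
    rf_params = rf_params or RFParams()
    validate_cohort(train, require_pairs=False)
    features = covariate_columns(train)
    x = train[features].to_numpy(dtype=float)
    y = train[OUTCOME_COL].to_numpy(dtype=int)
    forest = rf_params.fit_forest(x, y, seed)
    return BiMMModel(
        final_forest=forest,
        split_spec=None,
        n_iterations=1,
        trajectory=pd.DataFrame(
            [{"iteration": 1, "posterior_log_likelihood": np.nan, "n_outcome_flips": 0}]
        ),
        tolerance=np.inf,
        rf_params=rf_params,
        feature_names=features,
        mixed_fit=None,
        diagnostics={"converged": True, "plain_rf": True, "seed": seed},
    )
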