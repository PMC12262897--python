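"""Split functions h1, h2, h3 and the threshold-constant grid search.

A split function maps ``s = Y + Q`` — the original binary outcome plus the
mixed-model probability — back to {0, 1}, producing the updated working
outcome for the next forest fit:

* ``h1(s) = 0 if s <= k1 else 1`` with ``k1 in (0, 1)``. Since ``s >= 1``
  whenever ``Y = 1``, h1 can flip a 0 to a 1 but never a 1 to a 0; it is the
  sensitivity-maximising update.
* ``h2(s) = 0 if s < k2 else 1`` with ``k2 in (1, 2)``. Since ``s < 1``
  whenever ``Y = 0``, h2 can flip a 1 to a 0 but never a 0 to a 1; it is the
  specificity-preserving update.
* ``h3`` combines both with fixed constants k1 = 0.5 and k2 = 1.5: outside
  (0.5, 1.5) it is deterministic; inside, it returns 1 with probability Q.

The grid search mirrors the published protocol: k1 is varied from 0.05 to
0.95 and k2 from 1.05 to 1.95 in steps of 0.05 on one fixed train/eval
split, and the (function, constant) pair with the highest evaluation AUC
wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import BimmError

SplitKind = Literal["h1", "h2", "h3"]

# Fixed constants inside h3.
H3_K1 = 0.5
H3_K2 = 1.5


@dataclass(frozen=True)
class SplitFunctionSpec:
    """Which split function to use, and its free threshold constant.

    h1 requires ``k1`` in (0, 1); h2 requires ``k2`` in (1, 2); h3 has no
    free constants (its thresholds are fixed at 0.5 and 1.5).
    """

    kind: SplitKind
    k1: float | None = None
    k2: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "h1":
            if self.k1 is None or not 0.0 < self.k1 < 1.0:
                raise BimmError(f"h1 requires k1 in (0, 1); got {self.k1}")
        elif self.kind == "h2":
            if self.k2 is None or not 1.0 < self.k2 < 2.0:
                raise BimmError(f"h2 requires k2 in (1, 2); got {self.k2}")
        elif self.kind == "h3":
            if self.k1 is not None or self.k2 is not None:
                raise BimmError("h3 takes no free constants")
        else:
            raise BimmError(f"unknown split function kind {self.kind!r}")

    @property
    def constant(self) -> float | None:
        """The free constant, if any (for traces and reports)."""
        return self.k1 if self.kind == "h1" else self.k2 if self.kind == "h2" else None


def _check_k1(k1: float) -> None:
    if not 0.0 < k1 < 1.0:
        raise BimmError(f"k1 must lie in (0, 1); got {k1}")


def _check_k2(k2: float) -> None:
    if not 1.0 < k2 < 2.0:
        raise BimmError(f"k2 must lie in (1, 2); got {k2}")


def apply_h1(s, k1: float):
    """h1: 0 where ``s <= k1``, 1 where ``s > k1``.

    Accepts a scalar or array ``s`` in [0, 2]; returns int or int array.
    """
    _check_k1(k1)
    out = np.where(np.asarray(s) <= k1, 0, 1)
    return int(out) if np.isscalar(s) else out


def apply_h2(s, k2: float):
    """h2: 0 where ``s < k2``, 1 where ``s >= k2``."""
    _check_k2(k2)
    out = np.where(np.asarray(s) < k2, 0, 1)
    return int(out) if np.isscalar(s) else out


def apply_h3(y, q, rng: np.random.Generator):
    """h3 on ``s = y + q``: deterministic outside (0.5, 1.5), Bernoulli(q) inside.

    The measure-zero boundaries s = 0.5 and s = 1.5 are assigned to the
    stochastic branch. ``rng`` supplies the Bernoulli draws; scalar and
    array inputs are supported.
    """
    y_arr = np.asarray(y)
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr <= 0.0) or np.any(q_arr >= 1.0):
        raise BimmError("q must lie strictly in (0, 1)")
    s = y_arr + q_arr
    draws = rng.random(size=s.shape) < q_arr
    out = np.where(s < H3_K1, 0, np.where(s > H3_K2, 1, draws.astype(int)))
    return int(out) if np.isscalar(y) else out


def apply_spec(y, q, spec: SplitFunctionSpec, rng: np.random.Generator | None = None):
    """Dispatch ``h(y + q)`` elementwise according to ``spec``."""
    if spec.kind == "h1":
        return apply_h1(np.asarray(y) + np.asarray(q), spec.k1)
    if spec.kind == "h2":
        return apply_h2(np.asarray(y) + np.asarray(q), spec.k2)
    if rng is None:
        raise BimmError("h3 requires a random generator")
    return apply_h3(y, q, rng)


def default_k1_grid() -> np.ndarray:
    """k1 candidates 0.05, 0.10, ..., 0.95 (19 values)."""
    return np.round(np.arange(1, 20) * 0.05, 2)


def default_k2_grid() -> np.ndarray:
    """k2 candidates 1.05, 1.10, ..., 1.95 (19 values)."""
    return np.round(1.0 + np.arange(1, 20) * 0.05, 2)


def candidate_specs(
    k1_grid=None, k2_grid=None, include_h3: bool = True
) -> list[SplitFunctionSpec]:
    """Enumerate candidates in tie-break order: h1, then h2, then h3;
    smaller constants first."""
    k1_grid = default_k1_grid() if k1_grid is None else np.asarray(k1_grid, dtype=float)
    k2_grid = default_k2_grid() if k2_grid is None else np.asarray(k2_grid, dtype=float)
    specs = [SplitFunctionSpec("h1", k1=float(k)) for k in np.sort(k1_grid)]
    specs += [SplitFunctionSpec("h2", k2=float(k)) for k in np.sort(k2_grid)]
    if include_h3:
        specs.append(SplitFunctionSpec("h3"))
    if not specs:
        raise BimmError("no split-function candidates to search over")
    return specs


def grid_search_split(
    train: pd.DataFrame,
    eval_set: pd.DataFrame,
    rf_params=None,
    k1_grid=None,
    k2_grid=None,
    include_h3: bool = True,
    tolerance: float = 0.5,
    max_iter: int = 50,
    seed: int = 0,
    eval_is_final_test: bool = False,
) -> tuple[SplitFunctionSpec, float, pd.DataFrame]:
    """Select the split function and constant maximising evaluation AUC.

    Fits a full BiMM per candidate on the fixed ``train`` table, scores the
    fixed ``eval_set``, and returns ``(best_spec, best_auc, trace)`` where
    ``trace`` has columns kind, constant, auc — one row per candidate, in
    evaluation order. Ties go to the earlier candidate (h1 before h2 before
    h3, smaller constant first).

    Selecting on the final test set leaks that set into model choice; pass
    ``eval_is_final_test=True`` to acknowledge it explicitly (a warning is
    emitted), or carve a validation split from the training persons with
    :func:`bimm.evaluation.partition_by_individual`.
    """
    from .core import fit_bimm, predict_bimm  # deferred: core imports this module
    from .evaluation import compute_auc

    if eval_is_final_test:
        warnings.warn(
            "grid search is selecting on the final test set; the resulting "
            "AUC is optimistically biased",
            stacklevel=2,
        )
    specs = candidate_specs(k1_grid, k2_grid, include_h3)
    y_eval = eval_set["outcome"].to_numpy()
    rows = []
    best_spec, best_auc = None, -np.inf
    for spec in specs:
        model = fit_bimm(
            train, spec, rf_params=rf_params, tolerance=tolerance,
            max_iter=max_iter, seed=seed,
        )
        auc = compute_auc(y_eval, predict_bimm(model, eval_set))
        rows.append({"kind": spec.kind, "constant": spec.constant, "auc": auc})
        if auc > best_auc:
            best_spec, best_auc = spec, auc
    return best_spec, float(best_auc), pd.DataFrame(rows)
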