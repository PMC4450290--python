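"""Stepwise discriminant analysis (SDA) for texture feature selection.

Classic forward stepping with backward elimination on the partial-F test
of Wilks' lambda.  Wilks' lambda of a feature subset S is

    Λ(S) = det(W_S) / det(T_S)

with W the pooled within-class scatter and T the total scatter restricted
to S.  The partial lambda of adding feature j to S is Λ(S∪{j})/Λ(S) and
its F statistic (n samples, g classes, p = |S| already selected) is

    F = ((n − g − p) / (g − 1)) · (1 − Λ_p) / Λ_p .

Each step adds the candidate with the largest partial F exceeding
``f_enter``, then removes any selected feature whose partial F (against
the rest of the selection) falls below ``f_remove``; it stops when neither
action applies or ``max_features`` is reached.  Entirely deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SDAResult", "sda_select"]

F_ENTER_DEFAULT = 3.84
F_REMOVE_DEFAULT = 2.71
MAX_FEATURES_DEFAULT = 20


@dataclass
class SDAResult:
    """Outcome of a stepwise discriminant selection."""

    selected: list[int] = field(default_factory=list)       # indices in entry order
    lambda_trace: list[float] = field(default_factory=list)  # Λ after each entry
    f_entry: list[float] = field(default_factory=list)       # partial F at each entry
    steps: list[str] = field(default_factory=list)           # "enter i" / "remove i"


def _scatter_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-class scatter W and total scatter T."""
    mean = X.mean(axis=0)
    Xc = X - mean
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for c in np.unique(y):
        Xk = X[y == c]
        Xkc = Xk - Xk.mean(axis=0)
        W += Xkc.T @ Xkc
    return W, T


def _wilks(W: np.ndarray, T: np.ndarray, idx: list[int]) -> float:
    if not idx:
        return 1.0
    sub = np.ix_(idx, idx)
    sign_w, logdet_w = np.linalg.slogdet(W[sub])
    sign_t, logdet_t = np.linalg.slogdet(T[sub])
    if sign_w <= 0 or sign_t <= 0:
        return np.nan  # singular scatter: caller skips the feature
    return float(np.exp(logdet_w - logdet_t))


def sda_select(X: np.ndarray, y: np.ndarray,
               f_enter: float = F_ENTER_DEFAULT,
               f_remove: float = F_REMOVE_DEFAULT,
               max_features: int = MAX_FEATURES_DEFAULT) -> SDAResult:
    """Select a discriminative feature subset by stepwise Wilks'-lambda F tests.

    Requires at least two classes with at least two samples each and
    ``f_enter > f_remove`` (otherwise stepping could cycle).  Features
    whose addition makes the within-class scatter singular are skipped
    with a warning rather than silently regularized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    if not f_enter > f_remove:
        raise ValueError("f_enter must exceed f_remove")

    n, m = X.shape
    g = len(classes)
    W, T = _scatter_matrices(X, y)
    res = SDAResult()
    selected: list[int] = []
    lam_cur = 1.0
    warned: set[int] = set()

    def partial_f(lam_new: float, lam_old: float, p: int) -> float:
        if not np.isfinite(lam_new) or lam_new <= 0:
            return np.nan
        lam_p = lam_new / lam_old
        dof = n - g - p
        if dof <= 0:
            return np.nan
        return (dof / (g - 1)) * (1.0 - lam_p) / lam_p

    while len(selected) < max_features:
        # --- forward step ---
        best_j, best_f, best_lam = -1, -np.inf, np.nan
        for j in range(m):
            if j in selected:
                continue
            lam_new = _wilks(W, T, selected + [j])
            f = partial_f(lam_new, lam_cur, len(selected))
            if np.isnan(f):
                if j not in warned:
                    warnings.warn(f"feature {j}: singular scatter, skipped", stacklevel=2)
                    warned.add(j)
                continue
            if f > best_f:
                best_j, best_f, best_lam = j, f, lam_new
        if best_j < 0 or best_f <= f_enter:
            break
        selected.append(best_j)
        lam_cur = best_lam
        res.steps.append(f"enter {best_j}")
        res.f_entry.append(best_f)
        res.lambda_trace.append(lam_cur)

        # --- backward step(s): drop features whose partial F fell below f_remove ---
        changed = True
        while changed and len(selected) > 1:
            changed = False
            for j in list(selected):
                rest = [k for k in selected if k != j]
                lam_rest = _wilks(W, T, rest)
                f = partial_f(lam_cur, lam_rest, len(rest))
                if np.isfinite(f) and f < f_remove:
                    selected.remove(j)
                    lam_cur = lam_rest
                    res.steps.append(f"remove {j}")
                    changed = True
                    break

    res.selected = selected
    return res
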