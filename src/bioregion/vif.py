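"""Iterative variance-inflation-factor pruning of collinear variables.

``VIF_j = 1 / (1 - R²_j)`` where ``R²_j`` comes from the least-squares
regression of variable *j* on all the remaining variables plus an intercept.
The pruning loop drops the single worst variable per iteration until every
surviving variable has a VIF below the threshold (default 5), recording the
full trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["INFINITE_VIF", "VifReport", "vif_scores", "iterative_vif_prune"]

# Sentinel for an exactly (or numerically) collinear variable; infinite VIFs
# always outrank finite ones in the removal choice.
INFINITE_VIF = 1e12


@dataclass
class VifReport:
    """Trace of an iterative VIF-pruning run."""

    iterations: list[tuple[str | None, dict[str, float]]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    threshold: float = 5.0

    @property
    def removed(self) -> list[str]:
        return [name for name, _ in self.iterations if name is not None]

    @property
    def final_vifs(self) -> dict[str, float]:
        return self.iterations[-1][1] if self.iterations else {}

    def to_frame(self):
        """Long-format trace: (iteration, removed, variable, vif)."""
        import pandas as pd

        rows = []
        for i, (removed, vifs) in enumerate(self.iterations):
            for var, v in vifs.items():
                rows.append({"iteration": i, "removed": removed or "", "variable": var, "vif": v})
        return pd.DataFrame(rows)


def _as_matrix(table, variable_codes=None):
    if hasattr(table, "matrix"):  # PixelTable
        return np.asarray(table.matrix, dtype=float), list(table.variable_codes)
    X = np.asarray(table, dtype=float)
    codes = list(variable_codes) if variable_codes is not None else [f"v{j}" for j in range(X.shape[1])]
    return X, codes


def vif_scores(
    table,
    variable_codes: list[str] | None = None,
    *,
    max_rows: int | None = 200_000,
    seed: int | None = 0,
) -> dict[str, float]:
    """VIF of every column of an observations × variables matrix.

    Exactly collinear variables are flagged with the :data:`INFINITE_VIF`
    sentinel rather than raising; a constant column is an error (its VIF is
    undefined).  Scores are invariant to affine rescaling of any column.
    Tables longer than ``max_rows`` are scored on a seeded uniform row
    subsample (the statistic is already stable at that size).
    """
    X, codes = _as_matrix(table, variable_codes)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 variables for VIF")
    if n < p + 1:
        raise ValueError(f"need at least p+1={p + 1} observations, got {n}")
    if max_rows is not None and n > max_rows:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(n, size=max_rows, replace=False)]
        n = max_rows

    sd = X.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"constant column {codes[j]!r} has undefined VIF")

    # Work on standardized columns: then R²_j is computable from the
    # correlation structure and the regression is well-conditioned.
    Z = (X - X.mean(axis=0)) / sd
    out: dict[str, float] = {}
    for j in range(p):
        others = np.delete(Z, j, axis=1)
        y = Z[:, j]
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(y @ y)  # centred already
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            out[codes[j]] = INFINITE_VIF
        else:
            out[codes[j]] = min(1.0 / (1.0 - r2), INFINITE_VIF)
    return out


def iterative_vif_prune(
    table,
    threshold: float = 5.0,
    variable_codes: list[str] | None = None,
    *,
    max_rows: int | None = 200_000,
    seed: int | None = 0,
) -> VifReport:
    """Drop the max-VIF variable per iteration until all VIFs < threshold.

    Ties at the maximum are broken toward the variable that comes later in
    the input order, so the trace is deterministic.  Removing all variables
    (possible only on pathological input) is an error.
    """
    X, codes = _as_matrix(table, variable_codes)
    report = VifReport(threshold=float(threshold))
    keep = list(range(len(codes)))
    while True:
        if len(keep) < 2:
            raise ValueError("pruning would remove all but one variable")
        sub_codes = [codes[j] for j in keep]
        vifs = vif_scores(X[:, keep], sub_codes, max_rows=max_rows, seed=seed)
        worst = None
        worst_v = -np.inf
        for name in sub_codes:  # later-in-order wins ties via >=
            if vifs[name] >= worst_v:
                worst, worst_v = name, vifs[name]
        if worst_v < threshold:
            report.iterations.append((None, vifs))
            report.retained = sub_codes
            return report
        report.iterations.append((worst, vifs))
        keep.remove(codes.index(worst))
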