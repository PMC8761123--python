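"""Endemic-taxon checklists, indicator value analysis and endemism density.

A checklist records, per taxon, a presence flag for every analysis unit
(environmental cluster or subcluster).  From it the module builds binary
occurrence matrices, floristic dendrograms, Dufrêne–Legendre indicator
values with a permutation null, richness summaries, and the species–area
machinery: the Arrhenius power law E = c·A^z fitted by log-log least
squares, and the per-unit endemism-density α-index defined as observed
over area-expected endemic richness, α = E / (c·A^z).  By the residual
property of ordinary least squares on logs, the geometric mean of α over
the fitted units is exactly 1.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress

__all__ = [
    "Checklist",
    "ArrheniusFit",
    "load_checklist",
    "build_occurrence_matrix",
    "occurrence_distance",
    "indval",
    "richness_summary",
    "arrhenius_fit",
    "alpha_index",
    "area_richness_r2",
]

_META_COLUMNS = ("taxon", "family", "genus", "rank")
_UNIT_PREFIX = "unit:"


@dataclass
class Checklist:
    """Harmonized endemic-taxon records with per-unit presence flags."""

    table: pd.DataFrame  # index: taxon; columns: family, genus, rank, unit:<id>...

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("taxon names must be unique after harmonization")

    @property
    def units(self) -> list[str]:
        return [c[len(_UNIT_PREFIX):] for c in self.table.columns if c.startswith(_UNIT_PREFIX)]

    @property
    def n_taxa(self) -> int:
        return len(self.table)

    def presence(self) -> pd.DataFrame:
        """Taxa × units 0/1 frame."""
        cols = [c for c in self.table.columns if c.startswith(_UNIT_PREFIX)]
        out = self.table[cols].astype(int).clip(0, 1)
        out.columns = [c[len(_UNIT_PREFIX):] for c in cols]
        return out


def load_checklist(path: str) -> Checklist:
    """Load a checklist CSV/XLSX (columns: taxon,family,genus,rank,unit:<id>…).

    Duplicate taxon names are collapsed with a warning, presence being the
    union of the duplicates' flags.
    """
    if str(path).lower().endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]
    if df.empty:
        raise ValueError(f"checklist {path!r} is empty")
    if "taxon" not in df.columns:
        raise ValueError(f"checklist {path!r} lacks the mandatory 'taxon' column")
    unit_cols = [c for c in df.columns if c.startswith(_UNIT_PREFIX)]
    if not unit_cols:
        raise ValueError(f"checklist {path!r} has no 'unit:<id>' presence columns")
    for c in _META_COLUMNS[1:]:
        if c not in df.columns:
            df[c] = ""
    df["taxon"] = df["taxon"].astype(str).str.strip()
    df[unit_cols] = df[unit_cols].fillna(0).astype(int).clip(0, 1)

    if df["taxon"].duplicated().any():
        dups = sorted(df.loc[df["taxon"].duplicated(), "taxon"].unique())
        warnings.warn(f"collapsing duplicate taxon record(s): {dups}", stacklevel=2)
        agg = {c: "first" for c in _META_COLUMNS[1:]}
        agg.update({c: "max" for c in unit_cols})
        df = df.groupby("taxon", as_index=False, sort=False).agg(agg)
    df = df.set_index("taxon")
    return Checklist(df[[*(c for c in _META_COLUMNS[1:]), *unit_cols]])


def build_occurrence_matrix(checklist: Checklist, drop_empty_units: bool = True) -> pd.DataFrame:
    """Units × taxa binary matrix from a checklist.

    Taxa present nowhere are dropped with a warning; units hosting no taxon
    are excluded by default (flagged option), mirroring the treatment of
    endemic-free desert units in regional studies.
    """
    P = checklist.presence()  # taxa × units
    empty_taxa = P.index[P.sum(axis=1) == 0].tolist()
    if empty_taxa:
        warnings.warn(f"dropping {len(empty_taxa)} taxon/taxa with no presences", stacklevel=2)
        P = P.drop(index=empty_taxa)
    M = P.T  # units × taxa
    if drop_empty_units:
        empty_units = M.index[M.sum(axis=1) == 0].tolist()
        if empty_units:
            warnings.warn(f"excluding unit(s) with no endemic taxa: {empty_units}", stacklevel=2)
            M = M.drop(index=empty_units)
    return M.astype(int)


def occurrence_distance(matrix: pd.DataFrame, metric: str = "euclidean") -> pd.DataFrame:
    """Distance matrix between units from their binary occurrence rows."""
    if metric not in ("euclidean", "jaccard"):
        raise ValueError(f"unsupported metric {metric!r}")
    X = matrix.to_numpy(dtype=float)
    D = squareform(pdist(X, metric=metric))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


def _indval_components(X: np.ndarray, G: np.ndarray):
    """A (specificity), B (fidelity) and IndVal = 100·A·B.

    X: units × taxa binary; G: classes × units membership (0/1).
    """
    class_sizes = G.sum(axis=1, keepdims=True)  # classes × 1
    mean_pres = (G @ X) / class_sizes  # classes × taxa
    denom = mean_pres.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, mean_pres / denom, 0.0)
    B = (G @ (X > 0)) / class_sizes
    return A, B, 100.0 * A * B


@dataclass
class IndvalResult:
    """Per-taxon indicator values, best class and permutation p-values."""

    table: pd.DataFrame  # index taxon; indval:<class> columns, best_class, indval, p_value
    classes: list[str]
    n_perm: int
    seed: int | None
    method: str = "permutation"

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_value"] < alpha]


def indval(
    matrix: pd.DataFrame,
    classes: dict | pd.Series | None = None,
    n_perm: int = 1000,
    seed: int | None = 0,
    method: str = "permutation",
) -> IndvalResult:
    """Dufrêne–Legendre indicator value analysis with a permutation null.

    ``classes`` maps each unit to a class label; by default every unit is
    its own class (the degenerate one-unit-per-class design, statistically
    weak but supported).  The observed statistic per taxon is its maximum
    IndVal over classes; the null permutes the unit→class assignment.
    ``method="permutation"`` draws ``n_perm`` seeded random permutations
    and reports p = (1 + #{null ≥ observed}) / (1 + n_perm), never zero;
    ``method="exact"`` enumerates all distinct label arrangements and
    reports the exact fraction with null ≥ observed (identity included).
    Taxa absent from every unit are excluded with a warning.
    """
    if method not in ("permutation", "exact"):
        raise ValueError(f"unknown method {method!r}")
    units = list(matrix.index)
    if classes is None:
        classes = {u: str(u) for u in units}
    elif isinstance(classes, pd.Series):
        classes = classes.to_dict()
    labels = [str(classes[u]) for u in units]
    class_names = sorted(set(labels))
    if len(class_names) < 2:
        raise ValueError("indval needs at least 2 classes")

    X = matrix.to_numpy(dtype=float)
    absent = matrix.columns[(X.sum(axis=0) == 0)].tolist()
    if absent:
        warnings.warn(f"excluding {len(absent)} taxon/taxa absent everywhere", stacklevel=2)
        matrix = matrix.drop(columns=absent)
        X = matrix.to_numpy(dtype=float)

    lab_idx = np.array([class_names.index(l) for l in labels])
    n_classes, n_units = len(class_names), len(units)

    def membership(perm_idx: np.ndarray) -> np.ndarray:
        G = np.zeros((n_classes, n_units))
        G[perm_idx, np.arange(n_units)] = 1.0
        return G

    A, B, IV = _indval_components(X, membership(lab_idx))
    observed = IV.max(axis=0)  # per taxon
    best = IV.argmax(axis=0)

    if method == "exact":
        perms = {p for p in itertools.permutations(lab_idx.tolist())}
        null_ge = np.zeros_like(observed)
        for p in perms:
            _, _, IVp = _indval_components(X, membership(np.array(p)))
            null_ge += IVp.max(axis=0) >= observed - 1e-12
        p_values = null_ge / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros_like(observed)
        for _ in range(n_perm):
            _, _, IVp = _indval_components(X, membership(rng.permutation(lab_idx)))
            count += IVp.max(axis=0) >= observed - 1e-12
        p_values = (1.0 + count) / (1.0 + n_perm)
        n_used = n_perm

    out = pd.DataFrame(index=matrix.columns)
    for j, name in enumerate(class_names):
        out[f"indval:{name}"] = IV[j]
    out["best_class"] = [class_names[b] for b in best]
    out["indval"] = observed
    out["p_value"] = p_values
    return IndvalResult(table=out, classes=class_names, n_perm=n_used, seed=seed, method=method)


def richness_summary(matrix: pd.DataFrame, checklist: Checklist | None = None) -> pd.DataFrame:
    """Per-unit totals, exclusive-taxon counts and per-family totals.

    An *exclusive* taxon is present in exactly one unit; family columns
    (``family:<name>``) appear when a checklist provides family labels.
    """
    totals = matrix.sum(axis=1)
    exclusive_mask = matrix.sum(axis=0) == 1
    exclusives = matrix.loc[:, exclusive_mask].sum(axis=1)
    out = pd.DataFrame({"total_taxa": totals.astype(int), "exclusive_taxa": exclusives.astype(int)})
    if checklist is not None:
        fam = checklist.table["family"].reindex(matrix.columns).fillna("")
        for family in sorted(f for f in fam.unique() if f):
            taxa = fam.index[fam == family]
            out[f"family:{family}"] = matrix[taxa].sum(axis=1).astype(int)
    return out


@dataclass
class ArrheniusFit:
    """Power-law species–area fit E = c·A^z on log-log scale."""

    c: float
    z: float
    r2_loglog: float
    n_units: int

    def expected(self, area) -> np.ndarray:
        return self.c * np.asarray(area, dtype=float) ** self.z


def _units_frame(units) -> pd.DataFrame:
    if isinstance(units, pd.DataFrame):
        df = units.copy()
    else:
        df = pd.DataFrame(units, columns=["area_km2", "endemics"])
    if "area_km2" not in df.columns or "endemics" not in df.columns:
        raise ValueError("units need 'area_km2' and 'endemics' columns")
    return df


def arrhenius_fit(units) -> ArrheniusFit:
    """Least squares of ln E on ln A over units with E > 0 and A > 0."""
    df = _units_frame(units)
    usable = df[(df["endemics"] > 0) & (df["area_km2"] > 0)]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 units with positive area and endemics, got {len(usable)}")
    lx = np.log(usable["area_km2"].to_numpy(dtype=float))
    ly = np.log(usable["endemics"].to_numpy(dtype=float))
    fit = linregress(lx, ly)
    return ArrheniusFit(c=float(math.exp(fit.intercept)), z=float(fit.slope), r2_loglog=float(fit.rvalue**2), n_units=len(usable))


def alpha_index(fit: ArrheniusFit, units) -> pd.DataFrame:
    """Per-unit endemism density α = E / (c·A^z).

    α > 1 marks units richer than their area predicts.  Units with zero
    endemics get α = NaN (undefined) but are still listed.
    """
    df = _units_frame(units)
    expected = fit.expected(df["area_km2"])
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(df["endemics"] > 0, df["endemics"] / expected, np.nan)
    out = df.copy()
    out["expected_endemics"] = expected
    out["alpha"] = alpha
    return out


def area_richness_r2(units) -> float:
    """R² of the linear (untransformed) regression of endemics on area."""
    df = _units_frame(units)
    if len(df) < 3:
        raise ValueError("need >= 3 units")
    fit = linregress(df["area_km2"].to_numpy(dtype=float), df["endemics"].to_numpy(dtype=float))
    return float(fit.rvalue**2)
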