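"""Growth-curve phenotyping.

Optical-density trajectories become an area-under-the-curve (AUC) phenotype:
each strain x condition cell is the replicate-mean AUC, either the analytic
integral of a fitted logistic model N(t) = K / (1 + ((K-N0)/N0) e^{-rt}) or,
when the fit does not converge, the trapezoidal integral of the raw readings.
The matrix is z-scored per condition column, strains are grouped by
hierarchical clustering (average linkage, Euclidean), and per-condition
lineage differences are tested by one-way ANOVA with compact-letter grouping
from Holm-corrected pairwise Welch tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy

from .simulate import logistic_curve


@dataclass
class GrowthCurve:
    strain: str
    condition: str
    times: np.ndarray  # hours
    od: np.ndarray
    replicate: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have the same length")


@dataclass
class GrowthModelFit:
    strain: str
    condition: str
    replicate: int
    K: float
    r: float
    N0: float
    auc_fit: float  # OD*hours over the observation window
    auc_empirical: float
    converged: bool

    @property
    def auc(self) -> float:
        """Logistic AUC when converged, empirical otherwise."""
        return self.auc_fit if self.converged else self.auc_empirical


@dataclass
class PhenotypeMatrix:
    values: pd.DataFrame  # strains x conditions
    lineages: dict[str, str]
    normalized: bool = False
    provenance: pd.DataFrame | None = None  # fraction of converged fits per cell


def auc_empirical(curve: GrowthCurve) -> float:
    """Trapezoidal integral of OD over the observed time grid."""
    if len(curve.times) < 2:
        raise ValueError("need at least 2 points")
    if not np.all(np.diff(curve.times) > 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(curve.od, curve.times))


def _logistic_auc(K: float, r: float, N0: float, t0: float, t1: float) -> float:
    """Closed-form integral of the logistic curve over [t0, t1].

    Antiderivative (K/r) ln(A + e^{rt}) with A = (K-N0)/N0, evaluated in a
    log1p form that stays finite for large rt.
    """
    A = (K - N0) / N0

    def F(t: float) -> float:
        return (K / r) * (r * t + np.log1p(A * np.exp(-r * t)))

    return float(F(t1) - F(t0))


def fit_logistic(curve: GrowthCurve) -> GrowthModelFit:
    """Least-squares logistic fit; falls back to the empirical AUC on failure."""
    if len(curve.times) < 10:
        raise ValueError("need at least 10 time points")
    emp = auc_empirical(curve)
    od = curve.od
    if np.max(od) <= np.min(od) or od[-1] < od[0]:  # flat or shrinking culture
        return GrowthModelFit(curve.strain, curve.condition, curve.replicate,
                              float("nan"), float("nan"), float("nan"),
                              emp, emp, converged=False)
    K0 = float(np.max(od))
    N00 = float(max(od[0], 1e-6))
    try:
        popt, _ = optimize.curve_fit(
            logistic_curve, curve.times, od,
            p0=[K0, 0.5, N00],
            bounds=([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
        K, r, N0 = (float(v) for v in popt)
    except (RuntimeError, ValueError):
        return GrowthModelFit(curve.strain, curve.condition, curve.replicate,
                              float("nan"), float("nan"), float("nan"),
                              emp, emp, converged=False)
    auc_f = _logistic_auc(K, r, N0, float(curve.times[0]), float(curve.times[-1]))
    return GrowthModelFit(curve.strain, curve.condition, curve.replicate,
                          K, r, N0, auc_f, emp, converged=True)


def curves_from_long_table(df: pd.DataFrame) -> list[GrowthCurve]:
    """GrowthCurve objects from a long table (strain, condition, replicate, time_h, od)."""
    curves = []
    for (strain, cond, rep), grp in df.groupby(
        ["strain", "condition", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        curves.append(GrowthCurve(str(strain), str(cond),
                                  grp["time_h"].to_numpy(), grp["od"].to_numpy(), int(rep)))
    return curves


def build_matrix(
    fits: list[GrowthModelFit],
    lineages: dict[str, str] | None = None,
    allow_missing: bool = False,
) -> PhenotypeMatrix:
    """Strains x conditions matrix of replicate-mean AUC."""
    if not fits:
        raise ValueError("no fits supplied")
    df = pd.DataFrame(
        {
            "strain": [f.strain for f in fits],
            "condition": [f.condition for f in fits],
            "auc": [f.auc for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    matrix = df.pivot_table(index="strain", columns="condition", values="auc", aggfunc="mean")
    provenance = df.pivot_table(
        index="strain", columns="condition", values="converged", aggfunc="mean"
    )
    if matrix.isna().any().any() and not allow_missing:
        gaps = [
            f"{s}/{c}" for s in matrix.index for c in matrix.columns
            if pd.isna(matrix.loc[s, c])
        ]
        raise ValueError(f"missing strain x condition cells: {', '.join(gaps)}")
    return PhenotypeMatrix(matrix, lineages or {}, normalized=False, provenance=provenance)


def zscore_columns(matrix: PhenotypeMatrix) -> PhenotypeMatrix:
    """Column-wise (x - mean) / sd; a zero-variance condition is an error."""
    df = matrix.values
    sd = df.std(axis=0, ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance condition(s): {', '.join(map(str, zero))}")
    z = (df - df.mean(axis=0)) / sd
    return PhenotypeMatrix(z, matrix.lineages, normalized=True, provenance=matrix.provenance)


def _linkage_to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _linkage_to_newick(node.get_left(), labels)
    right = _linkage_to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster(
    matrix: PhenotypeMatrix, linkage: str = "average", metric: str = "euclidean"
) -> tuple[str, list[str]]:
    """Hierarchical clustering of strains -> (Newick string, leaf order).

    Rows are sorted by strain id before linkage so equal-distance merges
    break ties deterministically.
    """
    df = matrix.values.sort_index()
    if len(df) < 2:
        raise ValueError("need at least 2 strains")
    Z = hierarchy.linkage(df.to_numpy(), method=linkage, metric=metric)
    tree = hierarchy.to_tree(Z)
    labels = list(df.index)
    newick = _linkage_to_newick(tree, labels) + ";"
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return newick, order


def _compact_letters(names: list[str], significant: set[tuple[str, str]]) -> dict[str, str]:
    """Greedy compact-letter display over mean-ordered groups.

    From each group, extend a run of consecutively non-significant groups;
    maximal runs each receive a letter, so groups sharing a letter are not
    significantly different.
    """
    runs: list[set[str]] = []
    for i in range(len(names)):
        clique = [names[i]]
        for k in range(i + 1, len(names)):
            if all(tuple(sorted((names[k], m))) not in significant for m in clique):
                clique.append(names[k])
            else:
                break
        runs.append(set(clique))
    maximal: list[set[str]] = []
    for run in runs:
        if not any(run <= other for other in maximal):
            maximal.append(run)
    letters: dict[str, str] = {name: "" for name in names}
    for idx, grp in enumerate(maximal):
        letter = chr(ord("a") + idx)
        for name in names:
            if name in grp:
                letters[name] += letter
    return letters


def anova_by_condition(
    matrix: PhenotypeMatrix | pd.DataFrame,
    groups: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA per condition plus compact grouping letters.

    groups maps strain -> group label. F = MS_between / MS_within with the
    p-value from the F distribution; letters come from Holm-corrected pairwise
    Welch t-tests at the given alpha. Every group needs >= 2 observations.
    """
    df = matrix.values if isinstance(matrix, PhenotypeMatrix) else matrix
    rows = []
    for condition in df.columns:
        series = df[condition]
        by_group: dict[str, np.ndarray] = {}
        for strain, value in series.items():
            label = groups.get(str(strain))
            if label is None:
                raise ValueError(f"strain {strain!r} has no group label")
            by_group.setdefault(label, []).append(float(value))
        if len(by_group) < 2:
            raise ValueError("need at least 2 groups")
        for label, vals in by_group.items():
            if len(vals) < 2:
                raise ValueError(f"group {label!r} has fewer than 2 observations")
        arrays = {k: np.asarray(v) for k, v in by_group.items()}
        if all(np.allclose(v, next(iter(arrays.values()))[0]) for v in arrays.values()) and len(
            {v[0] for v in arrays.values()}
        ) == 1:
            F, p = 0.0, 1.0
        else:
            F, p = stats.f_oneway(*arrays.values())
            F, p = float(F), float(p)
            if np.isnan(F):  # zero within- and between-group variance
                F, p = 0.0, 1.0
        names = sorted(arrays, key=lambda g: -np.mean(arrays[g]))
        pairs = list(combinations(sorted(arrays), 2))
        pvals = []
        for a, b in pairs:
            va, vb = arrays[a], arrays[b]
            if np.var(va) == 0 and np.var(vb) == 0:
                pw = 1.0 if np.mean(va) == np.mean(vb) else 0.0
            else:
                pw = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
            pvals.append(pw)
        if pairs:
            from statsmodels.stats.multitest import multipletests

            reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
        else:
            reject = []
        significant = {
            tuple(sorted(pair)) for pair, rej in zip(pairs, reject) if rej
        }
        letters = _compact_letters(names, significant)
        rows.append(
            {
                "condition": condition,
                "F": F,
                "p_value": p,
                **{f"letter_{g}": letters[g] for g in sorted(letters)},
            }
        )
    return pd.DataFrame(rows)
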