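"""Feature triage: test–retest reproducibility (Lin's concordance),
mutual redundancy (Spearman), and tumor-volume dependency.

A feature is robust when it is reproducible (LCC >= 0.7), survives
redundancy pruning (no retained pair with rho >= 0.9 and P < 0.001), and is
not volume-coupled (Spearman rho vs volume <= 0.9 or nonsignificant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.optimize import curve_fit

LCC_THRESHOLD = 0.7
RHO_THRESHOLD = 0.9
P_THRESHOLD = 0.001


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    2 cov(x,y) / (var x + var y + (mean x - mean y)^2), population (1/n)
    moments. Undefined (ValueError) when both vectors are constant.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        raise ValueError("LCC undefined: both vectors constant")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def test_retest_screen(
    day1: pd.DataFrame, day2: pd.DataFrame, threshold: float = LCC_THRESHOLD
) -> pd.DataFrame:
    """Per-feature LCC across paired acquisitions.

    Rows must be paired by subject id; returns a frame with ``lcc`` and
    ``lcc_pass`` per feature (constant-in-both features get NaN / fail).
    """
    d1 = day1.copy()
    d2 = day2.copy()
    if isinstance(d1.index, pd.MultiIndex):
        d1.index = d1.index.get_level_values("subject_id")
    if isinstance(d2.index, pd.MultiIndex):
        d2.index = d2.index.get_level_values("subject_id")
    if set(d1.index) != set(d2.index):
        raise ValueError("day-1 and day-2 tables are not paired by subject")
    if list(d1.columns) != list(d2.columns):
        raise ValueError("feature columns differ between days")
    d2 = d2.loc[d1.index]
    rows = {}
    for col in d1.columns:
        try:
            c = lin_ccc(d1[col].to_numpy(), d2[col].to_numpy())
        except ValueError:
            c = np.nan
        rows[col] = c
    out = pd.DataFrame({"lcc": pd.Series(rows)})
    out["lcc_pass"] = out["lcc"] >= threshold
    out.index.name = "feature"
    return out


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and P matrices across features (columns).

    Constant features yield NaN rho for their pairs.
    """
    if len(table) < 5:
        raise ValueError("need at least 5 scans for cross-correlation")
    with np.errstate(invalid="ignore", divide="ignore"):
        rho, p = stats.spearmanr(table.to_numpy(), axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the 2-feature case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    cols = table.columns
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def prune_correlated(
    rho: pd.DataFrame,
    pmat: pd.DataFrame,
    lcc: pd.Series,
    rho_threshold: float = RHO_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> list[str]:
    """Greedy redundancy pruning.

    Among every pair with rho >= threshold and P < threshold, drop the
    member with the lower test–retest LCC (ties drop the later one in
    column order) until no retained pair is highly correlated.
    """
    features = list(rho.columns)
    r = rho.to_numpy()
    p = pmat.to_numpy()
    dropped: set[str] = set()
    for i, fi in enumerate(features):
        for j in range(i + 1, len(features)):
            fj = features[j]
            rij = abs(r[i, j])
            if np.isnan(rij) or rij < rho_threshold or p[i, j] >= p_threshold:
                continue
            li = lcc.get(fi, -np.inf)
            lj = lcc.get(fj, -np.inf)
            li = -np.inf if np.isnan(li) else li
            lj = -np.inf if np.isnan(lj) else lj
            # the lower-LCC member of each offending pair goes; ties drop
            # the later one in column order
            dropped.add(fi if li < lj else fj)
    return [f for f in features if f not in dropped]


def cluster_correlations(
    rho: pd.DataFrame, cut_distance: float = 0.5
) -> tuple[pd.Series, list[str]]:
    """Average-linkage clustering on distance 1 - |rho|.

    Returns cluster ids per feature and the dendrogram leaf order.
    """
    d = 1.0 - np.abs(rho.to_numpy())
    np.fill_diagonal(d, 0.0)
    d = np.nan_to_num(d, nan=1.0)
    d = (d + d.T) / 2.0
    condensed = d[np.triu_indices_from(d, k=1)]
    link = hierarchy.linkage(condensed, method="average")
    ids = hierarchy.fcluster(link, t=cut_distance, criterion="distance")
    leaves = hierarchy.leaves_list(link)
    cols = list(rho.columns)
    return (
        pd.Series(ids, index=cols, name="cluster_id"),
        [cols[i] for i in leaves],
    )


# ---------------------------------------------------- volume dependency

_FORMS = {
    "linear": (lambda v, a, b: a + b * v, False),
    "log": (lambda v, a, b: a + b * np.log(v), True),
    "power": (lambda v, a, b: a * v**b, True),
    "exponential": (lambda v, a, b: a * np.exp(b * v), False),
}


def _fit_form(name, volumes, feature):
    func, needs_pos = _FORMS[name]
    if needs_pos and np.any(volumes <= 0):
        return None
    try:
        if name == "linear":
            b, a = np.polyfit(volumes, feature, 1)
        elif name == "log":
            b, a = np.polyfit(np.log(volumes), feature, 1)
        elif name == "power":
            if np.any(feature <= 0):
                p0 = (1.0, 1.0)
            else:
                lb, la = np.polyfit(np.log(volumes), np.log(feature), 1)
                p0 = (np.exp(la), lb)
            (a, b), _ = curve_fit(func, volumes, feature, p0=p0, maxfev=5000)
        else:  # exponential
            if np.any(feature <= 0):
                p0 = (1.0, 0.0)
            else:
                lb, la = np.polyfit(volumes, np.log(feature), 1)
                p0 = (np.exp(la), lb)
            (a, b), _ = curve_fit(func, volumes, feature, p0=p0, maxfev=5000)
    except (RuntimeError, np.linalg.LinAlgError):
        return None
    resid = feature - func(volumes, a, b)
    return (float(a), float(b), float((resid**2).sum()))


def _aic_bic(rss: float, n: int, k: int) -> tuple[float, float]:
    # Gaussian log-likelihood; k = fitted parameters + 1 for the noise scale
    rss = max(rss, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    return 2 * k - 2 * ll, k * np.log(n) - 2 * ll


@dataclass
class VolumeDependency:
    rho: float
    p_value: float
    flagged: bool
    best_model: str | None
    coefficients: tuple[float, float] | None
    aic: float
    bic: float
    aic_bic_disagree: bool


def volume_dependency(
    feature, volumes, rho_threshold: float = RHO_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> VolumeDependency:
    """Volume coupling of one feature.

    Flagging is decided on the raw Spearman correlation against tumor
    volume; the best of four candidate functional forms (linear, log,
    power, exponential) is chosen by minimum AIC (BIC disagreement is
    reported, not acted on).
    """
    f = np.asarray(feature, float)
    v = np.asarray(volumes, float)
    if f.size != v.size or f.size < 8:
        raise ValueError("need >= 8 paired observations")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    rho, p = stats.spearmanr(f, v)
    flagged = bool(abs(rho) > rho_threshold and p < p_threshold)
    fits = {}
    for name in _FORMS:
        res = _fit_form(name, v, f)
        if res is not None:
            fits[name] = res
    if not fits:
        return VolumeDependency(float(rho), float(p), flagged, None, None,
                                np.nan, np.nan, False)
    scores = {
        name: _aic_bic(rss, f.size, 3)  # 2 coefficients + noise scale
        for name, (_, _, rss) in fits.items()
    }
    best_aic = min(scores, key=lambda n: scores[n][0])
    best_bic = min(scores, key=lambda n: scores[n][1])
    a, b, _ = fits[best_aic]
    return VolumeDependency(
        rho=float(rho),
        p_value=float(p),
        flagged=flagged,
        best_model=best_aic,
        coefficients=(a, b),
        aic=scores[best_aic][0],
        bic=scores[best_aic][1],
        aic_bic_disagree=best_aic != best_bic,
    )


def volume_screen(table: pd.DataFrame, volumes: pd.Series) -> pd.DataFrame:
    """Volume dependency of every feature column against tumor volume."""
    rows = []
    v = volumes.loc[table.index.get_level_values("subject_id")
                    if isinstance(table.index, pd.MultiIndex) else table.index]
    for col in table.columns:
        f = table[col].to_numpy()
        if np.all(f == f[0]):
            rows.append({"feature": col, "volume_rho": np.nan,
                         "volume_p": np.nan, "volume_flagged": False,
                         "best_volume_model": None, "aic": np.nan, "bic": np.nan})
            continue
        dep = volume_dependency(f, v.to_numpy())
        rows.append({
            "feature": col, "volume_rho": dep.rho, "volume_p": dep.p_value,
            "volume_flagged": dep.flagged, "best_volume_model": dep.best_model,
            "aic": dep.aic, "bic": dep.bic,
        })
    return pd.DataFrame(rows).set_index("feature")


@dataclass
class RobustnessReport:
    """Per-feature outcome of the three screens plus the robust set."""

    table: pd.DataFrame  # lcc, lcc_pass, cluster_id, redundancy_dropped, ...
    robust_features: list[str]

    @property
    def counts(self) -> dict[str, int]:
        t = self.table
        return {
            "n_screened": len(t),
            "n_reproducible": int(t["lcc_pass"].sum()),
            "n_after_redundancy": int((~t["redundancy_dropped"]).sum()),
            "n_volume_flagged": int(t["volume_flagged"].sum()),
            "n_robust": len(self.robust_features),
            "n_clusters": int(t["cluster_id"].max()) if len(t) else 0,
        }


def run_robustness_screen(
    day1: pd.DataFrame,
    day2: pd.DataFrame,
    features: pd.DataFrame,
    volumes: pd.Series,
    lcc_threshold: float = LCC_THRESHOLD,
    rho_threshold: float = RHO_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    cut_distance: float = 0.5,
) -> RobustnessReport:
    """LCC -> redundancy -> volume screen over a feature table.

    ``day1``/``day2`` are the paired test–retest tables, ``features`` the
    cohort table the redundancy and volume screens operate on.
    """
    tr = test_retest_screen(day1, day2, lcc_threshold)
    rho, pmat = spearman_matrix(features)
    retained = set(
        prune_correlated(rho, pmat, tr["lcc"], rho_threshold, p_threshold)
    )
    clusters, _ = cluster_correlations(rho, cut_distance)
    vol = volume_screen(features, volumes)

    t = tr.join(vol, how="left")
    t["cluster_id"] = clusters
    t["redundancy_dropped"] = [f not in retained for f in t.index]
    t["robust"] = t["lcc_pass"] & ~t["redundancy_dropped"] & ~t["volume_flagged"]
    return RobustnessReport(
        table=t, robust_features=[f for f in t.index if t.loc[f, "robust"]]
    )
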