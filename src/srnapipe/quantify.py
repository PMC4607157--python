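"""Count matrices, median-of-ratios normalization, and dispersion-mean fits.

Feature-level counts for a known miRNA sum its exact and shorter-longer
isomiR tags; reads matching the hairpin with 1-2 substitutions are kept at
the isomiR level but excluded from the miRNA's expression total. Library
normalization is the median-of-ratios size-factor estimator; the
negative-binomial dispersion-mean relationship is estimated per feature by
method of moments and smoothed with either a parametric (a0 + a1/q) or a
local-regression fit, the better fit (smaller residual sum of squares) being
selected for inference.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .annotate import Catalogue

MIN_DISPERSION = 1e-8
LOCAL_SPAN = 0.7

# categories counted toward a known miRNA's expression total
COUNTED_CATEGORIES = ("exact", "shorter_longer")


def feature_counts(catalogue: Catalogue, tag_counts: pd.DataFrame) -> pd.DataFrame:
    """Features x samples integer counts with the mismatch-exclusion rule.

    Known-miRNA totals sum only exact + shorter-longer member tags; cluster
    features (new miRNAs, moRNAs) sum all member tags.
    """
    counted: dict[str, set[str]] = {}
    for rec in catalogue.isomirs:
        if rec.category in COUNTED_CATEGORIES:
            counted.setdefault(rec.mature_id, set()).add(rec.tag)
    rows = {}
    for feat in catalogue.features:
        if feat.klass == "known_miRNA":
            tags = sorted(counted.get(feat.feature_id, set()))
        else:
            tags = feat.tags
        present = [t for t in tags if t in tag_counts.index]
        if present:
            rows[feat.feature_id] = tag_counts.loc[present].sum(axis=0)
        else:
            rows[feat.feature_id] = pd.Series(0, index=tag_counts.columns)
    out = pd.DataFrame(rows).T.astype(np.int64)
    out.index.name = "feature_id"
    return out.loc[sorted(out.index)]


def isomir_counts(catalogue: Catalogue, tag_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-isomiR counts with mature/category/region metadata columns."""
    rows = []
    for rec in catalogue.isomirs:
        if rec.tag not in tag_counts.index:
            continue
        row = {
            "isomir_id": f"{rec.mature_id}|{rec.category}|{rec.delta5:+d}|{rec.delta3:+d}|{rec.tag}",
            "mature_id": rec.mature_id,
            "category": rec.category,
            "region": rec.region,
            "sequence": rec.tag,
        }
        row.update(tag_counts.loc[rec.tag].to_dict())
        rows.append(row)
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows).set_index("isomir_id")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over features i (with positive counts in every sample) of
    k_ij / geometric-mean_i. Deterministic and invariant to feature order.
    """
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    usable = np.isfinite(logs).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no feature has positive counts in all samples; a pseudo-reference "
            "fallback would be required for size-factor estimation"
        )
    loggeo = logs[usable].mean(axis=1)
    s = np.exp(np.median(logs[usable] - loggeo[:, None], axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    return counts.div(sf, axis=1)


@dataclasses.dataclass
class DispersionFit:
    """A fitted dispersion-vs-mean function with its residual sum of squares."""

    method: str  # parametric | local
    predict: Callable[[np.ndarray], np.ndarray]
    rss: float
    params: dict
    chosen: bool = False

    def __call__(self, q) -> np.ndarray:
        return np.maximum(self.predict(np.asarray(q, dtype=float)), MIN_DISPERSION)


def mom_dispersions(
    counts: pd.DataFrame, sf: pd.Series, groups: dict[str, str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments per-feature dispersions from normalized counts.

    q_i = mean normalized count; w_i = sample variance of normalized counts,
    pooled within conditions when ``groups`` is given so a real expression
    difference does not masquerade as dispersion; z_i = q_i * mean(1/s_j) is
    the shot-noise part; alpha_i = (w_i - z_i)/q_i^2 floored at zero.
    """
    norm_df = normalize(counts, sf)
    norm = norm_df.to_numpy(dtype=float)
    q = norm.mean(axis=1)
    if groups is None:
        w = norm.var(axis=1, ddof=1)
    else:
        labels = sorted(set(groups.values()))
        ss = np.zeros(len(norm_df))
        for label in labels:
            cols = [s for s in norm_df.columns if groups[s] == label]
            sub = norm_df[cols].to_numpy(dtype=float)
            ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        w = ss / (norm.shape[1] - len(labels))
    z = q * float((1.0 / sf).mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(q > 0, np.maximum(0.0, w - z) / q**2, np.nan)
    return q, alpha


def fit_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series,
    method: str = "parametric",
    groups: dict[str, str] | None = None,
) -> DispersionFit:
    """Fit the dispersion-mean relationship with the requested method.

    ``parametric`` fits alpha(q) = a0 + a1/q by least squares; ``local`` is a
    tricube-weighted local linear regression of alpha on log q (span 0.7).
    The residual sum of squares is computed on features with positive mean.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate dispersion")
    q, alpha = mom_dispersions(counts, sf, groups)
    ok = np.isfinite(alpha) & (q > 0)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 features with positive mean")
    q_ok, a_ok = q[ok], alpha[ok]

    if method == "parametric":
        X = np.column_stack([np.ones_like(q_ok), 1.0 / q_ok])
        coef, *_ = np.linalg.lstsq(X, a_ok, rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])

        def predict(qq: np.ndarray) -> np.ndarray:
            with np.errstate(divide="ignore"):
                return a0 + a1 / qq

        params = {"a0": a0, "a1": a1}
    elif method == "local":
        x = np.log(q_ok)
        fitted = lowess(a_ok, x, frac=LOCAL_SPAN, it=1, return_sorted=True)
        grid_x, grid_y = fitted[:, 0], fitted[:, 1]

        def predict(qq: np.ndarray) -> np.ndarray:
            with np.errstate(divide="ignore"):
                return np.interp(np.log(np.maximum(qq, 1e-300)), grid_x, grid_y)

        params = {"span": LOCAL_SPAN}
    else:
        raise ValueError(f"unknown dispersion fit method {method!r}")

    rss = float(np.sum((a_ok - np.maximum(predict(q_ok), MIN_DISPERSION)) ** 2))
    return DispersionFit(method=method, predict=predict, rss=rss, params=params)


def select_fit(parametric: DispersionFit, local: DispersionFit) -> DispersionFit:
    """Return the fit with the smaller residual sum of squares.

    Ties go to the parametric fit. Both RSS values are recorded on the chosen
    fit for reporting.
    """
    chosen = parametric if parametric.rss <= local.rss else local
    chosen.chosen = True
    chosen.params = dict(
        chosen.params, rss_parametric=parametric.rss, rss_local=local.rss
    )
    return chosen


def fit_and_select(
    counts: pd.DataFrame, sf: pd.Series, groups: dict[str, str] | None = None
) -> DispersionFit:
    return select_fit(
        fit_dispersion(counts, sf, "parametric", groups),
        fit_dispersion(counts, sf, "local", groups),
    )
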