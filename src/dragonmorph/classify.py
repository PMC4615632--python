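"""Canonical discriminant analysis of morph colour variables.

Given per-individual colour feature vectors (proportion red, yellow and grey
of the throat, plus chromatic and achromatic contrast of the throat and bib)
labelled with a visually assigned morph, this module:

* extracts canonical variates from the generalized eigenproblem
  ``B v = lambda W v`` (between- vs within-group scatter), together with the
  percentage of discriminating variance per axis;
* tests group separation with Wilks' Lambda = prod 1/(1 + lambda_i)
  (equivalently det(W)/det(W + B)) and Rao's F approximation;
* classifies observations with linear discriminant scores (pooled
  covariance, equal priors by default) and estimates assignment accuracy by
  leave-one-out cross-validation.

The morph label order (orange, yellow, grey, orange_yellow) fixes tie
breaking and the confusion-matrix layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "MORPH_ORDER",
    "FEATURE_COLUMNS",
    "DFAResult",
    "LOOResult",
    "canonical_discriminant",
    "classify",
    "cross_validate_loo",
]

#: Canonical morph order: used for tie breaking and confusion-matrix layout.
MORPH_ORDER = ("orange", "yellow", "grey", "orange_yellow")

#: The seven colour variables entering the discriminant analysis.
FEATURE_COLUMNS = (
    "prop_red",
    "prop_yellow",
    "prop_grey",
    "throat_chromatic_jnd",
    "throat_achromatic_jnd",
    "bib_chromatic_jnd",
    "bib_achromatic_jnd",
)


@dataclass(frozen=True)
class DFAResult:
    """Fitted canonical discriminant analysis."""

    groups: tuple[str, ...]
    feature_names: tuple[str, ...]
    eigenvalues: np.ndarray            # descending, length min(p, g-1)
    coefficients: np.ndarray           # (p, n_axes) canonical coefficient vectors
    percent_variance: np.ndarray       # per axis, sums to 100
    wilks_lambda: float
    f_statistic: float
    df1: int
    df2: float
    centroids: np.ndarray              # (g, n_axes) group means in canonical space
    group_means: np.ndarray            # (g, p) in feature space
    pooled_cov: np.ndarray             # (p, p) within-group covariance
    group_sizes: tuple[int, ...]

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def transform(self, X) -> np.ndarray:
        """Project feature rows onto the canonical axes."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        grand = np.average(self.group_means, axis=0,
                           weights=np.asarray(self.group_sizes))
        return (X - grand) @ self.coefficients


@dataclass(frozen=True)
class LOOResult:
    """Leave-one-out cross-validated assignment accuracy."""

    groups: tuple[str, ...]
    confusion: np.ndarray       # (g, g) rows = true, columns = assigned
    per_class_rate: dict
    overall_rate: float


def _extract(table, feature_names):
    """Accept a DataFrame or a sequence of mappings; return (X, labels, names)."""
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.DataFrame(list(table))
    if "morph" not in df.columns:
        raise ValueError("table must carry a 'morph' label column")
    if feature_names is None:
        feature_names = tuple(c for c in FEATURE_COLUMNS if c in df.columns)
        if len(feature_names) == 0:
            feature_names = tuple(
                c for c in df.columns
                if c not in ("morph", "id", "individual_id", "week")
                and pd.api.types.is_numeric_dtype(df[c])
            )
    X = df.loc[:, list(feature_names)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature values must be finite")
    labels = df["morph"].astype(str).to_numpy()
    return X, labels, tuple(feature_names)


def _group_order(labels) -> tuple[str, ...]:
    seen = list(dict.fromkeys(labels))
    known = [m for m in MORPH_ORDER if m in seen]
    extra = sorted(set(seen) - set(MORPH_ORDER))
    return tuple(known + extra)


def _scatter_matrices(X, labels, groups, min_group_size=2):
    """Within-group (W) and between-group (B) scatter about the grand mean."""
    n, p = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    means = []
    sizes = []
    for gname in groups:
        Xg = X[labels == gname]
        if Xg.shape[0] < min_group_size:
            raise ValueError(
                f"group {gname!r} needs at least {min_group_size} observations"
            )
        mg = Xg.mean(axis=0)
        means.append(mg)
        sizes.append(Xg.shape[0])
        dev = Xg - mg
        W += dev.T @ dev
        dm = (mg - grand)[:, None]
        B += Xg.shape[0] * (dm @ dm.T)
    return W, B, np.array(means), tuple(sizes)


def canonical_discriminant(table, feature_names=None,
                           min_group_size: int = 2) -> DFAResult:
    """Fit the canonical discriminant analysis.

    Parameters
    ----------
    table : DataFrame or sequence of mappings
        Must carry a ``morph`` column plus numeric feature columns (the seven
        standard colour variables when present).
    feature_names : sequence of str, optional
        Explicit feature subset; defaults to the standard colour variables
        found in the table.
    """
    X, labels, feature_names = _extract(table, feature_names)
    groups = _group_order(labels)
    g = len(groups)
    n, p = X.shape
    if g < 2:
        raise ValueError("at least 2 groups are required")
    if n <= p + g:
        raise ValueError(
            f"too few observations (n={n}) for p={p} features and g={g} groups"
        )
    W, B, means, sizes = _scatter_matrices(X, labels, groups, min_group_size)

    cond = np.linalg.cond(W)
    if not np.isfinite(cond) or cond > 1e12:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            f"{feature_names[i]}~{feature_names[j]}"
            for i in range(p) for j in range(i + 1, p)
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(
            "pooled within-group scatter is singular; collinear features: "
            + (", ".join(pairs) if pairs else "(rank deficiency not pairwise)")
        )

    # Generalized symmetric eigenproblem B v = lambda W v
    eigvals, eigvecs = linalg.eigh(B, W)
    order = np.argsort(eigvals)[::-1]
    n_axes = min(p, g - 1)
    eigvals = np.clip(eigvals[order][:n_axes], 0.0, None)
    coeffs = eigvecs[:, order][:, :n_axes]
    # scale coefficient vectors to unit within-group variance per axis
    pooled_cov = W / (n - g)
    for k in range(n_axes):
        v = coeffs[:, k]
        s = float(v @ pooled_cov @ v)
        if s > 0:
            coeffs[:, k] = v / np.sqrt(s)

    total = eigvals.sum()
    percent = (eigvals / total * 100.0) if total > 0 else np.zeros(n_axes)

    wilks = float(np.prod(1.0 / (1.0 + eigvals)))

    # Rao's F approximation for Wilks' Lambda
    df1 = p * (g - 1)
    m = n - 1 - (p + g) / 2.0
    denom = p ** 2 + (g - 1) ** 2 - 5
    s = np.sqrt((p ** 2 * (g - 1) ** 2 - 4) / denom) if denom > 0 else 1.0
    df2 = m * s - df1 / 2.0 + 1.0
    lam_s = wilks ** (1.0 / s)
    f_stat = (1.0 - lam_s) / lam_s * (df2 / df1) if lam_s > 0 else np.inf

    grand = X.mean(axis=0)
    centroids = (means - grand) @ coeffs
    return DFAResult(
        groups=groups,
        feature_names=feature_names,
        eigenvalues=eigvals,
        coefficients=coeffs,
        percent_variance=percent,
        wilks_lambda=wilks,
        f_statistic=float(f_stat),
        df1=int(df1),
        df2=float(df2),
        centroids=centroids,
        group_means=means,
        pooled_cov=pooled_cov,
        group_sizes=sizes,
    )


def classify(result: DFAResult, row, priors: Mapping[str, float] | None = None):
    """Assign one feature row to a morph by linear discriminant score.

    Scores use the pooled within-group covariance and equal priors unless
    ``priors`` overrides them. Ties are broken by the fixed group order.
    Returns ``(label, scores)`` with ``scores`` a dict per group.
    """
    if isinstance(row, Mapping):
        x = np.array([float(row[f]) for f in result.feature_names])
    else:
        x = np.asarray(row, dtype=float)
        if x.shape != (len(result.feature_names),):
            raise ValueError(
                f"expected {len(result.feature_names)} features, got {x.shape}"
            )
    g = len(result.groups)
    if priors is None:
        log_priors = np.zeros(g)
    else:
        pr = np.array([float(priors[gname]) for gname in result.groups])
        if np.any(pr <= 0):
            raise ValueError("priors must be positive")
        log_priors = np.log(pr / pr.sum())
    Sinv = np.linalg.inv(result.pooled_cov)
    scores = {}
    best, best_score = None, -np.inf
    for k, gname in enumerate(result.groups):
        mu = result.group_means[k]
        sc = float(mu @ Sinv @ x - 0.5 * mu @ Sinv @ mu + log_priors[k])
        scores[gname] = sc
        if sc > best_score + 1e-12:
            best, best_score = gname, sc
    return best, scores


def cross_validate_loo(table, feature_names=None,
                       priors: Mapping[str, float] | None = None) -> LOOResult:
    """Leave-one-out cross-validated morph assignment.

    Each observation is classified by a discriminant refitted on the
    remaining n-1 rows; the procedure is deterministic.
    """
    X, labels, feature_names = _extract(table, feature_names)
    groups = _group_order(labels)
    for gname in groups:
        if (labels == gname).sum() < 2:
            raise ValueError(
                f"group {gname!r} has a single observation; it cannot be "
                "held out and still define a group"
            )
    df = pd.DataFrame(X, columns=list(feature_names))
    df["morph"] = labels
    g = len(groups)
    gidx = {gname: k for k, gname in enumerate(groups)}
    confusion = np.zeros((g, g), dtype=int)
    for i in range(len(df)):
        train = df.drop(index=df.index[i])
        # a size-2 group leaves one member when held out; it still defines
        # a group mean, contributing nothing to the within-group scatter
        fit = canonical_discriminant(train, feature_names=feature_names,
                                     min_group_size=1)
        label, _ = classify(fit, X[i], priors=priors)
        confusion[gidx[labels[i]], gidx[label]] += 1
    per_class = {
        gname: float(confusion[k, k] / confusion[k].sum())
        for k, gname in enumerate(groups)
    }
    overall = float(np.trace(confusion) / confusion.sum())
    return LOOResult(groups=groups, confusion=confusion,
                     per_class_rate=per_class, overall_rate=overall)
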