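"""Post-fermentation beverage analytics.

GC-MS relative peak areas (ethanol-normalised), per-compound percent-of-max
scaling, Ward hierarchical clustering of samples or compounds with bootstrap
node support (ordinary bootstrap proportions and approximately-unbiased
multiscale extrapolation), beer colour scales, phenol-sulfuric carbohydrate
quantitation against a glucose standard curve, and taste-sheet aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy


# ---------------------------------------------------------------------------
# GC-MS scaling


def relative_peak_area(
    compound_area: float, ethanol_area: float, ethanol_percent: float
) -> float:
    """Compound peak area relative to the ethanol internal standard.

    The ethanol peak area is first normalised by the sample's ethanol
    concentration (in percent, from distillation); the compound area divided
    by that is scaled by 1000 for presentable numbers.
    """
    if ethanol_area <= 0 or ethanol_percent <= 0:
        raise ValueError("ethanol area and percent must be > 0")
    if compound_area < 0:
        raise ValueError("compound area must be >= 0")
    normalized_ethanol = ethanol_area / ethanol_percent
    return compound_area / normalized_ethanol * 1000.0


def percent_of_max(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each compound column to percent of its maximum value.

    All-zero columns are left unchanged (a warning names them); everything
    else lands in [0, 100] with the column maximum at exactly 100.
    """
    out = matrix.astype(float).copy()
    zero_cols = [c for c in out.columns if out[c].max() == 0]
    if zero_cols:
        warnings.warn(f"all-zero compound columns left unscaled: {zero_cols}", stacklevel=2)
    for c in out.columns:
        m = out[c].max()
        if m > 0:
            out[c] = out[c] / m * 100.0
    return out


# ---------------------------------------------------------------------------
# Beer chemistry


def beer_color(absorbance_430: float) -> tuple[float, float]:
    """(SRM, EBC) beer colour from 430-nm absorbance in a 10-mm cuvette.

    Both scales are linear: SRM = 12.7 x A430, EBC = 25.0 x A430.
    """
    if absorbance_430 < 0:
        raise ValueError("absorbance must be >= 0")
    return 12.7 * absorbance_430, 25.0 * absorbance_430


@dataclass
class CalibrationCurve:
    slope: float  # absorbance per (ug/ml)
    intercept: float
    r_squared: float
    concentrations: np.ndarray
    absorbances: np.ndarray


def fit_calibration(
    concentrations: np.ndarray, absorbances: np.ndarray
) -> CalibrationCurve:
    """Least-squares standard line: absorbance on concentration (ug/ml)."""
    conc = np.asarray(concentrations, dtype=float)
    absb = np.asarray(absorbances, dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("need >= 2 distinct standard concentrations")
    res = stats.linregress(conc, absb)
    if res.slope == 0:
        raise ValueError("calibration slope is zero")
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        concentrations=conc,
        absorbances=absb,
    )


def phenol_sulfuric_quantify(
    curve: CalibrationCurve,
    unknown_absorbance: float,
    dilution_factor: float = 1000.0,
) -> tuple[float, bool]:
    """Total carbohydrates as glucose equivalents, g/liter.

    The unknown absorbance (485 nm) is inverted through the standard line
    (ug/ml), multiplied by the dilution factor (1 ml beer brought to 1 liter
    gives 1000x) and converted: ug/ml x 1000 (dilution) = ug/ml in beer;
    reported in g/liter (numerically equal to mg/ml).  Returns
    (concentration, extrapolated_flag); readings outside the standard
    absorbance range are flagged, not rejected.
    """
    conc_ug_ml = (unknown_absorbance - curve.intercept) / curve.slope
    extrapolated = not (
        min(curve.absorbances) <= unknown_absorbance <= max(curve.absorbances)
    )
    grams_per_liter = conc_ug_ml * dilution_factor / 1000.0
    return float(grams_per_liter), extrapolated


# ---------------------------------------------------------------------------
# Clustering with bootstrap support


@dataclass
class Dendrogram:
    """Ward merge tree over labelled items.

    ``linkage`` is a scipy linkage matrix; ``supports`` maps the frozenset
    of leaf labels under an internal node to {"bp": %, "au": %} once
    :func:`cluster_support` has run.
    """

    linkage: np.ndarray
    labels: list[str]
    supports: dict[frozenset, dict[str, float]] = field(default_factory=dict)

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def node_leaf_sets(self) -> list[frozenset]:
        """Leaf-label set under each internal node, in merge order."""
        n = len(self.labels)
        sets: list[frozenset] = []
        members = {i: frozenset([self.labels[i]]) for i in range(n)}
        for k, (i, j, _, _) in enumerate(self.linkage):
            merged = members[int(i)] | members[int(j)]
            members[n + k] = merged
            sets.append(merged)
        return sets

    def flagged_clusters(self, measure: str = "bp", threshold: float = 95.0) -> list[frozenset]:
        return sorted(
            (s for s, v in self.supports.items() if v.get(measure, 0.0) > threshold),
            key=sorted,
        )

    def to_newick(self) -> str:
        n = len(self.labels)
        reprs = {i: lab for i, lab in enumerate(self.labels)}
        heights = {i: 0.0 for i in range(n)}
        for k, (i, j, h, _) in enumerate(self.linkage):
            i, j = int(i), int(j)
            li = max(h - heights[i], 0.0)
            lj = max(h - heights[j], 0.0)
            reprs[n + k] = f"({reprs[i]}:{li:g},{reprs[j]}:{lj:g})"
            heights[n + k] = h
        return reprs[n + len(self.linkage) - 1] + ";"


def _ward_linkage(data: np.ndarray) -> np.ndarray:
    return hierarchy.linkage(data, method="ward")


def ward_dendrogram(matrix: pd.DataFrame, axis: str = "samples") -> Dendrogram:
    """Ward (variance-minimising) clustering on Euclidean distances.

    ``axis="samples"`` clusters rows; ``axis="compounds"`` clusters columns.
    Heights follow the ward.D2 convention (squared distances inside the
    criterion), so merges are monotone non-decreasing.
    """
    if axis == "samples":
        data, labels = matrix.to_numpy(dtype=float), list(matrix.index)
    elif axis == "compounds":
        data, labels = matrix.to_numpy(dtype=float).T, list(matrix.columns)
    else:
        raise ValueError("axis must be 'samples' or 'compounds'")
    if len(labels) < 2:
        raise ValueError("need >= 2 items to cluster")
    if np.isnan(data).any():
        raise ValueError("matrix contains missing values; impute before clustering")
    return Dendrogram(linkage=_ward_linkage(data), labels=labels)


def _bootstrap_proportions(
    data: np.ndarray,
    labels: list[str],
    observed_sets: list[frozenset],
    n_features: int,
    B: int,
    rng: np.random.Generator,
) -> dict[frozenset, float]:
    counts = {s: 0 for s in observed_sets}
    total_feats = data.shape[1]
    for _ in range(B):
        cols = rng.integers(0, total_feats, size=n_features)
        boot = Dendrogram(linkage=_ward_linkage(data[:, cols]), labels=labels)
        seen = set(boot.node_leaf_sets())
        for s in observed_sets:
            if s in seen:
                counts[s] += 1
    return {s: c / B for s, c in counts.items()}


def cluster_support(
    matrix: pd.DataFrame,
    axis: str = "samples",
    B: int = 1000,
    method: str = "bp",
    seed: int = 0,
    au_scales: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4),
) -> Dendrogram:
    """Bootstrap node support for the Ward dendrogram.

    Features (the non-clustered axis) are resampled with replacement; the
    bp support of a node is the percentage of bootstrap dendrograms that
    contain the identical leaf set.  ``method="au"`` additionally runs the
    multiscale bootstrap: resampling at feature counts scaled by
    ``au_scales``, then extrapolating the normal-quantile-transformed
    bootstrap probability to scale 1 from the fitted signed-distance and
    curvature terms.  Supports are percentages in [0, 100].
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if method not in ("bp", "au"):
        raise ValueError("method must be 'bp' or 'au'")
    dend = ward_dendrogram(matrix, axis=axis)
    data = (
        matrix.to_numpy(dtype=float)
        if axis == "samples"
        else matrix.to_numpy(dtype=float).T
    )
    n_features = data.shape[1]
    if n_features < 2:
        raise ValueError("need >= 2 features to resample")
    rng = np.random.default_rng(seed)
    observed = dend.node_leaf_sets()
    scored = [s for s in observed if 1 < len(s) < len(dend.labels)]
    bp = _bootstrap_proportions(data, dend.labels, scored, n_features, B, rng)
    for s in scored:
        dend.supports[s] = {"bp": 100.0 * bp[s]}
    if method == "au":
        per_scale: dict[float, dict[frozenset, float]] = {}
        for scale in au_scales:
            n_s = max(2, int(round(scale * n_features)))
            per_scale[n_s / n_features] = _bootstrap_proportions(
                data, dend.labels, scored, n_s, B, rng
            )
        for s in scored:
            dend.supports[s]["au"] = 100.0 * _au_extrapolate(
                {sc: props[s] for sc, props in per_scale.items()}, B
            )
    return dend


def _au_extrapolate(bp_by_scale: dict[float, float], B: int) -> float:
    """Multiscale-bootstrap extrapolation of a node's support.

    For scale ratio rho = n'/n, sigma = 1/sqrt(rho), the model is
    z(rho) = Phi^{-1}(1 - BP) = v*sigma + c/sigma with signed distance v and
    curvature c; the approximately unbiased support is 1 - Phi(v - c).
    Degenerate nodes (BP 0 or 1 at every scale) return that proportion.
    """
    eps = 1.0 / (2.0 * B)
    xs, ys = [], []
    for rho, bp in bp_by_scale.items():
        if bp <= 0 or bp >= 1:
            continue
        sigma = 1.0 / np.sqrt(rho)
        xs.append(sigma)
        ys.append(stats.norm.ppf(1.0 - bp))
    if len(xs) < 2:
        mean_bp = float(np.mean(list(bp_by_scale.values())))
        return min(1.0 - eps, max(eps, mean_bp))
    X = np.column_stack([xs, 1.0 / np.asarray(xs)])
    v, c = np.linalg.lstsq(X, np.asarray(ys), rcond=None)[0]
    return float(min(1.0, max(0.0, stats.norm.sf(v - c))))


# ---------------------------------------------------------------------------
# Taste sheets


def taste_profile(
    sheets: dict[str, dict[str, int]],
) -> tuple[dict[str, float], dict[str, list[str]]]:
    """Mean 1-5 score per attribute across tasters, plus a coverage report.

    ``sheets`` maps taster id -> {attribute: score}.  Attributes are
    normalised case-insensitively.  Returns (attribute -> mean score,
    attribute -> tasters who skipped it).  Any score outside 1..5 raises,
    naming the taster and attribute.
    """
    if not sheets:
        raise ValueError("no taste sheets")
    scores: dict[str, list[int]] = {}
    seen: dict[str, set[str]] = {}
    for taster, sheet in sheets.items():
        for attr, score in sheet.items():
            key = attr.strip().lower()
            if not (1 <= score <= 5):
                raise ValueError(
                    f"score {score} outside 1..5 (taster {taster!r}, attribute {attr!r})"
                )
            scores.setdefault(key, []).append(score)
            seen.setdefault(key, set()).add(taster)
    means = {attr: float(np.mean(vals)) for attr, vals in sorted(scores.items())}
    all_tasters = set(sheets)
    skipped = {
        attr: sorted(all_tasters - tasters)
        for attr, tasters in sorted(seen.items())
        if all_tasters - tasters
    }
    return means, skipped
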