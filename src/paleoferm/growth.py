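"""Growth-curve fingerprinting against a modern control strain.

Each strain's OD600 trajectory in wort is fitted, replicate by replicate,
to the three-parameter logistic model

    N(t) = K / (1 + ((K - N0)/N0) * exp(-r t))

with carrying capacity K (OD600), initial size N0 (OD600) and intrinsic
growth rate r (per hour).  Replicate r values are then compared to the
control strain's (Welch t test), fitted parameter vectors are projected by
PCA, and the distance-to-control fingerprint is correlated with whether the
strain came from a putative beverage vessel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class GrowthCurve:
    strain: str
    replicate: str
    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray  # OD600, >= 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if len(self.times) < 5:
            raise ValueError("growth curve needs >= 5 time points")
        if len(self.times) != len(self.od):
            raise ValueError("times and OD readings differ in length")
        if not np.all(np.isfinite(self.times)) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be finite and strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD600 readings must be >= 0")


@dataclass
class LogisticFit:
    K: float
    N0: float
    r: float
    rss: float
    converged: bool
    degenerate: bool = False  # flat curve, r unidentifiable

    def predict(self, times: np.ndarray) -> np.ndarray:
        return logistic(np.asarray(times, dtype=float), self.K, self.N0, self.r)


@dataclass
class StrainComparison:
    strain: str
    p_value: float
    call: str  # "similar" | "different"
    pca_coordinates: np.ndarray
    distance_to_control: float


def logistic(t: np.ndarray, K: float, N0: float, r: float) -> np.ndarray:
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def fit_logistic(curve: GrowthCurve, max_iterations: int = 500) -> LogisticFit:
    """Nonlinear least squares of the three-parameter logistic.

    Initialization: K from the maximum OD, N0 from the first reading
    (clipped to >= 1e-6), r from the slope of the linearised form
    log(N/(K-N)) over interior points.  Convergence at relative RSS change
    < 1e-10; a fit that does not converge returns the best point found with
    ``converged=False`` rather than raising.
    """
    t, y = curve.times, curve.od
    if np.allclose(y, y[0]):
        return LogisticFit(
            K=float(max(y[0], 1e-6)), N0=float(max(y[0], 1e-6)), r=0.0,
            rss=0.0, converged=True, degenerate=True,
        )
    k0 = float(np.max(y))
    n0 = float(max(y[0], 1e-6))
    interior = (y > 0) & (y < k0)
    if interior.sum() >= 2:
        z = np.log(y[interior] / (k0 - y[interior]))
        r0 = float(np.polyfit(t[interior], z, 1)[0])
        r0 = r0 if np.isfinite(r0) and r0 > 0 else 0.1
    else:
        r0 = 0.1
    p0 = [k0, n0, r0]
    bounds = ([1e-9, 1e-9, -np.inf], [np.inf, np.inf, np.inf])
    try:
        popt, _ = optimize.curve_fit(
            logistic, t, y, p0=p0, bounds=bounds,
            ftol=1e-10, xtol=1e-12, maxfev=max_iterations * 10,
        )
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    resid = y - logistic(t, *popt)
    return LogisticFit(
        K=float(popt[0]), N0=float(popt[1]), r=float(popt[2]),
        rss=float(resid @ resid), converged=converged,
    )


def fit_strain_replicates(
    curves: list[GrowthCurve],
) -> dict[str, dict[str, LogisticFit]]:
    """Fit every replicate individually: strain -> replicate -> fit."""
    fits: dict[str, dict[str, LogisticFit]] = {}
    for c in curves:
        fits.setdefault(c.strain, {})[c.replicate] = fit_logistic(c)
    return fits


def growth_rate_test(
    fits_strain: list[LogisticFit],
    fits_control: list[LogisticFit],
) -> float:
    """Two-sided Welch t test of replicate growth rates strain vs control."""
    if len(fits_strain) < 3 or len(fits_control) < 3:
        raise ValueError("need >= 3 replicate fits per strain (independent colonies)")
    rs = [f.r for f in fits_strain]
    rc = [f.r for f in fits_control]
    if np.allclose(rs, rc):
        return 1.0
    _, p = stats.ttest_ind(rs, rc, equal_var=False)
    return float(p)


def pca_parameters(
    params: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of per-strain fitted parameter vectors (rows: strains).

    Columns are standardised (zero mean, unit variance) first; zero-variance
    columns are dropped with a warning.  Components are ordered by
    decreasing explained variance and signed so the largest-magnitude
    loading of each component is positive.  Returns (scores, loadings,
    explained-variance fractions).
    """
    if len(params) < 3:
        raise ValueError("PCA needs >= 3 strains")
    X = params.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = list(params.columns[~keep])
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    cols = params.columns[keep]
    # economy SVD of the standardised matrix == eigen-decomposition of its
    # covariance, with better conditioning
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for k in range(Vt.shape[0]):
        if Vt[k, np.argmax(np.abs(Vt[k]))] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U * S
    var = S**2
    explained = var / var.sum() if var.sum() > 0 else var
    names = [f"PC{i + 1}" for i in range(len(S))]
    return (
        pd.DataFrame(scores, index=params.index, columns=names),
        pd.DataFrame(Vt, index=names, columns=cols),
        explained,
    )


def distance_classify(
    scores: pd.DataFrame,
    control_strain: str,
    p_values: dict[str, float],
    alpha: float = 0.01,
) -> list[StrainComparison]:
    """Distance to the control in PCA space plus the similarity call.

    The call follows the growth-rate test: "similar" iff p > alpha.  The
    control compares to itself at distance 0, p 1.
    """
    if control_strain not in scores.index:
        raise KeyError(control_strain)
    control = scores.loc[control_strain].to_numpy()
    out = []
    for strain in scores.index:
        coords = scores.loc[strain].to_numpy()
        d = float(np.linalg.norm(coords - control))
        p = 1.0 if strain == control_strain else float(p_values[strain])
        out.append(
            StrainComparison(
                strain=strain,
                p_value=p,
                call="similar" if p > alpha else "different",
                pca_coordinates=coords,
                distance_to_control=d,
            )
        )
    return out


def origin_correlation(
    values: dict[str, float],
    origins: dict[str, bool],
    negate: bool = True,
) -> float:
    """Point-biserial correlation of a growth fingerprint with vessel origin.

    ``values`` is a per-strain continuous fingerprint — either the PCA
    distance to the control (the default ``negate=True`` flips it so
    beverage-like, i.e. close to control, scores high) or an already
    beverage-high quantity such as a 0/1 similarity call (``negate=False``).
    ``origins[strain]`` is True for putative-beverage-vessel strains.
    """
    strains = sorted(values)
    if len(strains) < 3:
        raise ValueError("need >= 3 strains")
    labels = np.array([bool(origins[s]) for s in strains], dtype=float)
    if labels.min() == labels.max():
        raise ValueError("both origin classes must be present")
    x = np.array([values[s] for s in strains], dtype=float)
    if negate:
        x = -x
    if np.std(x) == 0:
        raise ValueError("fingerprint values have zero variance; correlation undefined")
    r, _ = stats.pointbiserialr(labels, x)
    return float(r)


def origin_correlation_from_comparisons(
    comparisons: list[StrainComparison],
    origins: dict[str, bool],
    use: str = "call",
) -> float:
    """Origin correlation straight from :func:`distance_classify` output.

    ``use="call"`` correlates the binary similarity call (similar = 1)
    with origin — the reading under which perfect fingerprinting gives
    r = 1.  ``use="distance"`` correlates the negated PCA distance, which
    keeps the continuous spread (including components that carry no
    between-strain signal).
    """
    if use == "call":
        values = {c.strain: 1.0 if c.call == "similar" else 0.0 for c in comparisons}
        return origin_correlation(values, origins, negate=False)
    if use == "distance":
        values = {c.strain: c.distance_to_control for c in comparisons}
        return origin_correlation(values, origins, negate=True)
    raise ValueError("use must be 'call' or 'distance'")
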