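"""pH-dependence models for transient-dwell formation and synthase-direction steps.

Two titration models drive the analysis:

* A Dixon-style log-log inhibition curve for the percent of power strokes
  that contain transient dwells (TDs),

      log10 T(pH) = log10 Tmin + log10(1 + 10**(K2 - pH))
                               - log10(1 + 10**(K1 - pH)),

  where ``Tmin`` is the high-pH plateau (percent) and ``K1``/``K2`` are
  log10 association constants of the group that must be protonated and
  the group that must be unprotonated for a TD to form. Apparent pKa
  values are read off the curve by intersecting the tangent at the
  inflection with the two plateaus (`extract_pkas`).

* A two-pKa Henderson-Hasselbalch occupancy model for the percent of TDs
  that lack a synthase-direction step,

      TN(pH) = P1 * X1(pKa1, pH) + P2 * Y2(pKa2, pH),

  with ``X1`` the protonated fraction of the low-pKa group and ``Y2`` the
  unprotonated fraction of the high-pKa group, and TS = 100 - TN.

Percentages are carried in percent units throughout (matching how the
experiment tabulates them); fractions appear only inside the
Henderson-Hasselbalch terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares


__all__ = [
    "PHCurveModel",
    "SynthaseStepModel",
    "EfficiencyMixture",
    "FitResult",
    "eval_td_occurrence",
    "fit_td_occurrence",
    "extract_pkas",
    "protonated_fraction",
    "unprotonated_fraction",
    "eval_tn",
    "eval_ts",
    "fit_synthase_model",
    "fit_three_gaussians",
]


@dataclass(frozen=True)
class PHCurveModel:
    """Parameters of the TD-occurrence titration curve.

    Attributes
    ----------
    tmin : float
        High-pH plateau of TD occurrence, in percent of power strokes.
        Must be >= 0 (zero is permitted as the degenerate "no TDs" model
        for simulation; fitting requires tmin > 0).
    k1, k2 : float
        log10 association constants (pK units) of the protonated-group
        and unprotonated-group limbs. ``k2 >= k1`` so that occurrence
        rises toward low pH.
    """

    tmin: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.tmin, self.k1, self.k2]).all():
            raise ValueError("PHCurveModel parameters must be finite")
        if self.tmin < 0:
            raise ValueError(f"tmin must be >= 0, got {self.tmin}")
        if self.k2 < self.k1:
            raise ValueError(f"requires k2 >= k1, got k1={self.k1}, k2={self.k2}")

    @property
    def t_saturating(self) -> float:
        """Low-pH saturating plateau, tmin * 10**(k2 - k1), in percent."""
        return self.tmin * 10.0 ** (self.k2 - self.k1)

    @property
    def pka1(self) -> float:
        return extract_pkas(self)[0]

    @property
    def pka2(self) -> float:
        return extract_pkas(self)[1]


@dataclass(frozen=True)
class SynthaseStepModel:
    """Parameters of the TN(pH) model for TDs without synthase-direction steps.

    ``p1``/``p2`` are percent weights of TDs formed by the
    protonated-only and unprotonated-only routes; ``pka1 < pka2``.
    """

    pka1: float
    p1: float
    pka2: float
    p2: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.pka1, self.p1, self.pka2, self.p2]).all():
            raise ValueError("SynthaseStepModel parameters must be finite")
        if not (0.0 <= self.p1 <= 100.0 and 0.0 <= self.p2 <= 100.0):
            raise ValueError("p1 and p2 must lie in [0, 100]")
        if self.p1 + self.p2 > 100.0 + 1e-9:
            raise ValueError("p1 + p2 must not exceed 100")
        if not self.pka1 < self.pka2:
            raise ValueError(f"requires pka1 < pka2, got {self.pka1}, {self.pka2}")


@dataclass(frozen=True)
class EfficiencyMixture:
    """Three-Gaussian decomposition of the per-data-set TD-percent histogram.

    Components are ordered low < medium < high by mean. Weights are the
    normalized areas of the components.
    """

    weights: tuple[float, float, float]
    means: tuple[float, float, float]
    sds: tuple[float, float, float]
    flagged: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        if w.shape != (3,) or m.shape != (3,) or s.shape != (3,):
            raise ValueError("mixture requires exactly 3 components")
        if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("weights must be >= 0 and sum to 1")
        if (s <= 0).any():
            raise ValueError("sds must be > 0")
        if (m < 0).any() or (m > 100).any():
            raise ValueError("means must lie in [0, 100]")
        if not (m[0] <= m[1] <= m[2]):
            raise ValueError("components must be sorted by mean")


@dataclass
class FitResult:
    """Container for a nonlinear least-squares fit.

    ``params`` holds the fitted model; ``stderr`` maps parameter names to
    standard errors from the Jacobian at the solution; ``flagged`` is set
    when the optimizer failed to converge or a constraint boundary is
    active (e.g. k2 == k1), in which case the parameters should not be
    trusted.
    """

    params: object
    stderr: dict = field(default_factory=dict)
    cov: np.ndarray | None = None
    residual: float = float("nan")
    flagged: bool = False
    message: str = ""


# ---------------------------------------------------------------------------
# TD occurrence curve
# ---------------------------------------------------------------------------

def eval_td_occurrence(model: PHCurveModel, ph) -> np.ndarray | float:
    """Percent of power strokes containing TDs at the given pH.

    T(pH) = tmin * (1 + 10**(k2 - pH)) / (1 + 10**(k1 - pH)), which rises
    from the high-pH plateau ``tmin`` to the low-pH plateau
    ``tmin * 10**(k2 - k1)``.
    """
    ph = np.asarray(ph, dtype=float)
    out = model.tmin * (1.0 + 10.0 ** (model.k2 - ph)) / (1.0 + 10.0 ** (model.k1 - ph))
    return float(out) if out.ndim == 0 else out


def _log10_td(tmin_log10: float, k1: float, k2: float, ph: np.ndarray) -> np.ndarray:
    return (
        tmin_log10
        + np.log10(1.0 + 10.0 ** (k2 - ph))
        - np.log10(1.0 + 10.0 ** (k1 - ph))
    )


def fit_td_occurrence(
    ph_values: Sequence[float],
    percents: Sequence[float],
    weights: Sequence[float] | None = None,
    boundary_tol: float = 1e-3,
) -> FitResult:
    """Fit the TD-occurrence curve by least squares on log10(percent).

    Parameters are (log10 tmin, k1, delta) with k2 = k1 + delta and
    delta >= 0, which enforces tmin > 0 and k2 >= k1. The fit is flagged
    when the optimizer fails or the delta = 0 boundary is active (the
    curve is then pH-independent and the pKas are undefined).
    """
    ph = np.asarray(ph_values, dtype=float)
    y = np.asarray(percents, dtype=float)
    if ph.size < 5:
        raise ValueError("need at least 5 pH points spanning both plateaus")
    if ph.shape != y.shape:
        raise ValueError("ph_values and percents must have matching shape")
    y = np.clip(y, 1e-3, None)  # log-space fit; guard nonpositive percents
    logy = np.log10(y)
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, float))

    lo, hi = float(y.min()), float(y.max())
    delta0 = max(np.log10(hi / lo), 0.05)
    # inflection of the log curve sits at (k1+k2)/2: seed from the pH at
    # which log10 T crosses the midpoint between plateaus
    mid = (np.log10(lo) + np.log10(hi)) / 2.0
    ph_mid = float(ph[np.argmin(np.abs(logy - mid))])
    x0 = np.array([np.log10(lo), ph_mid - delta0 / 2.0, delta0])

    def resid(x):
        return w * (_log10_td(x[0], x[1], x[1] + x[2], ph) - logy)

    sol = least_squares(
        resid,
        x0,
        bounds=([-6.0, ph.min() - 5.0, 0.0], [4.0, ph.max() + 5.0, 6.0]),
    )
    tmin = 10.0 ** sol.x[0]
    k1 = sol.x[1]
    delta = sol.x[2]
    model = PHCurveModel(tmin=tmin, k1=k1, k2=k1 + delta)

    flagged = bool((not sol.success) or delta < boundary_tol)
    cov, stderr = _covariance(sol, ("log10_tmin", "k1", "delta"))
    return FitResult(
        params=model,
        stderr=stderr,
        cov=cov,
        residual=float(np.sqrt(np.mean(sol.fun**2))),
        flagged=flagged,
        message="k2=k1 boundary active" if delta < boundary_tol else sol.message,
    )


def extract_pkas(model: PHCurveModel) -> tuple[float, float]:
    """Apparent pKa values from the tangent/plateau intercept construction.

    On the (pH, log10 T) curve the tangent is taken at the inflection
    pH* = (k1 + k2)/2, where the downhill slope is maximal. pKa1 is the
    pH where that tangent meets the low-pH plateau log10(tmin*10**(k2-k1));
    pKa2 where it meets the high-pH plateau log10(tmin). The construction
    is symmetric about pH*, with closed form

        |slope| = (b - a) / (2 + a + b),   a = 10**(-(k2-k1)/2), b = 1/a,
        pKa_{1,2} = pH* -/+ (k2 - k1) / (2 |slope|).
    """
    delta = model.k2 - model.k1
    if delta <= 0:
        raise ValueError("pKa construction undefined when k2 == k1")
    if model.tmin <= 0:
        raise ValueError("pKa construction requires tmin > 0")
    ph_star = 0.5 * (model.k1 + model.k2)
    a = 10.0 ** (-delta / 2.0)
    b = 10.0 ** (delta / 2.0)
    slope = (b - a) / (2.0 + a + b)
    half_width = (delta / 2.0) / slope
    return ph_star - half_width, ph_star + half_width


# ---------------------------------------------------------------------------
# Henderson-Hasselbalch occupancies and the synthase-step model
# ---------------------------------------------------------------------------

def protonated_fraction(pka: float, ph) -> np.ndarray | float:
    """Fraction of a group with the given pKa that is protonated at pH."""
    ph = np.asarray(ph, dtype=float)
    out = 1.0 / (1.0 + 10.0 ** (ph - pka))
    return float(out) if out.ndim == 0 else out


def unprotonated_fraction(pka: float, ph) -> np.ndarray | float:
    ph = np.asarray(ph, dtype=float)
    out = 1.0 / (1.0 + 10.0 ** (pka - ph))
    return float(out) if out.ndim == 0 else out


def eval_tn(model: SynthaseStepModel, ph) -> np.ndarray | float:
    """Percent of TDs lacking a synthase-direction step at the given pH."""
    x1 = protonated_fraction(model.pka1, ph)
    y2 = unprotonated_fraction(model.pka2, ph)
    out = model.p1 * np.asarray(x1) + model.p2 * np.asarray(y2)
    return float(out) if out.ndim == 0 else out


def eval_ts(model: SynthaseStepModel, ph) -> np.ndarray | float:
    """Percent of TDs containing a synthase-direction step: 100 - TN."""
    out = 100.0 - np.asarray(eval_tn(model, ph))
    return float(out) if out.ndim == 0 else out


def fit_synthase_model(
    ph_values: Sequence[float],
    tn_percents: Sequence[float],
    min_pka_gap: float = 0.05,
) -> FitResult:
    """Fit TN(pH) = P1*X1 + P2*Y2 by least squares in percent space.

    Parameters are (pka1, gap, p1, f) with pka2 = pka1 + gap (gap >=
    min_pka_gap, enforcing pka1 < pka2) and p2 = f*(100 - p1) with f in
    [0, 1], which keeps 0 <= P1, P2 and P1 + P2 <= 100 throughout.
    """
    ph = np.asarray(ph_values, dtype=float)
    y = np.asarray(tn_percents, dtype=float)
    if ph.size < 5:
        raise ValueError("need at least 5 pH points bracketing the TN minimum")
    if ph.shape != y.shape:
        raise ValueError("ph_values and tn_percents must have matching shape")

    i_min = int(np.argmin(y))
    p1_0 = float(np.clip(y[np.argmin(ph)], 1.0, 99.0))
    p2_0 = float(np.clip(y[np.argmax(ph)], 1.0, 99.0))
    f0 = float(np.clip(p2_0 / max(100.0 - p1_0, 1e-6), 1e-3, 1.0 - 1e-3))
    ph_min = float(ph[i_min])
    x0 = np.array([ph_min - 0.8, 1.6, p1_0, f0])

    def resid(x):
        pka1, gap, p1, f = x
        p2 = f * (100.0 - p1)
        x1 = 1.0 / (1.0 + 10.0 ** (ph - pka1))
        y2 = 1.0 / (1.0 + 10.0 ** ((pka1 + gap) - ph))
        return p1 * x1 + p2 * y2 - y

    sol = least_squares(
        resid,
        x0,
        bounds=(
            [ph.min() - 4.0, min_pka_gap, 0.0, 0.0],
            [ph.max() + 4.0, 6.0, 100.0, 1.0],
        ),
    )
    model = SynthaseStepModel(
        pka1=sol.x[0],
        p1=min(sol.x[2], 100.0),
        pka2=sol.x[0] + sol.x[1],
        p2=float(sol.x[3] * (100.0 - sol.x[2])),
    )
    cov, stderr = _covariance(sol, ("pka1", "gap", "p1", "f"))
    return FitResult(
        params=model,
        stderr=stderr,
        cov=cov,
        residual=float(np.sqrt(np.mean(sol.fun**2))),
        flagged=not sol.success,
        message=sol.message,
    )


# ---------------------------------------------------------------------------
# Efficiency-class mixture
# ---------------------------------------------------------------------------

def fit_three_gaussians(
    counts: Sequence[float],
    bin_edges: Sequence[float] | None = None,
) -> FitResult:
    """Fit a sum of three Gaussians to histogram counts at bin centers.

    Mirrors the figure-style procedure: the fit is to binned counts, not a
    likelihood on raw values. Components are reported sorted by mean with
    weights normalized to unit sum. Multi-start initialization places the
    means at the 25/50/75th percentiles of the binned mass, plus one-bin
    perturbations; the start with the lowest residual wins. A component
    whose sd collapses below a quarter bin width flags the fit.
    """
    counts = np.asarray(counts, dtype=float)
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 100.0, counts.size + 1)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size != counts.size + 1:
        raise ValueError("bin_edges must have len(counts) + 1 entries")
    if int((counts > 0).sum()) < 6:
        raise ValueError("need at least 6 nonempty bins for a 3-component fit")
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_w = float(np.mean(np.diff(edges)))

    # percentiles of the binned mass for initialization
    cdf = np.cumsum(counts) / counts.sum()
    quarts = [float(np.interp(q, cdf, centers)) for q in (0.25, 0.50, 0.75)]
    sd0 = max(1.5 * bin_w, float(np.sqrt(np.cov(centers, aweights=np.maximum(counts, 1e-9)))) / 2.0)
    amp0 = counts.max()

    def make_resid(k):
        def resid(x):
            model = np.zeros_like(centers)
            for i in range(k):
                a, mu, sd = x[3 * i], x[3 * i + 1], x[3 * i + 2]
                model = model + a * np.exp(-0.5 * ((centers - mu) / sd) ** 2)
            return model - counts
        return resid

    def fit_k(k):
        lo = [0.0, edges[0], bin_w / 8.0] * k
        hi = [10.0 * amp0 + 1.0, edges[-1], (edges[-1] - edges[0])] * k
        idx = {1: [1], 2: [0, 2], 3: [0, 1, 2]}[k]
        best = None
        for jitter in (0.0, -bin_w, bin_w):
            x0 = []
            for i in idx:
                mu = float(np.clip(quarts[i] + jitter, edges[0], edges[-1]))
                x0 += [amp0 / 2.0, mu, sd0]
            sol = least_squares(make_resid(k), np.asarray(x0), bounds=(lo, hi))
            if best is None or sol.cost < best.cost:
                best = sol
        return best

    # The three efficiency classes are a structural hypothesis, so the sum
    # of three Gaussians is fitted outright -- except in the degenerate case
    # where a single component already fits within Poisson counting noise
    # (reduced chi-square <= 2): a 3-component sum is unidentifiable on
    # unimodal data and would split one population arbitrarily. Absent
    # classes are reported with zero weight.
    sigma = np.sqrt(np.maximum(counts, 1.0))
    sol1 = fit_k(1)
    if float(np.mean((sol1.fun / sigma) ** 2)) <= 2.0:
        k_sel, best = 1, sol1
    else:
        k_sel, best = 3, fit_k(3)
    rms = {k_sel: float(np.sqrt(np.mean(best.fun**2)))}

    comps = sorted(
        [(best.x[3 * i], best.x[3 * i + 1], best.x[3 * i + 2]) for i in range(k_sel)],
        key=lambda c: c[1],
    )
    while len(comps) < 3:  # pad absent classes with zero-weight placeholders
        comps.append((0.0, comps[-1][1], bin_w))
    areas = np.array([a * sd for a, _, sd in comps])
    if areas.sum() <= 0:
        weights = np.full(3, 1.0 / 3.0)
    else:
        weights = areas / areas.sum()
    degenerate = any(sd < bin_w / 4.0 for a, _, sd in comps if a > 0)
    mixture = EfficiencyMixture(
        weights=tuple(float(w) for w in weights),
        means=tuple(float(np.clip(mu, 0.0, 100.0)) for _, mu, _ in comps),
        sds=tuple(float(sd) for _, _, sd in comps),
        flagged=degenerate or not best.success,
    )
    return FitResult(
        params=mixture,
        residual=rms[k_sel],
        flagged=mixture.flagged,
        message="degenerate component sd" if degenerate else best.message,
    )


# ---------------------------------------------------------------------------

def _covariance(sol, names):
    """Covariance and standard errors from a least_squares solution."""
    m, n = sol.jac.shape
    dof = max(m - n, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        stderr = {nm: float(np.sqrt(max(cov[i, i], 0.0))) for i, nm in enumerate(names)}
    except np.linalg.LinAlgError:
        cov, stderr = None, {nm: float("nan") for nm in names}
    return cov, stderr
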