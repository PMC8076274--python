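"""Wild vs proto-cereal classification and grain-size structure.

Cereal-type (proto-cereal) Poaceae pollen is identified morphometrically:
a longest axis of at least 40 µm, a large protuberant pore + annulus
(threshold 8 µm by default; 10 µm is the stricter literature variant) and
scabrate-to-verrucate exine sculpturing.  The criteria are conjunctive; a
``size_only`` switch reproduces the one-criterion ≥ 40 µm split used for
size histograms.  An earlier convention (Andersen) puts the size threshold
at 37 µm, available via :meth:`CerealCriteria.andersen`.

The size distribution itself is modelled as a univariate Gaussian mixture
(`GrainSizeMixture`, a statsmodels-style model whose ``fit`` returns a
results object), with the number of modes chosen by BIC — the question
being whether large grains are a distinct population or merely the tail of
the wild-grass mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .errors import PalynError
from .tables import MeasurementTable

WILD = "wild"
PROTO_CEREAL = "proto_cereal"


@dataclass(frozen=True)
class CerealCriteria:
    """Thresholds and policies for the cereal-type decision rule.

    ``missing_policy="size_only_partial"`` (default) classifies grains that
    lack pore or sculpture data on the longest axis alone and flags the
    call as partial; ``"strict"`` classifies such grains wild.
    ``size_only=True`` ignores pore and sculpture entirely (the binary
    split used for size histograms).
    """

    min_longest_axis_um: float = 40.0
    min_pore_annulus_um: float = 8.0
    require_sculpture: frozenset = frozenset({"scabrate", "verrucate"})
    missing_policy: str = "size_only_partial"
    size_only: bool = False

    def __post_init__(self):
        if self.min_longest_axis_um <= 0 or self.min_pore_annulus_um <= 0:
            raise PalynError("criteria thresholds must be > 0")
        if self.missing_policy not in ("size_only_partial", "strict"):
            raise PalynError(f"unknown missing_policy {self.missing_policy!r}")

    @classmethod
    def andersen(cls, **kw) -> "CerealCriteria":
        """The 37 µm size-threshold variant."""
        return cls(min_longest_axis_um=37.0, **kw)

    @classmethod
    def strict_annulus(cls, **kw) -> "CerealCriteria":
        """The 10 µm annulus-threshold variant."""
        return cls(min_pore_annulus_um=10.0, **kw)


def classify_grain(
    longest_axis_um: float,
    pore_annulus_um: float | None = None,
    sculpture: str = "unrecorded",
    criteria: CerealCriteria = CerealCriteria(),
) -> tuple[str, bool]:
    """Classify one grain; returns (class, partial_flag).

    All thresholds are inclusive (≥).  A grain that is measured on every
    criterion and fails any of them is wild (the criteria are a
    conjunction); criteria that could not be evaluated for lack of data
    are handled per ``criteria.missing_policy``.
    """
    if longest_axis_um is None or np.isnan(longest_axis_um):
        raise PalynError("longest axis is required for classification")
    if longest_axis_um < criteria.min_longest_axis_um:
        return WILD, False
    if criteria.size_only:
        return PROTO_CEREAL, False
    partial = False
    pa_missing = pore_annulus_um is None or np.isnan(pore_annulus_um)
    if pa_missing:
        if criteria.missing_policy == "strict":
            return WILD, False
        partial = True
    elif pore_annulus_um < criteria.min_pore_annulus_um:
        return WILD, False
    sc_missing = sculpture in ("unrecorded", None)
    if sc_missing:
        if criteria.missing_policy == "strict":
            return WILD, False
        partial = True
    elif sculpture not in criteria.require_sculpture:
        return WILD, False
    return PROTO_CEREAL, partial


def classify(
    measurements: MeasurementTable, criteria: CerealCriteria = CerealCriteria()
) -> pd.DataFrame:
    """Vectorised classification of a measurement table.

    Returns the measurement rows with ``grain_class`` and ``partial``
    appended.
    """
    df = measurements.data.copy()
    la = df["longest_axis_um"].to_numpy(float)
    pa = df["pore_annulus_um"].to_numpy(float)
    sc = df["sculpture"].to_numpy(object)

    size_ok = la >= criteria.min_longest_axis_um
    if criteria.size_only:
        cereal = size_ok
        partial = np.zeros(len(df), bool)
    else:
        pa_missing = np.isnan(pa)
        pa_ok = ~pa_missing & (pa >= criteria.min_pore_annulus_um)
        sc_missing = sc == "unrecorded"
        sc_ok = np.array([s in criteria.require_sculpture for s in sc])
        if criteria.missing_policy == "strict":
            cereal = size_ok & pa_ok & sc_ok
            partial = np.zeros(len(df), bool)
        else:
            cereal = size_ok & (pa_missing | pa_ok) & (sc_missing | sc_ok)
            partial = cereal & (pa_missing | sc_missing)
    df["grain_class"] = np.where(cereal, PROTO_CEREAL, WILD)
    df["partial"] = partial
    return df


def class_summary(
    measurements: MeasurementTable, criteria: CerealCriteria = CerealCriteria()
) -> pd.DataFrame:
    """Per-class n/mean/min/max for each morphometric variable.

    Classes with no grains are omitted (an empty class carries no
    summary).  Index: (grain_class, variable).
    """
    df = classify(measurements, criteria)
    rows = []
    for cls, sub in df.groupby("grain_class"):
        for var in ("longest_axis_um", "pore_um", "pore_annulus_um"):
            v = sub[var].dropna()
            if v.empty:
                continue
            rows.append({
                "grain_class": cls, "variable": var, "n": len(v),
                "mean": float(v.mean()), "min": float(v.min()),
                "max": float(v.max()),
            })
    return pd.DataFrame(rows).set_index(["grain_class", "variable"])


def size_histogram(
    measurements: MeasurementTable, bin_width_um: float = 2.5
) -> pd.DataFrame:
    """Left-closed, right-open histogram of longest axes, bins aligned at 0.

    Counts conserve the number of grains.
    """
    if bin_width_um <= 0:
        raise PalynError("bin width must be > 0")
    la = measurements.data["longest_axis_um"].to_numpy(float)
    if la.size == 0:
        return pd.DataFrame(columns=["bin_left_um", "bin_right_um", "count"])
    idx = np.floor(la / bin_width_um).astype(int)
    lo, hi = idx.min(), idx.max()
    edges = np.arange(lo, hi + 2) * bin_width_um
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    return pd.DataFrame({
        "bin_left_um": edges[:-1], "bin_right_um": edges[1:], "count": counts,
    })


# ---------------------------------------------------------------------------
# Gaussian-mixture model of the size distribution
# ---------------------------------------------------------------------------

@dataclass
class SizeMixtureResults:
    """Fitted k-component normal mixture of grain diameters.

    Components are sorted by ascending mean; weights sum to 1.
    """

    k: int
    weights: np.ndarray
    means_um: np.ndarray
    sds_um: np.ndarray
    log_likelihood: float
    bic: float
    converged: bool
    n: int

    def summary(self) -> str:
        lines = [
            "Grain-size Gaussian mixture",
            f"  components: {self.k}   n grains: {self.n}",
            f"  log-likelihood: {self.log_likelihood:.3f}   BIC: {self.bic:.3f}"
            f"   converged: {self.converged}",
            "  comp   weight   mean (um)   sd (um)",
        ]
        for i in range(self.k):
            lines.append(f"  {i + 1:>4} {self.weights[i]:>8.3f} "
                         f"{self.means_um[i]:>11.2f} {self.sds_um[i]:>9.2f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"weight": self.weights, "mean_um": self.means_um,
                             "sd_um": self.sds_um})


class GrainSizeMixture:
    """Univariate normal mixture model of pollen longest axes.

    EM-fitted with multiple restarts: one deterministic start from
    quantile-spread component means plus random restarts, all seeded, so a
    given seed reproduces the fit exactly.
    """

    def __init__(self, diameters_um, k: int, *, equal_variance: bool = False,
                 n_restarts: int = 10, max_iter: int = 500,
                 tol: float = 1e-8):
        x = np.asarray(diameters_um, float)
        x = x[~np.isnan(x)]
        if x.size < 10 * k:
            raise PalynError(
                f"need at least {10 * k} grains to fit {k} components"
            )
        self.x = x
        self.k = k
        self.equal_variance = equal_variance
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, seed: int | None = 0) -> SizeMixtureResults:
        X = self.x.reshape(-1, 1)
        cov_type = "tied" if self.equal_variance else "full"
        # deterministic start at quantile-spread means
        q = np.quantile(self.x, (np.arange(self.k) + 0.5) / self.k)
        best = None
        rng = np.random.default_rng(seed)
        for r in range(self.n_restarts):
            gm = GaussianMixture(
                n_components=self.k, covariance_type=cov_type,
                max_iter=self.max_iter, tol=self.tol, n_init=1,
                means_init=q.reshape(-1, 1) if r == 0 else None,
                random_state=int(rng.integers(2**31 - 1)),
            )
            with warnings.catch_warnings():
                # non-convergence is recorded on the results object instead
                warnings.simplefilter("ignore", ConvergenceWarning)
                gm.fit(X)
            ll = gm.score(X) * len(X)
            if best is None or ll > best[0]:
                best = (ll, gm)
        ll, gm = best
        means = gm.means_.ravel()
        if cov_type == "tied":
            sds = np.full(self.k, np.sqrt(gm.covariances_.ravel()[0]))
        else:
            sds = np.sqrt(gm.covariances_.ravel())
        order = np.argsort(means)
        return SizeMixtureResults(
            k=self.k, weights=gm.weights_[order], means_um=means[order],
            sds_um=sds[order], log_likelihood=float(ll),
            bic=float(gm.bic(X)), converged=bool(gm.converged_),
            n=len(self.x),
        )


def fit_size_mixture(
    measurements: MeasurementTable | np.ndarray,
    k_max: int = 4,
    seed: int | None = 0,
    **model_kw,
) -> SizeMixtureResults:
    """Fit mixtures with k = 1..k_max and return the best fit by BIC."""
    if isinstance(measurements, MeasurementTable):
        x = measurements.data["longest_axis_um"].to_numpy(float)
    else:
        x = np.asarray(measurements, float)
    if x.size < 10 * k_max:
        raise PalynError(f"need at least {10 * k_max} grains for k_max={k_max}")
    best = None
    for k in range(1, k_max + 1):
        res = GrainSizeMixture(x, k, **model_kw).fit(seed=seed)
        if best is None or res.bic < best.bic:
            best = res
    return best


def diameter_pore_r2(
    measurements: MeasurementTable, which: str = "pore"
) -> float:
    """R² of ordinary least squares of pore (or pore + annulus) on diameter.

    A value near zero means pore size carries no information about grain
    diameter — i.e. large grains are not simply scaled-up small ones.
    """
    col = {"pore": "pore_um", "pore_annulus": "pore_annulus_um"}.get(which)
    if col is None:
        raise PalynError(f"which must be 'pore' or 'pore_annulus', got {which!r}")
    df = measurements.data[["longest_axis_um", col]].dropna()
    if len(df) < 3:
        raise PalynError("need at least 3 grains with both measurements")
    x = df["longest_axis_um"].to_numpy(float)
    y = df[col].to_numpy(float)
    if np.ptp(x) == 0:
        raise PalynError("zero variance in grain diameter")
    if np.ptp(y) == 0:
        return 0.0
    res = stats.linregress(x, y)
    return float(res.rvalue**2)
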