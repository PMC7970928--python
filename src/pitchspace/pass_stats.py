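"""Per-pass space evaluation and pass-outcome statistics.

Each pass is scored by the state of its end point x_e at the moment t_o the
pass is made: the safety z1(x_e, t_o) and sparsity z2(x_e, t_o) of the end
location, plus the formation-relative distance R~. Across many passes the
outcome q (1 success, 0 failure) is modelled three ways:

* class-conditional normal fits of z1 given q (maximum likelihood, ddof=0);
* an empirical success curve, the mean of q in bins of z1;
* a logistic model P(q=1 | z1) = 1 / (1 + exp(-(a z1 + b))) fitted by
  maximum likelihood (default) or by least squares on the binned curve.

When the two class-conditional normals share a standard deviation, Bayes'
rule collapses the posterior P(q=1 | z1) exactly onto the logistic form with
a = (mu1 - mu0) / sigma^2 and b = -(mu1^2 - mu0^2) / (2 sigma^2) + log-odds
of the prior; with unequal sigmas the exact posterior is quadratic in z1,
which is why an empirical success curve can deviate from the best sigmoid in
one tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import json

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit

from .errors import NumericalError, ValidationError
from .formation import FRAME_TOL, r_tilde
from .motion_model import MotionParams
from .space_field import team_min_arrival, z_transform
from .tracking_io import PassEvent, Snapshot, nearest_snapshot, other_side

DEFAULT_Z1_BIN = 0.1
DEFAULT_MIN_COUNT = 30


@dataclass(frozen=True)
class PassFeature:
    """Derived evaluation of one pass: (z1, z2, R~) at (x_e, t_o) plus outcome."""

    z1: float
    z2: float
    r_tilde: float
    q: int
    pre_shot: bool = False


@dataclass(frozen=True)
class NormalFit:
    """Class-conditional normal parameters of z1 for successes (1) and failures (0)."""

    mu1: float
    sigma1: float
    mu0: float
    sigma0: float
    n1: int
    n0: int


@dataclass(frozen=True)
class SigmoidFit:
    """Logistic model of pass success on z1: P(q=1|z1) = expit(a z1 + b)."""

    a: float
    b: float
    se_a: float
    se_b: float
    n: int
    method: str = "mle"

    def predict(self, z1) -> np.ndarray:
        return expit(self.a * np.asarray(z1, dtype=float) + self.b)


@dataclass(frozen=True)
class BayesSigmoid:
    """Posterior derived from class-conditional normals via Bayes' rule.

    ``applicable`` is True only when the class sigmas agree, in which case the
    posterior is exactly logistic with coefficients (a, b). Otherwise a and b
    are None and ``posterior`` carries the exact quadratic-discriminant form.
    """

    applicable: bool
    a: float | None
    b: float | None
    posterior: Callable[[np.ndarray], np.ndarray]
    note: str


def evaluate_pass(
    pass_event: PassEvent,
    snapshot: Snapshot,
    params: MotionParams | None = None,
    *,
    include_goalkeepers: bool = True,
) -> PassFeature:
    """Score one pass from the snapshot at its origin time.

    The offense team is the pass record's possession side (falling back to the
    snapshot's); tau_of and tau_df are team minimum arrival times to x_e.
    """
    params = params or MotionParams()
    if abs(snapshot.time - pass_event.t_o) > FRAME_TOL + 1e-9:
        raise ValidationError(
            f"no snapshot within {FRAME_TOL} s of pass origin t_o={pass_event.t_o} "
            f"(got t={snapshot.time})"
        )
    offense = pass_event.possession or snapshot.possession
    if offense is None:
        raise ValidationError("pass and snapshot both lack a possession label")
    if (
        pass_event.possession is not None
        and snapshot.possession is not None
        and pass_event.possession != snapshot.possession
    ):
        raise ValidationError(
            f"pass possession {pass_event.possession!r} disagrees with snapshot "
            f"possession {snapshot.possession!r} at t={snapshot.time}"
        )
    tau_of = team_min_arrival(
        snapshot, offense, pass_event.x_e, params, include_goalkeepers=include_goalkeepers
    )
    tau_df = team_min_arrival(
        snapshot, other_side(offense), pass_event.x_e, params,
        include_goalkeepers=include_goalkeepers,
    )
    z1, z2 = z_transform(tau_of, tau_df)
    return PassFeature(
        z1=z1,
        z2=z2,
        r_tilde=r_tilde(pass_event, snapshot),
        q=pass_event.q,
        pre_shot=pass_event.pre_shot,
    )


def evaluate_passes(
    passes: Sequence[PassEvent],
    snapshots: Sequence[Snapshot],
    params: MotionParams | None = None,
    **kwargs,
) -> list[PassFeature]:
    """Score a batch of passes against their nearest snapshots."""
    return [
        evaluate_pass(p, nearest_snapshot(snapshots, p.t_o), params, **kwargs)
        for p in passes
    ]


def _z1_q(features) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(features, pd.DataFrame):
        z1 = features["z1"].to_numpy(dtype=float)
        q = features["q"].to_numpy()
    else:
        z1 = np.array([f.z1 for f in features], dtype=float)
        q = np.array([f.q for f in features])
    if len(z1) == 0:
        raise ValidationError("no pass features provided")
    if not np.isin(q, (0, 1)).all():
        raise ValidationError("pass outcomes must be 0 or 1")
    return z1, q.astype(int)


def fit_class_normals(features) -> NormalFit:
    """Maximum-likelihood normal fit of z1 within each outcome class (ddof=0)."""
    z1, q = _z1_q(features)
    out = {}
    for label in (1, 0):
        vals = z1[q == label]
        if len(vals) < 2:
            raise ValidationError(
                f"outcome class q={label} has {len(vals)} samples; need >= 2"
            )
        mu = float(vals.mean())
        sigma = float(vals.std(ddof=0))
        if sigma == 0:
            raise ValidationError(f"outcome class q={label} has zero variance")
        out[label] = (mu, sigma, len(vals))
    return NormalFit(
        mu1=out[1][0], sigma1=out[1][1], mu0=out[0][0], sigma0=out[0][1],
        n1=out[1][2], n0=out[0][2],
    )


def empirical_success_curve(
    features,
    bin_width: float = DEFAULT_Z1_BIN,
    min_count: int = DEFAULT_MIN_COUNT,
) -> pd.DataFrame:
    """Mean outcome per z1 bin; bins with fewer than ``min_count`` passes are dropped.

    Returns columns ``z1_bin_center, success_fraction, n``.
    """
    if bin_width <= 0:
        raise ValidationError(f"bin width must be positive, got {bin_width}")
    z1, q = _z1_q(features)
    idx = np.floor(z1 / bin_width).astype(int)
    grouped = (
        pd.DataFrame({"idx": idx, "q": q}).groupby("idx")["q"].agg(["mean", "size"]).reset_index()
    )
    grouped = grouped[grouped["size"] >= min_count]
    return pd.DataFrame(
        {
            "z1_bin_center": (grouped["idx"] + 0.5) * bin_width,
            "success_fraction": grouped["mean"],
            "n": grouped["size"].astype(int),
        }
    ).reset_index(drop=True)


def _check_separation(z1: np.ndarray, q: np.ndarray) -> None:
    z_pos, z_neg = z1[q == 1], z1[q == 0]
    if len(z_pos) == 0 or len(z_neg) == 0:
        raise ValidationError("both outcome classes must be present to fit a sigmoid")
    if z_neg.max() < z_pos.min() or z_pos.max() < z_neg.min():
        raise NumericalError(
            "perfect separation: a z1 threshold splits successes from failures "
            f"(failed z1 in [{z_neg.min():.3g}, {z_neg.max():.3g}], successful in "
            f"[{z_pos.min():.3g}, {z_pos.max():.3g}]); the logistic MLE diverges"
        )


def fit_sigmoid(
    features,
    *,
    method: str = "mle",
    bin_width: float = DEFAULT_Z1_BIN,
    min_count: int = DEFAULT_MIN_COUNT,
) -> SigmoidFit:
    """Fit P(q=1|z1) = expit(a z1 + b).

    ``method='mle'`` (default) is a maximum-likelihood logistic regression of
    the raw (z1, q) pairs solved by Newton iteration. ``method='binned'``
    instead least-squares fits the sigmoid to the empirical success curve,
    weighting each bin by its binomial standard error; it is provided for
    comparison with curve-level fitting.
    """
    z1, q = _z1_q(features)
    _check_separation(z1, q)
    if method == "mle":
        design = sm.add_constant(z1)
        try:
            res = sm.Logit(q, design).fit(method="newton", disp=0, tol=1e-10, maxiter=200)
        except Exception as err:  # statsmodels raises on hopeless fits
            raise NumericalError(f"logistic MLE failed to converge: {err}") from err
        b, a = res.params
        se_b, se_a = res.bse
        return SigmoidFit(a=float(a), b=float(b), se_a=float(se_a), se_b=float(se_b),
                          n=len(q), method="mle")
    if method == "binned":
        curve = empirical_success_curve(features, bin_width, min_count)
        if len(curve) < 3:
            raise ValidationError(
                f"binned fit needs >= 3 populated bins, got {len(curve)}"
            )
        x = curve["z1_bin_center"].to_numpy()
        p = curve["success_fraction"].to_numpy()
        n = curve["n"].to_numpy()
        sig = np.sqrt(np.clip(p * (1 - p), 1e-4, None) / n)

        def model(z, a, b):
            return expit(a * z + b)

        try:
            popt, pcov = optimize.curve_fit(model, x, p, p0=(1.0, 0.0), sigma=sig,
                                            absolute_sigma=True, maxfev=10000)
        except RuntimeError as err:
            raise NumericalError(f"binned sigmoid fit failed: {err}") from err
        se = np.sqrt(np.diag(pcov))
        return SigmoidFit(a=float(popt[0]), b=float(popt[1]), se_a=float(se[0]),
                          se_b=float(se[1]), n=int(n.sum()), method="binned")
    raise ValidationError(f"unknown sigmoid fit method {method!r}")


def bayes_sigmoid_from_normals(
    fit: NormalFit,
    prior1: float | None = None,
    *,
    rtol: float = 1e-6,
) -> BayesSigmoid:
    """Posterior success probability implied by the class-conditional normals.

    With equal class sigmas the posterior is exactly the logistic model and
    (a, b) are returned in closed form; otherwise the log-odds are quadratic
    in z1 and the reduction is flagged inapplicable, with the exact posterior
    returned as a callable. The default prior is the empirical success
    fraction n1 / (n1 + n0).
    """
    if prior1 is None:
        prior1 = fit.n1 / (fit.n1 + fit.n0)
    if not (0.0 < prior1 < 1.0):
        raise ValidationError(f"prior success probability must be in (0, 1), got {prior1}")
    log_odds_prior = float(np.log(prior1 / (1.0 - prior1)))

    def posterior(z1):
        z1 = np.asarray(z1, dtype=float)
        h = (
            stats.norm.logpdf(z1, fit.mu1, fit.sigma1)
            - stats.norm.logpdf(z1, fit.mu0, fit.sigma0)
            + log_odds_prior
        )
        return expit(h)

    if abs(fit.sigma1 - fit.sigma0) <= rtol * max(fit.sigma1, fit.sigma0):
        sigma2 = ((fit.sigma1 + fit.sigma0) / 2.0) ** 2
        a = (fit.mu1 - fit.mu0) / sigma2
        b = -(fit.mu1**2 - fit.mu0**2) / (2.0 * sigma2) + log_odds_prior
        return BayesSigmoid(
            applicable=True, a=float(a), b=float(b), posterior=posterior,
            note="equal class sigmas: posterior is exactly logistic in z1",
        )
    return BayesSigmoid(
        applicable=False, a=None, b=None, posterior=posterior,
        note=(
            f"sigma1={fit.sigma1:.4g} != sigma0={fit.sigma0:.4g}: the posterior "
            "log-odds are quadratic in z1, so the pure sigmoid reduction does not "
            "apply; deviations from a fitted sigmoid in one tail are expected"
        ),
    )


def filter_pre_shot(features):
    """Subset of features flagged as occurring just before a shot."""
    if isinstance(features, pd.DataFrame):
        if "pre_shot" not in features.columns:
            raise ValidationError("features table has no pre_shot column")
        return features[features["pre_shot"].astype(bool)].reset_index(drop=True)
    return [f for f in features if f.pre_shot]


def write_fits(path: str | Path, normal_fit: NormalFit, sigmoid_fit: SigmoidFit) -> None:
    """Write the combined fit summary as JSON."""
    payload = {
        "mu1": normal_fit.mu1,
        "sigma1": normal_fit.sigma1,
        "mu0": normal_fit.mu0,
        "sigma0": normal_fit.sigma0,
        "n1": normal_fit.n1,
        "n0": normal_fit.n0,
        "a": sigmoid_fit.a,
        "b": sigmoid_fit.b,
        "se_a": sigmoid_fit.se_a,
        "se_b": sigmoid_fit.se_b,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
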