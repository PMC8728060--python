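"""Converting outlier scores into CNV/normal labels.

The primary labeler is a two-component variational Bayesian Gaussian
mixture (VBGMM) fitted to the 1-D score vector S.  Each component m has a
mixing coefficient alpha_m (point-maximized each iteration as the mean
responsibility), a Gaussian posterior over its mean, and a Gamma posterior
over its precision; coordinate-ascent variational inference maximizes the
evidence lower bound (ELBO), which is monotonically nondecreasing across
sweeps.  The variance posteriors are kept away from zero by the prior, so
no component can collapse onto a single score the way maximum-likelihood
EM can.  Scores are assigned to the component with the larger
responsibility; the component with the larger posterior mean score is the
CNV component, since CNV segments have unusually large neighbor distances.

Plain maximum-likelihood GMM, a boxplot upper fence, and a top-n cutoff are
provided as baseline strategies for ablation studies.

Priors are weakly informative and data-scaled: the mean prior is centered
at the sample mean with the sample variance as spread, and the precision
prior is Gamma with 1/2 shape and sample-variance/2 rate (a 1-D Wishart
with one degree of freedom and scale equal to the inverse sample variance).
Because every prior scales with the data, the labels are invariant to
positive affine transforms of S.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class VBGMMFit:
    """Variational posterior state of a fitted 1-D Gaussian mixture.

    ``mu_mean``/``mu_var`` are the Gaussian hyperposterior location and
    spread per component mean; ``tau_shape``/``tau_rate`` the Gamma
    hyperposterior over each component's precision.  ``variances`` reports
    1 / E[tau].  ``elbo_trace`` holds the ELBO after every sweep.
    """

    n_components: int
    alphas: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    responsibilities: np.ndarray
    mu_mean: np.ndarray
    mu_var: np.ndarray
    tau_shape: np.ndarray
    tau_rate: np.ndarray
    elbo_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


@dataclass
class LabelVector:
    """Per-segment cluster index, binary CNV flag, and the CNV component id."""

    labels: np.ndarray
    is_cnv: np.ndarray
    cnv_component: int
    method: str = "vbgmm"


def _kmeanspp_centers(s: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding in 1-D: D^2-proportional center sampling."""
    centers = [s[rng.integers(len(s))]]
    for _ in range(m - 1):
        d2 = np.min((s[:, None] - np.asarray(centers)[None, :]) ** 2, axis=1)
        tot = d2.sum()
        if tot == 0:
            centers.append(s[rng.integers(len(s))])
        else:
            centers.append(s[rng.choice(len(s), p=d2 / tot)])
    return np.asarray(centers)


def _init_responsibilities(
    s: np.ndarray, m: int, rng: np.random.Generator, smoothing: float = 1e-3
) -> np.ndarray:
    centers = _kmeanspp_centers(s, m, rng)
    nearest = np.argmin(np.abs(s[:, None] - centers[None, :]), axis=1)
    h = np.full((len(s), m), smoothing)
    h[np.arange(len(s)), nearest] = 1.0
    return h / h.sum(axis=1, keepdims=True)


def _elbo(s, h, log_alpha, b0, s0sq, a0, r0, bm, s2m, am, betam):
    """Exact evidence lower bound for the current variational state."""
    et = am / betam  # E[tau]
    elt = digamma(am) - np.log(betam)  # E[log tau]
    sq = (s[:, None] - bm[None, :]) ** 2 + s2m[None, :]  # E[(s_i - mu_m)^2]
    ll = 0.5 * np.sum(h * (elt[None, :] - LOG2PI - et[None, :] * sq))
    lz = np.sum(h * log_alpha[None, :])
    lmu = np.sum(-0.5 * np.log(2 * np.pi * s0sq) - ((bm - b0) ** 2 + s2m) / (2 * s0sq))
    ltau = np.sum(a0 * np.log(r0) - gammaln(a0) + (a0 - 1) * elt - r0 * et)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_z = -np.sum(np.where(h > 0, h * np.log(h), 0.0))
    ent_mu = np.sum(0.5 * (np.log(2 * np.pi * s2m) + 1.0))
    ent_tau = np.sum(am - np.log(betam) + gammaln(am) + (1 - am) * digamma(am))
    return ll + lz + lmu + ltau + ent_z + ent_mu + ent_tau


def _cavi(s, h, b0, s0sq, a0, r0, max_iter, tol):
    n, m = h.shape
    alphas = h.mean(axis=0)
    # initial moment-matched posteriors from the seeded responsibilities
    bm = np.full(m, b0)
    s2m = np.full(m, s0sq)
    am = np.full(m, a0)
    betam = np.full(m, r0)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # q(mu): Gaussian with precision = prior precision + N_m E[tau_m]
        et = am / betam
        nm = h.sum(axis=0)
        prec = 1.0 / s0sq + nm * et
        bm = (b0 / s0sq + et * (h * s[:, None]).sum(axis=0)) / prec
        s2m = 1.0 / prec
        # q(tau): Gamma, rate absorbs expected squared deviations
        sq = (s[:, None] - bm[None, :]) ** 2 + s2m[None, :]
        am = a0 + 0.5 * nm
        betam = r0 + 0.5 * (h * sq).sum(axis=0)
        # q(Z): responsibilities from current expected log densities
        et = am / betam
        elt = digamma(am) - np.log(betam)
        log_alpha = np.log(np.clip(alphas, 1e-300, None))
        sq = (s[:, None] - bm[None, :]) ** 2 + s2m[None, :]
        logrho = log_alpha[None, :] + 0.5 * (elt[None, :] - LOG2PI) - 0.5 * (
            am / betam
        )[None, :] * sq
        h = np.exp(logrho - logsumexp(logrho, axis=1, keepdims=True))
        # mixing coefficients: ELBO-maximizing point estimate
        alphas = h.mean(axis=0)
        log_alpha = np.log(np.clip(alphas, 1e-300, None))
        trace.append(float(_elbo(s, h, log_alpha, b0, s0sq, a0, r0, bm, s2m, am, betam)))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    return h, alphas, bm, s2m, am, betam, trace, converged, it


def fit_vbgmm(
    scores: np.ndarray,
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 3,
    seed: int | np.random.Generator = 0,
) -> VBGMMFit:
    """Fit a 1-D variational Bayesian Gaussian mixture to the score vector.

    Runs ``n_restarts`` coordinate-ascent fits from k-means++-seeded
    responsibilities and keeps the one with the best final ELBO.  The fit
    is deterministic for a fixed seed.  Non-convergence within ``max_iter``
    sweeps returns the best state found with ``converged=False`` and a
    warning.
    """
    s = np.asarray(getattr(scores, "scores", scores), dtype=float).ravel()
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n = len(s)
    if n < n_components:
        raise ValueError(f"need at least {n_components} scores, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    b0 = s.mean()
    var = s.var()
    s0sq = max(var, 1e-10 * max(1.0, b0 * b0), 1e-12)
    a0 = 0.5  # one degree of freedom
    r0 = s0sq / 2.0  # scale = inverse sample variance

    best: VBGMMFit | None = None
    for _ in range(n_restarts):
        h0 = _init_responsibilities(s, n_components, rng)
        h, alphas, bm, s2m, am, betam, trace, converged, it = _cavi(
            s, h0, b0, s0sq, a0, r0, max_iter, tol
        )
        fit = VBGMMFit(
            n_components=n_components,
            alphas=alphas,
            means=bm,
            variances=betam / am,
            responsibilities=h,
            mu_mean=bm,
            mu_var=s2m,
            tau_shape=am,
            tau_rate=betam,
            elbo_trace=trace,
            converged=converged,
            n_iter=it,
        )
        if best is None or fit.elbo_trace[-1] > best.elbo_trace[-1]:
            best = fit
    assert best is not None
    if not best.converged:
        warnings.warn(
            f"VBGMM did not converge in {max_iter} iterations; "
            "returning best state found",
            RuntimeWarning,
        )
    return best


def select_cnv_component(fit: VBGMMFit, scores: np.ndarray) -> int:
    """Identify the outlier (CNV) component of a two-component fit.

    The component whose members have the larger responsibility-weighted
    mean score is the CNV component.  If the means coincide, the
    lower-weight component is chosen (outliers are the minority) with a
    warning; a CNV weight above 0.5 is also flagged.
    """
    if fit.n_components != 2:
        raise ValueError("CNV component selection expects a 2-component fit")
    s = np.asarray(getattr(scores, "scores", scores), dtype=float).ravel()
    w = fit.responsibilities.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        member_means = np.where(
            w > 0, (fit.responsibilities * s[:, None]).sum(axis=0) / w, -np.inf
        )
    if member_means[0] == member_means[1]:
        comp = int(np.argmin(fit.alphas))
        log.warning("component score means coincide; choosing lower-weight component")
    else:
        comp = int(np.argmax(member_means))
    if fit.alphas[comp] > 0.5:
        log.warning(
            "CNV component carries weight %.3f > 0.5; outliers are expected "
            "to be the minority",
            fit.alphas[comp],
        )
    return comp


def assign_labels(fit: VBGMMFit, scores: np.ndarray | None = None) -> LabelVector:
    """Hard labels from responsibilities: lambda_i = argmax_m h_im.

    Ties break toward the lower component index.  ``scores`` are needed to
    orient which component is the CNV one; if omitted the posterior
    component means are used.
    """
    labels = np.argmax(fit.responsibilities, axis=1)
    if scores is not None:
        comp = select_cnv_component(fit, scores)
    else:
        comp = int(np.argmax(fit.means))
    return LabelVector(
        labels=labels, is_cnv=labels == comp, cnv_component=comp, method="vbgmm"
    )


def _gmm_labels(s: np.ndarray, seed: int) -> LabelVector:
    gm = GaussianMixture(
        n_components=2, n_init=3, random_state=seed, reg_covar=1e-10
    ).fit(s[:, None])
    h = gm.predict_proba(s[:, None])
    labels = np.argmax(h, axis=1)
    w = h.sum(axis=0)
    member_means = np.where(w > 0, (h * s[:, None]).sum(axis=0) / w, -np.inf)
    comp = int(np.argmax(member_means))
    return LabelVector(labels, labels == comp, comp, method="gmm")


def boxplot_flags(s: np.ndarray, whisker: float = 0.75) -> np.ndarray:
    """Scores beyond the boxplot upper fence Q3 + whisker * IQR."""
    q1, q3 = np.percentile(s, [25, 75])
    return s > q3 + whisker * (q3 - q1)


def top_n_flags(s: np.ndarray, n: int) -> np.ndarray:
    """Flag the n largest scores (descending order, ties by ascending index)."""
    order = np.argsort(-s, kind="stable")
    flags = np.zeros(len(s), dtype=bool)
    flags[order[:n]] = True
    return flags


def baseline_labelers(
    scores: np.ndarray,
    strategy: str,
    whisker: float = 0.75,
    n: int | None = None,
    frac: float | None = None,
    seed: int = 0,
) -> LabelVector:
    """Threshold-selection baselines: plain ML GMM, boxplot fence, or top-n.

    For ``top_n`` pass either an absolute ``n`` or a fraction ``frac`` of
    the vector length (n = floor(frac * N)).
    """
    s = np.asarray(getattr(scores, "scores", scores), dtype=float).ravel()
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if strategy == "gmm":
        return _gmm_labels(s, seed)
    if strategy == "boxplot":
        flags = boxplot_flags(s, whisker)
        return LabelVector(flags.astype(int), flags, 1, method="boxplot")
    if strategy == "top_n":
        if n is None:
            if frac is None:
                raise ValueError("top_n needs n or frac")
            n = int(np.floor(frac * len(s)))
        flags = top_n_flags(s, n)
        return LabelVector(flags.astype(int), flags, 1, method="top_n")
    raise ValueError(f"unknown strategy {strategy!r}")
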