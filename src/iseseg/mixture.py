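"""Finite-mixture decomposition of one-dimensional fluorescence samples.

A propidium-iodide flow-cytometry sample of haploid males (plus diploid
females as internal standard) produces a fluorescence-area histogram
with one peak per male genome-size class, a female peak, and a debris
background.  This module fits a finite mixture of skew-normal (or
normal) components to the raw event vector by EM, selects the component
count g in [g_min, g_max] by BIC, maps components onto the expected
class positions derived from the clone's karyotype, merges components
that land on the same class (weights summed, location
weight-averaged), discards background components, and renormalises the
class proportions to one.

The EM for the skew-normal family uses the standard convolution
representation X = xi + Delta*|t| + e with t ~ N(0,1) truncated to
(0, inf) and e ~ N(0, Gamma), giving closed-form conditional moments of
t and exact M-step updates.  Initialisation is a deterministic quantile
split of the sorted events so that identical inputs give identical
fits; seeded random restarts are used only to rescue degenerate
components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import special
from scipy import stats as sps

__all__ = [
    "FluorescenceSample",
    "MixtureComponent",
    "MixtureFit",
    "GsClassEstimate",
    "fit_finite_mixture",
    "assign_components_to_classes",
    "renormalize_classes",
    "qc_cv",
    "CV_EXCLUSION_PERCENT",
]

#: Female-peak coefficient-of-variation threshold (%) above which a
#: measurement is excluded from analysis.
CV_EXCLUSION_PERCENT = 3.5

MIN_EVENTS = 200


@dataclass(frozen=True)
class FluorescenceSample:
    """Raw fluorescence-area events for one sample plus metadata."""

    events: np.ndarray
    clone_id: str = ""
    stage: str = ""  # sync | accum | hatched
    female_peak_position: Optional[float] = None
    n_individuals: Optional[int] = None

    def __post_init__(self) -> None:
        e = np.asarray(self.events, dtype=float).ravel()
        object.__setattr__(self, "events", e)
        if e.size and np.any(e <= 0):
            raise ValueError("fluorescence events must be strictly positive")

    @property
    def n_events(self) -> int:
        return int(self.events.size)


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    location: float
    scale: float
    skewness: float = 0.0
    tail_df: Optional[float] = None

    def mean(self) -> float:
        """Component mean (location shifted by the skewness offset)."""
        delta = self.skewness / math.sqrt(1.0 + self.skewness ** 2)
        return self.location + self.scale * delta * math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class MixtureFit:
    components: tuple
    g: int
    bic: float
    loglik: float
    converged: bool
    family: str
    n_iter: int
    n_events: int

    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def locations(self) -> np.ndarray:
        return np.array([c.location for c in self.components])


@dataclass(frozen=True)
class GsClassEstimate:
    """One GS class after component merging (class_k None = background)."""

    class_k: Optional[int]
    proportion: float
    mean_fluorescence: float
    member_component_ids: tuple


# ---------------------------------------------------------------------------
# EM core


def _quantile_init(x: np.ndarray, g: int, family: str) -> dict:
    """Deterministic starting values: g equal-count chunks of sorted data."""
    xs = np.sort(x)
    chunks = np.array_split(xs, g)
    loc = np.array([c.mean() for c in chunks])
    floor = max(x.std() * 1e-3, 1e-12)
    scale = np.array([max(c.std(), floor) for c in chunks])
    if family == "normal":
        lam = np.zeros(g)
    else:
        # a small nonzero start: lambda = 0 is a fixed point of the
        # Delta update, so seed the sign from each chunk's skewness
        lam = np.array(
            [0.5 if sps.skew(c) >= 0 else -0.5 for c in chunks]
        )
    return {"w": np.full(g, 1.0 / g), "xi": loc, "omega": scale, "lam": lam}


def _sn_logpdf(x: np.ndarray, xi, omega, lam) -> np.ndarray:
    """Skew-normal log density, vectorised over components (columns)."""
    z = (x[:, None] - xi[None, :]) / omega[None, :]
    return (
        math.log(2.0)
        - np.log(omega)[None, :]
        + sps.norm.logpdf(z)
        + special.log_ndtr(lam[None, :] * z)
    )


def _em_fit(
    x: np.ndarray,
    g: int,
    family: str,
    tol: float,
    max_iter: int,
    rng: np.random.Generator,
    max_restarts: int = 3,
) -> MixtureFit:
    n = x.size
    state = _quantile_init(x, g, family)
    w, xi, omega, lam = (state[k] for k in ("w", "xi", "omega", "lam"))
    scale_floor = max(x.std() * 1e-3, 1e-12)
    ll_prev = -np.inf
    ll = -np.inf
    converged = False
    restarts = 0
    it = 0

    for it in range(1, max_iter + 1):
        delta = lam / np.sqrt(1.0 + lam ** 2)
        Delta = omega * delta
        Gamma = np.maximum(omega ** 2 * (1.0 - delta ** 2), scale_floor ** 2)

        logp = _sn_logpdf(x, xi, omega, lam) + np.log(w)[None, :]
        lse = special.logsumexp(logp, axis=1)
        ll = float(lse.sum())
        z = np.exp(logp - lse[:, None])

        # conditional moments of the truncated-normal latent t
        denom = Gamma + Delta ** 2
        eta = (x[:, None] - xi[None, :]) * (Delta / denom)[None, :]
        tau = np.sqrt(Gamma / denom)
        r = eta / tau[None, :]
        hazard = np.exp(sps.norm.logpdf(r) - special.log_ndtr(r))
        e1 = eta + tau[None, :] * hazard
        e2 = eta ** 2 + (tau ** 2)[None, :] + eta * tau[None, :] * hazard

        W = z.sum(axis=0)
        if np.any(W < 1e-8 * n):
            # component starved of mass: reseed it at a random event
            if restarts >= max_restarts:
                break
            restarts += 1
            dead = W < 1e-8 * n
            xi = xi.copy()
            xi[dead] = rng.choice(x, size=int(dead.sum()))
            omega = omega.copy()
            omega[dead] = x.std() / g
            lam = lam.copy()
            lam[dead] = 0.0 if family == "normal" else 0.5
            w = np.full(g, 1.0 / g)
            ll_prev = -np.inf
            continue

        w = W / n
        if family == "normal":
            xi = (z * x[:, None]).sum(axis=0) / W
            resid2 = (x[:, None] - xi[None, :]) ** 2
            Gamma = (z * resid2).sum(axis=0) / W
            Gamma = np.maximum(Gamma, scale_floor ** 2)
            omega = np.sqrt(Gamma)
            Delta = np.zeros(g)
            lam = np.zeros(g)
        else:
            xi = (z * (x[:, None] - Delta[None, :] * e1)).sum(axis=0) / W
            dx = x[:, None] - xi[None, :]
            Delta = (z * dx * e1).sum(axis=0) / np.maximum(
                (z * e2).sum(axis=0), 1e-300
            )
            Gamma = (
                z * (dx ** 2 - 2.0 * Delta[None, :] * dx * e1
                     + (Delta ** 2)[None, :] * e2)
            ).sum(axis=0) / W
            Gamma = np.maximum(Gamma, scale_floor ** 2)
            omega = np.sqrt(Gamma + Delta ** 2)
            lam = Delta / np.sqrt(Gamma)

        if ll_prev > -np.inf and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-12):
            converged = True
            break
        ll_prev = ll

    # final log-likelihood with the updated parameters
    logp = _sn_logpdf(x, xi, omega, lam) + np.log(np.maximum(w, 1e-300))[None, :]
    ll = float(special.logsumexp(logp, axis=1).sum())

    n_par = (g - 1) + g * (2 if family == "normal" else 3)
    bic = -2.0 * ll + n_par * math.log(n)
    order = np.argsort(xi)
    comps = tuple(
        MixtureComponent(
            weight=float(w[j]),
            location=float(xi[j]),
            scale=float(omega[j]),
            skewness=float(lam[j]),
        )
        for j in order
    )
    return MixtureFit(
        components=comps,
        g=g,
        bic=float(bic),
        loglik=ll,
        converged=converged,
        family=family,
        n_iter=it,
        n_events=n,
    )


def fit_finite_mixture(
    sample: FluorescenceSample,
    g_min: int = 3,
    g_max: int = 8,
    family: str = "skew_normal",
    tol: float = 1e-5,
    max_iter: int = 1000,
    seed: int = 0,
) -> MixtureFit:
    """Fit mixtures for every g in [g_min, g_max]; return the BIC winner.

    Defaults mirror the search strategy used for these data: the
    component range deliberately exceeds the number of GS classes, since
    extra components absorb background fluorescence and improve class
    resolution; surplus components on one class are merged downstream by
    :func:`assign_components_to_classes`.  EM stops when the relative
    log-likelihood change drops below ``tol`` or after ``max_iter``
    sweeps.  Fits are deterministic: quantile-based initialisation, with
    seeded restarts only if a component degenerates.
    """
    if sample.n_events < MIN_EVENTS:
        raise ValueError(
            f"need at least {MIN_EVENTS} events to fit a mixture, "
            f"got {sample.n_events}"
        )
    if g_min < 1 or g_min > g_max:
        raise ValueError(f"invalid component range [{g_min}, {g_max}]")
    if family == "skew_t":
        raise NotImplementedError(
            "the skew-t family is not implemented; use 'skew_normal' "
            "(the default) or 'normal'"
        )
    if family not in ("skew_normal", "normal"):
        raise ValueError(f"unknown mixture family {family!r}")

    x = sample.events.astype(float)
    best: Optional[MixtureFit] = None
    fits = []
    for g in range(g_min, g_max + 1):
        rng = np.random.default_rng((seed, g))
        fit = _em_fit(x, g, family, tol, max_iter, rng)
        fits.append(fit)
        if np.isfinite(fit.bic) and (best is None or fit.bic < best.bic):
            best = fit
    if best is None:
        details = ", ".join(f"g={f.g}: bic={f.bic}" for f in fits)
        raise RuntimeError(f"no mixture fit converged to a finite BIC ({details})")
    return best


# ---------------------------------------------------------------------------
# component -> GS-class mapping


def assign_components_to_classes(
    fit: MixtureFit,
    expected_positions: Sequence[float],
    window: float = 0.05,
) -> list:
    """Map fitted components onto expected GS-class peak positions.

    ``expected_positions[k]`` is the fluorescence channel where class k
    should peak (male genome size scaled to the female internal
    standard).  A component belongs to the nearest class whose position
    is within a relative ``window`` (default +/-5%); several components
    on one class merge (weights summed, location weight-averaged).
    Components matching no class — or with weight < 0.02 and scale more
    than 3x the median matched-component scale — are labelled background
    (``class_k=None``).  Overlapping class windows mean the classes are
    not resolvable and raise.
    """
    pos = np.asarray(expected_positions, dtype=float)
    if pos.ndim != 1 or pos.size == 0:
        raise ValueError("expected_positions must be a non-empty 1-D vector")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("expected_positions must be strictly increasing")
    if not (0 < window < 1):
        raise ValueError("window must be a fraction in (0, 1)")
    gaps = np.diff(pos)
    overlap = gaps < window * (pos[:-1] + pos[1:])
    if np.any(overlap):
        k = int(np.flatnonzero(overlap)[0])
        raise ValueError(
            f"classes {k} and {k + 1} are closer than twice the matching "
            f"window ({pos[k]:.1f} vs {pos[k + 1]:.1f}); GS classes cannot "
            "be resolved for this karyotype"
        )

    assigned: dict = {}
    background_ids = []
    for cid, comp in enumerate(fit.components):
        rel = np.abs(comp.mean() - pos) / pos
        k = int(np.argmin(rel))
        if rel[k] <= window:
            assigned.setdefault(k, []).append(cid)
        else:
            background_ids.append(cid)

    # low-weight, very broad components are debris even inside a window;
    # the reference scale is a weight-weighted median so a dominant
    # narrow component defines "typical" even among few components
    matched = [fit.components[cid] for ids in assigned.values() for cid in ids]
    if matched:
        order = np.argsort([c.scale for c in matched])
        scales = np.array([matched[i].scale for i in order])
        wts = np.array([matched[i].weight for i in order])
        cum = np.cumsum(wts)
        scale_cut = 3.0 * float(scales[np.searchsorted(cum, 0.5 * cum[-1])])
        for k in list(assigned):
            keep = []
            for cid in assigned[k]:
                c = fit.components[cid]
                if c.weight < 0.02 and c.scale > scale_cut:
                    background_ids.append(cid)
                else:
                    keep.append(cid)
            if keep:
                assigned[k] = keep
            else:
                del assigned[k]

    estimates = []
    for k in sorted(assigned):
        ids = assigned[k]
        wts = np.array([fit.components[c].weight for c in ids])
        locs = np.array([fit.components[c].mean() for c in ids])
        estimates.append(
            GsClassEstimate(
                class_k=k,
                proportion=float(wts.sum()),
                mean_fluorescence=float((wts * locs).sum() / wts.sum()),
                member_component_ids=tuple(ids),
            )
        )
    for cid in sorted(background_ids):
        c = fit.components[cid]
        estimates.append(
            GsClassEstimate(
                class_k=None,
                proportion=c.weight,
                mean_fluorescence=c.mean(),
                member_component_ids=(cid,),
            )
        )
    return estimates


def renormalize_classes(estimates: Sequence[GsClassEstimate]) -> list:
    """Drop background components and rescale proportions to sum to one."""
    real = [e for e in estimates if e.class_k is not None]
    if not real:
        raise ValueError("all components were classified as background")
    total = sum(e.proportion for e in real)
    return [replace(e, proportion=e.proportion / total) for e in real]


def qc_cv(
    sample: FluorescenceSample,
    peak: float,
    window: float = 0.15,
) -> float:
    """Coefficient of variation (%) of the events forming one peak.

    Events within ``peak * (1 +/- window)`` are taken as the peak.  The
    spread is estimated robustly (1.4826 * median absolute deviation,
    which equals the standard deviation for a Gaussian peak) so that
    debris events falling under the peak window do not inflate the
    figure; CV = 100 * robust sd / median.  Samples whose
    female-standard peak exceeds ``CV_EXCLUSION_PERCENT`` should be
    excluded from analysis.
    """
    if peak <= 0:
        raise ValueError("peak position must be positive")
    e = sample.events
    inside = e[(e >= peak * (1 - window)) & (e <= peak * (1 + window))]
    if inside.size < 100:
        raise ValueError(
            f"only {inside.size} events within {window:.0%} of {peak}; "
            "need at least 100 to estimate a peak CV"
        )
    center = float(np.median(inside))
    sigma = 1.4826 * float(np.median(np.abs(inside - center)))
    return float(100.0 * sigma / center)
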