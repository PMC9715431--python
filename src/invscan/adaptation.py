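"""Divergent selection, geographic clines and trait associations.

Three ways an inversion's role in local adaptation is evaluated:

* a two-deme Wright-Fisher simulation with divergent selection and
  migration, run over a grid of deme-specific selection coefficients, and
  summarised as the probability that the inversion reaches an absolute
  allele-frequency difference between demes above 50%;
* maximum-likelihood fitting of sigmoid allele-frequency clines across a
  habitat transect, comparing ten model families (fixed/free frequency
  scaling x none/left/right/mirror/both exponential tails) by AICc;
* an additive linear model of trait on inversion dosage with an optional
  body-size covariate, reporting the effect per allele copy, the percentage
  of variance explained and Bonferroni-corrected p-values.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

# ---------------------------------------------------------------------------
# Two-deme Wright-Fisher simulation
# ---------------------------------------------------------------------------


@dataclass
class WFParams:
    """Two-deme Wright-Fisher parameters (forest / prairie demes).

    Rescaling by ``lam`` divides sizes and times and multiplies m and s,
    keeping Nm and Ns invariant. ``t_intro`` is the number of generations
    simulated after the variant is introduced as a single copy.
    """

    n_forest: float
    n_prairie: float
    m: float  # per-generation migration fraction, both directions
    s_forest: float
    s_prairie: float
    h: float = 0.5
    t_intro: int = 15_000
    intro_pop: str = "forest"
    lam: float = 1.0
    t_split: int = 2_200_000
    #: starting frequency in the introduction deme; None = a single copy,
    #: i.e. 1/(2N) at the simulated (scaled) size. Note single-copy
    #: introduction is itself scale-dependent — the rescaling identity
    #: (matched Ns, Nm, t/N) holds for trajectories from a *matched*
    #: initial frequency, so scaling validations fix init_freq explicitly.
    init_freq: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.m <= 1):
            raise ValueError("m must be in [0, 1]")
        if not (0 <= self.h <= 1):
            raise ValueError("h must be in [0, 1]")
        if self.lam < 1:
            raise ValueError("lam must be >= 1")
        if self.t_intro > self.t_split:
            raise ValueError("t_intro must be <= t_split")


def scale_params(p: WFParams, lam: float, max_scaled_s: float = 1.0) -> WFParams:
    """Rescale sizes/times down and rates up by ``lam`` (Nm, Ns invariant)."""
    if p.m * lam > 1:
        raise ValueError("scaled migration rate exceeds 1")
    if max(abs(p.s_forest), abs(p.s_prairie)) * lam > max_scaled_s:
        raise ValueError("scaled selection coefficient out of bounds")
    return dataclasses.replace(
        p,
        n_forest=p.n_forest / lam,
        n_prairie=p.n_prairie / lam,
        t_intro=int(round(p.t_intro / lam)),
        t_split=int(round(p.t_split / lam)),
        m=p.m * lam,
        s_forest=p.s_forest * lam,
        s_prairie=p.s_prairie * lam,
        lam=p.lam * lam,
    )


def _select(p: np.ndarray, s: float, h: float) -> np.ndarray:
    """Deterministic viability-selection update for allele A with fitnesses
    1+s, 1+hs, 1."""
    w_aa, w_ab = 1.0 + s, 1.0 + h * s
    wbar = p * p * w_aa + 2 * p * (1 - p) * w_ab + (1 - p) ** 2
    return p * (p * w_aa + (1 - p) * w_ab) / wbar


def wf_two_pop_sim(
    params: WFParams, n_reps: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate replicate allele-frequency trajectories; return final
    (forest, prairie) frequencies, shape (n_reps,) each.

    Life cycle each generation: selection -> migration -> binomial drift.
    The variant starts as a single copy (frequency 1/(2N)) in ``intro_pop``
    and is tracked for ``t_intro`` generations; lost replicates end at 0.
    Passing an infinite deme size turns drift off in that deme.
    """
    rng = np.random.default_rng(seed)
    nf, npr = params.n_forest, params.n_prairie
    pf = np.full(n_reps, 0.0)
    pp = np.full(n_reps, 0.0)
    if params.intro_pop == "forest":
        pf[:] = params.init_freq if params.init_freq is not None else 1.0 / (2 * nf)
    else:
        pp[:] = params.init_freq if params.init_freq is not None else 1.0 / (2 * npr)
    two_nf = int(round(2 * nf)) if math.isfinite(nf) else None
    two_np = int(round(2 * npr)) if math.isfinite(npr) else None
    for _ in range(params.t_intro):
        pf = _select(pf, params.s_forest, params.h)
        pp = _select(pp, params.s_prairie, params.h)
        pf, pp = (
            (1 - params.m) * pf + params.m * pp,
            (1 - params.m) * pp + params.m * pf,
        )
        if two_nf is not None:
            pf = rng.binomial(two_nf, pf) / two_nf
        if two_np is not None:
            pp = rng.binomial(two_np, pp) / two_np
    return pf, pp


def prob_freq_diff(
    final_freqs: tuple[np.ndarray, np.ndarray], threshold: float = 0.5
) -> float:
    """Fraction of replicates with |p_forest - p_prairie| > threshold."""
    pf, pp = final_freqs
    if len(pf) == 0:
        raise ValueError("need at least one replicate")
    return float(np.mean(np.abs(np.asarray(pf) - np.asarray(pp)) > threshold))


# ---------------------------------------------------------------------------
# Cline models
# ---------------------------------------------------------------------------

TAIL_FAMILIES = ("none", "left", "right", "mirror", "both")
SCALINGS = ("fixed", "free")


@dataclass
class ClineModel:
    """Sigmoid allele-frequency cline with optional exponential tails.

    Centre sigmoid on the frequency scale g(x) = (1 + tanh(2(x-c)/w)) / 2;
    p(x) = pmin + (pmax-pmin) g(x). Beyond distance delta from the centre a
    tail replaces the sigmoid by an exponential that is continuous at the
    junction, with initial slope tau x the sigmoid slope there (tau in
    [0, 1]; 'mirror' shares one delta/tau on both sides).
    """

    center: float
    width: float
    pmin: float = 0.0
    pmax: float = 1.0
    tails: str = "none"
    delta_l: float = 0.0
    tau_l: float = 1.0
    delta_r: float = 0.0
    tau_r: float = 1.0
    scaling: str = "fixed"

    def __post_init__(self) -> None:
        if not (0 <= self.pmin <= self.pmax <= 1):
            raise ValueError("need 0 <= pmin <= pmax <= 1")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.tails not in TAIL_FAMILIES:
            raise ValueError(f"unknown tail family {self.tails!r}")


def _sigmoid(x: np.ndarray, c: float, w: float) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(2.0 * (x - c) / w))


def _sigmoid_slope(x: float, c: float, w: float) -> float:
    return float(1.0 / (w * np.cosh(2.0 * (x - c) / w) ** 2))


def cline_predict(model: ClineModel, x: np.ndarray | float) -> np.ndarray:
    """Allele frequency at transect position(s) ``x``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    c, w = model.center, model.width
    g = _sigmoid(x, c, w)
    if model.tails in ("left", "mirror", "both"):
        dl, tl = model.delta_l, model.tau_l
        xl = c - dl
        gl = float(_sigmoid(np.array([xl]), c, w)[0])
        if gl > 0:
            k = tl * _sigmoid_slope(xl, c, w) / gl
            left = x < xl
            g[left] = gl * np.exp(k * (x[left] - xl))
    if model.tails in ("right", "mirror", "both"):
        dr = model.delta_l if model.tails == "mirror" else model.delta_r
        tr = model.tau_l if model.tails == "mirror" else model.tau_r
        xr = c + dr
        gr = float(_sigmoid(np.array([xr]), c, w)[0])
        if gr < 1:
            k = tr * _sigmoid_slope(xr, c, w) / (1.0 - gr)
            right = x > xr
            g[right] = 1.0 - (1.0 - gr) * np.exp(-k * (x[right] - xr))
    p = model.pmin + (model.pmax - model.pmin) * g
    return p if p.shape != (1,) else p


def _n_params(scaling: str, tails: str) -> int:
    k = 2 + (2 if scaling == "free" else 0)
    return k + {"none": 0, "left": 2, "right": 2, "mirror": 2, "both": 4}[tails]


def aicc(log_lik: float, k: int, n: int) -> float:
    """AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1); undefined (inf) for n <= k+1."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * log_lik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def cline_log_likelihood(
    model: ClineModel, x: np.ndarray, alt: np.ndarray, n_alleles: np.ndarray
) -> float:
    """Binomial log-likelihood of per-site allele counts under the cline."""
    p = np.clip(cline_predict(model, x), 1e-9, 1 - 1e-9)
    alt = np.asarray(alt, dtype=float)
    n = np.asarray(n_alleles, dtype=float)
    return float(np.sum(alt * np.log(p) + (n - alt) * np.log(1 - p)))


@dataclass
class ClineFit:
    model: ClineModel
    log_lik: float
    k: int
    aicc: float
    family: tuple[str, str]  # (scaling, tails)


def _fit_family(
    x: np.ndarray,
    alt: np.ndarray,
    n_alleles: np.ndarray,
    scaling: str,
    tails: str,
    rng: np.random.Generator,
    n_restarts: int,
) -> ClineFit | None:
    span = float(x.max() - x.min()) or 1.0
    lo_x, hi_x = float(x.min()) - 0.5 * span, float(x.max()) + 0.5 * span

    names = ["center", "width"]
    bounds = [(lo_x, hi_x), (1e-3 * span, 10 * span)]
    if scaling == "free":
        names += ["pmin", "pmax"]
        bounds += [(0.0, 1.0), (0.0, 1.0)]
    if tails in ("left", "mirror", "both"):
        names += ["delta_l", "tau_l"]
        bounds += [(0.0, 3 * span), (1e-3, 1.0)]
    if tails in ("right", "both"):
        names += ["delta_r", "tau_r"]
        bounds += [(0.0, 3 * span), (1e-3, 1.0)]
    k = len(names)
    if len(x) - k - 1 <= 0:
        return None

    def build(theta: np.ndarray) -> ClineModel | None:
        kw = dict(zip(names, theta))
        if kw.get("pmin", 0.0) > kw.get("pmax", 1.0):
            return None
        return ClineModel(scaling=scaling, tails=tails, **kw)

    def nll(theta: np.ndarray) -> float:
        m = build(theta)
        if m is None:
            return 1e10
        return -cline_log_likelihood(m, x, alt, n_alleles)

    best_val, best_theta = np.inf, None
    p_hat = np.asarray(alt, float) / np.asarray(n_alleles, float)
    for r in range(n_restarts):
        theta0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        if r == 0:  # informed start: empirical centre / width / range
            theta0[0] = float(np.interp(0.5, np.clip(p_hat, 0, 1), x))
            theta0[1] = span / 2
            if scaling == "free":
                theta0[2], theta0[3] = float(p_hat.min()), float(p_hat.max())
        res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x
    if best_theta is None:
        return None
    model = build(best_theta)
    ll = -best_val
    return ClineFit(model, ll, k, aicc(ll, k, len(x)), (scaling, tails))


def fit_cline(
    x: np.ndarray,
    alt_counts: np.ndarray,
    n_alleles: np.ndarray,
    families: list[tuple[str, str]] | None = None,
    n_restarts: int = 20,
    seed: int = 0,
) -> tuple[ClineFit, list[ClineFit]]:
    """Fit the ten cline model families by bounded ML; choose by AICc.

    ``x`` are site positions (km), ``alt_counts``/``n_alleles`` per-site
    allele counts. Families with too few sites for AICc are skipped. Ties
    (and near-ties) resolve toward fewer parameters through the sort order.
    Returns (best fit, all fits sorted by AICc).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 sites")
    if families is None:
        families = [(s, t) for s in SCALINGS for t in TAIL_FAMILIES]
    rng = np.random.default_rng(seed)
    fits = []
    for scaling, tails in families:
        f = _fit_family(x, alt_counts, n_alleles, scaling, tails, rng, n_restarts)
        if f is not None:
            fits.append(f)
    if not fits:
        raise ValueError("no family could be fitted (too few sites)")
    fits.sort(key=lambda f: (f.aicc, f.k))
    return fits[0], fits


# ---------------------------------------------------------------------------
# Genotype-phenotype association
# ---------------------------------------------------------------------------


@dataclass
class AssocResult:
    beta: float
    p_raw: float
    p_bonferroni: float
    pve: float  # percent of trait variance explained by genotype
    n: int


def assoc_additive(
    genotypes: np.ndarray,
    trait: np.ndarray,
    covariate: np.ndarray | None = None,
    n_tests: int = 13,
) -> AssocResult:
    """Additive linear model trait ~ genotype (+ covariate).

    Genotype is coded 0/1/2 (missing as NaN or -1, dropped). The genotype
    p-value comes from the sequential analysis-of-variance decomposition
    with genotype entered first (F test against the full-model residual);
    PVE is the genotype sum of squares over the total sum of squares.
    """
    g = np.asarray(genotypes, dtype=float)
    g[g < 0] = np.nan
    y = np.asarray(trait, dtype=float)
    ok = ~np.isnan(g) & ~np.isnan(y)
    cols = [np.ones_like(g), g]
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        ok &= ~np.isnan(cov)
        cols.append(cov)
    X = np.column_stack(cols)[ok]
    y = y[ok]
    n = len(y)
    if n < 3:
        raise ValueError("need >= 3 complete samples")
    if np.all(X[:, 1] == X[0, 1]):
        raise ValueError("constant genotype")
    beta_full, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_full
    rss_full = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    # sequential SS for genotype (entered first after the intercept)
    Xg = X[:, :2]
    bg, _, _, _ = np.linalg.lstsq(Xg, y, rcond=None)
    rss_g = float(np.sum((y - Xg @ bg) ** 2))
    ss_g = sst - rss_g
    df_resid = n - X.shape[1]
    if rss_full <= 0:  # perfect fit
        p_raw = 0.0
    else:
        f = (ss_g / 1.0) / (rss_full / df_resid)
        p_raw = float(stats.f.sf(f, 1, df_resid))
    pve = 100.0 * ss_g / sst if sst > 0 else np.nan
    return AssocResult(
        beta=float(beta_full[1]),
        p_raw=p_raw,
        p_bonferroni=min(1.0, n_tests * p_raw),
        pve=float(pve),
        n=n,
    )
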