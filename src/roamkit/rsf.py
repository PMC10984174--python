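"""Resource selection functions: used/available designs and per-habitat
binomial mixed models.

Habitat use is compared to availability at two third-order scales: a
fixed-radius disc around the owner's home (what the cat could reach from
its doorstep) and the animal's own 100 % MCP home range. For each animal,
``ratio`` available points per used GPS fix are drawn uniformly inside the
boundary by rejection sampling; points falling in excluded land covers
(undifferentiated, water) are dropped from both sets, and availables are
re-drawn so the configured ratio holds exactly.

Selection for each habitat is estimated from a logistic model of the
used/available indicator on a single in-habitat dummy (one model per
habitat — a joint model over exhaustive categories plus an intercept
would not be identifiable), with a per-animal random intercept absorbing
unequal fix counts. The mixed likelihood is maximised with an adaptive
Gauss–Hermite approximation (Laplace-centred nodes); when the
random-intercept variance collapses to the zero boundary the fit matches
plain logistic regression, and a fixed-effects fallback with
cluster-robust standard errors is available. A positive selection
coefficient β means the habitat is used more than its availability
predicts; exp(β) is the relative selection strength.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from shapely.geometry import Point, box
import statsmodels.api as sm

from .config import EXCLUDED_CATEGORIES, RunConfig
from .io import Landscape

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _sample_in_boundary(boundary, landscape: Landscape, n: int,
                        rng: np.random.Generator,
                        max_batches: int = 1000) -> np.ndarray:
    """Uniform points inside boundary ∩ landscape, excluded covers rejected."""
    xmin, ymin, xmax, ymax = boundary.bounds
    ext = box(*landscape.extent)
    excl_idx = {landscape.categories.index(c) for c in EXCLUDED_CATEGORIES}
    out = []
    got = 0
    from shapely import contains_xy
    for _ in range(max_batches):
        if got >= n:
            break
        m = max(4 * (n - got), 256)
        xs = rng.uniform(xmin, xmax, m)
        ys = rng.uniform(ymin, ymax, m)
        ok = contains_xy(boundary, xs, ys) & contains_xy(ext, xs, ys)
        xs, ys = xs[ok], ys[ok]
        if len(xs) == 0:
            continue
        cat = landscape.category_index_at(xs, ys)
        keep = ~np.isin(cat, list(excl_idx))
        xs, ys = xs[keep], ys[keep]
        take = min(len(xs), n - got)
        out.append(np.column_stack([xs[:take], ys[:take]]))
        got += take
    if got < n:
        raise ValueError(
            "boundary has essentially zero usable area after exclusions"
        )
    return np.concatenate(out)


def build_design(fixes: pd.DataFrame, boundaries: dict[str, object],
                 landscape: Landscape, ratio: int, seed: int,
                 scale: str) -> pd.DataFrame:
    """Used/available point table at one spatial scale.

    ``boundaries`` maps animal id → shapely polygon (MCP or owner disc).
    Used fixes outside the boundary, and any point in an excluded land
    cover, are dropped; availables are drawn until the available:used
    ratio holds exactly per animal. Deterministic for a seed.
    """
    rng = np.random.default_rng(seed)
    from shapely import contains_xy
    rows = []
    for animal, traj in fixes.groupby("animal_id", sort=True):
        if animal not in boundaries:
            continue
        boundary = boundaries[animal]
        xs = traj["x"].to_numpy(float)
        ys = traj["y"].to_numpy(float)
        # fixes with no land-cover coverage cannot enter the design
        exmin, eymin, exmax, eymax = landscape.extent
        in_ext = ((xs >= exmin) & (xs < exmax)
                  & (ys >= eymin) & (ys < eymax))
        if not in_ext.all():
            logger.warning("animal %s: %d fix(es) outside the landscape "
                           "extent skipped", animal, int((~in_ext).sum()))
            xs, ys = xs[in_ext], ys[in_ext]
        inside = contains_xy(boundary, xs, ys)
        # closed boundary: include points exactly on the edge
        edge = ~inside
        if edge.any():
            dist = np.array([boundary.exterior.distance(Point(x, y))
                             if not i else 0.0
                             for x, y, i in zip(xs, ys, inside)])
            inside |= edge & (dist <= 1e-9)
        xs, ys = xs[inside], ys[inside]
        if len(xs) == 0:
            logger.warning("animal %s: no fixes inside the %s boundary",
                           animal, scale)
            continue
        cats = np.asarray(landscape.category_at(xs, ys), dtype=object)
        keep = ~np.isin(cats, list(EXCLUDED_CATEGORIES))
        xs, ys, cats = xs[keep], ys[keep], cats[keep]
        n_used = len(xs)
        if n_used == 0:
            logger.warning("animal %s: all fixes in excluded covers", animal)
            continue
        try:
            avail = _sample_in_boundary(boundary, landscape,
                                        ratio * n_used, rng)
        except ValueError:
            logger.warning("animal %s dropped: unusable %s boundary",
                           animal, scale)
            continue
        acats = np.asarray(
            landscape.category_at(avail[:, 0], avail[:, 1]), dtype=object)
        for x, y, c in zip(xs, ys, cats):
            rows.append((animal, x, y, 1, c, scale))
        for (x, y), c in zip(avail, acats):
            rows.append((animal, x, y, 0, c, scale))
    return pd.DataFrame(
        rows, columns=["animal_id", "x", "y", "used", "habitat", "scale"])


# ---------------------------------------------------------------------------
# Random-intercept logistic regression (adaptive Gauss–Hermite ML)
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(15)


def _group_loglik(y, x, beta0, beta1, sigma):
    """Marginal log-likelihood of one animal's points, integrating the
    random intercept with Laplace-centred Gauss–Hermite quadrature."""
    eta0 = beta0 + beta1 * x

    def cond_ll(b):
        eta = eta0 + b
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    if sigma < 1e-8:
        return cond_ll(0.0)

    # Newton to the conditional mode
    b = 0.0
    for _ in range(30):
        p = 1.0 / (1.0 + np.exp(-(eta0 + b)))
        g = float(np.sum(y - p)) - b / sigma**2
        h = float(np.sum(p * (1 - p))) + 1.0 / sigma**2
        step = g / h
        b += step
        if abs(step) < 1e-10:
            break
    h = float(np.sum(p * (1 - p))) + 1.0 / sigma**2
    s = math.sqrt(2.0 / h)
    nodes = b + s * _GH_NODES
    vals = np.array([
        cond_ll(t) - t * t / (2 * sigma**2) + u * u
        for t, u in zip(nodes, _GH_NODES)
    ])
    log_prior_norm = -0.5 * math.log(2 * math.pi * sigma**2)
    mx = vals.max()
    integral = float(np.sum(_GH_WEIGHTS * np.exp(vals - mx)))
    return mx + math.log(integral) + math.log(s) + log_prior_norm


def _mixed_logit_negll(theta, groups):
    beta0, beta1, log_sigma = theta
    sigma = math.exp(log_sigma)
    return -sum(_group_loglik(y, x, beta0, beta1, sigma) for y, x in groups)


def _numeric_hessian(f, x0, eps=1e-4):
    n = len(x0)
    h = np.zeros((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            xpp = np.array(x0); xpp[i] += eps; xpp[j] += eps
            xpm = np.array(x0); xpm[i] += eps; xpm[j] -= eps
            xmp = np.array(x0); xmp[i] -= eps; xmp[j] += eps
            xmm = np.array(x0); xmm[i] -= eps; xmm[j] -= eps
            h[i, j] = h[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                4 * eps * eps)
    return h


@dataclass
class SelectionResult:
    habitat: str
    beta: float
    ci_lower: float
    ci_upper: float
    p_value: float
    random_intercept_var: float
    n_used: int
    n_available: int
    method: str  # "mixed" | "fixed"


def fit_habitat_model(design: pd.DataFrame, habitat: str,
                      ci_level: float = 0.95,
                      method: str = "mixed") -> SelectionResult:
    """Selection coefficient for one habitat from the used/available table.

    ``method="mixed"`` fits the random-intercept logistic by adaptive
    quadrature ML; ``method="fixed"`` fits plain logistic regression with
    cluster-robust (by animal) standard errors.
    """
    if habitat not in set(design["habitat"]):
        raise ValueError(f"habitat {habitat!r} absent from the design")
    y_all = design["used"].to_numpy(float)
    x_all = (design["habitat"] == habitat).to_numpy(float)

    # any empty cell of the 2x2 use/habitat table sends the ML estimate to
    # +/- infinity (complete or quasi-complete separation)
    for xv in (0.0, 1.0):
        for yv in (0.0, 1.0):
            if not np.any((x_all == xv) & (y_all == yv)):
                raise ValueError(
                    f"separation for habitat {habitat!r}: no points with "
                    f"used={int(yv)} in stratum in_habitat={int(xv)}; "
                    "consider a penalized fit"
                )

    n_used = int(design["used"].sum())
    n_avail = int((1 - design["used"]).sum())
    z = stats.norm.ppf(0.5 + ci_level / 2.0)

    if method == "fixed":
        X = sm.add_constant(x_all)
        codes = design["animal_id"].astype("category").cat.codes.to_numpy()
        rob = sm.Logit(y_all, X).fit(
            disp=0, cov_type="cluster", cov_kwds={"groups": codes})
        beta = float(rob.params[1])
        se = float(rob.bse[1])
        p = float(2 * stats.norm.sf(abs(beta / se)))
        return SelectionResult(habitat, beta, beta - z * se, beta + z * se,
                               p, 0.0, n_used, n_avail, "fixed")

    groups = [
        (g["used"].to_numpy(float),
         (g["habitat"] == habitat).to_numpy(float))
        for _, g in design.groupby("animal_id", sort=True)
    ]
    if len(groups) < 2:
        raise ValueError("need at least 2 animals for the mixed model")

    # warm start from the fixed-effects fit
    res0 = sm.Logit(y_all, sm.add_constant(x_all)).fit(disp=0)
    x0 = np.array([res0.params[0], res0.params[1], math.log(0.3)])
    opt = optimize.minimize(
        _mixed_logit_negll, x0, args=(groups,), method="L-BFGS-B",
        bounds=[(None, None), (None, None), (math.log(1e-6), math.log(50))])
    beta0, beta, log_sigma = opt.x
    sigma2 = math.exp(2 * log_sigma)

    at_boundary = math.exp(log_sigma) <= 1e-3
    if at_boundary:
        # variance pinned at zero: Wald SEs from the plain logistic fit
        se = float(res0.bse[1])
        beta = float(res0.params[1])
        sigma2 = 0.0
    else:
        hess = _numeric_hessian(lambda th: _mixed_logit_negll(th, groups),
                                opt.x)
        try:
            cov = np.linalg.inv(hess)
            se = float(math.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:  # pragma: no cover
            se = float("nan")
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else float("nan")
    return SelectionResult(habitat, float(beta), beta - z * se,
                           beta + z * se, p, sigma2, n_used, n_avail,
                           "mixed")


# ---------------------------------------------------------------------------
# Full RSF driver
# ---------------------------------------------------------------------------

def use_availability_proportions(design: pd.DataFrame) -> pd.DataFrame:
    """Habitat composition of used vs available points (per scale)."""
    rows = []
    for (scale, used), g in design.groupby(["scale", "used"], sort=True):
        frac = g["habitat"].value_counts(normalize=True)
        for hab, f in frac.items():
            rows.append({"scale": scale,
                         "set": "used" if used else "available",
                         "habitat": hab, "proportion": float(f)})
    return pd.DataFrame(rows)


def run_rsf(fixes: pd.DataFrame, homes: dict[str, tuple[float, float]],
            mcp_polygons: dict[str, object], landscape: Landscape,
            config: RunConfig, seed: int,
            method: str = "mixed") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Both-scale RSF: per-habitat selection coefficients plus the
    used/available habitat-proportion summary."""
    boundaries_owner = {
        a: Point(x, y).buffer(config.owner_buffer_radius, quad_segs=64)
        for a, (x, y) in homes.items()
    }
    designs = []
    for scale, bnds in (("owner_buffer", boundaries_owner),
                        ("mcp", mcp_polygons)):
        d = build_design(fixes, bnds, landscape, config.avail_ratio,
                         seed=seed + (0 if scale == "mcp" else 1),
                         scale=scale)
        if not d.empty:
            designs.append(d)
    design = pd.concat(designs, ignore_index=True)

    habitats = [c for c in landscape.categories
                if c not in EXCLUDED_CATEGORIES
                and c in set(design["habitat"])]
    rows = []
    for scale, d in design.groupby("scale", sort=True):
        for hab in habitats:
            if hab not in set(d["habitat"]):
                continue
            try:
                r = fit_habitat_model(d, hab, config.ci_level_rsf, method)
            except ValueError as err:
                logger.warning("scale %s habitat %s: %s", scale, hab, err)
                continue
            rows.append({"scale": scale, "habitat": hab, "beta": r.beta,
                         "ci_lo": r.ci_lower, "ci_hi": r.ci_upper,
                         "p": r.p_value, "ranef_var": r.random_intercept_var,
                         "n_used": r.n_used, "n_avail": r.n_available})
    return pd.DataFrame(rows), use_availability_proportions(design)
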