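"""Permutation mixed-model differential-abundance scan for paired regions.

Per OTU, read counts are Box-Cox transformed and modelled with a Gaussian
random-intercept linear mixed model:

    boxcox(count + 1) - boxcox(depth) ~ intercept + region + (1 | individual)

where the Box-Cox-transformed sample depth enters as an offset (coefficient
fixed at 1, i.e. moved to the response).  The test statistic is the change in
ML deviance when the region term is removed.  Because the transformed counts
are far from Gaussian, significance comes from a permutation null: the
per-sample (count, depth) pairs are jointly reshuffled across samples while
the design (region, individual) stays fixed, and both models are refitted for
every permutation.  Storey q-values control the false discovery rate across
the scanned OTU set; an OTU is called significant when both its permutation
p-value and its q-value fall below 0.05.

The mixed model is fitted by maximum likelihood with the fixed effects and
the residual variance profiled out, leaving a one-dimensional optimisation in
the variance ratio lambda = var_individual / var_residual.  The profile
likelihood is evaluated with grouped sums, vectorised across many response
vectors at once so that a 10^4-permutation null costs a few hundred
vectorised likelihood evaluations rather than 10^4 separate model fits.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .core_tables import CountTable, SampleMetadata, TaxonomyTable

_LOG2PI = math.log(2.0 * math.pi)
_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0

__all__ = [
    "BoxCoxFit", "boxcox_fit", "boxcox_transform",
    "LmeFit", "lme_fit_ml",
    "OtuPermutationResult", "otu_permutation_pvalue",
    "estimate_pi0", "storey_qvalue",
    "diff_abundance_scan", "heatmap_support",
]


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxCoxFit:
    """Profile-likelihood Box-Cox estimate; ``lambda_ = 0`` is the log branch."""

    lambda_: float
    shift: float
    loglik: float

    def transform(self, y) -> np.ndarray:
        return boxcox_transform(np.asarray(y, dtype=float) + self.shift,
                                self.lambda_)


def boxcox_transform(y, lambda_: float) -> np.ndarray:
    """(y^lambda - 1)/lambda, continuously extended to ln(y) at lambda = 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox transform requires strictly positive values")
    if abs(lambda_) < 1e-12:
        return np.log(y)
    return (np.power(y, lambda_) - 1.0) / lambda_


def _boxcox_profile_loglik(y: np.ndarray, lambda_: float) -> float:
    z = boxcox_transform(y, lambda_)
    var = z.var()
    if var <= 0:
        return -np.inf
    n = y.size
    return -0.5 * n * math.log(var) + (lambda_ - 1.0) * np.log(y).sum()


def boxcox_fit(y, shift: float = 0.0, bounds=(-2.0, 2.0)) -> BoxCoxFit:
    """Choose lambda on `bounds` maximising the Gaussian profile likelihood.

    `shift` is added to `y` before the transform (used to admit zero counts).
    """
    y = np.asarray(y, dtype=float) + float(shift)
    if y.size < 2:
        raise ValueError("need at least two observations to fit lambda")
    if np.any(y <= 0):
        raise ValueError("non-positive values remain after the shift; "
                         "increase `shift`")
    if np.ptp(y) == 0:
        # degenerate constant input: transform choice is immaterial
        return BoxCoxFit(1.0, float(shift), -np.inf)
    res = optimize.minimize_scalar(
        lambda lam: -_boxcox_profile_loglik(y, lam),
        bounds=bounds, method="bounded", options={"xatol": 1e-6})
    return BoxCoxFit(float(res.x), float(shift),
                     float(-res.fun))


# ---------------------------------------------------------------------------
# random-intercept ML fitting (profiled, vectorised)
# ---------------------------------------------------------------------------


class _Design:
    """Grouping structure for one random intercept: contiguous-group order."""

    def __init__(self, individual):
        individual = np.asarray(individual)
        _, codes = np.unique(individual, return_inverse=True)
        self.order = np.argsort(codes, kind="stable")
        sorted_codes = codes[self.order]
        self.starts = np.flatnonzero(np.r_[True, np.diff(sorted_codes) != 0])
        self.sizes = np.diff(np.r_[self.starts, codes.size]).astype(float)
        self.n = int(codes.size)
        self.n_groups = int(self.sizes.size)


class _Workspace:
    """Profile-likelihood evaluations for Y (n x m) given fixed X (n x p).

    Supports p = 1 (intercept only) and p = 2 (intercept + one contrast).
    All quantities are grouped sums, so a likelihood evaluation is O(G*m).
    """

    def __init__(self, X: np.ndarray, design: _Design, Y: np.ndarray):
        if X.ndim != 2 or X.shape[1] not in (1, 2):
            raise ValueError("X must be n x 1 or n x 2")
        self.design = design
        Xo = X[design.order]
        Yo = Y[design.order]
        self.p = X.shape[1]
        self.m = Y.shape[1]
        self.XtX = Xo.T @ Xo
        self.XtY = Xo.T @ Yo                      # (p, m)
        self.yty = np.einsum("ij,ij->j", Yo, Yo)  # (m,)
        self.Sx = np.add.reduceat(Xo, design.starts, axis=0)  # (G, p)
        self.Sy = np.add.reduceat(Yo, design.starts, axis=0)  # (G, m)

    def loglik(self, lams):
        """Profile log-likelihood at per-column variance ratios `lams` (m,).

        Returns (loglik, beta, sigma2_resid), each per column.
        """
        d = self.design
        lams = np.broadcast_to(np.asarray(lams, dtype=float), (self.m,))
        nl = d.sizes[:, None] * lams[None, :]          # (G, m)
        A = lams[None, :] / (1.0 + nl)                 # (G, m)
        logdet = np.log1p(nl).sum(axis=0)              # (m,)
        ytWy = self.yty - np.einsum("gm,gm,gm->m", self.Sy, self.Sy, A)
        if self.p == 1:
            sx = self.Sx[:, 0]
            M11 = self.XtX[0, 0] - (sx ** 2) @ A
            v1 = self.XtY[0] - np.einsum("g,gm,gm->m", sx, self.Sy, A)
            beta1 = v1 / M11
            rss = ytWy - beta1 * v1
            beta = beta1[None, :]
        else:
            sx1, sx2 = self.Sx[:, 0], self.Sx[:, 1]
            M11 = self.XtX[0, 0] - (sx1 ** 2) @ A
            M22 = self.XtX[1, 1] - (sx2 ** 2) @ A
            M12 = self.XtX[0, 1] - (sx1 * sx2) @ A
            v1 = self.XtY[0] - np.einsum("g,gm,gm->m", sx1, self.Sy, A)
            v2 = self.XtY[1] - np.einsum("g,gm,gm->m", sx2, self.Sy, A)
            det = M11 * M22 - M12 ** 2
            beta1 = (M22 * v1 - M12 * v2) / det
            beta2 = (M11 * v2 - M12 * v1) / det
            rss = ytWy - beta1 * v1 - beta2 * v2
            beta = np.vstack([beta1, beta2])
        rss = np.maximum(rss, 1e-300)
        s2 = rss / d.n
        ll = -0.5 * d.n * (_LOG2PI + 1.0 + np.log(s2)) - 0.5 * logdet
        return ll, beta, s2


#: log-lambda grid bracketing the optimum before golden-section refinement
_T_GRID = np.linspace(-12.0, 8.0, 21)
_GOLDEN_ITERS = 48


def _fit_workspace(ws: _Workspace):
    """Maximise the profile likelihood per column.

    Coarse grid on log(lambda), golden-section refinement, and an explicit
    boundary evaluation at lambda = 0 (no between-individual variance).
    Returns a dict of per-column arrays.
    """
    m = ws.m
    grid_ll = np.empty((_T_GRID.size, m))
    for k, t in enumerate(_T_GRID):
        grid_ll[k], _, _ = ws.loglik(np.full(m, math.exp(t)))
    best = np.argmax(grid_ll, axis=0)
    lo = _T_GRID[np.maximum(best - 1, 0)]
    hi = _T_GRID[np.minimum(best + 1, _T_GRID.size - 1)]
    a, b = lo.copy(), hi.copy()
    for _ in range(_GOLDEN_ITERS):
        x1 = b - _INVPHI * (b - a)
        x2 = a + _INVPHI * (b - a)
        f1, _, _ = ws.loglik(np.exp(x1))
        f2, _, _ = ws.loglik(np.exp(x2))
        take_right = f1 < f2
        a = np.where(take_right, x1, a)
        b = np.where(take_right, b, x2)
    lam = np.exp(0.5 * (a + b))
    ll, beta, s2 = ws.loglik(lam)
    ll0, beta0, s20 = ws.loglik(np.zeros(m))
    use0 = ll0 >= ll
    lam = np.where(use0, 0.0, lam)
    ll = np.where(use0, ll0, ll)
    s2 = np.where(use0, s20, s2)
    beta = np.where(use0[None, :], beta0, beta)
    return {"loglik": ll, "lambda_ratio": lam, "beta": beta,
            "var_residual": s2, "var_individual": lam * s2,
            "deviance": -2.0 * ll}


@dataclass(frozen=True)
class LmeFit:
    """Maximum-likelihood random-intercept fit (one grouping factor).

    ``fixed_effects`` maps term names to estimates; ``deviance`` is
    ``-2 * loglik``.  Fitted by ML, not REML, so deviances of nested
    fixed-effect structures are directly comparable.
    """

    fixed_effects: dict
    var_individual: float
    var_residual: float
    loglik: float
    deviance: float
    n_obs: int
    n_groups: int


def _region_design(region) -> tuple:
    region = np.asarray(region, dtype=str)
    levels = sorted(set(region))
    if len(levels) != 2:
        raise ValueError(f"region must have exactly 2 levels, got {levels}")
    x = (region == levels[1]).astype(float)
    return x, levels


def lme_fit_ml(y, region=None, individual=None, offset=None) -> LmeFit:
    """Fit ``y - offset ~ 1 (+ region) + (1 | individual)`` by ML.

    `region`, when given, is a two-level factor; the reported coefficient is
    the effect of the alphabetically second level (for oral/faecal labels:
    the oral excess).  `offset` enters with coefficient fixed at 1.  With a
    single individual the fit collapses to ordinary least squares with zero
    between-individual variance.
    """
    y = np.asarray(y, dtype=float).copy()
    if individual is None:
        raise ValueError("individual labels are required")
    if offset is not None:
        offset = np.asarray(offset, dtype=float)
        if offset.shape != y.shape:
            raise ValueError("offset must align with y")
        y = y - offset
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    design = _Design(individual)
    if y.size != design.n:
        raise ValueError("y and individual must align")
    names = ["intercept"]
    X = np.ones((y.size, 1))
    if region is not None:
        x, levels = _region_design(region)
        X = np.column_stack([X, x])
        names.append(f"region[{levels[1]}]")
    ws = _Workspace(X, design, y[:, None])
    fit = _fit_workspace(ws)
    fixed = {nm: float(fit["beta"][k, 0]) for k, nm in enumerate(names)}
    return LmeFit(fixed_effects=fixed,
                  var_individual=float(fit["var_individual"][0]),
                  var_residual=float(fit["var_residual"][0]),
                  loglik=float(fit["loglik"][0]),
                  deviance=float(fit["deviance"][0]),
                  n_obs=int(design.n), n_groups=int(design.n_groups))


# ---------------------------------------------------------------------------
# per-OTU permutation test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OtuPermutationResult:
    deviance_change: float
    p: float
    region_effect: float
    lambda_response: float
    lambda_offset: float
    n_perm: int
    degenerate: bool = False


def otu_permutation_pvalue(otu_counts, totals, region, individual,
                           n_perm: int = 10_000, seed=None,
                           shift: float = 1.0, shared_lambda: bool = True,
                           resample: str = "permute") -> OtuPermutationResult:
    """Deviance-change permutation test for one OTU's region effect.

    The observed statistic is deviance(model without region) minus
    deviance(full model), both fitted by ML on Box-Cox(count + shift) with
    Box-Cox(depth) as an offset.  The null distribution jointly reshuffles
    the per-sample (count, depth) pairs across samples -- preserving the
    count/depth coupling that the offset encodes while breaking any region
    association -- and refits both models per draw.  ``resample="bootstrap"``
    resamples pairs with replacement instead.

    By default one Box-Cox lambda -- profiled on the OTU's counts -- is used
    for both the response and the depth offset, keeping the two terms on a
    common transformed scale (an offset whose coefficient is fixed at 1 is
    only meaningful on the response's own scale; a separately estimated
    depth lambda is noisy at survey sample sizes and acts as an arbitrary
    depth covariate).  ``shared_lambda=False`` profiles the offset lambda
    separately on the depths.

    p = (1 + #{dd_null >= dd_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if resample not in ("permute", "bootstrap"):
        raise ValueError("resample must be 'permute' or 'bootstrap'")
    counts = np.asarray(otu_counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if counts.shape != totals.shape:
        raise ValueError("otu_counts and totals must align")
    bc_y = boxcox_fit(counts, shift=shift)
    if shared_lambda:
        bc_o = BoxCoxFit(bc_y.lambda_, 0.0, math.nan)
    else:
        bc_o = boxcox_fit(totals, shift=0.0)  # noisy at small n; see docstring
    z = bc_y.transform(counts) - bc_o.transform(totals)
    x, levels = _region_design(region)
    design = _Design(individual)
    if np.ptp(z) < 1e-12:
        warnings.warn("constant response after transform; returning "
                      "deviance change 0, p = 1", RuntimeWarning,
                      stacklevel=2)
        return OtuPermutationResult(0.0, 1.0, 0.0, bc_y.lambda_,
                                    bc_o.lambda_, n_perm, degenerate=True)
    X_full = np.column_stack([np.ones(z.size), x])
    X_null = np.ones((z.size, 1))
    full = _fit_workspace(_Workspace(X_full, design, z[:, None]))
    null = _fit_workspace(_Workspace(X_null, design, z[:, None]))
    dd_obs = float(null["deviance"][0] - full["deviance"][0])
    if dd_obs < -1e-6:
        raise RuntimeError(f"negative deviance change {dd_obs}: optimiser "
                           "failure on nested fits")
    dd_obs = max(dd_obs, 0.0)
    rng = np.random.default_rng(seed)
    n = z.size
    if resample == "permute":
        idx = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    else:
        idx = rng.integers(0, n, size=(n_perm, n))
    Z = z[idx.T]                       # (n, n_perm): columns are null draws
    full_n = _fit_workspace(_Workspace(X_full, design, Z))
    null_n = _fit_workspace(_Workspace(X_null, design, Z))
    dd_null = np.maximum(null_n["deviance"] - full_n["deviance"], 0.0)
    exceed = int(np.count_nonzero(dd_null >= dd_obs - 1e-9))
    p = (1.0 + exceed) / (1.0 + n_perm)
    return OtuPermutationResult(dd_obs, p, float(full["beta"][1, 0]),
                                bc_y.lambda_, bc_o.lambda_, n_perm)


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------


def estimate_pi0(p, lambdas=None) -> float:
    """Estimate the null fraction pi0 from the p-value distribution.

    Uses the lambda-grid estimator pi0(l) = #{p > l} / (m (1 - l)) on
    l = 0.05, 0.10, ..., 0.95, smoothed with a cubic least-squares fit and
    evaluated at the largest lambda; falls back to the raw maximum of the
    grid when the smoother is degenerate.  The estimate is clamped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    pi0_l = np.array([(p > l).mean() / (1.0 - l) for l in lambdas])
    pi0 = math.nan
    if lambdas.size >= 4:
        try:
            coefs = np.polyfit(lambdas, pi0_l, 3)
            pi0 = float(np.polyval(coefs, lambdas[-1]))
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate grid
            pi0 = math.nan
    if not math.isfinite(pi0) or pi0 <= 0:
        pi0 = float(min(1.0, max(pi0_l.max(), 0.0)))
    pi0 = min(pi0, 1.0)
    return max(pi0, 1e-8)


def storey_qvalue(p, pi0=None) -> np.ndarray:
    """q-values: pi0-scaled step-up FDR adjustment, monotone in p.

    With ``pi0=1`` this reduces exactly to Benjamini-Hochberg adjusted
    p-values.  Input p-values must lie in (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(pi0 * q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------


def diff_abundance_scan(table: CountTable, meta: SampleMetadata,
                        n_perm: int = 10_000, seed: int = 0,
                        tax: TaxonomyTable = None, totals=None,
                        shift: float = 1.0, alpha: float = 0.05,
                        resample: str = "permute") -> pd.DataFrame:
    """Run the per-OTU permutation test across a (prevalence-filtered) table.

    `totals` defaults to the table's own sample sums; pass the pre-filtering
    depths to keep the offset faithful to the sequencing effort.  Per-OTU
    failures are recorded in the ``error`` column and the scan continues.

    Returns a data frame with one row per OTU: deviance change, permutation
    p, Storey q, direction (``+oral`` / ``+faecal`` from the sign of the
    fitted region contrast) and the joint ``significant`` flag
    (p < alpha and q < alpha).
    """
    region = meta.region_of(table.sample_ids)
    individual = meta.individual_of(table.sample_ids)
    if totals is None:
        totals = table.sample_sums().astype(float)
    else:
        totals = np.asarray(totals, dtype=float)
        if totals.size != table.n_samples:
            raise ValueError("totals must align with the table's samples")
    # per-OTU stream keyed on the OTU id so results do not depend on the
    # column order of the input table
    seeds = [int(np.random.SeedSequence(
        [int(seed), zlib.crc32(otu.encode())]).generate_state(1)[0] % (2 ** 31))
        for otu in table.otu_ids]
    rows = []
    for j, otu in enumerate(table.otu_ids):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = otu_permutation_pvalue(
                    table.counts[:, j], totals, region, individual,
                    n_perm=n_perm, seed=seeds[j], shift=shift,
                    resample=resample)
            rows.append({"otu_id": otu, "deviance_change": res.deviance_change,
                         "p_perm": res.p, "region_effect": res.region_effect,
                         "lambda_response": res.lambda_response,
                         "lambda_offset": res.lambda_offset, "error": ""})
        except Exception as exc:  # record and continue
            rows.append({"otu_id": otu, "deviance_change": np.nan,
                         "p_perm": np.nan, "region_effect": np.nan,
                         "lambda_response": np.nan, "lambda_offset": np.nan,
                         "error": f"{type(exc).__name__}: {exc}"})
    out = pd.DataFrame(rows)
    ok = out["p_perm"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = storey_qvalue(out.loc[ok, "p_perm"].to_numpy())
    out["q"] = q
    out["direction"] = np.where(out["region_effect"] > 0, "+oral", "+faecal")
    out.loc[~ok, "direction"] = ""
    out["significant"] = ok & (out["p_perm"] < alpha) & (out["q"] < alpha)
    if tax is not None:
        out["taxonomy"] = [tax.lineage(o) if o in tax.df.index else ""
                           for o in out["otu_id"]]
    return out


def heatmap_support(table: CountTable, scan: pd.DataFrame, tree):
    """log10-scaled abundances of significant OTUs in phylogeny leaf order.

    Returns ``(frame, newick)``: a data frame with significant OTUs as rows
    (ordered by the sheared tree's leaf order) holding log10(count + 1), and
    the newick string of the sheared subtree.  With fewer than two
    significant OTUs the subtree is empty and table order is kept.
    """
    sig = list(scan.loc[scan["significant"], "otu_id"])
    if not sig:
        return (pd.DataFrame(columns=list(table.sample_ids)), "")
    if tree is not None and len(sig) >= 2:
        sub = tree.shear(sig)
        order = [n for n in sub.leaf_names() if n in set(sig)]
        newick = sub.to_newick()
    else:
        order, newick = sig, ""
    sub_table = table.select_otus(order)
    frame = pd.DataFrame(np.log10(sub_table.counts.T + 1.0), index=order,
                         columns=list(table.sample_ids))
    frame.index.name = "otu_id"
    return frame, newick
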