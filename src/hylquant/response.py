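"""Iron dose-response modelling and lysyl-hydroxylase knockout attribution.

Hydroxylation of lysine by PLOD enzymes requires Fe2+ as catalytic cofactor,
so the cumulative modification level of product from cultures run at graded
iron supplementation follows a one-site saturating (Emax) curve

    y(C) = b + (1 - b) * C / (EC50 + C)

on per-peptide max-normalized responses. The baseline b is kept free: even
at 0 µM added iron the inoculum carries residual iron from the precursor
culture, so the response does not start at zero. A free Hill slope is
available behind a flag but is not the default (no cooperativity is assumed
for a cofactor titration).

Knockout attribution fits an additive linear model of observed modification
level on the three PLOD knockout indicators (or continuous KO scores);
each isoenzyme's contribution share is its fitted reduction relative to the
summed reductions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponsePanel",
    "DoseResponseFit",
    "KOPanel",
    "ContributionEstimate",
    "normalize_panel",
    "fit_ec50",
    "plod_contribution",
    "emax",
]

PLOD_COLUMNS = ["ko_plod1", "ko_plod2", "ko_plod3"]


@dataclass
class DoseResponsePanel:
    """Iron titration panel for one peptide: concentrations (µM) and
    observed Hyl levels per replicate."""

    concentrations: np.ndarray
    responses: np.ndarray  # same length; replicates appear as repeated concs
    peptide_id: str = "K350"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")

    @property
    def n_distinct(self) -> int:
        return len(np.unique(self.concentrations))

    def mean_by_concentration(self) -> tuple[np.ndarray, np.ndarray]:
        concs = np.unique(self.concentrations)
        means = np.array(
            [self.responses[self.concentrations == c].mean() for c in concs]
        )
        return concs, means


@dataclass
class DoseResponseFit:
    ec50: float
    baseline: float
    top: float
    ci95: tuple[float, float]
    residual_sse: float
    hill: float = 1.0
    peptide_id: str = ""


def emax(c, ec50, baseline, hill=1.0):
    """Saturating one-site response with free baseline, top fixed at 1."""
    c = np.asarray(c, dtype=float)
    ch = np.power(c, hill, where=c > 0, out=np.zeros_like(c))
    return baseline + (1.0 - baseline) * ch / (ec50**hill + ch)


def normalize_panel(panel: DoseResponsePanel) -> DoseResponsePanel:
    """Scale responses by the maximum per-concentration mean (per peptide).

    Idempotent on already-normalized panels whose max mean is 1.
    """
    _, means = panel.mean_by_concentration()
    top = means.max()
    if top <= 0:
        raise ValueError("cannot normalize: all responses are zero")
    return DoseResponsePanel(
        concentrations=panel.concentrations.copy(),
        responses=panel.responses / top,
        peptide_id=panel.peptide_id,
        normalized=True,
    )


def _profile_ec50_many(
    c: np.ndarray, Y: np.ndarray, cmax: float, n_grid: int = 160
) -> np.ndarray:
    """Least-squares EC50 for many response vectors at once (hill = 1).

    The baseline enters the model linearly (y = b(1-u) + u with
    u = C/(EC50+C)), so for each candidate EC50 the optimal b has a closed
    form and the problem reduces to a 1-D profile minimized on a log grid
    with parabolic refinement. Used for the bootstrap, where thousands of
    refits are needed.
    """
    grid = np.geomspace(cmax * 1e-3, cmax * 10, n_grid)
    U = c[None, :] / (grid[:, None] + c[None, :])  # (G, P)
    V = 1.0 - U
    vv = np.sum(V * V, axis=1)
    uv = np.sum(U * V, axis=1)
    uu = np.sum(U * U, axis=1)
    YV = Y @ V.T  # (B, G)
    YU = Y @ U.T
    yy = np.sum(Y * Y, axis=1)
    b = np.clip((YV - uv[None, :]) / vv[None, :], 0.0, 1.0)
    cross = YV - uv[None, :]  # sum over points of (y - u) * v
    sse = (yy[:, None] - 2 * YU + uu[None, :]) - 2 * b * cross + b * b * vv[None, :]
    k = np.argmin(sse, axis=1)
    est = grid[k].astype(float)
    # parabolic refinement in log(EC50) where the minimum is interior
    interior = (k > 0) & (k < n_grid - 1)
    ki = k[interior]
    rows = np.nonzero(interior)[0]
    s0, s1, s2 = (sse[rows, ki - 1], sse[rows, ki], sse[rows, ki + 1])
    denom = s0 - 2 * s1 + s2
    shift = np.where(denom > 0, 0.5 * (s0 - s2) / np.maximum(denom, 1e-300), 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    step = np.log(grid[1] / grid[0])
    est[rows] = np.exp(np.log(grid[ki]) + shift * step)
    return est


def fit_ec50(
    panel: DoseResponsePanel,
    free_hill: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> DoseResponseFit:
    """Non-linear least-squares Emax fit with parametric-bootstrap 95% CI.

    The panel should be normalized (top fixed at 1). The CI resamples
    Gaussian residual noise around the fitted curve, refits, and takes the
    2.5/97.5 percentiles of the bootstrap EC50 distribution.
    """
    if not panel.normalized:
        panel = normalize_panel(panel)
    if panel.n_distinct < 4:
        raise ValueError("need at least 4 distinct concentrations")
    c, y = panel.concentrations, panel.responses
    cmax = c.max()

    def _fit(cc, yy):
        if free_hill:
            popt, _ = curve_fit(
                lambda x, e, b, h: emax(x, e, b, h),
                cc, yy,
                p0=[np.median(cc[cc > 0]), max(yy.min(), 0.0), 1.0],
                bounds=([1e-9, 0.0, 0.1], [10 * cmax, 1.0, 10.0]),
                maxfev=20000, xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            return popt[0], popt[1], popt[2]
        popt, _ = curve_fit(
            lambda x, e, b: emax(x, e, b),
            cc, yy,
            p0=[np.median(cc[cc > 0]), max(yy.min(), 0.0)],
            bounds=([1e-9, 0.0], [10 * cmax, 1.0]),
            maxfev=20000, xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        return popt[0], popt[1], 1.0

    try:
        ec50, b, hill = _fit(c, y)
    except RuntimeError as e:
        raise RuntimeError(f"EC50 fit failed: {e}") from e
    if not (0 < ec50 < 10 * cmax):
        raise RuntimeError(
            f"EC50 fit failed: estimate {ec50:.3g} µM outside (0, {10 * cmax:g})"
        )
    yhat = emax(c, ec50, b, hill)
    resid = y - yhat
    sse = float(np.sum(resid**2))

    rng = np.random.default_rng(seed)
    dof = max(len(y) - (3 if free_hill else 2), 1)
    sigma = np.sqrt(sse / dof)
    if sigma > 0 and n_boot > 0:
        # scale each replicate's noise by a chi-square draw so the CI also
        # carries the uncertainty of the residual-variance estimate
        scale = sigma * np.sqrt(dof / rng.chisquare(dof, size=n_boot))
        Y_star = yhat[None, :] + scale[:, None] * rng.normal(
            0.0, 1.0, size=(n_boot, len(y))
        )
        if free_hill:
            boots = []
            for y_star in Y_star:
                try:
                    e_star, _, _ = _fit(c, y_star)
                except RuntimeError:
                    continue
                boots.append(e_star)
            boots = np.asarray(boots)
        else:
            boots = _profile_ec50_many(c, Y_star, cmax)
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:  # noiseless data: bootstrap degenerates to the point estimate
        lo = hi = ec50
    lo, hi = min(lo, ec50), max(hi, ec50)
    return DoseResponseFit(
        ec50=float(ec50),
        baseline=float(b),
        top=1.0,
        ci95=(float(lo), float(hi)),
        residual_sse=sse,
        hill=float(hill),
        peptide_id=panel.peptide_id,
    )


@dataclass
class KOPanel:
    """Observed Hyl levels under combinations of PLOD1/2/3 knockouts.

    Indicators may be binary (0/1) or continuous KO scores in [0, 1]; the
    wild type (0, 0, 0) must be among the conditions.
    """

    design: pd.DataFrame  # columns ko_plod1..3
    hyl_level: np.ndarray
    conditions: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        missing = set(PLOD_COLUMNS) - set(self.design.columns)
        if missing:
            raise ValueError(f"KO design missing columns: {sorted(missing)}")
        self.design = self.design[PLOD_COLUMNS].astype(float).reset_index(drop=True)
        self.hyl_level = np.asarray(self.hyl_level, dtype=float)
        if len(self.design) != len(self.hyl_level):
            raise ValueError("design and hyl_level must align")
        patterns = {tuple(r) for r in self.design.itertuples(index=False)}
        if len(patterns) < 4:
            raise ValueError("need at least 4 distinct KO patterns")
        if (0.0, 0.0, 0.0) not in patterns:
            raise ValueError("panel must include the wild type (0,0,0)")


@dataclass
class ContributionEstimate:
    intercept: float  # fitted wild-type level
    coefficients: dict[str, float]  # signed level change per full KO
    shares_pct: dict[str, float]  # % of total reduction, negative coefs only
    flags: list[str] = field(default_factory=list)


def plod_contribution(panel: KOPanel) -> ContributionEstimate:
    """Additive OLS attribution of Hyl reduction to the three PLOD knockouts.

    Fits hyl_level ~ 1 + ko_plod1 + ko_plod2 + ko_plod3. Each negative
    coefficient is a reduction; shares normalize the reductions to 100%.
    A positive coefficient (a KO apparently *raising* the level) is excluded
    from the shares and flagged rather than clipped silently.
    """
    X = sm.add_constant(panel.design, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = panel.design.corr().abs()
        confounded = [
            c for c in PLOD_COLUMNS
            if panel.design[c].nunique() < 2
            or any(corr.loc[c, o] > 1 - 1e-12 for o in PLOD_COLUMNS if o != c)
        ]
        raise ValueError(
            f"rank-deficient KO design (rank {rank} < {X.shape[1]}); "
            f"confounded columns: {confounded or PLOD_COLUMNS}"
        )
    fit = sm.OLS(panel.hyl_level, X).fit()
    coefs = {c: float(fit.params[c]) for c in PLOD_COLUMNS}
    flags = []
    reductions = {}
    tol = 1e-10 * max(1.0, abs(float(fit.params["const"])))
    for c, v in coefs.items():
        if v < -tol:
            reductions[c] = -v
        elif v > tol:
            flags.append(f"{c}: positive coefficient {v:.4g} excluded from shares")
    total = sum(reductions.values())
    if total <= 0:
        flags.append("no reduction attributable: all shares undefined")
        shares = {c: float("nan") for c in PLOD_COLUMNS}
    else:
        shares = {c: 100.0 * reductions.get(c, 0.0) / total for c in PLOD_COLUMNS}
    return ContributionEstimate(
        intercept=float(fit.params["const"]),
        coefficients=coefs,
        shares_pct=shares,
        flags=flags,
    )
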