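"""Seeded generators for every input the pipeline consumes.

Each generator emulates one class of real input — search-engine evidence
tables, fed-batch culture trajectories, iron titration panels, knockout
panels — and returns the table together with its generating ground truth,
so every estimator in the package can be tested as a round trip.

The central contract: at zero noise, composing a generator with the matching
estimator is the identity. The evidence generator in particular is built so
the pooled-area estimator is algebraically exact — the modified pool f·T is
split between miscleaved (blocked, probability p_block) and cleaved species,
the unmodified pool (1−f)·T by the baseline miscleavage probability p_mc;
numerator and denominator then both sum to multiples of T and the ratio
returns f regardless of the split parameters.

Default presets sit at the magnitudes typical of this problem: a hot-spot
locus fraction around 0.12 with roughly a 40/60 cleaved/miscleaved split of
the modified signal, EC50 near 6 µM over a 0-60 µM titration, a 10-day
fed-batch horizon with a day-6 dip in the newly-formed fraction, and a
knockout panel in which PLOD3 carries about half the total reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import RATE_UNIT_FACTOR, CultureTimeSeries, two_logistic_g
from .peptide_core import Modification, ProteinChain, digest
from .quant import EvidenceRecord
from .response import DoseResponsePanel, KOPanel, emax

__all__ = [
    "EvidenceSimConfig",
    "CultureSimConfig",
    "PanelSimConfig",
    "gen_evidence",
    "gen_culture",
    "gen_panels",
    "DEFAULT_CHAIN",
]

#: A compact stand-in heavy-chain fragment (synthetic, not any real antibody
#: sequence) whose numbering places the tryptic hot-spot lysine of
#: LTVLSSASTK at reported position 350, followed by the GPSVFPLAPSSK
#: continuation that forms the miscleaved species.
DEFAULT_CHAIN = ProteinChain(
    chain_id="HC-K",
    sequence="DSTYSLSSTLTLSKLTVLSSASTKGPSVFPLAPSSKADYEK",
    numbering_offset=326,
)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class EvidenceSimConfig:
    """Truth for one chain's evidence table.

    ``site_fractions`` maps reported K positions to true modified fractions;
    ``p_mc`` is the baseline miscleavage probability at unmodified sites and
    ``p_block`` the probability that the modification blocks cleavage (so the
    modified material shows up in the 1-mc species).
    """

    chain: ProteinChain = DEFAULT_CHAIN
    site_fractions: dict[int, float] = field(default_factory=lambda: {350: 0.123})
    p_mc: float = 0.05
    p_block: float = 0.6
    abundance: float = 1e6
    sigma: float = 0.0  # log-normal area noise
    seed: int = 0

    def __post_init__(self) -> None:
        for s, f in self.site_fractions.items():
            _check_prob(f"f at K{s}", f)
        _check_prob("p_mc", self.p_mc)
        _check_prob("p_block", self.p_block)
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def gen_evidence(
    config: EvidenceSimConfig,
) -> tuple[list[EvidenceRecord], dict]:
    """Evidence table for each configured locus, plus ground truth.

    Expected areas per locus with total abundance T:

        Kox 1mc = f·p_block·T      Kox 0mc = f·(1−p_block)·T
        K   1mc = (1−f)·p_mc·T     K   0mc = (1−f)·(1−p_mc)·T

    Log-normal noise (median-preserving, sigma in log space) multiplies each
    area independently when sigma > 0.
    """
    rng = np.random.default_rng(config.seed)
    chain = config.chain
    records: list[EvidenceRecord] = []
    truth = {"site_fractions": dict(config.site_fractions),
             "p_mc": config.p_mc, "p_block": config.p_block,
             "sigma": config.sigma, "chain_id": chain.chain_id}

    peptides = digest(chain, max_missed_cleavages=1)
    for site, f in sorted(config.site_fractions.items()):
        i = chain.internal_position(site)
        if not (1 <= i <= len(chain)) or chain.sequence[i - 1] != "K":
            raise ValueError(f"configured site {site} is not a K in the chain")
        spanning = [p for p in peptides if p.start <= i <= p.end]
        short = min(spanning, key=lambda p: p.missed_cleavages)
        longs = [p for p in spanning if p.missed_cleavages == 1
                 and p.start == short.start]
        long_ = longs[0] if longs else None

        T = config.abundance
        expected = {
            ("mod", 0): f * (1.0 - config.p_block) * T,
            ("mod", 1): f * config.p_block * T,
            ("unmod", 0): (1.0 - f) * (1.0 - config.p_mc) * T,
            ("unmod", 1): (1.0 - f) * config.p_mc * T,
        }
        for (state, mc), area in expected.items():
            if area <= 0:
                continue
            pep = short if mc == 0 else long_
            if pep is None:
                continue
            if config.sigma > 0:
                area = area * rng.lognormal(0.0, config.sigma)
            records.append(
                EvidenceRecord(
                    chain_id=chain.chain_id,
                    sequence=pep.sequence,
                    start=chain.reported_position(pep.start),
                    end=chain.reported_position(pep.end),
                    missed_cleavages=mc,
                    modified=(state == "mod"),
                    mod_site=site if state == "mod" else None,
                    area=float(area),
                )
            )
    return records, truth


def _logistic_vcd(t, vcd0, vcd_max, rate):
    a = (vcd_max - vcd0) / vcd0
    return vcd_max / (1.0 + a * np.exp(-rate * np.asarray(t, dtype=float)))


def _default_g(t):
    """Day-6 dip preset: 0.10 down to ~0.02 around day 6, recovering to 0.08."""
    return two_logistic_g(t, 0.10, 0.02, 0.08, 5.5, 7.0, 4.0)


@dataclass
class CultureSimConfig:
    """Truth for a fed-batch trajectory on a daily sampling grid."""

    vcd0: float = 2e6  # cells/mL at day 0
    vcd_max: float = 2e7
    growth_rate: float = 0.5  # 1/day
    qp: float | Callable = 25.0  # pg/cell/day, constant or qp(t)
    qs_iron: float | Callable = -0.4  # fmol/cell/day (negative: consumption)
    iron0: float = 60.0  # µM
    days: Sequence[float] = tuple(range(0, 11))
    g: Optional[Callable] = None  # true newly-formed fraction g(t)
    sigma_vcd: float = 0.0  # multiplicative (log-normal) noise
    sigma_conc: float = 0.0  # additive Gaussian on P and S (relative scale)
    sigma_f: float = 0.0  # additive Gaussian on F_mod
    seed: int = 0
    dt: float = 1e-3  # integration step (days)


def gen_culture(config: CultureSimConfig) -> tuple[CultureTimeSeries, dict]:
    """Integrate dP/dt = qP·X and dS/dt = qS·X from the true profiles.

    F_mod is the product-weighted cumulative average of the true newly-formed
    fraction g(t). Iron is clipped at zero (uptake stalls on depletion), with
    a warning in the truth record.
    """
    days = np.asarray(config.days, dtype=float)
    if days[0] != 0:
        raise ValueError("sampling must start at day 0")
    qp = config.qp if callable(config.qp) else (lambda t, v=config.qp: np.full_like(np.asarray(t, float), v))
    qs = config.qs_iron if callable(config.qs_iron) else (lambda t, v=config.qs_iron: np.full_like(np.asarray(t, float), v))
    g = config.g if config.g is not None else _default_g

    tt = np.arange(0.0, days[-1] + config.dt / 2, config.dt)
    x = _logistic_vcd(tt, config.vcd0, config.vcd_max, config.growth_rate)
    # concentration change per day: q (per-cell) * X (cells/mL) / unit factor
    dp = qp(tt) * x / RATE_UNIT_FACTOR
    ds = qs(tt) * x / RATE_UNIT_FACTOR

    p = np.concatenate([[0.0], np.cumsum((dp[1:] + dp[:-1]) / 2 * config.dt)])
    s = config.iron0 + np.concatenate(
        [[0.0], np.cumsum((ds[1:] + ds[:-1]) / 2 * config.dt)]
    )
    clipped = bool(np.any(s < 0))
    if clipped:
        import warnings

        warnings.warn("iron depleted before harvest; clipping at 0 (uptake stalls)")
        s = np.maximum(s, 0.0)

    gp = g(tt) * dp  # modified product formation rate
    pool = np.concatenate([[0.0], np.cumsum((gp[1:] + gp[:-1]) / 2 * config.dt)])
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(p > 0, pool / np.maximum(p, 1e-300), np.nan)

    idx = np.searchsorted(tt, days)
    rng = np.random.default_rng(config.seed)
    vcd_obs = x[idx].copy()
    p_obs = p[idx].copy()
    s_obs = s[idx].copy()
    f_obs = f[idx].copy()
    if config.sigma_vcd > 0:
        vcd_obs *= rng.lognormal(0.0, config.sigma_vcd, size=len(days))
    if config.sigma_conc > 0:
        p_obs += rng.normal(0.0, config.sigma_conc * max(p_obs.max(), 1.0), len(days))
        s_obs += rng.normal(0.0, config.sigma_conc * max(s_obs.max(), 1.0), len(days))
        # concentration assays do not report negative values
        p_obs = np.clip(p_obs, 0.0, None)
        s_obs = np.clip(s_obs, 0.0, None)
    if config.sigma_f > 0:
        f_obs += rng.normal(0.0, config.sigma_f, size=len(days))

    series = CultureTimeSeries(
        t=days, vcd=vcd_obs, product=p_obs, iron=s_obs, f_mod=f_obs
    )
    truth = {
        "vcd": x[idx],
        "product": p[idx],
        "iron": s[idx],
        "f_mod": f[idx],
        "qp": qp,
        "qs_iron": qs,
        "g": g,
        "iron_clipped": clipped,
    }
    return series, truth


@dataclass
class PanelSimConfig:
    """Truth for the iron titration and knockout panels."""

    ec50: float = 6.0  # µM
    baseline: float = 0.15  # normalized response at 0 µM added iron
    concentrations: Sequence[float] = (0.0, 5.0, 10.0, 20.0, 30.0, 40.0, 60.0)
    n_replicates: int = 3
    sigma_dose: float = 0.05
    peptide_id: str = "K350"
    top_level: float = 0.12  # un-normalized saturation Hyl fraction

    wt_level: float = 0.12
    reductions: tuple[float, float, float] = (0.028, 0.027, 0.055)
    ko_replicates: int = 3
    sigma_ko: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if not (0.0 < self.wt_level <= 1.0):
            raise ValueError("wt_level must lie in (0, 1]")
        if any(r < 0 for r in self.reductions):
            raise ValueError("reductions must be >= 0")


def gen_panels(config: PanelSimConfig) -> tuple[DoseResponsePanel, KOPanel, dict]:
    """Emax dose-response panel and additive KO panel with Gaussian noise.

    The default KO truth puts roughly half of the total reduction on PLOD3,
    the dominant isoenzyme for hot-spot hydroxylation.
    """
    rng = np.random.default_rng(config.seed)
    concs = np.repeat(np.asarray(config.concentrations, float), config.n_replicates)
    clean = emax(concs, config.ec50, config.baseline) * config.top_level
    responses = clean + rng.normal(0.0, config.sigma_dose * config.top_level, len(concs))
    responses = np.clip(responses, 0.0, None)
    dose_panel = DoseResponsePanel(
        concentrations=concs, responses=responses, peptide_id=config.peptide_id
    )

    combos = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
    rows, levels, labels = [], [], []
    for combo in combos:
        clean_level = config.wt_level - sum(
            k * r for k, r in zip(combo, config.reductions)
        )
        for _ in range(config.ko_replicates):
            rows.append(dict(zip(("ko_plod1", "ko_plod2", "ko_plod3"), combo)))
            noisy = clean_level + rng.normal(0.0, config.sigma_ko)
            levels.append(max(noisy, 0.0))
            labels.append(
                "wt" if combo == (0, 0, 0)
                else "KO-" + "".join(str(i + 1) for i, k in enumerate(combo) if k)
            )
    ko_panel = KOPanel(
        design=pd.DataFrame(rows), hyl_level=np.array(levels), conditions=labels
    )
    truth = {
        "ec50": config.ec50,
        "baseline": config.baseline,
        "top_level": config.top_level,
        "wt_level": config.wt_level,
        "reductions": dict(zip(("ko_plod1", "ko_plod2", "ko_plod3"),
                               config.reductions)),
        "plod3_share_pct": 100.0 * config.reductions[2] / sum(config.reductions)
        if sum(config.reductions) > 0 else float("nan"),
    }
    return dose_panel, ko_panel, truth
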