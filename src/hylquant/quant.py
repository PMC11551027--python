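"""Missed-cleavage-aware relative quantification of lysine hydroxylation.

The estimator pools XIC areas of the four species that carry information
about one modifiable lysine locus — modified/unmodified crossed with
correctly cleaved (0 missed cleavages) / miscleaved (1 missed cleavage):

    frac_modified = (Kox0 + Kox1) / (K0 + K1 + Kox0 + Kox1)

Summing both cleavage forms in numerator and denominator is essential
because hydroxylation suppresses tryptic cleavage: the modified material is
strongly enriched in the miscleaved species, so quantifying the correctly
cleaved peptide alone grossly underestimates site occupancy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EvidenceRecord",
    "LocusQuant",
    "ReductionResult",
    "quantify_locus",
    "locus_report",
    "reduction",
    "miscleavage_enrichment",
    "evidence_from_frame",
    "evidence_to_frame",
    "read_evidence_csv",
]

EVIDENCE_COLUMNS = [
    "chain_id",
    "sequence",
    "start",
    "end",
    "missed_cleavages",
    "modified",
    "mod_site",
    "area",
]


@dataclass(frozen=True)
class EvidenceRecord:
    """One observed peptide species from a search-engine export.

    Coordinates and ``mod_site`` are reported positions (chain numbering offset applied), so
    they compare directly against locus positions like K350.
    """

    chain_id: str
    sequence: str
    start: int
    end: int
    missed_cleavages: int
    modified: bool
    area: float
    mod_site: Optional[int] = None

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be >= 0")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.modified:
            if self.mod_site is None:
                raise ValueError("modified record requires mod_site")
            if not (self.start <= self.mod_site <= self.end):
                raise ValueError("mod_site outside peptide coordinates")

    def covers(self, site: int) -> bool:
        return self.start <= site <= self.end


@dataclass(frozen=True)
class LocusQuant:
    """Pooled areas and relative modified fraction for one lysine locus."""

    chain_id: str
    site: int
    area_K_0mc: float
    area_K_1mc: float
    area_Kox_0mc: float
    area_Kox_1mc: float

    @property
    def total_area(self) -> float:
        return self.area_K_0mc + self.area_K_1mc + self.area_Kox_0mc + self.area_Kox_1mc

    @property
    def frac_modified(self) -> float:
        return (self.area_Kox_0mc + self.area_Kox_1mc) / self.total_area

    @property
    def frac_modified_cleaved(self) -> float:
        """Modified 0-mc species share of the common denominator."""
        return self.area_Kox_0mc / self.total_area

    @property
    def frac_modified_miscleaved(self) -> float:
        return self.area_Kox_1mc / self.total_area


@dataclass(frozen=True)
class ReductionResult:
    chain_id: str
    site: int
    frac_wt: float
    frac_ko: float

    @property
    def reduction_pct(self) -> float:
        return (self.frac_wt - self.frac_ko) / self.frac_wt * 100.0

    @property
    def reduction_pct_rounded(self) -> int:
        return round(self.reduction_pct)


def _pool_areas(
    evidence: Iterable[EvidenceRecord],
    chain_id: str,
    site: int,
    strict_mc: bool = False,
) -> tuple[float, float, float, float, int]:
    """Sum areas into the four estimator buckets for one locus.

    Records with >1 missed cleavage are folded into the 1-mc bucket by
    default (the search allowed one missed cleavage, so the miscleaved term
    names every non-0mc species); ``strict_mc`` drops them instead. Evidence
    whose modification is localized to a *different* residue is excluded from
    the locus entirely — it says nothing about this site's occupancy.
    """
    k0 = k1 = kox0 = kox1 = 0.0
    n_folded = 0
    for rec in evidence:
        if rec.chain_id != chain_id or not rec.covers(site):
            continue
        if rec.modified and rec.mod_site != site:
            continue
        mc = rec.missed_cleavages
        if mc > 1:
            if strict_mc:
                continue
            n_folded += 1
            mc = 1
        if rec.modified:
            if mc == 0:
                kox0 += rec.area
            else:
                kox1 += rec.area
        else:
            if mc == 0:
                k0 += rec.area
            else:
                k1 += rec.area
    if n_folded:
        logger.warning(
            "locus %s:K%d — folded %d records with >1 missed cleavage into the "
            "1-mc bucket",
            chain_id,
            site,
            n_folded,
        )
    return k0, k1, kox0, kox1, n_folded


def quantify_locus(
    evidence: Iterable[EvidenceRecord],
    chain_id: str,
    site: int,
    strict_mc: bool = False,
) -> LocusQuant:
    """Relative modified fraction at one lysine locus from pooled XIC areas."""
    k0, k1, kox0, kox1, _ = _pool_areas(evidence, chain_id, site, strict_mc)
    total = k0 + k1 + kox0 + kox1
    if total <= 0:
        raise ValueError(
            f"locus {chain_id}:K{site} — zero total area, fraction undefined"
        )
    return LocusQuant(
        chain_id=chain_id,
        site=site,
        area_K_0mc=k0,
        area_K_1mc=k1,
        area_Kox_0mc=kox0,
        area_Kox_1mc=kox1,
    )


def miscleavage_enrichment(
    evidence: Iterable[EvidenceRecord], chain_id: str, site: int
) -> tuple[Optional[float], Optional[float]]:
    """Modified fraction computed separately within each cleavage species.

    Returns ``(frac_in_1mc, frac_in_0mc)``; a component is None when its
    species was not observed at all. With cleavage blocking by the modified
    residue the 1-mc fraction is far higher than the 0-mc fraction (the
    "ca. 99% vs ca. 5%" asymmetry).
    """
    k0, k1, kox0, kox1, _ = _pool_areas(evidence, chain_id, site)
    f1 = kox1 / (kox1 + k1) if (kox1 + k1) > 0 else None
    f0 = kox0 / (kox0 + k0) if (kox0 + k0) > 0 else None
    return f1, f0


def reduction(wt: LocusQuant, ko: LocusQuant) -> ReductionResult:
    """Percentage reduction of the modified fraction from wild type to KO."""
    if (wt.chain_id, wt.site) != (ko.chain_id, ko.site):
        raise ValueError("wt and ko quantify different loci")
    if wt.frac_modified <= 0:
        raise ValueError("reduction undefined: wild-type fraction is zero")
    return ReductionResult(
        chain_id=wt.chain_id,
        site=wt.site,
        frac_wt=wt.frac_modified,
        frac_ko=ko.frac_modified,
    )


def locus_report(
    evidence: Sequence[EvidenceRecord],
    quant_floor_pct: float = 0.1,
    strict_mc: bool = False,
) -> pd.DataFrame:
    """Per-locus report with species rows and locus sums, Table-style.

    One block per (chain, K locus with any modified evidence): a short row
    ('s', correctly cleaved), a long row ('l', miscleaved, when observed) and
    a 'sum' row. Percentages are formatted at 1 decimal place; values below
    ``quant_floor_pct`` report as '<0.1' (detection confirmed, quantity not
    reportable).
    """
    loci = sorted(
        {(r.chain_id, r.mod_site) for r in evidence if r.modified},
        key=lambda x: (x[0], x[1]),
    )
    rows = []
    for chain_id, site in loci:
        lq = quantify_locus(evidence, chain_id, site, strict_mc=strict_mc)
        has_long = (lq.area_K_1mc + lq.area_Kox_1mc) > 0

        def fmt(frac: float) -> str:
            pct = frac * 100.0
            if 0 < pct < quant_floor_pct:
                return f"<{quant_floor_pct:g}"
            return f"{pct:.1f}"

        rows.append(
            dict(
                chain_id=chain_id,
                site=site,
                cleaved="s",
                pct=fmt(lq.frac_modified_cleaved),
                value=lq.frac_modified_cleaved * 100.0,
            )
        )
        if has_long:
            rows.append(
                dict(
                    chain_id=chain_id,
                    site=site,
                    cleaved="l",
                    pct=fmt(lq.frac_modified_miscleaved),
                    value=lq.frac_modified_miscleaved * 100.0,
                )
            )
        rows.append(
            dict(
                chain_id=chain_id,
                site=site,
                cleaved="sum",
                pct=fmt(lq.frac_modified),
                value=lq.frac_modified * 100.0,
            )
        )
    return pd.DataFrame(rows, columns=["chain_id", "site", "cleaved", "pct", "value"])


def evidence_from_frame(df: pd.DataFrame) -> list[EvidenceRecord]:
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        modified = bool(int(row.modified))
        mod_site = row.mod_site
        if mod_site is None or (isinstance(mod_site, float) and math.isnan(mod_site)):
            mod_site = None
        else:
            mod_site = int(mod_site)
        records.append(
            EvidenceRecord(
                chain_id=str(row.chain_id),
                sequence=str(row.sequence),
                start=int(row.start),
                end=int(row.end),
                missed_cleavages=int(row.missed_cleavages),
                modified=modified,
                mod_site=mod_site,
                area=float(row.area),
            )
        )
    return records


def evidence_to_frame(records: Sequence[EvidenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                chain_id=r.chain_id,
                sequence=r.sequence,
                start=r.start,
                end=r.end,
                missed_cleavages=r.missed_cleavages,
                modified=int(r.modified),
                mod_site=r.mod_site if r.mod_site is not None else "",
                area=r.area,
            )
            for r in records
        ],
        columns=EVIDENCE_COLUMNS,
    )


def read_evidence_csv(path) -> list[EvidenceRecord]:
    df = pd.read_csv(path)
    df["mod_site"] = pd.to_numeric(df["mod_site"], errors="coerce")
    return evidence_from_frame(df)
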