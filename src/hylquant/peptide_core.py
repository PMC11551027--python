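"""Sequence-level machinery for tryptic peptide mapping of antibody chains.

Covers in-silico tryptic digestion (fully specific, K/R not before P) with
modification-aware missed-cleavage handling, monoisotopic peptide and b/y
fragment masses, consensus-motif scanning around modifiable lysines, and
empirical flanking-residue probability matrices.

Positions are 1-based along the chain; "reported" positions add the chain's
``numbering_offset`` so that, e.g., the C_H1 hot-spot lysine of the knob heavy
chain reports as K350 even when only a fragment of the chain is supplied.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "AMINO_ACIDS",
    "MONOISOTOPIC_RESIDUE_MASS",
    "WATER_MONO",
    "PROTON_MONO",
    "OXYGEN_MONO",
    "ProteinChain",
    "Modification",
    "PeptideSpecies",
    "FragmentIon",
    "MotifMatrix",
    "digest",
    "peptide_mass",
    "fragment_ions",
    "ppm_delta",
    "scan_motifs",
    "motif_matrix",
    "read_fasta_chains",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = set(AMINO_ACIDS) | {"X"}

# Standard monoisotopic residue masses (Da), i.e. amino acid minus water.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER_MONO = 18.010565
PROTON_MONO = 1.007276
#: Monoisotopic mass of one oxygen atom — the hydroxylation delta.
OXYGEN_MONO = 15.994915


@dataclass(frozen=True)
class ProteinChain:
    """A named amino-acid chain, possibly with 'X' placeholder residues."""

    chain_id: str
    sequence: str
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"chain {self.chain_id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"chain {self.chain_id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reported_position(self, i: int) -> int:
        """Reported position of 1-based residue index ``i``."""
        return i + self.numbering_offset

    def internal_position(self, reported: int) -> int:
        return reported - self.numbering_offset


@dataclass(frozen=True)
class Modification:
    """A fixed-site mass modification; defaults describe lysine hydroxylation.

    Hydroxylysine appears in peptide maps as "Oxidation" on K: one added
    oxygen, +15.994915 Da monoisotopic (printed as 15.9949 or 15.9950).
    """

    site: int
    name: str = "Oxidation"
    delta_mass: float = OXYGEN_MONO
    target_residue: str = "K"

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_mass) or self.delta_mass == 0.0:
            raise ValueError("delta_mass must be finite and nonzero")
        if self.site < 1:
            raise ValueError("site is 1-based and must be >= 1")


@dataclass(frozen=True)
class PeptideSpecies:
    """One peptide species from a digest: coordinates, miscleavage count, mods.

    ``missed_cleavages`` is counted on the unmodified sequence: internal K/R
    (not before P) strictly before the last residue. A hydroxylated K still
    counts as a missed site, matching how search engines label the long
    Hyl-containing species "one missed cleavage".
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    mods: frozenset[Modification] = frozenset()

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("start/end do not match sequence length")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        for m in self.mods:
            if not (self.start <= m.site <= self.end):
                raise ValueError(f"mod site {m.site} outside [{self.start},{self.end}]")

    @property
    def modified(self) -> bool:
        return bool(self.mods)

    def mod_delta_at(self, i: int) -> float:
        """Total modification delta on 1-based chain position ``i``."""
        return sum(m.delta_mass for m in self.mods if m.site == i)


@dataclass(frozen=True)
class FragmentIon:
    series: str
    index: int
    mz: float
    carries_mod: bool


@dataclass(frozen=True)
class MotifMatrix:
    """Empirical residue probabilities at positions −2..+2 around modified K."""

    probs: dict[int, dict[str, float]]
    n_sites: int
    counts: dict[int, Counter] = field(default_factory=dict, compare=False)


def _cleavage_sites(sequence: str) -> list[int]:
    """1-based positions i such that trypsin cleaves after residue i.

    Fully specific trypsin: C-terminal to K or R, except when the next
    residue is P. 'X' placeholders are never cleavage sites and do not
    suppress cleavage of a preceding K/R (X is simply unknown, treated as
    non-P for the exception).
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            sites.append(i + 1)
    return sites


def digest(
    chain: ProteinChain,
    max_missed_cleavages: int = 1,
    mods: Iterable[Modification] = (),
) -> list[PeptideSpecies]:
    """Fully specific tryptic digest with 0..max_mc missed cleavages.

    Modifications are attached to every emitted species spanning their site.
    A modified K at a cleavage site is additionally treated as a candidate
    blocked site: the 1-mc species spanning it is emitted even when
    ``max_missed_cleavages`` is 0, because hydroxylation suppresses tryptic
    cleavage and the long species is what the instrument sees.
    """
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    mods = list(mods)
    seq = chain.sequence
    for m in mods:
        if seq[m.site - 1] != m.target_residue:
            raise ValueError(
                f"residue at site {m.site} is {seq[m.site - 1]}, "
                f"expected {m.target_residue}"
            )

    sites = _cleavage_sites(seq)
    bounds = [0] + sites + [len(seq)]  # 0-based slice boundaries
    n_base = len(bounds) - 1

    def make(i: int, j: int) -> PeptideSpecies:
        """Species spanning base peptides i..j-1 (0-based)."""
        lo, hi = bounds[i], bounds[j]
        start, end = lo + 1, hi
        local = frozenset(m for m in mods if start <= m.site <= end)
        return PeptideSpecies(
            sequence=seq[lo:hi],
            start=start,
            end=end,
            missed_cleavages=j - i - 1,
            mods=local,
        )

    out: dict[tuple[int, int], PeptideSpecies] = {}
    for i in range(n_base):
        for j in range(i + 1, min(i + max_missed_cleavages + 2, n_base + 1)):
            out[(i, j)] = make(i, j)

    # Blocked-site rule: always emit the join across a modified K cleavage site.
    site_set = {m.site for m in mods if seq[m.site - 1] in "KR"}
    for k, s in enumerate(sites):
        if s in site_set and (k, k + 2) not in out:
            out[(k, k + 2)] = make(k, k + 2)

    return sorted(out.values(), key=lambda p: (p.start, p.end))


def peptide_mass(sequence: str, mods: Iterable[Modification] = ()) -> float:
    """Neutral monoisotopic mass M of a peptide: residues + water + mod deltas."""
    if "X" in sequence:
        raise ValueError("cannot compute mass of peptide containing 'X'")
    if not sequence:
        raise ValueError("empty peptide")
    try:
        m = sum(MONOISOTOPIC_RESIDUE_MASS[r] for r in sequence)
    except KeyError as e:
        raise ValueError(f"unsupported residue {e.args[0]!r}") from None
    return m + WATER_MONO + sum(mod.delta_mass for mod in mods)


def fragment_ions(peptide: PeptideSpecies, series: str) -> list[FragmentIon]:
    """Singly protonated b- or y-series of a peptide species.

    b_n = sum of first n residue masses (+ mod deltas) + proton;
    y_n = sum of last n residue masses (+ mod deltas) + water + proton.
    """
    if series not in ("b", "y"):
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    seq = peptide.sequence
    if "X" in seq:
        raise ValueError("cannot compute fragments of peptide containing 'X'")
    n = len(seq)
    ions: list[FragmentIon] = []
    running = 0.0
    carries = False
    indices = range(n) if series == "b" else range(n - 1, -1, -1)
    for count, k in enumerate(indices, start=1):
        pos = peptide.start + k  # 1-based chain position of residue k
        delta = peptide.mod_delta_at(pos)
        running += MONOISOTOPIC_RESIDUE_MASS[seq[k]] + delta
        carries = carries or (delta != 0.0)
        if count == n and series == "b":
            break  # b_n == full peptide; conventionally not reported
        mz = running + PROTON_MONO + (WATER_MONO if series == "y" else 0.0)
        ions.append(FragmentIon(series=series, index=count, mz=mz, carries_mod=carries))
    return ions


def ppm_delta(observed_mz: float, theoretical_mz: float) -> float:
    """Relative mass deviation in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical_mz must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


@dataclass(frozen=True)
class MotifSite:
    chain_id: str
    position: int  # reported numbering (offset applied)
    pattern: str
    context: str


def scan_motifs(
    chain: ProteinChain, patterns: Sequence[str] = ("XKG", "XKA", "XKS")
) -> list[MotifSite]:
    """Find lysines matching Xaa-Lys-Zaa consensus templates.

    Each pattern is a 3-residue template 'XK?': any residue, lysine, then the
    residue class of interest at +1 (G for the canonical collagen XKG motif).
    A placeholder 'X' in the chain never matches at +1 (unknown is not
    evidence of a motif).
    """
    for p in patterns:
        if len(p) != 3 or p[0] != "X" or p[1] != "K":
            raise ValueError(f"pattern {p!r} must have the form 'XK<residue>'")
    seq = chain.sequence
    hits = []
    for i, r in enumerate(seq):
        if r != "K" or i + 1 >= len(seq):
            continue
        nxt = seq[i + 1]
        if nxt == "X":
            continue
        for p in patterns:
            if nxt == p[2]:
                lo = max(0, i - 2)
                hits.append(
                    MotifSite(
                        chain_id=chain.chain_id,
                        position=chain.reported_position(i + 1),
                        pattern=p,
                        context=seq[lo : i + 3],
                    )
                )
                break
    return hits


def motif_matrix(
    modified_sites: Sequence[tuple[str, int]],
    chains: dict[str, ProteinChain],
    window: tuple[int, int] = (-2, 2),
) -> MotifMatrix:
    """Empirical flanking-residue probabilities around modified lysines.

    ``modified_sites`` are (chain_id, reported K position) pairs. Counts are
    plain frequencies (no pseudocounts); windows truncated by chain termini
    renormalize over the residues actually observed at that offset.
    """
    if not modified_sites:
        raise ValueError("no modified sites supplied")
    lo, hi = window
    counts: dict[int, Counter] = {d: Counter() for d in range(lo, hi + 1)}
    for chain_id, pos in modified_sites:
        chain = chains[chain_id]
        i = chain.internal_position(pos)  # 1-based
        if not (1 <= i <= len(chain)) or chain.sequence[i - 1] != "K":
            raise ValueError(f"site {chain_id}:{pos} is not a lysine")
        for d in range(lo, hi + 1):
            j = i + d
            if 1 <= j <= len(chain):
                counts[d][chain.sequence[j - 1]] += 1
    probs = {
        d: {r: c / total for r, c in cnt.items()}
        for d, cnt in counts.items()
        if (total := sum(cnt.values())) > 0
    }
    return MotifMatrix(probs=probs, n_sites=len(modified_sites), counts=counts)


def read_fasta_chains(path) -> dict[str, ProteinChain]:
    """Read chains from FASTA; an ``offset=<int>`` tag in the description sets
    the numbering offset (default 0)."""
    from Bio import SeqIO

    chains: dict[str, ProteinChain] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        offset = 0
        for token in rec.description.split():
            if token.startswith("offset="):
                offset = int(token.split("=", 1)[1])
        chains[rec.id] = ProteinChain(
            chain_id=rec.id, sequence=str(rec.seq).upper(), numbering_offset=offset
        )
    return chains
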