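"""Peptide chemistry for 15N metabolic-labeling proteomics.

This module implements the dual light/heavy mass model used when MS data from
a 15N pulse-chase experiment is searched twice — once assuming every nitrogen
is 14N ("light", newly synthesised protein) and once assuming every nitrogen
is 15N ("heavy", protein made during the labeling pulse). It provides

* elemental compositions and monoisotopic masses of tryptic peptides
  (carbamidomethyl-C as the only fixed modification),
* the heavy-light mass shift, which is exactly linear in nitrogen count,
* isotopologue envelopes parameterised by the 15N enrichment of the nitrogen
  pool — the quantity estimated downstream as APE (average peptide
  enrichment), and
* in-silico tryptic digestion of protein sequences.

Envelopes are aggregated isotopic distributions: peaks are indexed by total
neutron shift, each carrying the summed probability and the probability-
weighted (centroid) mass offset from the light monoisotopic mass.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from pyteomics import fasta as _fasta
from pyteomics import parser as _parser

from .constants import (
    CARBAMIDOMETHYL,
    DELTA_MASS_15N,
    ISOTOPES,
    NATURAL_15N,
    PROTON_MASS,
    RESIDUE_FORMULAS,
    WATER,
)

_ELEMENTS = ("C", "H", "N", "O", "S")


@dataclass(frozen=True)
class ElementalComposition:
    """Counts of C, H, N, O, S atoms in a molecule."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in _ELEMENTS:
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) + getattr(other, el) for el in _ELEMENTS}
        )

    @property
    def n_nitrogen(self) -> int:
        return self.N

    def monoisotopic_mass(self) -> float:
        """Mass with every atom at its principal (lightest-listed) isotope."""
        return sum(
            getattr(self, el) * ISOTOPES[el][0][1] for el in _ELEMENTS
        )


_WATER_COMP = ElementalComposition(**{"C": 0, "S": 0, "N": 0, **WATER})
_CAM_COMP = ElementalComposition(**CARBAMIDOMETHYL)


def peptide_composition(
    sequence: str, carbamidomethyl_cys: bool = True
) -> ElementalComposition:
    """Elemental composition of a peptide: residues + one water.

    With ``carbamidomethyl_cys`` every cysteine carries the fixed
    carbamidomethyl modification (+57.02146 Da).
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    comp = _WATER_COMP
    for pos, aa in enumerate(sequence):
        formula = RESIDUE_FORMULAS.get(aa)
        if formula is None:
            raise ValueError(
                f"unknown residue {aa!r} at position {pos} in {sequence!r}"
            )
        comp = comp + ElementalComposition(**formula)
        if aa == "C" and carbamidomethyl_cys:
            comp = comp + _CAM_COMP
    return comp


def heavy_mass_shift(composition: ElementalComposition) -> float:
    """Mass added when every nitrogen is 15N: n_N x (m15N - m14N)."""
    return composition.n_nitrogen * DELTA_MASS_15N


def mz_from_mass(mass: float, charge: int) -> float:
    """m/z of the [M + zH]^z+ ion. The acquisition used charges 2-6."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (mass + charge * PROTON_MASS) / charge


@dataclass(frozen=True)
class PeptideSpecies:
    """A peptide with its light (all-14N) and heavy (all-15N) mass variants."""

    sequence: str
    composition: ElementalComposition
    n_nitrogen: int
    mass_light: float
    mass_heavy: float
    fixed_mods: tuple = ()

    def mz_light(self, charge: int) -> float:
        return mz_from_mass(self.mass_light, charge)

    def mz_heavy(self, charge: int) -> float:
        return mz_from_mass(self.mass_heavy, charge)


def peptide_species(
    sequence: str,
    carbamidomethyl_cys: bool = True,
    min_length: int = 6,
) -> PeptideSpecies:
    """Build a :class:`PeptideSpecies` from a sequence.

    ``min_length`` defaults to the identification rule of a minimum of six
    residues; pass a smaller value for ad-hoc species.
    """
    if len(sequence) < min_length:
        raise ValueError(
            f"peptide {sequence!r} shorter than minimum length {min_length}"
        )
    comp = peptide_composition(sequence, carbamidomethyl_cys)
    light = comp.monoisotopic_mass()
    mods = (
        tuple(("carbamidomethyl-C", i) for i, aa in enumerate(sequence) if aa == "C")
        if carbamidomethyl_cys
        else ()
    )
    return PeptideSpecies(
        sequence=sequence,
        composition=comp,
        n_nitrogen=comp.n_nitrogen,
        mass_light=light,
        mass_heavy=light + heavy_mass_shift(comp),
        fixed_mods=mods,
    )


# ---------------------------------------------------------------------------
# isotopologue envelopes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Aggregated isotopologue envelope at a given 15N enrichment.

    ``neutron_shifts[k]`` is the total neutron shift of peak k relative to the
    light monoisotopic species; ``mass_offsets[k]`` is its centroid mass
    offset in Da and ``probabilities[k]`` its summed probability.
    """

    enrichment_15N: float
    neutron_shifts: np.ndarray
    mass_offsets: np.ndarray
    probabilities: np.ndarray

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mass_offsets.tolist(), self.probabilities.tolist()))

    def centroid(self) -> float:
        """Probability-weighted mean mass offset of the retained peaks."""
        return float(
            np.average(self.mass_offsets, weights=self.probabilities)
        )


def _conv(pa, ma, pb, mb):
    # distributions carry (probability, probability-weighted total mass)
    p = np.convolve(pa, pb)
    m = np.convolve(ma, pb) + np.convolve(pa, mb)
    return p, m


def _n_atoms_dist(isotopes, n: int):
    """(p, m) arrays over neutron shift for n i.i.d. atoms of one element."""
    max_shift = max(s for s, _, _ in isotopes)
    p1 = np.zeros(max_shift + 1)
    m1 = np.zeros(max_shift + 1)
    for shift, mass, ab in isotopes:
        p1[shift] += ab
        m1[shift] += ab * mass
    # binary exponentiation
    p, m = np.array([1.0]), np.array([0.0])
    base_p, base_m = p1, m1
    k = n
    while k:
        if k & 1:
            p, m = _conv(p, m, base_p, base_m)
        k >>= 1
        if k:
            base_p, base_m = _conv(base_p, base_m, base_p, base_m)
    return p, m


def _composition_dist(
    composition: ElementalComposition, enrichment_15N: float
):
    """Full (p, m) distribution over neutron shift for a composition."""
    p, m = np.array([1.0]), np.array([0.0])
    for el in _ELEMENTS:
        n = getattr(composition, el)
        if n == 0:
            continue
        if el == "N":
            m14, m15 = ISOTOPES["N"][0][1], ISOTOPES["N"][1][1]
            isotopes = [(0, m14, 1.0 - enrichment_15N), (1, m15, enrichment_15N)]
        else:
            isotopes = ISOTOPES[el]
        ep, em = _n_atoms_dist(isotopes, n)
        p, m = _conv(p, m, ep, em)
    return p, m


def isotope_envelope(
    composition: ElementalComposition,
    enrichment_15N: float = NATURAL_15N,
    min_retained_prob: float = 0.999,
) -> IsotopeEnvelope:
    """Isotopologue envelope with the nitrogen pool at a given 15N fraction.

    Per-element isotope distributions are convolved exactly; nitrogen's
    natural 15N probability is replaced by ``enrichment_15N``. Peaks are
    aggregated by total neutron shift, sorted by mass, and truncated to the
    smallest high-probability set retaining at least ``min_retained_prob``.
    """
    if not 0.0 <= enrichment_15N <= 1.0:
        raise ValueError(f"enrichment must lie in [0, 1], got {enrichment_15N}")
    p, m = _composition_dist(composition, enrichment_15N)
    mono = composition.monoisotopic_mass()
    keep = p > 1e-15
    shifts = np.nonzero(keep)[0]
    probs = p[keep]
    offsets = m[keep] / probs - mono
    # retain the minimal set of most-probable peaks covering min_retained_prob
    order = np.argsort(probs)[::-1]
    cum = np.cumsum(probs[order])
    n_keep = int(np.searchsorted(cum, min_retained_prob) + 1)
    n_keep = min(n_keep, len(order))
    sel = np.sort(order[:n_keep])
    return IsotopeEnvelope(
        enrichment_15N=enrichment_15N,
        neutron_shifts=shifts[sel],
        mass_offsets=offsets[sel],
        probabilities=probs[sel],
    )


def envelope_probabilities_at(
    composition: ElementalComposition,
    enrichment_15N: float,
    neutron_shifts: Sequence[int],
) -> np.ndarray:
    """Envelope probabilities evaluated at specific neutron shifts."""
    p, _ = _composition_dist(composition, enrichment_15N)
    shifts = np.asarray(neutron_shifts, dtype=int)
    out = np.zeros(len(shifts))
    ok = (shifts >= 0) & (shifts < len(p))
    out[ok] = p[shifts[ok]]
    return out


# ---------------------------------------------------------------------------
# digestion and FASTA I/O
# ---------------------------------------------------------------------------

TRYPSIN_RULE = _parser.expasy_rules["trypsin"]  # cleave after K/R, not before P


def tryptic_digest(
    protein_sequence: str,
    missed_cleavages: int = 0,
    length_range: tuple[int, int] = (6, 50),
    carbamidomethyl_cys: bool = True,
) -> list[PeptideSpecies]:
    """In-silico tryptic digest: cleave C-terminal to K/R except before P.

    Emits peptides with 0..``missed_cleavages`` missed sites, filtered to
    ``length_range`` (inclusive; default 6-50, honouring the six-residue
    identification minimum). Ordered by position, then by span length.
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    lo, hi = length_range
    seen = []
    for start, pep in _parser.icleave(
        protein_sequence, TRYPSIN_RULE, missed_cleavages=missed_cleavages
    ):
        if lo <= len(pep) <= hi:
            seen.append((start, pep))
    seen.sort()
    return [
        peptide_species(pep, carbamidomethyl_cys, min_length=1)
        for _, pep in seen
    ]


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (identifier, sequence) from a plain or gzipped FASTA file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for header, seq in _fasta.read(handle, use_index=False):
            yield header.split()[0], seq


def write_peptide_table(
    path: str | Path, records: Iterable[tuple[str, PeptideSpecies]]
) -> None:
    """TSV of digested peptides: sequence, protein, N count, light/heavy mass."""
    with open(path, "w") as fh:
        fh.write("sequence\tprotein_id\tn_nitrogen\tmass_light\tmass_heavy\n")
        for protein_id, pep in records:
            fh.write(
                f"{pep.sequence}\t{protein_id}\t{pep.n_nitrogen}\t"
                f"{pep.mass_light:.6f}\t{pep.mass_heavy:.6f}\n"
            )
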