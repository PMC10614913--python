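"""Independent brute-force oracles used to validate the fast implementations."""

from __future__ import annotations

import itertools
import math

from isopulse.constants import ISOTOPES


def _integer_compositions(n: int, k: int):
    """All ways to place n identical atoms into k isotope bins."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _integer_compositions(n - first, k - 1):
            yield (first,) + rest


def _element_combos(symbol: str, n: int, enrichment_15n: float | None):
    """(neutron shift, total mass, probability) for every isotope assignment
    of n atoms of one element, enumerated multinomially."""
    isotopes = ISOTOPES[symbol]
    if symbol == "N" and enrichment_15n is not None:
        m14, m15 = isotopes[0][1], isotopes[1][1]
        isotopes = [(0, m14, 1.0 - enrichment_15n), (1, m15, enrichment_15n)]
    out = []
    for counts in _integer_compositions(n, len(isotopes)):
        prob = math.factorial(n)
        shift = 0
        mass = 0.0
        for c, (s, m, a) in zip(counts, isotopes):
            prob = prob // math.factorial(c)
            shift += c * s
            mass += c * m
        p = float(prob)
        for c, (_, _, a) in zip(counts, isotopes):
            p *= a**c
        out.append((shift, mass, p))
    return out


def brute_force_envelope(composition, enrichment_15n: float) -> dict[int, tuple[float, float]]:
    """Exhaustive isotopologue enumeration.

    Returns {neutron shift: (probability, centroid mass offset from the light
    monoisotopic mass)} aggregated over every combination of per-element
    isotope assignments.
    """
    per_element = []
    mono = 0.0
    for el in ("C", "H", "N", "O", "S"):
        n = getattr(composition, el)
        if n == 0:
            continue
        mono += n * ISOTOPES[el][0][1]
        per_element.append(_element_combos(el, n, enrichment_15n if el == "N" else None))
    agg: dict[int, list[float]] = {}
    for parts in itertools.product(*per_element):
        shift = sum(p[0] for p in parts)
        mass = sum(p[1] for p in parts)
        prob = math.prod(p[2] for p in parts)
        bucket = agg.setdefault(shift, [0.0, 0.0])
        bucket[0] += prob
        bucket[1] += prob * mass
    return {
        s: (p, pm / p - mono) for s, (p, pm) in sorted(agg.items()) if p > 0.0
    }


def all_peptides(alphabet: str, max_length: int):
    for length in range(1, max_length + 1):
        for combo in itertools.product(alphabet, repeat=length):
            yield "".join(combo)
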