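"""Independent reference implementations used to check the package's fast paths.

These deliberately use different algorithms from the implementation: string
pattern enumeration instead of vectorized window comparison, direct hypergeometric
enumeration instead of the library Fisher routine.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming_ball(core: str) -> list[str]:
    """All ACGT strings within Hamming distance 1 of ``core`` (incl. core)."""
    out = {core}
    for i, base in enumerate(core):
        for alt in "ACGT":
            if alt != base:
                out.add(core[:i] + alt + core[i + 1 :])
    return sorted(out)


def count_overlapping(seq: str, pattern: str) -> int:
    """Overlapping occurrences of ``pattern`` in ``seq`` via str.find."""
    count = 0
    start = seq.find(pattern)
    while start != -1:
        count += 1
        start = seq.find(pattern, start + 1)
    return count


def brute_force_motif_counts(seq: str, core: str) -> tuple[int, int]:
    """(exact, one-mismatch) counts in both orientations by pattern enumeration.

    A window containing a non-ACGT character can equal no ACGT pattern, so the
    exclusion of ambiguous windows is automatic.
    """
    seq = seq.upper()
    exact = 0
    one_mm = 0
    for orient in (core, revcomp(core)):
        exact += count_overlapping(seq, orient)
        one_mm += sum(count_overlapping(seq, p) for p in hamming_ball(orient))
    return exact, one_mm


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric point probabilities.

    Sums P(table) over all tables with the observed margins whose point
    probability is <= that of the observed table (relative tolerance 1e-7).
    """
    N = a + b + c + d
    r1 = a + b
    c1 = a + c
    amin = max(0, c1 - (N - r1))
    amax = min(r1, c1)
    support = np.arange(amin, amax + 1)
    pmf = hypergeom.pmf(support, N, r1, c1)
    p_obs = pmf[a - amin]
    return float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())


def all_tables_with_margins_leq(limit: int) -> list[tuple[int, int, int, int]]:
    """Every 2x2 table whose four margins are all <= ``limit``."""
    out = []
    for a in range(limit + 1):
        for b in range(limit + 1 - a):
            for c in range(limit + 1 - a):
                for d in range(limit + 1 - b):
                    if c + d <= limit:
                        out.append((a, b, c, d))
    return out


def canonical_table(t: tuple[int, int, int, int]) -> tuple[int, int, int, int]:
    """Representative under row swap / column swap / transpose symmetries."""
    a, b, c, d = t
    forms = [
        (a, b, c, d), (c, d, a, b), (b, a, d, c), (d, c, b, a),
        (a, c, b, d), (b, d, a, c), (c, a, d, b), (d, b, c, a),
    ]
    return min(forms)
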