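"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the Fisher oracle
enumerates all 2x2 tables with the observed margins in exact rational
arithmetic, and the motif oracle is a lookahead regular expression.
"""

from __future__ import annotations

import re
from fractions import Fraction
from math import comb

TIE = Fraction(10**7 + 1, 10**7)  # the contract's 1e-7 relative tie band


def fisher_oracle(m_c: int, u_c: int, m_t: int, u_t: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with exact fractions."""
    M = m_c + u_c + m_t + u_t
    K = m_c + m_t          # modified-row margin
    n = m_c + u_c          # control-column margin
    denom = comb(M, n)
    tables = {}
    for k in range(max(0, K + n - M), min(K, n) + 1):
        tables[k] = Fraction(comb(K, k) * comb(M - K, n - k), denom)
    p_obs = tables[m_c]
    return float(sum(p for p in tables.values() if p <= p_obs * TIE))


_RRACH_RE = re.compile(r"(?=[AG][AG]AC[AUC])")


def rrach_positions_regex(sequence: str) -> list[int]:
    """0-based central-A offsets of RRACH 5-mers, via regex lookahead."""
    return [m.start() + 2 for m in _RRACH_RE.finditer(sequence)]
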