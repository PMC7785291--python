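"""Independent brute-force transcriptions of the enrichment statistics.

Plain-Python, loop-based re-implementations used only as test oracles; they
share no code with the package and are written directly from the formula
definitions.
"""

import math


def fc_oracle(expt, ctrl):
    """Pseudocounted log2 fold-change, one value per group."""
    se = sum(x + 1 for x in expt)
    sc = sum(x + 1 for x in ctrl)
    return [
        math.log2(((e + 1) / se) / ((c + 1) / sc)) for e, c in zip(expt, ctrl)
    ]


def z_oracle(expt, ctrl):
    """Two-proportion Z on raw frequencies; 0 on degenerate variance."""
    te, tc = sum(expt), sum(ctrl)
    out = []
    for e, c in zip(expt, ctrl):
        fe, fc = e / te, c / tc
        fcomb = (e + c) / (te + tc)
        var = fcomb * (1 - fcomb) / te + fcomb * (1 - fcomb) / tc
        out.append((fe - fc) / math.sqrt(var) if var > 0 else 0.0)
    return out


def p_oracle(z):
    """Upper-tail standard-normal p via the complementary error function."""
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def bh_oracle(pvals):
    """Benjamini–Hochberg step-up, transcribed rank by rank."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank, 1.0)
        q[i] = running
    return q
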